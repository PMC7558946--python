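"""Fit the four classifier families and predict the held-out tablets.

NTC (summed blue + three thresholds), PLS-DA (one-hot PLS2 with
venetian-blinds component selection and strict class-0 rejection), RBF
SVM on the full RGB vectors, the same SVM on the blue channel only, and
the small CNN.  One stratified 50/50 split is shared by all models;
predictions go to results/tables/.
"""

import numpy as np
import pandas as pd

from _common import CROP_DIR, DOWNSAMPLE, SEED, TABLES, TEST_FRACTION, ensure_dirs
from tabletscan import classifiers as clf
from tabletscan import features as feat
from tabletscan.cli import _load_crops
from tabletscan.pipeline import stratified_split


def main() -> None:
    ensure_dirs()
    crops = [c for c in _load_crops(CROP_DIR) if c.class_true is not None]
    table = feat.build_features(crops, factor=DOWNSAMPLE)
    y = table.y.astype(int)
    ids = table.table["tablet_id"].tolist()
    tr, te = stratified_split(y, TEST_FRACTION, seed=SEED + 1)
    print(f"train {tr.size} / test {te.size} tablets")

    preds: dict[str, np.ndarray] = {}

    ntc = clf.fit_ntc(list(zip(table.s("B")[tr], y[tr])))
    preds["ntc"] = clf.predict_ntc(ntc, table.s("B")[te])
    print(f"ntc: thresholds {tuple(round(t, 1) for t in ntc.thresholds)}, "
          f"{ntc.train_errors} training errors")

    plsda = clf.fit_plsda(table.X[tr], y[tr], cv_folds=10)
    preds["plsda"] = plsda.predict(table.X[te])
    print(f"plsda: {plsda.n_components} latent variables "
          f"(venetian-blinds CV), class 0 = not strictly predicted")

    preds["svm"] = clf.fit_svm(table.X[tr], y[tr]).predict(table.X[te])
    preds["svm_blue"] = clf.fit_svm(table.X[tr], y[tr],
                                    channel_subset="B").predict(table.X[te])

    spec = clf.CnnSpec(epochs=30, batch_size=32, n_conv_blocks=2,
                       channels_per_block=(8, 16), train_per_class=None,
                       seed=SEED + 2)
    cnn = clf.fit_cnn([table.images[i] for i in tr], y[tr], spec)
    preds["cnn"] = cnn.predict([table.images[i] for i in te])
    print(f"cnn: {spec.epochs} epochs, final training accuracy "
          f"{cnn.log[-1]['train_acc']:.3f}")

    for name, p in preds.items():
        pd.DataFrame({
            "tablet_id": [ids[i] for i in te],
            "class_true": y[te],
            "class_pred": np.asarray(p, dtype=int),
        }).to_csv(TABLES / f"predictions_{name}.csv", index=False)
    print(f"wrote predictions for {len(preds)} models")


if __name__ == "__main__":
    main()
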