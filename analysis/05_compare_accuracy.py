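"""Score every classifier on the shared held-out tablets and rank them.

Accuracy is the printed-precision statistic (half-up to one decimal);
class-0 rejections count as misclassified.  Writes per-model reports and
the ranking table under results/tables/.
"""

import pandas as pd

from _common import TABLES, ensure_dirs
from tabletscan.evaluation import accuracy, compare_models


def main() -> None:
    ensure_dirs()
    reports = []
    for p in sorted(TABLES.glob("predictions_*.csv")):
        name = p.stem.removeprefix("predictions_")
        df = pd.read_csv(p)
        rep = accuracy(df.class_pred.astype(int), df.class_true.astype(int),
                       ids=df.tablet_id.tolist(), name=name)
        rep.write_json(TABLES / f"report_{name}.json")
        reports.append(rep)

    ranking = compare_models(reports)
    ranking.to_csv(TABLES / "comparison.csv", index=False)
    print(ranking.to_string(index=False))
    best = ranking.iloc[0]
    print(f"\nbest: {best.model} at {best.accuracy_pct}% "
          f"({int(best.n_misclassified)} misclassified)")
    pls = ranking[ranking.model == "plsda"]
    if not pls.empty and pls.iloc[0].accuracy_pct < ranking.accuracy_pct.max():
        print("plsda trails the margin-based models: with flat-colored "
              "tablets the class structure is nearly one-dimensional and "
              "linear one-hot regression masks the inner classes.")


if __name__ == "__main__":
    main()
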