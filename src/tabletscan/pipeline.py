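"""Config-driven orchestration: generate -> segment -> featurize -> fit ->
evaluate.

A :class:`RunConfig` fully determines a run: sheets are either simulated
(seeded) or loaded from image files, every tablet is segmented, featurized
and split into train/test, the selected classifiers are fit on the train
half and scored on the held-out half, and every artifact (features table,
predictions, per-model report, ranking) is written under the output
directory together with a verbatim echo of the config.  Re-running the
same config and seed reproduces every report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import classifiers as clf
from . import features as feat
from . import segmentation as seg
from . import synthetic as syn
from .core import SheetImage, TabletImage
from .evaluation import EvalReport, accuracy, compare_models

__all__ = ["RunConfig", "run", "assign_true_classes", "load_sheets",
           "stratified_split"]

log = logging.getLogger("tabletscan")

CLASSIFIER_NAMES = ("ntc", "plsda", "svm", "svm_blue", "cnn")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``synthetic`` configures the sheet generator (ignored when
    ``input_glob`` is set, in which case sheets and truth CSVs are read
    from disk).  ``downsample_factor`` defaults to 50, the convention for
    full-resolution 600 dpi scans; desk-scale synthetic runs use a smaller
    factor so a tablet keeps more than one pixel.  ``classifiers`` may be
    the string ``"all"``.
    """

    seed: int = 0
    outdir: str | None = None
    input_glob: str | None = None
    synthetic: dict = field(default_factory=lambda: {
        "scale": 0.05, "preset": "default", "tablets_per_sheet": 60,
    })
    segmentation: dict = field(default_factory=lambda: {
        "border_policy": "drop", "connectivity": 8, "padding": 0,
        "min_area": None,
    })
    downsample_factor: int = 50
    downsample_mode: str = "decimate"
    test_fraction: float = 0.5
    classifiers: Sequence[str] | str = ("ntc",)
    ntc_channel: str = "B"
    plsda: dict = field(default_factory=lambda: {
        "cv_folds": 10, "rule": "unique_above_cut", "cut": 0.5,
    })
    svm: dict = field(default_factory=dict)
    cnn: dict = field(default_factory=lambda: {
        "epochs": 30, "batch_size": 32, "n_conv_blocks": 2,
        "channels_per_block": (8, 16), "train_per_class": None,
    })

    def classifier_list(self) -> list[str]:
        names = (list(CLASSIFIER_NAMES) if self.classifiers == "all"
                 else list(self.classifiers))
        unknown = set(names) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifiers {sorted(unknown)}")
        return names

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["classifiers"] = (self.classifiers if isinstance(self.classifiers, str)
                            else list(self.classifiers))
        for key in ("synthetic", "segmentation", "plsda", "svm", "cnn"):
            d[key] = {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in d[key].items()}
        return yaml.safe_dump(d, sort_keys=True)


def load_sheets(pattern: str) -> tuple[list[SheetImage], syn.GroundTruth | None]:
    """Read sheet PNG/TIFF files (and, when present, sibling truth CSVs).

    A truth CSV named ``{stem}_truth.csv`` next to each image is picked up
    automatically; without truth the pipeline can segment and featurize
    but not fit or evaluate.
    """
    import glob as _glob

    import imageio.v3 as iio

    paths = sorted(_glob.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no sheets match {pattern!r}")
    sheets: list[SheetImage] = []
    truths: list[syn.GroundTruth] = []
    have_truth = True
    for p in paths:
        p = Path(p)
        pixels = np.asarray(iio.imread(p))
        if pixels.ndim == 2:
            pixels = np.stack([pixels] * 3, axis=-1)
        sheets.append(SheetImage(pixels=pixels[..., :3].astype(np.uint8),
                                 sheet_id=p.stem, meta={"path": str(p)}))
        tcsv = p.with_name(p.stem + "_truth.csv")
        if tcsv.exists():
            df = pd.read_csv(tcsv)
            truths.append(syn.GroundTruth([
                syn.TabletTruth(p.stem, int(r.tablet_id), int(r.class_id),
                                float(r.cx), float(r.cy), float(r.rx),
                                float(r.ry), float(r.angle_deg))
                for r in df.itertuples()
            ]))
        else:
            have_truth = False
    truth = syn.GroundTruth.concat(truths) if (have_truth and truths) else None
    return sheets, truth


def assign_true_classes(
    crops: Sequence[TabletImage], truth: syn.GroundTruth
) -> list[TabletImage]:
    """Label each crop with the class of the unique truth centroid its
    bounding box contains; crops matching zero or several centroids keep
    ``class_true=None``."""
    by_sheet: dict[str, list[syn.TabletTruth]] = {}
    for r in truth:
        by_sheet.setdefault(r.sheet_id, []).append(r)
    for c in crops:
        x0, y0, x1, y1 = c.bbox
        hits = [r for r in by_sheet.get(c.sheet_id, ())
                if x0 <= r.cx <= x1 and y0 <= r.cy <= y1]
        c.class_true = hits[0].class_id if len(hits) == 1 else None
    return list(crops)


def stratified_split(
    y: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class split; returns (train_idx, test_idx), each sorted."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for k in np.unique(y):
        members = np.flatnonzero(y == k)
        members = rng.permutation(members)
        n_test = max(1, int(round(test_fraction * members.size)))
        test.append(members[:n_test])
        train.append(members[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _fit_predict(
    name: str,
    cfg: RunConfig,
    table: feat.FeatureTable,
    train: np.ndarray,
    test: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, dict]:
    """Fit one classifier on the train rows, predict the test rows."""
    y = table.y.astype(int)
    extra: dict = {}
    if name == "ntc":
        s = table.s(cfg.ntc_channel)
        model = clf.fit_ntc(list(zip(s[train], y[train])), channel=cfg.ntc_channel)
        pred = clf.predict_ntc(model, s[test])
        extra["thresholds"] = list(model.thresholds)
    elif name == "plsda":
        model = clf.fit_plsda(table.X[train], y[train], **cfg.plsda)
        pred = model.predict(table.X[test])
        extra["n_components"] = model.n_components
    elif name in ("svm", "svm_blue"):
        subset = "B" if name == "svm_blue" else None
        model = clf.fit_svm(table.X[train], y[train], channel_subset=subset,
                            **cfg.svm)
        pred = model.predict(table.X[test])
    elif name == "cnn":
        spec = clf.CnnSpec(seed=seed, **cfg.cnn)
        model = clf.fit_cnn([table.images[i] for i in train], y[train], spec=spec)
        pred = model.predict([table.images[i] for i in test])
        extra["final_train_acc"] = model.log[-1]["train_acc"] if model.log else None
    else:  # pragma: no cover - guarded by classifier_list()
        raise ValueError(name)
    return np.asarray(pred, dtype=int), extra


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return {reports, comparison, info}.

    Artifacts are written under ``config.outdir`` when set: the config
    echo, per-sheet PNGs and truth CSVs (synthetic runs), the features
    table, per-model predictions and report JSONs, and the ranking CSV.
    """
    t0 = time.perf_counter()
    out = Path(config.outdir) if config.outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.to_yaml())

    # --- generate / load ---------------------------------------------------
    if config.input_glob:
        sheets, truth = load_sheets(config.input_glob)
        radius_min = 10.0
    else:
        scfg = dict(config.synthetic)
        sheet_kwargs = scfg.pop("sheet", None)
        template = syn.SheetSpec(**sheet_kwargs) if sheet_kwargs else syn.SheetSpec()
        sheets, truth = syn.batch_fixture(seed=config.seed, sheet=template, **scfg)
        radius_min = template.tablet_radius_px[0]
        if out:
            sheet_dir = out / "sheets"
            by_sheet: dict[str, list] = {}
            for r in truth:
                by_sheet.setdefault(r.sheet_id, []).append(r)
            for s in sheets:
                syn.write_sheet(s, syn.GroundTruth(by_sheet[s.sheet_id]), sheet_dir)
    if truth is None:
        raise ValueError("cannot fit or evaluate without ground-truth labels")
    log.info("stage=generate sheets=%d tablets=%d elapsed=%.2fs",
             len(sheets), len(truth), time.perf_counter() - t0)

    # --- segment ------------------------------------------------------------
    t1 = time.perf_counter()
    min_area = config.segmentation.get("min_area") or seg.default_min_area(radius_min)
    crops: list[TabletImage] = []
    all_regions = []
    n_rejected = 0
    for s in sheets:
        regions, sheet_crops, info = seg.segment_sheet(
            s, min_area=min_area,
            border_policy=config.segmentation.get("border_policy", "drop"),
            connectivity=config.segmentation.get("connectivity", 8),
            padding=config.segmentation.get("padding", 0),
        )
        crops.extend(sheet_crops)
        all_regions.extend(regions)
        n_rejected += info["n_rejected"]
    crops = assign_true_classes(crops, truth)
    labelled = [c for c in crops if c.class_true is not None]
    if out:
        seg.write_regions_csv(all_regions, out / "regions.csv")
    log.info("stage=segment crops=%d rejected_regions=%d unlabelled=%d "
             "elapsed=%.2fs", len(crops), n_rejected, len(crops) - len(labelled),
             time.perf_counter() - t1)
    if not labelled:
        raise ValueError("segmentation produced no labelled tablets")

    # --- featurize ----------------------------------------------------------
    t2 = time.perf_counter()
    table = feat.build_features(labelled, factor=config.downsample_factor,
                                mode=config.downsample_mode)
    if out:
        table.write_csv(out / "features.csv")
    log.info("stage=featurize tablets=%d canonical=%s elapsed=%.2fs",
             len(table.table), table.size, time.perf_counter() - t2)

    # --- fit / predict / evaluate -------------------------------------------
    y = table.y.astype(int)
    ids = table.table["tablet_id"].tolist()
    train, test = stratified_split(y, config.test_fraction, seed=config.seed + 1)
    reports: dict[str, EvalReport] = {}
    details: dict[str, dict] = {}
    for name in config.classifier_list():
        t3 = time.perf_counter()
        pred, extra = _fit_predict(name, config, table, train, test,
                                   seed=config.seed + 2)
        rep = accuracy(pred, y[test], ids=[ids[i] for i in test], name=name)
        reports[name] = rep
        details[name] = extra
        if out:
            pd.DataFrame({
                "tablet_id": [ids[i] for i in test],
                "class_true": y[test],
                "class_pred": pred,
            }).to_csv(out / f"predictions_{name}.csv", index=False)
            rep.write_json(out / f"report_{name}.json")
        log.info("stage=fit model=%s accuracy=%.1f%% elapsed=%.2fs",
                 name, rep.accuracy_pct, time.perf_counter() - t3)

    comparison = compare_models(list(reports.values())) if len(reports) > 1 else None
    if out and comparison is not None:
        comparison.to_csv(out / "comparison.csv", index=False)
    if out:
        (out / "run_summary.json").write_text(json.dumps({
            "seed": config.seed,
            "n_sheets": len(sheets),
            "n_tablets_truth": len(truth),
            "n_tablets_segmented": len(crops),
            "n_rejected_regions": n_rejected,
            "n_train": int(train.size),
            "n_test": int(test.size),
            "canonical_size": list(table.size),
            "accuracies_pct": {k: r.accuracy_pct for k, r in reports.items()},
            "details": details,
        }, indent=2, default=str))
    return {
        "reports": reports,
        "comparison": comparison,
        "features": table,
        "train_idx": train,
        "test_idx": test,
        "info": {"n_rejected_regions": n_rejected,
                 "n_tablets_segmented": len(crops),
                 "n_tablets_truth": len(truth)},
    }
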