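"""Simulate scanned sheets of the four coating batches, with ground truth.

Writes the sheet rasters (PNG) and per-sheet truth CSVs under scratch/,
and the per-class tablet bookkeeping under results/tables/.
"""

import pandas as pd

from _common import SCALE, SEED, SHEET_DIR, TABLES, ensure_dirs
from tabletscan import synthetic as syn


def main() -> None:
    ensure_dirs()
    sheets, truth = syn.batch_fixture(scale=SCALE, seed=SEED, preset="default")
    by_sheet: dict[str, list] = {}
    for r in truth:
        by_sheet.setdefault(r.sheet_id, []).append(r)
    for s in sheets:
        syn.write_sheet(s, syn.GroundTruth(by_sheet[s.sheet_id]), SHEET_DIR)

    counts = truth.class_counts()
    df = pd.DataFrame(
        {"class_id": list(counts), "n_tablets": list(counts.values())}
    )
    df.to_csv(TABLES / "batch_counts.csv", index=False)
    print(f"simulated {len(sheets)} sheets, {len(truth)} tablets "
          f"(scale {SCALE} of the 623/596/595/504 reference batches)")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
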