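"""Shared paths and constants for the numbered analysis scripts.

The scripts form one narrative: simulate scanned sheets of coated tablets
(01), segment every tablet (02), extract features (03), fit the four
classifier families (04), and compare their accuracies (05).  Large or
binary intermediates (sheet PNGs, crops, feature vectors) live under
scratch/; the tables each step reports live under results/tables/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
TABLES = ROOT / "results" / "tables"

SHEET_DIR = SCRATCH / "sheets"
CROP_DIR = SCRATCH / "crops"

SEED = 20260928
SCALE = 0.1          # 232 tablets: 62/60/60/50 across the four batches
DOWNSAMPLE = 4       # ~8 px tablets post-downsampling, like factor 50 at 600 dpi
TEST_FRACTION = 0.5


def ensure_dirs() -> None:
    for p in (SHEET_DIR, CROP_DIR, TABLES):
        p.mkdir(parents=True, exist_ok=True)
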