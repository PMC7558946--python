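import numpy as np
import pytest
from hypothesis import settings

from tabletscan import segmentation as seg
from tabletscan import synthetic as syn
from tabletscan.pipeline import assign_true_classes

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def zero_noise_sheet():
    """512x384 sheet, 5 tablets per class, no scanner noise."""
    spec = syn.SheetSpec(width_px=512, height_px=384, noise_sd=0.0, seed=1)
    return syn.generate_sheet(spec, syn.default_classes(5))


@pytest.fixture(scope="session")
def noisy_sheet():
    """Default-noise sheet, 5 tablets per class."""
    spec = syn.SheetSpec(width_px=512, height_px=384, seed=2)
    return syn.generate_sheet(spec, syn.default_classes(5))


@pytest.fixture(scope="session")
def labelled_crops(noisy_sheet):
    """Segmented, truth-labelled crops of the noisy sheet."""
    sheet, truth = noisy_sheet
    _, crops, _ = seg.segment_sheet(sheet, min_area=seg.default_min_area(14))
    crops = assign_true_classes(crops, truth)
    assert all(c.class_true is not None for c in crops)
    return crops


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
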