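import numpy as np
import pytest

from aortamac.calcium import (
    calcification_threshold,
    compute_lumen_reference,
    detect_calcification,
)
from aortamac.phantom import CalcArc, PhantomSpec, generate_phantom_slice


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def arc90_phantom():
    """Contrast-enhanced phantom with a single 90-degree full-wall arc."""
    spec = PhantomSpec(calc_arcs=(CalcArc(0.0, 90.0, 3.0, 600.0),), seed=42)
    return spec, *generate_phantom_slice(spec)


def detect_on_phantom(slc, mask, **kwargs):
    """Standard chain: lumen reference -> 5-SD threshold -> detection."""
    ref = compute_lumen_reference(slc, mask)
    thr = calcification_threshold(ref)
    return detect_calcification(slc, mask, thr, **kwargs)
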