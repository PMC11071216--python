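import numpy as np
import pytest

from regulome.motifs import PWM, pwm_from_counts
from regulome.peaks import GenomicInterval, Peak


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_peak(chrom, start, end, summit=None, source="", name=""):
    if summit is None:
        summit = (start + end) // 2
    return Peak(interval=GenomicInterval(chrom, start, end), summit=summit,
                source=source, name=name)


@pytest.fixture
def sharp_pwm():
    """Width-4 PWM strongly preferring ACGT."""
    counts = np.array([
        [90, 2, 2, 2],
        [4, 90, 2, 2],
        [4, 4, 90, 2],
        [2, 4, 6, 94],
    ], dtype=float)
    return pwm_from_counts("ACGT_SHARP", counts, pseudocount=0.01)


@pytest.fixture
def flat_pwm():
    """PWM equal to the uniform background at every column."""
    return PWM(id="FLAT", probs=np.full((4, 5), 0.25))
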