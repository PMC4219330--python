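import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass

from exposloc.exposure import (AMINO_ACIDS, DEFAULT_RANGE_BOUNDARIES,
                               ExposureProfile, ResidueRecord)


def random_profile(rng: np.random.Generator, length: int = 30,
                   pid: str = "P") -> ExposureProfile:
    """A fully covered random profile with exact range labels."""
    cuts = DEFAULT_RANGE_BOUNDARIES.cuts
    ranges = rng.integers(1, 7, size=length)
    aa_idx = rng.integers(0, 20, size=length)
    seq = "".join(AMINO_ACIDS[j] for j in aa_idx)
    residues = []
    for i in range(length):
        r = int(ranges[i])
        rsa = float(rng.uniform(cuts[r - 1], cuts[r]))
        residues.append(ResidueRecord(i + 1, seq[i], None, rsa, r, "structure"))
    return ExposureProfile(pid, seq, residues)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
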