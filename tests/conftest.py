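import numpy as np
import pytest

from idphub.disorder_profiles import BinaryMask, ResidueScoreTrack
from idphub.synthetic_data import SyntheticSpec, generate_proteome


def make_track(scores, protein_id="P1", predictor_id="predA"):
    return ResidueScoreTrack(protein_id, predictor_id, np.asarray(scores, dtype=float))


def make_mask(states, protein_id="P1", predictor_id="predA"):
    return BinaryMask(protein_id, predictor_id, np.asarray(states, dtype=bool))


def brute_force_idrs(states, min_window):
    """Independent run scanner: walk the mask residue by residue."""
    intervals = []
    start = None
    for i, s in enumerate(list(states) + [False]):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if i - start >= min_window:
                intervals.append((start + 1, i))  # 1-based inclusive
            start = None
    return intervals


@pytest.fixture(scope="session")
def small_dataset():
    """A modest noisy synthetic proteome shared across read-only tests."""
    spec = SyntheticSpec(n_proteins=120, seed=42)
    return generate_proteome(spec)
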