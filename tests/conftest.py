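import numpy as np
import pytest

from chromfiber import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_random_fiber(rng, length=500, molecule_id="m0", start=0):
    """A fiber with random sequence-derived A/CpG positions and random probabilities."""
    seq = simulate.random_sequence(length, rng, cpg_per_kb=20.0)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    a_pos = np.flatnonzero(arr == ord("A"))
    cpg_pos = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    from chromfiber.io import Fiber

    return Fiber(
        molecule_id=molecule_id,
        chrom="chrS",
        start=start,
        end=start + length,
        sequence=seq,
        a_positions=a_pos,
        m6da_prob=rng.random(len(a_pos)),
        cpg_positions=cpg_pos,
        m5dc_prob=rng.random(len(cpg_pos)),
    )
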