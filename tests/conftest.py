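import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cphotspot.io_formats import GenusAlignment
from cphotspot.simulate import SimConfig, simulate_genus


def make_aln(*seqs: str, ids=None, genus: str = "toy", reference_index: int = 0):
    """Build a GenusAlignment from raw aligned strings."""
    ids = tuple(ids) if ids else tuple(f"sp{i + 1}" for i in range(len(seqs)))
    return GenusAlignment(
        genus_label=genus,
        ids=ids,
        seqs=tuple(s.upper() for s in seqs),
        reference_index=reference_index,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture(scope="session")
def sim_pair():
    """A simulated two-taxon genus at default study conditions."""
    cfg = SimConfig(seed=1234)
    return simulate_genus(cfg)


def random_alignment(rng, n_seqs=4, length=120, gap_frac=0.05, ambig_frac=0.02,
                     diverge=0.1):
    """Random gapped/ambiguous alignment derived from one ancestor."""
    alphabet = np.array(list("ACGT"))
    anc = rng.integers(0, 4, size=length)
    seqs = []
    for _ in range(n_seqs):
        codes = anc.copy()
        mut = rng.random(length) < diverge
        codes[mut] = rng.integers(0, 4, size=int(mut.sum()))
        chars = alphabet[codes]
        gap = rng.random(length) < gap_frac
        amb = rng.random(length) < ambig_frac
        chars[amb] = "N"
        chars[gap] = "-"
        seqs.append("".join(chars))
    # guard: no gap-only columns
    for c in range(length):
        if all(s[c] == "-" for s in seqs):
            seqs[0] = seqs[0][:c] + "A" + seqs[0][c + 1:]
    return make_aln(*seqs, genus="rand")
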