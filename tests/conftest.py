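import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ampcon.seqio import Read, SeqRecord
from ampcon.simulate import (
    ErrorModel,
    LocusSpec,
    RunConfig,
    default_primer_pair,
    random_truth,
    simulate_run,
)


def make_read(seq: str, rid: str = "r", q: int = 30) -> Read:
    return Read(id=rid, seq=seq, qual=[q] * len(seq))


def diverge(seq: str, frac: float, seed: int, indel_frac: float = 0.3) -> str:
    """Congener-style divergent copy: substitutions plus indels."""
    rng = np.random.default_rng(seed)
    n_mut = int(frac * len(seq))
    idx = sorted(rng.choice(len(seq), size=n_mut, replace=False), reverse=True)
    s = list(seq)
    for i in idx:
        r = rng.random()
        if r < 1 - indel_frac:
            s[i] = "ACGT"[("ACGT".index(s[i]) + rng.integers(1, 4)) % 4]
        elif r < 1 - indel_frac / 2:
            del s[i]
        else:
            s.insert(i, "ACGT"[rng.integers(0, 4)])
    return "".join(s)


ERROR_FREE = ErrorModel(sub_rate=0.0, ins_rate=0.0, del_rate=0.0, qual_mean=20.0)


@pytest.fixture(scope="session")
def truth500():
    return SeqRecord("locus1", random_truth(500, [1, 0]))


@pytest.fixture(scope="session")
def primers():
    return default_primer_pair("locus1")


@pytest.fixture(scope="session")
def small_run(truth500):
    """300 default-error reads of one 500 bp locus, barcode BC01, seed 1."""
    cfg = RunConfig(loci=[LocusSpec("locus1", truth500, "BC01", 300)], seed=1)
    return simulate_run(cfg)


@pytest.fixture(scope="session")
def clean_reads(truth500):
    """40 error-free high-quality reads of the same locus."""
    cfg = RunConfig(loci=[LocusSpec("locus1", truth500, "BC01", 40)], seed=2)
    return simulate_run(cfg, ERROR_FREE).reads
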