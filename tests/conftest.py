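import numpy as np
import pandas as pd
import pytest

from methylbench.methylio import COLUMNS, MethylCallSet
from methylbench.synthio import SimConfig, AssayProfile, generate_truth, generate_callset


def make_callset(chroms, starts, n_meth, n_unmeth, strand="merged", metadata=None):
    starts = np.asarray(starts)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + (2 if strand == "merged" else 1),
            "strand": strand,
            "context": "CpG",
            "n_meth": n_meth,
            "n_unmeth": n_unmeth,
        }
    )
    return MethylCallSet(df[COLUMNS], dict(metadata or {}))


def random_callset(rng, n=1000, chroms=("chr1", "chr2"), metadata=None):
    parts = []
    for chrom in chroms:
        pos = np.sort(rng.choice(10 * n, size=n // len(chroms), replace=False)) * 2
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + 2,
                    "strand": "merged",
                    "context": "CpG",
                    "n_meth": rng.integers(0, 30, len(pos)),
                    "n_unmeth": rng.integers(0, 30, len(pos)),
                }
            )
        )
    df = pd.concat(parts, ignore_index=True)
    keep = (df["n_meth"] + df["n_unmeth"]) > 0
    return MethylCallSet(df[keep][COLUMNS], dict(metadata or {}))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_sites=3000, dm_fraction=0.1, chrom_layout=(("chr1", 1_000_000),))


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def small_callset(small_truth):
    return generate_callset(small_truth, "EMSeq", "A1")
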