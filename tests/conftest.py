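import numpy as np
import pandas as pd
import pytest

from methylrad import MethylationMatrix


def make_matrix(pos, coverage, methylated, groups, chrom="chr1"):
    """Build a one-chromosome matrix from plain lists (samples s0, s1, ...)."""
    coverage = np.atleast_2d(np.asarray(coverage))
    methylated = np.atleast_2d(np.asarray(methylated))
    samples = [f"s{i}" for i in range(coverage.shape[1])]
    if not isinstance(groups, dict):
        groups = dict(zip(samples, groups))
    sites = pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos, dtype=int)})
    return MethylationMatrix(sites, samples, coverage, methylated, groups)


@pytest.fixture
def small_matrix():
    """40 CpGs, 2 samples per group, moderate coverage."""
    rng = np.random.default_rng(7)
    pos = np.sort(rng.choice(np.arange(100, 5000), size=40, replace=False))
    cov = rng.poisson(20, size=(40, 4)) + 1
    meth = rng.binomial(cov, 0.5)
    return make_matrix(pos, cov, meth, ["a", "a", "b", "b"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
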