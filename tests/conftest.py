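import numpy as np
import pytest

from sexscan.popstats import GenotypeMatrix, SexLabels, HOM_REF, HET, HOM_ALT


def make_gm(codes, positions=None, chrom="chr1", samples=None):
    """GenotypeMatrix from a (sites x individuals) code array."""
    codes = np.asarray(codes, dtype=np.int8)
    n_sites, n_ind = codes.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_ind)]
    return GenotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions),
        ref=np.array(["A"] * n_sites),
        alt=np.array(["G"] * n_sites),
        codes=codes,
        samples=samples,
    )


def make_sexes(n_males, n_females, samples=None):
    if samples is None:
        samples = [f"s{i}" for i in range(n_males + n_females)]
    return SexLabels(
        sex={s: ("M" if i < n_males else "F") for i, s in enumerate(samples)}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
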