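"""Per-site and per-window population statistics from genotypes and sex labels.

The substrate for every downstream scan is a matrix of biallelic SNP
genotypes over a cohort of phenotypically sexed individuals.  This module
reads VCF input, applies the minor-allele-frequency filter, and computes
the per-site (Ho, He, F_IS, sex-heterozygosity classes) and per-window
(mean between-sex F_ST, het-site densities, SNP density, GC content,
normalized male/female coverage ratio) statistics used to locate
sex-linked regions.

Coordinates are 0-based half-open internally; VCF positions (1-based)
are converted at the I/O boundary.  Windows default to 50 kb sliding
with a 25 kb step, so overlapping windows intentionally double-count
sites.  Missing genotypes are excluded site-wise from every statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

# genotype codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1


@dataclass
class WindowSpec:
    """Sliding-window geometry: 50 kb windows advancing by 25 kb by default."""

    size: int = 50_000
    step: int = 25_000

    def __post_init__(self) -> None:
        if self.size <= 0 or self.step <= 0:
            raise ValueError("window size and step must be positive")
        if self.step > self.size:
            raise ValueError("window step must not exceed window size")

    def windows(self, chrom_length: int) -> np.ndarray:
        """(n, 2) array of [start, end) windows tiling [0, chrom_length)."""
        if chrom_length <= 0:
            raise ValueError("chromosome length must be positive")
        starts = np.arange(0, chrom_length, self.step, dtype=np.int64)
        ends = np.minimum(starts + self.size, chrom_length)
        # drop trailing windows fully contained in their predecessor
        keep = np.ones(len(starts), dtype=bool)
        if len(starts) > 1:
            keep[1:] = ends[1:] > ends[:-1]
        return np.column_stack([starts, ends])[keep]


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes: sites x individuals.

    ``positions`` are 1-based (as in VCF) and strictly increasing.
    ``codes`` holds {0: hom-ref, 1: het, 2: hom-alt, -1: missing}.
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    codes: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("sample ids must be unique")
        if self.codes.shape != (len(self.positions), len(self.samples)):
            raise ValueError("codes shape does not match positions x samples")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[i] for i in ids], dtype=np.intp)

    def take_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[mask],
            ref=np.asarray(self.ref)[mask],
            alt=np.asarray(self.alt)[mask],
            codes=self.codes[mask],
            samples=list(self.samples),
        )


@dataclass
class SexLabels:
    """Phenotypic sex per individual, plus exclusion flags for inferred
    sex-reversed individuals (set by the reversal-detection step)."""

    sex: dict[str, str]
    excluded: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {v for v in self.sex.values()} - {"M", "F"}
        if bad:
            raise ValueError(f"sex labels must be 'M' or 'F', got {bad}")

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = set(self.sex) - set(gm.samples)
        if missing:
            raise ValueError(f"labeled individuals absent from matrix: {sorted(missing)}")

    def ids(self, sex: str, include_excluded: bool = False) -> list[str]:
        return [
            i for i, s in self.sex.items()
            if s == sex and (include_excluded or i not in self.excluded)
        ]

    @classmethod
    def from_tsv(cls, path) -> "SexLabels":
        df = pd.read_csv(path, sep="\t", header=None, names=["id", "sex"], dtype=str)
        return cls(sex=dict(zip(df["id"], df["sex"])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for i, s in self.sex.items():
                fh.write(f"{i}\t{s}\n")


def read_vcf(path, region: str | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped (count logged).  Phased
    and unphased heterozygotes are both coded het.  Only a single
    chromosome may be present (pass ``region`` to subset).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if len(samples) != len(set(samples)):
        raise ValueError("sample ids in VCF are not unique")
    positions, refs, alts, rows = [], [], [], []
    chrom = None
    n_dropped = 0
    it = vcf(region) if region else vcf
    for rec in it:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_dropped += 1
            continue
        if chrom is None:
            chrom = rec.CHROM
        elif rec.CHROM != chrom:
            raise ValueError(
                f"multiple chromosomes in input ({chrom}, {rec.CHROM}); pass region="
            )
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        # gts012: 0 homref, 1 het, 2 homalt, 3 unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)
    codes = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(
        chrom=chrom or "NA",
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs),
        alt=np.array(alts),
        codes=codes,
        samples=samples,
    )


def alt_allele_frequency(codes: np.ndarray) -> np.ndarray:
    """Sample ALT allele frequency per site over non-missing genotypes."""
    called = codes != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, codes, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, alt / n_alleles, np.nan)


def filter_sites(gm: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Keep biallelic sites with minor allele frequency strictly above
    ``maf_min`` (computed over non-missing alleles)."""
    p = alt_allele_frequency(gm.codes)
    maf = np.minimum(p, 1.0 - p)
    keep = np.nan_to_num(maf, nan=0.0) > maf_min
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_sites: removed %d sites with MAF <= %g", n_removed, maf_min)
    return gm.take_sites(keep)


def fis_per_site(gm: GenotypeMatrix, subset: np.ndarray | None = None) -> pd.DataFrame:
    """Per-site Ho, He and F_IS = 1 - Ho/He.

    He is 2*p*(1-p) from the sample allele frequency, without
    small-sample correction.  Sites with He = 0 (monomorphic) or no
    called genotypes get NaN F_IS.
    """
    codes = gm.codes if subset is None else gm.codes[:, subset]
    called = codes != MISSING
    n = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, (codes == HET).sum(axis=1) / n, np.nan)
    p = alt_allele_frequency(codes)
    he = 2.0 * p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        fis = np.where(he > 0, 1.0 - ho / he, np.nan)
    return pd.DataFrame(
        {"chrom": gm.chrom, "pos": gm.positions, "ho": ho, "he": he, "fis": fis}
    )


def _wc_fst_components(codes: np.ndarray, groups: list[np.ndarray]):
    """Weir & Cockerham (1984) per-site variance components a, b, c for
    r groups of individuals (columns of ``codes``).  Vectorized over sites."""
    r = len(groups)
    n_i, p_i, h_i = [], [], []
    for idx in groups:
        sub = codes[:, idx]
        called = sub != MISSING
        ni = called.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(ni > 0, np.where(called, sub, 0).sum(axis=1) / (2 * ni), np.nan)
            hi = np.where(ni > 0, (sub == HET).sum(axis=1) / ni, np.nan)
        n_i.append(ni)
        p_i.append(pi)
        h_i.append(hi)
    n_i = np.array(n_i)   # (r, sites)
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    usable = (n_i >= 2).all(axis=0)
    return a, b, c, usable


def fst_per_site(gm: GenotypeMatrix, sexes: SexLabels) -> pd.DataFrame:
    """Per-site Weir-Cockerham F_ST between the male and female groups.

    Negative estimates are retained.  Sites monomorphic overall, or with
    fewer than two called genotypes in either sex, get NaN.
    """
    sexes.validate_against(gm)
    males = gm.sample_index(sexes.ids("M"))
    females = gm.sample_index(sexes.ids("F"))
    a, b, c, usable = _wc_fst_components(gm.codes, [males, females])
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(usable & (denom != 0), a / denom, np.nan)
    return pd.DataFrame(
        {"chrom": gm.chrom, "pos": gm.positions, "a": a, "b": b, "c": c, "fst": fst}
    )


def _window_values(
    positions: np.ndarray, windows: np.ndarray, values: np.ndarray, reduce: str
) -> np.ndarray:
    """Reduce per-site values into (possibly overlapping) windows.

    ``positions`` must be sorted, 0-based.  reduce in {mean, sum, max, count}.
    """
    out = np.full(len(windows), np.nan)
    for w, (start, end) in enumerate(windows):
        lo = np.searchsorted(positions, start, side="left")
        hi = np.searchsorted(positions, end, side="left")
        if reduce == "count":
            out[w] = hi - lo
            continue
        v = values[lo:hi]
        v = v[~np.isnan(v)]
        if len(v) == 0:
            continue
        if reduce == "mean":
            out[w] = v.mean()
        elif reduce == "sum":
            out[w] = v.sum()
        elif reduce == "max":
            out[w] = v.max()
        else:
            raise ValueError(f"unknown reduction {reduce!r}")
    return out


def _track_frame(chrom: str, windows: np.ndarray, **cols) -> pd.DataFrame:
    df = pd.DataFrame({"chrom": chrom, "start": windows[:, 0], "end": windows[:, 1]})
    for name, vals in cols.items():
        df[name] = vals
    return df


def fst_windowed(
    gm: GenotypeMatrix,
    sexes: SexLabels,
    spec: WindowSpec,
    chrom_length: int,
    mode: str = "mean",
) -> pd.DataFrame:
    """Windowed between-sex F_ST.

    mode='mean' (default) averages per-site Weir-Cockerham estimates;
    mode='weighted' uses the ratio of summed variance components (the
    vcftools "weighted" variant).  Windows with no usable site are NaN.
    """
    per_site = fst_per_site(gm, sexes)
    windows = spec.windows(chrom_length)
    pos0 = gm.positions - 1
    if mode == "mean":
        vals = _window_values(pos0, windows, per_site["fst"].to_numpy(), "mean")
    elif mode == "weighted":
        a = _window_values(pos0, windows, per_site["a"].to_numpy(), "sum")
        abc = _window_values(
            pos0, windows, (per_site["a"] + per_site["b"] + per_site["c"]).to_numpy(), "sum"
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(abc != 0, a / abc, np.nan)
    else:
        raise ValueError("mode must be 'mean' or 'weighted'")
    return _track_frame(gm.chrom, windows, fst=vals)


def sex_het_site_classes(
    gm: GenotypeMatrix,
    sexes: SexLabels,
    spec: WindowSpec,
    chrom_length: int,
    frac: float = 0.9,
) -> pd.DataFrame:
    """Per-window counts of sex-patterned heterozygous sites.

    ``het_mf``: sites het in >= frac of included males AND hom in >= frac
    of included females (the XY signature).  ``het_fm``: the mirror (ZW)
    class.  frac=1.0 gives the strict criterion used to pick genes for
    X-Y divergence.  Individuals flagged as sex-reversed are excluded.
    """
    sexes.validate_against(gm)
    males = gm.sample_index(sexes.ids("M"))
    females = gm.sample_index(sexes.ids("F"))
    if len(males) == 0 or len(females) == 0:
        raise ValueError("both sexes must have included individuals")
    mf, fm = site_sex_pattern_flags(gm.codes, males, females, frac)
    windows = spec.windows(chrom_length)
    pos0 = gm.positions - 1
    return _track_frame(
        gm.chrom,
        windows,
        het_mf=_window_values(pos0, windows, np.where(mf, 1.0, np.nan), "sum"),
        het_fm=_window_values(pos0, windows, np.where(fm, 1.0, np.nan), "sum"),
    ).fillna({"het_mf": 0.0, "het_fm": 0.0})


def site_sex_pattern_flags(
    codes: np.ndarray, males: np.ndarray, females: np.ndarray, frac: float = 0.9
):
    """Boolean per-site flags for (het-in-males, hom-in-females) and the mirror."""

    def _fracs(idx):
        sub = codes[:, idx]
        called = sub != MISSING
        n = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            het = np.where(n > 0, (sub == HET).sum(axis=1) / n, np.nan)
            hom = np.where(n > 0, ((sub == HOM_REF) | (sub == HOM_ALT)).sum(axis=1) / n, np.nan)
        return het, hom

    m_het, m_hom = _fracs(males)
    f_het, f_hom = _fracs(females)
    with np.errstate(invalid="ignore"):
        mf = (m_het >= frac) & (f_hom >= frac)
        fm = (f_het >= frac) & (m_hom >= frac)
    return mf, fm


def snp_density(
    gm: GenotypeMatrix, spec: WindowSpec, chrom_length: int
) -> pd.DataFrame:
    """Filtered SNPs per window."""
    windows = spec.windows(chrom_length)
    counts = _window_values(gm.positions - 1, windows, gm.positions.astype(float), "count")
    return _track_frame(gm.chrom, windows, snp_density=counts)


def assoc_track(
    assoc_df: pd.DataFrame, spec: WindowSpec, chrom_length: int, chrom: str
) -> pd.DataFrame:
    """Per-window maximum -log10 P from an association scan table."""
    windows = spec.windows(chrom_length)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(assoc_df["p"].to_numpy())
    vals = _window_values(assoc_df["pos"].to_numpy() - 1, windows, nlp, "max")
    sig = _window_values(
        assoc_df["pos"].to_numpy() - 1,
        windows,
        np.where(assoc_df["significant"].to_numpy(), 1.0, np.nan),
        "sum",
    )
    return _track_frame(chrom, windows, neglog10p_max=vals, n_significant=np.nan_to_num(sig))


def coverage_ratio(
    depth: pd.DataFrame, sexes: SexLabels, spec: WindowSpec, chrom_length: int
) -> pd.DataFrame:
    """Median-normalized male/female depth ratio per window.

    ``depth`` is long-form (chrom, start, end, individual, depth) on the
    same coordinate system as the windows.  Each sex's mean window depth
    is divided by that sex's genome-wide median before taking the ratio;
    zero female depth yields NaN (logged).  Fully Y-degenerate intervals
    are expected near 0.5: the homogametic sex carries two X copies.
    """
    males = set(sexes.ids("M", include_excluded=True))
    females = set(sexes.ids("F", include_excluded=True))
    d = depth.copy()
    d["mid"] = (d["start"] + d["end"]) // 2
    m = d[d["individual"].isin(males)]
    f = d[d["individual"].isin(females)]
    m_med = m["depth"].median()
    f_med = f["depth"].median()
    windows = spec.windows(chrom_length)
    chrom = depth["chrom"].iloc[0]
    if (depth["chrom"] != chrom).any():
        raise ValueError("coverage_ratio: mixed chromosome names in depth track")
    out = np.full(len(windows), np.nan)
    m_by_mid = m.groupby("mid")["depth"].mean()
    f_by_mid = f.groupby("mid")["depth"].mean()
    mids = m_by_mid.index.to_numpy()
    n_zero = 0
    for w, (start, end) in enumerate(windows):
        sel = (mids >= start) & (mids < end)
        if not sel.any():
            continue
        md = m_by_mid.to_numpy()[sel].mean()
        fd = f_by_mid.reindex(mids[sel]).to_numpy().mean()
        if fd == 0 or np.isnan(fd):
            n_zero += 1
            continue
        out[w] = (md / m_med) / (fd / f_med)
    if n_zero:
        logger.info("coverage_ratio: %d windows with zero female depth set missing", n_zero)
    return _track_frame(chrom, windows, cov_ratio=out)


def gc_windows(fasta_path, spec: WindowSpec, chrom: str, chrom_length: int | None = None) -> pd.DataFrame:
    """GC content (G+C)/(A+C+G+T) per window, ignoring Ns; all-N windows NaN."""
    fa = Fasta(str(fasta_path))
    if chrom not in fa:
        raise ValueError(f"chromosome {chrom!r} not found in FASTA")
    seq = str(fa[chrom][:]).upper()
    length = chrom_length if chrom_length is not None else len(seq)
    windows = spec.windows(length)
    vals = np.full(len(windows), np.nan)
    for w, (start, end) in enumerate(windows):
        sub = seq[start:min(end, len(seq))]
        gc = sub.count("G") + sub.count("C")
        at = sub.count("A") + sub.count("T")
        if gc + at > 0:
            vals[w] = gc / (gc + at)
    return _track_frame(chrom, windows, gc=vals)
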