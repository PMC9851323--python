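"""Sex-association scanning, heterogamety inference, sex-reversal
detection, and RAD-seq marker association.

The scan treats phenotypic sex as a binary trait and tests each SNP for
genotype-sex association with an exact allelic Fisher test (default) or
a genotypic chi-square.  Genome-wide significance uses the Bonferroni
threshold alpha / n_SNPs.  Among significant sites, the balance of
male-heterozygous versus female-heterozygous patterns identifies the
heterogametic sex (XY vs ZW); individuals whose genotypes at the most
strongly associated SNPs match the opposite sex's expected pattern are
flagged as likely sex-reversed and excluded from downstream statistics.

Note on the test choice: on real pedigreed cohorts a kinship-corrected
mixed model is preferable; the exact test here assumes unrelated
individuals, which the synthetic cohorts satisfy by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .popstats import (
    GenotypeMatrix,
    SexLabels,
    HET,
    HOM_REF,
    HOM_ALT,
    MISSING,
    site_sex_pattern_flags,
)

logger = logging.getLogger(__name__)


def bonferroni_threshold(n_snps: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / n_snps."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    return alpha / n_snps


@dataclass
class AssocResult:
    """Per-site association P-values plus the genome-wide threshold."""

    table: pd.DataFrame  # chrom, pos, p, significant
    test: str
    threshold: float
    n_tested: int


def _allele_counts(codes: np.ndarray, idx: np.ndarray):
    sub = codes[:, idx]
    called = sub != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    return alt, n_alleles - alt


def assoc_scan(
    gm: GenotypeMatrix,
    sexes: SexLabels,
    test: str = "fisher_allelic",
    alpha: float = 0.05,
) -> AssocResult:
    """Per-site two-sided association test of genotype with sex.

    fisher_allelic: 2x2 exact test on (ref, alt) allele counts by sex.
    chisq_genotypic: chi-square on the 2x3 genotype table (falls back to
    Fisher on the allelic table when expected counts are degenerate).
    Sites with no called genotypes in either sex get NaN P.
    """
    sexes.validate_against(gm)
    males = gm.sample_index(sexes.ids("M"))
    females = gm.sample_index(sexes.ids("F"))
    if len(males) < 2 or len(females) < 2:
        raise ValueError("need at least two individuals per sex")
    n_sites = gm.n_sites
    p = np.full(n_sites, np.nan)
    cache: dict[tuple, float] = {}
    if test == "fisher_allelic":
        m_alt, m_ref = _allele_counts(gm.codes, males)
        f_alt, f_ref = _allele_counts(gm.codes, females)
        for i in range(n_sites):
            key = (int(m_ref[i]), int(m_alt[i]), int(f_ref[i]), int(f_alt[i]))
            if key[0] + key[1] == 0 or key[2] + key[3] == 0:
                continue
            if key not in cache:
                cache[key] = stats.fisher_exact(
                    [[key[0], key[1]], [key[2], key[3]]], alternative="two-sided"
                ).pvalue
            p[i] = cache[key]
    elif test == "chisq_genotypic":
        for i in range(n_sites):
            mrow = [int((gm.codes[i, males] == g).sum()) for g in (HOM_REF, HET, HOM_ALT)]
            frow = [int((gm.codes[i, females] == g).sum()) for g in (HOM_REF, HET, HOM_ALT)]
            key = tuple(mrow + frow)
            if sum(mrow) == 0 or sum(frow) == 0:
                continue
            if key not in cache:
                tab = np.array([mrow, frow])
                tab = tab[:, tab.sum(axis=0) > 0]
                if tab.shape[1] < 2:
                    cache[key] = 1.0
                else:
                    cache[key] = float(stats.chi2_contingency(tab, correction=False).pvalue)
            p[i] = cache[key]
    else:
        raise ValueError("test must be 'fisher_allelic' or 'chisq_genotypic'")
    n_tested = int(np.isfinite(p).sum())
    thr = bonferroni_threshold(max(n_tested, 1), alpha)
    with np.errstate(invalid="ignore"):
        sig = p < thr
    table = pd.DataFrame(
        {"chrom": gm.chrom, "pos": gm.positions, "p": p, "significant": sig}
    )
    return AssocResult(table=table, test=test, threshold=thr, n_tested=n_tested)


@dataclass
class HeterogametyCall:
    """XY/ZW/undetermined call from the balance of significant-site classes."""

    n_male_het_sites: int
    n_female_het_sites: int
    fraction: float
    binom_p: float
    call: str  # XY | ZW | undetermined


def classify_significant_sites(
    gm: GenotypeMatrix,
    sexes: SexLabels,
    assoc: AssocResult,
    frac: float = 0.8,
) -> tuple[int, int]:
    """Counts of significant sites het-in-males/hom-in-females and the mirror.

    A site is in a class when >= ``frac`` of the included individuals of
    each sex show the pattern ("heterozygous in most males, homozygous
    in most females").
    """
    males = gm.sample_index(sexes.ids("M"))
    females = gm.sample_index(sexes.ids("F"))
    mf, fm = site_sex_pattern_flags(gm.codes, males, females, frac)
    sig = assoc.table["significant"].fillna(False).to_numpy()
    return int((mf & sig).sum()), int((fm & sig).sum())


def heterogamety_call(
    n_male_het: int,
    n_female_het: int,
    min_fraction: float = 0.8,
    alpha: float = 0.01,
) -> HeterogametyCall:
    """Infer the heterogametic sex from significant-site class counts.

    XY when male-het sites dominate (fraction >= min_fraction and an
    exact binomial test against 0.5 rejects at ``alpha``); ZW for the
    mirror; otherwise undetermined.  Zero significant sites in both
    classes yields undetermined (with a warning).
    """
    total = n_male_het + n_female_het
    if total == 0:
        logger.warning("heterogamety_call: no classified significant sites")
        return HeterogametyCall(0, 0, np.nan, np.nan, "undetermined")
    fraction = n_male_het / total
    p_xy = stats.binomtest(n_male_het, total, 0.5, alternative="greater").pvalue
    p_zw = stats.binomtest(n_female_het, total, 0.5, alternative="greater").pvalue
    if fraction >= min_fraction and p_xy < alpha:
        call = "XY"
        binom_p = p_xy
    elif (1 - fraction) >= min_fraction and p_zw < alpha:
        call = "ZW"
        binom_p = p_zw
    else:
        call = "undetermined"
        binom_p = min(p_xy, p_zw)
    return HeterogametyCall(n_male_het, n_female_het, fraction, binom_p, call)


@dataclass
class ReversalReport:
    """Per-individual opposite-sex match fractions at the top-K SNPs."""

    table: pd.DataFrame  # individual, sex, n_sites, match_fraction, flagged
    top_k: int
    match_frac: float
    flagged: list = field(default_factory=list)


def detect_sex_reversals(
    gm: GenotypeMatrix,
    sexes: SexLabels,
    assoc: AssocResult,
    heterogamety: HeterogametyCall,
    top_k: int = 100,
    match_frac: float = 0.9,
) -> tuple[ReversalReport, SexLabels]:
    """Flag individuals whose genotypes at the ``top_k`` most strongly
    sex-associated SNPs match the opposite sex's expected pattern.

    Under XY the expected male genotype at a Y-linked site is het and
    the expected female genotype hom (mirrored under ZW).  An individual
    is flagged when >= ``match_frac`` of its non-missing top-K genotypes
    show the opposite pattern; flagged ids are marked excluded in the
    returned SexLabels.  Ties in the P-value ranking break by (P, chrom,
    position) for determinism.  Runs as a single pass (no iteration).
    """
    if heterogamety.call == "undetermined":
        raise ValueError("cannot detect sex reversals: heterogamety undetermined")
    t = assoc.table.dropna(subset=["p"]).sort_values(
        ["p", "chrom", "pos"], kind="mergesort"
    )
    top = t.head(top_k)
    site_idx = np.searchsorted(gm.positions, top["pos"].to_numpy())
    codes = gm.codes[site_idx]

    het_sex = "M" if heterogamety.call == "XY" else "F"
    rows = []
    flagged = []
    for j, sid in enumerate(gm.samples):
        if sid not in sexes.sex:
            continue
        g = codes[:, j]
        called = g != MISSING
        n = int(called.sum())
        is_het = g[called] == HET
        expect_het = sexes.sex[sid] == het_sex
        # opposite-sex pattern: hom where het expected, het where hom expected
        opp = (~is_het) if expect_het else is_het
        frac = float(opp.mean()) if n else np.nan
        flag = bool(n and frac >= match_frac)
        if flag:
            flagged.append(sid)
        rows.append(
            {"individual": sid, "sex": sexes.sex[sid], "n_sites": n,
             "match_fraction": frac, "flagged": flag}
        )
    report = ReversalReport(
        table=pd.DataFrame(rows), top_k=top_k, match_frac=match_frac, flagged=flagged
    )
    updated = SexLabels(sex=dict(sexes.sex), excluded=set(sexes.excluded) | set(flagged))
    return report, updated


def rad_marker_assoc(
    depth: pd.DataFrame,
    sexes: SexLabels,
    min_depth: int = 5,
    alpha: float = 0.05,
    test: str = "fisher",
) -> pd.DataFrame:
    """Test presence/absence of RAD markers against phenotypic sex.

    A marker is "present" in an individual when its depth is at least
    ``min_depth``.  Markers absent in every individual are dropped.  The
    per-marker presence x sex table is tested with Fisher's exact test
    (default; the exact analogue of the chi-square used by radsex, valid
    at all counts) or a chi-square, Bonferroni-corrected over the tested
    markers.  Significant markers are classified male-linked or
    female-linked by which sex carries them more often.
    """
    if (depth.to_numpy() < 0).any():
        raise ValueError("marker depths must be nonnegative")
    males = [i for i in depth.columns if sexes.sex.get(i) == "M"]
    females = [i for i in depth.columns if sexes.sex.get(i) == "F"]
    present = depth >= min_depth
    keep = present.any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("rad_marker_assoc: dropped %d markers absent everywhere", n_dropped)
    present = present.loc[keep]
    n_tested = len(present)
    thr = alpha / max(n_tested, 1)
    pm = present[males].sum(axis=1).to_numpy()
    pf = present[females].sum(axis=1).to_numpy()
    nm, nf = len(males), len(females)
    cache: dict[tuple, float] = {}
    pvals = np.empty(n_tested)
    for i in range(n_tested):
        key = (int(pm[i]), int(pf[i]))
        if key not in cache:
            tab = [[key[0], nm - key[0]], [key[1], nf - key[1]]]
            if test == "fisher":
                cache[key] = float(stats.fisher_exact(tab, alternative="two-sided").pvalue)
            elif test == "chisq":
                t = np.array(tab)
                if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                    cache[key] = 1.0
                else:
                    cache[key] = float(stats.chi2_contingency(t, correction=False).pvalue)
            else:
                raise ValueError("test must be 'fisher' or 'chisq'")
        pvals[i] = cache[key]
    sig = pvals < thr
    linked_sex = np.where(pm / max(nm, 1) >= pf / max(nf, 1), "M", "F")
    return pd.DataFrame(
        {
            "marker": present.index,
            "n_present_males": pm,
            "n_present_females": pf,
            "p": pvals,
            "significant": sig,
            "linked_sex": np.where(sig, linked_sex, ""),
        }
    ).set_index("marker")
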