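"""Expression normalization, tissue specificity (tau) and enrichment.

TPM normalization, cross-sample quantile normalization, the tau
tissue-specificity index (tau = sum(1 - x_i/max) / (n-1), 0 for uniform
profiles and 1 for single-tissue expression), the classification rule
combining tau >= 0.8 with a top-three expression rank, a fold-change
definition of tissue bias, and one-sided Fisher exact tests for
chromosomal enrichment of gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

TAU_THRESHOLD = 0.8
TPM_EXPRESSED = 1.0


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from read counts and gene lengths (bp).

    Each column sums to 1e6.  Raises if a sample has zero total rate.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total rate: {bad}")
    return rate.div(totals, axis=1) * 1e6


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the same distribution (the mean of the
    per-column sorted values); ties within a column receive the average
    of the target values they span."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("quantile normalization expects nonnegative values")
    ranks = matrix.rank(method="average", axis=0)
    sorted_means = pd.DataFrame(
        np.sort(matrix.to_numpy(), axis=0), columns=matrix.columns
    ).mean(axis=1)
    # target value for (possibly fractional) rank r: interpolate between
    # the rank-mean values it spans
    target = sorted_means.to_numpy()
    out = np.empty_like(matrix.to_numpy(), dtype=float)
    r = ranks.to_numpy() - 1.0
    lo = np.floor(r).astype(int)
    hi = np.ceil(r).astype(int)
    out = target[lo] + (r - lo) * (target[hi] - target[lo])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def tau(profile) -> float:
    """Tissue-specificity index of one expression profile across tissues."""
    x = np.asarray(profile, dtype=float)
    if len(x) < 2:
        raise ValueError("tau needs at least two tissues")
    m = x.max()
    if m <= 0:
        return float("nan")
    xh = x / m
    return float((1.0 - xh).sum() / (len(x) - 1))


def tau_table(expr: pd.DataFrame, min_tpm: float = TPM_EXPRESSED) -> pd.DataFrame:
    """Per-gene tau over tissue columns, after dropping genes below
    ``min_tpm`` in every tissue (not expressed anywhere)."""
    expressed = (expr >= min_tpm).any(axis=1)
    sub = expr.loc[expressed]
    taus = sub.apply(tau, axis=1)
    argmax = sub.idxmax(axis=1)
    return pd.DataFrame({"tau": taus, "argmax_tissue": argmax})


def classify_tissue_specific(
    expr_norm: pd.DataFrame,
    taus: pd.Series | None = None,
    threshold: float = TAU_THRESHOLD,
    top_n: int = 3,
) -> pd.DataFrame:
    """Assign genes to the tissue where they are specifically expressed.

    A gene is tissue-specific when tau >= ``threshold`` (tau computed on
    the supplied, already-normalized matrix if not given) and is
    assigned to its highest-expressed tissue provided that tissue ranks
    within the gene's top ``top_n`` tissues (ties at the cut included).
    """
    if taus is None:
        taus = expr_norm.apply(tau, axis=1)
    taus = taus.reindex(expr_norm.index)
    rows = []
    vals = expr_norm.to_numpy()
    tissues = list(expr_norm.columns)
    for k, gene in enumerate(expr_norm.index):
        t = taus.iloc[k]
        assigned = None
        if np.isfinite(t) and t >= threshold:
            v = vals[k]
            order = np.argsort(-v, kind="mergesort")
            cut = v[order[min(top_n, len(v)) - 1]]
            top = {tissues[i] for i in range(len(v)) if v[i] >= cut}
            best = tissues[int(order[0])]
            if best in top:
                assigned = best
        rows.append({"gene": gene, "tau": t, "specific_tissue": assigned})
    return pd.DataFrame(rows).set_index("gene")


def tissue_biased(
    expr: pd.DataFrame, meta: pd.DataFrame, fold: float = 2.0
) -> pd.DataFrame:
    """Tissue-biased calls: TPM in a tissue at least ``fold`` x the mean
    TPM of the other tissues at the same developmental stage.

    ``meta`` indexes samples with 'tissue' and 'stage' columns; samples
    of the same tissue+stage are averaged first.  Returns a boolean
    frame genes x (tissue, stage).
    """
    meta = meta.loc[expr.columns]
    means = {}
    for (tissue, stage), grp in meta.groupby(["tissue", "stage"]):
        means[(tissue, stage)] = expr[grp.index].mean(axis=1)
    means = pd.DataFrame(means)
    out = {}
    for stage in meta["stage"].unique():
        cols = [c for c in means.columns if c[1] == stage]
        if len(cols) < 2:
            raise ValueError(f"need at least two tissues at stage {stage!r}")
        for col in cols:
            others = [c for c in cols if c != col]
            other_mean = means[others].mean(axis=1)
            out[col] = means[col] >= fold * other_mean
    return pd.DataFrame(out)


def chrom_enrichment(
    gene_set, universe: pd.Series, alpha: tuple[float, float] = (0.05, 0.01)
) -> pd.DataFrame:
    """One-sided (greater) Fisher exact enrichment of a gene set per
    chromosome/region label.

    ``universe`` maps every gene id to its chromosome or region label;
    ``gene_set`` must be a subset of its index.  Returns per-label
    counts, P, and significance marks ('*' P<0.05, '**' P<0.01; raw P,
    matching enrichment reported without multiple-testing correction).
    """
    gene_set = set(gene_set)
    missing = gene_set - set(universe.index)
    if missing:
        raise ValueError(f"gene set members absent from universe: {sorted(missing)[:5]}")
    n_univ = len(universe)
    n_set = len(gene_set)
    in_set = universe.index.isin(gene_set)
    rows = []
    for label, grp in universe.groupby(universe):
        on = int(grp.index.isin(gene_set).sum())
        n_chrom = len(grp)
        table = [
            [on, n_set - on],
            [n_chrom - on, n_univ - n_chrom - (n_set - on)],
        ]
        p = float(stats.fisher_exact(table, alternative="greater").pvalue)
        mark = "**" if p < alpha[1] else "*" if p < alpha[0] else ""
        rows.append(
            {"label": label, "set_on": on, "set_off": n_set - on,
             "bg_on": n_chrom - on, "bg_off": n_univ - n_chrom - (n_set - on),
             "p": p, "mark": mark}
        )
    return pd.DataFrame(rows).set_index("label")
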