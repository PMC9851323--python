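"""Change-point segmentation of window tracks and PAR/SLR boundary calling.

Binary segmentation under a Gaussian likelihood in which each segment
has its own mean AND variance: the cost of a segment of length n with
maximum-likelihood variance s2 is n*log(max(s2, var_floor)), so a split
is accepted when the log-likelihood gain 2*(ll_split - ll_whole) -- here
expressed directly as the cost reduction -- exceeds a penalty.  Up to
``max_cpts`` changepoints are accepted (three by default).  Because the
cost depends on data only through segment variances, changepoint
locations are invariant under adding a constant and under positive
scaling (up to the variance floor).

Boundaries from the F_ST, association -log10 P, and male-het-density
tracks are merged when concordant, and the resulting segments are
classified PAR / SLR / undetermined from significant-SNP content and
genome-wide percentiles of the supporting statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_VAR_FLOOR = 1e-8


@dataclass
class ChangepointSet:
    """Ordered changepoints (index of the last window of each left
    segment) with per-segment means/variances and the costs used."""

    indices: list            # indices into the original series
    n: int
    segment_means: list
    segment_vars: list
    gains: list
    penalty: float

    def segments(self) -> list[tuple[int, int]]:
        """[start, end) index pairs covering the series."""
        bounds = [0] + [i + 1 for i in self.indices] + [self.n]
        return list(zip(bounds[:-1], bounds[1:]))


def _seg_cost(cumsum, cumsq, start, end, var_floor):
    """n * log(sigma2_mle) for the slice [start, end) via prefix sums."""
    n = end - start
    s = cumsum[end] - cumsum[start]
    sq = cumsq[end] - cumsq[start]
    var = max(sq / n - (s / n) ** 2, var_floor)
    return n * np.log(var)


def _best_split(cumsum, cumsq, start, end, min_seg, var_floor):
    """Best single split of [start, end); returns (gain, split) or None."""
    whole = _seg_cost(cumsum, cumsq, start, end, var_floor)
    best = None
    for k in range(start + min_seg, end - min_seg + 1):
        cost = (
            _seg_cost(cumsum, cumsq, start, k, var_floor)
            + _seg_cost(cumsum, cumsq, k, end, var_floor)
        )
        gain = whole - cost
        if best is None or gain > best[0]:
            best = (gain, k)
    return best


def binseg_meanvar(
    series,
    max_cpts: int = 3,
    min_seg: int = 2,
    penalty="mbic",
    var_floor: float = DEFAULT_VAR_FLOOR,
) -> ChangepointSet:
    """Greedy binary segmentation for joint mean+variance changes.

    ``penalty`` is either a float (likelihood-gain threshold per split)
    or "mbic"/"bic" for 3*log(n) -- three extra parameters (mean,
    variance, location) per changepoint.  Missing values are dropped
    before segmentation and the reported indices refer to the original
    series.  A constant series (variance below ``var_floor``) yields no
    changepoints.
    """
    x = np.asarray(series, dtype=float)
    keep = np.isfinite(x)
    idx_map = np.flatnonzero(keep)
    x = x[keep]
    n = len(x)
    if n < 2 * min_seg:
        return ChangepointSet([], len(series), [float(np.mean(x)) if n else np.nan],
                              [float(np.var(x)) if n else np.nan], [], 0.0)
    pen = 3.0 * np.log(n) if isinstance(penalty, str) else float(penalty)
    if isinstance(penalty, str) and penalty.lower() not in ("mbic", "bic"):
        raise ValueError("penalty must be a number, 'mbic' or 'bic'")
    cumsum = np.concatenate([[0.0], np.cumsum(x)])
    cumsq = np.concatenate([[0.0], np.cumsum(x * x)])

    segments = [(0, n)]
    cpts: list[int] = []
    gains: list[float] = []
    while len(cpts) < max_cpts:
        best = None
        for (s, e) in segments:
            if e - s < 2 * min_seg:
                continue
            cand = _best_split(cumsum, cumsq, s, e, min_seg, var_floor)
            if cand is not None and (best is None or cand[0] > best[0]):
                best = (cand[0], cand[1], (s, e))
        if best is None or best[0] <= pen:
            break
        gain, k, seg = best
        segments.remove(seg)
        segments.extend([(seg[0], k), (k, seg[1])])
        cpts.append(k - 1)  # last index of the left segment
        gains.append(float(gain))
    cpts_sorted = sorted(cpts)
    bounds = [0] + [c + 1 for c in cpts_sorted] + [n]
    means = [float(x[s:e].mean()) for s, e in zip(bounds[:-1], bounds[1:])]
    variances = [float(x[s:e].var()) for s, e in zip(bounds[:-1], bounds[1:])]
    return ChangepointSet(
        indices=[int(idx_map[c]) for c in cpts_sorted],
        n=len(series),
        segment_means=means,
        segment_vars=variances,
        gains=gains,
        penalty=pen,
    )


@dataclass
class RegionCall:
    """Per-chromosome PAR/SLR/undetermined segmentation with support."""

    chrom: str
    segments: list  # (start, end, class)
    support: pd.DataFrame = field(default_factory=pd.DataFrame)

    def boundaries(self) -> list[int]:
        return [s[1] for s in self.segments[:-1]]

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for start, end, cls in self.segments:
                fh.write(f"{self.chrom}\t{start}\t{end}\t{cls}\n")


def _boundary_bp(track: pd.DataFrame, cp_index: int) -> float:
    """Boundary point estimate: midpoint of the centers of the last window
    of the left segment and the first of the right (windows overlap, so a
    point estimate is needed)."""
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    c1 = (starts[cp_index] + ends[cp_index]) / 2
    j = min(cp_index + 1, len(starts) - 1)
    c2 = (starts[j] + ends[j]) / 2
    return (c1 + c2) / 2


def _is_slr_segment(track, start, end, fst_q, het_q) -> bool:
    """SLR support rule: >=1 genome-wide-significant SNP plus mean F_ST
    and male-het density above the background reference quantiles."""
    mid = (track["start"].to_numpy() + track["end"].to_numpy()) / 2
    sel = (mid >= start) & (mid < end)
    if not sel.any():
        sel = (track["end"].to_numpy() > start) & (track["start"].to_numpy() < end)
    if not sel.any():
        return False
    seg = track[sel]
    with np.errstate(invalid="ignore"):
        mean_fst = float(np.nanmean(seg["fst"].to_numpy()))
        mean_het = float(np.nanmean(seg["het_mf"].to_numpy()))
        n_sig = float(np.nansum(seg["n_significant"].to_numpy()))
    return bool(
        n_sig >= 1
        and np.isfinite(mean_fst) and mean_fst > fst_q
        and np.isfinite(mean_het) and mean_het > het_q
    )


def call_regions(
    tracks: pd.DataFrame,
    assoc_track: pd.DataFrame,
    chrom_length: int,
    max_cpts: int = 3,
    concordance_bp: int | None = None,
    penalty="mbic",
    support_quantile: float = 0.9,
    background_thresholds: tuple[float, float] | None = None,
) -> RegionCall:
    """Segment the chromosome into PAR / SLR / undetermined regions.

    ``tracks`` must carry window columns (chrom, start, end) plus 'fst'
    and 'het_mf'; ``assoc_track`` the matching 'neglog10p_max' and
    'n_significant'.  Changepoints are computed independently on the
    three signal tracks and merged when within ``concordance_bp``
    (default: one window step).  A segment is SLR when it contains at
    least one genome-wide-significant SNP and both its mean F_ST and
    male-het density exceed the ``support_quantile`` quantile across all
    windows; PAR when it abuts an SLR and fails those criteria; else
    undetermined.  With no significant SNP anywhere, every segment is
    undetermined (no sex-linked region found).

    The reference quantiles are taken over windows that contain no
    significant SNP (a proxy for the genome-wide background when only
    the candidate chromosome is supplied); pass ``background_thresholds``
    = (fst, het_mf) to use thresholds computed over a whole genome.
    """
    track = tracks.merge(assoc_track, on=["chrom", "start", "end"], how="left")
    chrom = track["chrom"].iloc[0]
    if concordance_bp is None:
        starts = track["start"].to_numpy()
        concordance_bp = int(starts[1] - starts[0]) if len(starts) > 1 else 25_000

    cand: list[float] = []
    for col in ("fst", "neglog10p_max", "het_mf"):
        if col not in track:
            continue
        cps = binseg_meanvar(track[col].to_numpy(), max_cpts=max_cpts, penalty=penalty)
        cand.extend(_boundary_bp(track, i) for i in cps.indices)
    cand.sort()

    merged: list[float] = []
    for b in cand:
        if merged and b - merged[-1] <= concordance_bp:
            # concordant boundaries from different tracks: average them
            merged[-1] = (merged[-1] + b) / 2
        else:
            merged.append(b)
    bounds = [0] + [int(round(b)) for b in merged if 0 < b < chrom_length] + [chrom_length]
    bounds = sorted(set(bounds))

    if background_thresholds is not None:
        fst_q, het_q = background_thresholds
    else:
        bg = track[track["n_significant"].fillna(0) == 0]
        if len(bg) == 0 or bg["fst"].isna().all():
            bg = track
        with np.errstate(invalid="ignore"):
            fst_q = float(np.nanquantile(bg["fst"].to_numpy(), support_quantile))
            het_q = float(np.nanquantile(bg["het_mf"].to_numpy(), support_quantile))

    # classify raw segments, then coalesce adjacent segments of equal
    # SLR status (extra changepoints inside a homogeneous region are
    # harmless splits, not region boundaries)
    raw_flags = []
    for start, end in zip(bounds[:-1], bounds[1:]):
        raw_flags.append(_is_slr_segment(track, start, end, fst_q, het_q))
    merged_bounds = [bounds[0]]
    merged_flags = []
    for (start, end), flag in zip(zip(bounds[:-1], bounds[1:]), raw_flags):
        if merged_flags and flag == merged_flags[-1]:
            merged_bounds[-1] = end
        else:
            merged_bounds.append(end)
            merged_flags.append(flag)

    rows = []
    classes = []
    for (start, end), is_slr in zip(
        zip(merged_bounds[:-1], merged_bounds[1:]), merged_flags
    ):
        mid = (track["start"].to_numpy() + track["end"].to_numpy()) / 2
        sel = (mid >= start) & (mid < end)
        if not sel.any():  # very short segment: use overlapping windows
            sel = (track["end"].to_numpy() > start) & (track["start"].to_numpy() < end)
        seg = track[sel]
        mean_fst = float(np.nanmean(seg["fst"])) if sel.any() else np.nan
        mean_het = float(np.nanmean(seg["het_mf"])) if sel.any() else np.nan
        max_nlp = float(np.nanmax(seg["neglog10p_max"])) if sel.any() and seg["neglog10p_max"].notna().any() else np.nan
        n_sig = float(np.nansum(seg["n_significant"])) if sel.any() else 0.0
        classes.append("SLR" if is_slr else None)
        rows.append(
            {"start": start, "end": end, "mean_fst": mean_fst,
             "mean_het_mf": mean_het, "max_neglog10p": max_nlp, "n_significant": n_sig}
        )
    # PAR: non-SLR segment adjacent to an SLR segment
    final = []
    for i, cls in enumerate(classes):
        if cls == "SLR":
            final.append("SLR")
        elif (i > 0 and classes[i - 1] == "SLR") or (
            i + 1 < len(classes) and classes[i + 1] == "SLR"
        ):
            final.append("PAR")
        else:
            final.append("undetermined")
    support = pd.DataFrame(rows)
    support["class"] = final
    segments = [(r["start"], r["end"], c) for r, c in zip(rows, final)]
    return RegionCall(chrom=chrom, segments=segments, support=support)


def region_fractions(call: RegionCall, chrom_length: int) -> dict[str, float]:
    """Percentage of the chromosome occupied by each region class."""
    out: dict[str, float] = {}
    for start, end, cls in call.segments:
        out[cls] = out.get(cls, 0.0) + (end - start)
    return {cls: 100.0 * length / chrom_length for cls, length in out.items()}


def tip_gc_regions(
    gc_tracks: dict[str, pd.DataFrame],
    max_cpts: int = 3,
    penalty="mbic",
) -> tuple[pd.DataFrame, float]:
    """Detect chromosome-tip GC spikes by change-point analysis.

    For each chromosome, segments the GC track and reports a terminal
    segment (either end) whose mean GC exceeds the chromosome mean.
    Returns (BED-like frame of tip regions, fraction of the summed
    genome length they occupy).  Chromosomes shorter than two windows
    are skipped.
    """
    rows = []
    genome_len = 0
    tip_len = 0
    for chrom, track in gc_tracks.items():
        length = int(track["end"].max())
        genome_len += length
        gc = track["gc"].to_numpy()
        if len(gc) < 4:
            continue
        cps = binseg_meanvar(gc, max_cpts=max_cpts, penalty=penalty)
        chrom_mean = float(np.nanmean(gc))
        segs = cps.segments()
        if len(segs) < 2:
            continue
        for si in (0, len(segs) - 1):
            s, e = segs[si]
            seg_mean = float(np.nanmean(gc[s:e]))
            if seg_mean > chrom_mean:
                start_bp = int(track["start"].iloc[s])
                end_bp = int(track["end"].iloc[e - 1])
                rows.append(
                    {"chrom": chrom, "start": start_bp, "end": end_bp,
                     "mean_gc": seg_mean, "chrom_mean_gc": chrom_mean}
                )
                tip_len += end_bp - start_bp
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_gc", "chrom_mean_gc"])
    fraction = tip_len / genome_len if genome_len else 0.0
    return bed, fraction
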