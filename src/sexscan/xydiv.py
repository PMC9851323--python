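"""X-Y coding divergence via Nei-Gojobori (1986) Ka/Ks.

In a young XY system the Y has not degenerated: X and Y haplotypes can
be reconstructed directly from genes in which every variable CDS site is
heterozygous in all (non-reversed) males and homozygous in all females.
At such sites the female (homozygous) allele is the X allele and the
male-specific alternate allele is the Y allele.  Synonymous divergence
Ks between the reconstructed X and Y CDS then dates the recombination
arrest: values of a fraction of a percent indicate a very young region
or continued rare exchange.

Codon counting follows NG86: potential synonymous/nonsynonymous site
fractions per codon averaged over the two sequences, observed
differences averaged over all mutational pathways for multi-difference
codons (pathways through stop codons excluded by default), and the
Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p) applied to both
proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .popstats import GenotypeMatrix, SexLabels, HET, HOM_REF, HOM_ALT, MISSING
from .segment import RegionCall

logger = logging.getLogger(__name__)

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(s))


def _translate(codon: str) -> str | None:
    """Amino acid, '*' for stop, None for ambiguous codons."""
    if codon in _STOPS:
        return "*"
    return _CODON_TABLE.get(codon)


@dataclass
class XYGene:
    """Reconstructed X and Y CDS for one fully sex-linked gene."""

    gene_id: str
    x_cds: str
    y_cds: str
    n_variable_sites: int

    def __post_init__(self) -> None:
        if len(self.x_cds) != len(self.y_cds):
            raise ValueError("X and Y CDS lengths differ")
        if len(self.x_cds) % 3:
            raise ValueError("CDS length is not a multiple of 3")


@dataclass
class KaKsResult:
    """NG86 quantities for one X/Y pair.  Ka/Ks are NaN when the
    Jukes-Cantor correction is undefined ((4/3)p >= 1)."""

    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ka: float
    Ks: float


def _syn_fraction(codon: str) -> tuple[float, float]:
    """Potential (synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    aa = _translate(codon)
    s = 0.0
    for i in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if _translate(mut) == aa and aa != "*":
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _pathway_diffs(c1: str, c2: str, count_stop_pathways: bool = False):
    """Mean (syn, nonsyn) differences between two codons over all
    mutational pathways; pathways through stop codons are excluded
    unless none remain or ``count_stop_pathways`` is set."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        ok = True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if not count_stop_pathways and (_translate(nxt) == "*" or _translate(cur) == "*"):
                ok = False
                break
            if _translate(cur) == _translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        if not count_stop_pathways:
            return _pathway_diffs(c1, c2, count_stop_pathways=True)
        return 0.0, float(len(diff_pos))
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


def _jc(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return float("nan")
    return -0.75 * float(np.log(arg))


def ng86_ka_ks(x_cds: str, y_cds: str, count_stop_pathways: bool = False) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks between two aligned in-frame CDSs.

    Codons containing a missing/ambiguous base in either sequence are
    excluded entirely.  Raises on length mismatch, frame violation or an
    internal stop codon in either sequence.
    """
    x_cds, y_cds = x_cds.upper(), y_cds.upper()
    if len(x_cds) != len(y_cds):
        raise ValueError("sequences must be the same length")
    if len(x_cds) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    S = N = Sd = Nd = 0.0
    for k in range(0, len(x_cds), 3):
        cx, cy = x_cds[k:k + 3], y_cds[k:k + 3]
        if any(b not in _BASES for b in cx + cy):
            continue
        if _translate(cx) == "*" or _translate(cy) == "*":
            if k + 3 < len(x_cds):
                raise ValueError(f"internal stop codon at position {k}")
            continue  # terminal stop: excluded from counting
        sx, nx = _syn_fraction(cx)
        sy, ny = _syn_fraction(cy)
        S += (sx + sy) / 2
        N += (nx + ny) / 2
        sd, nd = _pathway_diffs(cx, cy, count_stop_pathways)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else float("nan")
    pn = Nd / N if N > 0 else float("nan")
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, Ka=_jc(pn), Ks=_jc(ps))


def _gene_cds_intervals(db, gene_id: str):
    """Sorted (start0, end0) CDS intervals and strand for a gene (gffutils db)."""
    gene = db[gene_id]
    cds = []
    for f in db.children(gene, featuretype="CDS", order_by="start"):
        cds.append((f.start - 1, f.end))  # GFF 1-based inclusive -> 0-based half-open
    return cds, gene.strand


def select_fully_sexlinked_genes(
    gm: GenotypeMatrix,
    sexes: SexLabels,
    db,
    regions: RegionCall | None = None,
) -> list[str]:
    """Genes in which every variable CDS site is het in all included
    males and homozygous (for the same allele) in all included females.

    ``db`` is a gffutils FeatureDB.  Genes with no variable CDS site
    cannot be assessed and are excluded (logged).  When ``regions`` is
    given, only genes inside SLR segments are considered.
    """
    sexes.validate_against(gm)
    males = gm.sample_index(sexes.ids("M"))
    females = gm.sample_index(sexes.ids("F"))
    slr = (
        [(s, e) for s, e, c in regions.segments if c == "SLR"]
        if regions is not None
        else None
    )
    selected = []
    n_novar = 0
    for gene in db.features_of_type("gene"):
        if gene.seqid != gm.chrom:
            continue
        g0, g1 = gene.start - 1, gene.end
        if slr is not None and not any(s <= g0 and g1 <= e for s, e in slr):
            continue
        cds, _ = _gene_cds_intervals(db, gene.id)
        site_mask = np.zeros(gm.n_sites, dtype=bool)
        for s, e in cds:
            lo = np.searchsorted(gm.positions - 1, s, side="left")
            hi = np.searchsorted(gm.positions - 1, e, side="left")
            site_mask[lo:hi] = True
        idx = np.flatnonzero(site_mask)
        if len(idx) == 0:
            n_novar += 1
            continue
        sub_m = gm.codes[np.ix_(idx, males)]
        sub_f = gm.codes[np.ix_(idx, females)]
        males_all_het = (sub_m == HET).all()
        females_ref = (sub_f == HOM_REF).all(axis=1)
        females_alt = (sub_f == HOM_ALT).all(axis=1)
        if males_all_het and (females_ref | females_alt).all():
            selected.append(gene.id)
    if n_novar:
        logger.info(
            "select_fully_sexlinked_genes: %d genes with no variable CDS site excluded",
            n_novar,
        )
    return selected


def build_xy_haplotypes(
    gene_id: str,
    gm: GenotypeMatrix,
    fasta,
    db,
    sexes: SexLabels,
) -> XYGene:
    """Reconstruct X and Y CDS for a fully sex-linked gene.

    X = reference CDS with the female-homozygous allele substituted at
    each variable site; Y = X with the male-specific alternate allele.
    Minus-strand genes are reverse-complemented (substituted bases
    complemented).  Raises if any included female is heterozygous at a
    used site.
    """
    females = gm.sample_index(sexes.ids("F"))
    cds, strand = _gene_cds_intervals(db, gene_id)
    chrom_seq = str(fasta[gm.chrom][:]).upper()
    x_parts, y_parts = [], []
    n_var = 0
    for s, e in cds:
        x = list(chrom_seq[s:e])
        y = list(chrom_seq[s:e])
        lo = np.searchsorted(gm.positions - 1, s, side="left")
        hi = np.searchsorted(gm.positions - 1, e, side="left")
        for i in range(lo, hi):
            fcodes = gm.codes[i, females]
            fcodes = fcodes[fcodes != MISSING]
            if (fcodes == HET).any():
                raise ValueError(
                    f"female heterozygous at {gm.chrom}:{gm.positions[i]} in gene {gene_id}"
                )
            x_allele = str(gm.alt[i]) if (fcodes == HOM_ALT).all() and len(fcodes) else str(gm.ref[i])
            y_allele = str(gm.ref[i]) if x_allele == str(gm.alt[i]) else str(gm.alt[i])
            off = int(gm.positions[i] - 1 - s)
            x[off] = x_allele
            y[off] = y_allele
            n_var += 1
        x_parts.append("".join(x))
        y_parts.append("".join(y))
    # exons concatenated in genomic order, then oriented by strand
    x_seq = "".join(x_parts)
    y_seq = "".join(y_parts)
    if strand == "-":
        x_seq, y_seq = _revcomp(x_seq), _revcomp(y_seq)
    for k in range(0, len(x_seq) - 3, 3):
        if _translate(x_seq[k:k + 3]) == "*":
            raise ValueError(f"internal stop codon in X CDS of {gene_id}")
    return XYGene(gene_id=gene_id, x_cds=x_seq, y_cds=y_seq, n_variable_sites=n_var)


def slr_divergence_summary(genes: list[XYGene], **ng86_kwargs):
    """Unweighted per-gene mean Ka and Ks across reconstructed X/Y pairs.

    Returns (mean_ka, mean_ks, per-gene DataFrame); NaN per-gene values
    (undefined Jukes-Cantor correction) are skipped in the means.
    """
    rows = []
    for g in genes:
        r = ng86_ka_ks(g.x_cds, g.y_cds, **ng86_kwargs)
        rows.append(
            {"gene": g.gene_id, "n_variable_sites": g.n_variable_sites,
             "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
             "ps": r.ps, "pn": r.pn, "Ka": r.Ka, "Ks": r.Ks}
        )
    table = pd.DataFrame(rows)
    if len(table) == 0:
        return float("nan"), float("nan"), table
    return float(np.nanmean(table["Ka"])), float(np.nanmean(table["Ks"])), table


def load_gff(path):
    """Build an in-memory gffutils FeatureDB from a GFF3 file."""
    import gffutils

    return gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
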