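"""Synthetic populations, RAD marker tables and expression matrices.

Generates diploid cohorts with the statistical structure the scan
assumes: one chromosome carrying pseudoautosomal region(s) (PAR) and a
young sex-linked region (SLR) where males are heterozygous X/Y at fixed
difference sites while females are homozygous X/X; Hardy-Weinberg
background polymorphism everywhere; optional sex-reversed individuals
(phenotypic label opposite to the genotypic sex), optional X-Y "leak"
(a terminal SLR block recombined onto the X in some males, eroding the
association), optional Y-degenerate sub-interval halving male coverage,
and per-individual Poisson sequencing depth.

Every simulation emits a machine-readable truth record so downstream
parameter-recovery tests can compare calls against the planted state.
Outputs round-trip through the VCF reader losslessly and are
byte-identical for identical seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .popstats import (
    GenotypeMatrix,
    SexLabels,
    HOM_REF,
    HET,
    HOM_ALT,
)

_BASES = np.array(list("ACGT"))

# mean 2p(1-p) for p ~ Uniform(0.05, 0.95); converts the per-bp expected
# heterozygosity `theta` into a per-bp density of background SNPs
_MEAN_2PQ = 0.365


@dataclass
class SimConfig:
    """Parameters of the synthetic sex-chromosome population.

    Defaults mirror the larger of the two study cohorts (30 males, 29
    females) on a 26.1 Mb chromosome whose first 1.28 Mb (4.9%) is the
    PAR and the remainder the SLR.  ``theta`` is the per-bp expected
    background heterozygosity; with allele frequencies uniform on
    [0.05, 0.95] the implied SNP density is theta / 0.365 per bp
    (~1 SNP/kb at the default).  ``xy_divergence`` is the per-bp
    probability of a fixed X/Y difference inside the SLR.
    """

    n_males: int = 30
    n_females: int = 29
    chrom_length: int = 26_100_000
    par_intervals: list = field(default_factory=lambda: [(0, 1_280_000)])
    slr_interval: tuple = (1_280_000, 26_100_000)
    theta: float = 3.65e-4
    xy_divergence: float = 1e-4
    reversal_rate: float = 0.0
    leak_rate: float = 0.0
    mean_depth: float = 20.0
    degenerate_fraction: float = 0.0
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chromosome length must be positive")
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("need at least one individual of each sex")
        for r in ("theta", "xy_divergence", "reversal_rate", "leak_rate",
                  "degenerate_fraction"):
            v = getattr(self, r)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{r} must be in [0, 1], got {v}")
        ivals = [tuple(i) for i in self.par_intervals]
        if self.slr_interval is not None:
            ivals.append(tuple(self.slr_interval))
        for s, e in ivals:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError(f"interval [{s}, {e}) outside chromosome")
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("PAR/SLR intervals overlap")


@dataclass
class SimTruth:
    """Planted ground truth: region boundaries, reversed individuals,
    per-site classes and the X-Y divergence actually used."""

    boundaries: list
    reversed_individuals: list
    per_site_class: list
    xy_divergence_used: float
    leak_blocks: dict
    degenerate_interval: tuple | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_jsonable)
            fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def _hwe_genotypes(rng, p, n_ind):
    """Hardy-Weinberg genotype codes for one site x n individuals."""
    u = rng.random(n_ind)
    g = np.full(n_ind, HOM_REF, dtype=np.int8)
    g[u < p * p] = HOM_ALT
    both = (u >= p * p) & (u < p * p + 2 * p * (1 - p))
    g[both] = HET
    return g


def simulate_sexchrom_population(config: SimConfig):
    """Simulate the cohort and return (GenotypeMatrix, SexLabels, depth, truth).

    Inside the SLR, every fixed X/Y difference site is het in each
    genotypic male (unless a leak block removed its Y haplotype there)
    and hom-ref in each genotypic female; reversed individuals carry the
    opposite pattern because their genotypic sex is flipped relative to
    the phenotypic label.  Background sites are HWE draws with allele
    frequency ~ Uniform(0.05, 0.95).  Depth per individual per 50 kb bin
    is Poisson(mean_depth), halved for males over the Y-degenerate
    sub-interval if one is configured.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_males + config.n_females
    sample_ids = [f"M{i+1:03d}" for i in range(config.n_males)] + [
        f"F{i+1:03d}" for i in range(config.n_females)
    ]
    pheno = np.array(["M"] * config.n_males + ["F"] * config.n_females)

    reversed_mask = rng.random(n) < config.reversal_rate
    genotypic_male = (pheno == "M") ^ reversed_mask

    # background site positions: Poisson process over the chromosome
    density = config.theta / _MEAN_2PQ
    n_bg = rng.poisson(density * config.chrom_length)
    bg_pos = np.sort(rng.integers(0, config.chrom_length, size=n_bg))

    # fixed X/Y difference sites inside the SLR
    slr = config.slr_interval
    if slr is not None and config.xy_divergence > 0:
        slr_len = slr[1] - slr[0]
        n_fix = rng.poisson(config.xy_divergence * slr_len)
        fix_pos = np.sort(rng.integers(slr[0], slr[1], size=n_fix))
    else:
        fix_pos = np.array([], dtype=np.int64)

    pos0 = np.concatenate([bg_pos, fix_pos])
    klass = np.array(["background"] * len(bg_pos) + ["slr_fixed"] * len(fix_pos))
    order = np.argsort(pos0, kind="stable")
    pos0, klass = pos0[order], klass[order]
    # drop duplicate coordinates (keep first)
    uniq = np.concatenate([[True], np.diff(pos0) > 0])
    pos0, klass = pos0[uniq], klass[uniq]

    n_sites = len(pos0)
    codes = np.empty((n_sites, n), dtype=np.int8)
    freqs = rng.uniform(0.05, 0.95, size=n_sites)
    is_fix = klass == "slr_fixed"
    for i in range(n_sites):
        if is_fix[i]:
            codes[i] = np.where(genotypic_male, HET, HOM_REF)
        else:
            codes[i] = _hwe_genotypes(rng, freqs[i], n)

    # leak: some genotypic males lose the Y haplotype over a terminal SLR block
    leak_blocks: dict[str, tuple[int, int]] = {}
    if slr is not None and config.leak_rate > 0:
        for j in np.flatnonzero(genotypic_male):
            if rng.random() < config.leak_rate:
                b = int(rng.integers(slr[0], slr[1]))
                leak_blocks[sample_ids[j]] = (b, slr[1])
                in_block = is_fix & (pos0 >= b) & (pos0 < slr[1])
                codes[in_block, j] = HOM_REF

    # alleles: REF = X allele, ALT = Y allele (fixed sites) or arbitrary
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]

    gm = GenotypeMatrix(
        chrom=config.chrom,
        positions=pos0 + 1,
        ref=ref,
        alt=alt,
        codes=codes,
        samples=sample_ids,
    )
    sexes = SexLabels(sex=dict(zip(sample_ids, pheno)))

    # depth per individual per 50 kb bin
    bin_size = 50_000
    starts = np.arange(0, config.chrom_length, bin_size, dtype=np.int64)
    ends = np.minimum(starts + bin_size, config.chrom_length)
    degen = None
    if config.degenerate_fraction > 0 and slr is not None:
        dlen = int(config.degenerate_fraction * (slr[1] - slr[0]))
        degen = (slr[1] - dlen, slr[1])
    rows = []
    mids = (starts + ends) // 2
    for j, sid in enumerate(sample_ids):
        lam = np.full(len(starts), config.mean_depth)
        if degen is not None and genotypic_male[j]:
            lam[(mids >= degen[0]) & (mids < degen[1])] = config.mean_depth / 2
        d = rng.poisson(lam)
        rows.append(
            pd.DataFrame(
                {"chrom": config.chrom, "start": starts, "end": ends,
                 "individual": sid, "depth": d}
            )
        )
    depth = pd.concat(rows, ignore_index=True)

    boundaries = []
    segs = sorted(
        [(tuple(i), "PAR") for i in config.par_intervals]
        + ([(tuple(slr), "SLR")] if slr is not None else [])
    )
    for (s1, e1), c1 in segs:
        for (s2, e2), c2 in segs:
            if s2 == e1:
                boundaries.append((int(e1), c1, c2))
    boundaries.sort()

    truth = SimTruth(
        boundaries=boundaries,
        reversed_individuals=[sample_ids[j] for j in np.flatnonzero(reversed_mask)],
        per_site_class=list(klass),
        xy_divergence_used=config.xy_divergence,
        leak_blocks=leak_blocks,
        degenerate_interval=degen,
    )
    return gm, sexes, depth, truth


def write_vcf(gm: GenotypeMatrix, path, contig_length: int | None = None) -> None:
    """Write a minimal VCF v4.2 with GT fields (deterministic bytes)."""
    code_to_gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_length is not None:
            fh.write(f"##contig=<ID={gm.chrom},length={contig_length}>\n")
        else:
            fh.write(f"##contig=<ID={gm.chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            gts = "\t".join(code_to_gt[int(c)] for c in gm.codes[i])
            fh.write(
                f"{gm.chrom}\t{gm.positions[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_population(outdir, gm, sexes, depth, truth, config: SimConfig) -> dict:
    """Write VCF, sex TSV, depth TSV and truth BED+JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "sex": outdir / "sex.tsv",
        "depth": outdir / "depth.tsv",
        "truth_json": outdir / "truth.json",
        "truth_bed": outdir / "truth.bed",
    }
    write_vcf(gm, paths["vcf"], contig_length=config.chrom_length)
    sexes.to_tsv(paths["sex"])
    depth.to_csv(paths["depth"], sep="\t", index=False)
    truth.to_json(paths["truth_json"])
    with open(paths["truth_bed"], "w") as fh:
        for s, e in config.par_intervals:
            fh.write(f"{config.chrom}\t{s}\t{e}\tPAR\n")
        if config.slr_interval is not None:
            s, e = config.slr_interval
            fh.write(f"{config.chrom}\t{s}\t{e}\tSLR\n")
    return {k: str(v) for k, v in paths.items()}


def simulate_expression_matrix(
    n_genes: int = 1000,
    tissues=("brain", "kidney", "testis", "ovary", "pouch", "skin"),
    n_specific: int = 20,
    fold: float = 20.0,
    seed: int = 0,
    sigma: float = 0.25,
):
    """Expression matrix (genes x tissues, TPM-like) with planted
    tissue-specific genes.

    Background is log-normal around a per-gene baseline; each planted
    gene has one tissue boosted ``fold``-fold.  Returns (matrix, truth)
    where truth maps each planted gene to its tissue.
    """
    tissues = list(tissues)
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if n_specific * len(tissues) > n_genes:
        raise ValueError("more planted specific genes than genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i+1:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=3.0, sigma=1.0, size=n_genes)
    expr = base[:, None] * rng.lognormal(0.0, sigma, size=(n_genes, len(tissues)))
    truth_rows = []
    gidx = rng.permutation(n_genes)[: n_specific * len(tissues)]
    for k, g in enumerate(gidx):
        t = k % len(tissues)
        expr[g, t] *= fold
        truth_rows.append({"gene": genes[g], "tissue": tissues[t]})
    mat = pd.DataFrame(expr, index=genes, columns=tissues)
    truth = pd.DataFrame(truth_rows, columns=["gene", "tissue"])
    return mat, truth


def simulate_rad_markers(
    n_markers: int = 1000,
    n_m: int = 20,
    n_f: int = 20,
    n_sex_linked: int = 10,
    mean_depth: float = 10.0,
    presence_prob: float = 0.9,
    seed: int = 0,
    linked_sex: str = "M",
):
    """Marker x individual depth matrix with planted sex-linked markers.

    Sex-linked markers get Poisson(mean_depth) reads only in the linked
    sex (zero elsewhere); background markers are present with
    ``presence_prob`` independently of sex.  Returns (depth matrix
    DataFrame, SexLabels, truth list of sex-linked marker ids).
    """
    if n_sex_linked > n_markers:
        raise ValueError("n_sex_linked exceeds n_markers")
    rng = np.random.default_rng(seed)
    ids = [f"M{i+1:03d}" for i in range(n_m)] + [f"F{i+1:03d}" for i in range(n_f)]
    is_m = np.array([True] * n_m + [False] * n_f)
    markers = [f"mk{i+1:05d}" for i in range(n_markers)]
    depth = rng.poisson(mean_depth, size=(n_markers, n_m + n_f))
    present = rng.random((n_markers, n_m + n_f)) < presence_prob
    depth = depth * present
    linked = rng.permutation(n_markers)[:n_sex_linked]
    carrier = is_m if linked_sex == "M" else ~is_m
    for m in linked:
        depth[m] = np.where(carrier, rng.poisson(mean_depth, size=n_m + n_f), 0)
    mat = pd.DataFrame(depth, index=markers, columns=ids)
    sexes = SexLabels(sex={i: ("M" if b else "F") for i, b in zip(ids, is_m)})
    truth = sorted(markers[m] for m in linked)
    return mat, sexes, truth


_STOPS = {"TAA", "TAG", "TGA"}


def simulate_sexlinked_genes(
    n_genes: int = 100,
    cds_len: int = 900,
    divergence: float = 0.002,
    n_males: int = 10,
    n_females: int = 10,
    seed: int = 0,
    intergenic: int = 500,
    minus_strand_fraction: float = 0.3,
    chrom: str = "chrSL",
):
    """Small synthetic genome + annotation with X/Y-diverged genes.

    Builds a single contig of ``n_genes`` single-exon CDSs separated by
    ``intergenic`` bp, plants X/Y differences uniformly over CDS
    positions at per-bp rate ``divergence`` (re-drawn if they would
    create a stop codon on either haplotype), and emits the genotype
    matrix (males het, females hom-ref at planted sites), sex labels,
    FASTA/GFF3 text, and per-gene truth.

    With uniform per-bp substitution the expected synonymous divergence
    per synonymous site equals ``divergence``, so the planted rate is
    directly comparable to the recovered mean Ks.
    """
    rng = np.random.default_rng(seed)
    if cds_len % 3:
        raise ValueError("cds_len must be a multiple of 3")
    seq = []
    genes = []  # (gene_id, start0, end0, strand)
    pos = intergenic
    genome_parts = [_BASES[rng.integers(0, 4, intergenic)]]
    for g in range(n_genes):
        # stop-free CDS in genome (plus) orientation for both strands:
        # generate codons avoiding stops in the reading frame of the gene
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        codons = []
        while len(codons) < cds_len // 3:
            c = "".join(_BASES[rng.integers(0, 4, 3)])
            if c not in _STOPS:
                codons.append(c)
        cds = "".join(codons)  # CDS in its own reading direction
        genome_seq = cds if strand == "+" else _revcomp(cds)
        genome_parts.append(np.array(list(genome_seq)))
        genes.append((f"gene{g+1:04d}", pos, pos + cds_len, strand))
        pos += cds_len
        genome_parts.append(_BASES[rng.integers(0, 4, intergenic)])
        pos += intergenic
    genome = np.concatenate(genome_parts)
    chrom_length = len(genome)

    # plant X/Y differences uniformly within CDSs
    ids = [f"M{i+1:03d}" for i in range(n_males)] + [f"F{i+1:03d}" for i in range(n_females)]
    is_m = np.array([True] * n_males + [False] * n_females)
    var_pos, var_ref, var_alt = [], [], []
    for gid, s, e, strand in genes:
        n_mut = rng.binomial(e - s, divergence)
        if n_mut == 0:
            continue
        sites = set()
        # track the accumulating Y haplotype so combinations of mutations
        # within one codon cannot create a stop either
        y_region = genome[s:e].copy()
        while len(sites) < n_mut:
            p0 = int(rng.integers(s, e))
            if p0 in sites:
                continue
            refb = genome[p0]
            altb = _BASES[(int(np.flatnonzero(_BASES == refb)[0]) + int(rng.integers(1, 4))) % 4]
            # reject substitutions creating a stop codon in the gene frame
            if _creates_stop(y_region, s, e, strand, p0, altb, offset=s):
                continue
            sites.add(p0)
            y_region[p0 - s] = altb
            var_pos.append(p0)
            var_ref.append(str(refb))
            var_alt.append(str(altb))
    order = np.argsort(var_pos)
    var_pos = np.array(var_pos, dtype=np.int64)[order]
    var_ref = np.array(var_ref)[order]
    var_alt = np.array(var_alt)[order]
    codes = np.where(is_m, HET, HOM_REF).astype(np.int8)
    codes = np.tile(codes, (len(var_pos), 1))
    gm = GenotypeMatrix(
        chrom=chrom, positions=var_pos + 1, ref=var_ref, alt=var_alt,
        codes=codes, samples=ids,
    )
    sexes = SexLabels(sex={i: ("M" if b else "F") for i, b in zip(ids, is_m)})
    fasta = f">{chrom}\n" + _wrap("".join(genome)) + "\n"
    gff_lines = ["##gff-version 3"]
    for gid, s, e, strand in genes:
        gff_lines.append(
            f"{chrom}\tsim\tgene\t{s+1}\t{e}\t.\t{strand}\t.\tID={gid}"
        )
        gff_lines.append(
            f"{chrom}\tsim\tmRNA\t{s+1}\t{e}\t.\t{strand}\t.\tID={gid}.t1;Parent={gid}"
        )
        gff_lines.append(
            f"{chrom}\tsim\tCDS\t{s+1}\t{e}\t.\t{strand}\t0\tID={gid}.cds;Parent={gid}.t1"
        )
    gff = "\n".join(gff_lines) + "\n"
    truth = pd.DataFrame(
        [{"gene": gid, "start": s, "end": e, "strand": strand} for gid, s, e, strand in genes]
    )
    return gm, sexes, fasta, gff, truth, chrom_length


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def _wrap(s: str, width: int = 70) -> str:
    return "\n".join(s[i:i + width] for i in range(0, len(s), width))


def _creates_stop(seq, s, e, strand, p0, altb, offset: int = 0) -> bool:
    """Would substituting ``altb`` at genome position ``p0`` create a stop
    codon in the reading frame of the CDS [s, e) on ``strand``?  ``seq``
    is indexed at genome position minus ``offset`` (pass the gene-local
    slice with offset=s, or the whole genome with offset=0)."""
    if strand == "+":
        off = p0 - s
        c0 = p0 - off % 3 - offset
        codon = list(seq[c0:c0 + 3])
        codon[off % 3] = altb
        return "".join(codon) in _STOPS
    off = e - 1 - p0  # position in the reverse-complemented CDS
    c_start_rc = off - off % 3  # codon offset in RC coordinates
    # RC codon spans genome positions [e-1-c_start_rc-2, e-1-c_start_rc]
    lo = e - 1 - c_start_rc - 2
    codon = list(seq[lo - offset:lo - offset + 3])
    codon[p0 - lo] = altb
    return _revcomp("".join(codon)) in _STOPS
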