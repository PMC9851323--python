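"""Tests for X/Y haplotype reconstruction and NG86 Ka/Ks."""

import math
from itertools import permutations, product

import numpy as np
import pytest
from pyfaidx import Fasta

import sexscan as sx
from sexscan.popstats import HET, HOM_REF, HOM_ALT
from sexscan.xydiv import (
    load_gff, select_fully_sexlinked_genes, build_xy_haplotypes,
    _syn_fraction, _translate,
)
from conftest import make_gm, make_sexes


# ---------------------------------------------------------------- NG86 core

def test_identical_sequences_have_zero_divergence():
    r = sx.ng86_ka_ks("ATGGCTAAA", "ATGGCTAAA")
    assert r.Ka == 0.0 and r.Ks == 0.0
    assert r.Sd == 0.0 and r.Nd == 0.0


def test_fourfold_synonymous_toy_matches_hand_computation():
    # GGN is fourfold degenerate: one third-position change, S=5, N=10
    x = "GGA" * 5
    y = "GGA" * 4 + "GGG"
    r = sx.ng86_ka_ks(x, y)
    assert r.S == pytest.approx(5.0)
    assert r.N == pytest.approx(10.0)
    assert r.Sd == 1.0 and r.Nd == 0.0
    assert r.ps == pytest.approx(0.2)
    assert r.Ks == pytest.approx(-0.75 * math.log(1 - 4 / 3 * 0.2), abs=1e-12)
    assert r.Ks == pytest.approx(0.2326, abs=1e-4)
    assert r.Ka == 0.0


def _pathway_oracle(c1, c2):
    """Brute-force pathway enumeration of (Sd, Nd) for a codon pair,
    excluding pathways through stop codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if _translate(cur) == "*" or _translate(nxt) == "*":
                ok = False
                break
            sd, nd = (sd + 1, nd) if _translate(cur) == _translate(nxt) else (sd, nd + 1)
            cur = nxt
        if ok:
            results.append((sd, nd))
    return results


def test_multi_difference_codons_average_over_pathways():
    # TTT (Phe) vs GTA (Val): hand-checkable two-difference-plus case
    for c1, c2 in [("TTT", "GTA"), ("ATG", "GCC"), ("AAA", "AGG"), ("TGC", "AGA")]:
        oracle = _pathway_oracle(c1, c2)
        if not oracle:
            continue
        exp_sd = np.mean([r[0] for r in oracle])
        exp_nd = np.mean([r[1] for r in oracle])
        r = sx.ng86_ka_ks(c1 + "GGA", c2 + "GGA")  # pad to keep frame trivial
        assert r.Sd == pytest.approx(exp_sd, abs=1e-12)
        assert r.Nd == pytest.approx(exp_nd, abs=1e-12)


def test_ng86_is_symmetric(rng):
    bases = "ACGT"
    for _ in range(20):
        x = "".join(rng.choice(list(bases), 30))
        y = "".join(rng.choice(list(bases), 30))
        if any(_translate(x[i:i+3]) == "*" or _translate(y[i:i+3]) == "*"
               for i in range(0, 27, 3)):
            continue
        r1 = sx.ng86_ka_ks(x, y)
        r2 = sx.ng86_ka_ks(y, x)
        for f in ("S", "N", "Sd", "Nd"):
            assert getattr(r1, f) == pytest.approx(getattr(r2, f), abs=1e-12)


def test_third_position_fourfold_changes_are_never_nonsynonymous():
    fourfold = ["GG", "GC", "CC", "CG", "CT", "TC", "AC", "GT"]
    for pre in fourfold:
        for b1, b2 in product("ACGT", repeat=2):
            if b1 == b2:
                continue
            r = sx.ng86_ka_ks(pre + b1, pre + b2)
            assert r.Nd == 0.0


def test_ng86_agrees_with_independent_reference(rng):
    # cross-check against Biopython's NG86 on random stop-free pairs
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    def random_cds(n_codons, mutate_from=None, n_mut=0):
        while True:
            if mutate_from is None:
                s = "".join(rng.choice(list("ACGT"), n_codons * 3))
            else:
                s = list(mutate_from)
                for pos in rng.choice(len(s), size=n_mut, replace=False):
                    s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
                s = "".join(s)
            if all(_translate(s[i:i+3]) not in ("*", None) for i in range(0, len(s), 3)):
                return s

    checked = 0
    for _ in range(10):
        x = random_cds(20)
        y = random_cds(20, mutate_from=x, n_mut=int(rng.integers(1, 6)))
        r = sx.ng86_ka_ks(x, y)
        dn, ds = cal_dn_ds(CodonSeq(x), CodonSeq(y), method="NG86")
        if math.isnan(r.Ka) or math.isnan(r.Ks):
            continue
        assert r.Ka == pytest.approx(dn, abs=1e-3)
        assert r.Ks == pytest.approx(ds, abs=1e-3)
        checked += 1
    assert checked >= 5


def test_ng86_error_conditions():
    with pytest.raises(ValueError):
        sx.ng86_ka_ks("ATG", "ATGGGG")
    with pytest.raises(ValueError):
        sx.ng86_ka_ks("ATGG", "ATGG")
    with pytest.raises(ValueError):
        sx.ng86_ka_ks("TAAGGG", "TAAGGG")  # internal stop
    # saturated divergence: Jukes-Cantor undefined
    r = sx.ng86_ka_ks("GGA" * 3, "GGT" * 3)
    assert math.isnan(r.Ks) or r.Ks > 0


def test_ambiguous_codons_are_excluded():
    r = sx.ng86_ka_ks("GGANNNGGA", "GGGNNNGGA")
    assert r.S == pytest.approx(2.0)  # only the two unambiguous codons counted
    assert r.Sd == 1.0


# ------------------------------------------------------- gene selection

def _gene_fixture(tmp_path, divergence=0.01, n_genes=12, seed=7, **kw):
    gm, sexes, fasta_txt, gff_txt, truth, L = sx.simulate_sexlinked_genes(
        n_genes=n_genes, cds_len=300, divergence=divergence, seed=seed, **kw
    )
    fa_path = tmp_path / "g.fa"
    gff_path = tmp_path / "g.gff3"
    fa_path.write_text(fasta_txt)
    gff_path.write_text(gff_txt)
    return gm, sexes, Fasta(str(fa_path)), load_gff(gff_path), truth


def test_fully_sexlinked_genes_selected_and_partial_het_excluded(tmp_path):
    gm, sexes, fa, db, truth = _gene_fixture(tmp_path)
    genes = select_fully_sexlinked_genes(gm, sexes, db)
    assert genes  # genes with planted variants retained
    # break the pattern at one gene's first variant: one male homozygous
    g0 = genes[0]
    feat = db[g0]
    pos_in_gene = (gm.positions - 1 >= feat.start - 1) & (gm.positions - 1 < feat.end)
    i = int(np.flatnonzero(pos_in_gene)[0])
    gm.codes[i, 0] = HOM_REF  # male 0 no longer het
    assert g0 not in select_fully_sexlinked_genes(gm, sexes, db)


def test_xy_haplotypes_place_female_allele_on_x(tmp_path):
    gm, sexes, fa, db, truth = _gene_fixture(tmp_path)
    genes = select_fully_sexlinked_genes(gm, sexes, db)
    for g in genes[:3]:
        xy = build_xy_haplotypes(g, gm, fa, db, sexes)
        assert len(xy.x_cds) == len(xy.y_cds)
        assert len(xy.x_cds) % 3 == 0
        diffs = sum(a != b for a, b in zip(xy.x_cds, xy.y_cds))
        assert diffs == xy.n_variable_sites
    # females hom-ref here, so X equals the reference CDS
    strand = truth.set_index("gene").loc[genes[0], "strand"]
    s, e = truth.set_index("gene").loc[genes[0], ["start", "end"]]
    ref_cds = str(fa[gm.chrom][int(s):int(e)]).upper()
    xy0 = build_xy_haplotypes(genes[0], gm, fa, db, sexes)
    if strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref_cds = "".join(comp[b] for b in reversed(ref_cds))
    assert xy0.x_cds == ref_cds


def test_minus_strand_substitution_is_complemented(tmp_path):
    gm, sexes, fa, db, truth = _gene_fixture(
        tmp_path, minus_strand_fraction=1.0, seed=11
    )
    genes = select_fully_sexlinked_genes(gm, sexes, db)
    assert genes
    info = truth.set_index("gene")
    g = genes[0]
    xy = build_xy_haplotypes(g, gm, fa, db, sexes)
    s, e = int(info.loc[g, "start"]), int(info.loc[g, "end"])
    idx = np.flatnonzero((gm.positions - 1 >= s) & (gm.positions - 1 < e))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i in idx:
        off_rc = e - 1 - (gm.positions[i] - 1)  # position in the RC CDS
        assert xy.y_cds[off_rc] == comp[str(gm.alt[i])]
        assert xy.x_cds[off_rc] == comp[str(gm.ref[i])]


def test_female_heterozygous_site_is_a_contract_violation(tmp_path):
    gm, sexes, fa, db, truth = _gene_fixture(tmp_path)
    genes = select_fully_sexlinked_genes(gm, sexes, db)
    g = genes[0]
    feat = db[g]
    i = int(np.flatnonzero(
        (gm.positions - 1 >= feat.start - 1) & (gm.positions - 1 < feat.end)
    )[0])
    f_idx = gm.sample_index(sexes.ids("F"))
    gm.codes[i, f_idx[0]] = HET
    with pytest.raises(ValueError, match="heterozygous"):
        build_xy_haplotypes(g, gm, fa, db, sexes)


# ------------------------------------------------------- divergence summary

def test_planted_divergence_recovered_in_mean_ks(tmp_path):
    gm, sexes, fa, db, truth = _gene_fixture(
        tmp_path, divergence=0.01, n_genes=60, seed=12
    )
    genes = select_fully_sexlinked_genes(gm, sexes, db)
    xy = [build_xy_haplotypes(g, gm, fa, db, sexes) for g in genes]
    ka, ks, table = sx.slr_divergence_summary(xy)
    # uniform per-bp substitution: E[Ks] ~ E[Ka] ~ planted rate
    assert ks == pytest.approx(0.01, rel=0.35)
    assert len(table) == len(genes)


def test_summary_of_identical_pairs_is_zero_and_single_gene_identity():
    g1 = sx.XYGene(gene_id="a", x_cds="ATGGCT", y_cds="ATGGCT", n_variable_sites=0)
    ka, ks, t = sx.slr_divergence_summary([g1])
    assert ka == 0.0 and ks == 0.0
    g2 = sx.XYGene(gene_id="b", x_cds="GGA" * 5, y_cds="GGA" * 4 + "GGG",
                   n_variable_sites=1)
    ka2, ks2, t2 = sx.slr_divergence_summary([g2])
    assert ks2 == pytest.approx(t2["Ks"].iloc[0])
    ka3, ks3, t3 = sx.slr_divergence_summary([])
    assert math.isnan(ks3) and len(t3) == 0
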