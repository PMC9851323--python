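"""Unit and property tests for per-site and windowed population statistics."""

import numpy as np
import pandas as pd
import pytest

import sexscan as sx
from sexscan.popstats import (
    HOM_REF, HET, HOM_ALT, MISSING,
    WindowSpec, fst_per_site, fis_per_site, filter_sites,
    site_sex_pattern_flags, coverage_ratio, gc_windows,
)
from conftest import make_gm, make_sexes


# ---------------------------------------------------------------- VCF I/O

VCF_TOY = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0|1
chr1\t200\t.\tC\tT,G\t.\tPASS\t.\tGT\t0/1\t1/2
chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\t./.
"""


def test_read_vcf_drops_multiallelic_and_codes_phased_het(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(VCF_TOY)
    gm = sx.read_vcf(p)
    assert gm.n_sites == 2  # multiallelic site dropped
    assert list(gm.positions) == [100, 300]
    # phased 0|1 and unphased 0/1 both het
    assert gm.codes[0, 0] == HET and gm.codes[0, 1] == HET
    assert gm.codes[1, 0] == HOM_ALT and gm.codes[1, 1] == MISSING


def test_vcf_round_trip_is_lossless(tmp_path):
    cfg = sx.SimConfig(n_males=5, n_females=5, chrom_length=200_000,
                       par_intervals=[(0, 50_000)], slr_interval=(50_000, 200_000),
                       xy_divergence=1e-4, seed=11)
    gm, *_ = sx.simulate_sexchrom_population(cfg)
    path = tmp_path / "sim.vcf"
    sx.write_vcf(gm, path)
    back = sx.read_vcf(path)
    assert np.array_equal(back.positions, gm.positions)
    assert np.array_equal(back.codes, gm.codes)
    assert list(back.ref) == list(gm.ref) and list(back.alt) == list(gm.alt)
    assert back.samples == gm.samples


# ---------------------------------------------------------------- MAF filter

@pytest.mark.parametrize(
    "genotypes,kept",
    [
        # 1 alt allele among 40 -> MAF 0.025, removed
        ([HET] + [HOM_REF] * 19, False),
        # monomorphic -> removed
        ([HOM_REF] * 20, False),
        # 2 homAlt + 8 homRef among 10 -> MAF 4/20 = 0.2, kept
        ([HOM_ALT] * 2 + [HOM_REF] * 8, True),
    ],
)
def test_filter_sites_maf_threshold(genotypes, kept):
    gm = make_gm([genotypes])
    out = filter_sites(gm, maf_min=0.05)
    assert out.n_sites == (1 if kept else 0)


def test_filter_sites_excludes_missing_from_allele_counts():
    # 1 alt among 4 called alleles -> MAF 0.25 despite missing genotypes
    gm = make_gm([[HET, HOM_REF, MISSING, MISSING]])
    assert filter_sites(gm, maf_min=0.05).n_sites == 1


# ---------------------------------------------------------------- F_IS

def test_fis_hand_computed_values():
    # 8 het + 2 homRef: p=0.4 alt, He=0.48, Ho=0.8, F_IS=1-0.8/0.48=-2/3
    gm = make_gm([[HET] * 8 + [HOM_REF] * 2])
    r = fis_per_site(gm)
    assert r["ho"][0] == pytest.approx(0.8)
    assert r["he"][0] == pytest.approx(0.48)
    assert r["fis"][0] == pytest.approx(-2.0 / 3.0, abs=1e-12)


def test_fis_extremes():
    all_het = fis_per_site(make_gm([[HET] * 10]))
    assert all_het["fis"][0] == pytest.approx(-1.0)  # Ho=1, He=0.5
    all_hom = fis_per_site(make_gm([[HOM_REF] * 5 + [HOM_ALT] * 5]))
    assert all_hom["fis"][0] == pytest.approx(1.0)  # Ho=0
    mono = fis_per_site(make_gm([[HOM_REF] * 10]))
    assert np.isnan(mono["fis"][0])  # He=0 -> missing


# ---------------------------------------------------------------- WC F_ST

def _wc_fst_bruteforce(male_codes, female_codes):
    """Independent scalar evaluation of the Weir-Cockerham (1984) a/(a+b+c)
    estimator for two populations at one site."""
    import math
    groups = [male_codes, female_codes]
    r = 2
    n = [len(g) for g in groups]
    p = [sum(g) / (2 * len(g)) for g in groups]
    h = [sum(1 for x in g if x == 1) / len(g) for g in groups]
    nbar = sum(n) / r
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c) if (a + b + c) != 0 else math.nan


def test_fst_identical_distributions_is_nonpositive():
    row = [HET] * 5 + [HOM_REF] * 5
    gm = make_gm([row + row])
    sexes = make_sexes(10, 10)
    fst = fst_per_site(gm, sexes)["fst"][0]
    assert fst <= 0


def test_fst_fixed_difference_is_one():
    gm = make_gm([[HOM_REF] * 10 + [HOM_ALT] * 10])
    sexes = make_sexes(10, 10)
    assert fst_per_site(gm, sexes)["fst"][0] == pytest.approx(1.0)


def test_fst_matches_bruteforce_on_males_het_females_homref():
    male = [HET] * 10
    female = [HOM_REF] * 10
    gm = make_gm([male + female])
    sexes = make_sexes(10, 10)
    expected = _wc_fst_bruteforce(male, female)
    assert fst_per_site(gm, sexes)["fst"][0] == pytest.approx(expected, abs=1e-12)


def test_fst_matches_bruteforce_on_random_toys(rng):
    for _ in range(25):
        nm, nf = rng.integers(2, 12, size=2)
        male = list(rng.integers(0, 3, size=nm))
        female = list(rng.integers(0, 3, size=nf))
        if len(set(male + female)) == 1:
            continue  # monomorphic
        gm = make_gm([male + female])
        sexes = make_sexes(nm, nf)
        got = fst_per_site(gm, sexes)["fst"][0]
        exp = _wc_fst_bruteforce(male, female)
        if np.isnan(exp):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(exp, abs=1e-12)


def test_fst_invariant_and_classes_swap_under_label_exchange(rng):
    codes = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
    gm = make_gm(codes)
    sexes = make_sexes(8, 12)
    swapped = sx.SexLabels(
        sex={k: ("F" if v == "M" else "M") for k, v in sexes.sex.items()}
    )
    f1 = fst_per_site(gm, sexes)["fst"]
    f2 = fst_per_site(gm, swapped)["fst"]
    assert np.allclose(f1, f2, equal_nan=True)
    m = gm.sample_index(sexes.ids("M")); f = gm.sample_index(sexes.ids("F"))
    mf1, fm1 = site_sex_pattern_flags(codes, m, f)
    mf2, fm2 = site_sex_pattern_flags(codes, f, m)
    assert np.array_equal(mf1, fm2) and np.array_equal(fm1, mf2)


# ---------------------------------------------------------------- windows

def test_nonoverlapping_windows_partition_sites():
    spec = WindowSpec(size=100, step=100)
    w = spec.windows(950)
    assert w[0].tolist() == [0, 100] and w[-1].tolist() == [900, 950]
    assert all(a[1] == b[0] for a, b in zip(w, w[1:]))


def test_overlapping_windows_double_count_sites():
    gm = make_gm([[HET, HOM_REF]] * 4, positions=[10, 60, 110, 160])
    spec = WindowSpec(size=100, step=50)
    dens = sx.snp_density(gm, spec, 200)["snp_density"]
    assert dens.sum() > gm.n_sites  # interior sites counted twice


def test_window_spec_validation():
    with pytest.raises(ValueError):
        WindowSpec(size=100, step=200)
    with pytest.raises(ValueError):
        WindowSpec(size=0, step=0)


# ---------------------------------------------------------------- het classes

def test_slr_fixed_sites_counted_in_male_het_class():
    cfg = sx.SimConfig(n_males=10, n_females=10, chrom_length=500_000,
                       par_intervals=[], slr_interval=(0, 500_000),
                       theta=0.0, xy_divergence=2e-4, seed=5)
    gm, sexes, _, truth = sx.simulate_sexchrom_population(cfg)
    track = sx.sex_het_site_classes(gm, sexes, WindowSpec(50_000, 50_000), 500_000)
    assert track["het_mf"].sum() == truth.per_site_class.count("slr_fixed")
    assert track["het_fm"].sum() == 0


def test_het_classes_require_both_sexes():
    gm = make_gm([[HET] * 4])
    sexes = sx.SexLabels(sex={f"s{i}": "F" for i in range(4)})
    with pytest.raises(ValueError):
        sx.sex_het_site_classes(gm, sexes, WindowSpec(100, 100), 1000)


# ---------------------------------------------------------------- coverage

def _depth_frame(vals_m, vals_f, bin_size=100):
    rows = []
    for ind, vals in [("m1", vals_m), ("f1", vals_f)]:
        for i, v in enumerate(vals):
            rows.append({"chrom": "chr1", "start": i * bin_size,
                         "end": (i + 1) * bin_size, "individual": ind, "depth": v})
    return pd.DataFrame(rows)


def test_coverage_ratio_equal_depth_is_one():
    depth = _depth_frame([10] * 10, [20] * 10)
    sexes = sx.SexLabels(sex={"m1": "M", "f1": "F"})
    track = coverage_ratio(depth, sexes, WindowSpec(100, 100), 1000)
    assert np.allclose(track["cov_ratio"], 1.0)  # normalization removes scale


def test_coverage_ratio_degenerate_y_is_half():
    # male depth halves over the last 2 bins (degenerate Y): ratio ~ 0.5
    depth = _depth_frame([10] * 8 + [5, 5], [10] * 10)
    sexes = sx.SexLabels(sex={"m1": "M", "f1": "F"})
    track = coverage_ratio(depth, sexes, WindowSpec(100, 100), 1000)
    assert np.allclose(track["cov_ratio"][:8], 1.0)
    assert np.allclose(track["cov_ratio"][8:], 0.5)


def test_coverage_ratio_zero_female_depth_missing():
    depth = _depth_frame([10] * 5, [10, 10, 0, 10, 10], bin_size=100)
    sexes = sx.SexLabels(sex={"m1": "M", "f1": "F"})
    track = coverage_ratio(depth, sexes, WindowSpec(100, 100), 500)
    assert np.isnan(track["cov_ratio"][2])


# ---------------------------------------------------------------- GC

def test_gc_windows_hand_counts(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">chr1\n" + "ACGT" * 25 + "GGGGGGGGGGGGGGGGGGGGCCCCCCCCCCCCCCCCCCCC"
                  + "N" * 40 + "\n")
    spec = WindowSpec(size=40, step=40)
    track = gc_windows(fa, spec, "chr1")
    assert track["gc"][0] == pytest.approx(0.5)       # ACGT repeats
    assert track["gc"][2] == pytest.approx(30 / 40)   # 5x ACGT + 20 G, by hand
    assert track["gc"][3] == pytest.approx(1.0)       # 20 C + 20 N: Ns ignored
    assert np.isnan(track["gc"][4])                   # all-N window
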