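"""Per-site and windowed statistics: F_IS, between-sex F_ST and the
sex-patterned heterozygosity classes that mark a young sex-linked region."""

import numpy as np
import sexscan as sx

cfg = sx.SimConfig(n_males=20, n_females=20, chrom_length=3_000_000,
                   par_intervals=[(0, 1_000_000)],
                   slr_interval=(1_000_000, 3_000_000),
                   xy_divergence=2e-4, seed=2)
gm, sexes, depth, truth = sx.simulate_sexchrom_population(cfg)
gm = sx.filter_sites(gm, maf_min=0.05)

fis = sx.fis_per_site(gm)
fixed = np.isin(gm.positions, [p for p, k in zip(
    sx.simulate_sexchrom_population(cfg)[0].positions, truth.per_site_class)
    if k == "slr_fixed"])
print(f"mean F_IS at background sites: {fis.loc[~fixed, 'fis'].mean():+.3f}")
print(f"mean F_IS at fixed X/Y sites:  {fis.loc[fixed, 'fis'].mean():+.3f}  "
      "(strongly negative: every male is heterozygous)")

spec = sx.WindowSpec(size=50_000, step=25_000)
fst = sx.fst_windowed(gm, sexes, spec, cfg.chrom_length)
hets = sx.sex_het_site_classes(gm, sexes, spec, cfg.chrom_length)
in_par = fst["end"] <= 1_000_000
print(f"mean windowed F_ST   PAR: {fst.loc[in_par,'fst'].mean():.4f}   "
      f"SLR: {fst.loc[~in_par,'fst'].mean():.4f}")
print(f"male-het/female-hom sites per window   PAR: "
      f"{hets.loc[in_par,'het_mf'].mean():.2f}   SLR: {hets.loc[~in_par,'het_mf'].mean():.2f}")
# Between-sex F_ST and male-het density jump at the PAR/SLR boundary; both
# are ~0 in the PAR, where inheritance is autosomal.
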