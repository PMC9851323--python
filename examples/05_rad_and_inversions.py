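"""RAD-seq sex markers and inversion genotyping: presence/absence
association with sex at a wild-cohort scale, and read-pair evidence
fractions classified into inversion genotypes."""

import pandas as pd

import sexscan as sx
from sexscan.svscreen import genotype_evidence_table

# 167 males + 57 females, 2000 markers, 25 of them present only in males
mat, sexes, truth = sx.simulate_rad_markers(
    n_markers=2000, n_m=167, n_f=57, n_sex_linked=25, seed=5)
res = sx.rad_marker_assoc(mat, sexes, min_depth=5)
sig = res[res["significant"]]
print(f"{len(sig)} markers significant after Bonferroni over {len(res)} tested")
print(f"planted sex-linked markers recovered: "
      f"{len(set(sig.index) & set(truth))}/{len(truth)}; "
      f"linked sex: {sig['linked_sex'].unique().tolist()}")

ev = pd.DataFrame({
    "chrom": ["chr4"] * 4, "start": [0, 1000, 2000, 3000],
    "end": [999, 1999, 2999, 3999],
    "n_support": [5, 40, 100, 0], "n_total": [100, 100, 100, 0],
})
out = genotype_evidence_table(ev)
print("\ninversion genotypes from read-pair support fractions:")
print(out[["start", "fraction", "genotype", "boundary_call"]].to_string(index=False))
# f < 0.25 -> homozygous reference arrangement, 0.25 < f < 1 -> heterozygous,
# f = 1 -> homozygous inverted, no informative pairs -> uninformative.
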