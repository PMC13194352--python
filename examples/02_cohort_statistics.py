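"""Group comparisons on a simulated 50-vs-50 index-level cohort.

Draws per-subject indices from the reference group means and SDs,
then runs the comparison battery: pooled t-tests on the five indices,
the sex chi-square, the index-covariate correlations in the ASD group,
and the age-stratified interaction check. With 50 subjects per group,
S2 splitting and S1-S2/RR separate clearly; the other three indices do
not.
"""

from asdscreen import default_cohort_spec, generate_cohort_indices, pearson_r
from asdscreen.stats import chi_square_2x2, compare_groups, subgroup_analysis
from asdscreen.synth import INDEX_COLUMNS

cohort = generate_cohort_indices(default_cohort_spec(n_per_group=50), seed=7)

table = compare_groups(cohort, INDEX_COLUMNS)
print(table.round(3).to_string(index=False))

m_ctrl = (cohort.query("group=='control'")["sex"] == "male").sum()
m_asd = (cohort.query("group=='ASD'")["sex"] == "male").sum()
sex = chi_square_2x2(m_ctrl, 50 - m_ctrl, m_asd, 50 - m_asd)
print(f"\nsex balance: chi2 = {sex.statistic:.3f}, p = {sex.p:.3f}")

asd = cohort[cohort["group"] == "ASD"]
r, p = pearson_r(asd["s2_split_ms"], asd["asd_size_mm"])
print(f"S2 split vs defect size (ASD group): r = {r:.2f}, p = {p:.2g}")

_, p_int = subgroup_analysis(cohort, "s2_split_ms")
print(f"age x group interaction for S2 split: p = {p_int:.2f} "
      "(no age dependence expected)")
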