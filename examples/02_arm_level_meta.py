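"""Arm-based meta-analysis: pooled incidences with heterogeneity statistics.

Pools the logit-transformed incidence of every control arm and every
intervention arm separately, per category — the arm-level summary table with
Q, tau^2, I^2, H^2 and a 95% prediction interval for a new comparable group.
"""

from armspill import StudyTable, default_paper_specs, generate_cohort
from armspill.prop_meta import arm_summary_table

records = []
for spec in default_paper_specs(seed=0).values():
    table, _ = generate_cohort(spec)
    records.extend(table.records)

summary = arm_summary_table(StudyTable(records), grouping="category")
cols = ["group", "arm_role", "k", "summary_pct", "tau2", "I2_pct", "H2",
        "pi95_lo_pct", "pi95_hi_pct"]
print(summary.loc[~summary.flagged, cols].round(2).to_string(index=False))

print()
print(
    "Read tau^2 / I^2 per arm: the antimicrobial CONTROL row shows the\n"
    "largest dispersion and the widest prediction interval even though its\n"
    "intervention row looks like every other category - the arm-level\n"
    "signature of harmful spillover onto concurrent controls."
)
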