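"""Generate a synthetic trial collection and inspect its structure.

Draws the three calibrated trial categories (non-antimicrobial,
antimicrobial with uneven harmful spillover, duplex with mild beneficial
spillover) and prints per-category arm counts and crude incidences.
"""

import numpy as np

from armspill import default_paper_specs, generate_cohort
from armspill.arm_data import ArmRole

for name, spec in default_paper_specs(seed=0).items():
    table, truth = generate_cohort(spec)
    ctrl = table.arms(ArmRole.CONTROL)
    inter = table.arms(ArmRole.INTERVENTION)
    crude_c = sum(r.events for r in ctrl) / sum(r.total for r in ctrl)
    crude_i = sum(r.events for r in inter) / sum(r.total for r in inter)
    print(
        f"{name:22s} k={spec.k_studies:3d}  condition {spec.condition}  "
        f"crude control incidence {crude_c:.1%}  intervention {crude_i:.1%}  "
        f"spilled studies {int(truth.spilled.sum())}"
    )

print()
print(
    "Control incidence runs above intervention incidence in every category;\n"
    "the antimicrobial category carries injected harmful spillover in half\n"
    "its trials, which the downstream diagnostics should surface as excess\n"
    "control-arm dispersion."
)
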