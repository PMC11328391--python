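"""Spillover simulation: perturb control counts and watch the summaries move.

Starts from a no-spillover cohort and adds (or removes) pneumonia events in
the control arms at 2.5, 5 and 10 per 100 control patients, recomputing the
contrast-based pooled OR and the arm-based control summary each time.
"""

from armspill.experiments import run_spillover_demo

grid = run_spillover_demo(seed=1)
cols = ["scenario", "or", "or_ci_lo", "or_ci_hi", "summary_pct", "tau2",
        "pi95_hi_pct"]
print(grid[cols].round(3).to_string(index=False))

print()
print(
    "Positive spillover (events ADDED to control arms) drags the pooled OR\n"
    "away from 1 - the intervention looks better - while the control summary\n"
    "incidence climbs. Negative spillover walks the OR back to and past 1.\n"
    "The intervention arms were never touched: the apparent effect size is\n"
    "moving entirely because of what happens to the controls."
)
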