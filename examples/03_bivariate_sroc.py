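"""Bivariate binomial-normal fit and an SROC-style plot.

Fits the paired-arm model to the antimicrobial category: summary incidences
for both arms, their random-effect spread and correlation, the summary odds
ratio, and an SROC plot with 95% confidence and prediction regions.
"""

from armspill import (
    default_paper_specs,
    fit_bivariate,
    generate_cohort,
    summary_dor,
    to_dta_layout,
)
from armspill.diagnose import LIBERAL_RANGE
from armspill.plots import PlotSpec, plot_sroc

table, _ = generate_cohort(default_paper_specs(seed=0)["antimicrobial"])
pairs = [tt for _, tt in to_dta_layout(table)]
fit = fit_bivariate(pairs)

sx, sy = fit.summary_point
dor, (lo, hi) = summary_dor(fit)
print(f"k = {fit.k} trials, converged = {fit.converged}")
print(f"summary control incidence      {sx:.1%}")
print(f"summary intervention incidence {sy:.1%}")
print(f"random-effect SDs (logit): control {fit.sigma_C:.2f}, "
      f"intervention {fit.sigma_I:.2f}, correlation {fit.rho:.2f}")
print(f"summary odds ratio {dor:.2f} (95% CI {lo:.2f}-{hi:.2f})")

out = plot_sroc(fit, table, PlotSpec(output_path="sroc_antimicrobial",
                                     benchmark=LIBERAL_RANGE))
print(f"wrote {out} (+ sidecar CSV of plotted coordinates)")
print()
print(
    "The odds ratio below 1 says the intervention looks protective, but the\n"
    "wide prediction region along the control axis says the control-arm\n"
    "incidence of a new comparable trial is barely predictable - dispersion\n"
    "a contrast-based summary cannot display."
)
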