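"""Fit the MUIC->TGR power law from paired survey points and use it.

Generates 24 synthetic national survey points (log-normal MUIC, power-law
goiter rate with multiplicative log-normal noise), fits the log-log OLS
model, and evaluates it at two reference iodine levels.
"""

from iddburden import (
    GeneratorConfig,
    REFERENCE_MODEL,
    classify_iodine_status,
    fit_power_model,
    generate_survey_points,
    predict_tgr,
)

points = generate_survey_points(GeneratorConfig(seed=4, n_survey_points=24))
fit = fit_power_model(points)

print(f"fitted model:    TGR = {fit.alpha:,.0f} x MUIC^{fit.beta:.2f}")
print(f"                 R2(log) = {fit.r_squared_log:.3f}, "
      f"beta SE = {fit.beta_se:.3f}, n = {fit.n_points}")
print(f"reference model: TGR = {REFERENCE_MODEL.alpha:,.0f} x "
      f"MUIC^{REFERENCE_MODEL.beta:.2f}")

for muic in (50.0, 100.0, 300.0):
    tgr = predict_tgr(REFERENCE_MODEL, muic)
    status = classify_iodine_status(muic).value
    print(f"MUIC {muic:5.0f} ug/L -> modeled TGR {tgr:5.2f}%  ({status})")

# The fitted coefficients recover the ground truth within sampling noise;
# at MUIC = 100 ug/L (lower edge of the optimal range) the reference model
# predicts ~6.1% goiter prevalence, just above the 5% elimination target,
# and ~1.0% at the upper edge of the optimal range.
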