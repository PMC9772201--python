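"""The focal mixed-effects analyses: does value (and does memorability)
drive choice and reaction time?

Fits four conditional models on a screened synthetic cohort:
  choice ~ |Δvalue| on the low-|Δmem| trials   (should be strong)
  choice ~ |Δmem|  on the low-|Δvalue| trials  (null by construction)
  log RT ~ |Δvalue| and log RT ~ |Δmem|        (negative / null)
then a Bayesian refit of the memorability model for BF01.
"""

import numpy as np

import memchoice as mc
from memchoice import cohort, inference, screening
from memchoice.bayes import fit_bayesian_mixed_logistic
from memchoice.inference import ModelSpec

config = mc.CohortConfig(seed=3)
bank = mc.make_item_bank(config)
template = inference.default_power_template(config, seed=3)
trials = cohort.simulate_choice_cohort(
    bank, template.z_mem, 44, config.choice_params, np.random.default_rng(7)
)
kept = screening.kept_trials(trials, screening.screen(trials))

specs = {
    "choice ~ |dValue| (low |dMem|)": (
        inference.fit_mixed_logistic,
        ModelSpec("chose_higher_value", ("abs_delta_value",), trial_filter="low_abs_delta_mem"),
    ),
    "choice ~ |dMem| (low |dValue|)": (
        inference.fit_mixed_logistic,
        ModelSpec("chose_more_memorable", ("abs_delta_mem",), trial_filter="low_abs_delta_value"),
    ),
    "log RT ~ |dValue| (low |dMem|)": (
        inference.fit_mixed_linear,
        ModelSpec("log_rt", ("abs_delta_value",), trial_filter="low_abs_delta_mem"),
    ),
    "log RT ~ |dMem| (low |dValue|)": (
        inference.fit_mixed_linear,
        ModelSpec("log_rt", ("abs_delta_mem",), trial_filter="low_abs_delta_value"),
    ),
}
for label, (fitter, spec) in specs.items():
    fit = fitter(kept, spec)
    focal = fit.table.iloc[-1]
    if fit.kind == "logistic":
        print(
            f"{label}: OR = {focal['or']:.2f} "
            f"(95% CI {focal['or_low']:.2f}-{focal['or_high']:.2f}), LRT p = {focal['lrt_p']:.3g}"
        )
    else:
        print(
            f"{label}: beta = {focal['estimate']:.3f} "
            f"(95% CI {focal['ci_low']:.3f} to {focal['ci_high']:.3f}), LRT p = {focal['lrt_p']:.3g}"
        )
print("\nan OR of ~3.6 per z-unit of |dValue| with OR ~1 for |dMem| reproduces the")
print("study-like pattern: choices track value, not memorability.")

bayes = fit_bayesian_mixed_logistic(
    kept,
    ModelSpec("chose_more_memorable", ("abs_delta_mem",), trial_filter="low_abs_delta_value"),
    prior_width=1.0,
    seed=1,
)
print(f"\nBF01 for the |dMem| effect = {bayes.bf01:.1f} (>1 favours the null of no effect)")
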