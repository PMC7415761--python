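"""Fit the success GLMM and the effort LMM on simulated data.

The success model is a binomial-logit mixed model with a random intercept
per pair: does a higher proportion of correct showing raise the odds that
the owner picks the target box?  The effort model is a Gaussian mixed
model with Satterthwaite-df t-tests on the nested time terms.
"""

from canishow import (
    SimConfig,
    build_observation_table,
    fit_effort_lmm,
    fit_success_glmm,
    simulate_dataset,
)

logs, contexts, truth = simulate_dataset(SimConfig(seed=7))
obs, _ = build_observation_table(logs)

glmm = fit_success_glmm(obs)
print(glmm.summary())
print()
lmm = fit_effort_lmm(obs)
print(lmm.summary())

# The prop_correct_showing coefficient is on the logit scale: the
# generator's true slope is 6.8, so the estimate should land near that.
# The effort model's phase terms are near zero here because the generator
# has no phase-dependent behavior rates.
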