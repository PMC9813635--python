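# Dose-response parameters of the salt -> SBP -> CVD-risk chain.
#
# The salt->SBP slopes (mm Hg per 1 g/day of salt reduction) come in two
# variants: a meta-regression of randomised salt-reduction trials (separate
# normotensive/hypertensive slopes; median trial duration 4-5 weeks) and a
# population study observed over ~8 years that captures the more prolonged
# effect (a single slope for all adults).
#
# The SBP->risk gradients are the proportional reduction in the relative
# risk of a first-ever event per 1 mm Hg of SBP reduction, by age band,
# pooled from large cohort collaborations.  95% CIs accompany every
# estimate and drive the Monte Carlo draws.
sbp_effect:
  beta_normo: {estimate: 0.75, ci: [0.20, 1.30]}
  beta_hyper: {estimate: 1.89, ci: [0.84, 2.93]}
  beta_all: {estimate: 1.93, ci: [1.45, 2.40]}
risk_gradient:
  ihd:
    "35-44": {estimate: 0.040, ci: [0.022, 0.055]}
    "45-54": {estimate: 0.036, ci: [0.022, 0.047]}
    "55-64": {estimate: 0.031, ci: [0.022, 0.038]}
    "65-74": {estimate: 0.025, ci: [0.022, 0.028]}
    "75-84": {estimate: 0.021, ci: [0.019, 0.022]}
  stroke:
    "35-44": {estimate: 0.051, ci: [0.047, 0.055]}
    "45-54": {estimate: 0.045, ci: [0.042, 0.048]}
    "55-64": {estimate: 0.039, ci: [0.036, 0.041]}
    "65-74": {estimate: 0.031, ci: [0.028, 0.033]}
    "75-84": {estimate: 0.022, ci: [0.020, 0.025]}
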