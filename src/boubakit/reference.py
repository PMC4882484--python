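"""Published group-level estimates used as default generating values.

These are the fixed-effect estimates reported for the original US and
Taiwanese samples of the radial-frequency Bouba/Kiki experiment (logit
units under the default predictor coding: frequency raw 4-9, amplitude
x 100, spikiness raw 0/1/30). The participant random-intercept SD was not
reported; 1.0 logit is this package's default, a typical inter-subject
spread for binary psychophysical judgements.
"""

from __future__ import annotations

from .synthetic_respondents import RespondentModel

__all__ = [
    "US_MODEL",
    "TW_MODEL",
    "POOLED_MODEL",
    "TWO_GROUP_MODEL",
    "GROUP_SIZES",
]

#: Published sample sizes per group.
GROUP_SIZES = {"US": 150, "TW": 88}

#: Separate-group fit, US sample (n=150).
US_MODEL = RespondentModel(
    beta0=-4.835, beta_freq=0.394, beta_amp=0.089, beta_spike=0.014, sigma_id=1.0
)

#: Separate-group fit, Taiwanese sample (n=88).
TW_MODEL = RespondentModel(
    beta0=-4.247, beta_freq=0.373, beta_amp=0.066, beta_spike=0.024, sigma_id=1.0
)

#: Pooled fit ignoring group (shared slopes model).
POOLED_MODEL = RespondentModel(
    beta0=-4.597, beta_freq=0.384, beta_amp=0.080, beta_spike=0.018, sigma_id=1.0
)

#: Two-group model with US-minus-Taiwan slope differences for amplitude and
#: spikiness only (the frequency weighting is culture-general).
TWO_GROUP_MODEL = RespondentModel(
    beta0=-4.567,
    beta_freq=0.386,
    beta_amp=0.067,
    beta_spike=0.025,
    delta_amp=0.021,
    delta_spike=-0.011,
    sigma_id=1.0,
)
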