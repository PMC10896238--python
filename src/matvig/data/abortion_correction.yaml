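# Default correction factors for the unsafe-abortion estimate.
#
# The estimate starts from hospitalizations with an abortion diagnosis,
# subtracts the expected number of hospitalized SPONTANEOUS abortions
# (modelled as a fraction of live births), and inflates the remainder by a
# multiplier for induced abortions that never reach a hospital.  These are
# EDITABLE DEFAULTS in the family of indirect-estimation (Guttmacher-style)
# methodologies; tune them to the setting under study.
spontaneous_fraction_of_live_births: 0.034
induced_not_hospitalized_multiplier: 4.0
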