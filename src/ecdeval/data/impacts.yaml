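# Intention-to-treat effect sizes (age-standardised SD units) with 95% CIs,
# per developmental outcome and delivery arm, versus the control group.
- outcome: cognition
  arm: group_only
  effect: 0.52
  ci_low: 0.21
  ci_high: 0.83
- outcome: receptive_language
  arm: group_only
  effect: 0.42
  ci_low: 0.08
  ci_high: 0.77
- outcome: socioemotional
  arm: group_only
  effect: 0.23
  ci_low: 0.03
  ci_high: 0.44
- outcome: cognition
  arm: mixed
  effect: 0.34
  ci_low: 0.05
  ci_high: 0.62
- outcome: receptive_language
  arm: mixed
  effect: 0.20
  ci_low: -0.11
  ci_high: 0.52
- outcome: socioemotional
  arm: mixed
  effect: 0.22
  ci_low: 0.05
  ci_high: 0.38
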