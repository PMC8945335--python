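# MER (NOM-059 Appendix II style) criterion level tables.
#
# Each criterion maps a qualitative level to an integer score in ascending
# order of risk; scores are normalized by the criterion maximum before
# summing, so the total lies in [0, 4].  Category thresholds: total >= 2.0
# -> in danger of extinction (EE); 1.70 <= total < 2.0 -> threatened (E);
# 1.5 <= total < 1.70 -> special protection (Pr).
#
# The level-to-score tables below are this package's own calibration (the
# governing standard describes the levels qualitatively); edit freely.

criteria:
  A:  # breadth of distribution
    levels:
      very_wide: 0
      wide: 1
      restricted: 2
      very_restricted: 3
    max: 3
  B:  # habitat status
    levels:
      favorable: 0
      intermediate: 1
      hostile: 2
    max: 2
  C:  # intrinsic biological vulnerability (ecological and genetic)
    levels:
      low: 0
      medium: 1
      high: 2
    max: 2
  D:  # human impact
    levels:
      low: 0
      moderate: 1
      high: 2
      very_high: 3
    max: 3

thresholds:
  EE: 2.0     # total >= 2.0
  E: 1.70     # 1.70 <= total < 2.0 (boundary goes to the higher-risk E)
  Pr: 1.5     # 1.5 <= total < 1.70

# Rules turning genetic evidence into a criterion-C sub-level.
genetic_rules:
  he_medium_below: 0.25      # mean He below this -> at least medium
  nm_medium_below: 1.0       # < 1 migrant/generation -> at least medium
  chi2_p_high_below: 0.05    # significant private-allele loss -> high
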