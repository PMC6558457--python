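# Base-case model inputs: point estimates with literature ranges, and
# age-indexed annual mortality curves. Probabilities are per year unless noted.
# The two mortality curves are anchored at the published endpoints (ages 45 and
# 85) with intermediate anchors on a log-convex schedule and a decelerated
# log-linear continuation beyond 85; see docs/methods.md for the rationale.
parameters:
  mort_sabr: {point: 0.0037, low: 0.0, high: 0.0208}
  mort_conv_rt: {point: 0.0010, low: 0.0010, high: 0.0010}
  mort_progression: {point: 0.6268, low: 0.4624, high: 0.8105}
  p_prog_lob: {point: 0.0400, low: 0.0133, high: 0.0742}
  p_prog_sabr: {point: 0.0790, low: 0.049, high: 0.1284}
  frac_lr_lob: {point: 0.0, low: 0.0, high: 0.0}
  frac_lr_sabr: {point: 0.1844, low: 0.1451, high: 0.4285}
  frac_rr_lob: {point: 0.2784, low: 0.0952, high: 0.4}
  frac_rr_sabr: {point: 0.1781, low: 0.0, high: 0.3333}
  p_salv_lr_sabr: {point: 0.2622, low: 0.2171, high: 0.4865}
  p_salv_rr_lob: {point: 0.3446, low: 0.3172, high: 0.3888}
  p_salv_rr_sabr: {point: 0.3010, low: 0.2941, high: 0.3095}
  p_salv_dm: {point: 0.0, low: 0.0, high: 0.0}
  p_prog_post_salv_lr_sabr: {point: 0.0679, low: 0.0, high: 0.0799}
  p_prog_post_salv_rr_lob: {point: 0.2639, low: 0.2342, high: 0.2865}
  p_prog_post_salv_rr_sabr: {point: 0.3115, low: 0.254, high: 0.3835}
  p_pN_positive: {point: 0.0, low: 0.0, high: 0.0}
curves:
  bg_mortality:
    interpolation: log-linear
    anchor_ages: [45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100]
    anchor_values: [0.002491, 0.002914435628, 0.003693845835, 0.005071619032, 0.007543241959, 0.01215382595, 0.02121346175, 0.04011009, 0.082156, 0.1115546101, 0.1514731856, 0.205676179]
  mort_lobectomy:
    interpolation: log-linear
    anchor_ages: [45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100]
    anchor_values: [0.0133, 0.0152495022, 0.01792738954, 0.02160905652, 0.02670618896, 0.03384117174, 0.04396795112, 0.05857124109, 0.08, 0.0935994598, 0.1095107359, 0.1281268216]
model:
  n_cycles: 15
  cycle_length: 1.0
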