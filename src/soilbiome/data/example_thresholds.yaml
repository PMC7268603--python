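# Example soil-quality thresholds -- SYNTHETIC, NON-NORMATIVE.
#
# These breakpoints are illustrative placeholders shaped like published
# soil-quality guideline ranges (four increasing breakpoints delimiting the
# categories very low / low / normal / high / very high, with per-land-use
# context overrides where management targets differ).  They are NOT the
# values of any official guideline; supply your own thresholds file for
# real assessments.
variables:
  pH:
    optimal: normal
    contexts:
      default: {breakpoints: [5.0, 5.5, 6.2, 6.6]}
  carbon_pct:
    optimal: normal
    contexts:
      default: {breakpoints: [1.0, 2.0, 10.0, 15.0]}
  total_n_pct:
    optimal: normal
    contexts:
      default: {breakpoints: [0.05, 0.12, 0.62, 0.80]}
  amn_mg_kg:
    optimal: normal
    contexts:
      default: {breakpoints: [15.0, 40.0, 170.0, 220.0]}
  olsen_p_mg_kg:
    optimal: normal
    contexts:
      default: {breakpoints: [5.0, 12.0, 52.0, 95.0]}
      horticulture: {breakpoints: [10.0, 25.0, 95.0, 140.0]}
  macroporosity_pct:
    optimal: normal
    contexts:
      default: {breakpoints: [3.0, 7.0, 24.0, 32.0]}
  bulk_density_t_m3:
    optimal: normal
    contexts:
      default: {breakpoints: [0.50, 0.70, 1.35, 1.55]}
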