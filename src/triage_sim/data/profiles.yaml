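# Default comorbidity profiles for the ICU triage simulation.
#
# baseline: triangular death-probability distribution Δ(minimum; maximum; mode)
#   for patients without impairments or pre-existing conditions (normalized
#   registry data; expected value 0.165).
#
# Each profile carries the published odds/hazard ratio ("relative risk of
# death") and its confidence interval (metadata only; the point estimate is
# applied to the baseline expectation).  The hypertension distribution is the
# published triple; the other four are derived by the "scale" calibration
# strategy at load time.
#
# prevalence_weight: EDITABLE PLACEHOLDERS.  The source figure for the
# assignment probabilities is not reproduced numerically anywhere, so these
# are population prevalence estimates for German adults (hypertension ~32%,
# type-2 diabetes ~9%, cardiovascular disease ~6%, trisomy 21 ~0.2%,
# amyotrophic lateral sclerosis ~0.008%).  Weights are normalized within each
# category at assignment time; every run manifest records the weights used.

baseline:
  minimum: 0.04
  maximum: 0.41
  mode: 0.045

profiles:
  - name: trisomy21
    category: impairment
    relative_risk: 4.52
    ci: [3.13, 7.36]
    ci_note: confidence interval reduced by 40% in the source
    strategy: scale
    prevalence_weight: 0.002

  - name: als
    category: impairment
    relative_risk: 3.00
    ci: [1.9, 4.9]
    strategy: scale
    prevalence_weight: 0.00008

  - name: cvd
    category: pre-existing
    relative_risk: 4.85
    ci: [3.07, 7.70]
    strategy: scale
    prevalence_weight: 0.06

  - name: hypertension
    category: pre-existing
    relative_risk: 2.12
    ci: [1.17, 3.82]
    strategy: printed-hypertension
    params:
      minimum: 0.19
      maximum: 0.63
      mode: 0.23
    prevalence_weight: 0.32

  - name: t2d
    category: pre-existing
    relative_risk: 2.03
    ci: [1.97, 2.09]
    strategy: scale
    prevalence_weight: 0.09
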