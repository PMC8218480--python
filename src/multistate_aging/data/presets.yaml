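# Ground-truth transition-model coefficient presets.
#
# Coefficients are on the age-centred scale used by the estimators: the
# intercept is the log relative risk (vs staying) at age 80 and the "age"
# term is per year of (age - 80); "age2" multiplies (age - 80)^2.  Sex is
# coded female = 1, CI (any cognitive impairment) with-CI = 1.  Only
# structurally permitted destinations appear: no recovery from moderate or
# severe cognitive impairment, none from 3+ ADL limitations.
presets:
  "null":
    description: >
      Identity dynamics: no transitions except staying put (all non-stay
      intercepts at -inf).  Running the projection on this preset keeps
      every entrant intact-active forever and nobody 65+ dies.
    cognitive:
      INTACT: {MILD: {intercept: -.inf}, MODERATE: {intercept: -.inf}, SEVERE: {intercept: -.inf}, DEAD: {intercept: -.inf}}
      MILD: {INTACT: {intercept: -.inf}, MODERATE: {intercept: -.inf}, SEVERE: {intercept: -.inf}, DEAD: {intercept: -.inf}}
      MODERATE: {SEVERE: {intercept: -.inf}, DEAD: {intercept: -.inf}}
      SEVERE: {DEAD: {intercept: -.inf}}
    functional:
      ACTIVE: {ADL12: {intercept: -.inf}, ADL3: {intercept: -.inf}, DEAD: {intercept: -.inf}}
      ADL12: {ACTIVE: {intercept: -.inf}, ADL3: {intercept: -.inf}, DEAD: {intercept: -.inf}}
      ADL3: {DEAD: {intercept: -.inf}}
  realistic:
    description: >
      Qualitatively realistic dynamics: worsening and death risks rise
      with age (log-linear with a mild quadratic for the cognitive
      process), recovery falls with age, women transition into cognitive
      impairment more and die less, men worsen functionally more.
    cognitive:
      INTACT:
        MILD:     {intercept: -2.55, age: 0.075, age2: 0.0008, sex: 0.25}
        MODERATE: {intercept: -3.80, age: 0.090, age2: 0.0010, sex: 0.20}
        SEVERE:   {intercept: -4.70, age: 0.100, age2: 0.0010, sex: 0.15}
        DEAD:     {intercept: -3.10, age: 0.095, age2: 0.0012, sex: -0.25}
      MILD:
        INTACT:   {intercept: -2.30, age: -0.055, age2: 0.0, sex: 0.15}
        MODERATE: {intercept: -2.50, age: 0.080, age2: 0.0008, sex: -0.20}
        SEVERE:   {intercept: -3.80, age: 0.090, age2: 0.0010, sex: -0.15}
        DEAD:     {intercept: -2.90, age: 0.090, age2: 0.0012, sex: 0.10}
      MODERATE:
        SEVERE:   {intercept: -2.20, age: 0.075, age2: 0.0008, sex: -0.20}
        DEAD:     {intercept: -2.60, age: 0.085, age2: 0.0012, sex: -0.10}
      SEVERE:
        DEAD:     {intercept: -1.70, age: 0.080, age2: 0.0012, sex: 0.10}
    functional:
      ACTIVE:
        ADL12: {intercept: -2.70, age: 0.070, sex: -0.20, ci: 0.50}
        ADL3:  {intercept: -4.00, age: 0.090, sex: -0.20, ci: 0.70}
        DEAD:  {intercept: -3.20, age: 0.090, sex: -0.25, ci: 0.60}
      ADL12:
        ACTIVE: {intercept: -1.90, age: -0.050, sex: 0.25, ci: -0.40}
        ADL3:   {intercept: -2.40, age: 0.080, sex: -0.25, ci: 0.55}
        DEAD:   {intercept: -2.80, age: 0.090, sex: -0.20, ci: 0.50}
      ADL3:
        DEAD:   {intercept: -1.60, age: 0.075, sex: -0.20, ci: 0.45}
  calibration:
    description: >
      Low-turnover world for interval-calibration (coverage) studies.
      Midpoint imputation over a two-year gap is consistent only when
      annual transition probabilities are small; this preset keeps stay
      probabilities near 0.95 at age 80 so the estimator is approximately
      unbiased for the truth kernel and percentile-interval coverage
      measures the bootstrap, not the estimator's bias.
    cognitive:
      INTACT:
        MILD:     {intercept: -3.60, age: 0.050, age2: 0.0004, sex: 0.15}
        MODERATE: {intercept: -4.60, age: 0.050, age2: 0.0004, sex: 0.10}
        SEVERE:   {intercept: -5.60, age: 0.050, age2: 0.0004, sex: 0.10}
        DEAD:     {intercept: -3.60, age: 0.050, age2: 0.0004, sex: -0.15}
      MILD:
        INTACT:   {intercept: -3.40, age: -0.040, age2: 0.0, sex: 0.10}
        MODERATE: {intercept: -3.60, age: 0.050, age2: 0.0004, sex: -0.10}
        SEVERE:   {intercept: -4.60, age: 0.050, age2: 0.0004, sex: -0.10}
        DEAD:     {intercept: -3.40, age: 0.050, age2: 0.0004, sex: 0.10}
      MODERATE:
        SEVERE:   {intercept: -3.40, age: 0.050, age2: 0.0004, sex: -0.10}
        DEAD:     {intercept: -3.20, age: 0.050, age2: 0.0004, sex: -0.10}
      SEVERE:
        DEAD:     {intercept: -2.80, age: 0.050, age2: 0.0004, sex: 0.10}
    functional:
      ACTIVE:
        ADL12: {intercept: -3.60, age: 0.050, sex: -0.15, ci: 0.40}
        ADL3:  {intercept: -4.60, age: 0.050, sex: -0.15, ci: 0.50}
        DEAD:  {intercept: -3.60, age: 0.050, sex: -0.15, ci: 0.40}
      ADL12:
        ACTIVE: {intercept: -3.20, age: -0.040, sex: 0.15, ci: -0.30}
        ADL3:   {intercept: -3.40, age: 0.050, sex: -0.15, ci: 0.40}
        DEAD:   {intercept: -3.40, age: 0.050, sex: -0.15, ci: 0.40}
      ADL3:
        DEAD:   {intercept: -2.80, age: 0.050, sex: -0.15, ci: 0.35}
  stress:
    description: >
      High-turnover stress scenario: large annual movement across states,
      used to exercise numerical robustness, not realism.
    cognitive:
      INTACT:
        MILD:     {intercept: -1.00, age: 0.050, age2: 0.0005, sex: 0.20}
        MODERATE: {intercept: -1.80, age: 0.060, age2: 0.0005, sex: 0.10}
        SEVERE:   {intercept: -2.40, age: 0.070, age2: 0.0005, sex: 0.10}
        DEAD:     {intercept: -1.60, age: 0.070, age2: 0.0008, sex: -0.20}
      MILD:
        INTACT:   {intercept: -1.20, age: -0.040, age2: 0.0, sex: 0.10}
        MODERATE: {intercept: -1.20, age: 0.060, age2: 0.0005, sex: -0.10}
        SEVERE:   {intercept: -2.00, age: 0.065, age2: 0.0005, sex: -0.10}
        DEAD:     {intercept: -1.60, age: 0.070, age2: 0.0008, sex: 0.10}
      MODERATE:
        SEVERE:   {intercept: -1.00, age: 0.060, age2: 0.0005, sex: -0.10}
        DEAD:     {intercept: -1.40, age: 0.065, age2: 0.0008, sex: -0.10}
      SEVERE:
        DEAD:     {intercept: -0.80, age: 0.060, age2: 0.0008, sex: 0.10}
    functional:
      ACTIVE:
        ADL12: {intercept: -1.20, age: 0.050, sex: -0.15, ci: 0.40}
        ADL3:  {intercept: -2.20, age: 0.060, sex: -0.15, ci: 0.50}
        DEAD:  {intercept: -1.80, age: 0.065, sex: -0.20, ci: 0.40}
      ADL12:
        ACTIVE: {intercept: -1.00, age: -0.040, sex: 0.15, ci: -0.30}
        ADL3:   {intercept: -1.20, age: 0.060, sex: -0.15, ci: 0.40}
        DEAD:   {intercept: -1.50, age: 0.065, sex: -0.15, ci: 0.40}
      ADL3:
        DEAD:   {intercept: -0.90, age: 0.060, sex: -0.15, ci: 0.35}
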