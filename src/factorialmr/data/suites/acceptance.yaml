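# Full-size Monte-Carlo validation suite.
# Acceptance bands are 3-SE binomial bands around the nominal rates;
# Monte-Carlo SEs are reported next to every rate in the output.
scenarios:
  - name: recovery_hr070
    analysis: recovery
    n_individuals: 20000
    n_replicates: 200
    seed: 11
    params: {hr50_a: 0.70}
  - name: recovery_hr090
    analysis: recovery
    n_individuals: 20000
    n_replicates: 200
    seed: 12
    params: {hr50_a: 0.90}
  - name: recovery_null
    analysis: recovery
    n_individuals: 20000
    n_replicates: 200
    seed: 13
    params: {hr50_a: 1.00}
  - name: ci_calibration
    analysis: recovery
    n_individuals: 2000
    n_replicates: 1000
    seed: 21
    params: {hr50_a: 0.85}
  - name: interaction_type1
    analysis: type1
    n_individuals: 5000
    n_replicates: 1000
    seed: 31
    params: {alpha: 0.05}
  - name: power_comparison
    analysis: power
    n_individuals: 5000
    n_replicates: 400
    seed: 41
    params: {alpha: 0.05, grid: [0.0, 0.04, 0.08, 0.12]}
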