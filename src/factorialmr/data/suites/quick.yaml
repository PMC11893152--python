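# Desk-check suite: same scenario shapes as `acceptance`, reduced sizes.
scenarios:
  - name: recovery_quick
    analysis: recovery
    n_individuals: 4000
    n_replicates: 40
    seed: 11
    params: {hr50_a: 0.85}
  - name: type1_quick
    analysis: type1
    n_individuals: 2000
    n_replicates: 60
    seed: 31
    params: {alpha: 0.05}
  - name: power_quick
    analysis: power
    n_individuals: 2000
    n_replicates: 40
    seed: 41
    params: {alpha: 0.05, grid: [0.0, 0.15]}
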