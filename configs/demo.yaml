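# Demo run: two life stages (dauer-like vs starved-adult-like), one imaged
# interneuron-like cohort, one tracked behavior cohort, one chemotaxis assay.
# All data are simulated; ground truth is written alongside.
seed: 42

protocol:
  imaging:
    pre_s: 20
    pulse_s: 60
    post_s: 40
    frame_rate: 2.0
    composition: "15% CO2"
  behavior:
    pre_s: 20
    pulse_s: 60
    post_s: 40
    frame_rate: 5.0
    composition: "2.5% CO2, 21% O2, balance N2"

calcium:
  neuron: AIB
  noise_sd: 0.01
  n_air_controls: 12
  groups:
    dauer:
      class_mix: {excitatory: 0.65, inhibitory: 0.05, silent: 0.30}
      amplitude: {kind: uniform, low: 15.0, high: 35.0}
      n: 16
    starved_adult:
      class_mix: {excitatory: 0.15, inhibitory: 0.05, silent: 0.80}
      amplitude: {kind: uniform, low: 8.0, high: 20.0}
      n: 16
  analysis:
    k_sd: 3.0
    statistic: extremum
    clustering: {metric: euclidean, linkage: average}

behavior:
  groups:
    dauer: {params: dauer_like, n: 18}
    starved_adult: {params: adult_like, n: 18}
  analysis:
    pause_speed_mm_s: 0.02
    min_bout_s: 0.6
    reversal_angle_deg: 120.0
    smooth_s: 1.0

chemotaxis:
  n_worms: 20
  n_plates: 17
  groups:
    well_fed: 0.2
    starved_adult: 0.8
    dauer: 0.8

comparisons:
  - name: aib_max_dauer_vs_adult
    table: calcium_calls
    metric: max_pct
    test: mann_whitney
    groups: [dauer, starved_adult]
  - name: aib_excitatory_fraction
    table: calcium_class_counts
    test: fisher_exact
    focus_class: excitatory
    groups: [dauer, starved_adult]
  - name: speed_windows_dauer
    table: behavior_metrics
    test: anova2_sidak
    group: dauer
    metrics: [speed_early, speed_late]
  - name: speed_windows_adult
    table: behavior_metrics
    test: anova2_sidak
    group: starved_adult
    metrics: [speed_early, speed_late]
  - name: pause_ratio_co2
    table: behavior_metrics
    metric: pause_ratio
    test: welch_t
    gas: CO2
    groups: [dauer, starved_adult]
  - name: chemotaxis_by_stage
    table: chemotaxis_metrics
    metric: chemotaxis_index
    test: kruskal_dunn
    groups: [well_fed, starved_adult, dauer]
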