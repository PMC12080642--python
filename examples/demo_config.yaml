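# Two-group demo: a control group and a "patient" group carrying an
# injected infraslow oscillation and a positive CoV trend.
seed: 42
out_dir: cptspect_demo
groups:
  - name: HC
    n: 20
    params:
      rt_mu: {mean: 430.0, sd: 35.0}
      rt_sigma: {mean: 50.0, sd: 10.0, min: 15.0}
      rt_tau: 30.0
      trend_slope: 0.0
      cov_trend: 0.0
      osc_amplitude: 0.0
      osc_freq: 0.04
      p_miss: 0.05
      p_commission: 0.01
  - name: BPd
    n: 20
    params:
      rt_mu: {mean: 470.0, sd: 40.0}
      rt_sigma: {mean: 60.0, sd: 12.0, min: 15.0}
      rt_tau: 40.0
      trend_slope: 0.05
      cov_trend: 0.005
      osc_amplitude: {mean: 80.0, sd: 15.0, min: 0.0}
      osc_freq: 0.063
      p_miss: 0.08
      p_commission: 0.02
reference_group: HC
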