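baseline:
  chambers:
    la:
      e_max: 0.25
      e_min: 0.12
      v0: 10.0
      onset: 0.03
      duration: 0.14
    lv:
      e_max: 0.12735799144513774
      e_min: 0.04022394242205744
      v0: 25.0
      onset: 0.17
      duration: 0.35
    ra:
      e_max: 0.2
      e_min: 0.1
      v0: 10.0
      onset: 0.03
      duration: 0.14
    rv:
      e_max: 0.364
      e_min: 0.06261064992020955
      v0: 20.0
      onset: 0.17
      duration: 0.35
  valves:
    mitral:
      a_max: 4.0
      theta_min: 0.0
      theta_max: 75.0
      k_p: 320000.0
      k_f: 50.0
      b_open: 2.4845861898261353e-05
      l_v: 0.0
    aortic:
      a_max: 3.0
      theta_min: 0.0
      theta_max: 75.0
      k_p: 320000.0
      k_f: 50.0
      b_open: 4.417042115246463e-05
      l_v: 0.0
    tricuspid:
      a_max: 5.0
      theta_min: 0.0
      theta_max: 75.0
      k_p: 320000.0
      k_f: 50.0
      b_open: 1.5901351614887267e-05
      l_v: 0.0
    pulmonic:
      a_max: 3.5
      theta_min: 0.0
      theta_max: 75.0
      k_p: 320000.0
      k_f: 50.0
      b_open: 3.245173798956585e-05
      l_v: 0.0
  compartments:
    sa:
      r: 0.7276536320492861
      c: 1.3
      v0: 500.0
      l: 0.0
    sv:
      r: 0.02
      c: 22.959358264841256
      v0: 2400.0
      l: 0.0
    pa:
      r: 0.1342548487488435
      c: 4.0
      v0: 120.0
      l: 0.0
    pv:
      r: 0.025
      c: 25.0
      v0: 400.0
      l: 0.0
  pump:
    speed_rpm: 5500.0
    a: 2.4247324962620694e-06
    b: 0.00017910519569867066
    c: 1.1151421835247943e-11
    r_c: 0.001146785666982802
    l_c: 0.02
    cannula_area: 1.54
  hr: 60.0
  total_volume: 4484.364921184208
  tags: {}
theta_min_mild: 22.92736323655874
theta_min_severe: 32.03854447609734
bp_factor: 0.500000012656603
uncouple_r_factor: 1.559195452965084
uncouple_c_factor: 0.08634113386275849
ai_svr_factor_mild: 1.2879392128704066
ai_svr_factor_severe: 3.3153301593641045
vasodil_c_factor: 10.0
vasodil_r_factor: 0.8
baseline_rpm: 5500.0
augmented_rpm: 6400.0
meta:
  calibration:
    residual_norm: 1.3748315779171874
    n_evaluations: 112
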