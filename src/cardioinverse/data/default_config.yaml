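# Default configuration: closed-loop 0D circulation with carotid baroreflex,
# LV-failure sampling ranges, featurization, network and evaluation settings.
#
# Units: pressure mmHg, volume ml, time s, flow ml/s, elastance mmHg/ml,
# resistance mmHg*s/ml, compliance ml/mmHg, inertance mmHg*s^2/ml,
# firing rates spikes/s.
model:
  total_blood_volume: 5300.0
  compartments:
    # R of arterial/venous compartments is the outflow resistance of the
    # compartment; peripheral R values are the *unregulated* component, the
    # sympathetic effector adds its contribution on top.
    systemic_arteries:        {R: 0.06,   C: 0.28,  L: 0.00022, Vu: 0.0}
    splanchnic_peripheral:    {R: 2.49,   C: 2.05,  Vu: 274.4}
    extrasplanchnic_peripheral: {R: 0.78, C: 1.67,  Vu: 336.6}
    splanchnic_venous:        {R: 0.038,  C: 61.11, Vu: 1435.4}
    extrasplanchnic_venous:   {R: 0.016,  C: 50.0,  Vu: 1537.0}
    pulmonary_arteries:       {R: 0.023,  C: 0.76,  L: 0.00018, Vu: 0.0}
    pulmonary_peripheral:     {R: 0.0894, C: 5.8,   Vu: 123.0}
    pulmonary_veins:          {R: 0.0056, C: 25.37, Vu: 120.0}
    left_atrium:              {R: 0.0025, C: 19.23, Vu: 25.0}
    right_atrium:             {R: 0.0025, C: 31.25, Vu: 25.0}
  left_ventricle:
    emax: 2.95          # E_max,lv  - reference end-systolic elastance
    emax0: 2.392        # E_max_lv,0 - elastance in absence of autoregulation
    emax_norm: 2.95     # normalization so E(t)=emax at nominal tone/parameters
    p0: 1.5
    ke: 0.014           # k_E,lv - EDPVR steepness
    vu: 16.77
    kr: 0.000375        # ejection resistance per unit isovolumic pressure
  right_ventricle:
    emax0: 1.412
    p0: 1.5
    ke: 0.011
    vu: 40.8
    kr: 0.0014
  timing:
    t0: 0.55            # intrinsic heart period offset
    t_min: 0.4          # period saturations: HR confined to [60, 150]/min
    t_max: 1.0
    tsys0: 0.5
    ksys: 0.075
  baroreflex:
    afferent: {p_n: 92.0, k_a: 11.758, f_min: 2.52, f_max: 47.78, tau_z: 6.37, tau_p: 2.076}
    sympathetic: {f_es_inf: 2.10, f_es_0: 16.11, k_es: 0.0675, f_es_min: 2.66}
    vagal: {f_ev_0: 3.2, f_ev_inf: 6.3, f_ab_0: 25.0, k_ev: 7.06}
    effectors:
      emax_lv:      {gain: 0.475,  delay: 2.0, tau: 8.0}   # G_Emax,lv (failure parameter)
      emax_rv:      {gain: 0.282,  delay: 2.0, tau: 8.0}
      r_sp:         {gain: 0.695,  delay: 2.0, tau: 6.0}
      r_ep:         {gain: 0.53,   delay: 2.0, tau: 6.0}
      vu_sv:        {gain: -265.4, delay: 5.0, tau: 20.0}
      vu_ev:        {gain: -132.5, delay: 5.0, tau: 20.0}
      period_sym:   {gain: -0.26,  delay: 2.0, tau: 2.0}
      period_vagal: {gain: 0.18,   delay: 0.2, tau: 1.5}

simulation:
  duration: 20.0
  dt: 0.002
  transient: 10.0       # discarded before any analysis/featurization
  steady_tol: 0.005     # max cycle-to-cycle MSAP relative change

# Admissible ranges of the four LV systolic-function parameters.  The lower
# corner sits in overt systolic failure (LVEF ~ 30%), the upper corner in
# normal function (LVEF ~ 60%); calibrated by forward simulation.
ranges:
  emax_lv: [1.0, 3.1]
  emax_lv0: [1.8, 2.392]
  g_emax_lv: [0.2, 0.475]
  ke_lv: [0.0105, 0.014]

features:
  M: 5                  # truncation order -> 2M+1 = 11 coefficients/signal
  n_t: 220              # resampled points over the feature window (dt = 10 ms)
  window: 2.2           # seconds, beat-onset-aligned within the analysis window

network:
  hidden_layers: 4
  hidden_units: 16
  learning_rate: 0.001
  batch_size: 32
  max_epochs: 1000
  patience: 50

evaluation:
  bsa: 2.0              # body surface area (m^2) for the cardiac index
  sensitivity_runs: 100
  epsilon: 0.01
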