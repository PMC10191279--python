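# Rat parameter set: physiological rows fixed, remaining rows scaled from mouse.
species: rat
physiology:
  BW: 0.25
  V_L: 0.078
  V_S: 0.0052
  V_Nb: 0.054
  Q_BL_i: 5.25
  Q_BL_o: 5.4
  Q_BS: 0.15
  H: 0.46
  fup: 0.06
  BPR: 0.84
  v_liver: 0.125
  v_spleen: 0.016
released:
  V_b: 0.67           # scaled from mouse by fu,blood ratio
  V_R: 0.2
  Q_BR: 0.007         # allometric (exponent 0.7)
  CL: 2.1             # in-vivo measured (used for goodness-of-fit runs)
  CL_range: [2.1, 2.8]   # in-vivo measured / in-vitro scaled
  Bmax_L: 99.0        # scaled by fu,blood ratio
  KD_L: 0.6
  P_L: 1.5
  Bmax_S: 251.8
  KD_S: 0.63
  P_S: 0.33
conjugated:
  N_BL: 0.0002        # scaled by blood->liver flow ratio
  N_BS: 4.0e-6        # scaled by blood->spleen flow ratio
  N_BR: 0.0
  K_NBL: 1.8          # scaled by fu,blood ratio
  K_NBS: 1000.0
  krel_b: 0.125
  krel_L: 0.016
  krel_S: 0.0063
  krel_R: 0.125
ivive:
  Clint: 48.7
  fuinc: 0.007
  hepatocellularity: 163.0
  liver_weight: 10.0
  Qh: 5.4
  measured_blood_CL: 2.1
  measured_plasma_CL: 1.8
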