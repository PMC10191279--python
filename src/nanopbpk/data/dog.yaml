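# Dog parameter set: physiological rows fixed, remaining rows scaled from mouse.
species: dog
physiology:
  BW: 10.0
  V_L: 0.048
  V_S: 0.0036
  V_Nb: 0.09
  Q_BL_i: 3.15
  Q_BL_o: 3.3
  Q_BS: 0.15
  H: 0.42
  fup: 0.06
  BPR: 0.97
  v_liver: 0.125
  v_spleen: 0.016
released:
  V_b: 0.59
  V_R: 0.19
  Q_BR: 0.0024
  CL: 1.5             # in-vivo measured (nominal for the sensitivity analysis)
  CL_range: [1.5, 2.5]   # in-vivo measured / in-vitro scaled
  Bmax_L: 85.0
  KD_L: 0.6
  P_L: 1.3
  Bmax_S: 217.8
  KD_S: 0.63
  P_S: 0.3
conjugated:
  N_BL: 0.0001
  N_BS: 4.0e-6
  N_BR: 0.0
  K_NBL: 1.6
  K_NBS: 1000.0
  krel_b: 0.125
  krel_L: 0.016
  krel_S: 0.0063
  krel_R: 0.125
ivive:
  Clint: 98.3
  fuinc: 0.007
  hepatocellularity: 169.0
  liver_weight: 384.0
  Qh: 3.3
  measured_blood_CL: 1.5
  measured_plasma_CL: 1.5
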