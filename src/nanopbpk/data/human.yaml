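# Human parameter set (projection only; CL from hepatocyte IVIVE).
species: human
physiology:
  BW: 70.0
  V_L: 0.024
  V_S: 0.0027
  V_Nb: 0.074
  Q_BL_i: 1.23
  Q_BL_o: 1.3
  Q_BS: 0.066
  H: 0.45
  fup: 0.03
  BPR: 0.77
  v_liver: 0.125
  v_spleen: 0.016
released:
  V_b: 0.37
  V_R: 0.12
  Q_BR: 0.0013
  CL: 0.32            # from hepatocyte Clint 15.5 uL/min/1e6 via IVIVE
  CL_range: [0.32]
  Bmax_L: 54.0
  KD_L: 0.6
  P_L: 0.83
  Bmax_S: 138.0
  KD_S: 0.63
  P_S: 0.19
conjugated:
  N_BL: 4.0e-5
  N_BS: 1.7e-6
  N_BR: 0.0
  K_NBL: 1.0
  K_NBS: 1000.0
  krel_b: 0.125
  krel_L: 0.016
  krel_S: 0.0063
  krel_R: 0.125
ivive:
  Clint: 15.5
  fuinc: 0.007
  hepatocellularity: 120.0
  liver_weight: 1680.0
  Qh: 1.3
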