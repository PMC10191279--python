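# Mouse parameter set (model originally fit in mouse; other species scale from it).
species: mouse
physiology:
  BW: 0.02            # kg
  V_L: 0.065          # L/kg, liver volume (physiological)
  V_S: 0.005          # L/kg, spleen volume (physiological)
  V_Nb: 0.085         # L/kg, blood volume (physiological)
  Q_BL_i: 8.36        # L/kg/h, blood->liver flow (= Q_BL_o - Q_BS)
  Q_BL_o: 9.1         # L/kg/h, liver->blood flow (physiological)
  Q_BS: 0.74          # L/kg/h, blood<->spleen flow (physiological)
  H: 0.45             # hematocrit (standard physiology compilations)
  fup: 0.03           # unbound fraction in plasma
  BPR: 0.84           # blood-to-plasma ratio (measured for the small molecule)
  v_liver: 0.125      # liver vascular volume fraction
  v_spleen: 0.016     # spleen vascular volume fraction
released:
  V_b: 0.34           # L/kg, apparent central volume (fit in mouse)
  V_R: 0.1            # L/kg, apparent peripheral volume (fit in mouse)
  Q_BR: 0.015         # L/kg/h, blood<->rest intercompartmental clearance
  CL: 1.0             # L/kg/h, nominal released-API clearance
  CL_range: [1.0, 2.0, 2.3]   # nominal / in-vitro scaled / in-vivo measured
  Bmax_L: 49.6        # ng/mL
  KD_L: 0.6           # ng/mL (constant across species)
  P_L: 0.76
  Bmax_S: 125.9       # ng/mL
  KD_S: 0.63          # ng/mL (constant across species)
  P_S: 0.17
conjugated:
  N_BL: 0.0003        # L/kg/h, blood<->liver extravasation rate
  N_BS: 2.0e-5        # L/kg/h, blood<->spleen extravasation rate
  N_BR: 0.0           # fixed to zero (floats to ~0 when fitted)
  K_NBL: 0.9
  K_NBS: 1000.0       # fixed; spleen->blood return effectively removed
  krel_b: 0.125       # 1/h (T50 = 5.5 h); constant across species
  krel_L: 0.016       # 1/h (T50 = 43 h)
  krel_S: 0.0063      # 1/h (T50 = 110 h)
  krel_R: 0.125       # = krel_b
ivive:
  Clint: 36.0            # uL/min per 1e6 hepatocytes
  fuinc: 0.007           # incubational unbound fraction
  hepatocellularity: 125.0  # 1e6 cells per g liver
  liver_weight: 1.25     # g
  Qh: 9.1                # L/kg/h, hepatic blood flow (= Q_BL_o)
  measured_blood_CL: 2.3 # L/kg/h, NCA of unconjugated API IV profile
  measured_plasma_CL: 2.0
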