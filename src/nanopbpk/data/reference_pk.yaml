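# Published plasma NCA summaries used as inputs to the dose-proportionality,
# clearance-identity and relative-exposure computations.
#
# nanoparticle: plasma NCA of total and released API after nanoparticle dosing.
# unconjugated: plasma AUC of the conventional-formulation (unconjugated) API.
nanoparticle:
  - {species: mouse, dose_mg_per_kg: 10,  auc_total: 2294,   thalf_total: 7.4, cl_total: 0.004, auc_released: 38.7, thalf_released: 7.6,  cl_released: 0.26}
  - {species: rat,   dose_mg_per_kg: 55,  auc_total: 19593,  thalf_total: 6.8, cl_total: 0.003, auc_released: 373,  thalf_released: 11.5, cl_released: 0.15}
  - {species: rat,   dose_mg_per_kg: 110, auc_total: 40187,  thalf_total: 8.0, cl_total: 0.003, auc_released: 694,  thalf_released: 14.0, cl_released: 0.16}
  - {species: rat,   dose_mg_per_kg: 505, auc_total: 136989, thalf_total: 15.0, cl_total: 0.004, auc_released: 1714, thalf_released: 20.7, cl_released: 0.3}
  - {species: dog,   dose_mg_per_kg: 12,  auc_total: 1812,   thalf_total: 7.8, cl_total: 0.007, auc_released: 56.3, thalf_released: 7.9,  cl_released: 0.21}
unconjugated:
  - {species: mouse, dose_mg_per_kg: 10, route: bolus,    plasma_auc: 5.6}
  - {species: rat,   dose_mg_per_kg: 50, route: infusion, plasma_auc: 28}
  - {species: dog,   dose_mg_per_kg: 12, route: infusion, plasma_auc: 8.9}
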