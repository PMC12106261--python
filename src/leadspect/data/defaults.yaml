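# Packaged defaults: nuclide emission data, collimator geometry, energy-window
# layouts, and planar system parameters for the Siemens Symbia Intevo
# measurement campaign this package models. All values overridable at the API.
#
# Units: energies keV, half-lives hours, collimator dimensions mm,
# sensitivities cps/MBq, tau_alpha 1/MBq.

nuclides:
  Pb-203:
    half_life_h: 51.9
    lines:
      - {energy_kev: 279.2, probability: 0.809, kind: gamma, origin: Pb-203}
      - {energy_kev: 401.3, probability: 0.034, kind: gamma, origin: Pb-203}
      - {energy_kev: 70.8,  probability: 0.255, kind: xray,  origin: Pb-203}
      - {energy_kev: 72.9,  probability: 0.430, kind: xray,  origin: Pb-203}
      # 82.1-85.1 keV band stored at midpoint with total probability
      - {energy_kev: 83.6,  probability: 0.190, kind: xray,  origin: Pb-203}
  Pb-212:
    half_life_h: 10.6
    lines:
      - {energy_kev: 238.6,  probability: 0.436, kind: gamma, origin: Pb-212}
      - {energy_kev: 300.1,  probability: 0.033, kind: gamma, origin: Pb-212}
      - {energy_kev: 74.8,   probability: 0.100, kind: xray,  origin: Pb-212}
      - {energy_kev: 77.1,   probability: 0.168, kind: xray,  origin: Pb-212}
      - {energy_kev: 88.45,  probability: 0.075, kind: xray,  origin: Pb-212}  # 86.8-90.1 band
      - {energy_kev: 727.3,  probability: 0.067, kind: gamma, origin: Bi-212}
      - {energy_kev: 785.4,  probability: 0.011, kind: gamma, origin: Bi-212}
      - {energy_kev: 1620.5, probability: 0.015, kind: gamma, origin: Bi-212}
      - {energy_kev: 277.4,  probability: 0.066, kind: gamma, origin: Tl-208}
      - {energy_kev: 510.8,  probability: 0.226, kind: gamma, origin: Tl-208}
      - {energy_kev: 583.2,  probability: 0.850, kind: gamma, origin: Tl-208}
      - {energy_kev: 763.1,  probability: 0.018, kind: gamma, origin: Tl-208}
      - {energy_kev: 860.6,  probability: 0.125, kind: gamma, origin: Tl-208}
      - {energy_kev: 2614.5, probability: 0.998, kind: gamma, origin: Tl-208}
      - {energy_kev: 72.8,   probability: 0.021, kind: xray,  origin: Tl-208}
      - {energy_kev: 75.0,   probability: 0.035, kind: xray,  origin: Tl-208}
      - {energy_kev: 86.05,  probability: 0.015, kind: xray,  origin: Tl-208}  # 84.5-87.6 band

collimators:
  MELP: {hole_length_mm: 40.64, septal_thickness_mm: 1.14, hole_diameter_mm: 2.94}
  HE:   {hole_length_mm: 59.7,  septal_thickness_mm: 2.0,  hole_diameter_mm: 4.0}

# Photopeak width fractions are relative to the photopeak center; scatter-window
# width fractions are relative to the photopeak center as well (not their own).
windows:
  Pb-203:
    279: {photopeak_center: 279.0, photopeak_width: 0.20,
          scatter_width: 0.10, scatter_centers: [237.0, 321.0]}
    72:  {photopeak_center: 72.0, photopeak_width: 0.40,
          scatter_width: 0.20, scatter_centers: [50.0, 94.0]}
  Pb-212:
    239: {photopeak_center: 239.0, photopeak_width: 0.20,
          scatter_width: 0.05, scatter_centers: [209.0, 269.0]}
    79:  {photopeak_center: 79.0, photopeak_width: 0.40,
          scatter_width: 0.20, scatter_centers: [55.0, 103.0]}

# Planar sensitivities (line source, 10 cm) and paralyzable dead-time scale for
# each (nuclide, collimator, photopeak-id) protocol. tau_alpha is 1/A_peak where
# the peak activity was reported directly (Pb-212); for Pb-203 it is derived
# from the reported 10%-loss activity via tau_alpha = -ln(0.9)/A_10.
system:
  Pb-203:
    MELP:
      279: {sensitivity_cps_per_mbq: 78.8,  tau_alpha_per_mbq: 7.394e-05}   # A10 = 1425 MBq
      72:  {sensitivity_cps_per_mbq: 242.0, tau_alpha_per_mbq: 1.1720e-04}  # A10 = 899 MBq
    HE:
      279: {sensitivity_cps_per_mbq: 45.2,  tau_alpha_per_mbq: 5.656e-05}   # A10 = 1863 MBq
      72:  {sensitivity_cps_per_mbq: 173.9, tau_alpha_per_mbq: 7.575e-05}   # A10 = 1391 MBq
  Pb-212:
    MELP:
      239: {sensitivity_cps_per_mbq: 1148.9, tau_alpha_per_mbq: 9.8039e-03}  # A_peak = 102 MBq
      79:  {sensitivity_cps_per_mbq: 965.2,  tau_alpha_per_mbq: 1.1236e-02}  # A_peak = 89 MBq
    HE:
      239: {sensitivity_cps_per_mbq: 622.7, tau_alpha_per_mbq: 5.1813e-03}   # A_peak = 193 MBq
      79:  {sensitivity_cps_per_mbq: 524.3, tau_alpha_per_mbq: 6.0241e-03}   # A_peak = 166 MBq

# NEMA IQ phantom fill schemes at scan time (kBq/ml); true_ratio is the
# unrounded sphere-to-background concentration ratio where one was reported.
phantom_presets:
  Pb-203:
    spheres-only: {sphere_kbq_ml: 39.8, background_kbq_ml: 0.0, true_ratio: null}
    contrast-8to1: {sphere_kbq_ml: 38.4, background_kbq_ml: 4.8, true_ratio: 7.73}
    contrast-4to1: {sphere_kbq_ml: 37.3, background_kbq_ml: 9.3, true_ratio: 3.94}
  Pb-212:
    spheres-only: {sphere_kbq_ml: 39.1, background_kbq_ml: 0.0, true_ratio: null}
    contrast-8to1: {sphere_kbq_ml: 31.6, background_kbq_ml: 4.0, true_ratio: 7.71}
    contrast-4to1: {sphere_kbq_ml: 25.8, background_kbq_ml: 6.4, true_ratio: 3.98}
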