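# Bundled polymer profile library (implementer-chosen model parameters).
#
# Band positions follow published NIR group-frequency assignments for each
# matrix (C-H first/second overtones 6000-5600 / 8600-8200 cm^-1,
# 2nu+delta combinations ~7200-7000, nu+delta combinations 4500-4200,
# N-H overtones 6700-6300, O-H overtones 7200-6200); every matrix carries a
# band at its difference-spectroscopy reference wavenumber.  Water-band
# center endpoints (1 % -> 10 % w/w) are the per-polymer shift ranges of
# the overtone (~6900 cm^-1) and combination (~5200 cm^-1) water bands;
# PTFE, which does not mix with water, gets unshifted bulk-water positions.
# Amplitudes (AU) and widths are realistic for diffuse-reflectance FT-NIR
# but are modelling choices, not measurements.
#
# Trends encoded along the hydrophilicity ranking (rank 1 = most
# hydrophobic): bulk-water shoulder weight decreases, residual bound-water
# amplitude increases, polymer-band/water coupling increases, and the
# overtone-band response exponent crosses from <= 1 (overtone leads the
# combination band) to > 1 (overtone lags).
#
# bands: [center_cm-1, fwhm_cm-1, amplitude_AU]

profiles:
  PTFE:
    rank: 1
    coupling: 0.05
    bands:
      - [8700, 300, 0.02]
      - [5944, 150, 0.06]
      - [4380, 160, 0.05]
    water:
      overtone_center_lo: 6900.0
      overtone_center_hi: 6900.0
      combination_center_lo: 5180.0
      combination_center_hi: 5180.0
      overtone_fwhm: 320.0
      combination_fwhm: 240.0
      overtone_amplitude_per_w: 5.5
      combination_amplitude_per_w: 7.5
      residual_amplitude: 0.0
      shoulder_offset: 450.0
      shoulder_weight: 0.55
      overtone_exponent: 1.0
      combination_exponent: 1.0
  PP:
    rank: 2
    coupling: 0.10
    bands:
      - [8400, 260, 0.18]
      - [8250, 220, 0.12]
      - [7180, 200, 0.10]
      - [6200, 180, 0.05]
      - [5796, 170, 0.55]
      - [5680, 180, 0.35]
      - [4330, 170, 0.45]
    water:
      overtone_center_lo: 6796.0
      overtone_center_hi: 6836.0
      combination_center_lo: 5180.0
      combination_center_hi: 5180.0
      overtone_fwhm: 280.0
      combination_fwhm: 230.0
      overtone_amplitude_per_w: 5.5
      combination_amplitude_per_w: 7.5
      residual_amplitude: 0.004
      shoulder_offset: 380.0
      shoulder_weight: 0.50
      overtone_exponent: 1.0
      combination_exponent: 1.0
  PS:
    rank: 3
    coupling: 0.15
    bands:
      - [8770, 250, 0.12]
      - [7180, 200, 0.06]
      - [5952, 160, 0.50]
      - [5770, 180, 0.25]
      - [4610, 160, 0.35]
      - [4250, 150, 0.30]
    water:
      overtone_center_lo: 6812.0
      overtone_center_hi: 6852.0
      combination_center_lo: 5248.0
      combination_center_hi: 5176.0
      overtone_fwhm: 290.0
      combination_fwhm: 230.0
      overtone_amplitude_per_w: 5.5
      combination_amplitude_per_w: 7.5
      residual_amplitude: 0.006
      shoulder_offset: 380.0
      shoulder_weight: 0.45
      overtone_exponent: 0.85
      combination_exponent: 1.0
  PVC:
    rank: 4
    coupling: 0.20
    bands:
      - [8450, 260, 0.10]
      - [7160, 200, 0.05]
      - [5828, 170, 0.45]
      - [5700, 190, 0.25]
      - [4340, 170, 0.35]
    water:
      overtone_center_lo: 6808.0
      overtone_center_hi: 6842.0
      combination_center_lo: 5256.0
      combination_center_hi: 5180.0
      overtone_fwhm: 290.0
      combination_fwhm: 230.0
      overtone_amplitude_per_w: 5.5
      combination_amplitude_per_w: 7.5
      residual_amplitude: 0.008
      shoulder_offset: 380.0
      shoulder_weight: 0.40
      overtone_exponent: 0.88
      combination_exponent: 1.0
  POM:
    rank: 5
    coupling: 0.25
    bands:
      - [8500, 260, 0.08]
      - [7150, 200, 0.06]
      - [5968, 170, 0.45]
      - [5800, 200, 0.20]
      - [4400, 180, 0.30]
    water:
      overtone_center_lo: 6822.0
      overtone_center_hi: 6826.0
      combination_center_lo: 5228.0
      combination_center_hi: 5204.0
      overtone_fwhm: 300.0
      combination_fwhm: 240.0
      overtone_amplitude_per_w: 5.5
      combination_amplitude_per_w: 7.5
      residual_amplitude: 0.012
      shoulder_offset: 380.0
      shoulder_weight: 0.30
      overtone_exponent: 1.08
      combination_exponent: 1.0
  PA:
    rank: 6
    coupling: 0.30
    bands:
      - [8300, 260, 0.10]
      - [6650, 240, 0.15]
      - [5960, 180, 0.20]
      - [5828, 180, 0.40]
      - [4870, 200, 0.25]
      - [4340, 170, 0.30]
    water:
      overtone_center_lo: 6828.0
      overtone_center_hi: 6840.0
      combination_center_lo: 5140.0
      combination_center_hi: 5164.0
      overtone_fwhm: 300.0
      combination_fwhm: 240.0
      overtone_amplitude_per_w: 5.5
      combination_amplitude_per_w: 7.5
      residual_amplitude: 0.014
      shoulder_offset: 380.0
      shoulder_weight: 0.20
      overtone_exponent: 1.12
      combination_exponent: 1.0
  lignin:
    rank: 7
    coupling: 0.35
    bands:
      - [8760, 260, 0.08]
      - [7090, 240, 0.12]
      - [5964, 180, 0.45]
      - [5780, 200, 0.20]
      - [4680, 200, 0.20]
    water:
      overtone_center_lo: 7084.0
      overtone_center_hi: 7064.0
      combination_center_lo: 5224.0
      combination_center_hi: 5208.0
      overtone_fwhm: 340.0
      combination_fwhm: 260.0
      overtone_amplitude_per_w: 5.5
      combination_amplitude_per_w: 7.5
      residual_amplitude: 0.016
      shoulder_offset: 450.0
      shoulder_weight: 0.15
      overtone_exponent: 1.15
      combination_exponent: 1.0
  chitin:
    rank: 8
    coupling: 0.40
    bands:
      - [8570, 260, 0.06]
      - [7080, 230, 0.15]
      - [6540, 260, 0.12]
      - [5800, 180, 0.40]
      - [4890, 200, 0.25]
      - [4620, 180, 0.30]
    water:
      overtone_center_lo: 7048.0
      overtone_center_hi: 7024.0
      combination_center_lo: 5176.0
      combination_center_hi: 5164.0
      overtone_fwhm: 330.0
      combination_fwhm: 250.0
      overtone_amplitude_per_w: 5.5
      combination_amplitude_per_w: 7.5
      residual_amplitude: 0.018
      shoulder_offset: 420.0
      shoulder_weight: 0.08
      overtone_exponent: 1.20
      combination_exponent: 1.0
  cellulose:
    rank: 9
    coupling: 0.45
    bands:
      - [9090, 420, 0.04]
      - [7000, 260, 0.18]
      - [6480, 300, 0.15]
      - [5604, 180, 0.45]
      - [4760, 200, 0.30]
      - [4280, 180, 0.25]
    water:
      overtone_center_lo: 7100.0
      overtone_center_hi: 7120.0
      combination_center_lo: 5180.0
      combination_center_hi: 5172.0
      overtone_fwhm: 340.0
      combination_fwhm: 260.0
      overtone_amplitude_per_w: 5.5
      combination_amplitude_per_w: 7.5
      residual_amplitude: 0.020
      shoulder_offset: 380.0
      shoulder_weight: 0.05
      overtone_exponent: 1.25
      combination_exponent: 1.0
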