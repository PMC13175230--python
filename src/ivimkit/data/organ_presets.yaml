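# Consensus acquisition constants and literature IVIM priors per organ.
#
# b-values in s/mm^2; D and Dstar in mm^2/s; TR in s; resolution and slice
# thickness in mm.  "abbreviated" b-sets are 3 values including b = 0;
# "minimal" sets are 6 values (repeats, notably b = 0, are intentional and
# preserved).  b_threshold is the segmented-fit cut-off.
#
# Priors: reconstructed placeholder values assembled from published
# organ-level IVIM meta-analyses and reviews (mean, sd per parameter).  The
# brain Dstar mean is pinned so that the factor-20 pseudo-diffusion
# suppression b-value ln(20)/Dstar equals the conventional 275 s/mm^2 brain
# threshold.  Override this file (or individual entries) to use your own
# literature table.
reference_snr: 25

organs:
  brain:
    abbreviated_b: [0, 300, 1000]
    minimal_b: [0, 0, 70, 300, 400, 1000]
    b_threshold: 300
    tr_min: 4.0
    te_rule: minimum
    averages_min: 1
    n_directions_min: 3
    fat_suppression: SPIR
    in_plane_resolution_mm: [1.0, 3.0]
    slice_thickness_mm: [1.2, 3.0]
    prior:
      f: {mean: 0.05, sd: 0.02}
      D: {mean: 0.00075, sd: 0.00015}
      Dstar: {mean: 0.0109, sd: 0.004}
  breast:
    abbreviated_b: [0, 200, 800]
    minimal_b: [0, 30, 70, 200, 330, 800]
    b_threshold: 200
    tr_min: 4.0
    te_rule: minimum
    averages_min: 1
    n_directions_min: 3
    fat_suppression: SPAIR
    in_plane_resolution_mm: [1.8, 3.0]
    slice_thickness_mm: [2.0, 4.0]
    prior:
      f: {mean: 0.08, sd: 0.04}
      D: {mean: 0.0012, sd: 0.0003}
      Dstar: {mean: 0.025, sd: 0.012}
  kidney:
    abbreviated_b: [0, 200, 800]
    minimal_b: [0, 30, 70, 100, 200, 800]
    b_threshold: 200
    tr_min: 3.0
    te_rule: minimum
    averages_min: 1
    n_directions_min: 3
    fat_suppression: SPAIR
    in_plane_resolution_mm: [2.0, 3.0]
    slice_thickness_mm: [2.5, 5.0]
    prior:
      f: {mean: 0.18, sd: 0.06}
      D: {mean: 0.0017, sd: 0.0003}
      Dstar: {mean: 0.030, sd: 0.015}
  liver:
    abbreviated_b: [0, 200, 500]
    minimal_b: [0, 10, 20, 100, 200, 500]
    b_threshold: 200
    tr_min: 3.0
    te_rule: minimum
    averages_min: 1
    n_directions_min: 3
    fat_suppression: SPAIR
    in_plane_resolution_mm: [2.0, 4.0]
    slice_thickness_mm: [4.0, 6.0]
    prior:
      f: {mean: 0.24, sd: 0.07}
      D: {mean: 0.0011, sd: 0.0002}
      Dstar: {mean: 0.070, sd: 0.030}
  muscle:
    abbreviated_b: [0, 200, 600]
    minimal_b: [0, 40, 70, 200, 300, 600]
    b_threshold: 200
    tr_min: 4.0
    te_rule: minimum
    averages_min: 2
    n_directions_min: 3
    fat_suppression: SPAIR
    in_plane_resolution_mm: [1.8, 3.0]
    slice_thickness_mm: [4.0, 6.0]
    prior:
      f: {mean: 0.09, sd: 0.04}
      D: {mean: 0.0014, sd: 0.0002}
      Dstar: {mean: 0.030, sd: 0.015}
  pancreas:
    abbreviated_b: [0, 200, 600]
    minimal_b: [0, 0, 50, 200, 290, 600]
    b_threshold: 200
    tr_min: 3.0
    te_rule: minimum
    averages_min: 1
    n_directions_min: 3
    fat_suppression: SPAIR
    in_plane_resolution_mm: [2.0, 3.0]
    slice_thickness_mm: [2.0, 4.0]
    prior:
      f: {mean: 0.12, sd: 0.05}
      D: {mean: 0.0013, sd: 0.0003}
      Dstar: {mean: 0.025, sd: 0.012}
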