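# Example run configuration for `gastrokt run --config configs/example.yaml --out runs/demo`
# Any omitted field falls back to the documented default.

n_frames: 60        # gated volumes to simulate
reduction: 3        # undersampling factor R at the k-space periphery
n_acs: 12           # fully sampled auto-calibration lines
kx_halfwidth: 2     # kernel taps along the frequency-encode axis: 2*2+1 = 5
per_slice: false    # share one kernel set across slices
positions: [2.0, 5.0]  # cross-section positions (mm) along the hinted antral axis
seed: 0

phantom:
  grid: [64, 64, 4]
  voxel_size: [0.5, 0.5, 1.5]      # mm
  contraction_amplitude: 0.231     # radius occlusion ratio
  contraction_frequency: 5.3       # cycles per minute
  contraction_velocity: 0.56       # mm/s along the antral axis
  respiration_rate: 40.0           # cycles per minute
  respiration_displacement: 0.0    # mm through-plane shift during bursts
  noise_sigma: 0.0                 # Gaussian sigma as a fraction of lumen signal

tissue:
  t1_lumen: 17.0      # ms, Gd-doped meal
  t1_tissue: 800.0    # ms, saturated surrounding tissue
  t_rec: 127.0        # ms, saturation-to-echo recovery interval
  background_level: 0.05

acquisition:
  tr: 10.6            # ms
  te: 1.6             # ms
  fa: 25.0            # degrees
  n_slices: 24
  slices_per_packet: 4
  n_packets: 6
  lines_per_slice_per_frame: 24
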