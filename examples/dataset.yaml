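# Synthetic mini-stack dataset: a rim-marker ring plus an interior disk at
# half its radius, imaged with a 70 nm-sigma PSF and Poisson noise.
image_size_px: 161
pixel_size_nm: 50.0
psf_sigma_nm: 70.0
poisson_noise: true
read_noise_sd: 0.0
background_level: 0.0
structures:
  - channel_name: giantin
    kind: ring
    radius_mean_px: 55
    radius_sd_px: 3
    ring_width_px: 2
    total_intensity: 200000
    center_jitter_px: 2
  - channel_name: marker
    kind: disk
    radius_ratio_of: giantin
    radius_ratio: 0.5
    total_intensity: 200000
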