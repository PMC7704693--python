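# Dynamic digital head-phantom study: full dose, 50% and 25% dose with
# plain regridding, plus KWIA at 50% (2 and 3 rings) and 25% (3 and 4
# rings) -- seven experimental conditions in total.
schema: kwia-study/1
name: digital-phantom
seed: 1

geometry:
  n_detectors: 728
  detector_spacing: 0.75   # mm
  n_views_per_rotation: 1152

phantom:
  preset: forbild-head
  image_size: 384
  pixel_spacing: 0.75      # mm
  n_frames: 27
  frame_interval: 2.0      # s

n_emitted: 4.8e6           # full-dose emitted photons per detector per view

kernel:
  beta: 16.25
  width: 7
  oversampling: 2

# dose levels 1.0 / 0.5 / 0.25 are always reconstructed plainly; KWIA
# conditions reference the published ring presets
kwia:
  - {dose: 0.5,  rings: kwia50-2ring}
  - {dose: 0.5,  rings: kwia50-3ring}
  - {dose: 0.25, rings: kwia25-3ring}
  - {dose: 0.25, rings: kwia25-4ring}

rois:
  snr:
    center_mm: [40.0, 20.0]
    radius_mm: 14.0

output:
  write_images: false
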