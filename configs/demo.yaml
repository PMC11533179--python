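# End-to-end demo: spectra chain (CLS, lifetimes, decay map) + trajectory
# analytics (motifs, RDF, hydration, VDOS).  Run with:
#   calpep run --config configs/demo.yaml --out calpep_run
seed: 7
stages: [spectra, trajectory]
spectra:
  waiting_times: [0.0, 0.2, 0.4, 0.6, 0.8, 1.2, 1.6, 2.0, 3.0, 4.0]
  noise_rms: 0.005
  cls_fit_window: 0.8
trajectory:
  n_frames: 600
  state_fractions:
    "1Ca@COO": 0.26
    "2Ca@COO": 0.26
    "1Ca@CO": 0.02
    "1Ca@COO+1Ca@CO": 0.13
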