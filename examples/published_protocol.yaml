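# Published-protocol configuration: 41 umbrella windows at 0.1 nm spacing
# (1.0-5.0 nm), 41 WHAM bins, bulk reference at r = 1.0 nm, hydrogen-bond
# cutoffs 3.5 angstrom / 30 degrees. The vacuum wall moves to 4.6 nm so the
# wider ladder is physically reachable.
published_protocol: true
master_seed: 7
windows:
  n_steps: 2000000   # 20000 stored frames per window; raise for production
slab:
  n_frames: 50
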