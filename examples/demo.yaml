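# Desk-scale demonstration run: an 8 nm double-wall segment whose outer
# wall recovers over 10 frames with slow patch reorientation.
# Run with:  excitube pipeline --config examples/demo.yaml
tube:
  radius_iw: 3.45     # nm (6.9 nm inner diameter)
  radius_ow: 6.75     # nm (13.5 nm outer diameter)
  length: 8.0         # nm
assembly:
  adsorption_rate: 0.3          # per empty site per step
  nucleation_orientation_spread: 3.14159265  # pi: fully random new patches
  patch_reorientation_rate: 0.5 # per step, scaled by inverse patch size
  n_steps: 9                    # 10 frames including the initial one
exciton:
  n_realizations: 200           # 1000 reproduces the full averaging
window:
  lo: 15324.0                   # cm^-1, wide band covering the wall spectrum
  hi: 18550.0
grid_step: 2.0
seed: 42
outdir: excitube_demo
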