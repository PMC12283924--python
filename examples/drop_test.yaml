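# Liver-like ellipsoid phantom dropped 0.5 m onto a frictional ground plane.
# Softest shear-wave-elastography preset (E = 2.1972 kPa, nu = 0.4597).
mesh:
  phantom:
    shape: ellipsoid
    semi_axes: [0.08, 0.05, 0.06]
    resolution: 8
material:
  preset: liver_soft
  density: 1000.0
solver:
  dt: 0.016666666666666666   # 60 fps frame step
  substeps: 64
  iterations: 1
  mode: xpbd
constraints:
  distance: true
  volume: true
  neo: true
  shape_matching:
    enabled: true
    clusters: grid
    cluster_cells: 3
colliders:
  - type: plane
    point: [0.0, 0.0, 0.0]
    normal: [0.0, 1.0, 0.0]
    friction: 0.5
    restitution: 0.0
initial:
  drop_height: 0.5
  jitter: 0.001
output:
  frame_format: none
frames: 45
seed: 1
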