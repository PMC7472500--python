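# Nominal geometry of the rigid dummy-foot validation rig.
#
# Three styrofoam box segments (toe, forefoot, rearfoot) rest on reference
# plates A, B, C; each plate carries markers o, x, z that define the
# ground-truth frames. Landmark coordinates are millimetres in the lab frame
# (right foot: X anterior from the heel, Y up from the floor, Z lateral).
#
# Marker placement on the boxes is a declared assumption of this package
# (the physical rig's placement was never published): each landmark sits at
# a plausible position on its box face, and the coordinates are chosen so
# that every nominal segment frame is exactly lab-aligned at the neutral
# position. Landmarks shared between adjoining segments (H1, H2, H5 at the
# toe/forefoot boundary; NV, B5 at the forefoot/rearfoot boundary) appear
# once per segment, mirroring the duplicated physical markers.
#
# Edit freely: the simulator reads whatever is here.

boxes:          # height, width, length in mm
  toe:      {height: 30, width: 80, length: 55}
  forefoot: {height: 50, width: 80, length: 95}
  rearfoot: {height: 50, width: 65, length: 75}

segment_markers:
  toe:
    P1: [220.0, 30.0, -26.0]
    H1: [172.0, 30.0, -26.0]
    H2: [172.0, 30.0, 0.0]
    H5: [172.0, 30.0, 34.0]
  forefoot:
    H1: [168.0, 50.0, -26.0]
    H2: [168.0, 50.0, 0.0]
    H5: [168.0, 50.0, 34.0]
    B1: [95.0, 50.0, -28.0]
    B2: [97.0, 50.0, 0.0]
    B5: [80.0, 50.0, 33.0]
    NV: [78.0, 50.0, -33.0]
  rearfoot:
    NV: [72.0, 50.0, -32.0]
    B5: [72.0, 50.0, 32.0]
    ST: [40.0, 38.0, -32.0]
    PT: [40.0, 36.0, 32.0]
    C1: [8.0, 50.0, 0.0]
    C2: [2.0, 12.0, 0.0]
  shank:        # rigid rod above the rearfoot; static in every sweep
    LM: [15.0, 60.0, 34.0]
    MM: [15.0, 60.0, -34.0]
    TT: [15.0, 400.0, 0.0]
    HF: [15.0, 395.0, 36.0]

plates:         # marker positions o, x, z on the floor (y = 0)
  A: {o: [197.5, 0.0, 0.0], x: [247.5, 0.0, 0.0], z: [197.5, 0.0, 50.0]}
  B: {o: [122.5, 0.0, 0.0], x: [172.5, 0.0, 0.0], z: [122.5, 0.0, 50.0]}
  C: {o: [37.5, 0.0, 0.0], x: [87.5, 0.0, 0.0], z: [37.5, 0.0, 50.0]}

plate_segment: {A: toe, B: forefoot, C: rearfoot}

# Which segment's copy supplies each marker when a trial carries one marker
# per landmark (static / living-body style trials).
canonical_attachment:
  P1: toe
  H1: forefoot
  H2: forefoot
  H5: forefoot
  B1: forefoot
  B2: forefoot
  B5: rearfoot
  NV: rearfoot
  ST: rearfoot
  PT: rearfoot
  C1: rearfoot
  C2: rearfoot
  LM: shank
  MM: shank
  TT: shank
  HF: shank
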