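# Static chemical knowledge for the six nucleobases handled by pairdex.
#
# Canonical numbering follows the usual purine (N1,C2,N3,C4,C5,C6,N7,C8,N9)
# and pyrimidine (N1,C2,N3,C4,C5,C6) schemes.  Ideal in-plane heavy-atom
# coordinates (Angstrom, z=0) come from standard nucleobase reference-frame
# geometries; "c1p" is the position of the glycosidic substituent carbon.
# Edge membership solves the constraint set implied by the full pair-name
# catalog (purine C8 on both H and S; pyrimidine C6 on S).

bases:
  A:
    kind: purine
    ring_atoms: [[1, N], [2, C], [3, N], [4, C], [5, C], [6, C], [7, N], [8, C], [9, N]]
    exocyclic_atoms: [[6, N, amino]]    # amino nitrogen is labelled by its ring position's number, stored under key 6 as N6
    glycosidic_atom: 9
    bonds: [[1, 2], [2, 3], [3, 4], [4, 5], [5, 6], [6, 1], [5, 7], [7, 8], [8, 9], [9, 4]]
    edges: {W: [1, 2, 6], H: [6, 7, 8], S: [2, 3, 8, 9]}
    neutral_nh: {R: [], free: [9]}
    coords:
      N1: [-0.668, 0.532]
      C2: [-1.912, 1.023]
      N3: [-2.320, 2.290]
      C4: [-1.267, 3.124]
      C5: [0.071, 2.771]
      C6: [0.369, 1.398]
      N6: [1.611, 0.909]
      N7: [0.877, 3.902]
      C8: [0.024, 4.897]
      N9: [-1.291, 4.498]
      c1p: [-2.479, 5.346]
  G:
    kind: purine
    ring_atoms: [[1, N], [2, C], [3, N], [4, C], [5, C], [6, C], [7, N], [8, C], [9, N]]
    exocyclic_atoms: [[6, O, carbonyl], [2, N, amino]]
    glycosidic_atom: 9
    bonds: [[1, 2], [2, 3], [3, 4], [4, 5], [5, 6], [6, 1], [5, 7], [7, 8], [8, 9], [9, 4]]
    edges: {W: [1, 2, 6], H: [6, 7, 8], S: [2, 3, 8, 9]}
    neutral_nh: {R: [1], free: [1, 9]}
    coords:
      N1: [-0.700, 0.641]
      C2: [-1.999, 1.087]
      N2: [-2.949, 0.139]
      N3: [-2.342, 2.364]
      C4: [-1.265, 3.177]
      C5: [0.071, 2.833]
      C6: [0.424, 1.460]
      O6: [1.554, 0.955]
      N7: [0.870, 3.969]
      C8: [0.023, 4.962]
      N9: [-1.289, 4.551]
      c1p: [-2.477, 5.399]
  Hx:
    kind: purine
    ring_atoms: [[1, N], [2, C], [3, N], [4, C], [5, C], [6, C], [7, N], [8, C], [9, N]]
    exocyclic_atoms: [[6, O, carbonyl]]
    glycosidic_atom: 9
    bonds: [[1, 2], [2, 3], [3, 4], [4, 5], [5, 6], [6, 1], [5, 7], [7, 8], [8, 9], [9, 4]]
    edges: {W: [1, 2, 6], H: [6, 7, 8], S: [2, 3, 8, 9]}
    neutral_nh: {R: [1], free: [1, 9]}
    coords:
      N1: [-0.700, 0.641]
      C2: [-1.999, 1.087]
      N3: [-2.342, 2.364]
      C4: [-1.265, 3.177]
      C5: [0.071, 2.833]
      C6: [0.424, 1.460]
      O6: [1.554, 0.955]
      N7: [0.870, 3.969]
      C8: [0.023, 4.962]
      N9: [-1.289, 4.551]
      c1p: [-2.477, 5.399]
  T:
    kind: pyrimidine
    ring_atoms: [[1, N], [2, C], [3, N], [4, C], [5, C], [6, C]]
    exocyclic_atoms: [[2, O, carbonyl], [4, O, carbonyl], [5, C, methyl]]
    glycosidic_atom: 1
    bonds: [[1, 2], [2, 3], [3, 4], [4, 5], [5, 6], [6, 1]]
    edges: {W: [2, 3, 4], H: [4, 5], S: [1, 2, 6]}
    neutral_nh: {R: [3], free: [1, 3]}
    coords:
      N1: [-1.284, 4.500]
      C2: [-1.462, 3.135]
      O2: [-2.562, 2.608]
      N3: [-0.298, 2.407]
      C4: [0.994, 2.897]
      O4: [1.944, 2.119]
      C5: [1.106, 4.338]
      C7: [2.466, 4.961]
      C6: [-0.024, 5.057]
      c1p: [-2.481, 5.354]
  U:
    kind: pyrimidine
    ring_atoms: [[1, N], [2, C], [3, N], [4, C], [5, C], [6, C]]
    exocyclic_atoms: [[2, O, carbonyl], [4, O, carbonyl]]
    glycosidic_atom: 1
    bonds: [[1, 2], [2, 3], [3, 4], [4, 5], [5, 6], [6, 1]]
    edges: {W: [2, 3, 4], H: [4, 5], S: [1, 2, 6]}
    neutral_nh: {R: [3], free: [1, 3]}
    coords:
      N1: [-1.284, 4.500]
      C2: [-1.462, 3.131]
      O2: [-2.563, 2.608]
      N3: [-0.302, 2.397]
      C4: [0.989, 2.884]
      O4: [1.935, 2.094]
      C5: [1.089, 4.311]
      C6: [-0.024, 5.053]
      c1p: [-2.481, 5.354]
  C:
    kind: pyrimidine
    ring_atoms: [[1, N], [2, C], [3, N], [4, C], [5, C], [6, C]]
    exocyclic_atoms: [[2, O, carbonyl], [4, N, amino]]
    glycosidic_atom: 1
    bonds: [[1, 2], [2, 3], [3, 4], [4, 5], [5, 6], [6, 1]]
    edges: {W: [2, 3, 4], H: [4, 5], S: [1, 2, 6]}
    neutral_nh: {R: [], free: [1]}
    coords:
      N1: [-1.285, 4.542]
      C2: [-1.472, 3.158]
      O2: [-2.628, 2.709]
      N3: [-0.391, 2.344]
      C4: [0.837, 2.868]
      N4: [1.875, 2.027]
      C5: [1.056, 4.275]
      C6: [-0.023, 5.068]
      c1p: [-2.477, 5.402]

# Bondi van der Waals radii (Angstrom) -- the convention of CSD contact work.
vdw_radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  F: 1.47
  P: 1.80
  S: 1.80
  Cl: 1.75
  Br: 1.85
  I: 1.98

# Cordero covalent radii (Angstrom) for bond inference; sparse -- elements
# missing here fall back to 1.5 A (generous, only relevant for metal contacts).
covalent_radii:
  H: 0.31
  B: 0.84
  C: 0.76
  N: 0.71
  O: 0.66
  F: 0.57
  Na: 1.66
  Mg: 1.41
  Si: 1.11
  P: 1.07
  S: 1.05
  Cl: 1.02
  K: 2.03
  Ca: 1.76
  Mn: 1.39
  Fe: 1.32
  Co: 1.26
  Ni: 1.24
  Cu: 1.32
  Zn: 1.22
  Br: 1.20
  I: 1.39

# Mean neutron-determined D-H covalent bond lengths (Angstrom) used to
# renormalize X-ray hydrogen positions.
neutron_dh:
  C: 1.083
  N: 1.009
  O: 0.983

geometry_defaults:
  da_margin: 1.0          # D...A must be within vdW sum + this margin (A)
  plane_angle_max: 45.0   # max angle between D...A vector and each ring plane (deg)
  dha_min: 120.0          # min D-H...A angle when H is modeled (deg)
  covalent_tolerance: 0.4 # bond inference slack over covalent-radius sum (A)
  min_hbonds: 2           # bonds required for a base pair
  contact_radius: 6.0     # symmetry-expansion envelope (A)
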