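# Methods

## Scope and model

`pairdex` treats a nucleobase homo-pair as two recognized base moieties
joined by at least two in-plane hydrogen bonds. The pipeline is purely
geometric/topological: no energies, no tautomer prediction, no pKa
modeling. Six bases are covered (A, G, Hx, T, U, C); modified bases and
hetero-pairs are out of scope (hetero-pair *naming* is supported as a
documented convention but no hetero fixtures are generated).

## Base recognition

Covalent bonds are inferred from interatomic distances (Cordero covalent
radii + 0.4 Å; each hydrogen is attached to its nearest heavy atom, and a
hydrogen with no heavy atom within 1.3 Å is dropped with a warning). An
explicit CIF `_geom_bond` table, when present, is used verbatim.

Each base template (ring topology + exocyclic groups, with elements) is
matched by induced subgraph isomorphism against every covalent molecule.
A match survives only if

* every non-hydrogen substituent sits at the glycosidic nitrogen and is a
  carbon (recorded as the C1′ substituent), and
* no matched atom is covalently bonded to an element outside
  {H, C, N, O, P, S, halogens, B, Se} (organometallic exclusion).

These two rules also disambiguate nested templates (hypoxanthine inside
guanine fails on the N2 substituent; uracil inside thymine fails on the
C5 methyl). The canonical atom numbering is unique for these templates —
no element-preserving automorphism exists — so the atom map needs no
tie-breaking.

In pair names and edge maps, a canonical number denotes the exocyclic
heavy atom where one exists at that position (A 6 → N6; G 2 → N2, 6 → O6;
U/T 2 → O2, 4 → O4; C 4 → N4) and the ring atom otherwise; thymine's
number 5 keeps meaning the ring C5, with the methyl carbon stored
separately.

### Protonation and charge

The protonation pattern lists every ring nitrogen in ascending order
(`1H` protonated, `1` not, `9R` substituted). A base's H statuses are
taken as determined iff the base carries **at least one** modeled
hydrogen; otherwise the pattern is `R?` / `No R?` and the charge is
unknown — nothing is ever imputed from chemical intuition. A hydrogen on
a carbonyl oxygen is recorded verbatim with a nonstandard-protonation
warning. Formal charge is

    charge = |observed ring N–H set| − |neutral reference set|

with neutral references A: {} (substituted) / {9} (free), G and Hx: {1} /
{1, 9}, T and U: {3} / {1, 3}, C: {} / {1}. Amino groups always carry two
protons and carbonyls none, so only ring nitrogens enter the count.

## Edge membership

Edge maps are fixed by solving the constraint set implied by the printed
pair-name catalog: purines W {1,2,6}, H {6,7,8}, S {2,3,8,9}; pyrimidines
W {2,3,4}, H {4,5}, S {1,2,6}. Purine C8 carries dual H/S membership
(forced by `HxHx_fHS_(68)(79)`) and pyrimidine C6 sits on the Sugar edge
(forced by `CC_fWS_(26)(31)(42)`). When an atom set fits more than one
edge, precedence is W > H > S.

## Hydrogen-bond criteria

A donor/acceptor candidate (roles derived from the protonation pattern;
unknown patterns get the donor/acceptor capability union) becomes a
hydrogen bond iff

1. d(D…A) ≤ vdW(D) + vdW(A) + 1.0 Å (Bondi radii),
2. the D…A vector lies within 45° of **both** ring planes (the stricter,
   symmetric reading of the planarity criterion), and
3. when a hydrogen is bonded to the donor, the best D–H…A angle over its
   hydrogens is ≥ 120°. Bases without modeled hydrogens skip this test,
   as does thymine's C5, whose donation is methyl-mediated (no hydrogen
   is bonded to C5 itself).

All passing candidates are then filtered to an **atom-exclusive**
assignment: each canonical atom joins at most one bond of the pair, the
contact with the most slack below its vdW threshold winning (ties broken
by larger angle, then atom numbers). No catalogued pair type reuses an
atom, while mechanical threshold application adds weak secondary
contacts (3.7–4.0 Å, 120–140°) riding on already-engaged atoms in at
least seven catalog geometries; the exclusivity rule keeps exactly the
defining bonds. This deliberately trades away genuinely bifurcated
motifs, which do not occur in the catalog.

Pairs need ≥ 2 bonds. Ring planes are least-squares fits to the
six-membered-ring circuit with the normal signed by the right-hand rule
around the canonical circuit, making it a face label: antiparallel
normals ⇒ `f` (flipped, cis-like), parallel ⇒ `m` (moved, trans-like). A
ring whose atoms are collinear (second singular value < 1e-6) raises a
degenerate-geometry error.

### D–H normalization

X-ray refinement places hydrogens ~0.2 Å too close to the donor, so for
all reported geometry the hydrogen is slid along the D–H direction to the
mean neutron length (C–H 1.083, N–H 1.009, O–H 0.983 Å); D…A is
untouched, H…A and D–H…A are recomputed. The operation is idempotent and
preserves collinearity. Acceptance/rejection of a bond uses the observed
hydrogen, normalization only affects statistics.

## Symmetry handling

When a cell and symmetry operators are present, whole covalent molecules
(never fragments) are copied under every operator and lattice translation
that brings any atom within the contact envelope (default 6 Å — a
superset of the maximum D…A threshold ≈ 4.1 Å plus molecular reach).
Identity images and copies coinciding with existing atoms are skipped,
which makes expansion idempotent. During pair detection, pairs between
two symmetry mates are skipped (they are images of an asymmetric-unit
pair) and surviving pairs are deduplicated by a canonical signature: the
pair name plus bond distances rounded to 0.01 Å and the interplanar angle
and C1′…C1′ distance quantized — below coordinate precision, above
numerical noise. Coordinate-only inputs (no cell) simply skip expansion.
R-factor filtering is off by default; `pairdex scan --max-r` enables it.

## Naming

Molecule order: edge precedence W > H > S; for equal edges, hetero pairs
put the purine first, then alphabetical; homo pairs put the molecule with
the lexicographically smaller sorted atom list first; fully symmetric
bond lists render identically either way. Bond groups are sorted by first
atom, then second. The renderer always emits ascending order; because one
published three-bond guanine name is spelled out of order, catalog
matching treats bond lists as sets. Short names (`AA_(16)(67)`) are
resolved against the 47-entry catalog, since the orientation letter is
not derivable from text alone. `f` ↔ *cis* and `m` ↔ *trans* for the
Leontis–Westhof mapping, with edges passed through unchanged.

## Survey aggregation

Frequencies count one occurrence per (refcode family, pair type): a
family is the six-letter stem of ids like `ABCDEF01`; anything not
matching that shape is its own family. A family showing several pair
types contributes to each. Geometry statistics (mean/sd/min/max of
normalized D–H, H…A, D…A, D–H…A, and C1′…C1′) use **all** depositions and
all unique bonds of symmetric pairs; hydrogen-free structures enter D…A
and C1′…C1′ statistics only. Protonation cross-tabs key on the
header-style class string (two differing patterns joined
least-protonated-first). "Substituted" aggregates the classes with an R
substituent plus `R?`; "free" the rest plus `No R?`. Percentages are kept
at full precision internally and rounded only for display.

Transcriptions of the published per-base count tables ship as TSV package
data, cells verbatim including `-` (cannot form under that protonation)
and `NA` (substituent forbids). Two transcription caveats: the guanine
table's printed grand total (103) disagrees with its own cells, which sum
to 104 (its printed `No R?` column sum omits one of two entries) — the
package reports the cell sum; and the published adenine/guanine headline
percentages 41.46 %, 13.23 %, 55.95 % and 27.38 % are inconsistent with
any column-sum denominator of those same tables, so the recomputed values
(41.67 %, 14.29 %, 56.63 %, 26.51 %) are what the arithmetic yields. All
other published percentages reproduce exactly.

## Synthetic fixtures

`ideal_base` builds a planar base at z = 0 from frozen internal
coordinates (standard nucleobase reference-frame geometries; ring and
exocyclic bond lengths 1.22–1.50 Å), places ring N–H and C–H along
exterior bisectors, amino hydrogens at ±60° from the C→N extension
(H–N–C = 120°), tetrahedral methyl hydrogens, and realizes substitution
as a methyl carbon at the glycosidic nitrogen.

`build_pair` keeps base 1 fixed, flips base 2 for `f` orientation
(rotation about an in-plane axis), and then solves the in-plane rigid
placement: the rotation angle is scanned on a 0.5° grid and for each
angle the translation satisfying the two anchor-bond distance constraints
exactly is obtained from the two-circle intersection in closed form — at
the concentric-circle degeneracy (symmetric pairs at 180°) the whole
circle of translations is sampled. Among distance-exact placements the
best by a soft score (D–H…A linearity, steric-clash penalty below 2.4 Å
heavy–heavy, targeted penalties on unwanted contacts) is polished with
Powell. Targets default to 2.9 Å for N/O donors and 3.4 Å for carbon
donors (the middle of the observed C–H…X range). Construction accepts a
placement when every bond is within 0.05 Å of target, relaxed to the
detection window for three-bond pairs, whose idealized geometry cannot
hold all three distances exactly. If detection then finds an incidental
extra contact, the placement is re-solved with a repulsion term on that
contact (at most three repair rounds).

One naming conflict is resolved here: the published table lists
`UU_mHS_(41)(52)` while the accompanying text calls the same pair
`fHS`; with ideal planar bases the same-face (`m`) placement cannot reach
clash-free geometry anywhere on the distance-exact family (closest
approach 2.13 Å), whereas the flipped placement is unstrained, so the
catalog uses `UU_fHS_(41)(52)`.

`perturb` adds seeded isotropic Gaussian noise and/or tips base 2 about
the in-plane axis through its own centroid perpendicular to the approach
direction — every D…A vector rotates out of the ring planes by roughly
the tilt angle, so 60° cleanly violates the 45° criterion while contact
distances stay nearly unchanged.

### What the generator does and does not emulate

Fixtures are idealized: exactly planar bases, one pair per structure,
coordinate-only (a P1 box is added only on file export), hydrogen-placed
unless a `?` pattern is requested, no solvent, counter-ions, disorder or
thermal motion, and no competing lattice contacts. Passing the round-trip
suite therefore demonstrates the correctness of the criteria, the
classification and the naming logic — not robustness to refinement
artifacts or to crowded crystal environments. The inversion-wrapped
uracil fixture exercises symmetry expansion and deduplication but covers
only one space group (P-1) beyond translational P1 images.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `da_margin` | 1.0 Å | D…A slack over the vdW-radius sum |
| `plane_angle_max` | 45° | max angle of D…A to each ring plane |
| `dha_min` | 120° | D–H…A floor when H is modeled |
| `covalent_tolerance` | 0.4 Å | bond-inference slack |
| `min_hbonds` | 2 | bonds required per pair |
| `contact_radius` | 6.0 Å | symmetry-expansion envelope |
| `neutron_dh` | C 1.083 / N 1.009 / O 0.983 Å | D–H normalization lengths |
| fixture `target_da` | 2.9 Å (N/O), 3.4 Å (C donor) | constructed bond lengths |

All thresholds live in `GeometryParams` and are overridable from the CLI
and the library.

## Known limitations

* Bifurcated hydrogen bonds within one pair are excluded by design (see
  atom-exclusive assignment above).
* The `?`-pattern determinacy rule is per-base and binary; a base whose
  ring N–H were modeled but whose amino H were not is treated as
  determined.
* Macromolecular mmCIF, disorder beyond highest-occupancy selection,
  anisotropic displacement and twinning are unsupported.
* Hetero-pair molecule ordering (purine-first, then alphabetical) is a
  provisional convention, untested against published hetero names.
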