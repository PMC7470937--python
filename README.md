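# pairdex

Detection, protonation classification and canonical naming of nucleobase
**homo-pairs** in small-molecule crystal structures, plus the survey
statistics (frequency tables, protonation cross-tabs, hydrogen-bond
geometry summaries) that such a census produces.

## The problem

Free nucleobases and their N1/N9 derivatives form hydrogen-bonded base
pairs in their own crystals, unconstrained by a sugar-phosphate backbone.
Cataloguing those pairs — which edges interact, which atoms are bonded,
whether the bases are protonated — tells us which pairing geometries are
intrinsic to the bases themselves and which are imposed by nucleic-acid
context. `pairdex` implements the full pipeline for six bases (adenine A,
guanine G, hypoxanthine Hx, thymine T, uracil U, cytosine C):

* **Recognition** — heavy-atom subgraph matching of base templates inside a
  bonded structure; molecules substituted anywhere except the glycosidic
  nitrogen, and bases bonded to metals, are excluded.
* **Pair search** — two bases pair when they share **two or more hydrogen
  bonds**: donor…acceptor within the Bondi vdW-radius sum **+ 1 Å**, the
  D…A vector within **45°** of both ring planes, and D–H…A ≥ **120°**
  whenever hydrogens are modeled. Crystallographic symmetry mates are
  generated so pairs across asymmetric units are found, then symmetry
  duplicates are collapsed.
* **Naming** — a name such as `AA_fWH_(16)(67)` records the base codes, the
  relative orientation of the second base (`f` flipped, `m` moved — the
  faces exposed are opposite or equal), the interacting edges in
  Watson–Crick > Hoogsteen > Sugar precedence, and one `(ab)` group per
  hydrogen bond (first molecule's atom first). `f`/`m` correspond to
  *cis*/*trans* in Leontis–Westhof nomenclature.
* **Protonation & charge** — ring-nitrogen H patterns are read off the
  structure (`"1H 3 7 9R"`; `"R?"`/`"No R?"` when hydrogens were not
  determined) and the formal charge is the excess of observed ring N–H over
  the neutral reference form.
* **Survey statistics** — occurrences counted once per refcode family,
  geometry statistics over every deposition, with X-ray D–H bond lengths
  renormalized to mean neutron values (N–H 1.009 Å, C–H 1.083 Å, O–H
  0.983 Å) before averaging.

A synthetic-structure generator (`pairdex.fixtures`) builds idealized,
planar realizations of all **47 catalogued homo-pair types** (15 A, 7 G,
5 Hx, 6 T, 7 U, 7 C) and is the package's test substrate.

## Worked example

Generate the "Calcutta" uracil pair (held by one N–H…O and one weak
C–H…O bond) and scan it:

```sh
$ pairdex fixtures --out fx --name "UU_fWH_(34)(45)"
$ pairdex scan fx/UU_fWH_3445.cif
structure_id  pair_name        n_bonds  bonds                                                    interplanar_angle  c1_c1   sub1  prot1  charge1  sub2  prot2  charge2
UU_fWH_3445   UU_fWH_(34)(45)  2        NH...O:2.902:1.009:1.918:164.0;CH...O:3.398:1.083:2.346:163.5  0.00        11.144  R     1R 3H  0        R     1R 3H  0
```

Reading the one detected pair: both uracils are N1-substituted (`R`) and
neutral (`1R 3H`, charge 0); the Watson–Crick edge of the first base meets
the Hoogsteen edge of the second (`fWH`, a *cis* pair in Leontis–Westhof
terms); bond `(34)` is N3–H…O4 at 2.90 Å (D–H…A 164°) and bond `(45)` is
O4…H–C5 at 3.40 Å; the glycosidic substituent carbons are 11.1 Å apart.

The same machinery is available as a library:

```python
from pairdex import read_structure, detect_pairs
pairs = detect_pairs(read_structure("mystructure.cif"))
for p in pairs:
    print(p.name, [hb.bond_class for hb in p.hbonds])
```

`pairdex report --printed --base C --category substituted` prints the
bundled transcription of the published cytosine count table and the
derived category percentages.

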