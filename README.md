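# barbedwire

Per-residue prediction-mode triage of AlphaFold2 models.

Low-confidence (pLDDT < 70) regions of AlphaFold2 predictions are not one
thing: some are nearly correct despite the score, some are secondary-
structure-shaped filler, and some are "barbed wire" - wide, looping coils
riddled with physically impossible backbone geometry that must be removed
before molecular replacement or model building. `barbedwire` classifies
every residue of a predicted structure into six mutually exclusive modes:

| mode | pLDDT | packing | outliers |
|---|---|---|---|
| predictive | >= 70 | packed | - |
| unpacked_high_plddt | >= 70 | unpacked | - |
| near_predictive | < 70 | packed | clean |
| unphysical | < 70 | packed | signature / high density |
| pseudostructure | < 70 | unpacked | clean |
| barbed_wire | < 70 | unpacked | signature / high density |

Three signals feed the tree: pLDDT from the B-factor field; a tertiary
packing score (steric contacts with vdW gap <= 0.5 A per heavy atom over
a five-residue window, excluding intra-element and sequence-local
contacts; packed when > 0.6 for helix/coil, > 0.35 for strands); and a
backbone-validation panel (Ramachandran, omega, CA-trace geometry,
covalent bond/angle z-scores). The outlier patterns diagnostic of badly
joined residues - upper-right-box Ramachandran outliers (-15 < phi < 170,
60 < psi < 170), cis-nonPro/twisted peptides and C-N-CA angle outliers
(marking both residues of the bond), contextual CA-geometry outliers and
cis-Pro - are treated as *signature* outliers, and a three-residue-window
density rule catches accumulations. Isolated one-or-two-residue islands
are smoothed into their surroundings in two passes. Each residue also
gets an `Lprocg` label (Low pLDDT, low packing, Ramachandran, omega,
CA-geometry, covalent geometry). See `docs/methods.md` for the full
model description.

## Worked example

Generate a small synthetic structure (a helix, a polyproline-II run and
a distorted coil, joined with chain breaks, all at pLDDT 40) and
classify it:

```
$ barbedwire fixtures mixed -n 24 --plddt 40 --seed 3 -o mixed.pdb
$ barbedwire analyze mixed.pdb output.type=json -o mixed.modes.json
INFO predictive                0 residues
INFO unpacked_high_plddt       0 residues
INFO near_predictive           0 residues
INFO pseudostructure          18 residues
INFO barbed_wire               6 residues
INFO unphysical                0 residues
```

The isolated helix and PPII segments are low-pLDDT and unpacked but
geometrically clean, so they come out as pseudostructure (18 residues);
the distorted coil segment carries cis/twisted peptides, compressed
C-N-CA angles and high-psi Ramachandran outliers, so its interior is
barbed wire (6 residues). Each JSON record carries the per-residue
evidence, e.g. a coil residue shows `"label": "Lpr---"` - low pLDDT,
low packing, Ramachandran outlier.

Other output types: `output.type=kin` writes kinemage markup (CA trace,
one togglable color-coded balllist per mode, Lprocg labels) viewable in
KiNG; `output.type=selection_file` writes a PDB pruned to selected modes
(default `predictive,near_predictive`, any set via `modes=...`);
`output.type=text` writes a TSV. All thresholds are config keys
(`barbedwire show-config`), overridable per run as trailing `key=value`
arguments. Library use mirrors the CLI:

```python
from barbedwire import read_structure, annotate
annotations = annotate(read_structure("model.pdb"))
```

`barbedwire compare structure.pdb tracks.json -o overlap.csv` overlaps
modes with user-supplied disorder-annotation ranges (MobiDB-style JSON,
`{feature: [[start, end], ...]}`), after pruning each pre-smoothing mode
segment to its unambiguous core (drop three residues each end, keep
cores of at least three).

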