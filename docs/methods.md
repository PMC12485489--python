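# Methods

## The problem

AlphaFold2 reports per-residue confidence as pLDDT (0-100, stored in the
B-factor field of its output files), and pLDDT >= 70 is the usual cutoff
for regions trusted in structural-biology pipelines. Below that cutoff,
predictions are a mixture of very different behaviors: regions whose
coordinates are nearly correct despite the low score, regions that merely
look like secondary structure, and "barbed wire" - wide looping coils
saturated with backbone-geometry outliers whose coordinates carry no
structural information at all. This package classifies every residue of a
prediction into six mutually exclusive modes so that usable regions can be
kept and unphysical ones pruned.

## The classification

Three per-residue quantities feed a fixed decision tree.

**pLDDT.** Read from the CA B-factor (falling back to the mean over the
residue's atoms). Files on the 0-1 scale (all B <= 1.0) are rescaled by
100. The high/low boundary is pLDDT >= 70, inclusive.

**Packing.** A steric contact is an unordered pair of non-hydrogen atoms
whose van der Waals surfaces approach within 0.5 A (gap = center distance
minus radius sum, united-atom radii with implicit-hydrogen carbons and
nitrogens slightly inflated). Two exclusions restrict the count to
tertiary structure: contacts between residues of the same helix or strand
element, and same-chain contacts with sequence separation <= 4. The
packing score of residue *i* is the number of distinct contacting pairs
touching the window *i*-2..*i*+2 divided by the window's heavy-atom
count (window truncated at termini and chain breaks). Helix and coil
residues are packed above 0.6 contacts per heavy atom; strand residues
above 0.35, because their intra-sheet contacts were excluded. The
original tool counts dot contacts on hydrogenated models; the heavy-atom
pair count used here has a different absolute scale, which is why both
cutoffs are exposed in config.

**Validation outliers.** Per residue: phi/psi/omega dihedrals; z-scores
of seven backbone bond/angle terms against a single Engh-Huber-style
target table (|z| > 4 is an outlier, strict); omega classified as cis
(|w| <= 30, split Pro/nonPro by the later residue), twisted
(30 < |w| < 150) or trans; CA-trace geometry (pseudo-angle outside
70-155 degrees, or the incoming/outgoing CA pseudo-dihedral pair outside
a coarse allowed map); and Ramachandran outliers against a coarse
box-region map keyed by residue class (general/Gly/Pro/pre-Pro).

Two derived markers capture the diagnostic outlier patterns:

*Signature outliers* - (a) a Ramachandran outlier in the upper-right box
(-15 < phi < 170, 60 < psi < 170); (b) a CA-geometry outlier in a
low-pLDDT, unpacked residue (the same outlier is permitted in predictive
regions); (c) a peptide bond carrying a C-N-CA angle outlier, a
cis-nonPro or any twisted omega marks BOTH residues sharing the bond;
(d) a cis-Pro in a low-pLDDT, unpacked residue (legitimate elsewhere).

*High outlier density* - for the three-residue window centered on the
residue (truncated at termini/breaks), at least two of: >= 2 residues
with cis-nonPro/twisted omegas; >= 2 with CA-geometry outliers; >= 2
with covalent-geometry outliers; all window residues in the high-psi
band (60 < psi < 170) with at least one Ramachandran outlier.

**The tree.** pLDDT >= 70: packed -> predictive, unpacked -> unpacked
high-pLDDT (validation outliers define no extra modes at high
confidence). pLDDT < 70, packed: clean -> near-predictive, outliers ->
unphysical. pLDDT < 70, unpacked: clean -> pseudostructure, outliers ->
barbed wire.

**Smoothing.** Two passes per chain segment (segments end at chain
breaks): first, runs of one or two pseudostructure residues flanked on
both sides by barbed wire, or on both sides by near-predictive, take the
flanking mode (mixed flanks are left alone); second, remaining runs of
one or two barbed-wire residues flanked by pseudostructure become
pseudostructure. Runs touching a terminus or break are never smoothed,
and no other mode participates.

Each residue also gets a six-position label, `Lprocg`: Low pLDDT, low
packing, Ramachandran outlier, omega outlier, CA-geometry outlier,
covalent-geometry outlier, with `-` for positions that do not apply.
`L-----` is the typical near-predictive label and `Lp----` the typical
pseudostructure label.

## Secondary structure from the CA trace

Element definition only matters for the contact exclusions, so the
assignment is deliberately minimal. Residue *i* opens a helix candidate
window when |CA(i)-CA(i+3)| is 4.5-6.0 A and the CA(i..i+3)
pseudo-dihedral is 35-65 degrees; a strand candidate when
|CA(i)-CA(i+2)| is 6.2-7.2 A and the pseudo-dihedral magnitude is
>= 120 degrees. Candidate windows are consolidated into runs; helix runs
need >= 4 residues and strand runs >= 3; everything else is coil. On
built ideal geometry: an alpha-helix measures 5.24 A / +51 degrees
(helix), an extended chain 6.76 A / -168 degrees (strand), and
polyproline II 6.60 A / -106 degrees - inside the strand distance bin
but below the dihedral bin, so PPII is coil, which is the desired
behavior (an unpaired PPII ribbon must not get the lenient strand
cutoff). Unpaired strands do receive the 0.35 cutoff; geometry alone
decides, with no pairing requirement.

## Reference maps and targets

The covalent target table (packaged, plain text) carries N-CA, CA-C,
C-N, C-O bonds and N-CA-C, CA-C-N, C-N-CA, CA-C-O angles with
Engh-Huber-style ideals and sigmas; one uniform set, no residue-type
variants. Junction-spanning terms are stored on the later residue of the
bond, matching the omega convention.

The Ramachandran map is a coarse set of axis-aligned allowed boxes per
residue class, and the CA-geometry map a set of allowed boxes in the
(incoming, outgoing) pseudo-dihedral plane. Both are packaged plain-text
tables, replaceable via config, and per-residue calls from external
validation software can be imported to override them (JSON keyed by
chain:seq_num). The coarse maps accept canonical alpha, beta, PPII and
left-handed-alpha geometry with margin and reject the unprotein-like
upper-right band; they are intentionally permissive in rarely populated
negative-phi territory, because the classifier consumes only outlier
calls plus the two quoted boxes, and false negatives there only make the
barbed-wire call more conservative.

## The synthetic generator

The generator emulates the conformational regimes the classifier must
separate, with no downloads:

- `helix_bundle`: two ideal antiparallel helices, axes 6.0 A apart
  (axial shift 1.0 A, azimuthal spin 210 degrees). The separation is
  tighter than physical four-helix bundles (~9-10 A) because heavy-atom
  gap contacts replace dot contacts; the chosen placement makes every
  residue window score > 0.6 for lengths 8-16, so the fixture is
  uniformly packed. Steric plausibility is irrelevant to the classifier
  and not a goal.
- `lone_helix` / `lone_strand` / `ppii`: single ideal elements
  (phi/psi = -57/-47, -120/+130, -75/+150), isolated in space, hence
  unpacked by construction.
- `barbed_coil`: dihedrals jittered +-15 degrees around a base point
  drawn inside the observed band (phi in -15..170, psi in 60..170); base
  points whose arc approaches itself (non-local CA-CA distance <= 10 A)
  are redrawn, because the emulated regime is by definition unpacked.
  A quarter of peptide bonds are distorted to twisted (+-135) or
  cis-nonPro (+8) omegas, and half the C-N-CA angles are drawn from a
  normal distribution centered on -4 sigma (sd 1 sigma), mirroring the
  systematic distortion observed in these regions, whose peak sits at
  the outlier threshold. All draws come from one seeded generator; the
  same spec yields a byte-identical file.
- `mixed`: helix + PPII + coil segments separated by 20 A gaps in one
  chain, producing chain breaks.

What the fixtures do NOT emulate: real side chains beyond CB, hydrogen
bonding, sheet pairing, pLDDT heterogeneity within a region, or the
pLDDT-mode correlations of real proteomes. Passing tests therefore
demonstrate that the rules are implemented as specified and behave
sensibly on canonical geometry, not that mode frequencies on real
AlphaFold models are reproduced.

## Backbone building and measurement

The builder places N/CA/C/O (+CB with L-chirality) by sequential
internal-to-Cartesian (NeRF) placement from the target table, with any
term overridable per residue; measuring a built structure recovers every
dihedral and override to < 1e-6 degrees, which the tests exploit for
round-trip checks. Dihedrals are signed (IUPAC), reported in (-180, 180];
collinear point sets yield NaN, and NaN propagates as "unevaluated"
rather than as an outlier. A chain break is declared when C(i-1)-N(i)
exceeds 2.5 A (about 1.8x the ideal bond) or either atom is missing; no
dihedral, z-score, window or smoothing run spans a break.

## Numerical and design choices

- High-pLDDT boundary inclusive (>= 70); outlier z threshold strict
  (|z| > 4), so a bond at exactly -4 sigma is not an outlier.
- Altlocs keep the highest-occupancy conformer; waters/ligands dropped.
- "Number of different steric contacts" is read as the count of unique
  contacting atom pairs touching the window, normalized by the window's
  own heavy atoms.
- Contact sequence-separation exclusion applies within a chain only;
  inter-chain contacts always count.
- Smoothing flanks must be the same mode on both sides; mixed flanks and
  terminus-touching runs are left unsmoothed; unphysical runs do not
  participate.
- The annotation-overlap survey uses PRE-smoothing runs, trims three
  residues from each end and keeps cores of >= 3 (runs under 9
  contribute nothing); high-pLDDT residues enter as one group under the
  plain cutoff rule. Annotation ranges are 1-based inclusive and must
  fit the structure's author numbering; mismatches fail loudly.

## Problem sizes

Tests and the acceptance script run on fixtures of 8-40 residues, the
contact oracle on structures up to 500 atoms, and the smoothing oracle
on all 6561 length-8 mode strings; these sizes exercise every rule while
keeping the whole suite in seconds.

## Known limitations

- The packing score's absolute scale differs from dot-based contact
  scoring; the 0.6/0.35 defaults are retained but results on real
  models may shift relative to the original tool (config-tunable).
- The coarse Ramachandran/CA maps under-call outliers in sparsely
  populated allowed regions; import external validation calls for
  fidelity studies.
- Secondary-structure assignment is geometry-only; 3-10/pi helices and
  sheet topology are not distinguished.
- Terminal residues lack the dihedrals needed for most flags, so chain
  ends of genuinely distorted regions tend to classify as
  pseudostructure rather than barbed wire.
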