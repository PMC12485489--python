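"""The six-mode residue classifier.

Combines pLDDT, tertiary-contact packing and the validation-outlier panel
into one of six prediction modes per residue:

* **predictive** - high pLDDT, packed
* **unpacked_high_plddt** - high pLDDT, unpacked
* **near_predictive** - low pLDDT, packed, clean geometry
* **pseudostructure** - low pLDDT, unpacked, clean geometry
* **barbed_wire** - low pLDDT, unpacked, signature outliers or a high
  outlier density
* **unphysical** - low pLDDT, packed, signature/high outliers (chain
  self-intersections and similar impossible geometry)

Signature outliers are the markers diagnostic of badly joined residues:
upper-right-box Ramachandran outliers; cis-nonPro, twisted peptides and
C-N-CA angle outliers (which mark BOTH residues sharing the peptide
bond); plus CA-geometry outliers and cis-Pro, which count only in
low-pLDDT unpacked context because both also occur in legitimate
predictive regions.

After raw assignment, isolated 1-2-residue islands of pseudostructure
surrounded by barbed wire or by near-predictive are smoothed into their
surroundings, then remaining 1-2-residue barbed-wire islands inside
pseudostructure are absorbed (two passes).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .backbone_geometry import BackboneGeometry, analyze_backbone
from .config import Config
from .contact_packing import (
    PackingResult,
    enumerate_contacts,
    load_radii,
    packing_scores,
)
from .secondary_structure import assign_ss
from .structure_io import Structure
from .validation_flags import (
    CIS_NONPRO,
    CIS_PRO,
    TWISTED,
    OMEGA_OUTLIER_STATES,
    ValidationFlags,
    apply_external_flags,
    compute_flags,
)


class Mode(str, Enum):
    PREDICTIVE = "predictive"
    UNPACKED_HIGH_PLDDT = "unpacked_high_plddt"
    NEAR_PREDICTIVE = "near_predictive"
    PSEUDOSTRUCTURE = "pseudostructure"
    BARBED_WIRE = "barbed_wire"
    UNPHYSICAL = "unphysical"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


DEFAULT_SELECTION = frozenset({Mode.PREDICTIVE, Mode.NEAR_PREDICTIVE})


@dataclass
class ResidueAnnotation:
    """Everything the classifier knows about one residue."""

    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    plddt: float
    ss: str
    packing_score: float
    packed: bool
    flags: ValidationFlags
    signature_outlier: bool
    high_outlier_density: bool
    mode_raw: Mode
    mode: Mode
    label: str


def _bond_is_marked(flags_later: ValidationFlags) -> bool:
    """Does the peptide bond stored on this (later) residue carry a
    bond-level signature: C-N-CA outlier, cis-nonPro or twisted?"""
    return flags_later.cnca_outlier or flags_later.omega_state in (
        CIS_NONPRO,
        TWISTED,
    )


def signature_outliers(
    flags: list[ValidationFlags],
    low_plddt: list[bool],
    packed: list[bool],
    break_before: list[bool],
) -> list[bool]:
    """Per-residue signature-outlier markers for one chain.

    Bond-level signatures (C-N-CA outlier, cis-nonPro, twisted peptide)
    mark both residues that share the peptide bond.  CA-geometry
    outliers and cis-Pro are contextual: they count only in low-pLDDT,
    unpacked regions, because both are also seen in legitimate
    structure.
    """
    n = len(flags)
    out = [False] * n
    for i in range(n):
        f = flags[i]
        if f.rama_upper_right:
            out[i] = True
        if f.ca_geom_outlier and low_plddt[i] and not packed[i]:
            out[i] = True
        if f.omega_state == CIS_PRO and low_plddt[i] and not packed[i]:
            out[i] = True
        # the bond preceding i marks both i-1 and i
        if i > 0 and not break_before[i] and _bond_is_marked(f):
            out[i] = True
            out[i - 1] = True
    return out


def high_outlier_density(
    flags: list[ValidationFlags],
    break_before: list[bool],
) -> list[bool]:
    """Three-residue-window outlier-density markers for one chain.

    A residue is marked when at least two of the following hold for the
    window i-1..i+1 (truncated at termini and chain breaks):

    1. two or more residues have cis-nonPro or twisted peptides;
    2. two or more residues have CA-geometry outliers;
    3. two or more residues have covalent bond/angle outliers;
    4. every window residue lies in the high-psi band and at least one
       is a Ramachandran outlier.
    """
    n = len(flags)
    out = [False] * n
    for i in range(n):
        lo = i if (i == 0 or break_before[i]) else i - 1
        hi = i if (i == n - 1 or break_before[i + 1]) else i + 1
        window = [flags[k] for k in range(lo, hi + 1)]
        n_omega = sum(f.omega_state in (CIS_NONPRO, TWISTED) for f in window)
        n_ca = sum(f.ca_geom_outlier for f in window)
        n_bond = sum(f.bond_geom_outlier for f in window)
        crit = 0
        crit += n_omega >= 2
        crit += n_ca >= 2
        crit += n_bond >= 2
        crit += all(f.high_psi_band for f in window) and any(
            f.rama_outlier for f in window
        )
        out[i] = crit >= 2
    return out


def assign_mode(
    plddt: float,
    packed: bool,
    signature: bool,
    density: bool,
    config: Config | None = None,
) -> Mode:
    """The decision tree: pLDDT first, then packing, then outliers."""
    config = config or Config()
    outliers = signature or density
    if plddt >= config.plddt_cutoff:
        return Mode.PREDICTIVE if packed else Mode.UNPACKED_HIGH_PLDDT
    if packed:
        return Mode.UNPHYSICAL if outliers else Mode.NEAR_PREDICTIVE
    return Mode.BARBED_WIRE if outliers else Mode.PSEUDOSTRUCTURE


def smooth(modes: list[Mode], break_before: list[bool]) -> list[Mode]:
    """Two-pass smoothing of isolated residues within one chain.

    Pass 1: maximal runs of 1-2 pseudostructure residues flanked on BOTH
    sides by barbed wire, or on both sides by near-predictive, take the
    flanking mode.  Pass 2: remaining runs of 1-2 barbed wire flanked by
    pseudostructure become pseudostructure.  Runs touching a terminus or
    chain break are never smoothed; no other mode changes.
    """
    out = list(modes)
    segments = _segments(len(modes), break_before)
    for lo, hi in segments:
        _smooth_pass(out, lo, hi, Mode.PSEUDOSTRUCTURE, (Mode.BARBED_WIRE,))
        _smooth_pass(out, lo, hi, Mode.PSEUDOSTRUCTURE, (Mode.NEAR_PREDICTIVE,))
    for lo, hi in segments:
        _smooth_pass(out, lo, hi, Mode.BARBED_WIRE, (Mode.PSEUDOSTRUCTURE,))
    return out


def _segments(n: int, break_before: list[bool]) -> list[tuple[int, int]]:
    segs = []
    start = 0
    for i in range(1, n):
        if break_before[i]:
            segs.append((start, i - 1))
            start = i
    if n:
        segs.append((start, n - 1))
    return segs


def _smooth_pass(
    modes: list[Mode], lo: int, hi: int, target: Mode, flank_modes: tuple[Mode, ...]
) -> None:
    """Recategorize 1-2-long runs of ``target`` in modes[lo..hi] whose two
    immediate neighbors are both the same member of ``flank_modes``."""
    i = lo
    while i <= hi:
        if modes[i] is not target:
            i += 1
            continue
        j = i
        while j + 1 <= hi and modes[j + 1] is target:
            j += 1
        run = j - i + 1
        if run <= 2 and i - 1 >= lo and j + 1 <= hi:
            left, right = modes[i - 1], modes[j + 1]
            if left is right and left in flank_modes:
                for k in range(i, j + 1):
                    modes[k] = left
        i = j + 1


def make_label(flags: ValidationFlags, low_plddt: bool, packed: bool) -> str:
    """Six-position Lprocg label: Low pLDDT, low packing, Ramachandran,
    omega, CA-geometry, covalent geometry; '-' where not applicable."""
    return "".join(
        [
            "L" if low_plddt else "-",
            "p" if not packed else "-",
            "r" if flags.rama_outlier else "-",
            "o" if flags.omega_state in OMEGA_OUTLIER_STATES else "-",
            "c" if flags.ca_geom_outlier else "-",
            "g" if flags.bond_geom_outlier else "-",
        ]
    )


def annotate(
    structure: Structure,
    config: Config | None = None,
    external_flags: dict | None = None,
) -> list[ResidueAnnotation]:
    """Run the full per-residue pipeline on a parsed structure.

    geometry -> secondary structure -> contacts -> packing -> validation
    flags -> signature/density -> mode tree -> smoothing -> labels.
    """
    config = config or Config()
    geometry = analyze_backbone(structure, config=config)
    ss, elements = assign_ss(structure, geometry, config)
    radii = load_radii(config.radii_table)
    contacts = enumerate_contacts(structure, elements, radii, config)
    packing = packing_scores(structure, contacts, ss, geometry, config)
    flags = compute_flags(structure, geometry, config)
    if external_flags:
        flags = apply_external_flags(structure, flags, external_flags)

    annotations: list[ResidueAnnotation] = []
    gi = 0
    for chain_id, residues in structure.chains.items():
        n = len(residues)
        chain_slice = slice(gi, gi + n)
        chain_flags = flags[chain_slice]
        chain_packing = packing[chain_slice]
        geoms = geometry[chain_id]
        break_before = [g.chain_break_before for g in geoms]
        low = [r.plddt < config.plddt_cutoff for r in residues]
        packed = [p.packed for p in chain_packing]
        signature = signature_outliers(chain_flags, low, packed, break_before)
        density = high_outlier_density(chain_flags, break_before)
        raw = [
            assign_mode(residues[i].plddt, packed[i], signature[i], density[i], config)
            for i in range(n)
        ]
        smoothed = smooth(raw, break_before)
        for i, res in enumerate(residues):
            annotations.append(
                ResidueAnnotation(
                    chain_id=chain_id,
                    seq_num=res.seq_num,
                    icode=res.icode,
                    res_name=res.res_name,
                    plddt=res.plddt,
                    ss=ss[chain_id][i],
                    packing_score=chain_packing[i].score,
                    packed=packed[i],
                    flags=chain_flags[i],
                    signature_outlier=signature[i],
                    high_outlier_density=density[i],
                    mode_raw=raw[i],
                    mode=smoothed[i],
                    label=make_label(chain_flags[i], low[i], packed[i]),
                )
            )
        gi += n
    return annotations


def mode_counts(annotations: list[ResidueAnnotation]) -> dict[str, int]:
    counts = {m.value: 0 for m in Mode}
    for ann in annotations:
        counts[ann.mode.value] += 1
    return counts
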