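"""Steric contacts and the per-residue packing score.

A contact is an unordered pair of non-hydrogen atoms whose van der Waals
surfaces come within 0.5 A of each other (gap = center distance minus
radius sum).  Pairs inside one secondary-structure element and same-chain
pairs closer than 5 in sequence are excluded so that the score reflects
tertiary packing: helices and strands must touch OTHER elements to count
as packed.  The score for residue i is the number of distinct contacting
pairs touching the five-residue window i-2..i+2 divided by the window's
heavy-atom count; helix/coil residues are packed above 0.6, strand
residues above 0.35 (their intra-sheet contacts having been excluded).

Contact enumeration uses a KD-tree; an all-pairs oracle lives in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .backbone_geometry import BackboneGeometry
from .config import Config
from .secondary_structure import STRAND, SSElement, element_ids
from .structure_io import Structure


def load_radii(path: str | Path | None = None) -> dict[str, float]:
    """Load the united-atom vdW radius table (atom-class -> Angstrom)."""
    if path is None:
        text = resources.files("barbedwire.data").joinpath("vdw_radii.txt").read_text()
    else:
        text = Path(path).read_text()
    radii = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, value = line.split()
        radii[name] = float(value)
    return radii


def atom_radius(atom_name: str, element: str, radii: dict[str, float]) -> float:
    """United-atom class lookup: backbone carbonyl C is bare, other C and N
    carry implicit hydrogens and use inflated radii."""
    el = element.upper()
    if el == "C":
        return radii["C"] if atom_name == "C" else radii["C_UNI"]
    if el == "N":
        return radii["N_UNI"] if atom_name == "N" else radii["N"]
    return radii.get(el, radii["DEFAULT"])


@dataclass(frozen=True)
class ContactPair:
    """One steric contact between heavy atoms of two residues.

    ``resid_a``/``resid_b`` are global residue indices in structure
    iteration order, with resid_a <= resid_b.
    """

    resid_a: int
    resid_b: int
    atom_a: str
    atom_b: str
    gap: float


@dataclass
class PackingResult:
    contact_count: int
    heavy_atoms: int
    score: float
    packed: bool


def _flatten(structure: Structure, radii: dict[str, float]):
    """Flat per-heavy-atom arrays plus per-residue bookkeeping."""
    positions, radii_arr, res_idx = [], [], []
    res_chain, res_pos = [], []  # per global residue: chain index, pos in chain
    gi = 0
    for ci, (chain_id, residues) in enumerate(structure.chains.items()):
        for pi, res in enumerate(residues):
            res_chain.append(ci)
            res_pos.append(pi)
            for atom in res.heavy_atoms:
                positions.append(atom.position)
                radii_arr.append(atom_radius(atom.name, atom.element, radii))
                res_idx.append(gi)
            gi += 1
    return (
        np.asarray(positions, dtype=float).reshape(-1, 3),
        np.asarray(radii_arr),
        np.asarray(res_idx, dtype=int),
        np.asarray(res_chain, dtype=int),
        np.asarray(res_pos, dtype=int),
    )


def enumerate_contacts(
    structure: Structure,
    elements: list[SSElement],
    radii: dict[str, float] | None = None,
    config: Config | None = None,
) -> list[ContactPair]:
    """All eligible heavy-atom contact pairs with vdW gap <= the cutoff.

    Exclusions: pairs within one helix/strand element; same-chain pairs
    with sequence separation <= 4 (inter-chain pairs are always
    eligible).
    """
    config = config or Config()
    radii = radii or load_radii(config.radii_table)
    pos, rad, a2r, res_chain, res_pos = _flatten(structure, radii)
    if len(pos) == 0:
        return []
    elem = element_ids(structure, elements)
    chain_keys = list(structure.chains)
    res_elem = np.array(
        [
            -1 if e is None else e
            for ci, chain_id in enumerate(chain_keys)
            for e in elem[chain_id]
        ],
        dtype=int,
    )
    # atom names for reporting
    names = [a.name for r in structure.residues() for a in r.heavy_atoms]

    cutoff = 2.0 * rad.max() + config.contact_gap_max
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    out: list[ContactPair] = []
    for ia, ib in pairs:
        ra, rb = int(a2r[ia]), int(a2r[ib])
        if ra == rb:
            continue
        if res_chain[ra] == res_chain[rb]:
            if abs(int(res_pos[ra]) - int(res_pos[rb])) <= config.seq_separation_min:
                continue
            ea, eb = res_elem[ra], res_elem[rb]
            if ea >= 0 and ea == eb:
                continue
        gap = float(np.linalg.norm(pos[ia] - pos[ib]) - (rad[ia] + rad[ib]))
        if gap <= config.contact_gap_max:
            a, b = (ra, rb) if ra <= rb else (rb, ra)
            na, nb = (names[ia], names[ib]) if ra <= rb else (names[ib], names[ia])
            out.append(ContactPair(a, b, na, nb, gap))
    return out


def packing_scores(
    structure: Structure,
    contacts: list[ContactPair],
    ss: dict[str, list[str]],
    geometry: dict[str, list[BackboneGeometry]],
    config: Config | None = None,
) -> list[PackingResult]:
    """Per-residue packing score and packed call, in structure order.

    The five-residue window i-2..i+2 is truncated at chain termini and
    chain breaks; both the contact tally and the heavy-atom count are
    restricted to the surviving window residues.  The packed cutoff is
    chosen by the residue's own secondary structure.
    """
    config = config or Config()
    hw = config.window_halfwidth

    # global indexing shared with enumerate_contacts
    order: list[tuple[str, int]] = []
    for chain_id, residues in structure.chains.items():
        for pi in range(len(residues)):
            order.append((chain_id, pi))
    index_of = {key: gi for gi, key in enumerate(order)}

    by_residue: dict[int, set[int]] = {}
    for k, pair in enumerate(contacts):
        by_residue.setdefault(pair.resid_a, set()).add(k)
        by_residue.setdefault(pair.resid_b, set()).add(k)

    results: list[PackingResult] = []
    for chain_id, residues in structure.chains.items():
        geoms = geometry[chain_id]
        n = len(residues)
        for i in range(n):
            lo = i
            while lo > i - hw and lo > 0 and not geoms[lo].chain_break_before:
                lo -= 1
            hi = i
            while hi < i + hw and hi < n - 1 and not geoms[hi].chain_break_after:
                hi += 1
            window = range(lo, hi + 1)
            heavy = sum(len(residues[k].heavy_atoms) for k in window)
            pair_ids: set[int] = set()
            for k in window:
                pair_ids |= by_residue.get(index_of[(chain_id, k)], set())
            count = len(pair_ids)
            score = count / heavy if heavy else 0.0
            cutoff = (
                config.cutoff_strand
                if ss[chain_id][i] == STRAND
                else config.cutoff_helix_coil
            )
            results.append(
                PackingResult(
                    contact_count=count,
                    heavy_atoms=heavy,
                    score=score,
                    packed=score > cutoff,
                )
            )
    return results
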