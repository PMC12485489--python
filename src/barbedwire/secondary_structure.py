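"""Helix/strand/coil assignment from CA-trace geometry.

The assignment exists to define the secondary-structure elements whose
internal contacts are excluded from the packing score, so it only needs
to recognize canonical helix and extended geometry; everything else is
coil.  Candidate windows are tested on CA-CA distances and CA
pseudo-dihedrals, then consolidated into elements meeting minimum
lengths.  No element crosses a chain break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone_geometry import BackboneGeometry, compute_dihedral
from .config import Config
from .structure_io import Structure

HELIX, STRAND, COIL = "H", "S", "C"
_KIND = {HELIX: "helix", STRAND: "strand", COIL: "coil"}


@dataclass(frozen=True)
class SSElement:
    kind: str  # "helix" | "strand" | "coil"
    chain_id: str
    start: int  # positional index within the chain, inclusive
    end: int  # inclusive


def assign_ss(
    structure: Structure,
    geometry: dict[str, list[BackboneGeometry]],
    config: Config | None = None,
) -> tuple[dict[str, list[str]], list[SSElement]]:
    """Per-residue SS letters (H/S/C) plus the consolidated element list.

    Residue i starts a helix-candidate window when |CA(i)-CA(i+3)| falls
    in the helix distance bin and the CA(i..i+3) pseudo-dihedral in the
    helix twist bin; a strand-candidate window when |CA(i)-CA(i+2)| falls
    in the strand distance bin and the pseudo-dihedral magnitude is
    extended.  Residues covered by candidate windows form runs; runs
    shorter than the element minima are demoted to coil; helix beats
    strand on overlap.
    """
    config = config or Config()
    ss: dict[str, list[str]] = {}
    for chain_id, residues in structure.chains.items():
        n = len(residues)
        geoms = geometry[chain_id]
        CA = [None if r.atom("CA") is None else r.atom("CA").position for r in residues]

        def contiguous(i: int, j: int) -> bool:
            if j >= n:
                return False
            if any(CA[k] is None for k in range(i, j + 1)):
                return False
            return not any(geoms[k].chain_break_before for k in range(i + 1, j + 1))

        helix_mark = [False] * n
        strand_mark = [False] * n
        for i in range(n):
            if not contiguous(i, i + 3):
                continue
            d3 = float(np.linalg.norm(CA[i + 3] - CA[i]))
            dih = compute_dihedral(CA[i], CA[i + 1], CA[i + 2], CA[i + 3])
            if (
                config.helix_ca3_min <= d3 <= config.helix_ca3_max
                and config.helix_dihedral_min <= dih <= config.helix_dihedral_max
            ):
                for k in range(i, i + 4):
                    helix_mark[k] = True
            elif (
                config.strand_ca2_min
                <= float(np.linalg.norm(CA[i + 2] - CA[i]))
                <= config.strand_ca2_max
                and abs(dih) >= config.strand_dihedral_min_abs
            ):
                for k in range(i, i + 3):
                    strand_mark[k] = True

        letters = [
            HELIX if helix_mark[i] else (STRAND if strand_mark[i] else COIL)
            for i in range(n)
        ]

        # demote runs shorter than the element minima
        for i, j in _runs(letters, geoms):
            kind = letters[i]
            min_len = {HELIX: config.helix_min_len, STRAND: config.strand_min_len}.get(
                kind, 1
            )
            if j - i + 1 < min_len:
                for k in range(i, j + 1):
                    letters[k] = COIL
        ss[chain_id] = letters

    elements: list[SSElement] = []
    for chain_id in structure.chains:
        for i, j in _runs(ss[chain_id], geometry[chain_id]):
            elements.append(SSElement(_KIND[ss[chain_id][i]], chain_id, i, j))
    return ss, elements


def _runs(letters: list[str], geoms: list[BackboneGeometry]):
    """Maximal same-letter runs not crossing chain breaks, as (start, end)."""
    n = len(letters)
    i = 0
    while i < n:
        j = i
        while (
            j + 1 < n
            and letters[j + 1] == letters[i]
            and not geoms[j + 1].chain_break_before
        ):
            j += 1
        yield i, j
        i = j + 1


def element_ids(
    structure: Structure, elements: list[SSElement]
) -> dict[str, list[int | None]]:
    """Map each residue to the id of its helix/strand element (None for coil)."""
    ids: dict[str, list[int | None]] = {
        chain_id: [None] * len(res) for chain_id, res in structure.chains.items()
    }
    for idx, el in enumerate(elements):
        if el.kind == "coil":
            continue
        for k in range(el.start, el.end + 1):
            ids[el.chain_id][k] = idx
    return ids
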