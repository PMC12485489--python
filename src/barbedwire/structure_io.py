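"""Structure reading and writing.

Parses PDB/mmCIF via :mod:`gemmi` into a small uniform chain/residue/atom
model with per-residue pLDDT taken from the B-factor field (the AlphaFold
convention), and writes plain PDB files for arbitrary residue selections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import gemmi
import numpy as np

log = logging.getLogger(__name__)


class StructureError(Exception):
    """Unparseable or unusable input structure."""


class EmptyStructureError(StructureError):
    """No polymer protein residues found."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) in Angstrom
    is_hydrogen: bool = False
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")
        self.is_hydrogen = self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    plddt: float = 0.0

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)


@dataclass
class Structure:
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_format: str = "pdb"
    title: str = ""

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        return info.is_amino_acid()
    return False


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc id order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Per-residue pLDDT is taken from the CA B-factor, falling back to the
    mean over the residue's atoms.  Files on the 0-1 pLDDT scale (all
    B <= 1.0) are rescaled to 0-100.  Hetero/non-amino-acid residues are
    dropped; only the first model of a multi-model file is used.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        None: gemmi.CoorFormat.Detect,
    }
    if format is not None and format not in fmt_map:
        raise StructureError(f"unknown format override: {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    if len(st) > 1:
        log.warning("%s: %d models; using the first only", path.name, len(st))
    model = st[0]

    source_format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format is not None:
        source_format = format
    out = Structure(source_format=source_format, title=st.name or "")

    n_dropped = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if not _is_amino_acid(res.name):
                n_dropped += 1
                continue
            # altloc policy: per atom name, keep the highest-occupancy copy
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            atoms = []
            for name, copies in by_name.items():
                at = _pick_altloc(copies)
                atoms.append(
                    Atom(
                        name=name,
                        element=at.element.name or "X",
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        b_factor=at.b_iso,
                    )
                )
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_num=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    res_name=res.name,
                    atoms=atoms,
                )
            )
        if residues:
            residues.sort(key=lambda r: (r.seq_num, r.icode))
            out.chains[chain.name] = residues
    if n_dropped:
        log.info("dropped %d non-amino-acid residues", n_dropped)
    if not out.chains:
        raise EmptyStructureError(f"{path}: no polymer protein residues")

    _assign_plddt(out)
    return out


def _assign_plddt(structure: Structure) -> None:
    all_b = [a.b_factor for r in structure.residues() for a in r.atoms]
    if not all_b or max(abs(b) for b in all_b) == 0.0:
        log.warning("B-factor field absent or all zero; pLDDT treated as 0")
        scale = 1.0
    elif max(all_b) <= 1.0:
        # 0-1 pLDDT dialect
        log.info("all B-values <= 1.0; interpreting as 0-1-scale pLDDT")
        scale = 100.0
    else:
        scale = 1.0
    for res in structure.residues():
        ca = res.atom("CA")
        if ca is not None:
            b = ca.b_factor
        elif res.atoms:
            b = float(np.mean([a.b_factor for a in res.atoms]))
        else:
            b = 0.0
        res.plddt = float(np.clip(b * scale, 0.0, 100.0))


# fixed-column PDB ATOM record
_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resn:>3s} {chain:1s}"
    "{seq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {elem:>2s}"
)


def _format_atom_name(name: str) -> str:
    # names of <4 chars start in column 14 (e.g. " CA "), 4-char names in 13
    return name if len(name) >= 4 else f" {name:<3s}"


def write_structure(
    structure: Structure,
    path: str | Path,
    keep: Callable[[Residue], bool] | None = None,
) -> None:
    """Write residues satisfying ``keep`` (default: all) as a PDB file.

    Chain ids, author residue numbers, coordinates and B-factors (the
    residue pLDDT) are preserved in standard fixed-column formatting.
    """
    if structure.n_residues == 0:
        raise StructureError("empty structure")
    keep = keep or (lambda r: True)
    lines = []
    if structure.title:
        lines.append(f"REMARK   3 {structure.title}"[:80])
    serial = 0
    n_written = 0
    for chain_id, residues in structure.chains.items():
        chain_has_atoms = False
        for res in residues:
            if not keep(res):
                continue
            n_written += 1
            for atom in res.atoms:
                serial += 1
                chain_has_atoms = True
                lines.append(
                    _ATOM_FMT.format(
                        serial=serial,
                        name=_format_atom_name(atom.name),
                        altloc=" ",
                        resn=res.res_name,
                        chain=chain_id[:1] or "A",
                        seq=res.seq_num,
                        icode=res.icode or " ",
                        x=atom.position[0],
                        y=atom.position[1],
                        z=atom.position[2],
                        occ=1.0,
                        b=res.plddt,
                        elem=atom.element[:2].upper(),
                    )
                )
        if chain_has_atoms:
            serial += 1
            lines.append(f"TER   {serial:>5d}")
    if n_written == 0:
        log.warning("selection kept no residues; writing header-only file")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
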