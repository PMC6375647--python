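"""Protein-ligand complex parsing, SYBYL atom typing and binding-residue selection.

A complex enters the pipeline as PDB text.  Parsing keeps protein heavy atoms
(hydrogens and waters are always discarded) and collects the remaining HETATM
records into hetero groups from which the ligand of interest is selected.
Every protein heavy atom is then assigned one of the SYBYL atom types used to
index the interaction-energy channels (C.2, C.3, C.ar, N.2, N.4, N.am, N.ar,
N.pl3, O.2, O.3, O.co2, P.3, S.3, F), via a shipped per-residue lookup table
with an element-level fallback so typing is total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import gemmi
import numpy as np
from scipy.spatial import cKDTree

#: SYBYL codes used as interaction-energy probe/protein atom types.
SYBYL_TYPES = (
    "C.2", "C.3", "C.ar",
    "N.2", "N.4", "N.am", "N.ar", "N.pl3",
    "O.2", "O.3", "O.co2",
    "P.3", "S.3", "F",
)

#: Element-level fallback applied when (residue, atom) has no table entry.
ELEMENT_FALLBACK = {
    "C": "C.3", "N": "N.am", "O": "O.2", "S": "S.3", "P": "P.3",
    "F": "F", "CL": "F", "BR": "F", "I": "F",
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


class LigandSelectionError(ValueError):
    """Raised when the requested hetero group cannot be selected."""


ResidueId = tuple[str, int, str]  # (chain id, residue number, insertion code)


@dataclass(frozen=True)
class Atom:
    """A single heavy atom with coordinates and (optionally) a SYBYL type."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: ResidueId
    coords: np.ndarray
    sybyl_type: str = "UNKNOWN"

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} has invalid coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial} has empty element")


@dataclass
class TypedStructure:
    """Ordered protein heavy atoms with a residue index."""

    atoms: list[Atom]

    @property
    def residue_index(self) -> dict[ResidueId, list[Atom]]:
        index: dict[ResidueId, list[Atom]] = {}
        for atom in self.atoms:
            index.setdefault(atom.residue_id, []).append(atom)
        return index

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TypedStructure":
        """Return a copy with coordinates mapped to ``rotation @ (x + translation)``."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        return TypedStructure(
            [replace(a, coords=rotation @ (a.coords + translation)) for a in self.atoms]
        )

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class HeteroGroup:
    """One non-water HETATM residue (candidate ligand)."""

    residue_name: str
    residue_id: ResidueId
    atoms: list[Atom]


@dataclass
class Ligand:
    """Selected ligand; ``center`` is the unweighted mean of heavy-atom coordinates."""

    atoms: list[Atom]

    @property
    def center(self) -> np.ndarray:
        return np.mean([a.coords for a in self.atoms], axis=0)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]).reshape(-1, 3)


@dataclass
class ResidueSet:
    """A subset of a structure's residues, e.g. the ligand-binding residues."""

    residue_ids: set[ResidueId]
    atoms: list[Atom]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]).reshape(-1, 3)


def _is_hydrogen(element: str) -> bool:
    return element.upper() in ("H", "D")


def parse_structure(pdb_text: str) -> tuple[TypedStructure, list[HeteroGroup]]:
    """Parse PDB text into protein heavy atoms plus non-water hetero groups.

    Hydrogens and waters are dropped.  Alternate locations are resolved to the
    highest-occupancy conformer (first record on a tie).  Raises
    :class:`ParseError` naming the first offending line when no coordinate
    record is present.
    """
    lines = pdb_text.splitlines()
    if not any(ln.startswith(("ATOM", "HETATM")) for ln in lines):
        offender = lines[0] if lines else "<empty file>"
        raise ParseError(f"no ATOM/HETATM records; first line: {offender!r}")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise ParseError(str(exc)) from exc
    if len(st) == 0:
        raise ParseError("no models in file")

    protein: list[Atom] = []
    hetero: dict[tuple[str, ResidueId], HeteroGroup] = {}
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES or res.is_water():
                continue
            rid: ResidueId = (chain.name, res.seqid.num, res.seqid.icode.strip())
            # resolve altlocs: group by atom name, keep highest occupancy
            by_name: dict[str, gemmi.Atom] = {}
            for ga in res:
                if _is_hydrogen(ga.element.name):
                    continue
                prev = by_name.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    by_name[ga.name] = ga
            atoms = [
                Atom(
                    serial=ga.serial,
                    name=ga.name,
                    element=ga.element.name.upper(),
                    residue_name=res.name,
                    residue_id=rid,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                )
                for ga in by_name.values()
            ]
            if not atoms:
                continue
            if res.het_flag == "H":
                hetero[(res.name, rid)] = HeteroGroup(res.name, rid, atoms)
            else:
                protein.extend(atoms)
    return TypedStructure(protein), list(hetero.values())


def write_pdb(protein: TypedStructure, ligands: list[HeteroGroup] | None = None) -> str:
    """Serialize a structure (plus optional hetero groups) back to PDB text."""
    out = []
    serial = 0
    for atom in protein.atoms:
        serial += 1
        out.append(_pdb_line("ATOM", serial, atom))
    for group in ligands or []:
        for atom in group.atoms:
            serial += 1
            out.append(_pdb_line("HETATM", serial, atom))
    out.append("END")
    return "\n".join(out) + "\n"


def _pdb_line(record: str, serial: int, atom: Atom) -> str:
    chain, resnum, icode = atom.residue_id
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    x, y, z = atom.coords
    return (
        f"{record:<6s}{serial:>5d} {name:<4s} {atom.residue_name:<3s} "
        f"{chain[:1]:1s}{resnum:>4d}{icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}"
    )


def load_typing_table(path=None) -> dict[tuple[str, str], str]:
    """Load a (residue_name, atom_name) -> SYBYL type table.

    Defaults to the shipped table covering the 20 standard amino acids.
    Residue name ``*`` matches any residue (backbone atoms).
    """
    if path is None:
        source = resources.files("voxpocket.data").joinpath("sybyl_protein.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[tuple[str, str], str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"typing table line not 3 tab-separated fields: {raw!r}")
        res, name, code = (f.strip() for f in fields)
        table[(res, name)] = code
    return table


def assign_sybyl_types(
    structure: TypedStructure, table: dict[tuple[str, str], str] | None = None
) -> tuple[TypedStructure, int]:
    """Assign a SYBYL code to every heavy atom.

    Lookup order: (residue, atom) entry, then ('*', atom) backbone entry, then
    element fallback.  Returns the typed structure and the number of atoms that
    needed the element fallback (also emitted as a warning when nonzero).
    Idempotent: re-typing changes nothing.
    """
    if table is None:
        table = load_typing_table()
    typed: list[Atom] = []
    n_fallback = 0
    for atom in structure.atoms:
        code = table.get((atom.residue_name, atom.name)) or table.get(("*", atom.name))
        if code is None:
            code = ELEMENT_FALLBACK.get(atom.element.upper(), "C.3")
            n_fallback += 1
        typed.append(replace(atom, sybyl_type=code))
    if n_fallback:
        warnings.warn(f"{n_fallback} atom(s) typed by element fallback", stacklevel=2)
    return TypedStructure(typed), n_fallback


def select_ligand(
    hetero_groups: list[HeteroGroup], resname: str, chain: str | None = None
) -> Ligand:
    """Select the ligand hetero group by residue name (and chain to disambiguate)."""
    matches = [g for g in hetero_groups if g.residue_name == resname]
    if chain is not None:
        matches = [g for g in matches if g.residue_id[0] == chain]
    if not matches:
        available = sorted({(g.residue_name, g.residue_id[0]) for g in hetero_groups})
        raise LigandSelectionError(
            f"no hetero group {resname!r}"
            + (f" in chain {chain!r}" if chain else "")
            + f"; available: {available}"
        )
    if len(matches) > 1:
        chains = sorted(g.residue_id[0] for g in matches)
        raise LigandSelectionError(
            f"{len(matches)} copies of {resname!r}; specify a chain from {chains}"
        )
    return Ligand(matches[0].atoms)


def binding_residues(
    structure: TypedStructure, ligand: Ligand, cutoff: float = 5.0
) -> ResidueSet:
    """Residues with >= 1 heavy atom within ``cutoff`` of >= 1 ligand heavy atom.

    The default 5 A heavy-atom cutoff matches the residue-mapping distance used
    for CAM-score aggregation.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(ligand.coords)
    dmin, _ = tree.query(structure.coords)
    ids = {a.residue_id for a, d in zip(structure.atoms, dmin) if d <= cutoff}
    if not ids:
        raise ValueError("no binding residues; increase cutoff")
    atoms = [a for a in structure.atoms if a.residue_id in ids]
    return ResidueSet(ids, atoms)
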