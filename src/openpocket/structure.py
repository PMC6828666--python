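"""Protein structure model: atoms, residues, PDB round-trip, shaving, SASA.

Coordinates are in Angstrom throughout.  Every retained atom carries a van
der Waals radius ``w_a`` and Lennard-Jones coefficients assigned from the
packaged parameter table (element-keyed with a generic fallback), so grid
potentials and density maps are always well defined.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .params import AtomParams, LJParams, ParameterTable, default_table
from .sasa import shrake_rupley

logger = logging.getLogger(__name__)

#: residue names exempt from shaving (no side chain beyond CB, or disulfide risk)
SHAVE_EXEMPT = {"ALA", "GLY", "CYS"}

#: atoms retained when a residue is shaved to alanine
_ALANINE_ATOMS = {"N", "CA", "C", "O", "OXT", "CB"}
_ALANINE_HYDROGENS = {"H", "H1", "H2", "H3", "HA", "HB", "HB1", "HB2", "HB3",
                      "1H", "2H", "3H", "1HB", "2HB", "3HB"}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class FormatError(ValueError):
    """Input text could not be parsed as a structure."""


class SelectionError(KeyError):
    """A residue or chain selection does not resolve in the structure."""


@dataclass
class Atom:
    """One atom with coordinates and grid-potential parameters."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) Angstrom
    w_a: float
    lj: LJParams
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not (self.w_a > 0):
            raise ValueError(f"atom {self.name}: w_a must be positive")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """A residue: chain id, number (+ insertion code), name, ordered atoms."""

    chain: str
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain}/{self.name}{self.number}{self.icode}".rstrip()

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise SelectionError(f"{self.label} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """Ordered residues, with provenance metadata."""

    residues: list[Residue] = field(default_factory=list)
    title: str = ""
    param_table_id: str = "default"

    def __iter__(self):
        return iter(self.residues)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def atoms(self, heavy_only: bool = False):
        for r in self.residues:
            for a in r.atoms:
                if heavy_only and a.is_hydrogen:
                    continue
                yield r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        pts = [a.coords for _, a in self.atoms(heavy_only=heavy_only)]
        return np.array(pts) if pts else np.zeros((0, 3))

    def radii(self, heavy_only: bool = False) -> np.ndarray:
        return np.array([a.w_a for _, a in self.atoms(heavy_only=heavy_only)])

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain, number, icode):
                return r
        raise SelectionError(f"no residue {chain}/{number}{icode}")

    def subset(self, chains: set[str]) -> "Structure":
        missing = chains - set(self.chains)
        if missing:
            raise SelectionError(f"chains absent from structure: {sorted(missing)}")
        return Structure(
            residues=[copy.deepcopy(r) for r in self.residues if r.chain in chains],
            title=self.title,
            param_table_id=self.param_table_id,
        )

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class ResidueSelection:
    """A set of (chain, residue number, insertion code) keys."""

    keys: frozenset[tuple[str, int, str]]

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self.keys

    def validate(self, structure: Structure) -> None:
        present = {r.key for r in structure.residues}
        missing = self.keys - present
        if missing:
            raise SelectionError(f"selection members absent: {sorted(missing)}")

    def residues(self, structure: Structure) -> list[Residue]:
        self.validate(structure)
        return [r for r in structure.residues if r.key in self.keys]


# ---------------------------------------------------------------------------
# PDB reading / writing


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties by altloc letter."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc or "~"))
        out.append(best)
    return out


def read_structure(
    pdb_text: str,
    *,
    include_hetero: bool = False,
    include_waters: bool = False,
    table: ParameterTable | None = None,
) -> Structure:
    """Parse PDB-format text into a parameterized :class:`Structure`.

    Waters and hetero records are excluded by default; alternate locations
    are resolved to the highest-occupancy copy (ties by altloc letter).
    """
    table = table or default_table()
    if "ATOM" not in pdb_text and "HETATM" not in pdb_text:
        raise FormatError("no ATOM records found in input text")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"PDB parse failed: {exc}") from exc
    st.setup_entities()
    title = ""
    for line in pdb_text.splitlines():
        if line.startswith("TITLE"):
            title = line[10:].strip()
            break
    out = Structure(title=title)
    if len(st) == 0:
        raise FormatError("no models in input text")
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            if res.name in _WATER_NAMES:
                if not include_waters:
                    continue
            elif het and not include_hetero:
                continue
            atoms: list[Atom] = []
            for at in res:
                element = at.element.name.upper() if at.element else ""
                p: AtomParams = table.lookup(at.name, element or "X")
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=element or "X",
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        w_a=p.w_a,
                        lj=p.lj,
                        occupancy=at.occ,
                        altloc="" if at.altloc in ("", "\x00") else at.altloc,
                    )
                )
            atoms = _resolve_altlocs(atoms)
            out.residues.append(
                Residue(
                    chain=chain.name,
                    number=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    name=res.name,
                    atoms=atoms,
                )
            )
    if out.n_atoms == 0:
        raise FormatError("no atoms retained after filtering")
    return out


def write_structure(structure: Structure) -> str:
    """Serialize to PDB text (ATOM/TER/END records, 3-decimal coordinates)."""
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title[:60]}")
    serial = 0
    prev_chain: str | None = None
    for res in structure.residues:
        if prev_chain is not None and res.chain != prev_chain:
            lines.append("TER")
        prev_chain = res.chain
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s}{a.altloc or ' ':1.1s}"
                f"{res.name:>3.3s} {res.chain[:1]:1s}{res.number:4d}"
                f"{res.icode or ' ':1.1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          "
                f"{a.element:>2.2s}"
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Shaving and selections


def shave_to_alanine(structure: Structure, selection: ResidueSelection) -> Structure:
    """Truncate selected side chains to alanine (Ala/Gly/Cys exempt).

    For each selected residue outside the exemption list, atoms beyond CB are
    removed and the residue is renamed ALA for parameterization; backbone and
    CB coordinates are untouched.  The input structure is not modified.
    """
    selection.validate(structure)
    out = structure.copy()
    for res in out.residues:
        if res.key not in selection or res.name in SHAVE_EXEMPT:
            continue
        if not res.has_atom("CA"):
            continue  # pseudo-atom residue, nothing to shave
        kept = [
            a for a in res.atoms
            if a.name in _ALANINE_ATOMS
            or (a.is_hydrogen and a.name in _ALANINE_HYDROGENS)
        ]
        res.atoms = kept
        res.name = "ALA"
    return out


def select_pocket_residues(
    structure: Structure, center: np.ndarray, radius: float
) -> ResidueSelection:
    """Residues having any heavy atom within ``radius`` of ``center``."""
    if not (radius > 0):
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    keys = set()
    for res in structure.residues:
        for a in res.atoms:
            if a.is_hydrogen:
                continue
            if np.dot(a.coords - center, a.coords - center) <= radius * radius:
                keys.add(res.key)
                break
    if not keys:
        logger.warning("no residues within %.2f A of %s", radius, center)
    return ResidueSelection(keys=frozenset(keys))


# ---------------------------------------------------------------------------
# Buried interface area


def buried_interface_area(
    structure: Structure,
    chains_a: set[str],
    chains_b: set[str],
    probe_radius: float = 1.4,
    n_points: int = 300,
) -> float:
    """Per-side buried solvent-accessible area between two chain sets (A^2).

    Computed as ``(SASA(A) + SASA(B) - SASA(A+B)) / 2`` with the Shrake-Rupley
    method on heavy atoms; this is the conventional per-side buried-area
    figure quoted for protein-protein interfaces.
    """
    if not chains_a or not chains_b:
        raise SelectionError("both chain sets must be non-empty")
    if chains_a & chains_b:
        raise SelectionError("chain sets must be disjoint")

    def total_sasa(sub: Structure) -> float:
        coords = sub.coords(heavy_only=True)
        radii = sub.radii(heavy_only=True)
        return float(shrake_rupley(coords, radii, probe_radius, n_points).sum())

    sa = total_sasa(structure.subset(chains_a))
    sb = total_sasa(structure.subset(chains_b))
    sab = total_sasa(structure.subset(chains_a | chains_b))
    buried = 0.5 * (sa + sb - sab)
    if buried < 0:
        # numerical jitter from the finite point lattice
        if buried < -1.0:
            warnings.warn(f"negative buried area {buried:.2f} A^2 clamped to 0")
        buried = 0.0
    return buried
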