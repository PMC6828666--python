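"""Atom parameterization: van der Waals radii and Lennard-Jones coefficients.

The packaged table (``data/atom_params.tsv``) maps atom classes to a van der
Waals radius ``w_a`` and 12-6 Lennard-Jones coefficients ``(A, B)`` in
kcal/mol Angstrom units.  Lookup is by PDB atom name first (``name:<NAME>``
rows, none shipped by default) and then by element symbol (``elem:<EL>``),
with ``elem:X`` as the generic carbon-like fallback.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass


class ParameterizationError(ValueError):
    """An atom could not be assigned van der Waals / LJ parameters."""


@dataclass(frozen=True)
class LJParams:
    """12-6 Lennard-Jones pair coefficients against a probe point.

    The single-atom potential ``A/d**12 - B/d**6`` has well depth
    ``B**2 / (4 * A)`` at distance ``(2 * A / B) ** (1 / 6)``.
    """

    A: float
    B: float

    def __post_init__(self) -> None:
        if not (self.A > 0):
            raise ValueError(f"A must be positive, got {self.A}")
        if self.B < 0:
            raise ValueError(f"B must be non-negative, got {self.B}")

    @property
    def well_depth(self) -> float:
        return self.B * self.B / (4.0 * self.A)

    @property
    def r_min(self) -> float:
        return (2.0 * self.A / self.B) ** (1.0 / 6.0) if self.B > 0 else 0.0


@dataclass(frozen=True)
class AtomParams:
    w_a: float
    lj: LJParams


class ParameterTable:
    """Atom-class keyed table of ``w_a`` and LJ coefficients."""

    def __init__(self, rows: dict[str, AtomParams]):
        if "elem:X" not in rows:
            raise ValueError("parameter table must contain an 'elem:X' fallback row")
        self._rows = dict(rows)

    @classmethod
    def from_text(cls, text: str) -> "ParameterTable":
        rows: dict[str, AtomParams] = {}
        header_seen = False
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # column-header line
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"malformed parameter row: {line!r}")
            key, w_a, a, b = fields
            rows[key] = AtomParams(w_a=float(w_a), lj=LJParams(A=float(a), B=float(b)))
        return cls(rows)

    @classmethod
    def default(cls) -> "ParameterTable":
        text = (
            importlib.resources.files("openpocket.data")
            .joinpath("atom_params.tsv")
            .read_text()
        )
        return cls.from_text(text)

    def lookup(self, atom_name: str, element: str) -> AtomParams:
        """Resolve parameters by atom name, element, then generic fallback."""
        for key in (f"name:{atom_name.upper()}", f"elem:{element.upper()}", "elem:X"):
            if key in self._rows:
                return self._rows[key]
        raise ParameterizationError(
            f"no parameters for atom {atom_name!r} (element {element!r})"
        )


_DEFAULT_TABLE: ParameterTable | None = None


def default_table() -> ParameterTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ParameterTable.default()
    return _DEFAULT_TABLE
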