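"""Synthetic structures and toy hit tables for testing every pipeline stage.

All generators are deterministic per seed and assert their own geometric
guarantees (cavity emptiness, side-chain collapse) at build time, so tests
downstream are self-validating.  Pseudo-atoms are parameterized as generic
carbons; peptide geometry uses ideal bond lengths and angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import sidechain
from .params import default_table
from .sidechain import place_atom, set_chis
from .structure import Atom, Residue, Structure
from .triage import HitRecord

_TABLE = default_table()


def _atom(serial: int, name: str, element: str, coords) -> Atom:
    p = _TABLE.lookup(name, element)
    return Atom(serial=serial, name=name, element=element,
                coords=np.asarray(coords, dtype=float),
                w_a=p.w_a, lj=p.lj)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = math.pi * (1.0 + 5.0**0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_hollow_sphere(inner_radius: float = 4.0,
                       shell_atom_count: int = 200,
                       seed: int = 0,
                       center=(0.0, 0.0, 0.0)) -> Structure:
    """Carbon pseudo-atom shell enclosing an empty cavity.

    Atom centres sit on a sphere of radius ``inner_radius + w_C`` so the van
    der Waals surface of the shell touches the cavity of the requested
    radius.  The lattice is rotated by a seed-dependent random rotation.
    """
    if inner_radius < 2:
        raise ValueError("inner_radius must be >= 2 A")
    if shell_atom_count < 50:
        raise ValueError("need at least 50 shell atoms")
    rng = np.random.default_rng(seed)
    w_c = _TABLE.lookup("C", "C").w_a
    radius = inner_radius + w_c
    pts = fibonacci_sphere(shell_atom_count) @ _random_rotation(rng).T
    coords = np.asarray(center, dtype=float) + radius * pts
    st = Structure(title=f"hollow sphere r={inner_radius} seed={seed}")
    for k, xyz in enumerate(coords):
        st.residues.append(Residue(
            chain="S", number=k + 1, icode="", name="UNK",
            atoms=[_atom(k + 1, "C", "C", xyz)]))
    # construction guarantees
    norms = np.linalg.norm(coords - np.asarray(center), axis=1)
    assert np.allclose(norms, radius, atol=1e-6)
    assert norms.min() >= inner_radius
    return st


def make_two_cavity(inner_radius: float = 4.0,
                    shell_atom_count: int = 200,
                    separation: float | None = None,
                    seed: int = 0) -> Structure:
    """Two disjoint hollow-sphere cavities in one structure."""
    w_c = _TABLE.lookup("C", "C").w_a
    if separation is None:
        separation = 4.0 * (inner_radius + w_c)
    a = make_hollow_sphere(inner_radius, shell_atom_count, seed,
                           center=(-separation / 2, 0, 0))
    b = make_hollow_sphere(inner_radius, shell_atom_count, seed + 1,
                           center=(+separation / 2, 0, 0))
    st = Structure(title=f"two cavities r={inner_radius} seed={seed}")
    serial = 0
    for src, chain in ((a, "S"), (b, "T")):
        for res in src.residues:
            serial += 1
            res = Residue(chain=chain, number=serial, icode="", name="UNK",
                          atoms=[_atom(serial, "C", "C",
                                       res.atoms[0].coords)])
            st.residues.append(res)
    return st


# ---------------------------------------------------------------------------
# Peptide builder (ideal internal coordinates)

_BACKBONE_GEOM = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.530,
}

#: ideal side-chain bond lengths for the simple chain builder
_SC_BOND = {"C": 1.53, "N": 1.49, "O": 1.42, "S": 1.81}

#: side-chain chain layout: ordered (name, element, branch) tuples where
#: branch is None for the main chain or (offset_deg) for a branch copy
_SC_CHAINS: dict[str, list[tuple[str, str, float | None]]] = {
    "SER": [("OG", "O", None)],
    "CYS": [("SG", "S", None)],
    "LYS": [("CG", "C", None), ("CD", "C", None), ("CE", "C", None),
            ("NZ", "N", None)],
    "ARG": [("CG", "C", None), ("CD", "C", None), ("NE", "N", None),
            ("CZ", "C", None)],
    "MET": [("CG", "C", None), ("SD", "S", None), ("CE", "C", None)],
    "LEU": [("CG", "C", None), ("CD1", "C", None), ("CD2", "C", 120.0)],
    "GLU": [("CG", "C", None), ("CD", "C", None), ("OE1", "O", None),
            ("OE2", "O", 120.0)],
}


def build_peptide(sequence: list[str],
                  chain: str = "A",
                  chi_angles: dict[int, list[float]] | None = None,
                  phi: float = -140.0, psi: float = 140.0) -> Structure:
    """Extended peptide with ideal geometry; side chains for a small set of
    residue types (others built to CB).  ``chi_angles`` maps residue index
    (0-based) to chi values in degrees (default all-trans, 180)."""
    chi_angles = chi_angles or {}
    st = Structure(title="synthetic peptide")
    serial = 0
    prev = None  # (N, CA, C) coords of previous residue
    for i, resname in enumerate(sequence):
        resname = resname.upper()
        if prev is None:
            n = np.zeros(3)
            ca = np.array([_BACKBONE_GEOM["N-CA"], 0.0, 0.0])
            c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca,
                           _BACKBONE_GEOM["CA-C"], 111.0, 40.0)
        else:
            pn, pca, pc = prev
            n = place_atom(pn, pca, pc, _BACKBONE_GEOM["C-N"], 116.0, psi)
            ca = place_atom(pca, pc, n, _BACKBONE_GEOM["N-CA"], 122.0, 180.0)
            c = place_atom(pc, n, ca, _BACKBONE_GEOM["CA-C"], 111.0, phi)
        atoms = []
        for name, xyz in (("N", n), ("CA", ca), ("C", c)):
            serial += 1
            atoms.append(_atom(serial, name, name[0], xyz))
        # carbonyl O opposite the next amide
        o = place_atom(n, ca, c, _BACKBONE_GEOM["C-O"], 121.0, psi + 180.0)
        serial += 1
        atoms.append(_atom(serial, "O", "O", o))
        if resname != "GLY":
            cb = place_atom(c, n, ca, _BACKBONE_GEOM["CA-CB"], 110.5, -122.6)
            serial += 1
            atoms.append(_atom(serial, "CB", "C", cb))
        res = Residue(chain=chain, number=i + 1, icode="", name=resname,
                      atoms=atoms)
        if resname in _SC_CHAINS:
            serial = _build_side_chain(res, serial,
                                       chi_angles.get(i))
        st.residues.append(res)
        prev = (n, ca, c)
    return st


def _build_side_chain(res: Residue, serial: int,
                      chis: list[float] | None) -> int:
    layout = _SC_CHAINS[res.name]
    n_main = sum(1 for _, _, br in layout if br is None)
    if chis is None:
        chis = [180.0] * n_main
    main = [res.atom("N").coords, res.atom("CA").coords,
            res.atom("CB").coords]
    k = 0
    for name, element, branch in layout:
        if branch is None:
            tau = chis[k] if k < len(chis) else 180.0
            xyz = place_atom(main[-3], main[-2], main[-1],
                             _SC_BOND[element], 111.0, tau)
            main.append(xyz)
            k += 1
        else:
            tau = (chis[k - 1] if k - 1 < len(chis) else 180.0) + branch
            xyz = place_atom(main[-4], main[-3], main[-2],
                             _SC_BOND[element], 111.0, tau)
        serial += 1
        res.atoms.append(_atom(serial, name, element, xyz))
    # align measured chis with requested values (builder frame conventions)
    try:
        set_chis(res, chis[:sidechain.n_chis(res)])
    except Exception:
        pass
    return serial


# ---------------------------------------------------------------------------
# Collapsed-pocket toy


def _pose_lysine(res: Residue, chis: tuple[float, float, float, float]) -> None:
    """Rebuild CG/CD/CE/NZ of a lysine from chi angles (ideal geometry)."""
    main = [res.atom("N").coords, res.atom("CA").coords,
            res.atom("CB").coords]
    for (name, element, _), tau in zip(_SC_CHAINS["LYS"], chis):
        xyz = place_atom(main[-3], main[-2], main[-1],
                         _SC_BOND[element], 111.0, tau)
        main.append(xyz)
        res.atom(name).coords = xyz


@dataclass
class CollapsedPocketFixture:
    """Collapsed-pocket toy: structure, cavity centre, and an open
    reference pose obtained by rotating the long side chains outward."""

    structure: Structure
    center: np.ndarray
    open_structure: Structure
    cavity_radius: float
    flexible_keys: list[tuple[str, int, str]]


def make_collapsed_pocket(seed: int = 0,
                          cavity_radius: float = 5.0,
                          n_wall: int = 260,
                          n_flexible: int = 4) -> CollapsedPocketFixture:
    """A rigid concave scaffold whose long side chains collapse into the
    cavity.

    A quasi-spherical wall of carbon pseudo-atoms (plus alanine scaffold
    residues) encloses a cavity; ``n_flexible`` lysines sit in wall openings
    with their side chains built pointing inward, obstructing the cavity.
    The returned open reference pose points the same side chains outward
    through their wall openings.
    """
    if not (3 <= n_flexible <= 5):
        raise ValueError("n_flexible must be in 3..5")
    rng = np.random.default_rng(seed)
    w_c = _TABLE.lookup("C", "C").w_a
    wall_radius = cavity_radius + w_c
    rot = _random_rotation(rng)
    wall_pts = wall_radius * (fibonacci_sphere(n_wall) @ rot.T)

    # anchor directions for the flexible residues: spread on the equator
    angles = np.linspace(0, 2 * math.pi, n_flexible, endpoint=False)
    dirs = np.column_stack([np.cos(angles), np.sin(angles),
                            np.zeros(n_flexible)])

    st = Structure(title=f"collapsed pocket seed={seed}")
    serial = 0
    flexible_keys: list[tuple[str, int, str]] = []
    collapsed: list[Residue] = []
    chi_grid = [float(a) for a in range(-180, 180, 30)]
    for idx, u in enumerate(dirs):
        inward = -u
        t1 = np.cross(inward, [0.0, 0.0, 1.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(u, t1)
        ca = (wall_radius + 1.5) * u
        n = ca + 1.458 * t1
        c = ca + 1.525 * (math.cos(math.radians(111.0)) * t1
                          + math.sin(math.radians(111.0)) * t2)
        o = c + 1.231 * u
        # CB tilted ~30 degrees off the inward radial so chi1 flips move
        # the chain between inside and outside the wall
        cb = ca + 1.530 * (math.cos(math.radians(30.0)) * inward
                           + math.sin(math.radians(30.0)) * t2)
        atoms = []
        for name, element, xyz in (
                ("N", "N", n), ("CA", "C", ca), ("C", "C", c),
                ("O", "O", o), ("CB", "C", cb)):
            serial += 1
            atoms.append(_atom(serial, name, element, xyz))
        res = Residue(chain="A", number=idx + 1, icode="", name="LYS",
                      atoms=atoms)
        for name, element, _ in _SC_CHAINS["LYS"]:
            serial += 1
            res.atoms.append(_atom(serial, name, element, ca))  # placeholder
        _pose_lysine(res, (180.0, 180.0, 180.0, 180.0))
        # deterministic grid search for the most collapsed pose
        best = None
        for chi1 in chi_grid:
            for chi2 in chi_grid:
                _pose_lysine(res, (chi1, chi2, 180.0, 180.0))
                tip = float(np.linalg.norm(res.atom("NZ").coords))
                chain_max = max(float(np.linalg.norm(res.atom(nm).coords))
                                for nm in ("CG", "CD", "CE", "NZ"))
                if chain_max > wall_radius + 0.5:
                    continue  # chain pokes through the wall band
                if best is None or tip < best[0]:
                    best = (tip, chi1, chi2)
        assert best is not None, "no collapsed pose found"
        _pose_lysine(res, (best[1], best[2], 180.0, 180.0))
        st.residues.append(res)
        flexible_keys.append(res.key)
        collapsed.append(res)

    # alanine scaffold residues on the wall (rigid, "backbone" flavour)
    n_scaffold = 12 - n_flexible
    scaffold_dirs = fibonacci_sphere(max(n_scaffold, 1))
    for j in range(n_scaffold):
        u = scaffold_dirs[j]
        base = (wall_radius + 1.2) * u
        t1 = np.cross(u, [0.0, 1.0, 0.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(u, [1.0, 0.0, 0.0])
        t1 /= np.linalg.norm(t1)
        atoms = []
        for name, element, xyz in (
                ("N", "N", base + 1.458 * t1), ("CA", "C", base),
                ("C", "C", base - 1.525 * t1),
                ("O", "O", base - 1.525 * t1 + 1.231 * np.cross(u, t1)),
                ("CB", "C", base - 1.53 * u)):
            serial += 1
            atoms.append(_atom(serial, name, element, xyz))
        st.residues.append(Residue(chain="A", number=100 + j, icode="",
                                   name="ALA", atoms=atoms))

    # open reference pose: grid-search the most outward-pointing torsions
    open_st = st.copy()
    for key in flexible_keys:
        res = open_st.residue(*key)
        best = None
        for chi1 in chi_grid:
            for chi2 in chi_grid:
                _pose_lysine(res, (chi1, chi2, 180.0, 180.0))
                tip = float(np.linalg.norm(res.atom("NZ").coords))
                chain_min = min(float(np.linalg.norm(res.atom(nm).coords))
                                for nm in ("CG", "CD", "CE", "NZ"))
                if best is None or (tip, chain_min) > (best[0], best[1]):
                    best = (tip, chain_min, chi1, chi2)
        _pose_lysine(res, (best[2], best[3], 180.0, 180.0))

    # keep wall atoms clear of both poses (entry/exit openings)
    all_sc = []
    for src in (st, open_st):
        for key in flexible_keys:
            res = src.residue(*key)
            for a in res.atoms:
                all_sc.append(a.coords)
    scaffold_atoms = [a.coords for r in st.residues if r.name == "ALA"
                      for a in r.atoms]
    keep = []
    for xyz in wall_pts:
        d_sc = min(np.linalg.norm(xyz - p) for p in all_sc)
        d_sf = min((np.linalg.norm(xyz - p) for p in scaffold_atoms),
                   default=np.inf)
        if d_sc > 3.0 and d_sf > 2.0:
            keep.append(xyz)
    for src in (st, open_st):
        for k, xyz in enumerate(keep):
            serial += 1
            src.residues.append(Residue(
                chain="W", number=k + 1, icode="", name="UNK",
                atoms=[_atom(serial, "C", "C", xyz)]))

    center = np.zeros(3)
    # construction guarantees: collapse inside, open pose outside
    for res in collapsed:
        tip = res.atom("NZ").coords
        assert np.linalg.norm(tip) < cavity_radius, \
            f"collapsed tip at {np.linalg.norm(tip):.2f} A not inside cavity"
    for key in flexible_keys:
        tip = open_st.residue(*key).atom("NZ").coords
        assert np.linalg.norm(tip) > wall_radius, \
            "open-pose tip not outside the wall"
    return CollapsedPocketFixture(
        structure=st, center=center, open_structure=open_st,
        cavity_radius=cavity_radius, flexible_keys=flexible_keys)


# ---------------------------------------------------------------------------
# Toy hit tables


def make_toy_hit_table(n: int, seed: int = 0,
                       fp_bits: int = 64,
                       duplicate_every: int = 10) -> list[HitRecord]:
    """Random docking-hit records emulating a screening deck at toy scale.

    Scores ~ Normal(-20, 10), MW ~ Uniform(100, 700), logP ~ Normal(2.5, 2),
    logS ~ Normal(-4, 1.5), anchor distances ~ Uniform(2, 15); fingerprints
    are random bit vectors with duplicate pairs planted every
    ``duplicate_every`` records (record k copies the fingerprint of k-1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    hits: list[HitRecord] = []
    width = len(str(n))
    for k in range(n):
        fp = (rng.random(fp_bits) < 0.3).astype(np.uint8)
        if duplicate_every and k % duplicate_every == 0 and k > 0:
            fp = hits[k - 1].fingerprint.copy()
        hits.append(HitRecord(
            compound_id=f"CMPD{k:0{width}d}",
            score=float(rng.normal(-20.0, 10.0)),
            mw=float(rng.uniform(100.0, 700.0)),
            logp=float(rng.normal(2.5, 2.0)),
            logs=float(rng.normal(-4.0, 1.5)),
            fingerprint=fp,
            anchor_distance=float(rng.uniform(2.0, 15.0)),
        ))
    return hits
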