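"""Post-docking hit triage: the screening funnel and the full-atom score.

The funnel retains docking hits scoring at or below a threshold (more
negative is better), removes chemical redundancy by greedy leader clustering
on fingerprint Tanimoto similarity, applies drug-like property windows
(molecular weight, logP, predicted solubility), dismisses poses whose
minimum heavy-atom distance to an anchor residue at the pocket bottom
exceeds a cutoff, and keeps the best-scoring candidates.  Every decision is
appended to each hit's filter trail, so reruns are reproducible
hit-for-hit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structure import SelectionError, Structure

#: default funnel parameters
SCORE_THRESHOLD = -30.0
ANCHOR_MAX_DISTANCE = 8.0
N_CANDIDATES = 100
DEFAULT_PROPERTY_RANGES: dict[str, tuple[float, float]] = {
    "mw": (150.0, 550.0),
    "logp": (-1.0, 5.0),
    "logs": (-6.0, float("inf")),
}


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the full-atom binding-score combination."""

    alpha1: float = 1.0   # electrostatics
    alpha2: float = 1.0   # hydrogen bonding
    alpha3: float = 1.0   # non-polar solvation
    alpha4: float = 1.0   # polar solvation
    T: float = 300.0      # K


@dataclass(frozen=True)
class EnergyComponents:
    """Per-complex energy terms (kcal/mol) entering the binding score."""

    E_int: float = 0.0     # ligand internal strain
    TdS_tor: float = 0.0   # torsional entropy loss x T
    E_vw: float = 0.0      # van der Waals
    E_el: float = 0.0      # electrostatic
    E_hb: float = 0.0      # hydrogen bonding
    E_hp: float = 0.0      # non-polar solvation
    E_sf: float = 0.0      # polar solvation


def full_atom_score(components: EnergyComponents,
                    weights: ScoreWeights | None = None) -> float:
    """Weighted sum ``E_int + T*dS_tor + E_vw + a1*E_el + a2*E_hb +
    a3*E_hp + a4*E_sf``; a pure function of its inputs."""
    w = weights or ScoreWeights()
    c = components
    return (c.E_int + c.TdS_tor + c.E_vw + w.alpha1 * c.E_el
            + w.alpha2 * c.E_hb + w.alpha3 * c.E_hp + w.alpha4 * c.E_sf)


@dataclass
class HitRecord:
    """One virtual-screening hit with its pose geometry and filter trail."""

    compound_id: str
    score: float
    mw: float | None = None
    logp: float | None = None
    logs: float | None = None
    fingerprint: np.ndarray | None = None   # fixed-length 0/1 vector
    pose_coords: np.ndarray | None = None   # (n, 3) heavy-atom pose
    anchor_distance: float | None = None    # precomputed, A
    commercially_available: bool = True
    trail: list[tuple[str, bool, float | None]] = field(default_factory=list)

    def log(self, filter_name: str, passed: bool,
            value: float | None = None) -> None:
        self.trail.append((filter_name, passed, value))

    def clone(self) -> "HitRecord":
        return replace(self, trail=list(self.trail))


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Bit-vector Tanimoto similarity |A&B| / |A|B|; 1.0 for two empty sets."""
    if fp_a.shape != fp_b.shape:
        raise ValueError("fingerprint length mismatch")
    a = fp_a.astype(bool)
    b = fp_b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def score_filter(hits: list[HitRecord],
                 threshold: float = SCORE_THRESHOLD,
                 strict: bool = False) -> list[HitRecord]:
    """Retain hits scoring at or below ``threshold`` (below only if strict)."""
    out = []
    for h in hits:
        passed = h.score < threshold if strict else h.score <= threshold
        h.log("score", passed, h.score)
        if passed:
            out.append(h)
    return out


def property_filter(hits: list[HitRecord],
                    ranges: dict[str, tuple[float, float]] | None = None
                    ) -> list[HitRecord]:
    """Retain hits whose configured properties all fall in closed intervals.

    ``ranges`` maps property names (``mw``, ``logp``, ``logs``) to
    ``(lo, hi)``; a missing property value fails that filter.
    """
    if ranges is None:
        ranges = DEFAULT_PROPERTY_RANGES
    unknown = set(ranges) - {"mw", "logp", "logs"}
    if unknown:
        raise ValueError(f"unknown properties: {sorted(unknown)}")
    out = []
    for h in hits:
        ok = True
        for prop, (lo, hi) in ranges.items():
            value = getattr(h, prop)
            in_range = value is not None and lo <= value <= hi
            h.log(f"property:{prop}", in_range, value)
            ok = ok and in_range
        if ok:
            out.append(h)
    return out


def anchor_distance_filter(hits: list[HitRecord],
                           structure: Structure | None = None,
                           anchor: tuple[str, int, str] | None = None,
                           max_distance: float = ANCHOR_MAX_DISTANCE
                           ) -> list[HitRecord]:
    """Dismiss hits farther than ``max_distance`` from the anchor residue.

    Distance is the minimum over all (pose heavy atom, anchor heavy atom)
    pairs; hits carrying a precomputed ``anchor_distance`` are filtered on
    it directly, otherwise ``structure`` and ``anchor`` (chain, resnum,
    icode) are required to locate the anchor's atoms.
    """
    anchor_coords: np.ndarray | None = None
    if structure is not None:
        if anchor is None:
            raise SelectionError("anchor residue spec required with structure")
        res = structure.residue(*anchor)  # raises SelectionError if absent
        anchor_coords = np.array(
            [a.coords for a in res.atoms if not a.is_hydrogen])
    out = []
    for h in hits:
        if h.anchor_distance is not None:
            dist = float(h.anchor_distance)
        elif h.pose_coords is not None and anchor_coords is not None:
            d = np.sqrt(np.sum(
                (h.pose_coords[:, None, :] - anchor_coords[None, :, :]) ** 2,
                axis=2))
            dist = float(d.min())
        else:
            h.log("anchor_distance", False, None)
            continue
        passed = dist <= max_distance
        h.log("anchor_distance", passed, dist)
        if passed:
            out.append(h)
    return out


@dataclass
class HitCluster:
    representative: HitRecord
    members: list[HitRecord]


def cluster_hits(hits: list[HitRecord],
                 similarity_threshold: float = 0.6) -> list[HitCluster]:
    """Greedy leader clustering on fingerprint Tanimoto similarity.

    Hits are visited in ascending score order (best first); each joins the
    first cluster whose representative is at least ``similarity_threshold``
    similar, else founds a new cluster.  The representative is the
    best-scoring member (the founder, given the visit order).
    """
    lengths = {h.fingerprint.shape for h in hits if h.fingerprint is not None}
    if len(lengths) > 1:
        raise ValueError("fingerprint length mismatch across hits")
    clusters: list[HitCluster] = []
    for h in sorted(hits, key=lambda h: (h.score, h.compound_id)):
        if h.fingerprint is None:
            raise ValueError(f"hit {h.compound_id} lacks a fingerprint")
        placed = False
        for cl in clusters:
            sim = tanimoto(h.fingerprint, cl.representative.fingerprint)
            if sim >= similarity_threshold:
                cl.members.append(h)
                placed = True
                break
        if not placed:
            clusters.append(HitCluster(representative=h, members=[h]))
    for cl in clusters:
        for h in cl.members:
            h.log("cluster", h is cl.representative, None)
    return clusters


def select_candidates(hits: list[HitRecord],
                      n: int = N_CANDIDATES) -> list[HitRecord]:
    """Best ``n`` hits by score (ties by compound id); respects the
    commercial-availability flag."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = [h for h in hits if h.commercially_available]
    pool.sort(key=lambda h: (h.score, h.compound_id))
    chosen = pool[:n]
    chosen_ids = {id(h) for h in chosen}
    for h in hits:
        h.log("select", id(h) in chosen_ids, None)
    return chosen


@dataclass
class FunnelReport:
    stages: list[tuple[str, int, int]] = field(default_factory=list)
    # (stage name, n in, n out)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append((name, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages,
                            columns=["stage", "n_in", "n_retained"])


def run_funnel(hits: list[HitRecord],
               score_threshold: float = SCORE_THRESHOLD,
               similarity_threshold: float = 0.6,
               property_ranges: dict[str, tuple[float, float]] | None = None,
               structure: Structure | None = None,
               anchor: tuple[str, int, str] | None = None,
               anchor_max_distance: float = ANCHOR_MAX_DISTANCE,
               n_candidates: int = N_CANDIDATES
               ) -> tuple[list[HitRecord], FunnelReport]:
    """Full triage cascade: score -> cluster representatives -> properties
    -> anchor distance -> top-N; returns survivors and a per-stage report."""
    report = FunnelReport()
    stage = score_filter(hits, score_threshold)
    report.add("score", len(hits), len(stage))
    clusters = cluster_hits(stage, similarity_threshold)
    reps = [cl.representative for cl in clusters]
    report.add("cluster", len(stage), len(reps))
    kept = property_filter(reps, property_ranges)
    report.add("properties", len(reps), len(kept))
    near = anchor_distance_filter(kept, structure, anchor,
                                  anchor_max_distance)
    report.add("anchor_distance", len(kept), len(near))
    final = select_candidates(near, n_candidates)
    report.add("select", len(near), len(final))
    return final, report


# ---------------------------------------------------------------------------
# Tabular IO

_COLUMNS = ["id", "score", "mw", "logp", "logs", "fp", "dist_anchor",
            "available"]


def hits_to_frame(hits: list[HitRecord]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append({
            "id": h.compound_id,
            "score": h.score,
            "mw": h.mw,
            "logp": h.logp,
            "logs": h.logs,
            "fp": "".join(map(str, h.fingerprint.astype(int)))
            if h.fingerprint is not None else "",
            "dist_anchor": h.anchor_distance,
            "available": int(h.commercially_available),
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_hit_table(hits: list[HitRecord]) -> str:
    buf = io.StringIO()
    hits_to_frame(hits).to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def read_hit_table(text: str) -> list[HitRecord]:
    df = pd.read_csv(io.StringIO(text), sep="\t",
                     dtype={"id": str, "fp": str})
    hits = []
    for _, row in df.iterrows():
        fp = None
        if isinstance(row.get("fp"), str) and row["fp"]:
            fp = np.array([int(c) for c in row["fp"]], dtype=np.uint8)

        def opt(name):
            v = row.get(name)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) \
                else float(v)

        hits.append(HitRecord(
            compound_id=row["id"],
            score=float(row["score"]),
            mw=opt("mw"), logp=opt("logp"), logs=opt("logs"),
            fingerprint=fp,
            anchor_distance=opt("dist_anchor"),
            commercially_available=bool(int(row.get("available", 1))),
        ))
    return hits
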