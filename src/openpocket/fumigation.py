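"""Pocket fumigation: open collapsed pockets by penalty-biased sampling.

The protocol fills the maximal cavity of a pocket with a repulsive
pseudo-ligand density and relaxes the side chains against it:

1. select pocket residues around a centre and shave them to alanine;
2. build the atom density map ``D`` of the shaved structure on a 0.5 A grid
   and its lambda = 12 A Gaussian convolution ``Dc``; the difference
   ``F = Dc - D`` is large exactly in the space a ligand could occupy;
3. run Metropolis Monte Carlo over the side-chain torsions of the original
   (unshaved) structure with ``w_F * sum_atoms F(atom)`` added as a penalty
   to a minimal physical energy (soft clash repulsion + 3-fold torsion term);
4. rank accepted conformers, keep the top twenty, and re-run pocket
   detection and druggability assessment on each.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import grids, pockets, sidechain
from .grids import ConvolutionSpec, GridMap
from .pockets import PocketConfig, PocketEnvelope, DruggabilityVerdict
from .structure import Residue, ResidueSelection, Structure, select_pocket_residues, shave_to_alanine

logger = logging.getLogger(__name__)

#: gas constant, kcal / (mol K)
R_KCAL = 1.987204259e-3

#: soft-clash onset fraction of the summed van der Waals radii
CLASH_FRACTION = 0.8
#: quartic clash stiffness, kcal/mol/A^4
CLASH_K = 10.0
#: 3-fold torsion barrier height, kcal/mol
TORSION_K = 0.3


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo sampling parameters."""

    steps: int = 10_000
    temperature: float = 300.0          # K
    w_F: float = 3.0                    # kcal/mol per density unit
    p_local: float = 0.7                # local-move probability (else jump)
    local_sigma: float = 15.0           # degrees
    seed: int = 0
    jump_angles: tuple[float, ...] | None = None  # discrete jump set, degrees

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.w_F < 0:
            raise ValueError("w_F must be >= 0")
        if not (0.0 <= self.p_local <= 1.0):
            raise ValueError("p_local must be a probability")


@dataclass
class EnergyBreakdown:
    """Physical (clash + torsion) and map-penalty energies, kcal/mol."""

    physical: float
    penalty: float

    @property
    def combined(self) -> float:
        return self.physical + self.penalty


@dataclass
class Conformer:
    """One sampled side-chain state: torsions, energies, acceptance step."""

    torsions: dict[tuple[str, int, str], tuple[float, ...]]
    energy: EnergyBreakdown
    step: int
    envelopes: list[PocketEnvelope] = field(default_factory=list)
    verdicts: list[DruggabilityVerdict] = field(default_factory=list)

    def torsion_signature(self, decimals: int = 4) -> tuple:
        return tuple(
            (key, tuple(round(a, decimals) for a in angles))
            for key, angles in sorted(self.torsions.items())
        )


@dataclass
class ConformerEnsemble:
    conformers: list[Conformer]
    config: McConfig
    best_trajectory: list[tuple[int, float]] = field(default_factory=list)
    acceptance_rate: float = 0.0

    def __len__(self) -> int:
        return len(self.conformers)


def _side_chain_atoms(res: Residue) -> list:
    return [a for a in res.atoms
            if not a.is_hydrogen and a.name not in sidechain.BACKBONE_ATOMS]


def _clash_energy(coords_a, w_a, coords_b, w_b) -> float:
    """Quartic soft repulsion between two atom sets (kcal/mol)."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0.0
    d = np.sqrt(np.sum(
        (coords_a[:, None, :] - coords_b[None, :, :]) ** 2, axis=2))
    d0 = CLASH_FRACTION * (w_a[:, None] + w_b[None, :])
    overlap = np.maximum(0.0, d0 - d)
    return float(CLASH_K * np.sum(overlap ** 4))


def _torsion_energy(chis_deg) -> float:
    chis = np.radians(np.asarray(chis_deg, dtype=float))
    return float(TORSION_K * np.sum(1.0 + np.cos(3.0 * chis)))


def combined_energy(structure: Structure, selection: ResidueSelection,
                    fmap: GridMap, config: McConfig) -> EnergyBreakdown:
    """Energy of the current pose: clash + torsion + map penalty.

    The clash term sums the quartic soft repulsion over unique pairs of a
    selected side-chain heavy atom with any heavy atom of another residue;
    the penalty samples ``F`` (trilinearly) at every selected side-chain
    heavy atom, weighted by ``w_F``.
    """
    selection.validate(structure)
    sel_residues = [r for r in structure.residues if r.key in selection]
    sc: list = []
    sc_res: list[int] = []
    for ridx, res in enumerate(structure.residues):
        if res.key in selection:
            for a in _side_chain_atoms(res):
                sc.append(a)
                sc_res.append(ridx)
    all_atoms = [(ridx, a) for ridx, res in enumerate(structure.residues)
                 for a in res.atoms if not a.is_hydrogen]
    penalty = 0.0
    if sc:
        sc_coords = np.array([a.coords for a in sc])
        penalty = config.w_F * float(
            np.sum(grids.sample_map_many(fmap, sc_coords)))
    clash = 0.0
    if sc and all_atoms:
        sc_coords = np.array([a.coords for a in sc])
        sc_w = np.array([a.w_a for a in sc])
        sc_resarr = np.array(sc_res)
        other_coords = np.array([a.coords for _, a in all_atoms])
        other_w = np.array([a.w_a for _, a in all_atoms])
        other_res = np.array([ridx for ridx, _ in all_atoms])
        d = np.sqrt(np.sum(
            (sc_coords[:, None, :] - other_coords[None, :, :]) ** 2, axis=2))
        d0 = CLASH_FRACTION * (sc_w[:, None] + other_w[None, :])
        overlap = np.maximum(0.0, d0 - d)
        e = CLASH_K * overlap ** 4
        e[sc_resarr[:, None] == other_res[None, :]] = 0.0  # intra-residue
        full = float(np.sum(e))
        # cross pairs between two selected side chains are counted twice
        sc_sel = np.isin(other_res, [r for r in sc_resarr]) & np.array(
            [a.name not in sidechain.BACKBONE_ATOMS for _, a in all_atoms])
        dup = float(np.sum(e[:, sc_sel]))
        clash = full - 0.5 * dup
    torsion = 0.0
    for res in sel_residues:
        torsion += _torsion_energy(sidechain.measure_chis(res))
    return EnergyBreakdown(physical=clash + torsion, penalty=penalty)


class _Sampler:
    """Incremental-energy Metropolis chain over side-chain torsions."""

    def __init__(self, structure: Structure, selection: ResidueSelection,
                 fmap: GridMap, config: McConfig):
        selection.validate(structure)
        self.structure = structure.copy()
        self.fmap = fmap
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.residues: list[Residue] = []
        skipped = []
        for res in self.structure.residues:
            if res.key not in selection:
                continue
            if sidechain.has_rotatable_side_chain(res):
                self.residues.append(res)
            else:
                skipped.append(res.label)
        if skipped:
            logger.info("skipping residues without rotatable side chains: %s",
                        skipped)
        if not self.residues:
            raise ValueError("no residues with rotatable side chains selected")
        # static heavy atoms: everything outside the sampled side chains;
        # tagged with their residue key so a residue's own backbone can be
        # excluded from its clash term (intra-residue pairs do not count)
        sampled_keys = {r.key for r in self.residues}
        static = []
        static_keys = []
        for res in self.structure.residues:
            for a in res.atoms:
                if a.is_hydrogen:
                    continue
                if res.key in sampled_keys and \
                        a.name not in sidechain.BACKBONE_ATOMS:
                    continue
                static.append(a)
                static_keys.append(res.key)
        self.static_coords = (np.array([a.coords for a in static])
                              if static else np.zeros((0, 3)))
        self.static_w = np.array([a.w_a for a in static])
        self._static_other = {
            r.key: np.array([k != r.key for k in static_keys], dtype=bool)
            for r in self.residues
        }
        self.sc_atoms = {r.key: _side_chain_atoms(r) for r in self.residues}
        self.chis = {r.key: sidechain.measure_chis(r) for r in self.residues}

    # -- per-residue local energy -------------------------------------------
    def _local_energy(self, res: Residue) -> tuple[float, float]:
        """(physical, penalty) terms attributable to ``res``'s side chain."""
        atoms = self.sc_atoms[res.key]
        coords = np.array([a.coords for a in atoms])
        w = np.array([a.w_a for a in atoms])
        mask = self._static_other[res.key]
        others = [self.static_coords[mask]] + [
            np.array([a.coords for a in self.sc_atoms[r.key]])
            for r in self.residues if r.key != res.key
        ]
        others_w = [self.static_w[mask]] + [
            np.array([a.w_a for a in self.sc_atoms[r.key]])
            for r in self.residues if r.key != res.key
        ]
        other_coords = np.concatenate([o for o in others if len(o)]) \
            if any(len(o) for o in others) else np.zeros((0, 3))
        other_w = np.concatenate([o for o in others_w if len(o)]) \
            if any(len(o) for o in others_w) else np.zeros(0)
        clash = _clash_energy(coords, w, other_coords, other_w)
        torsion = _torsion_energy(self.chis[res.key])
        penalty = self.config.w_F * float(
            np.sum(grids.sample_map_many(self.fmap, coords)))
        return clash + torsion, penalty

    def _propose(self, res: Residue) -> list[float]:
        chis = list(self.chis[res.key])
        cfg = self.config
        if self.rng.random() < cfg.p_local:
            k = int(self.rng.integers(len(chis)))
            chis[k] = float((chis[k] + self.rng.normal(0.0, cfg.local_sigma)
                             + 180.0) % 360.0 - 180.0)
        else:
            if cfg.jump_angles is not None:
                chis = [float(self.rng.choice(cfg.jump_angles))
                        for _ in chis]
            else:
                chis = [float(self.rng.uniform(-180.0, 180.0))
                        for _ in chis]
        return chis

    def _cross_sampled_clash(self) -> float:
        """Soft-clash energy over unique pairs of two sampled side chains."""
        total = 0.0
        for i, ra in enumerate(self.residues):
            ca = np.array([a.coords for a in self.sc_atoms[ra.key]])
            wa = np.array([a.w_a for a in self.sc_atoms[ra.key]])
            for rb in self.residues[i + 1:]:
                cb = np.array([a.coords for a in self.sc_atoms[rb.key]])
                wb = np.array([a.w_a for a in self.sc_atoms[rb.key]])
                total += _clash_energy(ca, wa, cb, wb)
        return total

    def run(self) -> ConformerEnsemble:
        cfg = self.config
        rt = R_KCAL * cfg.temperature
        # initial per-residue local energies
        phys = {r.key: 0.0 for r in self.residues}
        pen = {r.key: 0.0 for r in self.residues}
        for r in self.residues:
            phys[r.key], pen[r.key] = self._local_energy(r)
        # Cross pairs of two sampled side chains appear in both residues'
        # local clash terms; subtracting the unique-pair cross sum once makes
        # the recorded totals exact.  Metropolis deltas need no correction
        # because only one residue moves per step.
        conformers: list[Conformer] = []

        def snapshot(step: int) -> Conformer:
            eb = EnergyBreakdown(
                physical=sum(phys.values()) - self._cross_sampled_clash(),
                penalty=sum(pen.values()),
            )
            return Conformer(
                torsions={k: tuple(v) for k, v in self.chis.items()},
                energy=eb, step=step)

        first = snapshot(0)
        conformers.append(first)
        best = first.energy.combined
        best_traj = [(0, best)]
        accepted = 0
        for step in range(1, cfg.steps + 1):
            res = self.residues[int(self.rng.integers(len(self.residues)))]
            old_chis = list(self.chis[res.key])
            old_coords = [a.coords.copy() for a in self.sc_atoms[res.key]]
            old_phys, old_pen = phys[res.key], pen[res.key]
            new_chis = self._propose(res)
            sidechain.set_chis(res, new_chis)
            self.chis[res.key] = new_chis
            new_phys, new_pen = self._local_energy(res)
            delta = (new_phys + new_pen) - (old_phys + old_pen)
            u = self.rng.random()
            accept = delta <= 0.0 or (rt > 0.0 and u < math.exp(
                min(0.0, -delta / rt)))
            if rt == 0.0:
                accept = delta <= 0.0
            if accept:
                accepted += 1
                phys[res.key], pen[res.key] = new_phys, new_pen
                conf = snapshot(step)
                conformers.append(conf)
                if conf.energy.combined < best:
                    best = conf.energy.combined
                    best_traj.append((step, best))
            else:
                for a, c in zip(self.sc_atoms[res.key], old_coords):
                    a.coords = c
                self.chis[res.key] = old_chis
        return ConformerEnsemble(
            conformers=conformers, config=cfg, best_trajectory=best_traj,
            acceptance_rate=accepted / cfg.steps if cfg.steps else 0.0)


def sampling_selection(structure: Structure,
                       selection: ResidueSelection) -> ResidueSelection:
    """Subset of ``selection`` with rotatable side chains (what is sampled)."""
    selection.validate(structure)
    keys = frozenset(
        r.key for r in structure.residues
        if r.key in selection and sidechain.has_rotatable_side_chain(r))
    return ResidueSelection(keys=keys)


def sample_side_chains(structure: Structure, selection: ResidueSelection,
                       fmap: GridMap, config: McConfig) -> ConformerEnsemble:
    """Metropolis side-chain sampling biased by the fumigation map.

    Each step perturbs one randomly chosen residue (local Gaussian torsion
    move with probability ``p_local``, otherwise a large jump over all of
    its torsions) and accepts with probability ``min(1, exp(-dE / RT))``.
    Identical seeds give identical trajectories.
    """
    if len(selection) == 0:
        raise ValueError("selection is empty")
    sampler = _Sampler(structure, selection, fmap, config)
    return sampler.run()


def realize_conformer(structure: Structure, conformer: Conformer) -> Structure:
    """Apply a conformer's torsions to a copy of ``structure``."""
    out = structure.copy()
    for key, angles in conformer.torsions.items():
        res = out.residue(*key)
        sidechain.set_chis(res, list(angles))
    return out


def rank_and_select(ensemble: ConformerEnsemble, n: int = 20,
                    criterion: str = "combined") -> ConformerEnsemble:
    """The ``n`` lowest-energy distinct conformers (ties by step index)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if criterion not in ("combined", "physical"):
        raise ValueError("criterion must be 'combined' or 'physical'")

    def energy(c: Conformer) -> float:
        return c.energy.combined if criterion == "combined" \
            else c.energy.physical

    seen: set = set()
    distinct: list[Conformer] = []
    for c in sorted(ensemble.conformers, key=lambda c: (energy(c), c.step)):
        sig = c.torsion_signature()
        if sig in seen:
            continue
        seen.add(sig)
        distinct.append(c)
        if len(distinct) == n:
            break
    return ConformerEnsemble(conformers=distinct, config=ensemble.config,
                             best_trajectory=ensemble.best_trajectory,
                             acceptance_rate=ensemble.acceptance_rate)


@dataclass(frozen=True)
class FumigationConfig:
    pocket_radius: float = 8.0          # pocket-residue selection radius, A
    density_spacing: float = grids.DENSITY_SPACING
    density_padding: float = 8.0
    fumigation_lambda: float = grids.FUMIGATION_LAMBDA
    n_select: int = 20
    criterion: str = "combined"
    mc: McConfig = field(default_factory=McConfig)
    pocket: PocketConfig = field(default_factory=PocketConfig)


@dataclass
class FumigationResult:
    apo_envelopes: list[PocketEnvelope]
    apo_verdicts: list[DruggabilityVerdict]
    selected: ConformerEnsemble
    fmap: GridMap
    selection: ResidueSelection
    config: FumigationConfig
    input_energy: EnergyBreakdown | None = None

    @property
    def apo_max_volume(self) -> float:
        return max((e.volume for e in self.apo_envelopes), default=0.0)

    @property
    def best_volume(self) -> float:
        vols = [max((e.volume for e in c.envelopes), default=0.0)
                for c in self.selected.conformers]
        return max(vols, default=0.0)

    @property
    def best_penalty(self) -> float:
        return min((c.energy.penalty for c in self.selected.conformers),
                   default=float("nan"))


def fumigate(structure: Structure, pocket_center, config:
             FumigationConfig | None = None) -> FumigationResult:
    """Run the full pocket-opening protocol around ``pocket_center``.

    Shaving and the difference map use the shaved structure; sampling runs
    on the original, fully side-chained structure against that map.
    """
    config = config or FumigationConfig()
    center = np.asarray(pocket_center, dtype=float)
    selection = select_pocket_residues(structure, center,
                                       config.pocket_radius)
    if len(selection) == 0:
        raise ValueError("no pocket residues within radius of center")
    shaved = shave_to_alanine(structure, selection)
    spec = grids.make_grid(shaved, config.density_spacing,
                           config.density_padding)
    fmap = grids.fumigation_map(
        shaved, spec, ConvolutionSpec(lam=config.fumigation_lambda))
    sampled = sampling_selection(structure, selection)
    if len(sampled) == 0:
        raise ValueError("no pocket residues with rotatable side chains")
    input_energy = combined_energy(structure, sampled, fmap, config.mc)
    ensemble = sample_side_chains(structure, sampled, fmap, config.mc)
    selected = rank_and_select(ensemble, config.n_select, config.criterion)
    apo_envelopes = pockets.find_pockets(structure, config.pocket)
    apo_verdicts = pockets.assess_druggability(apo_envelopes, config.pocket)
    # per-conformer pocket detection reuses the static-atom potential: only
    # the sampled side chains move between conformers
    pocket_spec = grids.make_grid(structure, config.pocket.spacing,
                                  config.pocket.padding)
    moving = {(key, a.name)
              for key in sampled.keys
              for a in _side_chain_atoms(structure.residue(*key))}
    static_atoms = [a for r in structure.residues for a in r.atoms
                    if not a.is_hydrogen and (r.key, a.name) not in moving]
    p0_static = grids.lj_potential_from_atoms(static_atoms, pocket_spec)
    for conf in selected.conformers:
        model = realize_conformer(structure, conf)
        moving_atoms = [a for key in sampled.keys
                        for a in _side_chain_atoms(model.residue(*key))]
        p0_move = grids.lj_potential_from_atoms(moving_atoms, pocket_spec)
        p0 = p0_static.with_values(p0_static.values + p0_move.values,
                                   kind="P0")
        conf.envelopes = pockets.find_pockets(model, config.pocket,
                                              potential=p0)
        conf.verdicts = pockets.assess_druggability(conf.envelopes,
                                                    config.pocket)
    return FumigationResult(
        apo_envelopes=apo_envelopes, apo_verdicts=apo_verdicts,
        selected=selected, fmap=fmap, selection=selection, config=config,
        input_energy=input_energy)
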