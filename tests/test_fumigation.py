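"""Penalty-biased side-chain Monte Carlo: energies, sampling, protocol."""

import math

import numpy as np
import pytest

from openpocket import fumigation, grids
from openpocket.fixtures import build_peptide, make_collapsed_pocket
from openpocket.fumigation import (
    R_KCAL,
    FumigationConfig,
    McConfig,
    combined_energy,
    fumigate,
    rank_and_select,
    realize_conformer,
    sample_side_chains,
    sampling_selection,
)
from openpocket.grids import GridMap
from openpocket.structure import ResidueSelection


def _zero_map(structure, spacing=1.0, padding=10.0, kind="F"):
    spec = grids.make_grid(structure, spacing, padding)
    return GridMap(spec, np.zeros(spec.dims), kind=kind)


def _selection(structure, names):
    return ResidueSelection(frozenset(
        r.key for r in structure.residues if r.name in names))


class TestCombinedEnergy:
    def test_zero_field_zero_penalty(self):
        pep = build_peptide(["ALA", "LYS", "ALA"])
        sel = _selection(pep, {"LYS"})
        eb = combined_energy(pep, sel, _zero_map(pep), McConfig())
        assert eb.penalty == 0.0
        assert eb.combined == pytest.approx(eb.physical)

    def test_zero_weight_drops_penalty(self):
        pep = build_peptide(["ALA", "LYS", "ALA"])
        sel = _selection(pep, {"LYS"})
        fmap = _zero_map(pep)
        fmap.values[:] = 1.7  # constant nonzero field
        eb0 = combined_energy(pep, sel, fmap, McConfig(w_F=0.0))
        assert eb0.penalty == 0.0
        eb3 = combined_energy(pep, sel, fmap, McConfig(w_F=3.0))
        assert eb3.physical == pytest.approx(eb0.physical)
        assert eb3.penalty > 0

    def test_single_atom_at_node_gives_w_f_times_f(self):
        pep = build_peptide(["SER"])
        sel = _selection(pep, {"SER"})
        fmap = _zero_map(pep, spacing=0.5)
        # mark the nodes nearest the two side-chain atoms (CB, OG)
        spec = fmap.spec
        total = 0.0
        for name in ("CB", "OG"):
            xyz = pep.residues[0].atom(name).coords
            f_here = grids.sample_map(fmap, xyz)
            assert f_here == 0.0
        # place a constant field instead: penalty = w_F * sum(F at atoms)
        fmap.values[:] = 0.25
        eb = combined_energy(pep, sel, fmap, McConfig(w_F=2.0))
        assert eb.penalty == pytest.approx(2.0 * 0.25 * 2, abs=1e-9)
        del total

    def test_breakdown_additivity(self):
        pep = build_peptide(["LYS", "ALA", "MET"])
        sel = _selection(pep, {"LYS", "MET"})
        fmap = _zero_map(pep)
        fmap.values[:] = 0.4
        eb = combined_energy(pep, sel, fmap, McConfig())
        assert eb.combined == pytest.approx(eb.physical + eb.penalty,
                                            abs=1e-9)


class TestSampler:
    def _toy(self):
        pep = build_peptide(["ALA", "LYS", "ALA", "MET"])
        sel = _selection(pep, {"LYS", "MET"})
        fmap = _zero_map(pep)
        return pep, sel, fmap

    def test_zero_steps_returns_input(self):
        pep, sel, fmap = self._toy()
        ens = sample_side_chains(pep, sel, fmap, McConfig(steps=0, seed=4))
        assert len(ens) == 1
        conf = ens.conformers[0]
        model = realize_conformer(pep, conf)
        np.testing.assert_allclose(model.coords(), pep.coords(), atol=1e-9)

    def test_same_seed_identical_trajectories(self):
        pep, sel, fmap = self._toy()
        cfg = McConfig(steps=300, seed=11)
        e1 = sample_side_chains(pep, sel, fmap, cfg)
        e2 = sample_side_chains(pep, sel, fmap, cfg)
        assert len(e1) == len(e2)
        for a, b in zip(e1.conformers, e2.conformers):
            assert a.step == b.step
            assert a.torsions == b.torsions
            assert a.energy.combined == b.energy.combined

    def test_backbone_never_moves(self):
        pep, sel, fmap = self._toy()
        ens = sample_side_chains(pep, sel, fmap, McConfig(steps=200, seed=2))
        best = min(ens.conformers, key=lambda c: c.energy.combined)
        model = realize_conformer(pep, best)
        for r0, r1 in zip(pep.residues, model.residues):
            for name in ("N", "CA", "C", "O"):
                if r0.has_atom(name):
                    np.testing.assert_array_equal(r0.atom(name).coords,
                                                  r1.atom(name).coords)

    def test_best_so_far_non_increasing(self):
        pep, sel, fmap = self._toy()
        fmap.values[:] = 0.5
        ens = sample_side_chains(pep, sel, fmap, McConfig(steps=500, seed=3))
        energies = [e for _, e in ens.best_trajectory]
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))

    def test_infinite_temperature_accepts_everything(self):
        pep, sel, fmap = self._toy()
        ens = sample_side_chains(
            pep, sel, fmap,
            McConfig(steps=400, seed=5, temperature=1e12, w_F=0.0))
        assert ens.acceptance_rate == pytest.approx(1.0)

    def test_zero_temperature_only_downhill(self):
        pep, sel, fmap = self._toy()
        fmap.values[:] = 1.0
        ens = sample_side_chains(
            pep, sel, fmap, McConfig(steps=400, seed=6, temperature=1e-9))
        combined = [c.energy.combined for c in ens.conformers]
        assert all(b <= a + 1e-9 for a, b in zip(combined, combined[1:]))

    def test_stored_energies_match_recomputation(self):
        pep, sel, fmap = self._toy()
        fmap.values[:] = 0.3
        cfg = McConfig(steps=300, seed=9)
        ens = sample_side_chains(pep, sel, fmap, cfg)
        sampled = sampling_selection(pep, sel)
        for conf in ens.conformers[:: max(1, len(ens) // 5)]:
            model = realize_conformer(pep, conf)
            eb = combined_energy(model, sampled, fmap, cfg)
            assert conf.energy.combined == pytest.approx(eb.combined,
                                                         abs=1e-6)

    def test_empty_selection_rejected(self):
        pep, _, fmap = self._toy()
        with pytest.raises(ValueError):
            sample_side_chains(pep, ResidueSelection(frozenset()), fmap,
                               McConfig(steps=10))


class TestBoltzmannSampling:
    def test_two_state_frequencies(self):
        """A 1-residue chain over two discrete rotamers reaches Boltzmann
        occupancy within 3 standard errors."""
        pep = build_peptide(["SER"])
        sel = _selection(pep, {"SER"})
        fmap = _zero_map(pep)
        cfg = McConfig(steps=20000, seed=42, p_local=0.0,
                       jump_angles=(0.0, 60.0), w_F=0.0)
        # state energies from the torsion term: E(0) = 2k, E(60) = 0
        from openpocket.fumigation import TORSION_K

        delta_e = 2 * TORSION_K
        rt = R_KCAL * cfg.temperature
        p60 = 1.0 / (1.0 + math.exp(-delta_e / rt))
        ens = sample_side_chains(pep, sel, fmap, cfg)
        # reconstruct per-step occupancy from the accepted snapshots
        key = pep.residues[0].key
        occupancy = np.zeros(cfg.steps + 1)
        snaps = sorted(ens.conformers, key=lambda c: c.step)
        state = 0.0
        j = 0
        for step in range(cfg.steps + 1):
            while j < len(snaps) and snaps[j].step == step:
                state = snaps[j].torsions[key][0]
                j += 1
            occupancy[step] = state
        burn = 2000
        frac60 = np.mean(np.isclose(occupancy[burn:], 60.0))
        n_eff = (cfg.steps - burn) / 10.0  # conservative autocorrelation
        se = math.sqrt(p60 * (1 - p60) / n_eff)
        assert abs(frac60 - p60) < 3 * se


class TestRankAndSelect:
    def _ensemble(self, energies):
        confs = [
            fumigation.Conformer(
                torsions={("A", 1, ""): (float(i),)},
                energy=fumigation.EnergyBreakdown(physical=e, penalty=0.0),
                step=i)
            for i, e in enumerate(energies)
        ]
        return fumigation.ConformerEnsemble(conformers=confs,
                                            config=McConfig())

    def test_selects_n_lowest(self):
        rng = np.random.default_rng(0)
        energies = rng.normal(size=100)
        ens = self._ensemble(energies)
        top = rank_and_select(ens, n=20)
        got = [c.energy.combined for c in top.conformers]
        assert got == sorted(energies)[:20]

    def test_n_exceeding_size_returns_all_sorted(self):
        ens = self._ensemble([3.0, -1.0, 2.0])
        top = rank_and_select(ens, n=10)
        assert [c.energy.combined for c in top.conformers] == [-1.0, 2.0, 3.0]

    def test_duplicates_removed(self):
        confs = [
            fumigation.Conformer(
                torsions={("A", 1, ""): (60.0,)},
                energy=fumigation.EnergyBreakdown(physical=1.0, penalty=0.0),
                step=i)
            for i in range(5)
        ]
        ens = fumigation.ConformerEnsemble(conformers=confs,
                                           config=McConfig())
        top = rank_and_select(ens, n=5)
        assert len(top.conformers) == 1
        assert top.conformers[0].step == 0  # tie broken by step


class TestFumigateProtocol:
    def test_collapsed_toy_opens_and_penalty_drops(self):
        fx = make_collapsed_pocket(seed=1)
        cfg = FumigationConfig(pocket_radius=12.0,
                               mc=McConfig(steps=3000, seed=21))
        res = fumigate(fx.structure, fx.center, cfg)
        assert res.best_volume >= res.apo_max_volume
        assert res.best_penalty < res.input_energy.penalty

    def test_degenerate_config_reduces_to_apo(self):
        fx = make_collapsed_pocket(seed=2)
        cfg = FumigationConfig(pocket_radius=12.0,
                               mc=McConfig(steps=0, w_F=0.0, seed=0))
        res = fumigate(fx.structure, fx.center, cfg)
        assert len(res.selected.conformers) == 1
        conf = res.selected.conformers[0]
        assert [e.volume for e in conf.envelopes] == \
            [e.volume for e in res.apo_envelopes]

    def test_no_residues_near_center_is_error(self):
        fx = make_collapsed_pocket(seed=0)
        with pytest.raises(ValueError):
            fumigate(fx.structure, np.array([500.0, 0.0, 0.0]),
                     FumigationConfig(pocket_radius=2.0))
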