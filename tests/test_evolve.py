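"""Window objective, mutations, SA gating, and the evolutionary loop."""

import numpy as np
import pytest

from redoxsolv.chemgraph import featurize
from redoxsolv.evolve import (
    APPLICATION_WINDOWS,
    Candidate,
    EvolutionConfig,
    MUTATION_ACTIONS,
    ObjectiveResult,
    Rejection,
    TargetWindow,
    ensemble_objective,
    evolve_loop,
    mutate,
    sa_gate,
    window_score,
)
from redoxsolv.mpnn import Prediction
from redoxsolv.solventdb import get_solvent
from redoxsolv.synthetic import SyntheticTruth, gen_molecules, synth_potential


class TestWindowScore:
    def test_midpoint_of_wide_window_scores_one(self):
        w = TargetWindow(4.0, 5.0, steepness=50.0)
        assert window_score(4.5, w) == pytest.approx(1.0, abs=1e-3)

    def test_two_volts_outside_scores_zero(self):
        w = TargetWindow(4.0, 5.0, steepness=50.0)
        assert window_score(2.0, w) == pytest.approx(0.0, abs=1e-3)

    def test_edge_scores_half(self):
        w = TargetWindow(4.0, 5.0, steepness=50.0)
        assert window_score(4.0, w) == pytest.approx(0.5, abs=1e-3)

    def test_unimodal_about_midpoint(self):
        w = TargetWindow(0.0, 1.0, steepness=50.0)
        xs = np.linspace(-1.0, 0.5, 200)
        ys = [window_score(x, w) for x in xs]
        assert np.all(np.diff(ys) >= -1e-12)  # non-decreasing up to midpoint
        xs = np.linspace(0.5, 2.0, 200)
        ys = [window_score(x, w) for x in xs]
        assert np.all(np.diff(ys) <= 1e-12)  # non-increasing after

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            TargetWindow(1.0, 1.0)
        with pytest.raises(ValueError):
            TargetWindow(0.0, 1.0, steepness=0.0)

    def test_narrowest_application_window_still_scores_high_inside(self):
        # PPT window is only 0.25 V wide; default steepness must saturate it
        ppt = APPLICATION_WINDOWS["PPT"]
        w = TargetWindow(ppt["lo"], ppt["hi"])
        mid = 0.5 * (ppt["lo"] + ppt["hi"])
        assert window_score(mid, w) > 0.99


class TestSaGate:
    def test_benzene_passes_default_threshold(self):
        ok, score = sa_gate("c1ccccc1", threshold=4.5)
        assert ok and score < 4.5

    def test_zero_threshold_fails_everything(self):
        for smi in ("C", "c1ccccc1", "CC(=O)O"):
            ok, _ = sa_gate(smi, threshold=0.0)
            assert not ok

    def test_deterministic_per_canonical_smiles(self):
        _, s1 = sa_gate("OCC")
        _, s2 = sa_gate("CCO")
        assert s1 == s2


class TestMutate:
    def setup_method(self):
        self.cfg = EvolutionConfig(seed=0)

    def test_add_atom_to_methane(self):
        rng = np.random.default_rng(0)
        out = mutate(featurize("C"), "add_atom", self.cfg, rng)
        assert not isinstance(out, Rejection)
        assert out.n_heavy == 2

    def test_remove_atom_from_single_atom_rejected(self):
        out = mutate(featurize("C"), "remove_atom", self.cfg)
        assert isinstance(out, Rejection) and "empty" in out.reason

    def test_add_atom_beyond_size_cap_rejected(self):
        cfg = EvolutionConfig(max_heavy_atoms=15, seed=0)
        g15 = featurize("C" * 15)
        out = mutate(g15, "add_atom", cfg)
        assert isinstance(out, Rejection) and "size" in out.reason

    def test_unknown_action_is_an_error(self):
        with pytest.raises(ValueError, match="unknown action"):
            mutate(featurize("CC"), "teleport", self.cfg)

    @pytest.mark.parametrize("action", MUTATION_ACTIONS)
    def test_products_are_valid_and_constrained(self, action):
        rng = np.random.default_rng(11)
        cfg = EvolutionConfig(max_heavy_atoms=10, seed=0)
        for smi in ("CCO", "c1ccccc1", "CC(=O)NC"):
            for _ in range(5):
                out = mutate(featurize(smi), action, cfg, rng)
                if isinstance(out, Rejection):
                    continue
                assert out.n_heavy <= 10
                elems = {out.vocabulary[a.element_index] for a in out.nodes}
                assert elems <= cfg.allowed_elements


class _StubModel:
    """Predictor stub with a fixed or truth-driven potential."""

    def __init__(self, value=None, truth=None, offset=0.0):
        self.value, self.truth, self.offset = value, truth, offset

    def forward_sd(self, g, solvent):
        if self.truth is not None:
            ea, e_red = synth_potential(g, solvent, self.truth)
        else:
            ea, e_red = 0.0, self.value
        e_red += self.offset
        return Prediction(ea_component=ea, solvent_component=e_red - ea,
                          reduction_potential=e_red)


class TestEnsembleObjective:
    def test_all_members_at_midpoint_accepts(self):
        w = TargetWindow(4.0, 5.0)
        models = [_StubModel(value=4.5)] * 5
        res = ensemble_objective("CCO", models, get_solvent("ACN"), w)
        assert res.accept and res.score == pytest.approx(1.0, abs=1e-3)

    def test_four_of_five_inside_rejects(self):
        w = TargetWindow(4.0, 5.0)
        models = [_StubModel(value=4.5)] * 4 + [_StubModel(value=6.0)]
        res = ensemble_objective("CCO", models, get_solvent("ACN"), w)
        assert not res.accept

    def test_zero_models_is_error(self):
        with pytest.raises(ValueError):
            ensemble_objective("CCO", [], get_solvent("ACN"), TargetWindow(0, 1))

    def test_model_failure_rejects_with_reason(self):
        class Broken:
            def forward_sd(self, g, solvent):
                raise RuntimeError("boom")

        res = ensemble_objective("CCO", [Broken()], get_solvent("ACN"),
                                 TargetWindow(0, 1))
        assert not res.accept and "boom" in res.reason


class TestEvolveLoop:
    def test_constant_objective_terminates_at_max_generations(self):
        cfg = EvolutionConfig(population_size=5, max_generations=4, seed=0,
                              max_heavy_atoms=6)
        objective = lambda g: ObjectiveResult(score=1.0, accept=False)
        ranked, history = evolve_loop(["CC"], cfg, objective)
        assert len(history) == 4
        assert ranked == []

    def test_deterministic_for_fixed_seed(self):
        cfg = EvolutionConfig(population_size=5, max_generations=5, seed=3,
                              max_heavy_atoms=6)
        w = TargetWindow(2.0, 3.0)
        truth = SyntheticTruth(noise_sd=0.0, seed=0)
        models = [_StubModel(truth=truth)]
        objective = lambda g: ensemble_objective(g, models, get_solvent("ACN"), w)
        r1, _ = evolve_loop(["CCO"], cfg, objective)
        r2, _ = evolve_loop(["CCO"], cfg, objective)
        assert [c.smiles for c in r1] == [c.smiles for c in r2]

    def test_all_seeds_invalid_is_error(self):
        cfg = EvolutionConfig(seed=0, max_heavy_atoms=3)
        with pytest.raises(ValueError, match="seed"):
            evolve_loop(["not-a-smiles", "C" * 10], cfg, lambda g: None)

    def test_finds_candidates_in_attainable_window(self):
        """Search hits a window confirmed attainable by brute-force enumeration."""
        truth = SyntheticTruth(noise_sd=0.0, seed=0)
        solvent = get_solvent("ACN")
        # brute-force: enumerate the truth over small random molecules and
        # centre the window on the median attainable potential
        values = [synth_potential(featurize(s), solvent, truth)[1]
                  for s in gen_molecules(80, max_heavy=6, seed=42)]
        mid = float(np.median(values))
        w = TargetWindow(mid - 0.25, mid + 0.25)
        assert any(w.contains(v) for v in values)  # attainability confirmed

        models = [_StubModel(truth=truth),
                  _StubModel(truth=truth, offset=0.01),
                  _StubModel(truth=truth, offset=-0.01)]
        objective = lambda g: ensemble_objective(g, models, solvent, w)
        cfg = EvolutionConfig(population_size=20, max_generations=50, seed=1,
                              max_heavy_atoms=8, n_children=3)
        ranked, history = evolve_loop(["CC", "CCO"], cfg, objective)
        assert len(ranked) >= 1
        for c in ranked:
            assert all(w.contains(p) for p in c.ensemble_predictions)
            assert c.sa_score <= cfg.sa_threshold
            assert featurize(c.smiles).n_heavy <= cfg.max_heavy_atoms

    def test_shrinking_window_never_grows_accepted_set(self):
        truth = SyntheticTruth(noise_sd=0.0, seed=0)
        solvent = get_solvent("ACN")
        models = [_StubModel(truth=truth)]
        mid = 2.6
        wide = TargetWindow(mid - 0.4, mid + 0.4)
        narrow = TargetWindow(mid - 0.1, mid + 0.1)
        cfg = EvolutionConfig(population_size=10, max_generations=10, seed=5,
                              max_heavy_atoms=6)
        obj = lambda w: (lambda g: ensemble_objective(g, models, solvent, w))
        wide_set = {c.smiles for c in evolve_loop(["CCO"], cfg, obj(wide))[0]}
        narrow_set = {c.smiles for c in evolve_loop(["CCO"], cfg, obj(narrow))[0]}
        # fixed predictions per molecule: anything accepted by the narrow
        # window must be acceptable to the wide one
        for smi in narrow_set:
            v = synth_potential(featurize(smi), solvent, truth)[1]
            assert wide.contains(v)
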