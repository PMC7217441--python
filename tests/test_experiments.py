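"""Sweeps, phase diagrams, convergence curves, threshold detection."""

import numpy as np
import pytest

from langshift import (
    CompetitionModel,
    PopulationState,
    SweepSpec,
    bias_sweep,
    convergence_time_sweep,
    detect_threshold,
    get_fixture,
    phase_diagram,
    redistribute_utilities,
    rescale_initials,
    utility_sweep,
)
from langshift.experiments import SweepResult
from langshift.model import StateLabel, SteadyStateResult, find_steady_state


class TestProportionalRules:
    def test_redistribution_formula(self):
        out = redistribute_utilities([0.35, 0.29, 0.36], 0, 0.5)
        assert out[0] == 0.5
        assert out[1] == pytest.approx(0.29 * 0.5 / 0.65)  # 0.223077
        assert out[2] == pytest.approx(0.36 * 0.5 / 0.65)  # 0.276923
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_setting_current_value_is_identity(self):
        base = [0.35, 0.29, 0.36]
        out = redistribute_utilities(base, 1, 0.29)
        assert np.allclose(out, base, atol=1e-15)

    @pytest.mark.parametrize("value", [-0.1, 1.0, 1.5])
    def test_out_of_range_values_rejected(self, value):
        with pytest.raises(ValueError):
            redistribute_utilities([0.5, 0.5], 0, value)

    def test_rescale_initials_same_rule(self):
        out = rescale_initials(PopulationState([0.2, 0.5, 0.3]), 0, 0.6)
        assert np.allclose(out.fractions, [0.6, 0.25, 0.15])

    def test_rescale_identity_and_simplex(self):
        x = PopulationState([0.2, 0.5, 0.3])
        out = rescale_initials(x, 2, 0.3)
        assert np.allclose(out.fractions, x.fractions, atol=1e-15)
        assert abs(out.fractions.sum() - 1.0) <= 1e-12


@pytest.fixture(scope="module")
def sg():
    f = get_fixture("singapore")
    return f.model(), f.initial_state()


class TestUtilitySweep:
    def test_small_english_utility_gives_mandarin_dominance(self, sg):
        model, x0 = sg
        spec = SweepSpec(base_model=model, base_x0=x0, swept="utility",
                         grid=np.array([0.10, 0.20, 0.30]), language="English")
        result = utility_sweep(spec)
        for lbl in result.labels:
            assert lbl.kind == "dominance" and lbl.top_language == "Mandarin"

    def test_large_english_utility_gives_english_dominance(self, sg):
        model, x0 = sg
        spec = SweepSpec(base_model=model, base_x0=x0, swept="utility",
                         grid=np.array([0.40, 0.50]), language="English")
        result = utility_sweep(spec)
        for lbl in result.labels:
            assert lbl.kind == "dominance" and lbl.top_language == "English"

    def test_labels_invariant_under_permuting_unswept_languages(self, sg):
        model, x0 = sg
        grid = np.array([0.1, 0.3, 0.5])
        spec = SweepSpec(base_model=model, base_x0=x0, swept="utility",
                         grid=grid, language="English")
        # Swap Dialect and Mandarin (names travel with their utilities and
        # initial fractions); labels must be identical up to the renaming.
        perm = [0, 2, 1]
        m2 = CompetitionModel([model.names[i] for i in perm],
                              model.utilities[perm], model.alpha, model.beta)
        spec2 = SweepSpec(base_model=m2, base_x0=PopulationState(x0.fractions[perm]),
                          swept="utility", grid=grid, language="English")
        for a, b in zip(utility_sweep(spec).labels, utility_sweep(spec2).labels):
            assert a.kind == b.kind and a.top_language == b.top_language
            assert a.survivors == b.survivors

    def test_wrong_spec_kind_rejected(self, sg):
        model, x0 = sg
        spec = SweepSpec(base_model=model, base_x0=x0, swept="beta",
                         grid=np.array([0.5]))
        with pytest.raises(ValueError, match="utility"):
            utility_sweep(spec)


class TestBiasSweep:
    def test_small_aversion_keeps_mandarin_coexistence(self, sg):
        model, x0 = sg
        spec = SweepSpec(base_model=model, base_x0=x0, swept="aversion",
                         grid=np.array([0.05, 0.10, 0.20]))
        for lbl in bias_sweep(spec).labels:
            assert lbl.kind == "coexistence" and lbl.top_language == "Mandarin"

    def test_beta_sweep_regimes(self, sg):
        # With aversion held at the fitted 0.24: raising beta to 0.80 tips
        # the system into Mandarin dominance, 0.90 into Dialect dominance.
        model, x0 = sg
        spec = SweepSpec(base_model=model, base_x0=x0, swept="beta",
                         grid=np.array([0.80, 0.90]))
        labels = bias_sweep(spec).labels
        assert labels[0].kind == "dominance" and labels[0].top_language == "Mandarin"
        assert labels[1].kind == "dominance" and labels[1].top_language == "Dialect"

    def test_sweep_frame_layout(self, sg):
        model, x0 = sg
        spec = SweepSpec(base_model=model, base_x0=x0, swept="aversion",
                         grid=np.array([0.1, 0.3]))
        df = bias_sweep(spec).to_frame()
        assert list(df.columns[:5]) == ["value", "tau", "converged", "kind", "top"]
        assert len(df) == 2 and {"Xeq_English", "Xeq_Dialect", "Xeq_Mandarin"} <= set(df.columns)


class TestPhaseDiagram:
    def test_cells_match_one_dimensional_sweeps(self, sg):
        model, x0 = sg
        beta_grid = [0.5, 0.8]
        aversion_grid = [0.1, 0.3, 0.5]
        diagram = phase_diagram(model, x0, beta_grid, aversion_grid)
        for i, b in enumerate(beta_grid):
            row_model = model.with_biases(beta=b, aversion=model.aversion)
            spec = SweepSpec(base_model=row_model, base_x0=x0, swept="aversion",
                             grid=np.asarray(aversion_grid))
            for j, lbl in enumerate(bias_sweep(spec).labels):
                assert diagram.kinds[i, j] == lbl.kind
                assert diagram.top_languages[i, j] == lbl.top_language

    def test_high_aversion_hands_dominance_to_largest_initial(self, sg):
        # Above aversion 1.24 the initially largest language (Dialect) is
        # dominant at every majority-preference value.
        model, x0 = sg
        diagram = phase_diagram(model, x0, beta_grid=[0.2, 0.6, 0.9],
                                aversion_grid=[1.3, 1.6])
        assert np.all(diagram.kinds == "dominance")
        assert np.all(diagram.top_languages == "Dialect")

    def test_small_biases_favor_largest_utility(self, sg):
        model, x0 = sg
        diagram = phase_diagram(model, x0, beta_grid=[0.1], aversion_grid=[0.05])
        assert diagram.kinds[0, 0] == "coexistence"
        assert diagram.top_languages[0, 0] == "Mandarin"


class TestConvergenceCurve:
    def test_single_point_grid(self, sg):
        model, x0 = sg
        curve = convergence_time_sweep(model, x0, "Dialect", [0.5])
        assert len(curve.grid) == 1 and curve.peak_location == 0.5

    def test_tau_peaks_at_label_change(self, sg):
        # In a bistable regime (aversion 0.40) the long-run winner flips with
        # the initial Dialect share; critical slowdown puts the tau maximum
        # at or next to the flip.
        model, x0 = sg
        m = model.with_biases(aversion=0.40)
        grid = np.round(np.arange(0.05, 0.951, 0.05), 10)
        curve = convergence_time_sweep(m, x0, "Dialect", grid)
        labels = [(l.kind, l.top_language) for l in curve.labels]
        changes = [k for k in range(len(labels) - 1) if labels[k] != labels[k + 1]]
        assert changes, "expected a state transition along the grid"
        assert min(abs(curve.peak_index - k) for k in changes) <= 1

    def test_tau_smooth_away_from_transition(self, sg):
        model, x0 = sg
        m = model.with_biases(aversion=0.40)
        grid = np.round(np.arange(0.05, 0.951, 0.05), 10)
        curve = convergence_time_sweep(m, x0, "Dialect", grid)
        labels = [(l.kind, l.top_language) for l in curve.labels]
        changes = [k for k in range(len(labels) - 1) if labels[k] != labels[k + 1]]
        peak = curve.taus.max()
        for k in range(len(grid) - 1):
            near_change = min(abs(k - c) for c in changes) <= 1
            if not near_change:
                assert abs(curve.taus[k + 1] - curve.taus[k]) < peak / 10


def _labelled_sweep(sg_model, x0, grid, labels):
    """SweepResult with hand-written labels for threshold-detection tests."""
    results = []
    for kind, top in labels:
        survivors = frozenset([top]) if kind == "dominance" else frozenset([top, "other"])
        eq = PopulationState([0.99, 0.01] if kind == "dominance" else [0.6, 0.4])
        results.append(SteadyStateResult(
            equilibrium=eq, tau=1.0,
            label=StateLabel(kind=kind, top_language=top, survivors=survivors),
            converged=True, model=sg_model))
    spec = SweepSpec(base_model=sg_model, base_x0=x0, swept="beta",
                     grid=np.asarray(grid))
    return SweepResult(spec=spec, results=tuple(results))


class TestDetectThreshold:
    @pytest.fixture
    def two_lang(self):
        m = CompetitionModel(["a", "other"], [0.5, 0.5], 1.0, 0.5)
        return m, PopulationState([0.5, 0.5])

    def test_bracket_of_single_onset(self, two_lang):
        m, x0 = two_lang
        sweep = _labelled_sweep(m, x0, [0.1, 0.2, 0.3, 0.4],
                                [("coexistence", "a"), ("coexistence", "a"),
                                 ("dominance", "a"), ("dominance", "a")])
        report = detect_threshold(sweep, lambda l: l.kind == "dominance")
        assert report.found and report.monotone
        assert (report.last_false, report.first_true) == (0.2, 0.3)

    def test_never_true_reports_no_threshold(self, two_lang):
        m, x0 = two_lang
        sweep = _labelled_sweep(m, x0, [0.1, 0.2],
                                [("coexistence", "a"), ("coexistence", "a")])
        report = detect_threshold(sweep, lambda l: l.is_dominance)
        assert not report.found
        assert report.first_true is None and report.last_false == 0.2

    def test_always_true_reports_no_onset(self, two_lang):
        m, x0 = two_lang
        sweep = _labelled_sweep(m, x0, [0.1, 0.2],
                                [("dominance", "a"), ("dominance", "a")])
        report = detect_threshold(sweep, lambda l: l.is_dominance)
        assert report.last_false is None and report.first_true == 0.1

    def test_multiple_change_points_all_reported(self, two_lang):
        m, x0 = two_lang
        sweep = _labelled_sweep(m, x0, [0.1, 0.2, 0.3, 0.4],
                                [("coexistence", "a"), ("dominance", "a"),
                                 ("coexistence", "a"), ("dominance", "a")])
        report = detect_threshold(sweep, lambda l: l.is_dominance)
        assert not report.monotone
        assert report.change_points == ((0.1, 0.2), (0.2, 0.3), (0.3, 0.4))
        assert (report.last_false, report.first_true) == (0.1, 0.2)


class TestThresholdStability:
    def test_detected_threshold_unchanged_when_dt_halved(self, sg):
        # The English-utility dominance onset on a coarse grid must not move
        # when the integrator step is halved.
        model, x0 = sg
        grid = np.round(np.arange(0.30, 0.461, 0.02), 10)
        spec = SweepSpec(base_model=model, base_x0=x0, swept="utility",
                         grid=grid, language="English")
        pred = lambda l: l.is_dominance and l.top_language == "English"
        r1 = detect_threshold(utility_sweep(spec, dt=1.0), pred)
        r2 = detect_threshold(utility_sweep(spec, dt=0.5), pred)
        assert (r1.last_false, r1.first_true) == (r2.last_false, r2.first_true)
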