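"""FPCA contour decomposition, projection, restyling, reconstruction."""

import numpy as np
import pytest

from soprosody.contours import (
    Contour,
    FPCAModel,
    NormalizedContour,
    ScoreSet,
    fit_fpca,
    hz_to_semitones,
    normalize_time,
    project,
    reconstruct,
    restyle_scores,
)
from soprosody.errors import ContourError, GridError, OrderingError, RankError
from soprosody.specs import OBJECTIVE_SPEC, SUBJECTIVE_SPEC


def make_normalized(values, grid_size=101):
    grid = np.linspace(0, 1, grid_size)
    return NormalizedContour(grid=grid, values=np.asarray(values, float))


class TestContourValidation:
    def test_rejects_single_sample(self):
        with pytest.raises(ContourError):
            Contour(times=[0.0], values=[1.0])

    def test_rejects_nonmonotone_times(self):
        with pytest.raises(OrderingError):
            Contour(times=[0.0, 10.0, 5.0], values=[1.0, 2.0, 3.0])

    def test_rejects_nonfinite_values(self):
        with pytest.raises(ContourError):
            Contour(times=[0.0, 10.0], values=[1.0, np.nan])


class TestNormalizeTime:
    def test_constant_contour_stays_constant(self):
        c = Contour(times=[0, 50, 120], values=[5.0, 5.0, 5.0])
        nc = normalize_time(c, 21)
        assert np.allclose(nc.values, 5.0)

    def test_linear_ramp(self):
        c = Contour(times=[0.0, 100.0], values=[0.0, 10.0])
        nc = normalize_time(c, 11)
        assert np.allclose(nc.values, np.arange(11, dtype=float))

    def test_different_durations_share_grid_length(self):
        # the two condition-typical durations normalize to the same grid
        a = Contour(times=np.linspace(0, 235, 30), values=np.sin(np.arange(30)))
        b = Contour(times=np.linspace(0, 285, 40), values=np.cos(np.arange(40)))
        na, nb = normalize_time(a), normalize_time(b)
        assert na.grid.size == nb.grid.size == 101

    def test_endpoints_preserved_exactly(self):
        c = Contour(times=[3.0, 17.0, 41.0], values=[-2.5, 0.3, 7.25])
        nc = normalize_time(c, 13)
        assert nc.values[0] == -2.5 and nc.values[-1] == 7.25

    def test_small_grid_rejected(self):
        c = Contour(times=[0.0, 1.0], values=[0.0, 1.0])
        with pytest.raises(GridError):
            normalize_time(c, 9)


class TestFitFPCA:
    def test_identical_contours_give_zero_scores(self):
        common = np.sin(np.linspace(0, 1, 101))
        ncs = [make_normalized(common)] * 5
        model, scores = fit_fpca(ncs, n_components=1)
        assert np.allclose(model.mean_curve, common)
        assert all(abs(s.s1) < 1e-12 for s in scores)

    def test_rank_error_on_low_rank_data(self, rng):
        grid = np.linspace(0, 1, 101)
        base = np.sin(np.pi * grid)
        ncs = [make_normalized(s * base) for s in rng.normal(0, 1, 6)]
        with pytest.raises(RankError):
            fit_fpca(ncs, n_components=2)

    def test_single_component_recovery(self, rng):
        # contours built as mu + s*c for one known unit curve c
        grid = np.linspace(0, 1, 101)
        mu = 1.0 - grid
        c = np.sin(np.pi * grid)
        c = c / np.linalg.norm(c)
        s_true = rng.normal(0, 0.8, 30)
        ncs = [make_normalized(mu + s * c) for s in s_true]
        model, scores = fit_fpca(ncs, n_components=1)
        assert np.allclose(model.mean_curve, mu + s_true.mean() * c, atol=1e-12)
        sign = np.sign(model.components[0] @ c)
        assert np.allclose(sign * model.components[0], c, atol=1e-8)
        got = np.array([s.s1 for s in scores])
        centered = s_true - s_true.mean()
        assert np.max(np.abs(sign * got - centered)) < 1e-6 * np.abs(centered).max()

    def test_matches_svd_oracle(self, contour_set):
        _, normalized = contour_set
        model, scores = fit_fpca(normalized, n_components=3)
        X = np.stack([nc.values for nc in normalized])
        Xc = X - X.mean(axis=0)
        _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
        S = np.stack([s.as_array() for s in scores])
        for k in range(3):
            sign = np.sign(vt[k] @ model.components[k])
            assert np.abs(sign * vt[k] - model.components[k]).max() < 1e-8
            oracle_scores = Xc @ (sign * vt[k])
            assert np.abs(oracle_scores - S[:, k]).max() < 1e-8

    def test_orthonormal_components(self, fpca_model):
        model, _ = fpca_model
        gram = model.components @ model.components.T
        assert np.abs(gram - np.eye(3)).max() < 1e-8

    def test_score_variance_nonincreasing(self, fpca_model):
        model, scores = fpca_model
        S = np.stack([s.as_array() for s in scores])
        var = S.var(axis=0)
        assert np.all(np.diff(var) <= 1e-12)
        assert np.allclose(model.score_sds, S.std(axis=0))

    def test_scores_have_zero_mean(self, fpca_model):
        _, scores = fpca_model
        S = np.stack([s.as_array() for s in scores])
        assert np.abs(S.mean(axis=0)).max() < 1e-8

    def test_reconstruction_error_nonincreasing_in_k(self, contour_set):
        _, normalized = contour_set
        errors = []
        for k in (1, 2, 3):
            model, scores = fit_fpca(normalized, n_components=k)
            err = 0.0
            for nc, s in zip(normalized, scores):
                approx = model.mean_curve + s.as_array() @ model.components
                err += float(np.sum((nc.values - approx) ** 2))
            errors.append(err)
        assert errors[0] >= errors[1] >= errors[2]

    def test_mismatched_grids_rejected(self):
        a = make_normalized(np.zeros(101), 101)
        b = NormalizedContour(grid=np.linspace(0, 1, 51), values=np.ones(51))
        with pytest.raises(GridError):
            fit_fpca([a, a, b, a], n_components=1)


class TestProject:
    def test_mean_curve_projects_to_zero(self, fpca_model):
        model, _ = fpca_model
        nc = NormalizedContour(grid=model.grid, values=model.mean_curve)
        s = project(model, nc)
        assert np.abs(s.as_array()).max() < 1e-12

    def test_roundtrip_identity_on_scores(self, fpca_model, rng):
        model, _ = fpca_model
        for _ in range(10):
            s = ScoreSet(*rng.normal(0, 1, 3))
            rec = reconstruct(model, s, duration_ms=500.0, step_ms=5.0)
            # re-normalize onto the model grid and project back
            nc = NormalizedContour(
                grid=model.grid,
                values=np.interp(model.grid, rec.times / 500.0, rec.values))
            back = project(model, nc)
            # interpolation between the 5-ms lattice and the grid is lossy;
            # projecting the exact grid curve is not
            exact = NormalizedContour(
                grid=model.grid,
                values=model.mean_curve + s.as_array() @ model.components)
            assert np.abs(project(model, exact).as_array() - s.as_array()).max() < 1e-8
            assert np.abs(back.as_array() - s.as_array()).max() < 0.05

    def test_matches_least_squares_oracle(self, fpca_model, contour_set):
        model, _ = fpca_model
        _, normalized = contour_set
        nc = normalized[7]
        lsq, *_ = np.linalg.lstsq(model.components.T,
                                  nc.values - model.mean_curve, rcond=None)
        assert np.abs(project(model, nc).as_array() - lsq).max() < 1e-8

    def test_grid_mismatch_rejected(self, fpca_model):
        model, _ = fpca_model
        nc = NormalizedContour(grid=np.linspace(0, 1, 51), values=np.zeros(51))
        with pytest.raises(GridError):
            project(model, nc)


class TestRestyle:
    @pytest.mark.parametrize(
        "scores, condition, expected",
        [
            (ScoreSet(0.2, 1.1, 0.4), "subjective", (0.2, +0.335, -0.065)),
            (ScoreSet(-0.7, 0.0, 0.0), "objective", (-0.7, -0.515, +0.025)),
        ],
    )
    def test_condition_targets(self, scores, condition, expected):
        got = restyle_scores(scores, condition)
        assert got.as_array() == pytest.approx(expected, abs=0)

    def test_idempotent(self):
        s = ScoreSet(0.3, -2.0, 5.0)
        once = restyle_scores(s, "subjective")
        assert restyle_scores(once, "subjective") == once

    def test_unknown_condition(self):
        from soprosody.errors import ConditionError
        with pytest.raises(ConditionError):
            restyle_scores(ScoreSet(0, 0, 0), "neutral")

    def test_condition_contrast_conserved(self):
        # subjective-minus-objective target differences, exactly
        assert SUBJECTIVE_SPEC.s2_target - OBJECTIVE_SPEC.s2_target == pytest.approx(+0.85, abs=1e-12)
        assert SUBJECTIVE_SPEC.s3_target - OBJECTIVE_SPEC.s3_target == pytest.approx(-0.09, abs=1e-12)
        d_dur = SUBJECTIVE_SPEC.target_duration_ms - OBJECTIVE_SPEC.target_duration_ms
        assert d_dur == 50.0


class TestReconstruct:
    def test_zero_scores_give_mean_curve(self, fpca_model):
        model, _ = fpca_model
        rec = reconstruct(model, ScoreSet(0.0, 0.0, 0.0), duration_ms=500.0)
        expected = np.interp(rec.times / 500.0, model.grid, model.mean_curve)
        assert np.allclose(rec.values, expected)

    def test_sample_count_285ms_at_5ms(self, fpca_model):
        model, _ = fpca_model
        rec = reconstruct(model, ScoreSet(0, 0, 0), duration_ms=285.0, step_ms=5.0)
        assert rec.times.size == 58
        assert rec.times[0] == 0.0 and rec.times[-1] == 285.0

    def test_indivisible_duration_has_no_terminal_point(self, fpca_model):
        model, _ = fpca_model
        rec = reconstruct(model, ScoreSet(0, 0, 0), duration_ms=283.0, step_ms=5.0)
        assert rec.times[-1] == 280.0

    def test_subjective_restyle_bulges_at_midspan(self):
        # model with a concave-positive FPC2: the subjective-minus-objective
        # reconstruction difference peaks mid-span (delta s2 = +0.85)
        grid = np.linspace(0, 1, 101)
        c1 = np.ones_like(grid) / np.sqrt(grid.size)
        c2 = np.sin(np.pi * grid)
        c2 = (c2 - c2 @ c1 * c1)
        c2 /= np.linalg.norm(c2)
        c3 = np.sin(2 * np.pi * grid)
        c3 /= np.linalg.norm(c3)
        model = FPCAModel(grid=grid, mean_curve=np.zeros_like(grid),
                          components=np.stack([c1, c2, c3]),
                          score_sds=np.array([1.0, 0.5, 0.25]))
        base = ScoreSet(0.4, 0.0, 0.0)
        sub = reconstruct(model, restyle_scores(base, "subjective"), 280.0)
        obj = reconstruct(model, restyle_scores(base, "objective"), 280.0)
        diff = sub.values - obj.values
        mid = diff[diff.size // 2]
        assert mid > diff[0] and mid > diff[-1]

    def test_invalid_arguments(self, fpca_model):
        model, _ = fpca_model
        with pytest.raises(ValueError):
            reconstruct(model, ScoreSet(0, 0, 0), duration_ms=-1.0)
        with pytest.raises(RankError):
            reconstruct(model, ScoreSet(0.0), duration_ms=100.0)


def test_hz_to_semitones_octave_and_median_reference():
    st = hz_to_semitones(np.array([100.0, 200.0, 400.0]), reference_hz=100.0)
    assert np.allclose(st, [0.0, 12.0, 24.0])
    st_med = hz_to_semitones(np.array([100.0, 200.0, 400.0]))
    assert st_med[1] == 0.0  # median reference
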