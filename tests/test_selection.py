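"""Leave-one-patient-out CV, GCV/AIC arithmetic, and LR tests."""

import numpy as np
import pandas as pd
import pytest

from dtgam.data_model import PersonPeriodTable
from dtgam.datasets import pbc_model_comparison
from dtgam.pgam import DiscreteHazardGAM, fit_pgam
from dtgam.selection import (
    aic,
    gcv_score,
    grid_search_cv,
    lr_test,
    term_pvalues,
    variant_cv,
)
from dtgam.splines import LinearTermSpec, SmoothTermSpec


def make_table(sids, x, y, frame_extra=None):
    """Single-row-per-visit person-period table from plain arrays."""
    n = len(sids)
    frame = pd.DataFrame(
        {
            "subject_id": [str(s) for s in sids],
            "interval": 1,
            "t_start": 0.0,
            "t_end": 100.0,
            "midpoint": 50.0,
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=int),
        }
    )
    # subjects with repeated ids get consecutive interval indices
    frame["interval"] = frame.groupby("subject_id").cumcount() + 1
    if frame_extra:
        for k, v in frame_extra.items():
            frame[k] = v
    return PersonPeriodTable(frame=frame, covariate_names=["x"])


def loo_oracle(Z, y, groups):
    """Hand-rolled refit-and-predict leave-one-group-out loop."""
    total = 0.0
    for rows in groups:
        mask = np.ones(len(y), dtype=bool)
        mask[rows] = False
        fold = fit_pgam(Z[mask], y[mask])
        eta = Z[rows] @ fold.beta
        total += float(np.sum(y[rows] * eta - np.logaddexp(0.0, eta)))
    return -2.0 * total


class TestVariantCV:
    def test_singleton_subjects_equal_ordinary_loo(self, rng):
        """With one row per subject the variant CV is ordinary LOO."""
        n = 50
        x = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(x - 0.5))))
        table = make_table(range(n), x, y)
        model = DiscreteHazardGAM([LinearTermSpec("x")])
        score = variant_cv(model, table)
        design = model.build(table)
        oracle = loo_oracle(design.Z, y.astype(float), [[i] for i in range(n)])
        assert score == pytest.approx(oracle, abs=1e-10)

    def test_three_subject_intercept_only_oracle(self):
        table = make_table([1, 1, 2, 2, 3], [0.0] * 5, [0, 1, 0, 0, 1])
        model = DiscreteHazardGAM([])
        score = variant_cv(model, table)
        y = table.frame["y"].to_numpy(dtype=float)
        Z = np.ones((5, 1))
        oracle = loo_oracle(Z, y, [[0, 1], [2, 3], [4]])
        assert score == pytest.approx(oracle, abs=1e-8)

    def test_duplicated_subjects_contribute_equally(self, rng):
        x = rng.normal(size=6)
        y = [0, 1, 0, 1, 0, 0]
        table = make_table(["a", "b", "c", "a2", "b2", "c2"], np.tile(x[:3], 2), y[:3] * 2)
        model = DiscreteHazardGAM([LinearTermSpec("x")])
        from dtgam.selection import _held_out_logliks

        contribs = _held_out_logliks(model, table, {})
        for sid in ("a", "b", "c"):
            assert contribs[sid] == pytest.approx(contribs[sid + "2"], abs=1e-9)

    def test_needs_two_subjects(self):
        table = make_table([1, 1], [0.0, 1.0], [0, 1])
        with pytest.raises(ValueError, match="two subjects"):
            variant_cv(DiscreteHazardGAM([]), table)


class TestGridSearch:
    def test_grid_of_size_one(self, small_table):
        model = DiscreteHazardGAM(
            [LinearTermSpec("age"), SmoothTermSpec("bili", n_interior=4)]
        )
        res = grid_search_cv(model, small_table, {"bili": [0.5]})
        assert res.best_lambdas["bili"] == 0.5
        assert res.best_score == pytest.approx(res.scores[0])
        assert res.best_score == pytest.approx(
            -2.0 * sum(res.contributions.values())
        )

    def test_optimum_attains_grid_minimum(self, small_table):
        model = DiscreteHazardGAM([SmoothTermSpec("bili", n_interior=4)])
        res = grid_search_cv(model, small_table, {"bili": [1e-3, 1.0, 1e3]})
        assert res.best_score == pytest.approx(res.scores.min())
        assert all(res.best_score <= s + 1e-12 for s in res.scores)

    def test_empty_grid_rejected(self, small_table):
        model = DiscreteHazardGAM([SmoothTermSpec("bili")])
        with pytest.raises(ValueError, match="empty"):
            grid_search_cv(model, small_table, {"bili": []})

    def test_linear_truth_selects_large_lambda(self, rng):
        """A linear true effect drives the selected lambda to the smooth end."""
        from dtgam.synthetic import SimulationConfig, simulate_cohort
        from dtgam.data_model import expand_person_period

        cfg = SimulationConfig(
            n_subjects=120,
            f_bili=lambda b: 0.25 * (b - 3.0),  # linear truth
            transplant_threshold=None,
        )
        subjects, _ = simulate_cohort(cfg, seed=7)
        table = expand_person_period(subjects)
        model = DiscreteHazardGAM(
            [LinearTermSpec("age"), SmoothTermSpec("bili", n_interior=6)]
        )
        grid = [1e-4, 1e-1, 1e2, 1e5]
        res = grid_search_cv(model, table, {"bili": grid})
        assert res.best_lambdas["bili"] >= grid[-2]


class TestCriteria:
    def test_gcv_arithmetic(self, small_table):
        model = DiscreteHazardGAM([LinearTermSpec("age")])
        fit = model.fit(small_table)
        expected = fit.n_rows * fit.deviance / (fit.n_rows - fit.edf) ** 2
        assert gcv_score(fit) == pytest.approx(expected, rel=1e-12)

    def test_aic_is_dev_plus_twice_edf(self, small_table):
        model = DiscreteHazardGAM([LinearTermSpec("age")])
        fit = model.fit(small_table)
        assert aic(fit) == pytest.approx(fit.deviance + 2 * fit.edf, rel=1e-12)

    def test_published_model_table_aic_arithmetic(self):
        """Dev + 2*(N - residual df) reconstructs the published AIC column."""
        ref = pbc_model_comparison()
        N = 1945
        for _, row in ref.iterrows():
            recon = row["deviance"] + 2 * (N - row["residual_df"])
            assert recon == pytest.approx(row["aic"], abs=0.02)


class TestLRTest:
    def test_identical_models_give_null_result(self, small_table):
        model = DiscreteHazardGAM([LinearTermSpec("age")])
        f1, f2 = model.fit(small_table), model.fit(small_table)
        delta, df, p = lr_test(f1, f2)
        assert delta == pytest.approx(0.0, abs=1e-9)
        assert p == 1.0

    def test_published_bilirubin_delta(self):
        """The spline-vs-linear deviance gap matches the published tables."""
        ref = pbc_model_comparison()
        delta = ref.loc["V", "deviance"] - ref.loc["IV", "deviance"]
        assert delta == pytest.approx(22.97, abs=0.02)

    def test_non_nested_larger_full_deviance_rejected(self, small_table):
        m1 = DiscreteHazardGAM([LinearTermSpec("age"), LinearTermSpec("bili")])
        m0 = DiscreteHazardGAM([LinearTermSpec("age")])
        full, nested = m1.fit(small_table), m0.fit(small_table)
        with pytest.raises(ValueError, match="not nested"):
            lr_test(full, nested)  # swapped on purpose


class TestTermPvalues:
    def test_pvalues_in_unit_interval(self, small_table):
        model = DiscreteHazardGAM(
            [LinearTermSpec("age"), SmoothTermSpec("bili", n_interior=5)],
            {"bili": 1.0},
        )
        ps = term_pvalues(model.fit(small_table))
        assert set(ps) == {"age", "bili"}
        assert all(0.0 <= p <= 1.0 for p in ps.values())

    def test_strong_simulated_effect_is_significant(self):
        """Bilirubin drives the synthetic hazard, so its p-value is tiny."""
        from dtgam.data_model import expand_person_period
        from dtgam.synthetic import SimulationConfig, simulate_cohort

        subjects, _ = simulate_cohort(SimulationConfig(n_subjects=200), seed=3)
        table = expand_person_period(subjects)
        model = DiscreteHazardGAM(
            [LinearTermSpec("age"), SmoothTermSpec("bili", n_interior=5)],
            {"bili": 1.0},
        )
        ps = term_pvalues(model.fit(table))
        assert ps["bili"] < 1e-3
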