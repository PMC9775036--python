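"""Concordance, IPCW Brier score and the cross-validation harness."""

import numpy as np
import pytest

from dfsc import (
    GeneratorConfig,
    LassoCoxSpec,
    brier_score,
    concordance_index,
    cross_validate,
    compare_models,
    generate,
    integrated_brier,
)
from dfsc.evaluation import default_time_grid
from conftest import make_dataset, random_censored


def brute_force_cindex(time, event, risk):
    """O(n^2) pair-enumeration oracle."""
    conc = ties = comp = 0
    n = len(time)
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if time[i] < time[j]:
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    ties += 1
    return (conc + 0.5 * ties) / comp


class TestConcordance:
    def test_perfect_ranking(self):
        t = np.array([1.0, 2.0, 3.0])
        assert concordance_index(t, [1, 1, 1], [3.0, 2.0, 1.0]) == 1.0

    def test_all_tied_risks(self):
        assert concordance_index([1, 2, 3], [1, 1, 1], [5.0, 5.0, 5.0]) == 0.5

    def test_hand_enumerated_censored_case(self):
        # comparable pairs are (1,2) and (1,3); only (1,2) is concordant
        assert concordance_index([2, 4, 5], [1, 0, 1], [0.5, 0.2, 0.9]) == 0.5

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 60))
            t, e, r = random_censored(rng, n, with_ties=True)
            try:
                expected = brute_force_cindex(t, e, r)
            except ZeroDivisionError:
                continue
            assert concordance_index(t, e, r) == pytest.approx(expected, abs=1e-12)

    def test_flip_symmetry_without_ties(self, rng):
        t, e, r = random_censored(rng, 50)
        assert concordance_index(t, e, r) + concordance_index(t, e, -r) == pytest.approx(1.0)

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1, 2], [0, 0], [0.1, 0.2])

    def test_permutation_invariance(self, rng):
        t, e, r = random_censored(rng, 40)
        perm = rng.permutation(40)
        assert concordance_index(t, e, r) == pytest.approx(
            concordance_index(t[perm], e[perm], r[perm]), abs=1e-12
        )


class TestBrier:
    def test_perfect_predictions_no_censoring(self):
        t = np.array([1.0, 2.0, 5.0, 6.0])
        e = np.ones(4, dtype=int)
        S = np.array([0.0, 0.0, 1.0, 1.0])  # died before t=3 vs survived
        assert brier_score(t, e, S, 3.0) == pytest.approx(0.0)

    def test_constant_half_no_censoring(self):
        t = np.array([1.0, 2.0, 5.0, 6.0])
        assert brier_score(t, np.ones(4, int), np.full(4, 0.5), 3.0) == pytest.approx(0.25)

    def test_hand_computed_ipcw_weights(self):
        # times (2,3,5,7), events (1,0,1,1), horizon t=4.
        # Censoring KM: one censoring event at 3 with 3 at risk -> G(3)=2/3.
        # Weights: subject 1 died at 2 -> 1/G(2-)=1; subject 2 zero weight;
        # subjects 3,4 alive past 4 -> 1/G(4)=3/2.
        # Score = [1*(0-0.3)^2 + 1.5*(1-0.8)^2 + 1.5*(1-0.9)^2]/4 = 0.04125
        t = np.array([2.0, 3.0, 5.0, 7.0])
        e = np.array([1, 0, 1, 1])
        S = np.array([0.3, 0.4, 0.8, 0.9])
        assert brier_score(t, e, S, 4.0) == pytest.approx(0.04125, abs=1e-12)

    def test_reduces_to_mse_without_censoring(self, rng):
        n = 50
        t = rng.exponential(1, n)
        e = np.ones(n, int)
        S = rng.uniform(size=n)
        tau = float(np.quantile(t, 0.5))
        status = (t > tau).astype(float)
        assert brier_score(t, e, S, tau) == pytest.approx(
            float(np.mean((status - S) ** 2)), abs=1e-12
        )

    def test_matches_reference_implementation(self, rng):
        from sksurv.metrics import brier_score as sk_brier
        from sksurv.util import Surv

        for _ in range(10):
            n = 60
            t = rng.exponential(1, n) + rng.uniform(0, 1e-9, n)
            e = rng.integers(0, 2, n)
            if e.sum() < 5:
                continue
            S = rng.uniform(0.1, 0.9, n)
            tau = float(np.quantile(t[e == 1], 0.5))
            y = Surv.from_arrays(e.astype(bool), t)
            _, expected = sk_brier(y, y, S.reshape(-1, 1), [tau])
            assert brier_score(t, e, S, tau) == pytest.approx(expected[0], abs=1e-9)

    def test_unestimable_horizon_rejected(self):
        from dfsc.evaluation import _censoring_km

        # censoring distribution estimated on fully censored training data
        # hits 0, so weights past that point are undefined
        km = _censoring_km(np.array([1.0, 2.0]), np.array([0, 0]))
        t = np.array([1.0, 4.0, 5.0])
        e = np.array([1, 1, 1])
        with pytest.raises(ValueError, match="horizon"):
            brier_score(t, e, np.full(3, 0.5), 3.0, censor_km=km)


class TestIntegratedBrier:
    def test_perfect_is_zero(self):
        t = np.array([1.0, 2.0, 5.0, 6.0])
        e = np.ones(4, int)
        grid = np.array([1.5, 3.0, 4.0])
        curves = np.array([[float(ti > g) for g in grid] for ti in t])
        assert integrated_brier(t, e, curves, grid) == pytest.approx(0.0)

    def test_constant_half_is_quarter(self):
        t = np.array([1.0, 2.0, 5.0, 6.0])
        e = np.ones(4, int)
        grid = np.array([1.5, 3.0])
        assert integrated_brier(t, e, np.full((4, 2), 0.5), grid) == pytest.approx(0.25)

    def test_two_point_grid_is_mean_of_pointwise(self, rng):
        n = 40
        t = rng.exponential(1, n)
        e = np.ones(n, int)
        grid = np.array([0.3, 0.9])
        curves = rng.uniform(0.2, 0.8, (n, 2))
        pointwise = [brier_score(t, e, curves[:, k], g) for k, g in enumerate(grid)]
        assert integrated_brier(t, e, curves, grid) == pytest.approx(
            float(np.mean(pointwise)), abs=1e-12
        )

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            integrated_brier(np.ones(3), np.ones(3, int), np.ones((3, 0)), np.array([]))


def _small_signal_dataset(seed=0, n=120, p=15):
    data, _ = generate(GeneratorConfig(n_samples=n, n_genes=p, n_causal=3,
                                       correlation_block_size=1, test_fraction=0.1,
                                       random_seed=seed))
    return data.labeled()


class TestCrossValidation:
    def test_folds_partition_and_reproducibility(self):
        ds = _small_signal_dataset()
        rep1 = cross_validate(ds, LassoCoxSpec(), k=4, seed=3)
        rep2 = cross_validate(ds, LassoCoxSpec(), k=4, seed=3)
        assert rep1.rows["cindex"].tolist() == rep2.rows["cindex"].tolist()
        assert len(rep1.rows) == 4

    def test_leave_one_out_runs_on_tiny_data(self):
        ds = _small_signal_dataset(n=30, p=5)
        rep = cross_validate(ds, LassoCoxSpec(), k=ds.n_samples, seed=0)
        assert len(rep.rows) == ds.n_samples

    def test_compare_models_same_spec_identical_rows(self):
        ds = _small_signal_dataset(seed=1)
        a, b = LassoCoxSpec(), LassoCoxSpec(name="lasso-cox-2")
        rep = compare_models(ds, [a, b], k=3, seed=5)
        pa = rep.rows[rep.rows.model == "lasso-cox"]["cindex"].to_numpy()
        pb = rep.rows[rep.rows.model == "lasso-cox-2"]["cindex"].to_numpy()
        np.testing.assert_allclose(pa, pb)

    def test_default_grid_needs_events(self):
        with pytest.raises(ValueError):
            default_time_grid(np.array([1.0, 2.0]), np.array([0, 0]))
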