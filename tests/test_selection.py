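import json
from itertools import combinations

import numpy as np
import pytest

from speclai.exceptions import ChainingError, ParameterError
from speclai.selection import (
    SelectionResult,
    _spa_chain,
    cars_select,
    cars_spa_select,
    edf_count,
    edf_ratio,
    spa_select,
)


def _orthogonal_design(n=32, p=6, norms=None, seed=0):
    """Columns of exactly zero mutual inner product with chosen norms."""
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(n, n))
    Q, _ = np.linalg.qr(M)
    norms = np.asarray(norms if norms is not None else np.linspace(2.0, 1.0, p))
    return Q[:, :p] * norms


class TestSPA:
    def test_orthogonal_columns_chain_from_informative_start(self):
        # y built from columns 2 and 5 (1-based); column 5 has the largest
        # norm among the rest, so the chain from 2 adds it first
        norms = [1.0, 1.2, 0.9, 0.8, 1.8, 0.7]
        X = _orthogonal_design(p=6, norms=norms)
        y = 2.0 * X[:, 1] + 1.5 * X[:, 4]
        chain = _spa_chain(X, start=1, k_max=2)
        assert chain == [1, 4]
        res = spa_select(X, y, k_min=2, k_max=2, seed=0)
        assert res.selected_indices == [2, 5]

    def test_k1_is_exhaustive_best_single_column(self, rng):
        X = rng.normal(size=(40, 7))
        y = X[:, 3] + rng.normal(0, 0.1, 40)
        res = spa_select(X, y, k_min=1, k_max=1, seed=11)
        # oracle: score every single column on the same split
        perm = np.random.default_rng(11).permutation(40)
        n_val = int(round(0.3 * 40))
        val, cal = perm[:n_val], perm[n_val:]
        def score(j):
            A = np.column_stack([np.ones(len(cal)), X[cal][:, [j]]])
            c = np.linalg.lstsq(A, y[cal], rcond=None)[0]
            pred = np.column_stack([np.ones(len(val)), X[val][:, [j]]]) @ c
            return np.sqrt(np.mean((pred - y[val]) ** 2))
        best = min(range(7), key=score)
        assert res.selected_indices == [best + 1]

    def test_duplicate_column_never_joins_chain(self, rng):
        X = rng.normal(size=(30, 5))
        X[:, 4] = X[:, 1]  # exact duplicate
        for start in range(5):
            chain = _spa_chain(X, start, 5)
            assert not ({1, 4} <= set(chain))

    def test_oracle_equivalence_on_chain_reachable_instances(self):
        # orthogonal designs whose best subset consists of top-norm columns
        # (then the optimum is in SPA's candidate family) - brute force over
        # all subsets with p <= 8, k_max <= 3 must agree
        for seed in range(4):
            rng = np.random.default_rng(seed)
            norms = np.sort(rng.uniform(0.5, 2.0, 7))[::-1]
            X = _orthogonal_design(n=40, p=7, norms=norms, seed=seed)
            y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + rng.normal(0, 0.05, 40)
            res = spa_select(X, y, k_min=2, k_max=3, seed=seed)

            perm = np.random.default_rng(seed).permutation(40)
            n_val = int(round(0.3 * 40))
            val, cal = perm[:n_val], perm[n_val:]

            def score(cols):
                A = np.column_stack([np.ones(len(cal)), X[np.ix_(cal, cols)]])
                c = np.linalg.lstsq(A, y[cal], rcond=None)[0]
                pred = np.column_stack([np.ones(len(val)), X[np.ix_(val, cols)]]) @ c
                return np.sqrt(np.mean((pred - y[val]) ** 2))

            brute = min(
                (list(c) for k in (2, 3) for c in combinations(range(7), k)), key=score
            )
            assert res.selected_indices == [c + 1 for c in sorted(brute)]
            assert res.score == pytest.approx(score(brute))

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 8))
        y = X[:, 2] - X[:, 6] + rng.normal(0, 0.1, 30)
        a = spa_select(X, y, k_min=2, k_max=4, seed=3)
        b = spa_select(X, y, k_min=2, k_max=4, seed=3)
        assert a.selected_indices == b.selected_indices and a.score == b.score

    def test_kmin_greater_than_kmax(self, rng):
        X = rng.normal(size=(20, 5))
        with pytest.raises(ParameterError):
            spa_select(X, X[:, 0], k_min=4, k_max=2)

    def test_trace_has_rmse_by_k(self, rng):
        X = rng.normal(size=(30, 6))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        res = spa_select(X, y, k_min=2, k_max=4, seed=0)
        assert set(res.trace["rmse_by_k"]) == {2, 3, 4}


class TestCARS:
    @pytest.mark.parametrize("p,n_runs", [(94, 50), (20, 10), (500, 7), (3, 2), (1000, 100)])
    def test_edf_endpoint_identities(self, p, n_runs):
        assert edf_count(1, p, n_runs) == p
        assert edf_count(n_runs, p, n_runs) == 2
        assert edf_ratio(1, p, n_runs) * p == pytest.approx(p)

    @pytest.mark.parametrize("p,n_runs", [(94, 50), (37, 13)])
    def test_edf_schedule_monotone(self, p, n_runs):
        counts = [edf_count(i, p, n_runs) for i in range(1, n_runs + 1)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_retained_count_trace_monotone(self, rng):
        X = rng.normal(size=(60, 30))
        y = X[:, 3] - X[:, 17] + rng.normal(0, 0.2, 60)
        res = cars_select(X, y, seed=1)
        counts = res.trace["retained_count"]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] == 30  # r_1 covers all variables

    def test_informative_columns_recovered(self):
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 60))
            beta = np.zeros(60)
            beta[[3, 17, 29, 41, 55]] = [3, -2.5, 2, 3.5, -3]
            y = X @ beta + rng.normal(0, 0.3, 100)
            got = set(np.array(cars_select(X, y, seed=seed).selected_indices) - 1)
            hits += {3, 17, 29, 41, 55} <= got
        assert hits == 3

    def test_deterministic(self, rng):
        X = rng.normal(size=(50, 20))
        y = X[:, 5] + rng.normal(0, 0.2, 50)
        a = cars_select(X, y, seed=9)
        b = cars_select(X, y, seed=9)
        assert a.selected_indices == b.selected_indices and a.score == b.score

    def test_parameter_validation(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ParameterError):
            cars_select(X, X[:, 0])  # p < 3
        X = rng.normal(size=(20, 5))
        with pytest.raises(ParameterError):
            cars_select(X, X[:, 0], n_runs=1)


class TestCARSSPA:
    def test_cars_stage_matches_direct_call(self, rng):
        X = rng.normal(size=(60, 20))
        y = X[:, 2] + 0.5 * X[:, 11] - X[:, 17] + rng.normal(0, 0.2, 60)
        chained = cars_spa_select(
            X, y, spa_params={"k_min": 5, "k_max": 10, "seed": 4},
            cars_params={"seed": 4, "n_runs": 20},
        )
        spa_cols = [i - 1 for i in chained.trace["spa"]["selected_indices"]]
        direct = cars_select(X[:, spa_cols], y, seed=4, n_runs=20)
        mapped = sorted(spa_cols[j - 1] + 1 for j in direct.selected_indices)
        assert chained.selected_indices == mapped
        assert chained.score == pytest.approx(direct.score)

    def test_subset_of_spa_selection(self, rng):
        X = rng.normal(size=(60, 20))
        y = X[:, 2] - X[:, 17] + rng.normal(0, 0.2, 60)
        chained = cars_spa_select(
            X, y, spa_params={"k_min": 5, "k_max": 10, "seed": 1},
            cars_params={"seed": 1, "n_runs": 20},
        )
        assert set(chained.selected_indices) <= set(chained.trace["spa"]["selected_indices"])
        assert chained.method == "CARS_SPA"

    def test_chaining_error_when_spa_too_small(self, rng):
        X = rng.normal(size=(40, 8))
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        with pytest.raises(ChainingError):
            cars_spa_select(X, y, spa_params={"k_min": 1, "k_max": 2, "seed": 0})


@pytest.mark.slow
class TestSubsetsNeverWorseThanIntercept:
    def test_calibration_rmse_beats_intercept_baseline(self, trimmed):
        from speclai.evaluation import rmse as rmse_fn
        from speclai.evaluation import split_by_area
        from speclai.models import ModelSpec, fit_model

        cal, _ = split_by_area(trimmed)
        ids = cal.metadata["sample_id"].to_numpy()
        baseline = rmse_fn(cal.lai, np.full_like(cal.lai, cal.lai.mean()))
        res = cars_select(cal.reflectance, cal.lai, n_runs=15, seed=7)
        cols = [i - 1 for i in res.selected_indices]
        specs = {
            "PLSR": None,
            "SVR": None,
            "GBT": ModelSpec("GBT", {"n_estimators": [50], "max_depth": [2]}),
        }
        for method, spec in specs.items():
            model = fit_model(method, cal.reflectance[:, cols], cal.lai,
                              spec=spec, sample_ids=ids)
            fit_rmse = rmse_fn(cal.lai, model.predict(cal.reflectance[:, cols]))
            assert fit_rmse <= baseline


class TestSelectionResult:
    def test_indices_must_be_increasing_unique(self):
        with pytest.raises(Exception):
            SelectionResult("SPA", [3, 2])
        with pytest.raises(Exception):
            SelectionResult("SPA", [2, 2])

    def test_json_serialization(self, rng):
        X = rng.normal(size=(30, 6))
        y = X[:, 1] + rng.normal(0, 0.1, 30)
        res = spa_select(X, y, wavelengths=np.arange(458.0, 458 + 24, 4.0), k_min=2, k_max=3)
        data = json.loads(res.to_json())
        assert data["method"] == "SPA"
        assert data["selected_indices"] == res.selected_indices
        assert len(data["selected_wavelengths"]) == res.n_selected

    def test_trace_frames(self, rng):
        X = rng.normal(size=(40, 10))
        y = X[:, 2] + rng.normal(0, 0.2, 40)
        spa_frame = spa_select(X, y, k_min=2, k_max=4, seed=0).trace_frame()
        assert list(spa_frame.columns) == ["n_bands", "rmse"]
        cars_frame = cars_select(X, y, n_runs=10, seed=0).trace_frame()
        assert "rmsecv" in cars_frame.columns and len(cars_frame) == 10
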