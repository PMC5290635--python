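"""Gaussian-mixture clone clustering, BIC model selection, fate classification."""

import subprocess

import numpy as np
import pytest

from longevol.evolution import (
    DegenerateFitError,
    classify_clusters,
    classify_trajectory,
    fit_mixture,
    select_model,
)


def _two_blob_data(rng, n=200, sep=5.0, sd=0.05, d=3):
    a = rng.normal(0.2, sd, size=(n, d))
    b = rng.normal(0.2 + sep * sd, sd, size=(n, d))
    X = np.vstack([a, b])
    labels = np.array([0] * n + [1] * n)
    return X, labels


class TestFitMixture:
    def test_single_tight_component(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0.5, 0.01, size=(100, 3))
        fit = fit_mixture(X, k=1, family="spherical", seed=0)
        assert fit.k == 1 and fit.weights[0] == pytest.approx(1.0)
        assert np.allclose(fit.means[0], 0.5, atol=0.01)

    @pytest.mark.parametrize("family", ["spherical", "diagonal", "full"])
    def test_two_separated_components_recovered(self, family):
        X, labels = _two_blob_data(np.random.default_rng(1))
        fit = fit_mixture(X, k=2, family=family, seed=1)
        hard = fit.assignments
        acc = max(np.mean(hard == labels), np.mean(hard == 1 - labels))
        assert acc >= 0.99

    def test_more_components_than_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture(np.zeros((3, 2)) + np.arange(3)[:, None], k=5)

    def test_identical_rows_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_mixture(np.ones((50, 3)), k=2)

    def test_loglik_nondecreasing_over_iterations(self):
        X, _ = _two_blob_data(np.random.default_rng(2), sep=2.0)
        fit = fit_mixture(X, k=2, family="full", seed=2, n_restarts=1)
        traj = np.array(fit.loglik_trajectory)
        assert np.all(np.diff(traj) >= -1e-7 * np.abs(traj[:-1]))

    def test_nested_families_loglik_ordering(self):
        X, _ = _two_blob_data(np.random.default_rng(3))
        lls = {
            fam: fit_mixture(X, k=2, family=fam, seed=3).loglik
            for fam in ("spherical", "diagonal", "full")
        }
        assert lls["full"] >= lls["diagonal"] - 1e-6
        assert lls["diagonal"] >= lls["spherical"] - 1e-6

    def test_responsibilities_rows_sum_to_one(self):
        X, _ = _two_blob_data(np.random.default_rng(4))
        fit = fit_mixture(X, k=2, seed=4)
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(fit.assignments == fit.responsibilities.argmax(axis=1))

    def test_deterministic_given_seed(self):
        X, _ = _two_blob_data(np.random.default_rng(5))
        f1 = fit_mixture(X, k=2, seed=42)
        f2 = fit_mixture(X, k=2, seed=42)
        assert np.array_equal(f1.means, f2.means) and f1.loglik == f2.loglik

    def test_bic_definition(self):
        X, _ = _two_blob_data(np.random.default_rng(6))
        fit = fit_mixture(X, k=2, family="diagonal", seed=6)
        assert fit.bic == pytest.approx(fit.n_params * np.log(len(X)) - 2 * fit.loglik)
        assert fit.n_params == 2 * 3 + 1 + 2 * 3  # means + weights + diag covs


class TestSelectModel:
    def test_two_components_selected(self):
        X, _ = _two_blob_data(np.random.default_rng(7))
        fit = select_model(X, k_max=6, seed=7)
        assert fit.k == 2

    def test_unimodal_data_selects_single_component(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0.5, 0.05, size=(100, 3))
        assert select_model(X, k_max=3, seed=8).k == 1

    def test_kmax_one_is_identity(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, size=(30, 2))
        fit = select_model(X, k_max=1, families=("full",), seed=9)
        ref = fit_mixture(X, k=1, family="full", seed=9)
        assert fit.k == 1 and fit.loglik == pytest.approx(ref.loglik)

    def test_degenerate_combinations_skipped(self):
        # identical rows: k>1 degenerate everywhere, but k=1 still fits
        fit = select_model(np.ones((20, 2)), k_max=3, seed=0)
        assert fit.k == 1


def test_selected_k_agrees_with_mclust(tmp_path):
    """Independent cross-check: model-based clustering in R (Mclust) selects
    the same number of components on a well-separated two-blob dataset."""
    X, _ = _two_blob_data(np.random.default_rng(12), n=100)
    csv = tmp_path / "x.csv"
    np.savetxt(csv, X, delimiter=",")
    script = (
        "suppressMessages(library(mclust));"
        f"x <- read.csv('{csv}', header=FALSE);"
        "m <- Mclust(x, G=1:6, verbose=FALSE);"
        "cat(m$G)"
    )
    res = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert res.returncode == 0, res.stderr
    assert int(res.stdout.strip()) == select_model(X, k_max=6, seed=12).k == 2


class TestClassification:
    @pytest.mark.parametrize(
        "trajectory,expected",
        [
            ([0.92, 0.88, 0.85], "preserved"),
            ([0.60, 0.03, 0.01], "lost"),
            ([0.02, 0.04, 0.45], "emerged@3"),
            ([0.02, 0.50, 0.55], "emerged@2"),
            ([0.50, 0.02, 0.60], "transient"),
            ([0.02, 0.50, 0.02], "transient"),
            ([0.01, 0.02, 0.03], "transient"),
        ],
    )
    def test_trajectory_rules(self, trajectory, expected):
        assert classify_trajectory(trajectory, 0.10) == expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify_trajectory([0.5], 0.0)

    def test_class_multiset_invariant_to_component_order(self):
        rng = np.random.default_rng(10)
        means = [(0.9, 0.9, 0.9), (0.6, 0.0, 0.0), (0.0, 0.0, 0.6)]
        X = np.vstack([rng.normal(m, 0.03, size=(60, 3)) for m in means])
        classes = []
        for seed in (0, 1, 2):
            fit = fit_mixture(X, k=3, family="diagonal", seed=seed)
            classes.append(
                sorted(c.evo_class for c in classify_clusters(fit, 0.10))
            )
        assert classes[0] == classes[1] == classes[2]
        assert classes[0] == ["emerged@3", "lost", "preserved"]

    def test_cluster_sizes_cover_all_rows(self):
        rng = np.random.default_rng(11)
        X = np.vstack(
            [rng.normal(0.1, 0.02, (40, 2)), rng.normal(0.8, 0.02, (40, 2))]
        )
        fit = fit_mixture(X, k=2, seed=0)
        clusters = classify_clusters(fit)
        assert sum(c.size for c in clusters) == len(X)
        assert all(c.size >= 1 for c in clusters)


def test_planted_patient_clones_recovered(patient, ccf_matrix):
    """Full-pipeline recovery on one simulated patient: BIC selects the four
    planted clones and every evolution class is recovered."""
    _, rows = ccf_matrix.clustering_matrix()
    fit = select_model(rows, k_max=6, seed=11)
    assert fit.k == 4
    classes = sorted(c.evo_class for c in classify_clusters(fit))
    assert classes == ["emerged@2", "emerged@3", "lost", "preserved"]
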