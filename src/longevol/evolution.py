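"""Clone tracking by finite Gaussian mixture clustering of clonality trajectories.

Mutations are clustered on their clonality-rate vectors across timepoints with
a Gaussian mixture fitted by EM; the number of components and the covariance
family are selected by the Bayesian Information Criterion (here minimised as
``n_params * ln(n) - 2 * loglik``). Each fitted component's mean trajectory is
then classified into an evolution class: ``preserved`` (present at every
timepoint), ``lost`` (present at the first, absent at the last),
``emerged@t`` (absent before t, present from t on), or ``transient``.

Three covariance families are fitted — spherical, diagonal and full — which
span the volume/shape spectrum relevant for low-dimensional ccf data.
Initialisation is k-means++ with multiple restarts; restart seeds are derived
deterministically from the base seed, so fits are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

__all__ = [
    "MixtureFit",
    "CloneCluster",
    "DegenerateFitError",
    "fit_mixture",
    "select_model",
    "classify_clusters",
    "classify_trajectory",
    "FAMILIES",
]

FAMILIES = ("spherical", "diagonal", "full")
_SKLEARN_COV = {"spherical": "spherical", "diagonal": "diag", "full": "full"}
COV_FLOOR = 1e-6
EM_TOL = 1e-6
EM_MAX_ITER = 500


class DegenerateFitError(ValueError):
    """Raised when a mixture fit is ill-posed (e.g. all rows identical, k>1)."""


@dataclass
class MixtureFit:
    """A fitted Gaussian mixture with hard assignments and model-choice scores."""

    k: int
    family: str
    weights: np.ndarray
    means: np.ndarray  # (k, d)
    covariances: np.ndarray
    loglik: float
    bic: float
    n_params: int
    assignments: np.ndarray  # (n,)
    responsibilities: np.ndarray  # (n, k)
    loglik_trajectory: list[float]
    seed: int
    converged: bool

    @property
    def n(self) -> int:
        return self.responsibilities.shape[0]

    def to_jsonable(self) -> dict:
        return {
            "k": self.k,
            "family": self.family,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "n_params": self.n_params,
            "n": self.n,
            "seed": self.seed,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class CloneCluster:
    """One mixture component interpreted as a clone with a temporal fate."""

    cluster_id: int
    mean_trajectory: tuple[float, ...]
    size: int
    evo_class: str

    def to_jsonable(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "mean_trajectory": list(self.mean_trajectory),
            "size": self.size,
            "evo_class": self.evo_class,
        }


def _n_parameters(k: int, d: int, family: str) -> int:
    mean_p = k * d
    weight_p = k - 1
    if family == "spherical":
        cov_p = k
    elif family == "diagonal":
        cov_p = k * d
    elif family == "full":
        cov_p = k * d * (d + 1) // 2
    else:
        raise ValueError(f"unknown covariance family {family!r}")
    return mean_p + weight_p + cov_p


def _restart_seed(seed: int, restart: int) -> int:
    ss = np.random.SeedSequence(entropy=[int(seed), int(restart)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def fit_mixture(
    rows: np.ndarray,
    k: int,
    family: str = "full",
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> MixtureFit:
    """Fit a k-component Gaussian mixture by EM, best of ``n_restarts``.

    EM runs to convergence (relative log-likelihood change < ``tol`` or
    ``max_iter`` iterations) from k-means++ starts with a 1e-6 floor on the
    covariance diagonals. The per-iteration total log-likelihood trajectory of
    the winning restart is retained (it is non-decreasing, a standard EM
    guarantee used as a self-check).
    """
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2:
        raise ValueError("rows must be a 2-D array")
    n, d = X.shape
    if family not in FAMILIES:
        raise ValueError(f"unknown covariance family {family!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot fit {k} components to {n} rows")
    if k > 1 and np.all(X == X[0]):
        raise DegenerateFitError("all rows identical; mixture with k>1 is degenerate")

    best: tuple[float, GaussianMixture, list[float], bool] | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for r in range(n_restarts):
            gm = GaussianMixture(
                n_components=k,
                covariance_type=_SKLEARN_COV[family],
                reg_covar=COV_FLOOR,
                tol=0.0,
                max_iter=1,
                n_init=1,
                init_params="k-means++",
                warm_start=True,
                random_state=_restart_seed(seed, r),
            )
            traj: list[float] = []
            converged = False
            prev = -np.inf
            for _ in range(max_iter):
                gm.fit(X)  # one EM iteration per call (warm start)
                ll = float(gm.score(X) * n)
                traj.append(ll)
                if np.isfinite(prev) and abs(ll - prev) <= tol * max(abs(prev), 1e-300):
                    converged = True
                    break
                prev = ll
            ll = traj[-1]
            if best is None or ll > best[0]:
                best = (ll, gm, traj, converged)

    loglik, gm, traj, converged = best
    n_params = _n_parameters(k, d, family)
    resp = gm.predict_proba(X)
    return MixtureFit(
        k=k,
        family=family,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=np.asarray(gm.covariances_).copy(),
        loglik=loglik,
        bic=n_params * np.log(n) - 2.0 * loglik,
        n_params=n_params,
        assignments=resp.argmax(axis=1),  # argmax ties resolve to lowest id
        responsibilities=resp,
        loglik_trajectory=traj,
        seed=seed,
        converged=converged,
    )


def select_model(
    rows: np.ndarray,
    k_max: int,
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    n_restarts: int = 10,
) -> MixtureFit:
    """Fit all (k, family) combinations for k = 1..k_max and return the
    minimum-BIC fit.

    Ties break toward smaller k, then family order spherical < diagonal <
    full. Degenerate (k, family) combinations are skipped; an error is raised
    only if every combination fails.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    bad = [f for f in families if f not in FAMILIES]
    if bad:
        raise ValueError(f"unknown families {bad}")
    ordered = [f for f in FAMILIES if f in families]
    best: MixtureFit | None = None
    errors: list[str] = []
    for k in range(1, k_max + 1):
        for family in ordered:
            try:
                fit = fit_mixture(rows, k, family, seed=seed, n_restarts=n_restarts)
            except (ValueError, np.linalg.LinAlgError) as exc:
                errors.append(f"k={k},{family}: {exc}")
                continue
            if best is None or fit.bic < best.bic:
                best = fit
    if best is None:
        raise DegenerateFitError(
            "no (k, family) combination could be fitted: " + "; ".join(errors)
        )
    return best


def classify_trajectory(
    mean_trajectory: Sequence[float], presence_threshold: float = 0.10
) -> str:
    """Classify a mean clonality trajectory into an evolution class.

    A clone is *present* at a timepoint when its mean ccf is at or above the
    presence threshold. ``preserved``: present everywhere; ``lost``: present
    at the first timepoint, absent at the last; ``emerged@t``: absent at all
    timepoints before t, present from t onward (t > 1); anything else is
    ``transient``.
    """
    if not (0.0 < presence_threshold < 1.0):
        raise ValueError("presence_threshold must be in (0,1)")
    present = [m >= presence_threshold for m in mean_trajectory]
    if all(present):
        return "preserved"
    if present[0] and not present[-1]:
        return "lost"
    if any(present):
        t = present.index(True)
        if t > 0 and all(present[t:]):
            return f"emerged@{t + 1}"
    return "transient"


def classify_clusters(
    fit: MixtureFit, presence_threshold: float = 0.10
) -> list[CloneCluster]:
    """Interpret each mixture component as a clone and classify its fate.

    Components that attract no hard-assigned mutations are dropped (they carry
    no observable clone).
    """
    counts = np.bincount(fit.assignments, minlength=fit.k)
    clusters = []
    for c in range(fit.k):
        if counts[c] == 0:
            continue
        traj = tuple(float(x) for x in fit.means[c])
        clusters.append(
            CloneCluster(
                cluster_id=c,
                mean_trajectory=traj,
                size=int(counts[c]),
                evo_class=classify_trajectory(traj, presence_threshold),
            )
        )
    return clusters
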