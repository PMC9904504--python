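"""Mutual-information and conditional-mutual-information estimators.

Two estimator kinds are provided:

``gaussian``
    Closed-form estimate from covariance determinants,
    ``I(A;B) = 0.5 * ln( |Sigma_A| |Sigma_B| / |Sigma_AB| )`` nats, exact
    for jointly Gaussian data and equal to the linear-predictability
    (partial-correlation) information otherwise.  Fast enough to sit
    inside permutation loops; non-negative by construction.

``ksg``
    The Kraskov-Stoegbauer-Grassberger k-nearest-neighbour estimator
    (algorithm 1) and its conditional extension (Frenzel-Pompe), using
    Chebyshev-ball neighbour counts.  Consistent for non-Gaussian and
    nonlinear dependencies; small-sample estimates may be slightly
    negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

__all__ = [
    "EstimatorConfig",
    "mutual_information",
    "conditional_mutual_information",
]

_JITTER = 1e-10  # ridge added to a singular covariance


@dataclass
class EstimatorConfig:
    """Configuration shared by all information-theoretic estimation steps.

    Parameters
    ----------
    kind : {"gaussian", "ksg"}
        Estimator family.
    knn_k : int
        Neighbour count for the ksg estimator.
    alpha_embed : float
        Significance level of the maximum-statistic test used during
        greedy embedding selection.
    n_perm_embed : int
        Permutations per candidate test during embedding selection.
    k_max : int
        Largest candidate past lag searched (samples).
    n_perm_ais : int
        Permutations of the time-domain storage significance test.
    max_samples_ksg : int
        Pooled-sample cap for the ksg estimator; larger pools are
        subsampled (evenly strided) to keep neighbour searches tractable.
    max_samples_embed : int
        Pooled-sample cap during embedding selection (even temporal
        stride within trials).  Selection only has to find the
        informative lags, not estimate their contribution precisely, so
        a capped pool trades a higher CMI detection floor for a large
        speedup of the permutation tests; the final storage estimate
        always uses the full pool.
    seed : int
        Seed for all estimator-internal randomness.
    """

    kind: str = "gaussian"
    knn_k: int = 4
    alpha_embed: float = 0.05
    n_perm_embed: int = 200
    k_max: int = 20
    n_perm_ais: int = 200
    max_samples_ksg: int = 2000
    max_samples_embed: int = 10_000
    # ksg-only caps inside the embedding-selection permutation loops, where
    # thousands of neighbour searches run; selection needs detection power,
    # not precision, so a coarser subsample and fewer permutations suffice
    max_samples_ksg_embed: int = 800
    n_perm_embed_ksg: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("gaussian", "ksg"):
            raise ValueError(f"unknown estimator kind {self.kind!r}")
        if not 0 < self.alpha_embed < 1:
            raise ValueError("alpha_embed must be in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def _as_matrix(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError("sample arrays must be 1-D or 2-D")
    return a


def _logdet(m: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(m)
    if sign <= 0 or not np.isfinite(ld):
        warnings.warn(
            "singular covariance regularized with jitter", RuntimeWarning, stacklevel=3
        )
        sign, ld = np.linalg.slogdet(m + _JITTER * np.eye(m.shape[0]))
        if sign <= 0:
            raise np.linalg.LinAlgError("covariance not positive definite")
    return ld


def _gaussian_mi(a: np.ndarray, b: np.ndarray) -> float:
    ab = np.concatenate([a, b], axis=1)
    cov = np.cov(ab, rowvar=False)
    cov = np.atleast_2d(cov)
    da = a.shape[1]
    mi = 0.5 * (_logdet(cov[:da, :da]) + _logdet(cov[da:, da:]) - _logdet(cov))
    return max(mi, 0.0)


def _gaussian_cmi(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    # I(A;B|C) = 0.5 * ( ln|S_AC| + ln|S_BC| - ln|S_C| - ln|S_ABC| )
    da, db = a.shape[1], b.shape[1]
    full = np.concatenate([a, b, c], axis=1)
    cov = np.atleast_2d(np.cov(full, rowvar=False))
    ia = np.arange(da)
    ib = np.arange(da, da + db)
    ic = np.arange(da + db, full.shape[1])
    iac = np.concatenate([ia, ic])
    ibc = np.concatenate([ib, ic])
    cmi = 0.5 * (
        _logdet(cov[np.ix_(iac, iac)])
        + _logdet(cov[np.ix_(ibc, ibc)])
        - _logdet(cov[np.ix_(ic, ic)])
        - _logdet(cov)
    )
    return max(cmi, 0.0)


def _ksg_subsample(arrs: list[np.ndarray], cfg: EstimatorConfig) -> list[np.ndarray]:
    n = arrs[0].shape[0]
    if n <= cfg.max_samples_ksg:
        return arrs
    idx = np.linspace(0, n - 1, cfg.max_samples_ksg).astype(int)
    return [a[idx] for a in arrs]


def _ball_counts(pts: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Number of points strictly within per-point Chebyshev radii (minus self)."""
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, radii, p=np.inf, return_length=True)
    return np.asarray(counts) - 1


def _ksg_mi(a: np.ndarray, b: np.ndarray, k: int) -> float:
    # KSG algorithm 1 with Chebyshev metric
    n = a.shape[0]
    joint = np.concatenate([a, b], axis=1)
    dist, _ = cKDTree(joint).query(joint, k=k + 1, p=np.inf)
    eps = dist[:, -1] * (1 - 1e-12)  # strictly-within-eps counts
    na = _ball_counts(a, eps)
    nb = _ball_counts(b, eps)
    return float(
        digamma(k) + digamma(n) - np.mean(digamma(na + 1) + digamma(nb + 1))
    )


def _ksg_cmi(a: np.ndarray, b: np.ndarray, c: np.ndarray, k: int) -> float:
    # Frenzel-Pompe conditional estimator
    joint = np.concatenate([a, b, c], axis=1)
    dist, _ = cKDTree(joint).query(joint, k=k + 1, p=np.inf)
    eps = dist[:, -1] * (1 - 1e-12)
    n_ac = _ball_counts(np.concatenate([a, c], axis=1), eps)
    n_bc = _ball_counts(np.concatenate([b, c], axis=1), eps)
    n_c = _ball_counts(c, eps)
    return float(
        digamma(k) - np.mean(digamma(n_ac + 1) + digamma(n_bc + 1) - digamma(n_c + 1))
    )


def _gaussian_logdet_cmi_setup(present: np.ndarray, sel_past: np.ndarray):
    """Prepare a fast evaluator of I(present; cand | sel_past), gaussian kind.

    Returns a callable mapping a matrix of candidate columns (n, P) to a
    vector of P conditional-MI values.  The fixed blocks of the joint
    covariance (present and selected past) are computed once; per column
    only the cross-covariances are needed (one matmul for all P columns).
    Used by the embedding-selection permutation test, where the same
    candidate is evaluated under hundreds of within-trial shuffles.
    """
    present = np.atleast_2d(np.asarray(present, dtype=float))
    sel_past = np.asarray(sel_past, dtype=float)
    if sel_past.ndim == 1:
        sel_past = sel_past[:, None]
    n = present.shape[0]
    m = sel_past.shape[1]
    a = present - present.mean(axis=0)
    c = sel_past - sel_past.mean(axis=0) if m else sel_past.reshape(n, 0)
    base = np.concatenate([a, c], axis=1)  # columns: [a, c_1..c_m]
    s_base = base.T @ base / (n - 1)  # (1+m, 1+m)
    ld_ac = _logdet(s_base)
    ld_c = _logdet(s_base[1:, 1:]) if m else 0.0
    s_c = s_base[1:, 1:]

    def evaluate(cols: np.ndarray) -> np.ndarray:
        cols = cols - cols.mean(axis=0)
        p_count = cols.shape[1]
        cross = base.T @ cols / (n - 1)  # rows: [a.b, c.b]; shape (1+m, P)
        var_b = np.einsum("ij,ij->j", cols, cols) / (n - 1)
        # stacked S_{b,c}: (P, 1+m, 1+m)
        s_bc = np.empty((p_count, 1 + m, 1 + m))
        s_bc[:, 0, 0] = var_b
        s_bc[:, 0, 1:] = cross[1:].T
        s_bc[:, 1:, 0] = cross[1:].T
        s_bc[:, 1:, 1:] = s_c
        # stacked S_{a,b,c}: (P, 2+m, 2+m), order [a, b, c]
        s_abc = np.empty((p_count, 2 + m, 2 + m))
        s_abc[:, 0, 0] = s_base[0, 0]
        s_abc[:, 0, 1] = cross[0]
        s_abc[:, 1, 0] = cross[0]
        s_abc[:, 1, 1] = var_b
        s_abc[:, 0, 2:] = s_base[0, 1:]
        s_abc[:, 2:, 0] = s_base[1:, 0][None, :]
        s_abc[:, 1, 2:] = cross[1:].T
        s_abc[:, 2:, 1] = cross[1:].T
        s_abc[:, 2:, 2:] = s_base[1:, 1:]
        sign_bc, ld_bc = np.linalg.slogdet(s_bc)
        sign_abc, ld_abc = np.linalg.slogdet(s_abc)
        bad = (sign_bc <= 0) | (sign_abc <= 0)
        if np.any(bad):
            eye_bc = _JITTER * np.eye(1 + m)
            eye_abc = _JITTER * np.eye(2 + m)
            _, ld_bc_f = np.linalg.slogdet(s_bc[bad] + eye_bc)
            _, ld_abc_f = np.linalg.slogdet(s_abc[bad] + eye_abc)
            ld_bc = np.where(bad, np.nan, ld_bc)
            ld_abc = np.where(bad, np.nan, ld_abc)
            ld_bc[bad] = ld_bc_f
            ld_abc[bad] = ld_abc_f
        return np.maximum(0.5 * (ld_ac + ld_bc - ld_c - ld_abc), 0.0)

    return evaluate


def mutual_information(a, b, cfg: EstimatorConfig | None = None) -> float:
    """Estimate I(A; B) in nats.

    ``a`` and ``b`` are sample matrices (rows = observations, columns =
    embedding dimensions); vectors are treated as single columns.
    """
    cfg = cfg or EstimatorConfig()
    a, b = _as_matrix(a), _as_matrix(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("a and b must have equal row counts")
    if a.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if cfg.kind == "gaussian":
        return _gaussian_mi(a, b)
    a, b = _ksg_subsample([a, b], cfg)
    return _ksg_mi(a, b, cfg.knn_k)


def conditional_mutual_information(a, b, c=None, cfg: EstimatorConfig | None = None) -> float:
    """Estimate I(A; B | C) in nats; empty ``c`` reduces exactly to the MI."""
    cfg = cfg or EstimatorConfig()
    if c is None or (np.asarray(c).size == 0):
        return mutual_information(a, b, cfg)
    a, b, c = _as_matrix(a), _as_matrix(b), _as_matrix(c)
    if not (a.shape[0] == b.shape[0] == c.shape[0]):
        raise ValueError("a, b, c must have equal row counts")
    if a.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if cfg.kind == "gaussian":
        return _gaussian_cmi(a, b, c)
    a, b, c = _ksg_subsample([a, b, c], cfg)
    return _ksg_cmi(a, b, c, cfg.knn_k)
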