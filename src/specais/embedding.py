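"""Greedy non-uniform embedding of a process's past state.

The past state ``Y_<t`` entering the storage measure is not a fixed
uniform lag grid but a data-driven subset of candidate lags
``{1, ..., k_max}``.  Selection is greedy forward inclusion: at each step
the candidate lag maximizing the conditional mutual information with the
present value, given the already selected lags, is admitted only if it
survives a maximum-statistic permutation test — the candidate's CMI must
beat the distribution of the *maximum* CMI obtained after shuffling every
remaining candidate in time (within trials).  Taking the maximum over
candidates controls the family-wise error of the selection step, so on a
memoryless process the returned lag set is empty at rate ~alpha.

Samples are pooled across trials after discarding the first ``k_max``
samples of each trial, treating trials as interchangeable realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .information import (
    EstimatorConfig,
    _gaussian_logdet_cmi_setup,
    conditional_mutual_information,
)

__all__ = ["EmbeddingSpec", "select_embedding", "lagged_matrices"]


@dataclass(frozen=True)
class EmbeddingSpec:
    """An ordered set of past lags defining the past state.

    ``lags`` is a sorted tuple of positive sample offsets; an empty tuple
    means "no significant storage structure found".
    """

    lags: tuple = field(default_factory=tuple)
    k_max: int = 20

    def __post_init__(self):
        lags = tuple(sorted(int(l) for l in self.lags))
        object.__setattr__(self, "lags", lags)
        if any(l < 1 for l in lags):
            raise ValueError("lags must be positive integers")
        if len(set(lags)) != len(lags):
            raise ValueError("duplicate lags")
        if lags and max(lags) > self.k_max:
            raise ValueError("max(lags) must not exceed k_max")

    def __bool__(self) -> bool:
        return bool(self.lags)

    def union(self, other: "EmbeddingSpec") -> "EmbeddingSpec":
        return EmbeddingSpec(
            lags=tuple(set(self.lags) | set(other.lags)),
            k_max=max(self.k_max, other.k_max),
        )


def lagged_matrices(data: np.ndarray, lags, k_max: int):
    """Pooled (present, past) sample matrices for a trial matrix.

    The first ``k_max`` samples of every trial are discarded so that all
    candidate lags index valid history, keeping the pooled sample set
    identical across candidate sets.

    Returns
    -------
    present : ndarray, shape (n_trials * (N - k_max), 1)
    past : ndarray, shape (n_trials * (N - k_max), len(lags))
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_trials, n = data.shape
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be smaller than trial length {n}")
    present = data[:, k_max:].reshape(-1, 1)
    past = np.empty((n_trials * (n - k_max), len(lags)))
    for i, d in enumerate(lags):
        past[:, i] = data[:, k_max - d : n - d].reshape(-1)
    return present, past


def _shuffle_within_trials(block: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each row (trial) of a (trials, M) matrix."""
    return rng.permuted(block, axis=-1)


def _max_stat_pvalue_gaussian(
    present, sel_past, cand_blocks, best_cmi, cfg, rng
) -> float:
    """Max-statistic permutation p-value, vectorized for the gaussian kind.

    For each permutation, every remaining candidate is shuffled within
    trials and its CMI given the selected set recomputed; the permutation
    statistic is the maximum over candidates.  All shuffled CMIs for one
    candidate are evaluated from a single cross-covariance matmul.
    """
    setup = _gaussian_logdet_cmi_setup(present, sel_past)
    n_perm = cfg.n_perm_embed
    max_cmi = np.full(n_perm, -np.inf)
    for block in cand_blocks:
        # all permutations at once: (n_perm, trials, M), shuffled along time
        shuf = rng.permuted(
            np.broadcast_to(block, (n_perm,) + block.shape).copy(), axis=-1
        )
        cols = shuf.reshape(n_perm, -1).T
        cmis = setup(cols)
        np.maximum(max_cmi, cmis, out=max_cmi)
    n_ge = int(np.sum(max_cmi >= best_cmi))
    return (1 + n_ge) / (1 + n_perm)


def _max_stat_pvalue_generic(
    present, sel_past, cand_blocks, best_cmi, cfg, rng
) -> float:
    c = sel_past if sel_past.shape[1] else None
    n_perm = cfg.n_perm_embed_ksg if cfg.kind == "ksg" else cfg.n_perm_embed
    n_ge = 0
    for _ in range(n_perm):
        mx = -np.inf
        for block in cand_blocks:
            shuf = _shuffle_within_trials(block, rng).reshape(-1, 1)
            mx = max(mx, conditional_mutual_information(present, shuf, c, cfg))
        if mx >= best_cmi:
            n_ge += 1
    return (1 + n_ge) / (1 + n_perm)


def select_embedding(data, cfg: EstimatorConfig | None = None, rng=None) -> EmbeddingSpec:
    """Greedy non-uniform selection of informative past lags.

    Parameters
    ----------
    data : ndarray or TrialEnsemble
        (trials, samples) matrix.
    cfg : EstimatorConfig
        Estimator kind, candidate bound ``k_max``, selection level
        ``alpha_embed`` and permutation budget.
    rng : numpy Generator, optional
        Randomness source for the permutation tests; defaults to
        ``default_rng(cfg.seed)``.

    Returns
    -------
    EmbeddingSpec
        Possibly empty set of selected lags.
    """
    if hasattr(data, "data"):
        data = data.data
    data = np.atleast_2d(np.asarray(data, dtype=float))
    cfg = cfg or EstimatorConfig()
    if cfg.kind == "ksg":
        # selection runs thousands of CMI evaluations; coarsen the subsample
        cfg = replace(cfg, max_samples_ksg=cfg.max_samples_ksg_embed)
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_trials, n = data.shape
    k_max = cfg.k_max
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be smaller than trial length {n}")

    # cap the pooled sample count by an even temporal stride within trials;
    # (present, candidate) sample pairs stay intact, only fewer of them
    m_full = n - k_max
    stride = max(1, int(np.ceil(n_trials * m_full / cfg.max_samples_embed)))
    cols = np.arange(0, m_full, stride)

    present = data[:, k_max:][:, cols].reshape(-1, 1)
    cand = {d: data[:, k_max - d : n - d][:, cols] for d in range(1, k_max + 1)}
    selected: list[int] = []

    while len(selected) < k_max:
        remaining = [d for d in range(1, k_max + 1) if d not in selected]
        if not remaining:
            break
        sel_past = np.column_stack(
            [cand[d].reshape(-1) for d in selected]
        ) if selected else np.empty((present.shape[0], 0))
        c = sel_past if selected else None
        # ascending lag order + strict improvement => ties break to smaller lag
        best_d, best_cmi = None, -np.inf
        for d in remaining:
            v = conditional_mutual_information(
                present, cand[d].reshape(-1, 1), c, cfg
            )
            if v > best_cmi:
                best_d, best_cmi = d, v
        blocks = [cand[d] for d in remaining]
        if cfg.kind == "gaussian":
            p = _max_stat_pvalue_gaussian(present, sel_past, blocks, best_cmi, cfg, rng)
        else:
            p = _max_stat_pvalue_generic(present, sel_past, blocks, best_cmi, cfg, rng)
        if p > cfg.alpha_embed:
            break
        selected.append(best_d)
    return EmbeddingSpec(lags=tuple(selected), k_max=k_max)
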