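"""NIPALS principal component analysis with native missing-value handling.

The NIPALS iteration extracts one component at a time by alternating
least-squares updates of a score vector t and a unit-norm loading vector p,
followed by deflation X <- X - t p'.  Every inner product skips missing
cells, so a missing cell has zero residual and no leverage on the estimated
parameters.  Explained variance is accounted per component as the drop in
observed-cell residual sum of squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import BlockMatrix

log = logging.getLogger(__name__)

__all__ = ["PcaModel", "JackknifeIntervals", "nipals_pca", "jackknife_loading_ci"]


@dataclass
class PcaModel:
    scores: np.ndarray  # (n_obs, A), columns t_1..t_A
    loadings: np.ndarray  # (n_vars, A), unit-norm columns p_1..p_A
    r2_per_component: np.ndarray  # (A,)
    means: np.ndarray  # column means stored by preprocessing
    residual: np.ndarray  # (n_obs, n_vars), exactly 0 at missing cells
    n_iterations: list[int]
    converged: list[bool]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @property
    def cumulative_r2(self) -> np.ndarray:
        return np.cumsum(self.r2_per_component)


def _fix_sign(t: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # convention: the loading element of largest absolute value is positive
    j = int(np.argmax(np.abs(p)))
    if p[j] < 0:
        return -t, -p
    return t, p


def nipals_component(
    X: np.ndarray,
    observed: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Extract one NIPALS component from a zero-filled matrix.

    ``X`` must already contain 0.0 at unobserved cells.  Returns
    (t, p, n_iter, converged) with p of unit norm.  No deflation is done.
    """
    col_ss = (X**2).sum(axis=0)
    t = X[:, int(np.argmax(col_ss))].copy()
    if not np.any(t):
        # degenerate start (all-zero column): fall back to the first nonzero column
        nz = np.flatnonzero(col_ss)
        if nz.size == 0:
            return np.zeros(X.shape[0]), np.zeros(X.shape[1]), 0, True
        t = X[:, nz[0]].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # p_k = sum_i x_ik t_i / sum_{i observed} t_i^2   (per-column denominators)
        denom_p = (observed * (t**2)[:, None]).sum(axis=0)
        denom_p[denom_p == 0] = 1.0
        p = (X * t[:, None]).sum(axis=0) / denom_p
        norm = np.linalg.norm(p)
        if norm == 0:
            break
        p /= norm
        denom_t = (observed * (p**2)[None, :]).sum(axis=1)
        denom_t[denom_t == 0] = 1.0
        t_new = (X * p[None, :]).sum(axis=1) / denom_t
        delta = np.linalg.norm(t_new - t)
        t = t_new
        if delta <= tol * max(np.linalg.norm(t), 1e-300):
            converged = True
            break
    return t, p, it, converged


def nipals_pca(
    block: BlockMatrix,
    n_components: int | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
    cum_r2: float = 0.95,
) -> PcaModel:
    """Sequential NIPALS PCA on a centered block.

    If ``n_components`` is None, components are extracted until the
    cumulative explained variance reaches ``cum_r2`` (or the rank limit).
    R2 denominators use observed cells only.
    """
    if block.preprocessing == "raw":
        raise ValueError(f"block {block.name!r} must be centered before PCA")
    n, p = block.shape
    max_rank = min(n, p)
    if n_components is not None and n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_obs, n_vars)={max_rank}"
        )
    limit = n_components if n_components is not None else max_rank
    X = block.filled(0.0)
    observed = block.observed
    ss0 = float((X**2).sum())
    if ss0 == 0:
        raise ValueError(f"block {block.name!r} has zero total variance")

    scores, loadings, r2s, iters, convs = [], [], [], [], []
    ss_prev = ss0
    for _ in range(limit):
        t, pv, it, conv = nipals_component(X, observed, tol=tol, max_iter=max_iter)
        if not conv:
            warnings.warn(
                f"NIPALS component {len(scores) + 1} did not converge "
                f"within {max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        t, pv = _fix_sign(t, pv)
        X = X - np.where(observed, np.outer(t, pv), 0.0)
        ss_now = float((X**2).sum())
        scores.append(t)
        loadings.append(pv)
        r2s.append((ss_prev - ss_now) / ss0)
        iters.append(it)
        convs.append(conv)
        ss_prev = ss_now
        if n_components is None and sum(r2s) >= cum_r2:
            break
        if ss_now <= ss0 * 1e-14:
            break
    return PcaModel(
        scores=np.column_stack(scores) if scores else np.zeros((n, 0)),
        loadings=np.column_stack(loadings) if loadings else np.zeros((p, 0)),
        r2_per_component=np.asarray(r2s),
        means=block.col_means.copy(),
        residual=X,
        n_iterations=iters,
        converged=convs,
    )


@dataclass
class JackknifeIntervals:
    loadings: np.ndarray  # full-model loadings (n_vars, A)
    se: np.ndarray  # jackknife standard errors, same shape
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_excluded: int  # refits dropped for non-convergence


def jackknife_loading_ci(
    block: BlockMatrix,
    n_components: int = 1,
    level: float = 0.95,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> JackknifeIntervals:
    """Leave-one-observation-out confidence intervals for PCA loadings.

    Each refit re-centers the remaining rows, refits the PCA, and is
    sign-aligned to the full-model loadings component-wise.  The interval is
    loading +/- t-quantile x jackknife standard error.
    """
    n = block.n_obs
    if n < 3:
        raise ValueError("jackknife requires at least 3 observations")
    full = nipals_pca(block, n_components, tol=tol, max_iter=max_iter)
    P_full = full.loadings

    # refits operate on raw-equivalent data: undo then redo centering per subset
    raw_values = block.values * block.col_scales + block.col_means
    refit_loadings = []
    n_excluded = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = BlockMatrix(
            name=block.name,
            values=raw_values[keep],
            missing_mask=block.missing_mask[keep],
            var_names=list(block.var_names),
            obs_ids=[o for o, k in zip(block.obs_ids, keep) if k],
            preprocessing="raw",
        )
        from .preprocess import center_scale

        mode = "center_only" if block.preprocessing == "centered" else "center_and_uv_scale"
        try:
            model_i = nipals_pca(
                center_scale(sub, mode), n_components, tol=tol, max_iter=max_iter
            )
        except ValueError:
            n_excluded += 1
            continue
        if not all(model_i.converged):
            log.warning("jackknife refit without observation %s did not converge", i)
            n_excluded += 1
            continue
        P = model_i.loadings.copy()
        for a in range(n_components):
            if P[:, a] @ P_full[:, a] < 0:
                P[:, a] = -P[:, a]
        refit_loadings.append(P)

    m = len(refit_loadings)
    if m < 2:
        raise ValueError("too few successful jackknife refits")
    if n_excluded:
        log.warning("jackknife: %d of %d refits excluded", n_excluded, n)
    L = np.stack(refit_loadings)  # (m, n_vars, A)
    mean_L = L.mean(axis=0)
    se = np.sqrt((m - 1) / m * ((L - mean_L) ** 2).sum(axis=0))
    q = stats.t.ppf(0.5 + level / 2, df=m - 1)
    return JackknifeIntervals(
        loadings=P_full,
        se=se,
        lower=P_full - q * se,
        upper=P_full + q * se,
        level=level,
        n_excluded=n_excluded,
    )
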