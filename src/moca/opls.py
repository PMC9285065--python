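"""Two-block latent-variable engines: PLS2, single-y OPLS, pairwise joint fits.

All inner products skip missing cells (zero-residual convention), mirroring
the PCA engine.  ``fit_pairwise_joint`` implements the first step of the
multiblock decomposition: the number of joint components shared by a pair of
blocks is read off the singular values of the norm-equalized cross-product
matrix Xa'Xb, so that each block enters with equal weight regardless of its
number of variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import BlockMatrix

__all__ = [
    "PlsModel",
    "OplsModel",
    "PairwiseJointSet",
    "fit_pls",
    "fit_opls",
    "fit_pairwise_joint",
]


def _col_regress(X: np.ndarray, observed: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Per-column least-squares slope of X on t over observed cells."""
    denom = (observed * (t**2)[:, None]).sum(axis=0)
    denom[denom == 0] = 1.0
    return (X * t[:, None]).sum(axis=0) / denom


def _row_project(X: np.ndarray, observed: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-row least-squares projection of X onto w over observed cells."""
    denom = (observed * (w**2)[None, :]).sum(axis=1)
    denom[denom == 0] = 1.0
    return (X * w[None, :]).sum(axis=1) / denom


def _deflate(X: np.ndarray, observed: np.ndarray, t: np.ndarray, p: np.ndarray) -> np.ndarray:
    return X - np.where(observed, np.outer(t, p), 0.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# PLS2
# ---------------------------------------------------------------------------


@dataclass
class PlsModel:
    x_scores: np.ndarray  # T (n, A)
    x_loadings: np.ndarray  # P (px, A)
    y_scores: np.ndarray  # U (n, A)
    y_loadings: np.ndarray  # C (py, A)
    weights: np.ndarray  # W (px, A)
    x_residual: np.ndarray  # E
    y_residual: np.ndarray  # F
    inner_residual: np.ndarray  # G = Y - T C' residual of the inner relation
    r2x: np.ndarray  # per component
    r2y: np.ndarray  # per component
    q2: np.ndarray | None = None  # cumulative, per component

    @property
    def n_components(self) -> int:
        return self.x_scores.shape[1]

    def predict(self, X_new: np.ndarray, observed: np.ndarray | None = None) -> np.ndarray:
        """Predict (preprocessed-scale) Y for preprocessed X rows."""
        X = np.array(X_new, dtype=float)
        if observed is None:
            observed = ~np.isnan(X)
        X = np.where(observed, X, 0.0)
        yhat = np.zeros((X.shape[0], self.y_loadings.shape[0]))
        for a in range(self.n_components):
            t = _row_project(X, observed, self.weights[:, a])
            yhat += np.outer(t, self.y_loadings[:, a])
            X = _deflate(X, observed, t, self.x_loadings[:, a])
        return yhat


def _fit_pls_arrays(
    X: np.ndarray,
    obs_x: np.ndarray,
    Y: np.ndarray,
    obs_y: np.ndarray,
    n_components: int,
    tol: float = 1e-10,
    max_iter: int = 500,
):
    n = X.shape[0]
    ssx0 = float((X**2).sum())
    ssy0 = float((Y**2).sum())
    T, P, U, C, W = [], [], [], [], []
    r2x, r2y = [], []
    ssx_prev, ssy_prev = ssx0, ssy0
    for _ in range(n_components):
        u = Y[:, int(np.argmax((Y**2).sum(axis=0)))].copy()
        if not np.any(u):
            break
        t = np.zeros(n)
        for _it in range(max_iter):
            w = _col_regress(X, obs_x, u)
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t_new = _row_project(X, obs_x, w)
            c = _col_regress(Y, obs_y, t_new)
            nc = np.linalg.norm(c)
            if nc == 0:
                t = t_new
                break
            u = _row_project(Y, obs_y, c / nc)
            delta = np.linalg.norm(t_new - t)
            t = t_new
            if delta <= tol * max(np.linalg.norm(t), 1e-300):
                break
        p = _col_regress(X, obs_x, t)
        c = _col_regress(Y, obs_y, t)
        X = _deflate(X, obs_x, t, p)
        Y = _deflate(Y, obs_y, t, c)
        ssx_now, ssy_now = float((X**2).sum()), float((Y**2).sum())
        T.append(t)
        P.append(p)
        U.append(u)
        C.append(c)
        W.append(w)
        r2x.append((ssx_prev - ssx_now) / ssx0 if ssx0 else 0.0)
        r2y.append((ssy_prev - ssy_now) / ssy0 if ssy0 else 0.0)
        ssx_prev, ssy_prev = ssx_now, ssy_now
    A = len(T)
    return (
        np.column_stack(T) if A else np.zeros((n, 0)),
        np.column_stack(P) if A else np.zeros((X.shape[1], 0)),
        np.column_stack(U) if A else np.zeros((n, 0)),
        np.column_stack(C) if A else np.zeros((Y.shape[1], 0)),
        np.column_stack(W) if A else np.zeros((X.shape[1], 0)),
        X,
        Y,
        np.asarray(r2x),
        np.asarray(r2y),
    )


def fit_pls(
    X: BlockMatrix,
    Y: BlockMatrix,
    n_components: int,
    cv_folds: int = 7,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PlsModel:
    """NIPALS PLS2 with missing-value support and K-fold cross-validated Q2.

    Cross-validation uses contiguous observation folds; the left-out rows
    are predicted with a model refitted on the remaining (already
    preprocessed) rows and Q2_a = 1 - PRESS_a / SS(Y).
    """
    if X.obs_ids != Y.obs_ids:
        raise ValueError("X and Y must share observations")
    if X.preprocessing == "raw" or Y.preprocessing == "raw":
        raise ValueError("blocks must be preprocessed before fit_pls")
    rank = min(X.n_obs, X.n_vars)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank bound {rank}")
    Xf, obs_x = X.filled(0.0), X.observed
    Yf, obs_y = Y.filled(0.0), Y.observed
    T, P, U, C, W, E, F, r2x, r2y = _fit_pls_arrays(
        Xf.copy(), obs_x, Yf.copy(), obs_y, n_components, tol, max_iter
    )
    G = np.where(obs_y, Yf - T @ C.T, 0.0)

    # Q2 by contiguous folds
    q2 = None
    n = X.n_obs
    if cv_folds and cv_folds >= 2 and n >= cv_folds:
        A = T.shape[1]
        press = np.zeros(A)
        ssy_tot = 0.0
        bounds = np.linspace(0, n, cv_folds + 1).astype(int)
        for k in range(cv_folds):
            test = np.zeros(n, dtype=bool)
            test[bounds[k] : bounds[k + 1]] = True
            res = _fit_pls_arrays(
                Xf[~test].copy(), obs_x[~test], Yf[~test].copy(), obs_y[~test],
                A, tol, max_iter,
            )
            Pk, Ck, Wk = res[1], res[3], res[4]
            Xt = Xf[test].copy()
            ot = obs_x[test]
            yhat = np.zeros((test.sum(), Yf.shape[1]))
            ytrue = np.where(obs_y[test], Yf[test], 0.0)
            ssy_tot += float((ytrue**2).sum())
            for a in range(Pk.shape[1]):
                t = _row_project(Xt, ot, Wk[:, a])
                yhat += np.outer(t, Ck[:, a])
                Xt = _deflate(Xt, ot, t, Pk[:, a])
                err = np.where(obs_y[test], ytrue - yhat, 0.0)
                press[a] += float((err**2).sum())
            for a in range(Pk.shape[1], A):  # fold model ran out of rank
                press[a] += press[max(Pk.shape[1] - 1, 0)] if Pk.shape[1] else 0.0
        q2 = 1 - press / ssy_tot if ssy_tot else np.zeros(A)

    return PlsModel(
        x_scores=T, x_loadings=P, y_scores=U, y_loadings=C, weights=W,
        x_residual=E, y_residual=F, inner_residual=G, r2x=r2x, r2y=r2y, q2=q2,
    )


# ---------------------------------------------------------------------------
# single-y OPLS
# ---------------------------------------------------------------------------


@dataclass
class OplsModel:
    predictive_score: np.ndarray  # t_p (n,)
    predictive_loading: np.ndarray  # p_p (px,)
    predictive_weight: np.ndarray  # w (px,)
    predictive_y_loading: float  # q_p
    ortho_scores: np.ndarray  # T_o (n, n_ortho)
    ortho_loadings: np.ndarray  # P_o (px, n_ortho)
    ortho_weights: np.ndarray  # W_o (px, n_ortho)
    x_residual: np.ndarray  # E
    y_residual: np.ndarray  # f
    y_mean_removed: bool
    r2x_pred: float
    r2x_ortho: float
    r2y: float

    @property
    def n_ortho(self) -> int:
        return self.ortho_scores.shape[1]

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X = np.nan_to_num(np.asarray(X_new, dtype=float))
        obs = ~np.isnan(np.asarray(X_new, dtype=float))
        for a in range(self.n_ortho):
            t_o = _row_project(X, obs, self.ortho_weights[:, a])
            X = _deflate(X, obs, t_o, self.ortho_loadings[:, a])
        t = _row_project(X, obs, self.predictive_weight)
        return t * self.predictive_y_loading


def fit_opls(
    X: BlockMatrix,
    y: BlockMatrix,
    n_ortho: int = 0,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> OplsModel:
    """Single-y OPLS: X = t_p p_p' + T_o P_o' + E,  y = t_p q_p + f.

    By construction there is exactly one predictive component; ``n_ortho``
    y-orthogonal components are stripped from X first.
    """
    if y.n_vars != 1:
        raise ValueError("fit_opls requires a single-column y block")
    if X.obs_ids != y.obs_ids:
        raise ValueError("X and y must share observations")
    if X.preprocessing == "raw" or y.preprocessing == "raw":
        raise ValueError("blocks must be preprocessed before fit_opls")
    yv = y.filled(0.0)[:, 0]
    if np.allclose(yv, yv[0] if len(yv) else 0.0):
        raise ValueError("y is constant")

    Xw, obs = X.filled(0.0), X.observed
    ssx0 = float((Xw**2).sum())
    ssy0 = float((yv**2).sum())

    T_o, P_o, W_o = [], [], []
    for _ in range(n_ortho):
        w = _col_regress(Xw, obs, yv)
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = _row_project(Xw, obs, w)
        p = _col_regress(Xw, obs, t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo <= 1e-12 * np.linalg.norm(p):
            break  # no y-orthogonal systematic variation left
        w_o /= n_wo
        t_o = _row_project(Xw, obs, w_o)
        p_o = _col_regress(Xw, obs, t_o)
        Xw = _deflate(Xw, obs, t_o, p_o)
        T_o.append(t_o)
        P_o.append(p_o)
        W_o.append(w_o)

    w = _col_regress(Xw, obs, yv)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X carries no covariance with y")
    w /= nw
    t = _row_project(Xw, obs, w)
    p = _col_regress(Xw, obs, t)
    q = float(yv @ t / (t @ t))
    E = _deflate(Xw, obs, t, p)
    f = yv - t * q

    k = len(T_o)
    ss_pred = float((np.where(obs, np.outer(t, p), 0.0) ** 2).sum())
    return OplsModel(
        predictive_score=t,
        predictive_loading=p,
        predictive_weight=w,
        predictive_y_loading=q,
        ortho_scores=np.column_stack(T_o) if k else np.zeros((X.n_obs, 0)),
        ortho_loadings=np.column_stack(P_o) if k else np.zeros((X.n_vars, 0)),
        ortho_weights=np.column_stack(W_o) if k else np.zeros((X.n_vars, 0)),
        x_residual=E,
        y_residual=f,
        y_mean_removed=True,
        r2x_pred=ss_pred / ssx0 if ssx0 else 0.0,
        r2x_ortho=1 - (float((E**2).sum()) + ss_pred) / ssx0 if ssx0 else 0.0,
        r2y=1 - float((f**2).sum()) / ssy0 if ssy0 else 0.0,
    )


# ---------------------------------------------------------------------------
# pairwise joint components (multiblock step 1)
# ---------------------------------------------------------------------------


@dataclass
class PairwiseJointSet:
    block_a: str
    block_b: str
    n_joint: int
    scores_a: np.ndarray  # (n, n_joint)
    scores_b: np.ndarray
    loadings_a: np.ndarray  # (pa, n_joint) right/left singular directions
    loadings_b: np.ndarray
    correlations: np.ndarray  # per-component |Pearson| between paired scores
    singular_values: np.ndarray  # all singular values of the cross-product
    sv_fractions: np.ndarray  # fractions of the nuclear norm
    noise_edge: float  # Gaussian-null singular-value edge estimate
    retention_threshold: float = field(default=0.0)

    def scores_for(self, name: str) -> np.ndarray:
        if name == self.block_a:
            return self.scores_a
        if name == self.block_b:
            return self.scores_b
        raise KeyError(name)


def fit_pairwise_joint(
    Xa: BlockMatrix,
    Xb: BlockMatrix,
    sv_fraction_threshold: float = 0.02,
    max_rank: int = 10,
    noise_sv_multiplier: float = 1.3,
    min_score_correlation: float = 0.35,
) -> PairwiseJointSet:
    """Estimate how many latent components two blocks share.

    Both blocks are divided by the square root of their total observed sum
    of squares (equal weight independent of block size), then the SVD of
    Xa'Xb is taken.  A component is retained while all of the following
    hold: its singular value exceeds ``sv_fraction_threshold`` of the
    nuclear norm, it exceeds ``noise_sv_multiplier`` times the analytic
    Gaussian-noise edge (sqrt(pa)+sqrt(pb))/sqrt(n*pa*pb), and the paired
    score correlation is at least ``min_score_correlation``.  An empty
    result (n_joint=0) is a valid outcome, not an error.
    """
    if Xa.obs_ids != Xb.obs_ids:
        raise ValueError("blocks must share identical observation sets")
    if Xa.preprocessing == "raw" or Xb.preprocessing == "raw":
        raise ValueError("blocks must be preprocessed")
    n, pa = Xa.shape
    pb = Xb.n_vars
    A = Xa.filled(0.0)
    B = Xb.filled(0.0)
    ssa, ssb = float((A**2).sum()), float((B**2).sum())
    if ssa == 0 or ssb == 0:
        raise ValueError("block with zero variance")
    An = A / np.sqrt(ssa)
    Bn = B / np.sqrt(ssb)
    C = An.T @ Bn
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    nuclear = float(s.sum())
    fractions = s / nuclear if nuclear > 0 else s
    edge = (np.sqrt(pa) + np.sqrt(pb)) / np.sqrt(n * pa * pb)

    obs_a, obs_b = Xa.observed, Xb.observed
    kept = 0
    corrs = []
    score_cols_a, score_cols_b = [], []
    for k in range(min(len(s), max_rank)):
        if fractions[k] <= sv_fraction_threshold:
            break
        if s[k] <= noise_sv_multiplier * edge:
            break
        # scores by per-row projection over observed cells (zero-residual
        # contract: missing cells exert no leverage on the score)
        ta = _row_project(A, obs_a, U[:, k])
        tb = _row_project(B, obs_b, Vt[k])
        r = abs(_pearson(ta, tb))
        if r < min_score_correlation:
            break
        corrs.append(r)
        score_cols_a.append(ta)
        score_cols_b.append(tb)
        kept += 1

    scores_a = np.column_stack(score_cols_a) if kept else np.zeros((n, 0))
    scores_b = np.column_stack(score_cols_b) if kept else np.zeros((n, 0))
    return PairwiseJointSet(
        block_a=Xa.name,
        block_b=Xb.name,
        n_joint=kept,
        scores_a=scores_a,
        scores_b=scores_b,
        loadings_a=U[:, :kept],
        loadings_b=Vt[:kept].T,
        correlations=np.asarray(corrs),
        singular_values=s,
        sv_fractions=fractions,
        noise_edge=edge,
        retention_threshold=min_score_correlation,
    )
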