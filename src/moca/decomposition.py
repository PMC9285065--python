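"""Multiblock Orthogonal Component Analysis: the five-step decomposition.

Given N preprocessed blocks sharing one observation index, the model splits
every block's variance into globally joint components (shared by all
blocks), locally joint components (shared by a strict subset of at least
two blocks), unique components (systematic structure of a single block) and
an unmodelled residual:

1. pairwise joint fits of all block pairs (``opls.fit_pairwise_joint``);
2. per block, the collected pairwise score vectors are compressed by PCA
   into an orthonormal joint score basis;
3. each block is split into its projection on the (accepted) basis and a
   residual carrying the candidate unique variation;
4. PCA on the residual extracts the unique components;
5. the joint bases of all blocks are re-assessed and divided into global
   and local components by iterative consensus extraction, governed by the
   strictness parameter.

The strictness parameter lies in [-1, 0); a block joins a joint component
only if the absolute correlation of its score vector with the consensus
score (and with every other member's score) is at least 1 + strictness, so
values near 0 are strict and -0.5 is lax.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nipals import PcaModel, nipals_component, nipals_pca, _fix_sign
from .opls import PairwiseJointSet, fit_pairwise_joint, _pearson
from .preprocess import BlockMatrix, MultiBlockData

log = logging.getLogger(__name__)

__all__ = [
    "MocaOptions",
    "MocaComponent",
    "MocaModel",
    "fit_moca",
    "collect_and_compress",
    "split_joint_unique",
    "extract_unique",
    "classify_joint",
    "consensus_and_disagreement",
    "strictness_sweep",
    "sweep_table_pca",
    "save_model",
    "load_model",
]


@dataclass
class MocaOptions:
    """Tunable thresholds of the decomposition (defaults follow the library's
    documented behaviour; all are deterministic, no RNG is used in fitting)."""

    strictness: float = -0.03
    sv_fraction_threshold: float = 0.02
    max_pairwise_rank: int = 10
    noise_sv_multiplier: float = 1.3
    min_score_correlation: float = 0.35
    compression_r2: float = 0.98
    consensus_align_floor: float = 0.35
    unique_r2_threshold: float = 0.02
    unique_edge_multiplier: float = 1.3
    min_local_blocks: int = 2
    nipals_tol: float = 1e-9
    nipals_max_iter: int = 500

    def __post_init__(self) -> None:
        if not (-1.0 <= self.strictness < 0.0):
            raise ValueError(
                f"strictness must lie in [-1, 0); got {self.strictness}"
            )

    @property
    def correlation_threshold(self) -> float:
        return 1.0 + self.strictness


@dataclass
class MocaComponent:
    index: int  # 1-based, model-wide
    kind: str  # "global" | "local" | "unique"
    member_blocks: list[str]
    scores: dict[str, np.ndarray]  # per member block, ||t||^2 = explained SS
    loadings: dict[str, np.ndarray]  # unit-norm per member block
    r2_per_block: dict[str, float]
    consensus_score: np.ndarray
    disagreement: np.ndarray


@dataclass
class MocaModel:
    components: list[MocaComponent]
    block_names: list[str]
    obs_ids: list[str]
    n_obs: int
    r2xj: dict[str, float]
    r2xu: dict[str, float]
    r2_residual: dict[str, float]
    options: MocaOptions

    @property
    def joint_components(self) -> list[MocaComponent]:
        return [c for c in self.components if c.kind in ("global", "local")]

    @property
    def unique_components(self) -> list[MocaComponent]:
        return [c for c in self.components if c.kind == "unique"]

    def component(self, index: int) -> MocaComponent:
        for c in self.components:
            if c.index == index:
                return c
        raise KeyError(index)


# ---------------------------------------------------------------------------
# step 2: compression
# ---------------------------------------------------------------------------


def collect_and_compress(
    block_name: str,
    pairwise_sets: list[PairwiseJointSet],
    r2_threshold: float = 0.98,
) -> np.ndarray:
    """Compress a block's pairwise score vectors into an orthonormal basis.

    All score vectors of ``block_name`` from its pairwise fits are collected
    into one matrix; PCA (via SVD) keeps components until the cumulative
    explained variance reaches ``r2_threshold``.  Returns an (n_obs, m)
    matrix with orthonormal columns; m may be 0 if the block shares nothing.
    """
    cols = []
    n = None
    for ps in pairwise_sets:
        if block_name in (ps.block_a, ps.block_b):
            sc = ps.scores_for(block_name)
            n = sc.shape[0]
            for k in range(ps.n_joint):
                cols.append(sc[:, k])
    if not cols:
        return np.zeros((0 if n is None else n, 0))
    M = np.column_stack(cols)
    M = M - M.mean(axis=0)  # scores of centered blocks; re-center for safety
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if s[0] == 0:
        return np.zeros((M.shape[0], 0))
    r2 = s**2 / (s**2).sum()
    keep = int(np.searchsorted(np.cumsum(r2), r2_threshold) + 1)
    keep = min(keep, int((s > s[0] * 1e-9).sum()))
    return U[:, :keep]


# ---------------------------------------------------------------------------
# step 3: joint/unique split
# ---------------------------------------------------------------------------


def split_joint_unique(
    block: BlockMatrix, joint_basis: np.ndarray
) -> tuple[np.ndarray, BlockMatrix, list[dict]]:
    """Split a block into its projection on a joint score basis and a residual.

    Basis columns are regressed out sequentially (per data column, observed
    cells only), so per-vector explained sums of squares add up exactly.
    Returns (joint part, residual block, per-vector stats); the residual is
    0 at missing cells.
    """
    R = block.filled(0.0)
    observed = block.observed
    original = R.copy()
    stats = []
    for k in range(joint_basis.shape[1]):
        u = joint_basis[:, k]
        denom = (observed * (u**2)[:, None]).sum(axis=0)
        denom[denom == 0] = 1.0
        p = (R * u[:, None]).sum(axis=0) / denom
        layer = np.where(observed, np.outer(u, p), 0.0)
        R = R - layer
        stats.append({"ss_explained": float((layer**2).sum()), "loading": p})
    joint = original - R
    residual_block = BlockMatrix(
        name=block.name,
        values=np.where(observed, R, np.nan),
        missing_mask=block.missing_mask.copy(),
        var_names=list(block.var_names),
        obs_ids=list(block.obs_ids),
        col_means=block.col_means.copy(),
        col_scales=block.col_scales.copy(),
        preprocessing=block.preprocessing,
    )
    return joint, residual_block, stats


# ---------------------------------------------------------------------------
# step 4: unique components
# ---------------------------------------------------------------------------


def extract_unique(
    residual: BlockMatrix,
    original_ss: float | None = None,
    r2_threshold: float = 0.02,
    edge_multiplier: float = 1.3,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """PCA on a residual block, keeping only components above the noise floor.

    A component is kept while it explains at least ``r2_threshold`` of the
    ORIGINAL block's observed sum of squares and its singular value exceeds
    ``edge_multiplier`` times the Gaussian-noise top-singular-value estimate
    sd*(sqrt(n)+sqrt(p)) with sd^2 taken from the current residual.
    Returns (score, unit loading, r2) triples.
    """
    X = residual.filled(0.0)
    observed = residual.observed
    n, p = X.shape
    if original_ss is None:
        original_ss = float((X**2).sum())
    if original_ss == 0:
        return []
    out = []
    for _ in range(min(n, p)):
        ss_before = float((X**2).sum())
        n_cells = int(observed.sum())
        if ss_before <= original_ss * 1e-12 or n_cells == 0:
            break
        t, pv, _, conv = nipals_component(X, observed, tol=tol, max_iter=max_iter)
        if not np.any(pv):
            break
        t, pv = _fix_sign(t, pv)
        layer = np.where(observed, np.outer(t, pv), 0.0)
        explained = float((layer**2).sum())
        sd2 = ss_before / n_cells
        edge_ss = sd2 * (np.sqrt(n) + np.sqrt(p)) ** 2
        r2 = explained / original_ss
        if r2 < r2_threshold or explained < (edge_multiplier**2) * edge_ss:
            break
        X = X - layer
        out.append((t, pv, r2))
    return out


# ---------------------------------------------------------------------------
# step 5: global/local classification
# ---------------------------------------------------------------------------


def classify_joint(
    bases: dict[str, np.ndarray],
    strictness: float,
    n_blocks_total: int | None = None,
    min_local_blocks: int = 2,
    align_floor: float = 0.35,
) -> list[dict]:
    """Divide block joint bases into global and local consensus components.

    Iteratively: the first principal direction across all remaining basis
    vectors proposes a consensus score; each block answers with its
    best-matching direction (the normalized projection of the consensus
    onto the block's remaining basis span, so matching is invariant to how
    the compression happened to rotate the basis).  A block becomes a
    *member* if the |correlation| of its matched direction with the
    consensus reaches 1 + strictness; members are then pruned until every
    pair of member scores also satisfies the bound.  A component is emitted
    when at least ``min_local_blocks`` members remain (global if all blocks
    joined, local otherwise).

    Every block whose matched direction is structurally aligned with the
    candidate (|correlation| >= ``align_floor``) has that direction deflated
    from its basis, member or not: non-member variance is thereby routed
    back to the block's unique pool.  Because both the candidate sequence
    and the deflations depend only on ``align_floor`` (never on
    strictness), memberships are nested across strictness values, which
    makes each block's joint explained variance non-decreasing as the
    strictness relaxes.  Deflation of at least one direction per round
    guarantees termination.

    Returns a list of dicts with keys kind ("global"/"local"/"discarded"),
    members: {block: matched unit score direction}, consensus: candidate
    consensus score.
    """
    thr = 1.0 + strictness
    if n_blocks_total is None:
        n_blocks_total = len(bases)
    work = {name: b.copy() for name, b in bases.items()}
    results: list[dict] = []

    def _deflate_direction(name: str, v: np.ndarray) -> None:
        # orthonormal basis of the span with the matched direction removed
        B = work[name]
        resid = B - np.outer(v, v @ B)
        U2, s2, _ = np.linalg.svd(resid, full_matrices=False)
        keep = s2 > (s2[0] if s2.size else 0.0) * 1e-8
        work[name] = U2[:, keep] if s2.size and s2[0] > 1e-12 else B[:, :0]

    while True:
        remaining = [b for b in work.values() if b.shape[1] > 0]
        if not remaining:
            break
        M = np.column_stack(remaining)
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        consensus = U[:, 0]

        matched: dict[str, tuple[float, np.ndarray]] = {}
        for name, B in work.items():
            if B.shape[1] == 0:
                continue
            proj = B @ (B.T @ consensus)
            norm = np.linalg.norm(proj)
            if norm <= 1e-12:
                continue
            v = proj / norm
            matched[name] = (abs(_pearson(v, consensus)), v)

        aligned = {n: b for n, b in matched.items() if b[0] >= align_floor}
        if not aligned:
            # candidate aligns with no single block above the floor: consume
            # the best-matching direction so the iteration always progresses
            name, (_, v) = max(matched.items(), key=lambda kv: kv[1][0])
            results.append(
                {"kind": "discarded", "members": {name: v}, "consensus": consensus}
            )
            _deflate_direction(name, v)
            continue

        members = {n: b for n, b in aligned.items() if b[0] >= thr}
        # enforce the pairwise member-correlation bound: drop weakest members
        while len(members) >= 2:
            names = list(members)
            pair_min = {}
            ok = True
            for a in names:
                worst = min(
                    abs(_pearson(members[a][1], members[b][1]))
                    for b in names
                    if b != a
                )
                pair_min[a] = worst
                if worst < thr:
                    ok = False
            if ok:
                break
            weakest = min(names, key=lambda a: (pair_min[a], members[a][0]))
            del members[weakest]

        if len(members) >= min_local_blocks:
            kind = "global" if len(members) == n_blocks_total else "local"
            results.append(
                {
                    "kind": kind,
                    "members": {n: v for n, (_, v) in members.items()},
                    "consensus": consensus,
                }
            )
        else:
            results.append(
                {
                    "kind": "discarded",
                    "members": {n: v for n, (_, v) in aligned.items()},
                    "consensus": consensus,
                }
            )
        for n_, (_, v) in aligned.items():
            _deflate_direction(n_, v)
    return results


def consensus_and_disagreement(
    scores: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Average of aligned member score vectors and per-observation spread.

    Member scores are scaled to unit variance and sign-aligned to the first
    member; the consensus is their elementwise mean, and the disagreement at
    observation i is the RMS deviation of member scores from the consensus.
    """
    names = list(scores)
    if not names:
        raise ValueError("no member scores")
    mats = []
    ref = None
    for n_ in names:
        s = np.asarray(scores[n_], dtype=float)
        sd = s.std(ddof=1)
        s = s / sd if sd > 0 else s * 0.0
        if ref is None:
            ref = s
        elif _pearson(s, ref) < 0:
            s = -s
        mats.append(s)
    S = np.column_stack(mats)
    consensus = S.mean(axis=1)
    disagreement = np.sqrt(((S - consensus[:, None]) ** 2).mean(axis=1))
    return consensus, disagreement


# ---------------------------------------------------------------------------
# the full fit
# ---------------------------------------------------------------------------


def _prepare(data: MultiBlockData, options: MocaOptions):
    """Steps 1-2 (strictness-independent): pairwise fits and compressed bases."""
    if len(data) < 2:
        raise ValueError("MOCA requires at least 2 blocks")
    for b in data:
        if b.preprocessing == "raw":
            raise ValueError(f"block {b.name!r} must be preprocessed")
        if b.total_ss() == 0:
            raise ValueError(f"block {b.name!r} has zero variance")
    names = data.block_names
    pair_sets = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair_sets.append(
                fit_pairwise_joint(
                    data[names[i]],
                    data[names[j]],
                    sv_fraction_threshold=options.sv_fraction_threshold,
                    max_rank=options.max_pairwise_rank,
                    noise_sv_multiplier=options.noise_sv_multiplier,
                    min_score_correlation=options.min_score_correlation,
                )
            )
    bases = {
        n_: collect_and_compress(n_, pair_sets, options.compression_r2)
        for n_ in names
    }
    for n_ in names:
        if bases[n_].shape[0] == 0:  # block appeared in no pairwise set at all
            bases[n_] = np.zeros((data.n_obs, 0))
    return pair_sets, bases


def _finalize(
    data: MultiBlockData, bases: dict[str, np.ndarray], options: MocaOptions
) -> MocaModel:
    """Steps 3-5 for a given strictness: classify, split, extract unique."""
    names = data.block_names
    n_obs = data.n_obs
    classified = classify_joint(
        bases, options.strictness, n_blocks_total=len(names),
        min_local_blocks=options.min_local_blocks,
        align_floor=options.consensus_align_floor,
    )
    joint_groups = [c for c in classified if c["kind"] in ("global", "local")]

    # per block: the accepted basis vectors, in joint-group order
    accepted: dict[str, list[tuple[int, np.ndarray]]] = {n_: [] for n_ in names}
    for gi, grp in enumerate(joint_groups):
        for n_, v in grp["members"].items():
            accepted[n_].append((gi, v))

    block_stats: dict[str, dict] = {}
    unique_per_block: dict[str, list] = {}
    for n_ in names:
        block = data[n_]
        ss0 = block.total_ss()
        vecs = [v for (_, v) in accepted[n_]]
        basis = np.column_stack(vecs) if vecs else np.zeros((n_obs, 0))
        _, residual, stats = split_joint_unique(block, basis)
        per_group = {}
        for (gi, _), st in zip(accepted[n_], stats):
            per_group[gi] = {
                "r2": st["ss_explained"] / ss0,
                "loading": st["loading"],
            }
        block_stats[n_] = {"ss0": ss0, "per_group": per_group}
        unique_per_block[n_] = extract_unique(
            residual,
            original_ss=ss0,
            r2_threshold=options.unique_r2_threshold,
            edge_multiplier=options.unique_edge_multiplier,
            tol=options.nipals_tol,
            max_iter=options.nipals_max_iter,
        )

    # assemble components: global (desc. mean r2), local (desc.), unique per block
    def group_component(gi: int, grp: dict) -> MocaComponent:
        members = sorted(grp["members"], key=names.index)
        scores, loadings, r2pb = {}, {}, {}
        for n_ in members:
            st = block_stats[n_]["per_group"][gi]
            u = grp["members"][n_]
            p = st["loading"]
            norm_p = np.linalg.norm(p)
            t = u * norm_p  # ||t||^2 = explained SS when basis vector is unit norm
            if norm_p > 0:
                p = p / norm_p
            t, p = _fix_sign(t, p)
            scores[n_] = t
            loadings[n_] = p
            r2pb[n_] = st["r2"]
        consensus, disagreement = consensus_and_disagreement(scores)
        return MocaComponent(
            index=0,
            kind=grp["kind"],
            member_blocks=members,
            scores=scores,
            loadings=loadings,
            r2_per_block=r2pb,
            consensus_score=consensus,
            disagreement=disagreement,
        )

    globals_ = [
        group_component(gi, grp)
        for gi, grp in enumerate(joint_groups)
        if grp["kind"] == "global"
    ]
    locals_ = [
        group_component(gi, grp)
        for gi, grp in enumerate(joint_groups)
        if grp["kind"] == "local"
    ]
    mean_r2 = lambda c: float(np.mean(list(c.r2_per_block.values())))
    globals_.sort(key=mean_r2, reverse=True)
    locals_.sort(key=mean_r2, reverse=True)

    uniques = []
    for n_ in names:
        for t, p, r2 in unique_per_block[n_]:
            uniques.append(
                MocaComponent(
                    index=0,
                    kind="unique",
                    member_blocks=[n_],
                    scores={n_: t},
                    loadings={n_: p},
                    r2_per_block={n_: r2},
                    consensus_score=t / (t.std(ddof=1) or 1.0),
                    disagreement=np.zeros(n_obs),
                )
            )

    components = globals_ + locals_ + uniques
    for i, c in enumerate(components, start=1):
        c.index = i

    r2xj = {n_: 0.0 for n_ in names}
    r2xu = {n_: 0.0 for n_ in names}
    for c in components:
        for n_, r2 in c.r2_per_block.items():
            if c.kind == "unique":
                r2xu[n_] += r2
            else:
                r2xj[n_] += r2
    r2_res = {n_: 1.0 - r2xj[n_] - r2xu[n_] for n_ in names}

    return MocaModel(
        components=components,
        block_names=names,
        obs_ids=list(data.obs_ids),
        n_obs=n_obs,
        r2xj=r2xj,
        r2xu=r2xu,
        r2_residual=r2_res,
        options=options,
    )


def fit_moca(data: MultiBlockData, options: MocaOptions | None = None) -> MocaModel:
    """Fit the full five-step multiblock decomposition."""
    options = options or MocaOptions()
    _, bases = _prepare(data, options)
    return _finalize(data, bases, options)


# ---------------------------------------------------------------------------
# strictness sweep meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    table: pd.DataFrame  # rows = strictness conditions, columns = blocks (R2Xj)
    pca: PcaModel | None
    models: dict[float, MocaModel] = field(default_factory=dict)


def sweep_table_pca(table: pd.DataFrame, n_components: int = 2) -> PcaModel:
    """Center-only PCA on a conditions-by-blocks joint-variance table."""
    from .preprocess import center_scale

    block = BlockMatrix(
        name="r2xj_table",
        values=table.to_numpy(dtype=float),
        missing_mask=None,
        var_names=[str(c) for c in table.columns],
        obs_ids=[str(i) for i in table.index],
        preprocessing="raw",
    )
    centered = center_scale(block, "center_only")
    return nipals_pca(centered, n_components=min(n_components, min(block.shape)))


def strictness_sweep(
    data: MultiBlockData,
    strictness_values: list[float],
    options: MocaOptions | None = None,
    n_pca_components: int = 2,
) -> SweepResult:
    """Refit the decomposition over a grid of strictness values.

    The strictness parameter only affects the classification step, so the
    pairwise fits and compression are computed once and reclassified per
    value.  The per-block fraction of joint variation (R2Xj) is tabulated
    (one row per condition) and summarized by a center-only PCA.
    """
    base = options or MocaOptions()
    _, bases = _prepare(data, base)
    rows = {}
    models = {}
    for s in strictness_values:
        opts = MocaOptions(**{**asdict(base), "strictness": s})
        model = _finalize(data, bases, opts)
        rows[s] = model.r2xj
        models[s] = model
    table = pd.DataFrame(
        [[rows[s][b] for b in data.block_names] for s in strictness_values],
        index=pd.Index(strictness_values, name="strictness"),
        columns=data.block_names,
    )
    pca = None
    if len(strictness_values) >= 2:
        pca = sweep_table_pca(table, n_components=n_pca_components)
    else:
        warnings.warn("single strictness value: PCA on the sweep table skipped")
    return SweepResult(table=table, pca=pca, models=models)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def save_model(model: MocaModel, out_dir: str | Path) -> Path:
    """Serialize a fitted model: model.json + TSV score/loading tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    score_cols = {}
    for c in model.components:
        for n_ in c.member_blocks:
            score_cols[f"c{c.index}:{n_}"] = c.scores[n_]
        score_cols[f"c{c.index}:consensus"] = c.consensus_score
        score_cols[f"c{c.index}:disagreement"] = c.disagreement
    scores_df = pd.DataFrame(score_cols, index=pd.Index(model.obs_ids, name="obs_id"))
    _write_tsv(out / "scores.tsv", scores_df)

    loading_files = {}
    for n_ in model.block_names:
        cols = {
            f"c{c.index}": c.loadings[n_]
            for c in model.components
            if n_ in c.member_blocks
        }
        if cols:
            fname = f"loadings_{n_}.tsv"
            _write_tsv(out / fname, pd.DataFrame(cols))
            loading_files[n_] = fname

    doc = {
        "format": "moca-model/1",
        "options": asdict(model.options),
        "n_obs": model.n_obs,
        "block_names": model.block_names,
        "r2xj": model.r2xj,
        "r2xu": model.r2xu,
        "r2_residual": model.r2_residual,
        "scores_file": "scores.tsv",
        "loading_files": loading_files,
        "components": [
            {
                "index": c.index,
                "kind": c.kind,
                "member_blocks": c.member_blocks,
                "r2_per_block": c.r2_per_block,
            }
            for c in model.components
        ],
    }
    (out / "model.json").write_text(json.dumps(doc, indent=2))
    return out / "model.json"


def load_model(model_dir: str | Path) -> MocaModel:
    """Reload a serialized model (scores/loadings read back from the TSVs)."""
    d = Path(model_dir)
    doc = json.loads((d / "model.json").read_text())
    scores_df = pd.read_csv(d / doc["scores_file"], sep="\t", index_col=0)
    loadings = {
        n_: pd.read_csv(d / f, sep="\t", index_col=0)
        for n_, f in doc["loading_files"].items()
    }
    components = []
    for cd in doc["components"]:
        idx = cd["index"]
        sc = {n_: scores_df[f"c{idx}:{n_}"].to_numpy() for n_ in cd["member_blocks"]}
        ld = {
            n_: loadings[n_][f"c{idx}"].to_numpy()
            for n_ in cd["member_blocks"]
            if n_ in loadings and f"c{idx}" in loadings[n_]
        }
        components.append(
            MocaComponent(
                index=idx,
                kind=cd["kind"],
                member_blocks=cd["member_blocks"],
                scores=sc,
                loadings=ld,
                r2_per_block=cd["r2_per_block"],
                consensus_score=scores_df[f"c{idx}:consensus"].to_numpy(),
                disagreement=scores_df[f"c{idx}:disagreement"].to_numpy(),
            )
        )
    return MocaModel(
        components=components,
        block_names=doc["block_names"],
        obs_ids=[str(i) for i in scores_df.index],
        n_obs=doc["n_obs"],
        r2xj=doc["r2xj"],
        r2xu=doc["r2xu"],
        r2_residual=doc["r2_residual"],
        options=MocaOptions(**doc["options"]),
    )
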