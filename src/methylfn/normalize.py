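"""Two-step functional normalization with fixed/random effects and CV.

Step 1 (cross-sample): for every quantile subset and every quantile index,
probe-intensity quantiles are regressed on the top principal components of
the 42 x n control matrix (plus optional fixed effects and random
intercepts); the technical contribution is removed, retaining the grand
level plus the unexplained (biological) residual as each sample's
*normalized quantiles*.

Step 2 (per sample): each sample's probe intensities are mapped through a
monotone interpolation from its own empirical quantile function to its
normalized quantiles.  This step needs only the sample itself and its
targets, so samples can be finalized one at a time, in any order, on any
server — the streaming / federated contract.  All cross-sample reductions in
step 1 run over samples sorted by id, so results are bit-identical under any
input permutation or partition.

Degenerate case: with zero principal components and no effects the model is
empty and every sample's target is the per-index cross-sample mean — i.e.
classical between-sample quantile normalization per subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CONTROL_TYPES, Manifest, RawDataset, RawSample  # noqa: F401
from .qc import SUBSET_KEYS, QCObject, build_control_matrix, build_qc_object, noob_correct
from .qc import _subset_masks  # shared subset definition

__all__ = [
    "ControlPCA",
    "NormalizationModel",
    "NormalizedQuantiles",
    "NormalizationResult",
    "control_pca",
    "fit_quantile_model",
    "finalize_sample",
    "compute_beta",
    "betas_for_sample",
    "normalize_dataset",
    "select_pcs_cv",
]

_DEFAULT_BETA_OFFSET = 100.0


# ---------------------------------------------------------------------------
# Control-matrix PCA
# ---------------------------------------------------------------------------


@dataclass
class ControlPCA:
    """Row-standardized PCA of a control matrix.

    Control types have wildly different intensity scales, so each of the 42
    rows is centered and scaled before the SVD.  ``project`` maps new
    samples' control summaries onto the fitted loadings.
    """

    k: int
    center: pd.Series  # 42-vector
    scale: pd.Series  # 42-vector
    loadings: np.ndarray  # 42 x k

    def project(self, control_matrix: pd.DataFrame) -> np.ndarray:
        Z = ((control_matrix.reindex(list(CONTROL_TYPES)).T - self.center) / self.scale)
        return Z.to_numpy() @ self.loadings


def fit_control_pca(control_matrix: pd.DataFrame, k: int) -> tuple[np.ndarray, ControlPCA]:
    """SVD scores of the column-centered, row-scaled control matrix.

    Returns (scores n x k, fitted ControlPCA).  Scores are orthogonal and
    ordered by decreasing variance; component signs are fixed so the largest
    |loading| of each component is positive.
    """
    n = control_matrix.shape[1]
    if n < 2:
        raise ValueError("control PCA needs at least 2 samples")
    if not 0 <= k <= min(42, n - 1):
        raise ValueError(f"k must be in [0, min(42, n-1)] = [0, {min(42, n - 1)}], got {k}")
    M = control_matrix.reindex(list(CONTROL_TYPES))
    center = M.mean(axis=1)
    scale = M.std(axis=1, ddof=1).replace(0.0, 1.0).fillna(1.0)
    Z = ((M.T - center) / scale).to_numpy()  # n x 42, columns centered
    if k == 0:
        return np.zeros((n, 0)), ControlPCA(0, center, scale, np.zeros((42, 0)))
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt[:k].T  # 42 x k
    sign = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(k)])
    sign[sign == 0] = 1.0
    V = V * sign
    scores = Z @ V
    return scores, ControlPCA(k, center, scale, V)


def control_pca(control_matrix: pd.DataFrame, k: int) -> np.ndarray:
    """Sample scores (n x k) on the top control-matrix principal components."""
    scores, _ = fit_control_pca(control_matrix, k)
    return scores


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _fixed_design(qc_sorted: Sequence[QCObject], fixed) -> pd.DataFrame:
    """Dummy-coded fixed-effect design (no intercept column).

    ``fixed`` may be a list of batch-variable names (dummy-coded, first
    level dropped) or a numeric DataFrame indexed by sample id.
    """
    ids = [qc.sample_id for qc in qc_sorted]
    if fixed is None:
        return pd.DataFrame(index=ids)
    if isinstance(fixed, pd.DataFrame):
        missing = set(ids) - set(fixed.index)
        if missing:
            raise ValueError(f"fixed-effect design missing samples: {sorted(missing)[:5]}")
        return fixed.loc[ids].astype(float)
    cols = {}
    for name in fixed:
        levels = pd.Series([qc.batch.get(name) for qc in qc_sorted], index=ids)
        if levels.isna().any():
            raise ValueError(f"batch variable {name!r} missing for some samples")
        dummies = pd.get_dummies(levels, prefix=name, dtype=float)
        dummies = dummies[sorted(dummies.columns)]
        cols[name] = dummies.iloc[:, 1:]  # drop first level
    if not cols:
        return pd.DataFrame(index=ids)
    return pd.concat(cols.values(), axis=1)


def _check_design(design: pd.DataFrame) -> None:
    """Reject singular designs, naming the collinear columns.

    The typical failure is a batch variable whose induced group sizes are
    too small to be modelled as a fixed effect.
    """
    if design.shape[1] == 0:
        return
    X = np.column_stack([np.ones(len(design)), design.to_numpy()])
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # greedy identification of columns that add no rank
    bad = []
    cur = np.ones((len(design), 1))
    for j, col in enumerate(design.columns):
        cand = np.column_stack([cur, design.to_numpy()[:, j]])
        if np.linalg.matrix_rank(cand) > cur.shape[1]:
            cur = cand
        else:
            bad.append(str(col))
    raise ValueError(
        "singular fixed-effect design; collinear columns: "
        f"{bad}. It was not possible to model these as fixed effects "
        "(induced group sizes may be too small)."
    )


def _random_groups(qc_sorted: Sequence[QCObject], random) -> dict[str, pd.Series]:
    ids = [qc.sample_id for qc in qc_sorted]
    groups = {}
    for name in (random or []):
        levels = pd.Series([qc.batch.get(name) for qc in qc_sorted], index=ids)
        if levels.isna().any():
            raise ValueError(f"random-effect variable {name!r} missing for some samples")
        sizes = levels.value_counts()
        if len(sizes) < 2 or (sizes < 2).any():
            raise ValueError(
                f"random-effect variable {name!r} needs >=2 levels with >=2 samples each; "
                f"got sizes {dict(sizes)}"
            )
        groups[name] = levels
    return groups


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class NormalizedQuantiles:
    """Per-sample target quantiles after step-1 normalization.

    Sufficient — together with the sample's own raw intensities — to finish
    normalizing that sample alone.
    """

    sample_id: str
    targets: dict[str, np.ndarray]

    def to_dict(self) -> dict:
        return {"sample_id": self.sample_id,
                "targets": {k: [float(x) for x in np.asarray(v)]
                            for k, v in self.targets.items()}}

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizedQuantiles":
        return cls(sample_id=d["sample_id"],
                   targets={k: np.asarray(v, dtype=float)
                            for k, v in d["targets"].items()})


@dataclass
class NormalizationModel:
    n_pcs: int
    pca: ControlPCA
    fixed_columns: list[str]
    random_effects: list[str]
    coefficients: dict[str, np.ndarray] = field(default_factory=dict)  # subset -> (1+p) x n_q


# ---------------------------------------------------------------------------
# Random-intercept REML machinery
# ---------------------------------------------------------------------------

_LOGLAM_GRID = np.arange(-10.0, 10.5, 0.5)


def _reml_random_intercept(Y: np.ndarray, X: np.ndarray, Z: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Fit y_j = X b + Z u + e per column j with a single random intercept.

    The variance ratio lambda = var(u)/var(e) is estimated per column by
    profiled REML on a log-scale grid (step 0.5), using one shared
    eigendecomposition of ZZ'.  Columns whose REML optimum is at lambda=0
    degrade gracefully to the fixed-effect-only fit.

    Returns (B fixed coefficients p x n_q, Zu n x n_q random contributions).
    """
    n, p = X.shape
    n_q = Y.shape[1]
    d, Q = np.linalg.eigh(Z @ Z.T)
    d = np.maximum(d, 0.0)
    Xt = Q.T @ X
    Yt = Q.T @ Y

    lams = np.concatenate([[0.0], np.exp(_LOGLAM_GRID)])
    crit = np.empty((len(lams), n_q))
    for li, lam in enumerate(lams):
        w = 1.0 / (1.0 + lam * d)
        XtW = Xt * w[:, None]
        G = Xt.T @ XtW
        B = np.linalg.solve(G, XtW.T @ Yt)
        R = Yt - Xt @ B
        rss = np.einsum("ij,ij->j", R * w[:, None], R)
        rss = np.maximum(rss, 1e-300)
        sign, logdetG = np.linalg.slogdet(G)
        crit[li] = (np.sum(np.log1p(lam * d)) + logdetG
                    + (n - p) * np.log(rss))
    best = np.argmin(crit, axis=0)

    Bout = np.empty((p, n_q))
    Zu = np.zeros((n, n_q))
    for li in np.unique(best):
        cols = np.flatnonzero(best == li)
        lam = lams[li]
        w = 1.0 / (1.0 + lam * d)
        XtW = Xt * w[:, None]
        G = Xt.T @ XtW
        B = np.linalg.solve(G, XtW.T @ Yt[:, cols])
        Bout[:, cols] = B
        if lam > 0:
            R = Yt[:, cols] - Xt @ B
            # BLUP: u = lam Z' V^{-1} r,  V^{-1} r = Q diag(w) Q' r
            Zu[:, cols] = lam * (Z @ (Z.T @ (Q @ (w[:, None] * R))))
    return Bout, Zu


def _reml_multi(Y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray]
                ) -> tuple[np.ndarray, np.ndarray]:
    """Generic REML for several random intercepts (slower path)."""
    from scipy.optimize import minimize

    n, p = X.shape
    n_q = Y.shape[1]
    As = [Z @ Z.T for Z in Zs]

    Bout = np.empty((p, n_q))
    Zu_out = np.zeros((n, n_q))
    for j in range(n_q):
        y = Y[:, j]

        def neg2reml(loglams: np.ndarray) -> float:
            V = np.eye(n)
            for ll, A in zip(loglams, As):
                V = V + np.exp(ll) * A
            try:
                c = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e30
            logdetV = 2.0 * np.sum(np.log(np.diag(c)))
            Vi_X = np.linalg.solve(V, X)
            G = X.T @ Vi_X
            beta = np.linalg.solve(G, Vi_X.T @ y)
            r = y - X @ beta
            rss = float(r @ np.linalg.solve(V, r))
            s, logdetG = np.linalg.slogdet(G)
            return logdetV + logdetG + (n - p) * np.log(max(rss, 1e-300))

        x0 = np.zeros(len(Zs))
        res = minimize(neg2reml, x0, method="Nelder-Mead",
                       options={"xatol": 0.05, "fatol": 1e-6, "maxiter": 200})
        lams = np.exp(res.x)
        ols_crit = neg2reml(np.full(len(Zs), -30.0))
        if ols_crit <= res.fun:
            lams = np.zeros(len(Zs))
        V = np.eye(n)
        for lam, A in zip(lams, As):
            V = V + lam * A
        Vi_X = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, Vi_X.T @ y)
        r = y - X @ beta
        Vi_r = np.linalg.solve(V, r)
        zu = np.zeros(n)
        for lam, Z in zip(lams, Zs):
            zu += lam * (Z @ (Z.T @ Vi_r))
        Bout[:, j] = beta
        Zu_out[:, j] = zu
    return Bout, Zu_out


# ---------------------------------------------------------------------------
# Step 1: quantile model
# ---------------------------------------------------------------------------


def fit_quantile_model(qc_objects: Sequence[QCObject], k: int,
                       fixed=None, random: Sequence[str] | None = None
                       ) -> tuple[NormalizationModel, list[NormalizedQuantiles]]:
    """Normalize probe-intensity quantiles across samples.

    For each subset and quantile index, fits
    ``quantile ~ 1 + k control PCs + fixed effects (+ random intercepts)``
    and retains ``intercept + residual`` (technical contributions removed,
    grand level kept) as the sample's normalized quantile, monotonized by
    sorting.  With ``k=0`` and no effects the target is the cross-sample
    mean per index: classical quantile normalization.

    All reductions run over samples sorted by id, so the result is invariant
    (bit-exact) under input permutation.
    """
    if len(qc_objects) < 3:
        raise ValueError("quantile normalization needs at least 3 samples")
    ids = [qc.sample_id for qc in qc_objects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids among QC objects")
    order = np.argsort(np.asarray(ids, dtype=object))
    qc_sorted = [qc_objects[i] for i in order]
    sorted_ids = [qc.sample_id for qc in qc_sorted]

    ctrl = build_control_matrix(qc_sorted)
    scores, pca = fit_control_pca(ctrl, k)
    fixed_df = _fixed_design(qc_sorted, fixed)
    design = pd.DataFrame(scores, index=sorted_ids,
                          columns=[f"pc{i+1}" for i in range(k)])
    design = pd.concat([design, fixed_df], axis=1)
    _check_design(design)
    groups = _random_groups(qc_sorted, random)
    Zs = []
    for name, levels in groups.items():
        Zs.append(pd.get_dummies(levels, dtype=float).to_numpy())

    n = len(qc_sorted)
    D = design.to_numpy()
    X = np.column_stack([np.ones(n), D])
    empty_model = D.shape[1] == 0 and not Zs

    n_q = qc_sorted[0].n_q
    model = NormalizationModel(n_pcs=k, pca=pca,
                               fixed_columns=[str(c) for c in design.columns[k:]],
                               random_effects=list(groups.keys()))
    targets_by_sample: dict[str, dict[str, np.ndarray]] = {sid: {} for sid in sorted_ids}

    for key in SUBSET_KEYS:
        vecs = [np.asarray(qc.quantiles.get(key, [])) for qc in qc_sorted]
        sizes = {v.size for v in vecs}
        if sizes == {0}:
            for sid in sorted_ids:
                targets_by_sample[sid][key] = np.array([])
            continue
        if 0 in sizes:
            raise ValueError(f"subset {key} empty for some samples but not others")
        Y = np.vstack(vecs)  # n x n_q
        if empty_model:
            mean = Y.mean(axis=0)
            norm = np.tile(mean, (n, 1))
            model.coefficients[key] = mean[None, :]
        else:
            if not Zs:
                B, *_ = np.linalg.lstsq(X, Y, rcond=None)
                Zu = np.zeros_like(Y)
            elif len(Zs) == 1:
                B, Zu = _reml_random_intercept(Y, X, Zs[0])
            else:
                B, Zu = _reml_multi(Y, X, Zs)
            model.coefficients[key] = B
            # remove PC/fixed/random contributions, keep intercept + residual
            norm = Y - D @ B[1:, :] - Zu
        norm = np.sort(norm, axis=1)  # monotonization by isotonic pooling
        for i, sid in enumerate(sorted_ids):
            targets_by_sample[sid][key] = norm[i]

    normalized = [NormalizedQuantiles(sample_id=sid, targets=targets_by_sample[sid])
                  for sid in ids]
    return model, normalized


# ---------------------------------------------------------------------------
# Step 2: per-sample finalization
# ---------------------------------------------------------------------------


def finalize_sample(sample: RawSample, targets: NormalizedQuantiles,
                    manifest: Manifest) -> tuple[pd.Series, pd.Series]:
    """Adjust one (noob-corrected) sample's intensities to its targets.

    Within each subset, intensities are mapped through piecewise-linear
    interpolation from the sample's empirical quantile function to the
    target quantiles (constant extrapolation beyond the extreme knots);
    ranks within a subset are preserved.  Uses only this sample and its
    targets — the order-independence contract of streaming / federated
    normalization.  SNP probes are carried through unchanged.
    """
    masks, cpg_ids = _subset_masks(manifest)
    meth = sample.meth.copy()
    unmeth = sample.unmeth.copy()
    meth_cpg = meth.reindex(cpg_ids).to_numpy()
    unmeth_cpg = unmeth.reindex(cpg_ids).to_numpy()
    out = {"meth": meth_cpg.copy(), "unmeth": unmeth_cpg.copy()}

    for key in SUBSET_KEYS:
        mask = masks[key]
        if not mask.any():
            continue
        if key not in targets.targets or np.asarray(targets.targets[key]).size == 0:
            raise ValueError(f"missing normalized-quantile targets for subset {key}")
        tgt = np.asarray(targets.targets[key], dtype=float)
        signal = key.split(".")[1]
        x = (meth_cpg if signal == "meth" else unmeth_cpg)[mask]
        probs = np.linspace(0.0, 1.0, tgt.size)
        own = np.quantile(x, probs)
        # residual-based targets can dip below zero; intensities stay >= 0
        out[signal][mask] = np.maximum(np.interp(x, own, tgt), 0.0)

    meth.loc[cpg_ids] = out["meth"]
    unmeth.loc[cpg_ids] = out["unmeth"]
    return meth, unmeth


def compute_beta(meth, unmeth, offset: float = _DEFAULT_BETA_OFFSET):
    """Infinium beta value ``meth / (meth + unmeth + offset)`` in [0, 1)."""
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if offset <= 0:
        raise ValueError("offset must be positive")
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValueError("intensities must be non-negative")
    return meth / (meth + unmeth + offset)


def betas_for_sample(meth: pd.Series, unmeth: pd.Series,
                     offset: float = _DEFAULT_BETA_OFFSET) -> pd.Series:
    return pd.Series(compute_beta(meth.to_numpy(), unmeth.to_numpy(), offset),
                     index=meth.index)


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------


@dataclass
class NormalizationResult:
    betas: pd.DataFrame  # probes x samples
    targets: dict[str, NormalizedQuantiles]
    model: NormalizationModel
    qc_objects: list[QCObject]


def normalize_dataset(dataset: RawDataset, k: int = 2, fixed=None,
                      random: Sequence[str] | None = None, n_q: int = 500,
                      offset: float = _DEFAULT_BETA_OFFSET,
                      qc_objects: Sequence[QCObject] | None = None
                      ) -> NormalizationResult:
    """QC-object construction, step-1 fit, and per-sample finalization."""
    manifest = dataset.manifest
    if qc_objects is None:
        qc_objects = [build_qc_object(s, manifest, n_q=n_q) for s in dataset.samples]
    model, targets = fit_quantile_model(qc_objects, k, fixed=fixed, random=random)
    by_id = {t.sample_id: t for t in targets}
    cols = {}
    for s in dataset.samples:
        corrected = noob_correct(s, manifest)
        meth, unmeth = finalize_sample(corrected, by_id[s.sample_id], manifest)
        cols[s.sample_id] = betas_for_sample(meth, unmeth, offset)
    betas = pd.DataFrame(cols)
    return NormalizationResult(betas=betas, targets=by_id, model=model,
                               qc_objects=list(qc_objects))


# ---------------------------------------------------------------------------
# Cross-validated selection of the number of PCs
# ---------------------------------------------------------------------------


def select_pcs_cv(qc_objects: Sequence[QCObject], k_candidates: Sequence[int],
                  n_folds: int = 10, fixed=None,
                  random: Sequence[str] | None = None, seed: int = 0,
                  autosomal_only: bool = True,
                  n_repeats: int = 1) -> tuple[int, pd.DataFrame]:
    """Pick the PC count minimizing held-out residual quantile variance.

    Samples are partitioned into ``n_folds`` folds by a seeded shuffle; for
    each candidate k, PC loadings and regression coefficients are fitted on
    the training folds only, held-out samples are projected onto the
    training loadings, and the fraction of held-out quantile variation left
    unexplained is recorded per subset (scale-free, so no single
    high-intensity subset dominates) and averaged.  Returns the k minimizing
    the mean CV residual-variance fraction
    (smallest k within machine tolerance of the minimum) plus the scree
    table.  Candidates exceeding the training-fold capacity are dropped with
    a warning.

    By default the metric uses autosomal subsets only: sex-chromosome
    quantile variation is dominated by sample sex, which control probes
    cannot (and should not) explain.  ``n_repeats`` averages the scree over
    that many independent fold splits, stabilizing the argmin when the curve
    is nearly flat beyond the optimum.
    """
    n = len(qc_objects)
    if not 2 <= n_folds <= n:
        raise ValueError(f"need n_samples >= n_folds >= 2; got n={n}, folds={n_folds}")
    ids = [qc.sample_id for qc in qc_objects]
    order = np.argsort(np.asarray(ids, dtype=object))
    qc_sorted = [qc_objects[i] for i in order]
    sorted_ids = [qc.sample_id for qc in qc_sorted]

    rng = np.random.default_rng(seed)
    folds_per_repeat = []
    for _ in range(max(1, int(n_repeats))):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        for f in range(n_folds):
            fold_of[perm[f::n_folds]] = f
        folds_per_repeat.append(fold_of)
    min_train = min((fold_of != f).sum()
                    for fold_of in folds_per_repeat for f in range(n_folds))
    kmax = min(42, min_train - 1)
    kept = [k for k in k_candidates if 0 <= k <= kmax]
    dropped = sorted(set(k_candidates) - set(kept))
    if dropped:
        warnings.warn(f"dropping PC candidates beyond training-fold capacity "
                      f"(max {kmax}): {dropped}")
    if not kept:
        raise ValueError("no feasible PC candidates")

    ctrl = build_control_matrix(qc_sorted)
    fixed_df = _fixed_design(qc_sorted, fixed)
    groups = _random_groups(qc_sorted, random)
    group_dummies = {name: pd.get_dummies(levels, dtype=float)
                     for name, levels in groups.items()}

    Ys = {}
    for key in SUBSET_KEYS:
        if autosomal_only and not key.endswith(".autosomal"):
            continue
        vecs = [np.asarray(qc.quantiles.get(key, [])) for qc in qc_sorted]
        if all(v.size for v in vecs):
            Ys[key] = np.vstack(vecs)

    def _fold_mse(k: int, train: np.ndarray, test: np.ndarray) -> float:
        tr_scores, pca = fit_control_pca(ctrl.loc[:, np.asarray(sorted_ids)[train]], k)
        te_scores = pca.project(ctrl.loc[:, np.asarray(sorted_ids)[test]])
        X_tr = np.column_stack([np.ones(train.sum()), tr_scores, fixed_df.to_numpy()[train]])
        X_te = np.column_stack([np.ones(test.sum()), te_scores, fixed_df.to_numpy()[test]])
        Z_tr = [dm.to_numpy()[train] for dm in group_dummies.values()]
        Z_te = [dm.to_numpy()[test] for dm in group_dummies.values()]
        fracs = []
        for key, Y in Ys.items():
            Ytr, Yte = Y[train], Y[test]
            if not Z_tr:
                B, *_ = np.linalg.lstsq(X_tr, Ytr, rcond=None)
                pred = X_te @ B
            elif len(Z_tr) == 1:
                B, Zu = _reml_random_intercept(Ytr, X_tr, Z_tr[0])
                # recover level BLUPs from Zu via least squares on Z
                U, *_ = np.linalg.lstsq(Z_tr[0], Zu, rcond=None)
                pred = X_te @ B + Z_te[0] @ U
            else:
                B, Zu = _reml_multi(Ytr, X_tr, Z_tr)
                pred = X_te @ B  # BLUPs omitted in the generic path
            # fraction of the subset's quantile variation left unexplained:
            # scale-free, so no single high-intensity subset dominates
            total = float(((Yte - Ytr.mean(axis=0)) ** 2).mean())
            fracs.append(float(((Yte - pred) ** 2).mean()) / max(total, 1e-300))
        return float(np.mean(fracs))

    records = []
    for k in kept:
        fold_mse = [
            _fold_mse(k, fold_of != f, fold_of == f)
            for fold_of in folds_per_repeat
            for f in range(n_folds)
        ]
        records.append({"k": k, "cv_residual_variance": float(np.mean(fold_mse)),
                        "cv_sd": float(np.std(fold_mse, ddof=1))})
    scree = pd.DataFrame(records).set_index("k")
    best_val = scree["cv_residual_variance"].min()
    tol = best_val * 1e-12 + 1e-300
    best_k = int(min(k for k in scree.index
                     if scree.loc[k, "cv_residual_variance"] <= best_val + tol))
    return best_k, scree.reset_index()
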