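"""EWAS stage: per-CpG regressions, surrogate variables, cell composition.

Four regression models are fitted per run — no covariates, supplied
covariates, covariates plus SVA surrogate variables, and a fourth slot
filled by SVA with an alternative probe-weighting scheme (labelled
``sva.alt``) — so hidden-confounder handling can be compared across models.
Cellular composition is estimated by constrained projection of a
methylation profile onto reference cell-type profiles (weights nonnegative,
summing to at most one).  Batch association diagnostics regress principal
components of the most variable probes on batch variables (ANOVA F with
post-hoc t per level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CellReference",
    "EWASResult",
    "estimate_cell_counts",
    "sva_surrogates",
    "run_ewas",
    "controls_as_covariates_ewas",
    "batch_association_tests",
    "CollinearityWarning",
]


class CollinearityWarning(UserWarning):
    """A covariate is (nearly) collinear with the variable of interest."""


# ---------------------------------------------------------------------------
# Cell-type reference and constrained projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellReference:
    """Reference beta matrix (probes x cell types), values in [0, 1]."""

    betas: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.betas.to_numpy()
        if v.size and ((v < 0).any() or (v > 1).any()):
            raise ValueError("reference betas must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.betas.columns)

    def discriminating_probes(self, n_top: int | None = None) -> pd.Index:
        """Probes ranked by between-cell-type variance (descending)."""
        var = self.betas.var(axis=1)
        order = var.sort_values(ascending=False).index
        return order if n_top is None else order[:n_top]


def _simplex_face_lstsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||b - Aw||^2 s.t. w >= 0 and sum(w) = 1 (small active-set solve)."""
    m = A.shape[1]
    active = list(range(m))
    for _ in range(4 * m):
        As = A[:, active]
        ka = len(active)
        K = np.zeros((ka + 1, ka + 1))
        K[:ka, :ka] = As.T @ As
        K[:ka, ka] = 1.0
        K[ka, :ka] = 1.0
        rhs = np.concatenate([As.T @ b, [1.0]])
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
        w_active = sol[:ka]
        if (w_active >= -1e-12).all():
            w = np.zeros(m)
            w[active] = np.maximum(w_active, 0.0)
            return w
        drop = active[int(np.argmin(w_active))]
        active.remove(drop)
        if not active:
            break
    w = np.zeros(m)
    if active:
        w[active[0]] = 1.0
    return w


def estimate_cell_counts(betas: pd.Series, reference: CellReference,
                         n_top: int | None = None) -> pd.Series:
    """Constrained projection onto reference cell-type profiles.

    Solves ``min ||b - A w||^2`` subject to ``w >= 0`` and ``sum(w) <= 1``
    on the reference's discriminating probes.  The unconstrained-sum case is
    solved exactly by nonnegative least squares; if the weights overshoot
    the simplex, the sum-one face is solved by a small active-set step.
    """
    probes = reference.discriminating_probes(n_top)
    shared = probes.intersection(betas.index)
    if len(shared) == 0:
        raise ValueError("no probes shared between sample and reference")
    if len(shared) < len(reference.cell_types):
        raise ValueError(
            f"need at least {len(reference.cell_types)} shared probes, got {len(shared)}"
        )
    A = reference.betas.loc[shared].to_numpy()
    b = betas.loc[shared].to_numpy(dtype=float)
    w, _ = nnls(A, b)
    if w.sum() > 1.0 + 1e-12:
        w = _simplex_face_lstsq(A, b)
    return pd.Series(w, index=reference.cell_types, name=betas.name)


# ---------------------------------------------------------------------------
# Vectorized per-probe OLS
# ---------------------------------------------------------------------------


def _ols_block(Y: np.ndarray, X: np.ndarray, coef_idx: int) -> pd.DataFrame:
    """OLS of each row of Y (probes x samples) on X; stats for one column."""
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"too few complete cases: n={n}, parameters={p}")
    XtX = X.T @ X
    XtXi = np.linalg.pinv(XtX)
    B = Y @ X @ XtXi.T  # probes x p
    resid = Y - B @ X.T
    dof = n - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(sigma2 * XtXi[coef_idx, coef_idx])
    coef = B[:, coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    p_val = 2.0 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame({"coef": coef, "se": se, "t": t, "p": p_val})


def _finish_block(df: pd.DataFrame, index: pd.Index) -> pd.DataFrame:
    df = df.set_axis(index)
    df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    df["p_fdr"] = multipletests(df["p"].fillna(1.0), method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Surrogate variable analysis
# ---------------------------------------------------------------------------


def _n_sv_permutation(R: np.ndarray, rng: np.random.Generator,
                      n_perm: int = 20, alpha: float = 0.05) -> int:
    """Permutation-based eigenvalue test for the number of surrogates.

    Rows of the residual matrix are permuted independently, breaking any
    cross-sample structure; a component is kept while its variance
    proportion exceeds the permutation distribution at level ``alpha``,
    stopping at the first failure.
    """
    sv = np.linalg.svd(R, compute_uv=False)
    prop = sv**2 / np.sum(sv**2)
    kmax = len(prop)
    perm_props = np.empty((n_perm, kmax))
    Rp = R.copy()
    for b in range(n_perm):
        idx = np.argsort(rng.random(Rp.shape), axis=1)
        Rp = np.take_along_axis(R, idx, axis=1)
        s = np.linalg.svd(Rp, compute_uv=False)
        perm_props[b] = s**2 / np.sum(s**2)
    n_sv = 0
    for k in range(kmax):
        p = (1 + np.sum(perm_props[:, k] >= prop[k])) / (n_perm + 1)
        if p <= alpha:
            n_sv += 1
        else:
            break
    return n_sv


def sva_surrogates(betas: pd.DataFrame, model: pd.DataFrame | None,
                   n_sv: int | str = "auto", n_iter: int = 5,
                   weighting: str = "prob", seed: int = 0) -> pd.DataFrame:
    """Estimate surrogate variables from a probes x samples beta matrix.

    Residualizes the betas on the model, extracts leading right singular
    vectors, and iteratively reweights probes by their evidence of
    association with the current surrogates before re-extracting.
    ``weighting="prob"`` weights probes by 1 - p (association probability);
    ``weighting="threshold"`` restricts to probes with association p < 0.05
    (the alternative scheme used for the fourth EWAS model slot).
    ``n_sv="auto"`` uses a permutation-based eigenvalue test.
    """
    Y = betas.to_numpy(dtype=float)
    n = Y.shape[1]
    X = np.ones((n, 1)) if model is None else np.column_stack(
        [np.ones(n), np.asarray(model, dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate model: design matrix is rank-deficient")
    if n <= X.shape[1] + 1:
        raise ValueError("need n_samples > rank(model) + 1")

    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    R = Y - Y @ H
    rng = np.random.default_rng(seed)
    if n_sv == "auto":
        n_sv = _n_sv_permutation(R, rng)
    n_sv = int(n_sv)
    if n_sv == 0:
        return pd.DataFrame(index=betas.columns)

    def top_svs(M: np.ndarray) -> np.ndarray:
        _, _, Vt = np.linalg.svd(M, full_matrices=False)
        return Vt[:n_sv].T  # n x n_sv

    svs = top_svs(R)
    for _ in range(n_iter):
        # joint association evidence across surrogates via F-test
        p_sv = svs.shape[1]
        XtS = np.column_stack([np.ones(n), svs])
        fitted = R @ XtS @ np.linalg.pinv(XtS.T @ XtS).T @ XtS.T
        rss1 = ((R - fitted) ** 2).sum(axis=1)
        rss0 = (R**2).sum(axis=1)
        df1, df2 = p_sv, n - p_sv - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(rss1 > 0, ((rss0 - rss1) / df1) / (rss1 / df2), np.inf)
        p_assoc = stats.f.sf(F, df1, df2)
        if weighting == "prob":
            w = 1.0 - p_assoc
            svs = top_svs(R * w[:, None])
        elif weighting == "threshold":
            keep = p_assoc < 0.05
            if keep.sum() < n_sv + 1:
                keep = np.argsort(p_assoc) < max(n_sv + 1, 50)
            svs = top_svs(R[keep])
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
    cols = [f"sv{i+1}" for i in range(n_sv)]
    return pd.DataFrame(svs, index=betas.columns, columns=cols)


# ---------------------------------------------------------------------------
# EWAS
# ---------------------------------------------------------------------------


@dataclass
class EWASResult:
    """Per-CpG statistics under each regression model, plus metadata."""

    variable: str
    blocks: dict[str, pd.DataFrame]  # model name -> coef/se/t/p table
    metadata: dict = field(default_factory=dict)

    def significant(self, model: str, alpha: float = 0.05,
                    method: str = "p_bonferroni") -> pd.Index:
        t = self.blocks[model]
        return t.index[t[method] < alpha]


def _complete_cases(variable: pd.Series, covariates: pd.DataFrame | None,
                    betas: pd.DataFrame):
    samples = betas.columns
    v = variable.reindex(samples)
    mask = v.notna()
    if covariates is not None:
        missing_all = covariates.columns[covariates.reindex(samples).isna().all()]
        if len(missing_all):
            raise ValueError(f"covariates entirely missing: {list(missing_all)}")
        mask &= covariates.reindex(samples).notna().all(axis=1)
    keep = samples[mask.to_numpy()]
    return keep


def _encode(series_or_df) -> np.ndarray:
    df = pd.DataFrame(series_or_df)
    out = []
    for col in df.columns:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, drop_first=True, dtype=float)
            out.append(d.to_numpy())
        else:
            out.append(s.to_numpy(dtype=float)[:, None])
    return np.column_stack(out) if out else np.empty((len(df), 0))


def run_ewas(betas: pd.DataFrame, variable: pd.Series,
             covariates: pd.DataFrame | None = None,
             cell_counts: pd.DataFrame | None = None,
             svs: pd.DataFrame | None = None,
             n_sv: int | str = "auto", seed: int = 0) -> EWASResult:
    """Per-CpG ordinary least squares under the four model configurations.

    Blocks: ``none`` (variable only), ``covariates`` (plus supplied
    covariates and cell-count estimates), ``sva`` (plus SVA surrogates) and
    ``sva.alt`` (surrogates from the alternative probe-weighting scheme).
    Bonferroni and Benjamini-Hochberg columns are appended per block.
    """
    v_all = variable.reindex(betas.columns)
    if v_all.nunique(dropna=True) < 2:
        raise ValueError("variable of interest is constant")
    covs = None
    if covariates is not None or cell_counts is not None:
        parts = [c.reindex(betas.columns) for c in (covariates, cell_counts)
                 if c is not None]
        covs = pd.concat(parts, axis=1)
    keep = _complete_cases(variable, covs, betas)
    Y = betas[keep].to_numpy(dtype=float)
    v = _encode(variable.reindex(keep))
    if v.shape[1] != 1:
        raise ValueError("variable of interest must encode to a single column")
    C = _encode(covs.reindex(keep)) if covs is not None else np.empty((len(keep), 0))
    ones = np.ones((len(keep), 1))

    model_df = pd.DataFrame(np.column_stack([v, C]), index=keep)
    if svs is None:
        sv_a = sva_surrogates(betas[keep], model_df, n_sv=n_sv,
                              weighting="prob", seed=seed)
        sv_b = sva_surrogates(betas[keep], model_df, n_sv=n_sv,
                              weighting="threshold", seed=seed + 1)
    else:
        sv_a = sv_b = svs.reindex(keep)

    designs = {
        "none": np.column_stack([ones, v]),
        "covariates": np.column_stack([ones, v, C]),
        "sva": np.column_stack([ones, v, C, sv_a.to_numpy()]),
        "sva.alt": np.column_stack([ones, v, C, sv_b.to_numpy()]),
    }
    blocks = {}
    for name, X in designs.items():
        blocks[name] = _finish_block(_ols_block(Y, X, coef_idx=1), betas.index)
    meta = {"n_samples": len(keep), "n_probes": len(betas),
            "n_sv": int(sv_a.shape[1]), "models": list(designs.keys())}
    return EWASResult(variable=str(variable.name or "variable"),
                      blocks=blocks, metadata=meta)


def controls_as_covariates_ewas(betas: pd.DataFrame, variable: pd.Series,
                                control_matrix: pd.DataFrame,
                                n_pcs: int | None = None,
                                collinearity_r: float = 0.99) -> EWASResult:
    """EWAS adjusting for control summaries directly in the regression.

    When batch and phenotype are perfectly confounded, some controls (e.g.
    hybridization families) can perfectly separate the groups; the model is
    then unstable.  Covariates whose correlation with the variable exceeds
    ``collinearity_r`` are dropped with a prominent warning — never silently
    retained or silently removed.
    """
    keep = _complete_cases(variable, None, betas)
    Y = betas[keep].to_numpy(dtype=float)
    v = _encode(variable.reindex(keep))
    ctrl = control_matrix[keep].T  # samples x 42
    if n_pcs is not None:
        Z = (ctrl - ctrl.mean()) / ctrl.std(ddof=1).replace(0.0, 1.0)
        U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
        ctrl = pd.DataFrame(U[:, :n_pcs] * S[:n_pcs], index=keep,
                            columns=[f"ctrlpc{i+1}" for i in range(n_pcs)])
    ctrl = ctrl.loc[:, ctrl.std(ddof=1) > 0]

    vv = v[:, 0]
    dropped = []
    for col in list(ctrl.columns):
        r = np.corrcoef(vv, ctrl[col].to_numpy(dtype=float))[0, 1]
        if np.abs(r) > collinearity_r:
            dropped.append(str(col))
            ctrl = ctrl.drop(columns=[col])
    if dropped:
        warnings.warn(
            f"control covariates highly collinear with {variable.name!r} "
            f"(|r| > {collinearity_r}) dropped from the model: {dropped}. "
            "Batch and phenotype may be perfectly confounded; estimates for "
            "the remaining model are likely unstable.",
            CollinearityWarning,
        )
    X = np.column_stack([np.ones(len(keep)), v, ctrl.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # drop redundant control columns until full rank, loudly
        redundant = []
        base = np.column_stack([np.ones(len(keep)), v])
        cols = []
        for j, name in enumerate(ctrl.columns):
            cand = np.column_stack([base] + cols + [ctrl.to_numpy()[:, j]])
            if np.linalg.matrix_rank(cand) > base.shape[1] + len(cols):
                cols.append(ctrl.to_numpy()[:, j:j + 1])
            else:
                redundant.append(str(name))
        warnings.warn(f"dropping rank-deficient control covariates: {redundant}",
                      CollinearityWarning)
        ctrl = ctrl.drop(columns=redundant)
        X = np.column_stack([np.ones(len(keep)), v, ctrl.to_numpy(dtype=float)])
    block = _finish_block(_ols_block(Y, X, coef_idx=1), betas.index)
    return EWASResult(variable=str(variable.name or "variable"),
                      blocks={"controls": block},
                      metadata={"dropped_covariates": dropped,
                                "n_control_covariates": ctrl.shape[1]})


# ---------------------------------------------------------------------------
# Batch association diagnostics
# ---------------------------------------------------------------------------


def batch_association_tests(betas: pd.DataFrame, batch: pd.DataFrame,
                            n_probes: int = 1000, n_pcs: int = 5,
                            threshold: float = 0.01
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA F (and post-hoc t) of beta-matrix PCs on batch variables.

    PCs of the ``n_probes`` most variable probes are regressed on each batch
    variable; per (PC, variable) an ANOVA F test, per level a post-hoc t
    test (level vs rest).  Returns (full table, rows passing ``threshold``).
    Single-level variables are skipped with a note row.
    """
    var = betas.var(axis=1)
    top = var.sort_values(ascending=False).index[:n_probes]
    M = betas.loc[top].to_numpy(dtype=float)
    M = M - M.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    n_pcs = min(n_pcs, len(S))
    scores = pd.DataFrame(Vt[:n_pcs].T * S[:n_pcs], index=betas.columns,
                          columns=[f"PC{i+1}" for i in range(n_pcs)])

    rows = []
    for varname in batch.columns:
        levels = batch[varname].reindex(betas.columns)
        uniq = levels.dropna().unique()
        if len(uniq) < 2:
            rows.append({"variable": varname, "pc": "", "test": "skipped",
                         "level": "", "statistic": np.nan, "p": np.nan,
                         "note": "single-level variable"})
            continue
        for pc in scores.columns:
            groups = [scores.loc[levels == g, pc].to_numpy() for g in uniq]
            F, p = stats.f_oneway(*groups)
            rows.append({"variable": varname, "pc": pc, "test": "F",
                         "level": "", "statistic": float(F), "p": float(p),
                         "note": ""})
            for g in uniq:
                a = scores.loc[levels == g, pc].to_numpy()
                b = scores.loc[levels != g, pc].to_numpy()
                t, tp = stats.ttest_ind(a, b, equal_var=True)
                rows.append({"variable": varname, "pc": pc, "test": "t",
                             "level": str(g), "statistic": float(t),
                             "p": float(tp), "note": ""})
    full = pd.DataFrame(rows)
    significant = full[(full["test"].isin(["F", "t"])) & (full["p"] < threshold)]
    return full, significant
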