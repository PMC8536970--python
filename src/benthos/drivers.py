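"""Attribution of assembly processes to environmental and biotic drivers.

Environmental factors and keystone abundances are min-max scaled,
combined by PCA, and the PCA axes are fitted to the betaNTI and RC_bray
matrices by distance-based redundancy analysis (dbRDA) with forward
model selection on adjusted R^2 and permutation p-values.  The variable
with the highest absolute loading on a retained axis is the axis's
primary factor; factors on betaNTI-retained axes are selection-related,
factors on axes retained by RC_bray but not betaNTI are
dispersal-related.

Because betaNTI/RC matrices are z-scores, not metric distances, they
are shifted to non-negative dissimilarities (off-diagonal minimum
subtracted) and embedded by principal coordinates with a Lingoes
correction before the constrained fit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import EnvTable, OtuTable

__all__ = [
    "PcaResult",
    "DbrdaForwardSelection",
    "DbrdaResults",
    "DriverAttribution",
    "minmax_scale",
    "minmax_scale_table",
    "pca",
    "dbrda_forward_select",
    "attribute_drivers",
    "rda_explained",
    "random_subcommunity_test",
]


# ---------------------------------------------------------------------------
# scaling and PCA
# ---------------------------------------------------------------------------

def minmax_scale(values) -> np.ndarray:
    """(x - min) / (max - min); errors on a constant vector."""
    arr = np.asarray(values, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ValueError("constant vector cannot be min-max scaled")
    return (arr - lo) / (hi - lo)


def minmax_scale_table(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise min-max scaling; constant columns dropped with a warning."""
    keep, dropped = {}, []
    for col in df.columns:
        try:
            keep[col] = minmax_scale(df[col].to_numpy())
        except ValueError:
            dropped.append(col)
    if dropped:
        warnings.warn(f"dropping constant column(s): {dropped}", stacklevel=2)
    if not keep:
        raise ValueError("all columns constant")
    return pd.DataFrame(keep, index=df.index)


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x axes
    loadings: pd.DataFrame      # variables x axes (orthonormal columns)
    explained: pd.Series        # % variance per axis, non-increasing

    @property
    def axes(self) -> list[str]:
        return list(self.scores.columns)


def pca(matrix: pd.DataFrame) -> PcaResult:
    """PCA of column-centred data via SVD.

    Axes are ordered by eigenvalue; each axis is flipped so its
    largest-magnitude loading is positive (fixed sign convention).
    Axes with numerically zero variance are not returned, so the axis
    count is at most min(samples - 1, variables).
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ValueError("PCA needs >= 3 samples and >= 2 variables")
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        raise ValueError("rank-0 input (all rows identical)")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s.max() * max(xc.shape) * np.finfo(float).eps
    keep = s > tol
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # sign convention: largest-|loading| element of each axis positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    var = s**2
    explained = 100.0 * var / var.sum()
    axes = [f"PC{i+1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=axes),
        loadings=pd.DataFrame(vt.T, index=matrix.columns, columns=axes),
        explained=pd.Series(explained, index=axes, name="explained_pct"),
    )


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

def _hellinger(df: pd.DataFrame) -> np.ndarray:
    arr = df.to_numpy(dtype=float)
    totals = arr.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("sample with zero total")
    return np.sqrt(arr / totals)


def rda_explained(
    community: OtuTable | pd.DataFrame,
    env: EnvTable | pd.DataFrame,
    transform: str = "hellinger",
) -> float:
    """Total constrained variance (%) of a redundancy analysis.

    Community data are Hellinger-transformed by default (``transform=
    "identity"`` uses values as given); the constrained inertia is the
    variance of the fitted values of the multivariate regression of the
    centred community matrix on the centred constraints.
    """
    comm = community.counts if isinstance(community, OtuTable) else community
    env_df = env.values if isinstance(env, EnvTable) else env
    if list(comm.index) != list(env_df.index):
        env_df = env_df.loc[comm.index]
    n = comm.shape[0]
    if env_df.shape[1] > n - 1:
        raise ValueError("more constraints than samples - 1")
    y = _hellinger(comm) if transform == "hellinger" else comm.to_numpy(dtype=float)
    y = y - y.mean(axis=0)
    x = env_df.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    total = (y**2).sum()
    if total == 0:
        raise ValueError("community matrix has no variance")
    return float(100.0 * (fitted**2).sum() / total)


def random_subcommunity_test(
    table: OtuTable,
    env: EnvTable,
    keystone_ids,
    k: int | None = None,
    n_draws: int = 99,
    seed: int | None = None,
    transform: str = "hellinger",
):
    """Compare keystone RDA fit against random same-size subcommunities.

    Draws ``n_draws`` random ``k``-taxon subsets, scores each with
    :func:`rda_explained`, and ranks the keystone set within that null:
    upper-tail p = (1 + #{null >= obs}) / (1 + n_draws), mirrored for
    the lower tail; the two-sided p is twice the smaller tail (capped
    at 1).  Returns a dict with the observed value, the null values and
    the three p-values; a zero-variance null is flagged degenerate.
    """
    keystone_ids = list(keystone_ids)
    if k is None:
        k = len(keystone_ids)
    n_taxa = table.shape[1]
    if k >= n_taxa:
        raise ValueError("k must be smaller than the number of taxa")
    obs = rda_explained(table.select_taxa(keystone_ids), env, transform=transform)
    rng = np.random.default_rng(seed)
    taxa = np.array(table.taxon_ids)
    null = np.array([
        rda_explained(table.select_taxa(list(rng.choice(taxa, size=k, replace=False))),
                      env, transform=transform)
        for _ in range(n_draws)
    ])
    degenerate = bool(np.isclose(null.std(), 0.0))
    if degenerate:
        warnings.warn("degenerate null distribution (all draws equal)", stacklevel=2)
    p_upper = (1 + int((null >= obs - 1e-12).sum())) / (1 + n_draws)
    p_lower = (1 + int((null <= obs + 1e-12).sum())) / (1 + n_draws)
    return {
        "observed": obs,
        "null": null,
        "p_upper": p_upper,
        "p_lower": p_lower,
        "p_two_sided": min(1.0, 2 * min(p_upper, p_lower)),
        "degenerate": degenerate,
    }


# ---------------------------------------------------------------------------
# dbRDA with forward selection
# ---------------------------------------------------------------------------

def _lingoes_pcoa(dist: np.ndarray) -> np.ndarray:
    """Principal-coordinate embedding with Lingoes correction.

    Returns real coordinates whose pairwise squared Euclidean distances
    reproduce the (corrected) squared dissimilarities.
    """
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n

    def gower(d2):
        return -0.5 * j @ d2 @ j

    d2 = dist**2
    b = gower(d2)
    eig = np.linalg.eigvalsh(b)
    if eig.min() < -1e-9 * max(1.0, abs(eig).max()):
        c = -eig.min()
        d2 = d2 + 2.0 * c * (1 - np.eye(n))
        b = gower(d2)
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-9 * max(1.0, vals.max())
    return vecs[:, keep] * np.sqrt(vals[keep])


def _r2(y: np.ndarray, x: np.ndarray) -> float:
    """Redundancy R^2 of centred response Y on centred predictors X."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    return float((fitted**2).sum() / (y**2).sum())


def _adj_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class DbrdaResults:
    retained: list[dict]          # {axis, r2, adj_r2, p} in retention order
    full_adj_r2: float
    permutations: int
    alpha: float

    @property
    def retained_axes(self) -> list[str]:
        return [d["axis"] for d in self.retained]

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(self.retained, columns=["axis", "r2", "adj_r2", "p"])
        df.attrs["full_adj_r2"] = self.full_adj_r2
        return df


class DbrdaForwardSelection:
    """Forward model selection of predictor axes against a dissimilarity.

    The response matrix (betaNTI or RC_bray) is shifted to a
    non-negative dissimilarity, embedded by Lingoes-corrected principal
    coordinates, and predictor axes are added one at a time by largest
    adjusted-R^2 gain.  Selection stops when the best candidate's
    permutation p exceeds ``alpha``, when the model's adjusted R^2
    would exceed the full-model adjusted R^2, or when no candidate
    improves it.
    """

    def __init__(self, response: pd.DataFrame, predictors: pd.DataFrame):
        if list(response.index) != list(response.columns):
            raise ValueError("response must be a square labelled matrix")
        if not np.allclose(response.to_numpy(), response.to_numpy().T, atol=1e-8):
            raise ValueError("response matrix must be symmetric")
        if list(predictors.index) != list(response.index):
            raise ValueError("predictor rows must match response samples")
        self.response = response
        self.predictors = predictors

    def fit(
        self,
        permutations: int = 999,
        alpha: float = 0.05,
        seed: int | None = None,
    ) -> DbrdaResults:
        arr = self.response.to_numpy(dtype=float).copy()
        n = arr.shape[0]
        off = ~np.eye(n, dtype=bool)
        if arr[off].min() < 0:  # z-score responses; proper dissimilarities pass through
            arr[off] = arr[off] - arr[off].min()
        np.fill_diagonal(arr, 0.0)
        y = _lingoes_pcoa(arr)
        y = y - y.mean(axis=0)

        x_all = self.predictors.to_numpy(dtype=float)
        x_all = x_all - x_all.mean(axis=0)
        names = list(self.predictors.columns)
        p_total = len(names)
        p_cap = min(p_total, n - 2)  # saturated models have no adjusted R^2
        full_adj = _adj_r2(_r2(y, x_all[:, :p_cap]), n, p_cap)

        rng = np.random.default_rng(seed)
        total_ss = (y**2).sum()
        selected: list[int] = []
        retained: list[dict] = []
        current_adj = 0.0
        while len(selected) < p_cap:
            remaining = [j for j in range(p_total) if j not in selected]
            if not remaining:
                break
            # residualise response and candidates on the current model
            if selected:
                xs = x_all[:, selected]
                hat = xs @ np.linalg.pinv(xs)
                y_fit = hat @ y
                y_res = y - y_fit
                x_res = x_all[:, remaining] - hat @ x_all[:, remaining]
            else:
                y_fit = np.zeros_like(y)
                y_res = y
                x_res = x_all[:, remaining].copy()
            norms = (x_res**2).sum(axis=0)
            ok = norms > 1e-12 * max(1.0, norms.max())
            if not ok.any():
                break
            x_res[:, ~ok] = 0.0
            norms[~ok] = np.inf

            def gains(resid):
                return ((x_res.T @ resid) ** 2).sum(axis=1) / norms / total_ss

            obs_gains = gains(y_res)
            best_pos = int(np.argmax(obs_gains))
            best = remaining[best_pos]
            base_r2 = _r2(y, x_all[:, selected]) if selected else 0.0
            best_r2 = base_r2 + float(obs_gains[best_pos])
            best_adj = _adj_r2(best_r2, n, len(selected) + 1)
            if best_adj <= current_adj + 1e-12:
                break
            if best_adj > full_adj + 1e-12:
                break
            # max-statistic permutation test of the best candidate: permute
            # the reduced-model residuals (Freedman-Lane) and compare the
            # observed gain with the null distribution of the *largest*
            # candidate gain, which accounts for picking the best of many
            count = 0
            obs = obs_gains[best_pos]
            idx = np.arange(n)
            for _ in range(permutations):
                rng.shuffle(idx)
                if gains(y_res[idx]).max() >= obs - 1e-12:
                    count += 1
            p_val = (1 + count) / (1 + permutations)
            if p_val > alpha:
                break
            selected.append(best)
            current_adj = best_adj
            retained.append({"axis": names[best], "r2": best_r2, "adj_r2": best_adj, "p": p_val})
        return DbrdaResults(
            retained=retained, full_adj_r2=full_adj,
            permutations=permutations, alpha=alpha,
        )


def dbrda_forward_select(
    response: pd.DataFrame,
    predictors: pd.DataFrame | PcaResult,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> DbrdaResults:
    """Functional wrapper around :class:`DbrdaForwardSelection`."""
    scores = predictors.scores if isinstance(predictors, PcaResult) else predictors
    return DbrdaForwardSelection(response, scores).fit(
        permutations=permutations, alpha=alpha, seed=seed
    )


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------

@dataclass
class DriverAttribution:
    """Factor -> process map from retained dbRDA axes.

    ``selection_related``/``dispersal_related`` map each retained axis
    to its top-|loading| variable; environmental variables and taxa are
    also ranked separately when the split is provided.
    """

    selection_axes: list[str]
    dispersal_axes: list[str]
    selection_related: dict[str, str]
    dispersal_related: dict[str, str]
    top_loadings: pd.DataFrame   # axis, variable, loading, scope, process

    def summary(self) -> pd.DataFrame:
        return self.top_loadings


def _top_loader(loadings: pd.DataFrame, axis: str, rows=None) -> tuple[str, float]:
    col = loadings[axis]
    if rows is not None:
        col = col.loc[[r for r in rows if r in col.index]]
    if col.empty:
        raise ValueError(f"no candidate variables for axis {axis}")
    var = col.abs().idxmax()
    return var, float(col.loc[var])


def attribute_drivers(
    bnti_axes,
    rc_axes,
    loadings: pd.DataFrame | PcaResult,
    env_variables=None,
) -> DriverAttribution:
    """Identify primary factors per retained axis (max absolute loading).

    Axes retained for betaNTI mark their top loaders selection-related;
    axes retained for RC_bray but not betaNTI mark theirs
    dispersal-related.  When ``env_variables`` is given, the top
    environmental variable and the top taxon are reported per axis as
    well as the overall top loader.
    """
    ldf = loadings.loadings if isinstance(loadings, PcaResult) else loadings
    bnti_axes = list(bnti_axes)
    rc_axes = list(rc_axes)
    dispersal_only = [a for a in rc_axes if a not in set(bnti_axes)]
    env_variables = list(env_variables) if env_variables is not None else None
    taxa_variables = (
        [v for v in ldf.index if v not in set(env_variables)] if env_variables else None
    )
    rows = []
    sel_map: dict[str, str] = {}
    disp_map: dict[str, str] = {}
    for process, axes, target in (
        ("selection", bnti_axes, sel_map),
        ("dispersal", dispersal_only, disp_map),
    ):
        for axis in axes:
            if axis not in ldf.columns:
                raise KeyError(f"axis {axis!r} not in loadings")
            var, load = _top_loader(ldf, axis)
            target[axis] = var
            rows.append({"axis": axis, "variable": var, "loading": load,
                         "scope": "all", "process": process})
            if env_variables:
                evar, eload = _top_loader(ldf, axis, env_variables)
                rows.append({"axis": axis, "variable": evar, "loading": eload,
                             "scope": "environmental", "process": process})
                if taxa_variables:
                    tvar, tload = _top_loader(ldf, axis, taxa_variables)
                    rows.append({"axis": axis, "variable": tvar, "loading": tload,
                                 "scope": "taxa", "process": process})
    cols = ["axis", "variable", "loading", "scope", "process"]
    return DriverAttribution(
        selection_axes=bnti_axes,
        dispersal_axes=dispersal_only,
        selection_related=sel_map,
        dispersal_related=disp_map,
        top_loadings=pd.DataFrame(rows, columns=cols),
    )
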