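"""Alpha/beta diversity, group tests and ordination.

Shannon entropy (nats by default), Chao1 richness, Bray-Curtis distances,
rank-based ANOSIM, the group presence rule, classical PCoA and the
taxa-environment Pearson screen.  Heavy lifting is delegated to
scikit-bio and scipy; this module mostly fixes conventions (log base,
add-one permutation p-values, presence threshold at half the group).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import skbio
from scipy.spatial.distance import squareform, pdist
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .data import EnvTable, GroupMap, OtuTable

__all__ = [
    "DistanceMatrix",
    "AnosimResult",
    "shannon",
    "chao1",
    "bray_curtis",
    "euclidean",
    "anosim",
    "presence_filter",
    "pcoa",
    "pearson_screen",
]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with sample ids and a metric name."""

    values: np.ndarray
    ids: list[str]
    metric: str = "unknown"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if arr.shape[0] != len(self.ids):
            raise ValueError("ids do not match matrix size")
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = 0.5 * (arr + arr.T)
        np.fill_diagonal(self.values, 0.0)
        self.ids = [str(i) for i in self.ids]

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metric: str = "unknown") -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column ids differ")
        return cls(df.to_numpy(dtype=float), list(df.index), metric)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")


@dataclass
class AnosimResult:
    r: float
    p_value: float
    permutations: int


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts, base: float | None = None) -> float:
    """Shannon-Wiener index H = -sum p_i log p_i over positive counts.

    Natural log by default (reported in nats); pass ``base=2`` for bits.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be a vector")
    if (arr < 0).any():
        raise ValueError("negative counts")
    if arr.sum() <= 0:
        raise ValueError("all-zero count vector")
    return float(_skbio_shannon(arr, base=np.e if base is None else base))


def chao1(counts) -> float:
    """Chao1 richness estimate.

    S_obs + F1^2 / (2 F2) when doubletons exist; the bias-corrected
    S_obs + F1 (F1 - 1) / 2 when F2 = 0.
    """
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("chao1 requires integer counts")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("negative counts")
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y)."""
    df = table.counts if isinstance(table, OtuTable) else table
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (arr.sum(axis=1) <= 0).any():
        raise ValueError("sample with zero total")
    mat = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(mat, list(df.index), metric="bray-curtis")


def euclidean(df: pd.DataFrame) -> DistanceMatrix:
    mat = squareform(pdist(df.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(mat, list(df.index), metric="euclidean")


def anosim(
    dist: DistanceMatrix,
    groups: GroupMap,
    permutations: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Analysis of similarities with mid-ranked ties.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4);
    p-value by group-label permutation with the add-one convention, so
    the smallest attainable p is 1/(permutations+1).
    """
    labels = groups.labels_for(dist.ids)
    sizes = pd.Series(labels).value_counts()
    if len(sizes) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    if seed is not None:
        np.random.seed(seed % (2**32))
    res = _skbio_anosim(dist.to_skbio(), labels, permutations=permutations)
    return AnosimResult(
        r=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        permutations=permutations,
    )


def presence_filter(table: OtuTable, groups: GroupMap) -> pd.DataFrame:
    """Group-level presence/absence (groups x taxa).

    A taxon is present in a group when it has a positive count in at
    least half of that group's samples (>= ceil(n/2), i.e. >=4 of 8).
    """
    out = {}
    for group, samples in groups.groups().items():
        sub = table.counts.loc[[s for s in samples if s in table.counts.index]]
        if sub.shape[0] == 0:
            raise ValueError(f"group {group!r} has no samples in the table")
        need = -(-sub.shape[0] // 2)  # ceil(n/2)
        out[group] = (sub > 0).sum(axis=0) >= need
    return pd.DataFrame(out).T.astype(bool)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame          # samples x positive-eigenvalue axes
    eigenvalues: np.ndarray            # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Negative eigenvalues are reported as-is; coordinates span only the
    positive-eigenvalue axes.
    """
    res = _skbio_pcoa(dist.to_skbio(), method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-12 * max(1.0, abs(eig).max())
    coords = res.samples.to_numpy()[:, pos]
    axes = [f"PCo{i+1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=dist.ids, columns=axes),
        eigenvalues=eig,
        proportion_explained=res.proportion_explained.to_numpy(),
    )


def pearson_screen(taxa: pd.DataFrame, env: EnvTable | pd.DataFrame):
    """Pearson r and two-sided t-test p for every taxon-factor pair.

    Constant columns yield NaN (flagged, not coerced to 0).  Returns
    ``(r, p)`` DataFrames of shape taxa x factors.
    """
    env_df = env.values if isinstance(env, EnvTable) else env
    if list(taxa.index) != list(env_df.index):
        env_df = env_df.loc[taxa.index]
    n = taxa.shape[0]
    if n < 3:
        raise ValueError("pearson screen needs at least 3 samples")
    x = taxa.to_numpy(dtype=float)
    y = env_df.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = xc.std(axis=0, ddof=0)
    sy = yc.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / n / np.outer(sx, sy)
    r[:, sy == 0] = np.nan
    r[sx == 0, :] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[np.isnan(r)] = np.nan
    rdf = pd.DataFrame(r, index=taxa.columns, columns=env_df.columns)
    pdf = pd.DataFrame(p, index=taxa.columns, columns=env_df.columns)
    return rdf, pdf
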