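"""Gower-distance principal coordinates analysis of meristic tables.

The ordination mirrors the descriptive multivariate comparison of fossil and
extant specimens over integer meristic counts (fin spines/rays, vertebral
counts, supraneural number). Gower's coefficient is used because it degrades
gracefully under missing values: each pairwise distance is the mean of
range-normalised absolute differences over the variables both specimens
share. PCoA is classical metric scaling: double-centre −1/2·J·D²·J and
eigendecompose; axes for negative eigenvalues (possible for non-Euclidean
distances) are reported and dropped, with no Cailliez/Lingoes correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from shapely.geometry import MultiPoint

__all__ = [
    "MeristicTable",
    "PCoAResult",
    "gower_distance",
    "pcoa",
    "group_overlap",
]


@dataclass
class MeristicTable:
    """Specimen x variable grid of counts with group labels; NaN = missing."""

    data: pd.DataFrame  # numeric, index = specimen ids
    groups: pd.Series  # specimen id -> group label

    def __post_init__(self) -> None:
        if len(self.data) < 2:
            raise ValueError("need >= 2 specimens")
        ok = self.data.notna().sum(axis=0) >= 2
        if not ok.all():
            bad = list(self.data.columns[~ok])
            raise ValueError(f"variable(s) with <2 observed values: {bad}")
        self.groups = self.groups.reindex(self.data.index)

    @classmethod
    def from_tsv(cls, path, group_col: str = "group") -> "MeristicTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        groups = df[group_col].astype(str)
        data = df.drop(columns=[group_col]).apply(pd.to_numeric)
        return cls(data=data, groups=groups)


def gower_distance(table: MeristicTable) -> pd.DataFrame:
    """Symmetric Gower distance matrix in [0, 1].

    d(i,j) = mean over shared (both non-missing) variables of
    |x_iv − x_jv| / range_v, with range_v the observed range of variable v.
    A pair sharing no variable is an error.
    """
    X = table.data.to_numpy(dtype=float)
    n, p = X.shape
    rng = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
    rng[rng == 0] = 1.0  # constant variable contributes 0 to every distance
    obs = ~np.isnan(X)
    D = np.zeros((n, n))
    for i in range(n):
        shared = obs[i] & obs  # (n, p)
        diff = np.abs(X[i] - X) / rng
        diff = np.where(shared, diff, 0.0)
        counts = shared.sum(axis=1)
        empty = np.where(counts == 0)[0]
        empty = empty[empty != i]
        if empty.size:
            a, b = table.data.index[i], table.data.index[empty[0]]
            raise ValueError(f"specimens {a!r} and {b!r} share no observed variable")
        with np.errstate(invalid="ignore"):
            D[i] = diff.sum(axis=1) / counts
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=table.data.index, columns=table.data.index)


@dataclass
class PCoAResult:
    eigenvalues: np.ndarray  # all, descending (negatives included)
    coordinates: pd.DataFrame  # specimens x retained (positive) axes
    percent_variance: np.ndarray  # over positive eigenvalues, sums to 100
    negative_eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(distances: pd.DataFrame, atol: float = 1e-10) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix."""
    D = np.asarray(distances, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals[np.abs(vals) < atol] = 0.0
    pos = vals > 0
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    index = distances.index if isinstance(distances, pd.DataFrame) else range(n)
    ncol = int(pos.sum())
    return PCoAResult(
        eigenvalues=vals,
        coordinates=pd.DataFrame(
            coords, index=index, columns=[f"PCo{i+1}" for i in range(ncol)]
        ),
        percent_variance=100.0 * vals[pos] / vals[pos].sum() if ncol else np.array([]),
        negative_eigenvalues=vals[vals < 0],
    )


@dataclass
class GroupPairOverlap:
    group_a: str
    group_b: str
    hulls_intersect: bool | None  # None when either group has <3 points
    centroid_distance: float


def group_overlap(result: PCoAResult, labels: pd.Series) -> list:
    """Pairwise 2-D convex-hull overlap and centroid distances on axes 1–2.

    Groups with fewer than three specimens get a centroid-only comparison
    (``hulls_intersect`` is None).
    """
    if result.n_axes < 2:
        raise ValueError("need at least two positive axes")
    xy = result.coordinates.iloc[:, :2]
    labels = labels.reindex(xy.index)
    out = []
    names = sorted(labels.dropna().unique())
    pts = {g: xy[labels == g].to_numpy() for g in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ca, cb = pts[a].mean(axis=0), pts[b].mean(axis=0)
            dist = float(np.hypot(*(ca - cb)))
            if len(pts[a]) >= 3 and len(pts[b]) >= 3:
                ha = MultiPoint([tuple(p) for p in pts[a]]).convex_hull
                hb = MultiPoint([tuple(p) for p in pts[b]]).convex_hull
                inter = bool(ha.intersects(hb))
            else:
                inter = None
            out.append(
                GroupPairOverlap(
                    group_a=a, group_b=b, hulls_intersect=inter, centroid_distance=dist
                )
            )
    return out
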