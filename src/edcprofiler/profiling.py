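"""Phenotypic profiles: robust scaling, condition aggregation, cosine
clustering and 2-D embedding.

A profile is the per-feature median of robust-scaled well rows of one
treatment condition; conditions are compared by the cosine distance
between profiles and organised by average-linkage hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .catalogue import FEATURE_NAMES


@dataclass
class ScaledFeatureTable:
    """Robust-scaled well table plus the scaling parameters.

    ``params`` has one row per feature with columns median, iqr; features
    whose IQR was zero over the scaling population are listed in
    ``degenerate`` and were only centred.
    """

    table: pd.DataFrame
    params: pd.DataFrame
    degenerate: list[str]

    def apply_to(self, other: pd.DataFrame) -> pd.DataFrame:
        """Reapply the stored scaling to held-out rows."""
        out = other.copy()
        for name in self.params.index:
            med = self.params.loc[name, "median"]
            iqr = self.params.loc[name, "iqr"]
            out[name] = (other[name] - med) / (iqr if iqr > 0 else 1.0)
        return out


def robust_scale(
    table: pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> ScaledFeatureTable:
    """Scale each feature to x' = (x - median) / IQR, IQR = Q3 - Q1.

    Quantiles use linear interpolation.  Features with IQR = 0 are centred
    only (guard against division by zero) and flagged.  Raises on fewer
    than two rows — a single well cannot define a spread.
    """
    if len(table) < 2:
        raise ValueError("robust_scale needs at least 2 rows")
    out = table.copy()
    params = []
    degenerate: list[str] = []
    for name in feature_names:
        x = table[name].to_numpy(dtype=float)
        med = float(np.nanmedian(x))
        q1, q3 = np.nanpercentile(x, [25.0, 75.0])
        iqr = float(q3 - q1)
        if iqr > 0:
            out[name] = (x - med) / iqr
        else:
            out[name] = x - med
            degenerate.append(name)
        params.append({"feature": name, "median": med, "iqr": iqr})
    pdf = pd.DataFrame(params).set_index("feature")
    return ScaledFeatureTable(table=out, params=pdf, degenerate=degenerate)


def aggregate_profiles(
    scaled: ScaledFeatureTable | pd.DataFrame,
    by: tuple[str, ...] = ("compound", "dose_uM"),
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Median-aggregate scaled well rows per treatment condition."""
    t = scaled.table if isinstance(scaled, ScaledFeatureTable) else scaled
    return t.groupby(list(by), sort=True)[list(feature_names)].median()


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """d(u, v) = 1 - u.v / (|u||v|); raises on a zero-norm vector."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero-norm vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def cosine_distance_matrix(
    profiles: pd.DataFrame, linkage_method: str = "average"
) -> tuple[pd.DataFrame, np.ndarray, list, str]:
    """Pairwise cosine distances between condition profiles plus an
    average-linkage dendrogram.

    Returns (distance matrix, scipy linkage, leaf order as index labels,
    Newick string of the condition tree).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    X = profiles.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = [str(profiles.index[i]) for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-norm profile(s): {bad}")
    condensed = pdist(X, metric="cosine")
    dm = pd.DataFrame(
        squareform(condensed), index=profiles.index, columns=profiles.index
    )
    Z = hierarchy.linkage(condensed, method=linkage_method)
    order = [profiles.index[i] for i in hierarchy.leaves_list(Z)]
    names = ["_".join(str(p) for p in (idx if isinstance(idx, tuple) else (idx,)))
             for idx in profiles.index]
    newick = _to_newick(hierarchy.to_tree(Z), names)
    return dm, Z, order, newick


def _to_newick(node, names: list[str]) -> str:
    def rec(n, parent_dist):
        length = max(parent_dist - n.dist, 0.0)
        if n.is_leaf():
            return f"{names[n.id]}:{length:.6g}"
        return f"({rec(n.left, n.dist)},{rec(n.right, n.dist)}):{length:.6g}"

    return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)});"


def embed_wells(
    scaled_rows: pd.DataFrame,
    method: str = "umap",
    seed: int = 0,
    labels: pd.Series | None = None,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    n_neighbors: int = 15,
) -> tuple[pd.DataFrame, float | None]:
    """2-D embedding of scaled well rows via an established implementation.

    Returns (coords with columns x, y, indexed like the input) and, when
    binary ``labels`` are given, the silhouette score of the grouping in
    the embedded space as a separability diagnostic.  Deterministic under
    ``seed``.
    """
    if len(scaled_rows) < 10:
        raise ValueError("need at least 10 rows to embed")
    X = scaled_rows[list(feature_names)].to_numpy(dtype=float)
    if method == "umap":
        import umap

        nn = min(n_neighbors, len(scaled_rows) - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(n_components=2, random_state=seed, n_neighbors=nn)
            coords = reducer.fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}; supported: 'umap'")
    df = pd.DataFrame(coords, columns=["x", "y"], index=scaled_rows.index)
    sil = None
    if labels is not None:
        from sklearn.metrics import silhouette_score

        lab = np.asarray(labels)
        if len(np.unique(lab)) >= 2 and not np.allclose(coords.std(axis=0), 0):
            sil = float(silhouette_score(coords, lab))
        else:
            warnings.warn("degenerate embedding or single class; no silhouette")
    return df, sil
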