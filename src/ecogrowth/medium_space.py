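"""Low-dimensional structure of the medium-combination space.

Component concentrations are rescaled per component into the unit
interval, projected onto their leading principal components, clustered by
k-means on the (PC1, PC2) plane, and the scores are correlated with the
growth parameters by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .synthetic import MediumDesign


@dataclass
class ScoreTable:
    """Per-combination PC scores with explained-variance fractions."""

    scores: pd.DataFrame               # columns PC1, PC2, ...
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame             # rows components, columns PCs
    labels: pd.Series | None = None    # cluster label per combination


def normalize_concentrations(design: MediumDesign | pd.DataFrame) -> pd.DataFrame:
    """Rescale each component into [0, 1] by its maximum across combinations.

    The designed minimum of every component is zero, so this is min-max
    scaling with the minimum pinned at 0.  All-zero columns stay all-zero;
    an entirely zero design is an error.
    """
    table = design.combinations if isinstance(design, MediumDesign) else design
    if (table < 0).to_numpy().any():
        raise ValueError("concentrations must be non-negative")
    maxima = table.max(axis=0)
    if (maxima == 0).all():
        raise ValueError("design is entirely zero; nothing to normalize")
    scale = maxima.replace(0, 1.0)
    return table / scale


def pca_scores(matrix: pd.DataFrame, n_pc: int = 2) -> ScoreTable:
    """Mean-centred PCA of the normalized medium matrix.

    The sign of each principal axis is fixed so that the largest-magnitude
    entry of its loading vector is positive, making scores deterministic.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 combinations and 2 components")
    values = matrix.to_numpy(float)
    if np.allclose(values - values.mean(axis=0), 0):
        raise ValueError("matrix has rank 0 after centring; PCA undefined")
    n_pc = min(n_pc, min(matrix.shape))
    pca = PCA(n_components=n_pc)
    scores = pca.fit_transform(values)
    loadings = pca.components_.copy()
    for i in range(n_pc):
        peak = np.argmax(np.abs(loadings[i]))
        if loadings[i, peak] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    cols = [f"PC{i + 1}" for i in range(n_pc)]
    return ScoreTable(
        scores=pd.DataFrame(scores, index=matrix.index, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(loadings.T, index=matrix.columns, columns=cols),
    )


def kmeans_clusters(scores: ScoreTable, k: int = 4, seed: int = 0) -> pd.Series:
    """K-means on the (PC1, PC2) plane with seeded multi-start.

    Ten restarts; best inertia kept.  Labels are relabelled by descending
    cluster size (ties broken by original label) so the labelling is
    deterministic.  The labels are also stored on ``scores.labels``.
    """
    pts = scores.scores[["PC1", "PC2"]].to_numpy()
    n_distinct = len(np.unique(pts, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct score points")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(pts)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = pd.Series(remap[raw], index=scores.scores.index, name="cluster")
    scores.labels = labels
    return labels


def correlate_with_parameters(scores: ScoreTable, params: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of each PC with each growth parameter.

    Rows flagged unreliable for a parameter (``flag_<parameter>`` columns,
    when present) and rows with missing values are dropped pairwise.  A
    constant input vector leaves rho undefined (NaN).
    """
    rows = []
    common = scores.scores.index.intersection(params.index)
    for pc in scores.scores.columns:
        for param in ("tau", "rate", "capacity"):
            if param not in params.columns:
                continue
            sub = pd.DataFrame({
                "score": scores.scores.loc[common, pc],
                "value": params.loc[common, param],
            })
            flag_col = f"flag_{param}"
            if flag_col in params.columns:
                sub = sub[~params.loc[common, flag_col].astype(bool)]
            sub = sub.dropna()
            if len(sub) < 3:
                raise ValueError(
                    f"fewer than 3 paired observations for {pc} vs {param}")
            if sub["score"].nunique() == 1 or sub["value"].nunique() == 1:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(sub["score"], sub["value"])
            rows.append({"pc": pc, "parameter": param, "rho": rho,
                         "p_value": p, "n": len(sub)})
    return pd.DataFrame(rows)
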