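"""Asset-based socioeconomic score and weighted quintiles.

The household socioeconomic score is the first principal component of
the standardized asset battery (correlation-matrix PCA, the usual choice
for binary assets of unequal prevalence). Quintiles are cut on
cumulative survey weight so each holds ~20% of the weighted population.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._stats import _as_weights, fractional_rank, rank_quintile


@dataclass
class WealthResult:
    scores: pd.Series            # one score per row, mean ~0
    loadings: pd.Series          # per-asset weight on the first component
    explained_share: float       # share of variance carried by the score
    dropped: list[str]           # constant asset columns removed


def wealth_scores(assets: pd.DataFrame, weights=None,
                  orient_asset: str | None = None) -> WealthResult:
    """First-principal-component SES score from an asset matrix.

    Parameters
    ----------
    assets
        Binary (or real) asset indicators, one column per asset.
    weights
        Optional survey weights; when given, standardization and the
        covariance use the weights (weighted PCA). Default unweighted.
    orient_asset
        Column whose loading is forced positive, declaring which asset
        marks the "privileged" direction. Default: the asset with the
        largest absolute loading is oriented positive.
    """
    assets = pd.DataFrame(assets).astype(float)
    if assets.shape[0] == 0:
        raise ValueError("empty asset matrix")
    w = _as_weights(weights, len(assets))
    sw = w.sum()

    means = assets.mul(w, axis=0).sum() / sw
    var = (assets.sub(means) ** 2).mul(w, axis=0).sum() / sw
    dropped = list(var.index[var <= 0])
    if dropped:
        warnings.warn(f"dropping constant asset columns: {dropped}", stacklevel=2)
    keep = [c for c in assets.columns if c not in dropped]
    if not keep:
        raise ValueError("no asset variance: all asset columns are constant")

    X = assets[keep]
    Z = (X - means[keep]) / np.sqrt(var[keep])
    if weights is None:
        pca = PCA(n_components=1)
        scores = pca.fit_transform(Z.to_numpy())[:, 0]
        loadings = pca.components_[0]
        explained = float(pca.explained_variance_ratio_[0])
    else:
        C = (Z.to_numpy().T * w) @ Z.to_numpy() / sw
        eigval, eigvec = np.linalg.eigh(C)
        loadings = eigvec[:, -1]
        scores = Z.to_numpy() @ loadings
        explained = float(eigval[-1] / eigval.sum())

    loadings = pd.Series(loadings, index=keep, name="loading")
    if orient_asset is not None:
        if orient_asset not in loadings.index:
            raise ValueError(f"orientation asset {orient_asset!r} not among asset columns")
        flip = loadings[orient_asset] < 0
    else:
        flip = loadings.iloc[np.argmax(np.abs(loadings.to_numpy()))] < 0
    if flip:
        loadings, scores = -loadings, -scores

    return WealthResult(scores=pd.Series(scores, index=assets.index, name="ses_score"),
                        loadings=loadings, explained_share=explained, dropped=dropped)


def weighted_quintiles(score, weights=None) -> np.ndarray:
    """Quintile labels 1-5 with boundaries at cumulative-weight fractions
    0.2/0.4/0.6/0.8; tied scores share the quintile of their tie group's
    mid-point cumulative weight."""
    score = np.asarray(score, dtype=float)
    if len(score) == 0:
        raise ValueError("empty score vector")
    return rank_quintile(fractional_rank(score, weights))
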