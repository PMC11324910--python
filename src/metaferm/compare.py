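"""Cross-project comparison of taxonomic profiles.

Profiles (per-sample relative abundances over taxa) are compared with the
Bray-Curtis dissimilarity, BC = 1 - sum_t min(p_t, q_t) on the simplex.
For ordination the dissimilarities are inverted to similarities S = 1 - BC
and a PCA is run on the rows of S, mirroring pipelines that feed a
similarity matrix row-wise into a generic PCA; classical principal
coordinates on the dissimilarity itself is available as an alternative
mode.  Bray-Curtis is a semimetric (no triangle inequality), and PCA
scores are only defined up to rotation and sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

logger = logging.getLogger("metaferm")


def _as_composition(p: pd.Series, warn_label: str = "profile") -> pd.Series:
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = float(p.sum())
    if total == 0:
        raise ValueError("profile sums to zero")
    if abs(total - 1.0) > 1e-8:
        logger.warning("%s not normalized (sum %.4g); renormalizing", warn_label, total)
        return p / total
    return p


def bray_curtis(p: pd.Series, q: pd.Series) -> float:
    """Bray-Curtis dissimilarity of two relative-abundance profiles.

    Profiles are aligned on the union of taxa (missing taxa count as zero)
    and renormalized with a warning if needed.  0 = identical, 1 = disjoint.
    """
    taxa = p.index.union(q.index)
    pv = _as_composition(p.reindex(taxa, fill_value=0.0), "first profile")
    qv = _as_composition(q.reindex(taxa, fill_value=0.0), "second profile")
    return float(1.0 - np.minimum(pv.to_numpy(), qv.to_numpy()).sum())


def bc_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis matrix; rows of ``profiles`` are samples."""
    sums = profiles.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("every profile must have positive total abundance")
    if (np.abs(sums - 1.0) > 1e-8).any():
        logger.warning("profiles not normalized; renormalizing rows")
    norm = profiles.div(sums, axis=0)
    d = squareform(pdist(norm.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # sample x (PC1, PC2)
    explained_variance: tuple[float, float]
    degenerate: bool = False         # fewer than 3 distinct profiles


def ordinate(profiles: pd.DataFrame, mode: str = "pca") -> OrdinationResult:
    """2-D ordination of inverted Bray-Curtis dissimilarities.

    ``mode="pca"`` runs PCA on the rows of the similarity matrix 1 - BC;
    ``mode="pcoa"`` runs classical principal coordinates (metric MDS via
    double centering) on BC itself.  Requires >= 3 samples; fewer than 3
    distinct profiles is flagged as degenerate.
    """
    if profiles.shape[0] < 3:
        raise ValueError("ordination needs at least 3 samples")
    bc = bc_matrix(profiles)
    degenerate = len(np.unique(np.round(profiles.to_numpy(), 12), axis=0)) < 3
    if degenerate:
        logger.warning("fewer than 3 distinct profiles; ordination is degenerate")
    if mode == "pca":
        S = 1.0 - bc.to_numpy()
        pca = PCA(n_components=2)
        with np.errstate(invalid="ignore"):  # zero variance when degenerate
            coords = pca.fit_transform(S)
            evr = np.nan_to_num(pca.explained_variance_ratio_)
    elif mode == "pcoa":
        D2 = bc.to_numpy() ** 2
        n = D2.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ D2 @ J
        vals, vecs = np.linalg.eigh(G)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        pos = np.clip(vals, 0.0, None)
        coords = vecs[:, :2] * np.sqrt(pos[:2])
        total = pos.sum() or 1.0
        evr = pos[:2] / total
    else:
        raise ValueError(f"unknown ordination mode {mode!r}")
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=profiles.index, columns=["PC1", "PC2"]),
        explained_variance=(float(evr[0]), float(evr[1])),
        degenerate=degenerate,
    )
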