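"""Two-round clustering: genus co-occurrence, then gene expression patterns.

Round one clusters genus-level relative-count profiles with repeated
k-means (k = 1..20, 50 restarts each) and scores each k by the mean
pairwise Adjusted Rand Index of the restart partitions ("cluster
support"); the chosen k maximizes support for k >= 2 and the reported
partition is the restart with the lowest within-cluster sum of squares.  A
clustergram table traces how cluster means split as k grows.

Round two takes the differentially expressed genes of each genus, row-
normalizes them to shares, and clusters them with DBSCAN (minpts fixed at
3) over an epsilon grid expressed as percentages of the maximum pairwise
distance.  Each clustering is scored with the tau concordance index
(within-pair vs between-pair distance comparisons) and the best-tau
epsilon is kept unless an explicit override is given.  Clusters are then
classified into the three trajectory classes seen in fermentation data:
expressed only at t0, expressed only in the control at 48 h, or silent at
t0 and upregulated later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.cluster import DBSCAN

from .io import SampleMeta

logger = logging.getLogger("metaferm")

NOISE = "NOISE"
PATTERN_CLASSES = ("T0_ONLY", "CONTROL_LATE", "UP_LATE", "OTHER")


@dataclass
class GenusFilterParams:
    min_avg_count: float = 10.0
    min_condition_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.min_avg_count < 0 or self.min_condition_fraction < 0:
            raise ValueError("filter parameters must be >= 0")


def select_genera(
    counts: pd.DataFrame,
    genus_labels: Mapping[str, str],
    samples: Sequence[SampleMeta],
    params: GenusFilterParams | None = None,
) -> list[str]:
    """Genera worth clustering: abundant on average or dominant somewhere.

    A genus is kept iff its mean count per gene (over its genes and all
    samples) is >= ``min_avg_count``, or its share of all reads exceeds
    ``min_condition_fraction`` in at least one condition.
    """
    params = params or GenusFilterParams()
    genus = pd.Series({g: genus_labels[g] for g in counts.index})
    cond_of = {s.sample_id: s.condition for s in samples}
    cond_totals = counts.sum(axis=0).groupby(cond_of).sum()
    kept = []
    for name, idx in genus.groupby(genus).groups.items():
        sub = counts.loc[idx]
        avg = sub.to_numpy().mean()
        shares = sub.sum(axis=0).groupby(cond_of).sum() / cond_totals
        if avg >= params.min_avg_count or (shares > params.min_condition_fraction).any():
            kept.append(name)
    return sorted(kept)


def genus_profiles(
    counts: pd.DataFrame,
    genus_labels: Mapping[str, str],
    genera: Sequence[str],
) -> pd.DataFrame:
    """Genus x sample relative-count matrix over the selected genera."""
    genus = pd.Series({g: genus_labels[g] for g in counts.index})
    mask = genus.isin(genera)
    sums = counts.loc[mask].groupby(genus[mask]).sum()
    sums = sums.reindex(sorted(genera))
    totals = sums.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"sample(s) with zero counts over selected genera: {bad}")
    return sums / totals


# ---------------------------------------------------------------------------
# k-means stability


@dataclass
class ClusterStabilityReport:
    support_per_k: pd.Series           # k -> mean pairwise ARI over restarts
    chosen_k: int
    final_partition: pd.Series         # row label -> cluster id
    clustergram: pd.DataFrame          # k, cluster, size, center_mean, parent
    skipped_k: list[int] = field(default_factory=list)
    n_degenerate_runs: int = 0


def adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand Index of two labelings via the contingency table.

    Chance-corrected pair-counting agreement; 1 for identical partitions,
    ~0 for independent ones.  Degenerate pairs (both partitions trivial)
    return 1.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    n = len(a)
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    cont = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb)

    def comb2(x: np.ndarray) -> float:
        return float((x * (x - 1) / 2).sum())

    index = comb2(cont)
    sum_a = comb2(cont.sum(axis=1))
    sum_b = comb2(cont.sum(axis=0))
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((index - expected) / (max_index - expected))


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (deterministic output)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def kmeans_stability(
    matrix: pd.DataFrame,
    k_range: Iterable[int] = range(1, 21),
    n_restarts: int = 50,
    max_iter: int = 100_000,
    seed: int = 0,
) -> ClusterStabilityReport:
    """Stability-assessed k-means over a range of cluster counts.

    For each k, ``n_restarts`` runs with distinct sub-seeds are performed;
    support is the mean Adjusted Rand Index over all run pairs.  k values
    exceeding the number of rows are skipped with a warning; k = 1 is
    reported but never chosen (its support is trivially 1).
    """
    X = matrix.to_numpy(dtype=float)
    n_rows = X.shape[0]
    if n_rows < 2:
        raise ValueError("need at least two rows to cluster")
    rng = np.random.default_rng(seed)
    support: dict[int, float] = {}
    best_runs: dict[int, np.ndarray] = {}
    skipped: list[int] = []
    n_degenerate = 0
    for k in k_range:
        if k > n_rows:
            skipped.append(k)
            logger.warning("k=%d exceeds %d rows; skipped", k, n_rows)
            continue
        labelings = []
        inertias = []
        for _ in range(n_restarts):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # empty-cluster guard below
                centers, labels = kmeans2(
                    X, k, iter=min(max_iter, 100), minit="++", seed=sub_seed
                )
            if len(np.unique(labels)) < k:
                n_degenerate += 1
            labelings.append(labels)
            inertias.append(float(((X - centers[labels]) ** 2).sum()))
        pairs = []
        for i in range(len(labelings)):
            for j in range(i + 1, len(labelings)):
                pairs.append(adjusted_rand(labelings[i], labelings[j]))
        support[k] = float(np.mean(pairs)) if pairs else 1.0
        best_runs[k] = _canonical_labels(labelings[int(np.argmin(inertias))])
    support_s = pd.Series(support).sort_index()
    # k = 1 and k = n_rows are trivially stable (one cluster / all
    # singletons), so they are reported but never chosen
    candidates = support_s[(support_s.index >= 2) & (support_s.index < n_rows)]
    if candidates.empty:
        candidates = support_s[support_s.index >= 2]
    if candidates.empty:
        raise ValueError("no usable k >= 2 in k_range")
    chosen_k = int(candidates.idxmax())  # ties -> smallest k
    final = pd.Series(best_runs[chosen_k], index=matrix.index, name="cluster")
    # clustergram: per-k cluster means with plurality parent at k-1
    rows = []
    prev_k = None
    for k in sorted(best_runs):
        labels = best_runs[k]
        for c in range(labels.max() + 1):
            members = labels == c
            parent = -1
            if prev_k is not None:
                parent_labels = best_runs[prev_k][members]
                parent = int(np.bincount(parent_labels).argmax())
            rows.append(
                {
                    "k": k, "cluster": c, "size": int(members.sum()),
                    "center_mean": float(X[members].mean()) if members.any() else np.nan,
                    "parent": parent,
                }
            )
        prev_k = k
    return ClusterStabilityReport(
        support_per_k=support_s,
        chosen_k=chosen_k,
        final_partition=final,
        clustergram=pd.DataFrame(rows),
        skipped_k=skipped,
        n_degenerate_runs=n_degenerate,
    )


# ---------------------------------------------------------------------------
# row normalization and tau


def row_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Divide each row by its sum; all-zero rows are removed and reported."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative entries")
    sums = matrix.sum(axis=1)
    dropped = sums.index[sums == 0].tolist()
    if dropped:
        logger.warning("row_normalize: dropped %d all-zero rows", len(dropped))
    kept = matrix.loc[sums > 0]
    return kept.div(kept.sum(axis=1), axis=0), dropped


def tau_index(labels: Sequence[int], distances: np.ndarray) -> float:
    """Concordance between pairwise distances and cluster co-membership.

    Over all (within-cluster pair w, between-cluster pair b) comparisons,
    concordant means d(w) < d(b) and discordant d(w) > d(b); ties count
    zero.  tau = (C - D) / (|W| |B|), in [-1, 1].  ``distances`` may be a
    square matrix or a condensed vector in ``pdist`` order.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if distances.ndim == 2:
        d = squareform(distances, checks=False)
    else:
        d = np.asarray(distances, dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    w = np.sort(d[same])
    b = np.sort(d[~same])
    if len(w) == 0 or len(b) == 0 or len(np.unique(labels)) < 2:
        raise ValueError("tau undefined: need >= 2 clusters with within and between pairs")
    # for each within distance: count strictly larger / strictly smaller b
    conc = len(b) * len(w) - np.searchsorted(b, w, side="right").sum()
    disc = np.searchsorted(b, w, side="left").sum()
    return float((conc - disc) / (len(w) * len(b)))


# ---------------------------------------------------------------------------
# DBSCAN pattern detection


@dataclass
class DbscanSelection:
    minpts: int = 3
    epsilon_grid: tuple[float, ...] = tuple(np.arange(1, 51) / 100.0)
    override_epsilon: float | None = None
    override_reason: str = ""


@dataclass
class DbscanResult:
    labels: pd.Series                  # row -> cluster id, -1 for noise
    chosen_epsilon: float              # fraction of the max pairwise distance
    tau_curve: pd.DataFrame            # epsilon, tau (NaN where undefined)
    max_distance: float


def dbscan_patterns(
    matrix: pd.DataFrame, selection: DbscanSelection | None = None
) -> DbscanResult:
    """Euclidean DBSCAN over an epsilon grid with tau model selection.

    Epsilons are fractions of the maximum pairwise distance.  The epsilon
    with the highest tau wins (ties -> smallest epsilon); if tau is
    undefined everywhere (e.g. a single cluster), the labeling with the
    fewest noise points at the smallest epsilon is returned.  Fewer than
    ``minpts`` rows yields all-noise.
    """
    sel = selection or DbscanSelection()
    n = matrix.shape[0]
    if n < sel.minpts:
        return DbscanResult(
            labels=pd.Series(-1, index=matrix.index),
            chosen_epsilon=float("nan"),
            tau_curve=pd.DataFrame({"epsilon": [], "tau": []}),
            max_distance=float("nan"),
        )
    X = matrix.to_numpy(dtype=float)
    d = pdist(X)
    max_d = float(d.max())
    rows = []
    results: dict[float, np.ndarray] = {}
    for frac in sel.epsilon_grid:
        eps = frac * max_d
        if eps <= 0:
            rows.append({"epsilon": frac, "tau": np.nan, "n_clusters": 0, "n_noise": n})
            continue
        labels = DBSCAN(eps=eps, min_samples=sel.minpts).fit(X).labels_
        results[frac] = labels
        core = labels >= 0
        tau = np.nan
        if core.sum() >= 2 and len(np.unique(labels[core])) >= 2:
            sub = squareform(d, checks=False)[np.ix_(core, core)]
            try:
                tau = tau_index(labels[core], sub)
            except ValueError:
                tau = np.nan
        rows.append(
            {
                "epsilon": frac, "tau": tau,
                "n_clusters": int(len(np.unique(labels[core]))) if core.any() else 0,
                "n_noise": int((~core).sum()),
            }
        )
    curve = pd.DataFrame(rows)
    if sel.override_epsilon is not None:
        chosen = sel.override_epsilon
        if chosen not in results:
            eps = chosen * max_d
            results[chosen] = DBSCAN(eps=eps, min_samples=sel.minpts).fit(X).labels_
        logger.info("dbscan: epsilon override %.3f (%s)", chosen, sel.override_reason)
    elif curve["tau"].notna().any():
        # ties at the best tau: prefer the clustering explaining more
        # points (fewest noise), then the smaller epsilon
        best = curve.sort_values(
            ["tau", "n_noise", "epsilon"], ascending=[False, True, True]
        ).iloc[0]
        chosen = float(best["epsilon"])
    else:
        defined = curve.dropna(subset=["n_noise"])
        min_noise = defined["n_noise"].min()
        chosen = float(defined.loc[defined["n_noise"] == min_noise, "epsilon"].min())
        if chosen not in results:  # eps grid was all zero-distance
            results[chosen] = np.zeros(n, dtype=int)
    labels = pd.Series(results[chosen], index=matrix.index, name="cluster")
    return DbscanResult(
        labels=labels, chosen_epsilon=chosen,
        tau_curve=curve[["epsilon", "tau"]], max_distance=max_d,
    )


# ---------------------------------------------------------------------------
# pattern classification


@dataclass(frozen=True)
class PatternAssignment:
    gene_id: str
    genus: str
    cluster: int                        # -1 for noise
    pattern: str | None                 # None for noise

    @property
    def is_noise(self) -> bool:
        return self.cluster < 0


def _classify_gene(
    cell_means: pd.Series, theta: float
) -> str:
    """Pattern of one row-normalized gene over (condition, time) cell means."""
    expressed = cell_means[cell_means >= theta]
    t0_expr = any(t == 0 for _, t in expressed.index)
    later = [(c, t) for c, t in expressed.index if t > 0]
    if t0_expr and not later:
        return "T0_ONLY"
    if not t0_expr and later and all(c == "BLANK" and t == 48 for c, t in later):
        return "CONTROL_LATE"
    if not t0_expr and later:
        times = np.array([t for _, t in cell_means.index], dtype=float)
        rho = spearmanr(cell_means.to_numpy(), times).statistic
        if np.isnan(rho) or rho >= 0:
            return "UP_LATE"
    return "OTHER"


def classify_patterns(
    matrix: pd.DataFrame,
    samples: Sequence[SampleMeta],
    clusters: pd.Series,
    genus: str = "",
    theta: float = 0.15,
) -> list[PatternAssignment]:
    """Assign a trajectory class to every clustered gene.

    ``matrix`` rows must be normalized to sum 1; a (condition, time) cell is
    "expressed" when its mean share over replicates is >= ``theta``.  The
    label of a DBSCAN cluster is the majority vote of its member genes;
    noise genes carry no pattern.
    """
    meta = {s.sample_id: (s.condition, s.time_h) for s in samples}
    cols = list(matrix.columns)
    if not any(meta[c][1] == 0 for c in cols):
        raise ValueError("no t0 columns in sample metadata")
    cells = pd.MultiIndex.from_tuples([meta[c] for c in cols])
    cell_means = matrix.T.groupby(cells).mean().T  # genes x (condition, time)
    gene_patterns = {
        g: _classify_gene(cell_means.loc[g], theta) for g in matrix.index
    }
    out: list[PatternAssignment] = []
    for c in sorted(clusters.unique()):
        members = clusters.index[clusters == c]
        if c < 0:
            out.extend(PatternAssignment(g, genus, -1, None) for g in members)
            continue
        votes = pd.Series([gene_patterns[g] for g in members])
        majority = votes.value_counts().idxmax()
        out.extend(PatternAssignment(g, genus, int(c), majority) for g in members)
    return out
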