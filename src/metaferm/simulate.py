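"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates an in-vitro fermentation metatranscriptome: a small
bacterial taxonomy, a gene catalog annotated down to species, negative-
binomial time-series counts in which both genus-level co-occurrence
clusters and gene-level expression patterns are planted, alignment-hit
tables with known post-filter LCA ground truth, and 16S relative-abundance
tables rank-coupled to the expression-derived activity at a chosen Spearman
correlation.  Every quantity is drawn from a single :class:`numpy.random
.Generator`, so a fixed seed reproduces byte-identical files.

Planted gene patterns mirror the three trajectory classes the pattern
mining stage is meant to recover: genes expressed only at t0, genes
expressed only in the substrate-free control at 48 h, and genes silent at
t0 that rise monotonically afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io import (
    CONDITIONS,
    CountMatrix,
    GeneRecord,
    SampleMeta,
    AlignmentHit,
    write_catalog,
    write_counts,
    write_hits,
    write_taxonomy,
)
from .taxonomy import TaxonomyTree

# genus, family, order  (orders are shared where the real lineages share them,
# so higher-rank LCAs are exercised)
_GENUS_TABLE = [
    ("Bacteroides", "Bacteroidaceae", "Bacteroidales"),
    ("Bifidobacterium", "Bifidobacteriaceae", "Bifidobacteriales"),
    ("Lactobacillus", "Lactobacillaceae", "Lactobacillales"),
    ("Enterococcus", "Enterococcaceae", "Lactobacillales"),
    ("Clostridium", "Clostridiaceae", "Clostridiales"),
    ("Escherichia", "Enterobacteriaceae", "Enterobacteriales"),
    ("Anaerostipes", "Lachnospiraceae", "Clostridiales"),
    ("Ruminococcus", "Ruminococcaceae", "Clostridiales"),
]

GENE_PATTERNS = ("T0_ONLY", "CONTROL_LATE", "UP_LATE", "FLAT")

#: Trajectory shapes for planted genus co-occurrence clusters.
CLUSTER_SHAPES = ("T0_PEAK", "IMMP_UP", "STEADY", "CONTROL_LATE")

#: Glycoside hydrolase family 13 / starch-and-sucrose enzymes carried by the
#: simulated catalogs (alpha-amylase, oligo-1,6-glucosidase, dextranase,
#: alpha-glucosidase, amylo-alpha-1,6-glucosidase, isomaltase, pullulanase-
#: type, glycogen phosphorylase, 4-alpha-glucanotransferase).
GH13_ECS = (
    "3.2.1.1", "3.2.1.10", "3.2.1.11", "3.2.1.20", "3.2.1.33",
    "3.2.1.68", "3.2.1.135", "2.4.1.1", "2.4.1.25",
)

_HOUSEKEEPING_ECS = (
    "1.1.1.1", "2.7.7.6", "6.1.1.1", "1.2.1.12", "2.3.1.9",
    "4.1.1.1", "1.6.5.3", "5.3.1.9", "2.7.1.1", "3.6.4.12",
)


def simulate_taxonomy(
    n_genera: int, species_per_genus: int, seed: int = 0
) -> TaxonomyTree:
    """Six-level taxonomy: root / superkingdom / order / family / genus / species.

    Genus names cycle through common gut genera (Bacteroides,
    Bifidobacterium, ...); all leaves sit at species rank.  The layout is
    deterministic; ``seed`` is accepted for interface symmetry.
    """
    if n_genera < 1:
        raise ValueError("n_genera must be >= 1")
    edges: list[tuple[int, int, str]] = [(1, 1, "no rank"), (2, 1, "superkingdom")]
    names: dict[int, str] = {1: "root", 2: "Bacteria"}
    next_id = 3
    order_ids: dict[str, int] = {}
    for i in range(n_genera):
        if i < len(_GENUS_TABLE):
            genus, family, order = _GENUS_TABLE[i]
        else:
            genus, family, order = f"Genus{i}", f"Family{i}", f"Order{i % 4}"
        if order not in order_ids:
            order_ids[order] = next_id
            edges.append((next_id, 2, "order"))
            names[next_id] = order
            next_id += 1
        fam_id = next_id
        edges.append((fam_id, order_ids[order], "family"))
        names[fam_id] = family
        next_id += 1
        gen_id = next_id
        edges.append((gen_id, fam_id, "genus"))
        names[gen_id] = genus
        next_id += 1
        for j in range(species_per_genus):
            edges.append((next_id, gen_id, "species"))
            names[next_id] = f"{genus} sp{j + 1}"
            next_id += 1
    return TaxonomyTree.from_edges(edges, names)


@dataclass
class SimulationDesign:
    """Study design and noise model for the synthetic fermentation experiment.

    Defaults mirror the real set-up: five incubation conditions (a blank and
    four IMMP substrates), sampling at 0/6/12/24/48 h, two replicates, and
    negative-binomial counts (variance mu + alpha * mu^2, alpha = 0.3) with
    log-normal library sizes around ``mean_depth``.
    """

    n_genera: int = 8
    genes_per_genus: int = 40
    species_per_genus: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    time_points_h: tuple[float, ...] = (0, 6, 12, 24, 48)
    replicates: int = 2
    pattern_proportions: dict = field(
        default_factory=lambda: {
            "T0_ONLY": 0.15, "CONTROL_LATE": 0.10, "UP_LATE": 0.45, "FLAT": 0.30,
        }
    )
    cluster_of_genus: tuple[int, ...] | None = None  # default: genus i -> i % 4
    nb_dispersion: float = 0.3
    mean_depth: float = 1e5
    contamination_rate: float = 0.1
    libsize_sigma: float = 0.3
    rho_16s: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.pattern_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("pattern proportions must sum to 1")
        if self.cluster_of_genus is None:
            self.cluster_of_genus = tuple(i % len(CLUSTER_SHAPES) for i in range(self.n_genera))
        if len(self.cluster_of_genus) != self.n_genera:
            raise ValueError("cluster_of_genus must cover all genera")

    def sample_sheet(self) -> list[SampleMeta]:
        samples = []
        for cond in self.conditions:
            exp = "A" if cond in ("BLANK", "IMMP27", "IMMP94") else "B"
            for t in self.time_points_h:
                for rep in range(1, self.replicates + 1):
                    samples.append(
                        SampleMeta(
                            sample_id=f"{cond}_t{int(t)}_r{rep}",
                            condition=cond,
                            time_h=float(t),
                            replicate=rep,
                            experiment=exp,
                        )
                    )
        return samples


def _genus_factor(shape: str, condition: str, time_h: float) -> float:
    """Relative-activity trajectory of one planted genus cluster."""
    frac = time_h / 48.0
    if shape == "T0_PEAK":
        return 1.0 if time_h == 0 else 0.05
    if shape == "IMMP_UP":
        return 0.1 if condition == "BLANK" else 0.2 + 0.8 * frac
    if shape == "STEADY":
        return 0.5 + 0.3 * frac
    if shape == "CONTROL_LATE":
        return 1.0 if (condition == "BLANK" and time_h == 48) else 0.08
    raise ValueError(f"unknown cluster shape {shape!r}")


def _pattern_factor(pattern: str, condition: str, time_h: float) -> float:
    """Expression-pattern multiplier for one planted gene class."""
    if pattern == "FLAT":
        return 1.0
    if pattern == "T0_ONLY":
        return 1.0 if time_h == 0 else 0.0
    if pattern == "CONTROL_LATE":
        return 1.0 if (condition == "BLANK" and time_h == 48) else 0.0
    if pattern == "UP_LATE":
        return time_h / 48.0
    raise ValueError(f"unknown gene pattern {pattern!r}")


def simulate_catalog(
    tree: TaxonomyTree, design: SimulationDesign, rng: np.random.Generator
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Gene catalog plus per-gene ground truth (genus, species, pattern).

    A handful of genes per genus carry glycoside-hydrolase-13 EC numbers so
    the functional profiling stage has realistic starch/sucrose members;
    the rest carry housekeeping ECs, partial ECs, KO ids, or nothing.
    """
    genus_ids = tree.nodes_at_rank("genus")
    if len(genus_ids) != design.n_genera:
        raise ValueError("tree does not match design.n_genera")
    patterns = list(design.pattern_proportions)
    genes: list[GeneRecord] = []
    truth_rows = []
    gi = 0
    for g_idx, genus in enumerate(genus_ids):
        species = [t for t in tree.parent if tree.parent[t] == genus]
        n = design.genes_per_genus
        # deterministic per-genus pattern counts, shuffled within the genus
        counts = {p: int(round(design.pattern_proportions[p] * n)) for p in patterns}
        while sum(counts.values()) < n:
            counts["FLAT"] += 1
        while sum(counts.values()) > n:
            counts[max(counts, key=counts.get)] -= 1
        labels = [p for p in patterns for _ in range(counts[p])]
        rng.shuffle(labels)
        for k in range(n):
            gene_id = f"g{gi:05d}"
            sp = int(rng.choice(species))
            length = int(np.clip(rng.lognormal(mean=6.8, sigma=0.5), 150, 6000))
            ecs: tuple[str, ...] = ()
            kos: tuple[str, ...] = ()
            cazy: tuple[str, ...] = ()
            if k < 6:  # GH13 block
                ecs = (GH13_ECS[(g_idx + k) % len(GH13_ECS)],)
                cazy = ("GH13",)
                kos = (f"K{1176 + k:05d}",)
            elif rng.random() < 0.55:
                ecs = (str(rng.choice(_HOUSEKEEPING_ECS)),)
                if rng.random() < 0.3:
                    kos = (f"K{int(rng.integers(2000, 20000)):05d}",)
            elif rng.random() < 0.1:
                ecs = ("3.2.1.-",)
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=f"contig{gi // 4:04d}",
                    length_bp=length,
                    ec_numbers=ecs,
                    ko_ids=kos,
                    cazy_families=cazy,
                    taxon_id=sp,
                )
            )
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "genus": tree.name[genus],
                    "genus_taxid": genus,
                    "species_taxid": sp,
                    "pattern": labels[k],
                }
            )
            gi += 1
    return genes, pd.DataFrame(truth_rows)


@dataclass
class SimulatedCounts:
    matrix: CountMatrix
    mean_matrix: pd.DataFrame       # realized NB means (depth-rescaled)
    raw_means: pd.DataFrame         # planted trajectory x pattern surface
    library_sizes: pd.Series


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mu + alpha * mu^2 (Poisson as alpha->0)."""
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if alpha <= 1e-12:
        out[pos] = rng.poisson(mu[pos])
        return out
    n = 1.0 / alpha
    p = n / (n + mu[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_counts(
    design: SimulationDesign,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> SimulatedCounts:
    """Counts around genus-trajectory x gene-pattern mean surfaces.

    The per-gene mean is base weight x genus trajectory x pattern profile,
    column-rescaled to a log-normal library size.  Cells with exactly zero
    mean receive a small Poisson contamination (default 0.1 expected
    counts) so downstream zero handling is exercised.
    """
    if truth.empty:
        raise ValueError("empty catalog")
    samples = design.sample_sheet()
    n_genes, n_samples = len(truth), len(samples)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    raw = np.zeros((n_genes, n_samples))
    shapes = [CLUSTER_SHAPES[c] for c in design.cluster_of_genus]
    # genus order in the truth table follows the tree (design order); map
    # shapes by first occurrence
    genus_names = truth["genus"].tolist()
    first_seen: dict[str, int] = {}
    for name in genus_names:
        if name not in first_seen:
            first_seen[name] = len(first_seen)
    shape_of_genus_name = {
        name: shapes[first_seen[name]] for name in first_seen
    }
    patterns = truth["pattern"].tolist()
    for j, s in enumerate(samples):
        for i in range(n_genes):
            raw[i, j] = (
                base[i]
                * _genus_factor(shape_of_genus_name[genus_names[i]], s.condition, s.time_h)
                * _pattern_factor(patterns[i], s.condition, s.time_h)
            )
    lib = design.mean_depth * np.exp(
        rng.normal(0.0, design.libsize_sigma, size=n_samples)
        - design.libsize_sigma**2 / 2.0
    )
    col_mass = raw.sum(axis=0)
    mu = raw / col_mass * lib
    counts = _nb_draw(rng, mu, design.nb_dispersion)
    if design.contamination_rate > 0:
        zero = mu == 0
        counts[zero] += rng.poisson(design.contamination_rate, size=int(zero.sum()))
    gene_ids = truth["gene_id"].tolist()
    cols = [s.sample_id for s in samples]
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=cols),
        samples=samples,
    )
    return SimulatedCounts(
        matrix=cm,
        mean_matrix=pd.DataFrame(mu, index=cm.counts.index, columns=cols),
        raw_means=pd.DataFrame(raw, index=cm.counts.index, columns=cols),
        library_sizes=pd.Series(lib, index=cols),
    )


# ---------------------------------------------------------------------------
# alignment hits with LCA ground truth


@dataclass
class HitSimParams:
    """Rates for true-lineage hits and the three engineered decoy classes."""

    n_true_hits: int = 2
    sibling_prob: float = 0.3
    decoy_low_score_rate: float = 0.5
    decoy_short_rate: float = 0.5
    decoy_out_of_band_rate: float = 0.5


def simulate_hits(
    truth: pd.DataFrame,
    tree: TaxonomyTree,
    params: HitSimParams,
    rng: np.random.Generator,
) -> tuple[list[AlignmentHit], pd.DataFrame, pd.DataFrame]:
    """Hit tables with known post-filter LCA.

    Per gene: true-lineage hits engineered to pass every filter (top
    bit-score T in [150, 300), others within 92-100% of T, lengths > 100,
    tiny E-values), optionally one hit to a sibling species (making the
    designed LCA the genus), plus decoys each engineered to fail exactly
    one filter: bit-score <= 50, length <= 100, or bit-score below the 10%
    band.  Returns (hits, per-row truth labels, per-gene designed LCA).
    """
    hits: list[AlignmentHit] = []
    label_rows = []
    lca_rows = []
    all_species = tree.nodes_at_rank("species")
    for r in truth.itertuples():
        gene, sp, genus = r.gene_id, int(r.species_taxid), int(r.genus_taxid)
        t_best = float(rng.uniform(150, 300))
        gene_hits: list[tuple[AlignmentHit, str]] = []

        def mk(taxid, bitscore, length, evalue, ident):
            return AlignmentHit(
                query=gene, subject=f"acc{int(rng.integers(0, 10**6)):06d}",
                identity=round(float(ident), 1), length=int(length),
                mismatches=int(rng.integers(0, 10)), gap_opens=int(rng.integers(0, 3)),
                qstart=1, qend=int(length), sstart=1, send=int(length),
                evalue=float(evalue), bitscore=round(float(bitscore), 1), taxid=int(taxid),
            )

        truth_taxa = [sp]
        for k in range(params.n_true_hits):
            b = t_best if k == 0 else rng.uniform(0.92 * t_best, t_best)
            gene_hits.append(
                (mk(sp, b, rng.integers(150, 501), 1e-30, rng.uniform(90, 100)), "true")
            )
        if rng.random() < params.sibling_prob:
            siblings = [
                t for t in all_species if tree.parent[t] == genus and t != sp
            ]
            if siblings:
                sib = int(rng.choice(siblings))
                truth_taxa.append(sib)
                gene_hits.append(
                    (mk(sib, rng.uniform(0.92 * t_best, 0.99 * t_best),
                        rng.integers(150, 501), 1e-25, rng.uniform(85, 99)), "true")
                )
        other_species = [t for t in all_species if tree.parent[t] != genus]
        if other_species and rng.random() < params.decoy_low_score_rate:
            b = 50.0 if rng.random() < 0.25 else rng.uniform(20, 50)
            gene_hits.append(
                (mk(rng.choice(other_species), b, rng.integers(150, 501),
                    1e-8, rng.uniform(70, 90)), "decoy_low_score")
            )
        if other_species and rng.random() < params.decoy_short_rate:
            gene_hits.append(
                (mk(rng.choice(other_species), rng.uniform(0.92 * t_best, t_best),
                    rng.integers(40, 101), 1e-10, rng.uniform(80, 95)), "decoy_short")
            )
        if other_species and rng.random() < params.decoy_out_of_band_rate:
            gene_hits.append(
                (mk(rng.choice(other_species), rng.uniform(0.5 * t_best, 0.88 * t_best),
                    rng.integers(150, 501), 1e-10, rng.uniform(75, 95)), "decoy_out_of_band")
            )
        order = rng.permutation(len(gene_hits))
        for idx in order:
            h, label = gene_hits[idx]
            label_rows.append({"row": len(hits), "gene_id": gene, "label": label})
            hits.append(h)
        designed = int(r.genus_taxid) if len(truth_taxa) > 1 else sp
        lca_rows.append({"gene_id": gene, "taxid": designed})
    return hits, pd.DataFrame(label_rows), pd.DataFrame(lca_rows)


# ---------------------------------------------------------------------------
# 16S tables


def simulate_16s(
    activity: pd.DataFrame, rho_target: float, seed: int = 0
) -> pd.DataFrame:
    """16S relative-abundance table rank-coupled to an activity profile.

    Per genus, a Gaussian copula couples the ranks of the 16S values to the
    ranks of the activity values at Spearman ``rho_target`` (the Pearson
    parameter is 2 sin(pi rho / 6)); the 16S row is then the genus's own
    activity values re-ordered by the coupled ranks, and columns are
    renormalized.  rho_target = 1 therefore reproduces the activity table
    exactly.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    r = 2.0 * np.sin(np.pi * rho_target / 6.0)
    out = np.zeros(activity.shape)
    n = activity.shape[1]
    for i, (_, row) in enumerate(activity.iterrows()):
        vals = row.to_numpy(dtype=float)
        z = norm.ppf(rankdata(vals) / (n + 1))
        y = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
        order = rankdata(y, method="ordinal").astype(int) - 1
        out[i] = np.sort(vals)[order]
    df = pd.DataFrame(out, index=activity.index, columns=activity.columns)
    sums = df.sum(axis=0)
    sums[sums == 0] = 1.0
    return df / sums


# ---------------------------------------------------------------------------
# focused fixtures for calibration / recovery studies


def simulate_de_benchmark(
    n_genes: int = 2000,
    de_fraction: float = 0.0,
    fold: float = 4.0,
    mean_depth: float = 1e5,
    dispersion: float = 0.3,
    conditions: tuple[str, ...] = ("BLANK", "IMMP94"),
    times: tuple[float, ...] = (0, 48),
    replicates: int = 2,
    contamination_rate: float = 0.1,
    libsize_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Null / power benchmark counts for the differential-expression stage.

    With ``de_fraction`` = 0 every gene is flat (pure null).  Otherwise the
    first ``de_fraction`` of genes follow the late-upregulation pattern:
    mean ~ 0 at t0 rising to ``fold`` x their base weight at 48 h, in every
    condition.  Returns the counts and the boolean truth vector.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for cond in conditions:
        for t in times:
            for rep in range(1, replicates + 1):
                samples.append(
                    SampleMeta(f"{cond}_t{int(t)}_r{rep}", cond, float(t), rep, "A")
                )
    n_de = int(round(de_fraction * n_genes))
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[:n_de] = True
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    t_max = max(times)
    raw = np.zeros((n_genes, len(samples)))
    for j, s in enumerate(samples):
        frac = s.time_h / t_max if t_max > 0 else 0.0
        raw[:, j] = np.where(is_de, fold * base * frac, base)
    lib = mean_depth * np.exp(
        rng.normal(0.0, libsize_sigma, size=len(samples)) - libsize_sigma**2 / 2
    )
    mu = raw / raw.sum(axis=0) * lib
    counts = _nb_draw(rng, mu, dispersion)
    if contamination_rate > 0:
        zero = mu == 0
        counts[zero] += rng.poisson(contamination_rate, size=int(zero.sum()))
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    cm = CountMatrix(
        counts=pd.DataFrame(
            counts, index=pd.Index(gene_ids, name="gene_id"),
            columns=[s.sample_id for s in samples],
        ),
        samples=samples,
    )
    return cm, is_de


def planted_profile_matrix(
    n_clusters: int = 4,
    rows_per_cluster: int = 3,
    n_features: int = 25,
    noise_sd: float = 1.0,
    separation: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Well-separated planted row clusters for stability studies.

    Cluster centers sit on distinct coordinate axes, scaled so that the
    between-center distance is ``separation`` times the expected within-
    cluster radius (noise_sd * sqrt(n_features)); the separation parameter
    is therefore in units of the full noise scale of a row.
    """
    if n_features < n_clusters:
        raise ValueError("need n_features >= n_clusters")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_clusters), rows_per_cluster)
    centers = np.zeros((n_clusters, n_features))
    for c in range(n_clusters):
        centers[c, c] = separation * noise_sd * np.sqrt(n_features / 2.0)
    X = centers[labels] + rng.normal(0.0, noise_sd, size=(len(labels), n_features))
    idx = [f"row{i}" for i in range(len(labels))]
    return pd.DataFrame(X, index=idx), labels


def planted_pattern_profiles(
    genes_per_pattern: int = 40,
    noise_sd: float = 0.02,
    conditions: tuple[str, ...] = ("BLANK", "IMMP94"),
    times: tuple[float, ...] = (0, 24, 48),
    replicates: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[SampleMeta]]:
    """Row-normalized gene profiles with three planted trajectory classes.

    Prototypes: all mass at t0 (T0_ONLY); all mass in the blank at 48 h
    (CONTROL_LATE); mass proportional to time (UP_LATE).  Gaussian noise of
    ``noise_sd`` is added before re-normalizing each row to sum 1.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for cond in conditions:
        for t in times:
            for rep in range(1, replicates + 1):
                samples.append(
                    SampleMeta(f"{cond}_t{int(t)}_r{rep}", cond, float(t), rep, "A")
                )
    n_cols = len(samples)
    protos = {}
    v = np.array([1.0 if s.time_h == 0 else 0.0 for s in samples])
    protos["T0_ONLY"] = v / v.sum()
    v = np.array(
        [1.0 if (s.condition == "BLANK" and s.time_h == 48) else 0.0 for s in samples]
    )
    protos["CONTROL_LATE"] = v / v.sum()
    v = np.array([s.time_h for s in samples], dtype=float)
    protos["UP_LATE"] = v / v.sum()
    rows, labels = [], []
    for pat, proto in protos.items():
        for _ in range(genes_per_pattern):
            row = np.clip(proto + rng.normal(0.0, noise_sd, size=n_cols), 0.0, None)
            if row.sum() == 0:
                row = proto.copy()
            rows.append(row / row.sum())
            labels.append(pat)
    X = pd.DataFrame(
        np.asarray(rows),
        index=[f"gene{i}" for i in range(len(rows))],
        columns=[s.sample_id for s in samples],
    )
    return X, labels, samples


# ---------------------------------------------------------------------------
# full dataset assembly


@dataclass
class SimulatedDataset:
    design: SimulationDesign
    tree: TaxonomyTree
    genes: list[GeneRecord]
    truth: pd.DataFrame            # gene_id, genus, genus_taxid, species_taxid, pattern
    counts: SimulatedCounts
    hits: list[AlignmentHit]
    truth_hits: pd.DataFrame       # row, gene_id, label
    truth_lca: pd.DataFrame        # gene_id, taxid
    sixteen_s: pd.DataFrame        # genus x sample relative abundance


def simulate_dataset(
    design: SimulationDesign | None = None,
    hit_params: HitSimParams | None = None,
) -> SimulatedDataset:
    """Generate every pipeline input for one seeded design."""
    design = design or SimulationDesign()
    hit_params = hit_params or HitSimParams()
    rng = np.random.default_rng(design.seed)
    tree = simulate_taxonomy(design.n_genera, design.species_per_genus, design.seed)
    genes, truth = simulate_catalog(tree, design, rng)
    counts = simulate_counts(design, truth, rng)
    hits, truth_hits, truth_lca = simulate_hits(truth, tree, hit_params, rng)
    genus_of = dict(zip(truth["gene_id"], truth["genus"]))
    mat = counts.matrix.counts
    genus_sums = mat.groupby([genus_of[g] for g in mat.index]).sum()
    activity = genus_sums / genus_sums.sum(axis=0)
    sixteen = simulate_16s(activity, design.rho_16s, seed=design.seed + 1)
    return SimulatedDataset(
        design=design, tree=tree, genes=genes, truth=truth, counts=counts,
        hits=hits, truth_hits=truth_hits, truth_lca=truth_lca, sixteen_s=sixteen,
    )


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_taxonomy(ds.tree, out / "nodes.dmp", out / "names.dmp")
    write_catalog(ds.genes, out / "catalog.tsv")
    write_counts(ds.counts.matrix, out / "counts.tsv", out / "samples.tsv")
    write_hits(ds.hits, out / "hits.tsv")
    ds.truth_hits.to_csv(out / "truth_hits.tsv", sep="\t", index=False, lineterminator="\n")
    ds.truth_lca.to_csv(out / "truth_lca.tsv", sep="\t", index=False, lineterminator="\n")
    ds.truth[["gene_id", "genus", "pattern"]].to_csv(
        out / "truth_patterns.tsv", sep="\t", index=False, lineterminator="\n"
    )
    s16 = ds.sixteen_s.copy()
    s16.index.name = "genus"
    s16.to_csv(out / "sixteen_s.tsv", sep="\t", float_format="%.10g", lineterminator="\n")
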