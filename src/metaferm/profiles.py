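"""Functional aggregation of expression: RPKM, activity shares, pathways.

Covers reads-per-kilobase-per-million normalization, per-genus relative
transcript activity (with pooling of low-abundance genera), the fraction
of annotated reads falling on a pathway gene set (the starch-and-sucrose /
glycoside-hydrolase-13 set by default), per-organism per-enzyme RPKM
tables, recovery of EC numbers from free-text domain names by normalized
string matching, and Spearman correlation of expression-derived activity
against 16S relative abundance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import EC_PATTERN, SampleMeta

logger = logging.getLogger("metaferm")

OTHER_LABEL = "Other taxonomic assignments"


def rpkm(
    counts: pd.DataFrame,
    gene_lengths_bp: Mapping[str, int],
    mapped_totals: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of gene length per million mapped reads."""
    lengths = pd.Series({g: gene_lengths_bp[g] for g in counts.index}, dtype=float)
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")
    if mapped_totals is None:
        totals = counts.sum(axis=0).astype(float)
    else:
        totals = pd.Series({s: mapped_totals[s] for s in counts.columns}, dtype=float)
    if (totals <= 0).any():
        raise ValueError("per-sample mapped totals must be > 0")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def genus_activity(
    counts: pd.DataFrame,
    genus_labels: Mapping[str, str],
    min_display_share: float = 0.01,
) -> pd.DataFrame:
    """Per-genus share of classified reads per sample.

    Genera that never reach ``min_display_share`` in any sample are pooled
    into "Other taxonomic assignments"; unassigned genes are excluded from
    the denominator (shares are over classified reads).
    """
    genus = pd.Series({g: genus_labels[g] for g in counts.index})
    classified = genus != "Unassigned"
    sums = counts.loc[classified].groupby(genus[classified]).sum()
    shares = sums / sums.sum(axis=0)
    minor = shares.max(axis=1) < min_display_share
    if minor.any():
        pooled = shares.loc[minor].sum(axis=0)
        shares = shares.loc[~minor]
        shares.loc[OTHER_LABEL] = pooled
    return shares


@dataclass(frozen=True)
class PathwayGeneSet:
    """A named set of EC numbers, e.g. the starch-and-sucrose enzymes."""

    name: str
    ec_members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ec_members:
            raise ValueError("pathway gene set must be non-empty")
        for ec in self.ec_members:
            if not EC_PATTERN.match(ec):
                raise ValueError(f"malformed EC {ec!r} in pathway {self.name}")


#: Starch and sucrose metabolism members, glycoside hydrolase family 13
#: (alpha-amylase 3.2.1.1, oligo-1,6-glucosidase 3.2.1.10, dextranase
#: 3.2.1.11, alpha-glucosidase 3.2.1.20, amylo-alpha-1,6-glucosidase
#: 3.2.1.33, isomaltase-type 3.2.1.68, pullulan hydrolase 3.2.1.135,
#: glycogen phosphorylase 2.4.1.1, 4-alpha-glucanotransferase 2.4.1.25).
STARCH_SUCROSE = PathwayGeneSet(
    name="starch-and-sucrose",
    ec_members=frozenset(
        {"3.2.1.1", "3.2.1.10", "3.2.1.11", "3.2.1.20", "3.2.1.33",
         "3.2.1.68", "3.2.1.135", "2.4.1.1", "2.4.1.25"}
    ),
)


def _ec_matches(gene_ecs: Iterable[str], members: frozenset[str], prefix: bool) -> bool:
    for ec in gene_ecs:
        if ec in members:
            return True
        if prefix and ec.endswith("-"):
            stem = ec.rstrip("-")
            if any(m.startswith(stem) for m in members):
                return True
    return False


def pathway_fraction(
    counts: pd.DataFrame,
    gene_annotations: Mapping[str, Sequence[str]],
    gene_set: PathwayGeneSet = STARCH_SUCROSE,
    prefix_match: bool = False,
) -> pd.Series:
    """Per-sample fraction of annotated reads on pathway member genes.

    The denominator is reads on genes carrying at least one EC/KO
    annotation.  Partial ECs like "3.2.1.-" match no specific member unless
    ``prefix_match`` is set.
    """
    annotated = [g for g in counts.index if gene_annotations.get(g)]
    if not annotated:
        raise ValueError("no annotated genes: pathway fraction undefined")
    members = [
        g for g in annotated
        if _ec_matches(gene_annotations[g], gene_set.ec_members, prefix_match)
    ]
    denom = counts.loc[annotated].sum(axis=0).astype(float)
    denom[denom == 0] = np.nan
    return counts.loc[members].sum(axis=0) / denom


def organism_enzyme_matrix(
    rpkm_matrix: pd.DataFrame,
    genus_labels: Mapping[str, str],
    gene_ecs: Mapping[str, Sequence[str]],
    sample_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """(genus x EC) table of summed member-gene RPKM over selected samples."""
    cols = list(sample_subset) if sample_subset is not None else list(rpkm_matrix.columns)
    totals: dict[tuple[str, str], float] = {}
    sub = rpkm_matrix[cols]
    for g in sub.index:
        val = float(sub.loc[g].sum())
        for ec in gene_ecs.get(g, ()):  # a gene contributes to each of its ECs
            key = (genus_labels[g], ec)
            totals[key] = totals.get(key, 0.0) + val
    if not totals:
        return pd.DataFrame()
    ser = pd.Series(totals)
    return ser.unstack(fill_value=0.0).sort_index()


# ---------------------------------------------------------------------------
# EC recovery from domain names


@dataclass
class EcMatchParams:
    """Normalization rules for matching domain names to enzyme names."""

    stoplist: frozenset[str] = frozenset(
        {"type", "terminal", "subunit", "domain", "enzyme", "like"}
    )
    strip_pattern: str = r"[^0-9a-z]+"


def normalize_enzyme_name(name: str, params: EcMatchParams | None = None) -> str:
    """Lowercase, strip punctuation to spaces, drop generic tokens, collapse.

    Single-letter alphabetic fragments (the "C" left over from "C-terminal")
    are dropped as partial terms; single digits are kept since they carry
    substrate positions ("oligo 1 6 glucosidase").
    """
    params = params or EcMatchParams()
    tokens = re.sub(params.strip_pattern, " ", name.lower()).split()
    return " ".join(
        t for t in tokens
        if t not in params.stoplist and not (len(t) == 1 and t.isalpha())
    )


def ec_from_names(
    domain_names: Mapping[str, Sequence[str]],
    name_to_ec: Mapping[str, str | Sequence[str]],
    params: EcMatchParams | None = None,
) -> pd.DataFrame:
    """Match per-gene domain-name strings against an enzyme-name dictionary.

    Both sides are normalized identically; exact normalized-string equality
    yields the EC.  Returns long-format rows (gene_id, domain_name, ec,
    multiple) where ``multiple`` flags genes that matched more than one EC.
    """
    params = params or EcMatchParams()
    lut: dict[str, list[str]] = {}
    for raw_name, ecs in name_to_ec.items():
        key = normalize_enzyme_name(raw_name, params)
        if not key:
            continue
        if isinstance(ecs, str):
            ecs = [ecs]
        lut.setdefault(key, []).extend(ecs)
    rows = []
    for gene, names in domain_names.items():
        found: list[tuple[str, str]] = []
        for nm in names:
            key = normalize_enzyme_name(nm, params)
            for ec in lut.get(key, []):
                found.append((nm, ec))
        multiple = len({ec for _, ec in found}) > 1
        for nm, ec in found:
            rows.append(
                {"gene_id": gene, "domain_name": nm, "ec": ec, "multiple": multiple}
            )
    return pd.DataFrame(rows, columns=["gene_id", "domain_name", "ec", "multiple"])


# ---------------------------------------------------------------------------
# activity vs 16S


@dataclass
class ActivityCorrelation:
    per_genus: pd.DataFrame   # genus, rho, n
    pooled_rho: float
    pooled_n: int


def activity_vs_16s(
    activity: pd.DataFrame, sixteen_s: pd.DataFrame
) -> ActivityCorrelation:
    """Spearman correlation of expression activity against 16S abundance.

    Correlations use average-rank tie handling; genera with fewer than 3
    matched samples are skipped with a warning.  The pooled estimate runs
    over all (genus, sample) pairs of the shared genera.
    """
    genera = sorted(set(activity.index) & set(sixteen_s.index))
    samples = [s for s in activity.columns if s in set(sixteen_s.columns)]
    rows = []
    pooled_a: list[float] = []
    pooled_b: list[float] = []
    for g in genera:
        a = activity.loc[g, samples].to_numpy(dtype=float)
        b = sixteen_s.loc[g, samples].to_numpy(dtype=float)
        if len(samples) < 3:
            logger.warning("genus %s: fewer than 3 matched samples, skipped", g)
            continue
        rho = spearmanr(a, b).statistic
        rows.append({"genus": g, "rho": rho, "n": len(samples)})
        pooled_a.extend(a)
        pooled_b.extend(b)
    if len(pooled_a) < 3:
        raise ValueError("fewer than 3 matched points overall")
    pooled = spearmanr(pooled_a, pooled_b).statistic
    return ActivityCorrelation(
        per_genus=pd.DataFrame(rows, columns=["genus", "rho", "n"]),
        pooled_rho=float(pooled),
        pooled_n=len(pooled_a),
    )


def flag_upregulated_pathways(
    pathways: Iterable[PathwayGeneSet],
    up_genes: Iterable[str],
    gene_ecs: Mapping[str, Sequence[str]],
    min_member_fraction: float = 0.7,
) -> pd.DataFrame:
    """Flag pathways where most member enzymes have an upregulated gene.

    A pathway is flagged when at least ``min_member_fraction`` of its member
    ECs are covered by >= 1 differentially expressed (up) gene.  This is a
    coarse table-level surrogate for manual metabolic-map inspection.
    """
    up = set(up_genes)
    covered_ecs: set[str] = set()
    for g in up:
        covered_ecs.update(gene_ecs.get(g, ()))
    rows = []
    for pw in pathways:
        frac = len(pw.ec_members & covered_ecs) / len(pw.ec_members)
        rows.append(
            {"pathway": pw.name, "covered_fraction": frac,
             "flagged": frac >= min_member_fraction}
        )
    return pd.DataFrame(rows)
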