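"""Taxonomic assignment of expressed genes by a banded lowest-common-ancestor.

Each gene's alignment hits are filtered in three steps before the LCA is
taken: an E-value ceiling, absolute bit-score and alignment-length floors
(both strict inequalities), and a top-band filter that keeps only hits whose
band statistic lies within a fixed fraction of the best hit.  Assignment
then cascades through up to three search tiers (primary nucleotide search,
fallback nucleotide search, protein search against an orthology database);
the first tier with a surviving hit set decides.  For the protein tier the
band is taken relative to the maximum percent identity rather than the best
bit-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import logging

logger = logging.getLogger("metaferm")


class TaxonomyError(ValueError):
    """The taxonomy dump does not describe a single rooted tree."""


class BandCriterion(str, Enum):
    BITSCORE = "bitscore"
    LENGTH = "length"
    IDENTITY = "identity"


class AssignmentTier(str, Enum):
    NT_PRIMARY = "NT_PRIMARY"
    NT_FALLBACK = "NT_FALLBACK"
    PROTEIN_KO = "PROTEIN_KO"


UNASSIGNED = "UNASSIGNED"

#: Ranks used by the synthetic taxonomies, from root to leaf.
RANKS = ("no rank", "superkingdom", "order", "family", "genus", "species")


@dataclass
class TaxonomyTree:
    """Rooted taxon tree with parent pointers, ranks and scientific names."""

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]
    root: int = field(init=False)

    def __post_init__(self) -> None:
        roots = [t for t, p in self.parent.items() if t == p]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        for t, p in self.parent.items():
            if p not in self.parent:
                raise TaxonomyError(f"node {t} lists unknown parent {p}")
        self.depth: dict[int, int] = {}
        for t in self.parent:
            self._depth_of(t)
        self._lineages: dict[int, tuple[int, ...]] = {}

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[int, int, str]],
        names: Mapping[int, str] | None = None,
    ) -> "TaxonomyTree":
        parent: dict[int, int] = {}
        rank: dict[int, str] = {}
        for taxid, par, rk in edges:
            if taxid in parent:
                raise TaxonomyError(f"duplicate taxid {taxid}")
            parent[taxid] = par
            rank[taxid] = rk
        names = dict(names or {})
        name = {t: names.get(t, str(t)) for t in parent}
        return cls(parent=parent, rank=rank, name=name)

    def _depth_of(self, taxid: int) -> int:
        # iterative walk with cycle detection
        chain = []
        t = taxid
        while t not in self.depth:
            if t == self.parent[t]:
                self.depth[t] = 0
                break
            chain.append(t)
            t = self.parent[t]
            if len(chain) > len(self.parent):
                raise TaxonomyError(f"cycle detected at taxid {taxid}")
        for i, c in enumerate(reversed(chain)):
            self.depth[c] = self.depth[self.parent[c]] + 1
        return self.depth[taxid]

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def lineage(self, taxid: int) -> tuple[int, ...]:
        """Path of taxids from the root down to ``taxid`` (inclusive)."""
        if taxid not in self.parent:
            raise TaxonomyError(f"unknown taxon {taxid}")
        cached = self._lineages.get(taxid)
        if cached is not None:
            return cached
        path = []
        t = taxid
        while t != self.parent[t]:
            path.append(t)
            t = self.parent[t]
        path.append(t)
        lin = tuple(reversed(path))
        self._lineages[taxid] = lin
        return lin

    def lca(self, taxa: Iterable[int]) -> int:
        """Deepest node ancestral-or-equal to every taxon in ``taxa``."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        cur = taxa[0]
        if cur not in self.parent:
            raise TaxonomyError(f"unknown taxon {cur}")
        for t in taxa[1:]:
            if t not in self.parent:
                raise TaxonomyError(f"unknown taxon {t}")
            a, b = cur, t
            while self.depth[a] > self.depth[b]:
                a = self.parent[a]
            while self.depth[b] > self.depth[a]:
                b = self.parent[b]
            while a != b:
                a = self.parent[a]
                b = self.parent[b]
            cur = a
        return cur

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        for t in self.lineage(taxid):
            if self.rank[t] == rank:
                return t
        return None

    def nodes_at_rank(self, rank: str) -> list[int]:
        return sorted(t for t in self.parent if self.rank[t] == rank)

    def find(self, name: str) -> int | None:
        for t, n in self.name.items():
            if n == name:
                return t
        return None


@dataclass
class LcaParams:
    """Hit-filtering thresholds for one search tier.

    ``band_fraction`` is the top-band width: among threshold-passing hits,
    only those whose band statistic b satisfies b >= (1 - f) * max(b)
    survive.  The nucleotide tiers band on bit-score (the MEGAN top-percent
    convention); the protein tier bands on percent identity.
    """

    min_bitscore: float = 50.0
    min_length_nt: int = 100
    band_fraction: float = 0.10
    band_criterion: BandCriterion = BandCriterion.BITSCORE
    max_evalue: float = 1e-4

    def __post_init__(self) -> None:
        if not 0 <= self.band_fraction < 1:
            raise ValueError("band_fraction must be in [0, 1)")
        if self.min_bitscore <= 0 or self.min_length_nt <= 0:
            raise ValueError("thresholds must be positive")
        self.band_criterion = BandCriterion(self.band_criterion)


#: Per-tier defaults: bit-score band for both nucleotide tiers, identity
#: band for the protein tier.
DEFAULT_TIER_PARAMS = {
    AssignmentTier.NT_PRIMARY: LcaParams(),
    AssignmentTier.NT_FALLBACK: LcaParams(),
    AssignmentTier.PROTEIN_KO: LcaParams(band_criterion=BandCriterion.IDENTITY),
}


@dataclass(frozen=True)
class TaxAssignment:
    gene_id: str
    taxon_id: int | str  # taxid, or UNASSIGNED
    tier: AssignmentTier | None
    n_hits_used: int

    @property
    def assigned(self) -> bool:
        return self.taxon_id != UNASSIGNED


def filter_hits(hits: Sequence, params: LcaParams) -> list:
    """Apply threshold and top-band filters to one gene's hit list.

    Hits must expose ``evalue``, ``bitscore``, ``length`` and ``identity``
    attributes.  Thresholds are strict ("exceeded a bit-score of 50",
    "length of more than 100 nucleotides"); the band keeps hits within
    ``band_fraction`` of the best band statistic.
    """
    passing = [
        h
        for h in hits
        if h.evalue <= params.max_evalue
        and h.bitscore > params.min_bitscore
        and h.length > params.min_length_nt
    ]
    if not passing:
        return []
    crit = params.band_criterion
    if crit is BandCriterion.BITSCORE:
        stat = [h.bitscore for h in passing]
    elif crit is BandCriterion.LENGTH:
        stat = [h.length for h in passing]
    else:
        stat = [h.identity for h in passing]
    cutoff = (1.0 - params.band_fraction) * max(stat)
    return [h for h, s in zip(passing, stat) if s >= cutoff]


def assign_gene(
    gene_id: str,
    hit_tiers: Sequence[Sequence],
    tree: TaxonomyTree,
    params_per_tier: Mapping[AssignmentTier, LcaParams] | None = None,
) -> TaxAssignment:
    """Assign a taxon via the first tier whose filtered hit set is non-empty.

    ``hit_tiers`` is an ordered list of per-tier hit lists (primary
    nucleotide, fallback nucleotide, protein).  Hits to taxa absent from the
    tree are dropped with a warning before the LCA.
    """
    params_per_tier = params_per_tier or DEFAULT_TIER_PARAMS
    tiers = list(AssignmentTier)[: len(hit_tiers)]
    for tier, hits in zip(tiers, hit_tiers):
        accepted = filter_hits(hits, params_per_tier[tier])
        known = [h for h in accepted if h.taxid in tree]
        if len(known) < len(accepted):
            logger.warning(
                "gene %s: dropped %d accepted hits to taxa absent from the tree",
                gene_id, len(accepted) - len(known),
            )
        if known:
            taxon = tree.lca([h.taxid for h in known])
            return TaxAssignment(gene_id, taxon, tier, len(known))
    return TaxAssignment(gene_id, UNASSIGNED, None, 0)


def genus_rollup(
    assignments: Iterable[TaxAssignment], tree: TaxonomyTree
) -> dict[str, str]:
    """Collapse assignments to genus-or-fallback display labels.

    Genes assigned at or below genus report the genus name; genes assigned
    above genus report ``"unclassified <lowest assigned taxon>"`` (the
    unclassified fraction within the next classifiable level); unassigned
    genes report ``"Unassigned"``.
    """
    labels: dict[str, str] = {}
    for a in assignments:
        if not a.assigned:
            labels[a.gene_id] = "Unassigned"
            continue
        genus = tree.ancestor_at_rank(int(a.taxon_id), "genus")
        if genus is not None:
            labels[a.gene_id] = tree.name[genus]
        else:
            labels[a.gene_id] = f"unclassified {tree.name[int(a.taxon_id)]}"
    return labels
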