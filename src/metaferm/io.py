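"""Readers and writers for the tabular formats around the pipeline.

Everything on disk is tab-separated text with a single header line
(taxonomy dumps use the NCBI pipe-delimited dialect instead), so that
inputs coming from upstream aligners/annotators and our own outputs stay
diffable.  The in-memory containers are small dataclasses plus pandas
DataFrames.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .taxonomy import TaxonomyTree

logger = logging.getLogger("metaferm")

#: The five incubation conditions: a substrate-free control and four
#: isomalto/malto-polysaccharide (IMMP) preparations; the suffix gives the
#: percentage of alpha-(1->6) linkages, "dig" marks the amylase-digested one.
CONDITIONS = ("BLANK", "IMMP27", "IMMP94", "IMMP96", "IMMPdig27")

#: Sampling time points of the batch fermentations, in hours.
TIME_POINTS_H = (0, 6, 12, 24, 48)

EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(n?\d+|-)$")


class FormatError(ValueError):
    """A file does not conform to its declared tabular dialect."""


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column alignment table (outfmt-6 dialect) plus taxid."""

    query: str
    subject: str
    identity: float
    length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    taxid: int


@dataclass(frozen=True)
class GeneRecord:
    """A predicted protein-coding gene with its functional annotations."""

    gene_id: str
    contig_id: str
    length_bp: int
    ec_numbers: tuple[str, ...] = ()
    ko_ids: tuple[str, ...] = ()
    cazy_families: tuple[str, ...] = ()
    taxon_id: int | None = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"gene {self.gene_id}: length_bp must be >= 1")
        for ec in self.ec_numbers:
            if not EC_PATTERN.match(ec):
                raise ValueError(f"gene {self.gene_id}: malformed EC number {ec!r}")


@dataclass(frozen=True)
class SampleMeta:
    """Design metadata for one sequencing sample."""

    sample_id: str
    condition: str
    time_h: float
    replicate: int
    experiment: str = "A"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.experiment not in ("A", "B"):
            raise ValueError(f"experiment must be A or B, got {self.experiment!r}")

    @property
    def key(self) -> tuple:
        return (self.condition, self.time_h, self.replicate, self.experiment)


@dataclass
class CountMatrix:
    """Integer gene x sample expression counts plus the sample design.

    ``counts`` is a genes x samples DataFrame whose columns follow the order
    of ``samples``.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise ValueError("count columns do not match sample sheet order")
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("(condition, time, replicate, experiment) not unique")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype("int64")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "time_h": [s.time_h for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "experiment": [s.experiment for s in self.samples],
            }
        )


# ---------------------------------------------------------------------------
# alignment hit tables


def read_hits(path: str | Path, taxid_column: int = 13) -> list[AlignmentHit]:
    """Read an outfmt-6-like alignment table with a subject-taxid column.

    The first 12 tab-separated columns are the classic qseqid..bitscore
    layout; ``taxid_column`` (1-based, default 13) holds the subject taxid.
    Rows whose mandatory numeric fields cannot be parsed raise
    :class:`FormatError` naming the line; rows whose taxid is missing or
    unparseable are dropped with a warning (the source databases contain
    records without usable taxonomy).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits: list[AlignmentHit] = []
    n_dropped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                parsed = dict(
                    query=fields[0],
                    subject=fields[1],
                    identity=float(fields[2]),
                    length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                raw = fields[taxid_column - 1]
                taxid = int(raw.split(";")[0])
            except (IndexError, ValueError):
                n_dropped += 1
                continue
            hits.append(AlignmentHit(taxid=taxid, **parsed))
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing/unparseable taxid", path, n_dropped)
    logger.info("read %d alignment hits from %s", len(hits), path)
    return hits


def write_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query, h.subject, f"{h.identity:.1f}", h.length,
                        h.mismatches, h.gap_opens, h.qstart, h.qend,
                        h.sstart, h.send, f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
                        h.taxid,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# taxonomy dumps (NCBI dialect: "taxid\t|\tparent\t|\trank\t|")


def _parse_dmp_line(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\n").rstrip("|").split("|")]


def read_taxonomy(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from nodes/names dump files."""
    edges: list[tuple[int, int, str]] = []
    with Path(nodes_path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            edges.append((int(fields[0]), int(fields[1]), fields[2]))
    names: dict[int, str] = {}
    with Path(names_path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            # prefer the scientific name class when present
            if len(fields) < 4 or fields[3] == "scientific name" or int(fields[0]) not in names:
                names[int(fields[0])] = fields[1]
    return TaxonomyTree.from_edges(edges, names)


def write_taxonomy(tree: TaxonomyTree, nodes_path: str | Path, names_path: str | Path) -> None:
    with Path(nodes_path).open("w") as fh:
        for taxid in sorted(tree.parent):
            fh.write(f"{taxid}\t|\t{tree.parent[taxid]}\t|\t{tree.rank[taxid]}\t|\n")
    with Path(names_path).open("w") as fh:
        for taxid in sorted(tree.parent):
            fh.write(f"{taxid}\t|\t{tree.name[taxid]}\t|\t\t|\tscientific name\t|\n")


# ---------------------------------------------------------------------------
# count matrices, sample sheets, catalogs


def write_counts(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t", lineterminator="\n")
    cm.meta_frame().to_csv(samples_path, sep="\t", index=False, lineterminator="\n")


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(samples_path, sep="\t")
    samples = [
        SampleMeta(
            sample_id=str(r.sample_id),
            condition=str(r.condition),
            time_h=float(r.time_h),
            replicate=int(r.replicate),
            experiment=str(r.experiment),
        )
        for r in meta.itertuples()
    ]
    counts.columns = [str(c) for c in counts.columns]
    return CountMatrix(counts=counts, samples=samples)


def _join(values: Sequence[str]) -> str:
    return ",".join(values) if values else "-"


def _split(raw: str) -> tuple[str, ...]:
    return tuple() if raw in ("-", "") else tuple(raw.split(","))


def write_catalog(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "contig_id": g.contig_id,
            "length_bp": g.length_bp,
            "ec_numbers": _join(g.ec_numbers),
            "ko_ids": _join(g.ko_ids),
            "cazy_families": _join(g.cazy_families),
            "taxon_id": g.taxon_id if g.taxon_id is not None else "-",
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_catalog(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for r in df.itertuples():
        genes.append(
            GeneRecord(
                gene_id=r.gene_id,
                contig_id=r.contig_id,
                length_bp=int(r.length_bp),
                ec_numbers=_split(r.ec_numbers),
                ko_ids=_split(r.ko_ids),
                cazy_families=_split(r.cazy_families),
                taxon_id=None if r.taxon_id == "-" else int(r.taxon_id),
            )
        )
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate gene ids in catalog")
    return genes


# ---------------------------------------------------------------------------
# sequence utility


def at_content_filter(
    sequences: Iterable[tuple[str, str]], threshold: float = 0.80
) -> list[str]:
    """Return ids of sequences whose A/T fraction does not exceed ``threshold``.

    The assembly step discards AT-rich contigs (A/T content strictly greater
    than 80% by default); N bases are excluded from the denominator.  Empty
    sequences (or all-N) are excluded with a warning.
    """
    kept: list[str] = []
    for seq_id, seq in sequences:
        s = seq.upper()
        denom = sum(s.count(b) for b in "ACGT")
        if denom == 0:
            logger.warning("sequence %s has no A/C/G/T bases; excluded", seq_id)
            continue
        at = (s.count("A") + s.count("T")) / denom
        if at <= threshold:
            kept.append(seq_id)
    return kept


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return cfg


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=None,  # stderr
        level=logging.DEBUG if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
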