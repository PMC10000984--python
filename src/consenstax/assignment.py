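"""Similarity-hit filtering, per-cluster consensus assignment and compositions.

The assignment stage mirrors the post-search half of an amplicon
identification workflow: tabular similarity hits (BLAST outfmt-6 style) are
hard-filtered on e-value, percent identity and query coverage, post-filtered
on bitscore distance to the per-cluster best hit, and the surviving hit taxa
are dereplicated to a unique-taxon set that votes for a consensus node at a
minimal consensus level.  Cluster assignments are then aggregated into a
per-sample composition (read counts and proportions of total assigned
reads), to which a detection threshold and a rank roll-up can be applied.

Proportions are never renormalised after thresholding: the denominator
stays the total of assigned reads, so the benchmark sees the same scale on
both sides.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "BlastHit",
    "FilterParams",
    "ClusterAssignment",
    "CompositionEntry",
    "Composition",
    "BlastTabFormatError",
    "DEFAULT_BLAST_COLUMNS",
    "parse_blast_tab",
    "read_cluster_counts",
    "counts_from_query_ids",
    "query_coverage",
    "apply_hard_filters",
    "apply_bitscore_filter",
    "assign_cluster",
    "assign_all",
    "build_composition",
    "apply_detection_threshold",
    "rollup_to_rank",
    "write_composition_tsv",
    "read_composition_tsv",
]


class BlastTabFormatError(Exception):
    """A tabular hit file did not carry the declared columns."""


#: Default outfmt-6-style column layout expected by :func:`parse_blast_tab`.
DEFAULT_BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "qlen",
    "qstart",
    "qend",
    "evalue",
    "bitscore",
    "staxids",
)

_REQUIRED_COLUMNS = set(DEFAULT_BLAST_COLUMNS)


@dataclass(frozen=True)
class BlastHit:
    """One similarity match of a query cluster against a reference sequence.

    Multi-taxid subject rows are expanded upstream, so each hit carries
    exactly one taxid.  Coordinates are 1-based inclusive on the query.
    """

    query_id: str
    subject_id: str
    taxid: int
    pident: float
    qlen: int
    align_len: int
    qstart: int
    qend: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class FilterParams:
    """Hit-filtering and assignment parameters.

    Defaults are the validated operating point: e-value 1e-10, identity 97%,
    coverage 100%, bitscore window 4 bits, majority consensus 0.51 and a
    0.1% detection threshold.
    """

    max_evalue: float = 1.0e-10
    min_pident: float = 97.0
    min_qcov_percent: float = 100.0
    bitscore_delta: float = 4.0
    consensus_level: float = 0.51
    detection_threshold: float = 0.001

    def __post_init__(self) -> None:
        if not 0.5 < self.consensus_level <= 1.0:
            raise ValueError("consensus_level must be in (0.5, 1.0]")
        if self.bitscore_delta < 0:
            raise ValueError("bitscore_delta must be >= 0")
        if not 0 <= self.detection_threshold < 1:
            raise ValueError("detection_threshold must be in [0, 1)")


@dataclass(frozen=True)
class ClusterAssignment:
    """Consensus assignment of one read cluster.

    ``assigned_taxid`` is None for a "no hit" cluster (nothing survived the
    filters); such clusters never enter a composition.
    """

    query_id: str
    assigned_taxid: int | None
    assigned_rank: str | None
    n_hits_retained: int
    read_count: int


@dataclass(frozen=True)
class CompositionEntry:
    reads: int
    proportion: float
    above_rank: bool = False


@dataclass
class Composition:
    """Per-sample mapping taxid -> (reads, proportion of assigned reads)."""

    sample_id: str
    entries: dict[int, CompositionEntry] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(e.reads for e in self.entries.values())

    def proportions(self) -> dict[int, float]:
        return {t: e.proportion for t, e in self.entries.items()}


# ---------------------------------------------------------------------------
# parsing


def parse_blast_tab(
    path: str | Path,
    columns: Sequence[str] = DEFAULT_BLAST_COLUMNS,
) -> list[BlastHit]:
    """Parse an outfmt-6-style TSV into hits, one per (row x subject taxid).

    ``columns`` names the file's fields in order and must include every
    field a :class:`BlastHit` needs.  A ``staxids`` field may hold several
    semicolon-separated taxids; the row is expanded to one hit per taxid.
    Rows with an empty taxid field are dropped (counted in a log warning).
    """
    missing = _REQUIRED_COLUMNS - set(columns)
    if missing:
        raise BlastTabFormatError(f"missing declared columns: {sorted(missing)}")
    idx = {name: i for i, name in enumerate(columns)}
    hits: list[BlastHit] = []
    n_no_taxid = 0
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(columns):
                raise BlastTabFormatError(
                    f"{path}:{lineno}: expected {len(columns)} columns, got {len(row)}"
                )
            staxids = row[idx["staxids"]].strip()
            if not staxids or staxids in ("N/A", "0"):
                n_no_taxid += 1
                continue
            for tid in staxids.split(";"):
                hits.append(
                    BlastHit(
                        query_id=row[idx["qseqid"]],
                        subject_id=row[idx["sseqid"]],
                        taxid=int(tid),
                        pident=float(row[idx["pident"]]),
                        qlen=int(row[idx["qlen"]]),
                        align_len=int(row[idx["length"]]),
                        qstart=int(row[idx["qstart"]]),
                        qend=int(row[idx["qend"]]),
                        evalue=float(row[idx["evalue"]]),
                        bitscore=float(row[idx["bitscore"]]),
                    )
                )
    if n_no_taxid:
        logger.warning("%s: dropped %d rows with empty taxid", path, n_no_taxid)
    return hits


_SIZE_RE = re.compile(r";size=(\d+)")


def counts_from_query_ids(query_ids: Iterable[str]) -> dict[str, int] | None:
    """Extract ``;size=N`` read counts embedded in cluster ids, if present.

    Returns None when no id carries the annotation (caller should fall back
    to a counts table).
    """
    counts: dict[str, int] = {}
    seen_any = False
    for qid in query_ids:
        m = _SIZE_RE.search(qid)
        if m:
            seen_any = True
            counts[qid] = int(m.group(1))
    return counts if seen_any else None


def read_cluster_counts(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV (query_id, reads) of per-cluster read counts."""
    counts: dict[str, int] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise BlastTabFormatError(
                    f"{path}:{lineno}: expected 2 columns (query_id, reads)"
                )
            counts[row[0]] = int(row[1])
    return counts


# ---------------------------------------------------------------------------
# filters


def query_coverage(hit: BlastHit) -> float:
    """Percent of the query spanned by the alignment (1-based inclusive)."""
    return 100.0 * (hit.qend - hit.qstart + 1) / hit.qlen


def apply_hard_filters(
    hits: Iterable[BlastHit], params: FilterParams
) -> list[BlastHit]:
    """Keep hits passing the e-value, identity and coverage thresholds."""
    return [
        h
        for h in hits
        if h.evalue <= params.max_evalue
        and h.pident >= params.min_pident
        and query_coverage(h) >= params.min_qcov_percent - 1e-9
    ]


def apply_bitscore_filter(
    hits: Iterable[BlastHit], delta: float
) -> list[BlastHit]:
    """Per query, keep hits within ``delta`` bits of that query's best hit."""
    hits = list(hits)
    best: dict[str, float] = {}
    for h in hits:
        if h.bitscore > best.get(h.query_id, float("-inf")):
            best[h.query_id] = h.bitscore
    return [h for h in hits if h.bitscore >= best[h.query_id] - delta]


# ---------------------------------------------------------------------------
# assignment


def assign_cluster(
    query_id: str,
    hits: Sequence[BlastHit],
    taxonomy: Taxonomy,
    consensus_level: float = 0.51,
    read_count: int = 1,
) -> ClusterAssignment:
    """Assign one cluster a consensus taxon from its (already filtered) hits.

    Hit taxids are dereplicated to the unique taxon set before voting, so a
    taxon over-represented in the reference database carries no extra
    weight.  Zero hits yield a "no hit" assignment rather than an error.
    """
    if not hits:
        return ClusterAssignment(query_id, None, None, 0, read_count)
    unique = sorted({taxonomy.resolve(h.taxid) for h in hits})
    taxid = taxonomy.consensus(unique, consensus_level)
    return ClusterAssignment(
        query_id, taxid, taxonomy.rank(taxid), len(hits), read_count
    )


def assign_all(
    hits: Iterable[BlastHit],
    taxonomy: Taxonomy,
    params: FilterParams,
    read_counts: Mapping[str, int],
) -> list[ClusterAssignment]:
    """Run the full filter + consensus chain over a multi-cluster hit set.

    Clusters present in ``read_counts`` but absent from the retained hits
    are reported as "no hit" assignments.
    """
    retained = apply_bitscore_filter(
        apply_hard_filters(hits, params), params.bitscore_delta
    )
    by_query: dict[str, list[BlastHit]] = {}
    for h in retained:
        by_query.setdefault(h.query_id, []).append(h)
    out = []
    for qid in read_counts:
        out.append(
            assign_cluster(
                qid,
                by_query.get(qid, []),
                taxonomy,
                params.consensus_level,
                read_counts[qid],
            )
        )
    return out


def build_composition(
    assignments: Iterable[ClusterAssignment], sample_id: str
) -> Composition:
    """Sum read counts per assigned taxid; proportions over assigned reads.

    Unassigned ("no hit") clusters are excluded from the denominator; yield
    accounting is the benchmark module's job.
    """
    reads: dict[int, int] = {}
    for a in assignments:
        if a.assigned_taxid is None:
            continue
        reads[a.assigned_taxid] = reads.get(a.assigned_taxid, 0) + a.read_count
    total = sum(reads.values())
    if total == 0:
        logger.warning("sample %s: no assigned clusters, empty composition", sample_id)
        return Composition(sample_id)
    entries = {
        t: CompositionEntry(r, r / total) for t, r in sorted(reads.items())
    }
    return Composition(sample_id, entries)


def apply_detection_threshold(comp: Composition, threshold: float) -> Composition:
    """Drop entries below the detection threshold (kept at exactly T).

    Surviving proportions are NOT renormalised: they stay fractions of the
    total assigned reads.
    """
    entries = {
        t: e for t, e in comp.entries.items() if e.proportion >= threshold
    }
    return Composition(comp.sample_id, entries)


def rollup_to_rank(
    comp: Composition, taxonomy: Taxonomy, rank: str
) -> Composition:
    """Replace each entry by its ancestor at ``rank``, merging counts.

    Entries whose lineage has no node at that rank (assignments above the
    rank) keep their node and are flagged ``above_rank``.
    """
    reads: dict[int, int] = {}
    props: dict[int, float] = {}
    above: dict[int, bool] = {}
    for taxid, e in comp.entries.items():
        anc = taxonomy.ancestor_at_rank(taxid, rank)
        if anc is None:
            key, flag = taxonomy.resolve(taxid), True
        else:
            key, flag = anc, False
        reads[key] = reads.get(key, 0) + e.reads
        props[key] = props.get(key, 0.0) + e.proportion
        above[key] = above.get(key, False) or flag
    entries = {
        t: CompositionEntry(reads[t], props[t], above[t]) for t in sorted(reads)
    }
    return Composition(comp.sample_id, entries)


# ---------------------------------------------------------------------------
# composition I/O


def write_composition_tsv(
    comp: Composition, taxonomy: Taxonomy, path: str | Path
) -> None:
    """Write sample_id, taxid, scientific_name, rank, reads, proportion."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["sample_id", "taxid", "scientific_name", "rank", "reads", "proportion"]
        )
        for taxid, e in comp.entries.items():
            w.writerow(
                [
                    comp.sample_id,
                    taxid,
                    taxonomy.name(taxid),
                    taxonomy.rank(taxid),
                    e.reads,
                    f"{e.proportion:.10g}",
                ]
            )


def read_composition_tsv(path: str | Path) -> list[Composition]:
    """Read one or more per-sample compositions from the TSV dialect above."""
    comps: dict[str, Composition] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sid = row["sample_id"]
            comp = comps.setdefault(sid, Composition(sid))
            comp.entries[int(row["taxid"])] = CompositionEntry(
                int(row["reads"]), float(row["proportion"])
            )
    return list(comps.values())
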