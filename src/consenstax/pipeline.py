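"""Convenience chain: hit table -> filtered assignments -> compositions.

Glues the assignment and benchmark modules together for multi-sample runs
where cluster ids carry a ``sample|cluster`` prefix (the fixture and CLI
convention).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .assignment import (
    BlastHit,
    Composition,
    FilterParams,
    assign_all,
    build_composition,
)
from .benchmark import ExpectedComposition
from .fixtures import SampleData
from .taxonomy import Taxonomy

__all__ = [
    "hits_from_rows",
    "split_by_sample",
    "compositions_from_hits",
    "run_samples",
]


def hits_from_rows(rows: Iterable[Sequence]) -> list[BlastHit]:
    """Build hits from in-memory outfmt-6-style rows (default column order)."""
    return [
        BlastHit(
            query_id=str(r[0]),
            subject_id=str(r[1]),
            taxid=int(r[9]),
            pident=float(r[2]),
            qlen=int(r[4]),
            align_len=int(r[3]),
            qstart=int(r[5]),
            qend=int(r[6]),
            evalue=float(r[7]),
            bitscore=float(r[8]),
        )
        for r in rows
    ]


def split_by_sample(query_ids: Iterable[str]) -> dict[str, list[str]]:
    """Group ``sample|cluster`` ids by their sample prefix."""
    out: dict[str, list[str]] = {}
    for qid in query_ids:
        sample = qid.split("|", 1)[0] if "|" in qid else ""
        out.setdefault(sample, []).append(qid)
    return out


def compositions_from_hits(
    hits: Sequence[BlastHit],
    counts: Mapping[str, int],
    taxonomy: Taxonomy,
    params: FilterParams = FilterParams(),
) -> dict[str, Composition]:
    """Filter + assign all clusters and build one composition per sample."""
    assignments = assign_all(hits, taxonomy, params, counts)
    by_sample = split_by_sample(counts)
    a_by_qid = {a.query_id: a for a in assignments}
    return {
        sample: build_composition([a_by_qid[q] for q in qids], sample)
        for sample, qids in by_sample.items()
    }


def run_samples(
    samples: Sequence[SampleData],
    taxonomy: Taxonomy,
    params: FilterParams = FilterParams(),
) -> tuple[list[Composition], list[ExpectedComposition]]:
    """Run the assignment chain over fixture samples; return both sides."""
    observed: list[Composition] = []
    expected: list[ExpectedComposition] = []
    for s in samples:
        comps = compositions_from_hits(
            hits_from_rows(s.hit_rows), s.counts, taxonomy, params
        )
        observed.append(comps[s.sample_id])
        expected.append(ExpectedComposition(s.sample_id, dict(s.expected)))
    return observed, expected
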