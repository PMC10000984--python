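"""Synthetic inputs: mini taxonomies, references, hit tables, FASTQ.

Everything the toolkit consumes can be generated here deterministically
from a seed, so the whole analysis chain runs and validates without any
download.  The generator emulates the structure of a meat-metabarcoding
validation panel:

* a small taxonomy of species under genera under families;
* pseudo-mitochondrial references embedding a primer pair around a short
  (default 75 bp) taxon-specific barcode insert;
* per-sample cluster hit tables realising planted compositions (samples
  enriched for components around 1%, the common reporting limit) at a
  fixed read depth, each cluster carrying a perfect hit to its true taxon
  plus decoy hits that the e-value/identity/coverage and bitscore filters
  must remove;
* sub-threshold noise clusters assigned to off-panel taxa, mimicking trace
  contamination rather than sequencing-error chemistry;
* synchronized paired FASTQ for down-sampling tests.

Read depth defaults to 5000 — the recommended minimum sequencing depth for
a robust analysis — which also keeps the fixtures fast.
"""

from __future__ import annotations

import csv
import gzip
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .barcode import PrimerPair, extract_barcodes, revcomp
from .taxonomy import TaxNode, Taxonomy

__all__ = [
    "FixtureSpec",
    "SampleData",
    "DEFAULT_PRIMER_PAIR",
    "DEFAULT_SAMPLE_PLAN",
    "ROOT_TAXID",
    "species_taxid",
    "genus_taxid",
    "family_taxid",
    "make_taxonomy",
    "write_taxdump",
    "make_references",
    "make_blast_data",
    "make_fastq",
    "write_references",
    "write_blast_data",
    "make_all",
]

#: Primer pair planted into every generated reference (degenerate positions
#: exercise the IUPAC matcher; concrete realisations are embedded).
DEFAULT_PRIMER_PAIR = PrimerPair(
    forward="GACGAGAAGACCCTRTGGAGC",
    reverse="CGCTGTTATCCCTAGGGTAAY",
    name="16s_fixture",
)

ROOT_TAXID = 1
_CLADE_TAXID = 2


def species_taxid(index: int) -> int:
    return 1000 + index


def genus_taxid(genus_index: int) -> int:
    return 200 + genus_index


def family_taxid(family_index: int) -> int:
    return 100 + family_index


#: Default sample plan: taxon index -> proportion of total assigned reads.
#: Each sample sums to 0.999, leaving a 0.1% budget for sub-threshold noise
#: clusters; every sample carries a component at the 1% reporting limit and
#: no two components of a sample share a genus.
DEFAULT_SAMPLE_PLAN: tuple[dict[int, float], ...] = (
    {0: 0.899, 2: 0.05, 4: 0.04, 6: 0.01},
    {1: 0.699, 3: 0.25, 5: 0.05},
    {7: 0.959, 9: 0.03, 1: 0.01},
)


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic dataset.

    ``divergence`` is the number of substitutions separating successive
    sister species within a genus (0 makes siblings share a barcode);
    ``sample_plan`` maps species indices to planted proportions, summing
    to <= 1 per sample with the remainder filled by noise clusters, each
    kept below ``noise_floor`` of the total.
    """

    seed: int = 0
    n_taxa: int = 12
    species_per_genus: int = 2
    genera_per_family: int = 2
    barcode_length: int = 75
    divergence: int = 3
    flank_length: int = 20
    sample_plan: tuple[dict[int, float], ...] = DEFAULT_SAMPLE_PLAN
    noise_floor: float = 0.0005
    depth: int = 5000

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        for plan in self.sample_plan:
            total = sum(plan.values())
            if total > 1 + 1e-9:
                raise ValueError(f"sample plan proportions sum to {total} > 1")
            if any(i >= self.n_taxa for i in plan):
                raise ValueError("sample plan references a taxon index out of range")


# ---------------------------------------------------------------------------
# taxonomy


def make_taxonomy(spec: FixtureSpec) -> Taxonomy:
    """Build the fixture tree: root -> clade -> families -> genera -> species."""
    nodes: dict[int, TaxNode] = {
        ROOT_TAXID: TaxNode(ROOT_TAXID, ROOT_TAXID, "no rank", "root"),
        _CLADE_TAXID: TaxNode(_CLADE_TAXID, ROOT_TAXID, "clade", "Amniota"),
    }
    n_genera = -(-spec.n_taxa // spec.species_per_genus)
    n_families = -(-n_genera // spec.genera_per_family)
    for f in range(n_families):
        tid = family_taxid(f)
        nodes[tid] = TaxNode(tid, _CLADE_TAXID, "family", f"Family_{f}")
    for g in range(n_genera):
        tid = genus_taxid(g)
        nodes[tid] = TaxNode(
            tid, family_taxid(g // spec.genera_per_family), "genus", f"Genus_{g}"
        )
    for i in range(spec.n_taxa):
        g = i // spec.species_per_genus
        tid = species_taxid(i)
        nodes[tid] = TaxNode(
            tid,
            genus_taxid(g),
            "species",
            f"Genus_{g} species_{i % spec.species_per_genus}",
        )
    return Taxonomy(nodes)


def write_taxdump(
    taxonomy: Taxonomy, out_dir: str | Path, merged: Mapping[int, int] | None = None
) -> Path:
    """Write nodes.dmp / names.dmp (and merged.dmp if given) NCBI-style."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "nodes.dmp", "w") as fh:
        for node in taxonomy.nodes.values():
            fh.write(f"{node.taxid}\t|\t{node.parent}\t|\t{node.rank}\t|\n")
    with open(out / "names.dmp", "w") as fh:
        for node in taxonomy.nodes.values():
            fh.write(f"{node.taxid}\t|\t{node.name}\t|\t\t|\tscientific name\t|\n")
    if merged:
        with open(out / "merged.dmp", "w") as fh:
            for old, new in merged.items():
                fh.write(f"{old}\t|\t{new}\t|\n")
    return out


# ---------------------------------------------------------------------------
# references


_SUBST = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _concrete(primer: str) -> str:
    """Resolve degenerate positions to one concrete realisation."""
    from .barcode import IUPAC_SETS

    return "".join(
        c if c in "ACGT" else sorted(IUPAC_SETS[c])[0] for c in primer.upper()
    )


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _species_insert(base: str, sibling_index: int, divergence: int) -> str:
    """Mutate the first ``sibling_index * divergence`` positions of the base.

    Nested mutation blocks make the pairwise distance between siblings k1
    and k2 exactly |k1 - k2| * divergence substitutions.
    """
    k = sibling_index * divergence
    if k == 0:
        return base
    if k > len(base):
        raise ValueError("divergence too large for barcode length")
    return "".join(_SUBST[c] for c in base[:k]) + base[k:]


def make_references(
    spec: FixtureSpec, pair: PrimerPair = DEFAULT_PRIMER_PAIR
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Per taxon, a pseudo-mitochondrial record FWD + insert + revcomp(REV).

    Inserts are genus-level random sequences with sibling species separated
    by ``spec.divergence`` substitutions.  The construction is verified
    (and re-drawn on a deterministic sub-seed if necessary) so that barcode
    extraction recovers exactly one barcode per record, equal to the
    planted insert — random flanks cannot fake a second primer site.
    """
    n_genera = -(-spec.n_taxa // spec.species_per_genus)
    fwd = _concrete(pair.forward)
    rev = _concrete(pair.reverse)
    for attempt in range(50):
        rng = random.Random(spec.seed * 1000003 + attempt)
        bases = [_random_seq(rng, spec.barcode_length) for _ in range(n_genera)]
        refs: list[tuple[str, str]] = []
        taxid_map: dict[str, int] = {}
        inserts: dict[str, str] = {}
        for i in range(spec.n_taxa):
            g, k = divmod(i, spec.species_per_genus)
            insert = _species_insert(bases[g], k, spec.divergence)
            seq = (
                _random_seq(rng, spec.flank_length)
                + fwd
                + insert
                + revcomp(rev)
                + _random_seq(rng, spec.flank_length)
            )
            seq_id = f"ref_{i}"
            refs.append((seq_id, seq))
            taxid_map[seq_id] = species_taxid(i)
            inserts[seq_id] = insert
        found = extract_barcodes(refs, taxid_map, pair)
        per_source: dict[str, list[str]] = {}
        for b in found:
            per_source.setdefault(b.source_id, []).append(b.sequence)
        if all(per_source.get(sid) == [inserts[sid]] for sid, _ in refs):
            return refs, taxid_map
    raise RuntimeError("could not build clean references in 50 attempts")


# ---------------------------------------------------------------------------
# hit tables


@dataclass
class SampleData:
    """One synthetic sample: hit rows, cluster read counts, planted truth."""

    sample_id: str
    hit_rows: list[list] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    expected: dict[int, float] = field(default_factory=dict)
    reads_in: int = 0


def _hit_row(
    qid: str,
    taxid: int,
    pident: float = 100.0,
    qlen: int = 75,
    qstart: int = 1,
    qend: int = 75,
    evalue: float = 1e-30,
    bitscore: float = 140.0,
    subject: str = "subj",
) -> list:
    length = qend - qstart + 1
    return [qid, subject, pident, length, qlen, qstart, qend, evalue, bitscore, taxid]


def _cluster_rows(qid: str, taxid: int, decoy_taxid: int) -> list[list]:
    """A perfect hit plus one decoy per filter the pipeline must apply."""
    return [
        _hit_row(qid, taxid, subject=f"true_{taxid}"),
        # second in-window hit to the same taxon (survives, changes nothing)
        _hit_row(qid, taxid, pident=98.7, bitscore=137.0, subject=f"dup_{taxid}"),
        # identity decoy: 96.9 < 97 boundary
        _hit_row(qid, decoy_taxid, pident=96.9, subject="decoy_pident"),
        # bitscore decoy: 130 < 140 - 4
        _hit_row(qid, decoy_taxid, bitscore=130.0, subject="decoy_bitscore"),
        # coverage decoy: alignment misses the query start
        _hit_row(qid, decoy_taxid, qstart=3, subject="decoy_coverage"),
        # e-value decoy
        _hit_row(qid, decoy_taxid, evalue=1e-5, subject="decoy_evalue"),
    ]


def make_blast_data(spec: FixtureSpec) -> list[SampleData]:
    """Realise the sample plan as cluster hit tables with decoys and noise.

    Component reads are ``round(p * depth)``; the largest component is split
    across two clusters (exercising aggregation).  Leftover reads up to the
    depth are spread over noise clusters assigned to off-panel taxa, each
    below ``noise_floor`` of the depth.  Every sample also carries one
    decoy-only cluster of 10 reads that must end up unassigned ("no hit"),
    counted in ``reads_in`` but not in the composition denominator.
    """
    samples: list[SampleData] = []
    max_noise = max(1, int(math.ceil(spec.noise_floor * spec.depth)) - 1)
    for s_idx, plan in enumerate(spec.sample_plan):
        sid = f"sample_{s_idx}"
        data = SampleData(sample_id=sid)
        items = sorted(plan.items(), key=lambda kv: -kv[1])
        reads = {i: round(p * spec.depth) for i, p in items}
        planted_genera = {i // spec.species_per_genus for i in plan}
        off_panel = [
            i
            for i in range(spec.n_taxa)
            if i // spec.species_per_genus not in planted_genera
        ] or [i for i in range(spec.n_taxa) if i not in plan]
        if not off_panel:
            raise ValueError(f"sample {sid}: no off-panel taxon available for noise")
        cluster_idx = 0

        def add_cluster(taxon_index: int, n_reads: int) -> None:
            nonlocal cluster_idx
            qid = f"{sid}|cluster_{cluster_idx}"
            cluster_idx += 1
            decoy = species_taxid((taxon_index + 1) % spec.n_taxa)
            data.hit_rows.extend(_cluster_rows(qid, species_taxid(taxon_index), decoy))
            data.counts[qid] = n_reads

        for rank_i, (i, p) in enumerate(items):
            r = reads[i]
            if rank_i == 0 and r >= 2:
                add_cluster(i, r // 2)
                add_cluster(i, r - r // 2)
            else:
                add_cluster(i, r)
            data.expected[species_taxid(i)] = p
        leftover = spec.depth - sum(reads.values())
        if leftover > max_noise * len(off_panel):
            raise ValueError(
                f"sample {sid}: {leftover} noise reads cannot stay below the "
                f"noise floor across {len(off_panel)} off-panel taxa"
            )
        j = 0
        while leftover > 0:
            n = min(max_noise, leftover)
            add_cluster(off_panel[j], n)  # distinct taxon per noise cluster
            leftover -= n
            j += 1
        # decoy-only cluster: all its hits fail a filter -> "no hit"
        qid = f"{sid}|cluster_{cluster_idx}"
        decoy = species_taxid(0)
        data.hit_rows.append(_hit_row(qid, decoy, pident=95.0, subject="decoy_only"))
        data.hit_rows.append(_hit_row(qid, decoy, evalue=1e-3, subject="decoy_only2"))
        data.counts[qid] = 10
        data.reads_in = spec.depth + 10
        samples.append(data)
    return samples


# ---------------------------------------------------------------------------
# fastq


def make_fastq(
    spec: FixtureSpec,
    n_reads: int,
    out_r1: str | Path,
    out_r2: str | Path,
    read_length: int = 150,
) -> None:
    """Write synchronized paired FASTQ (gzipped when the suffix is .gz)."""
    rng = random.Random(spec.seed * 9176 + 11)
    pairs = []
    for i in range(n_reads):
        s1 = _random_seq(rng, read_length)
        s2 = _random_seq(rng, read_length)
        pairs.append((f"read_{i}", s1, s2))
    qual = "I" * read_length
    for path, mate in ((out_r1, 1), (out_r2, 2)):
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for rid, s1, s2 in pairs:
                fh.write(f"@{rid}/{mate}\n{s1 if mate == 1 else s2}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# writers


def write_references(
    refs: Sequence[tuple[str, str]],
    taxid_map: Mapping[str, int],
    fasta_path: str | Path,
    taxid_tsv: str | Path,
) -> None:
    with open(fasta_path, "w") as fh:
        for sid, seq in refs:
            fh.write(f">{sid}\n{seq}\n")
    with open(taxid_tsv, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for sid, _ in refs:
            w.writerow([sid, taxid_map[sid]])


def write_blast_data(
    samples: Sequence[SampleData],
    hits_path: str | Path,
    counts_path: str | Path,
    expected_path: str | Path,
) -> None:
    """Write combined hits.tsv / counts.tsv / expected.tsv for a sample set.

    Cluster ids carry their sample as a ``sample|cluster`` prefix, so the
    combined tables can be split back per sample.
    """
    with open(hits_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for s in samples:
            w.writerows(s.hit_rows)
    with open(counts_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for s in samples:
            for qid, n in s.counts.items():
                w.writerow([qid, n])
    with open(expected_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "taxid", "proportion"])
        for s in samples:
            for taxid, p in s.expected.items():
                w.writerow([s.sample_id, taxid, f"{p:.10g}"])


def make_all(
    spec: FixtureSpec,
    out_dir: str | Path,
    pair: PrimerPair = DEFAULT_PRIMER_PAIR,
    n_fastq_reads: int = 2000,
) -> Path:
    """Write the full fixture bundle into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    taxonomy = make_taxonomy(spec)
    write_taxdump(taxonomy, out / "taxdump")
    refs, taxid_map = make_references(spec, pair)
    write_references(refs, taxid_map, out / "reference.fasta", out / "taxids.tsv")
    samples = make_blast_data(spec)
    write_blast_data(
        samples, out / "hits.tsv", out / "counts.tsv", out / "expected.tsv"
    )
    make_fastq(spec, n_fastq_reads, out / "r1.fastq.gz", out / "r2.fastq.gz")
    return out
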