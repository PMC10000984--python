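"""In-silico barcode resolution: primer matching, extraction, identities.

Given a reference sequence collection and an IUPAC primer pair, this module
predicts how well the amplified fragment (the "barcode") distinguishes
taxa.  Primer sites are located by ungapped sliding-window matching with
permissive thresholds (80% coverage anchored at the primer 3' end, 65%
identity over the aligned span); sequences flanked by facing primer sites
are extracted with the primers removed, dereplicated taxon-wise, and
compared all-against-all by global alignment.  For each barcode, the taxa
of all neighbours within an identity level vote for a majority (0.51)
consensus node — the rank of that node is the resolution the barcode would
achieve if clustered at that identity.
"""

from __future__ import annotations

import csv
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "IUPAC_SETS",
    "PrimerPair",
    "PrimerMatch",
    "BarcodeRecord",
    "BarcodeSet",
    "revcomp",
    "match_primer",
    "extract_barcodes",
    "dereplicate_taxonwise",
    "global_identity",
    "identity_matrix",
    "resolution_summary",
    "presence_absence",
    "read_fasta_with_taxids",
    "write_barcode_fasta",
]

#: IUPAC degenerate nucleotide codes and their expansion sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair; the reverse primer is 5'->3' on the opposite strand."""

    forward: str
    reverse: str
    name: str = ""

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{label} primer is empty")
            bad = set(seq.upper()) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"{label} primer has non-IUPAC symbols: {bad}")


@dataclass(frozen=True)
class PrimerMatch:
    """A primer site on the target plus strand (0-based half-open coords).

    ``strand`` is '+' when the primer reads 5'->3' along the plus strand
    and '-' when it reads along the minus strand.  ``aligned_length`` is
    the number of primer positions on the target (3'-anchored partial
    matches may clip the 5' end).
    """

    start: int
    end: int
    strand: str
    mismatches: int
    aligned_length: int


def _match_plus(
    primer: str, target: str, min_coverage: float, min_identity: float
) -> list[tuple[int, int, int, int]]:
    """Ungapped matches of the primer along the given strand of target.

    Returns (start, end, mismatches, aligned_length) tuples.  The primer 3'
    end must lie on the target; the 5' end may overhang the left edge as
    long as coverage stays >= min_coverage.
    """
    L = len(primer)
    n = len(target)
    psets = [IUPAC_SETS[c] for c in primer.upper()]
    max_overhang = L - int(-(-min_coverage * L // 1))  # L - ceil(cov*L)
    out = []
    for o in range(-max_overhang, n - L + 1):
        lo = max(0, -o)
        aligned = L - lo
        if aligned <= 0 or o + L > n:
            continue
        mism = 0
        for i in range(lo, L):
            if target[o + i] not in psets[i]:
                mism += 1
        if aligned / L >= min_coverage and 1 - mism / aligned >= min_identity:
            out.append((o + lo, o + L, mism, aligned))
    return out


def match_primer(
    primer: str,
    target: str,
    min_coverage: float = 0.8,
    min_identity: float = 0.65,
) -> list[PrimerMatch]:
    """Find primer sites on both strands by ungapped IUPAC window matching.

    Degenerate primer positions match any base of their expansion set; an N
    in the target matches nothing.  Coverage is anchored at the primer 3'
    end: the 3'-proximal ``min_coverage`` of the primer must lie on the
    target.  Identity is computed over the aligned span.
    """
    target = target.upper()
    matches = [
        PrimerMatch(s, e, "+", m, a)
        for s, e, m, a in _match_plus(primer, target, min_coverage, min_identity)
    ]
    rc = revcomp(target)
    n = len(target)
    for s, e, m, a in _match_plus(primer, rc, min_coverage, min_identity):
        matches.append(PrimerMatch(n - e, n - s, "-", m, a))
    return sorted(matches, key=lambda pm: (pm.start, pm.strand))


@dataclass(frozen=True)
class BarcodeRecord:
    """An inter-primer sequence tied to a source taxid.

    ``start``/``end`` are 0-based half-open on the source plus strand;
    minus-strand products are normalised to the forward orientation (the
    stored sequence always reads forward-primer side first).
    """

    taxid: int
    sequence: str
    source_id: str
    start: int
    end: int
    strand: str


@dataclass
class BarcodeSet:
    """Taxon-wise dereplicated barcodes with per-(taxid, sequence) counts."""

    records: list[BarcodeRecord] = field(default_factory=list)
    counts: dict[tuple[int, str], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def extract_barcodes(
    references: Iterable[tuple[str, str]],
    taxid_map: Mapping[str, int],
    pair: PrimerPair,
    max_product_len: int = 2000,
    min_coverage: float = 0.8,
    min_identity: float = 0.65,
) -> list[BarcodeRecord]:
    """Extract inter-primer sequences from (seq_id, sequence) references.

    A product needs facing primer sites: the forward primer on one strand
    and the reverse primer pointing back at it on the other, within
    ``max_product_len`` from outer end to outer end.  Primer spans are
    removed and minus-strand products are reverse-complemented so every
    barcode reads in the amplicon's forward orientation.  Records missing
    from ``taxid_map`` are skipped with a warning.
    """
    out: list[BarcodeRecord] = []
    for seq_id, seq in references:
        if seq_id not in taxid_map:
            logger.warning("reference %s has no taxid mapping, skipped", seq_id)
            continue
        taxid = taxid_map[seq_id]
        seq = seq.upper()
        fwd = match_primer(pair.forward, seq, min_coverage, min_identity)
        rev = match_primer(pair.reverse, seq, min_coverage, min_identity)
        # plus-strand product: FWD(+) ... revcomp(REV) i.e. REV(-)
        for f in (m for m in fwd if m.strand == "+"):
            for r in (m for m in rev if m.strand == "-"):
                if f.end <= r.start and r.end - f.start <= max_product_len:
                    insert = seq[f.end : r.start]
                    if insert:
                        out.append(
                            BarcodeRecord(taxid, insert, seq_id, f.end, r.start, "+")
                        )
        # minus-strand product: REV(+) ... FWD(-) — amplicon on the other strand
        for r in (m for m in rev if m.strand == "+"):
            for f in (m for m in fwd if m.strand == "-"):
                if r.end <= f.start and f.end - r.start <= max_product_len:
                    insert = seq[r.end : f.start]
                    if insert:
                        out.append(
                            BarcodeRecord(
                                taxid, revcomp(insert), seq_id, r.end, f.start, "-"
                            )
                        )
    return out


def dereplicate_taxonwise(barcodes: Iterable[BarcodeRecord]) -> BarcodeSet:
    """One representative per (taxid, exact sequence); counts preserved.

    Identical sequences under different taxids remain distinct records —
    uniqueness is scoped within each taxon.
    """
    bset = BarcodeSet()
    for b in barcodes:
        key = (b.taxid, b.sequence)
        if key not in bset.counts:
            bset.counts[key] = 0
            bset.records.append(b)
        bset.counts[key] += 1
    return bset


# ---------------------------------------------------------------------------
# identities

_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 2
_ALIGNER.mismatch_score = -4
_ALIGNER.open_gap_score = -20
_ALIGNER.extend_gap_score = -2


def global_identity(a: str, b: str) -> float:
    """End-to-end alignment identity: 1 - hamming / alignment length.

    The hamming distance counts non-identical alignment columns (mismatches
    plus gap columns), making the formula well-defined for unequal lengths.
    Scoring: match +2, mismatch -4, gap open -20, gap extend -2.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def identity_matrix(bset: BarcodeSet) -> tuple[np.ndarray, list[BarcodeRecord]]:
    """Symmetric pairwise identity matrix over a barcode set (diagonal 1)."""
    recs = bset.records
    n = len(recs)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = global_identity(
                recs[i].sequence, recs[j].sequence
            )
    return mat, recs


# ---------------------------------------------------------------------------
# resolution


def _rank_or_below(taxonomy: Taxonomy, taxid: int, rank: str) -> bool:
    return taxonomy.ancestor_at_rank(taxid, rank) is not None


def resolution_summary(
    bset: BarcodeSet,
    taxonomy: Taxonomy,
    identity_levels: Sequence[float] = (0.97, 1.0),
    consensus_level: float = 0.51,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict the consensus rank each barcode resolves to per identity level.

    For every barcode, all set members with pairwise identity >= level
    (itself included) contribute their unique taxa to a majority-consensus
    vote; the consensus node's rank is recorded.  Returns (summary, detail):
    the summary has one row per identity level with the fraction of
    barcodes whose consensus sits at species-or-below and genus-or-below,
    plus taxid and length statistics; the detail table has one row per
    (barcode, level) with the consensus taxid and rank.
    """
    mat, recs = identity_matrix(bset)
    n = len(recs)
    lengths = [len(r.sequence) for r in recs]
    per_taxid = pd.Series([r.taxid for r in recs]).value_counts()
    detail_rows = []
    summary_rows = []
    for level in identity_levels:
        n_species = 0
        n_genus = 0
        for i in range(n):
            members = [j for j in range(n) if mat[i, j] >= level]
            unique = sorted({recs[j].taxid for j in members})
            cons = taxonomy.consensus(unique, consensus_level)
            rank = taxonomy.rank(cons)
            sp = _rank_or_below(taxonomy, cons, "species")
            ge = _rank_or_below(taxonomy, cons, "genus")
            n_species += sp
            n_genus += ge
            detail_rows.append(
                {
                    "barcode_index": i,
                    "taxid": recs[i].taxid,
                    "identity_level": level,
                    "consensus_taxid": cons,
                    "consensus_rank": rank,
                    "species_or_below": sp,
                    "genus_or_below": ge,
                }
            )
        summary_rows.append(
            {
                "identity_level": level,
                "n_barcodes": n,
                "n_taxids": int(per_taxid.size),
                "median_barcodes_per_taxid": float(per_taxid.median()),
                "median_barcode_length": float(statistics.median(lengths)),
                "pct_species_or_below": 100.0 * n_species / n if n else float("nan"),
                "pct_genus_or_below": 100.0 * n_genus / n if n else float("nan"),
            }
        )
    return pd.DataFrame(summary_rows), pd.DataFrame(detail_rows)


def presence_absence(
    bset: BarcodeSet, target_taxids: Sequence[int]
) -> pd.DataFrame:
    """'+'/'0' amplifiability table for a target-species taxid list."""
    present = {r.taxid for r in bset.records}
    return pd.DataFrame(
        {
            "taxid": list(target_taxids),
            "amplified": ["+" if t in present else "0" for t in target_taxids],
        }
    )


# ---------------------------------------------------------------------------
# I/O


def read_fasta_with_taxids(
    fasta_path: str | Path, taxid_tsv: str | Path
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Load FASTA references and a (sequence_id, taxid) TSV mapping."""
    refs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")]
    taxid_map: dict[str, int] = {}
    with open(taxid_tsv, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            taxid_map[row[0]] = int(row[1])
    return refs, taxid_map


def write_barcode_fasta(barcodes: Iterable[BarcodeRecord], path: str | Path) -> None:
    """Write barcodes as FASTA; headers carry taxid, source and 1-based coords."""
    with open(path, "w") as fh:
        for i, b in enumerate(barcodes):
            fh.write(
                f">barcode_{i} taxid={b.taxid} source={b.source_id} "
                f"pos={b.start + 1}-{b.end} strand={b.strand}\n{b.sequence}\n"
            )
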