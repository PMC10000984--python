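"""Validation metrics: confusion counts, P/R/F-scores, distances, sweeps.

Observed compositions are compared against expected (gravimetric) sample
compositions at a chosen taxonomic rank after applying a detection
threshold.  Evaluation is open-world: components are counted as true
positives, false positives and false negatives — there is no meaningful
true-negative count when the reference database spans thousands of taxa.

The threshold sweep recomputes aggregate confusion over a sample set at
every threshold on a fixed grid and reports the smallest threshold
maximising the F2-score (recall weighted double); this is how an operating
point such as 0.1% is derived from a validation panel.
"""

from __future__ import annotations

import csv
import gzip
import logging
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .assignment import Composition, apply_detection_threshold, rollup_to_rank
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "ExpectedComposition",
    "ConfusionCounts",
    "BenchmarkReport",
    "SweepResult",
    "read_expected_tsv",
    "match_compositions",
    "precision_recall",
    "percent",
    "fbeta",
    "gpr",
    "pr_threshold_sweep",
    "euclidean_distance",
    "relative_error",
    "relative_errors",
    "yield_fraction",
    "staged_yields",
    "splitting_level",
    "downsample_seed",
    "downsample_reads",
    "evaluate",
]


@dataclass
class ExpectedComposition:
    """Known sample composition: taxid -> expected proportion (fraction).

    Entries may sum to less than 1 (trace-contaminated reference material);
    no renormalisation is applied.
    """

    sample_id: str
    entries: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class SweepResult:
    """Precision-recall curve over a threshold grid and its F2 optimum."""

    curve: pd.DataFrame  # columns: threshold, tp, fp, fn, precision, recall, fbeta
    optimal_threshold: float
    beta: float


@dataclass
class BenchmarkReport:
    """Aggregate confusion and metrics plus per-sample rows."""

    confusion: ConfusionCounts
    precision: float | None
    recall: float | None
    fbeta: float | None
    gpr: float | None
    per_sample: pd.DataFrame  # sample_id, tp, fp, fn, euclidean
    relative_errors: pd.DataFrame  # sample_id, taxid, expected, predicted, error

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
            },
            "precision": self.precision,
            "recall": self.recall,
            "fbeta": self.fbeta,
            "gpr": self.gpr,
        }


def read_expected_tsv(path: str | Path) -> list[ExpectedComposition]:
    """Read expected compositions: TSV of sample_id, taxid, proportion."""
    out: dict[str, ExpectedComposition] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header and header[0] != "sample_id":
            fh.seek(0)
            reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row:
                continue
            sid = row[0]
            exp = out.setdefault(sid, ExpectedComposition(sid))
            exp.entries[int(row[1])] = float(row[2])
    return list(out.values())


# ---------------------------------------------------------------------------
# confusion and scores


def _rank_sets(
    expected: ExpectedComposition,
    observed: Composition,
    taxonomy: Taxonomy,
    rank: str,
    threshold: float,
) -> tuple[set[int], Composition, Composition]:
    """Threshold + roll both sides to ``rank``; return (expected set, rolled)."""
    obs = rollup_to_rank(
        apply_detection_threshold(observed, threshold), taxonomy, rank
    )
    exp_comp = Composition(
        expected.sample_id,
        {
            t: _entry_from_prop(p)
            for t, p in expected.entries.items()
        },
    )
    exp = rollup_to_rank(exp_comp, taxonomy, rank)
    return set(exp.entries), obs, exp


def _entry_from_prop(p: float):
    from .assignment import CompositionEntry

    return CompositionEntry(reads=0, proportion=p)


def match_compositions(
    expected: ExpectedComposition,
    observed: Composition,
    taxonomy: Taxonomy,
    rank: str,
    threshold: float = 0.0,
) -> ConfusionCounts:
    """Open-world confusion at a rank.

    TP: observed rank-level components matching an expected component;
    FP: remaining observed components (including assignments stuck above
    the rank); FN: expected components never observed.
    """
    exp_set, obs, _ = _rank_sets(expected, observed, taxonomy, rank, threshold)
    obs_matchable = {
        t for t, e in obs.entries.items() if not e.above_rank
    }
    tp = len(obs_matchable & exp_set)
    fp = len(obs.entries) - tp
    fn = len(exp_set - obs_matchable)
    return ConfusionCounts(tp, fp, fn)


def precision_recall(
    conf: ConfusionCounts,
) -> tuple[float | None, float | None]:
    """Exact precision and recall; an undefined ratio is None, not 0."""
    precision = conf.tp / (conf.tp + conf.fp) if conf.tp + conf.fp > 0 else None
    recall = conf.tp / (conf.tp + conf.fn) if conf.tp + conf.fn > 0 else None
    return precision, recall


def percent(fraction: float) -> int:
    """Integer percent, rounding half away from zero (report display)."""
    x = fraction * 100.0
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fbeta(precision: float, recall: float, beta: float = 2.0) -> float:
    """Weighted harmonic mean (1+b^2)PR / (b^2 P + R); 0 when both are 0."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if precision == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def gpr(precision: float, recall: float) -> float:
    """Geometric mean of precision and recall ("average precision")."""
    return math.sqrt(precision * recall)


# ---------------------------------------------------------------------------
# distances and errors


def euclidean_distance(
    expected: ExpectedComposition,
    observed: Composition,
    taxonomy: Taxonomy,
    rank: str,
    threshold: float = 0.0,
) -> float:
    """L2 distance between rank-level proportion vectors on the taxa union."""
    exp_set, obs, exp = _rank_sets(expected, observed, taxonomy, rank, threshold)
    taxa = sorted(set(obs.entries) | set(exp.entries))
    e = np.array([exp.entries[t].proportion if t in exp.entries else 0.0 for t in taxa])
    o = np.array([obs.entries[t].proportion if t in obs.entries else 0.0 for t in taxa])
    return float(np.linalg.norm(o - e))


def relative_error(expected_p: float, predicted_p: float) -> float:
    """Signed relative error E = (predicted - expected) / expected."""
    if expected_p <= 0:
        raise ValueError("relative error is defined for expected proportion > 0")
    return (predicted_p - expected_p) / expected_p


def relative_errors(
    expected: ExpectedComposition,
    observed: Composition,
    taxonomy: Taxonomy,
    rank: str,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-true-positive relative errors at a rank (FP/FN are excluded)."""
    exp_set, obs, exp = _rank_sets(expected, observed, taxonomy, rank, threshold)
    rows = []
    for t in sorted(exp_set & set(obs.entries)):
        if obs.entries[t].above_rank:
            continue
        e_p = exp.entries[t].proportion
        o_p = obs.entries[t].proportion
        rows.append(
            {
                "sample_id": expected.sample_id,
                "taxid": t,
                "expected": e_p,
                "predicted": o_p,
                "error": relative_error(e_p, o_p),
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "taxid", "expected", "predicted", "error"]
    )


# ---------------------------------------------------------------------------
# yield and splitting


def yield_fraction(reads_in: int, reads_assigned: int) -> float:
    """Fraction of input reads surviving to taxonomic assignment."""
    if reads_in <= 0:
        raise ValueError("reads_in must be > 0")
    if not 0 <= reads_assigned <= reads_in:
        raise ValueError("need reads_in >= reads_assigned >= 0")
    return reads_assigned / reads_in


def staged_yields(stages: Mapping[str, int]) -> dict[str, float]:
    """Per-stage yields relative to the first stage (e.g. raw input).

    ``stages`` maps stage name -> read count, in pipeline order; the first
    entry is the denominator.
    """
    items = list(stages.items())
    if not items:
        raise ValueError("need at least one stage")
    _, reads_in = items[0]
    return {name: yield_fraction(reads_in, n) for name, n in items[1:]}


def splitting_level(n_clusters: int, n_expected_components: int) -> float:
    """log10 of clusters per expected component; 0 = one cluster each."""
    if n_clusters < 1 or n_expected_components < 1:
        raise ValueError("counts must be >= 1")
    return math.log10(n_clusters / n_expected_components)


# ---------------------------------------------------------------------------
# threshold sweep


def pr_threshold_sweep(
    expected_set: Sequence[ExpectedComposition],
    observed_set: Sequence[Composition],
    taxonomy: Taxonomy,
    rank: str = "genus",
    step: float = 0.0001,
    beta: float = 2.0,
) -> SweepResult:
    """Aggregate P/R/F-beta over a threshold grid; pick the F-beta optimum.

    Thresholds run from 0 to the largest observed proportion in ``step``
    increments (0.0001 = 0.01% of total composition).  The optimal
    threshold is the smallest one attaining the maximal F-beta.
    """
    if not expected_set or len(expected_set) != len(observed_set):
        raise ValueError("need matching, non-empty expected and observed sets")
    if step <= 0:
        raise ValueError("step must be > 0")
    max_prop = max(
        (e.proportion for obs in observed_set for e in obs.entries.values()),
        default=0.0,
    )
    n_steps = int(math.ceil(max_prop / step)) + 1
    rows = []
    for i in range(n_steps + 1):
        t = i * step
        conf = ConfusionCounts()
        for exp, obs in zip(expected_set, observed_set):
            conf = conf + match_compositions(exp, obs, taxonomy, rank, t)
        p, r = precision_recall(conf)
        f = fbeta(p, r, beta) if p is not None and r is not None else None
        rows.append(
            {
                "threshold": t,
                "tp": conf.tp,
                "fp": conf.fp,
                "fn": conf.fn,
                "precision": p,
                "recall": r,
                "fbeta": f,
            }
        )
    curve = pd.DataFrame(rows)
    scored = curve.dropna(subset=["fbeta"])
    best = scored["fbeta"].max()
    optimal = float(scored.loc[scored["fbeta"] >= best, "threshold"].iloc[0])
    return SweepResult(curve=curve, optimal_threshold=optimal, beta=beta)


# ---------------------------------------------------------------------------
# full report


def evaluate(
    expected_set: Sequence[ExpectedComposition],
    observed_set: Sequence[Composition],
    taxonomy: Taxonomy,
    rank: str = "genus",
    threshold: float = 0.001,
    beta: float = 2.0,
) -> BenchmarkReport:
    """Aggregate confusion + metrics over a sample set at one threshold."""
    if not expected_set or len(expected_set) != len(observed_set):
        raise ValueError("need matching, non-empty expected and observed sets")
    conf = ConfusionCounts()
    sample_rows = []
    err_frames = []
    for exp, obs in zip(expected_set, observed_set):
        c = match_compositions(exp, obs, taxonomy, rank, threshold)
        conf = conf + c
        sample_rows.append(
            {
                "sample_id": exp.sample_id,
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "euclidean": euclidean_distance(exp, obs, taxonomy, rank, threshold),
            }
        )
        err_frames.append(relative_errors(exp, obs, taxonomy, rank, threshold))
    p, r = precision_recall(conf)
    f = fbeta(p, r, beta) if p is not None and r is not None else None
    g = gpr(p, r) if p is not None and r is not None else None
    return BenchmarkReport(
        confusion=conf,
        precision=p,
        recall=r,
        fbeta=f,
        gpr=g,
        per_sample=pd.DataFrame(sample_rows),
        relative_errors=pd.concat(err_frames, ignore_index=True)
        if err_frames
        else pd.DataFrame(),
    )


# ---------------------------------------------------------------------------
# down-sampling


def downsample_seed(size: int, replicate: int) -> int:
    """Seed = decimal digits of the sample size concatenated with the replicate."""
    return int(f"{size}{replicate}")


def _open_fastq(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def downsample_reads(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    size: int,
    replicate: int,
    out_r1: str | Path,
    out_r2: str | Path,
) -> int:
    """Sample ``size`` read pairs without replacement, preserving pairing.

    The same index set, drawn with seed ``int(str(size) + str(replicate))``,
    is applied to both mates, and output order follows input order, so a
    given (size, replicate) pair always produces byte-identical files.
    Returns the seed used.
    """
    with _open_fastq(fastq_r1) as fh:
        r1 = list(SeqIO.parse(fh, "fastq"))
    with _open_fastq(fastq_r2) as fh:
        r2 = list(SeqIO.parse(fh, "fastq"))
    if len(r1) != len(r2):
        raise ValueError(
            f"mate files differ in record count: {len(r1)} vs {len(r2)}"
        )
    if size > len(r1):
        raise ValueError(f"requested {size} pairs but only {len(r1)} available")
    seed = downsample_seed(size, replicate)
    idx = sorted(random.Random(seed).sample(range(len(r1)), size))
    with _open_fastq(out_r1, "wt") as fh:
        SeqIO.write((r1[i] for i in idx), fh, "fastq")
    with _open_fastq(out_r2, "wt") as fh:
        SeqIO.write((r2[i] for i in idx), fh, "fastq")
    return seed
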