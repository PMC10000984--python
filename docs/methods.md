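# Methods

## Consensus assignment model

The taxonomy is the NCBI tree restricted to whatever taxdump the user
loads: nodes carry a taxid, a parent taxid (the root is its own parent), a
rank label and a scientific name. "no rank" nodes stay in lineages and are
skipped only by rank-addressed queries (`ancestor_at_rank`, roll-ups).
Merged taxids remap silently with a log record; deleted/unknown taxids
raise — remapping is routine housekeeping, but silently inventing data for
a deleted id would hide loss.

A cluster's assignment is the *fractional consensus* of its hit taxa: the
deepest node whose subtree covers at least a fraction `level` of the votes.
`level` is restricted to (0.5, 1.0]: above one half, two siblings can never
both qualify at the same depth, so the qualifying nodes form a chain from
the root and the deepest is unique — no tie-break rule is needed, and
`level ≤ 0.5` is rejected rather than resolved arbitrarily. At
`level = 1.0` the consensus degenerates to the last common ancestor. The
implementation descends from the root through the unique qualifying child;
the test suite checks it against an independent node-enumeration oracle on
thousands of random trees. Coverage comparisons use `count/n >= level`
("at least"), so a vote fraction exactly equal to the level qualifies.

Votes count with multiplicity at the taxonomy layer; the *assignment* layer
dereplicates hit taxids to the unique taxon set before voting, so a taxon
over-represented in the reference database gains no extra weight. This
separation keeps the tree operation a pure weighted vote and makes the
policy (unique-taxon voting, unweighted by hit count or bitscore) explicit
and testable. One useful consequence, verified by property test: the LCA
always lies on the consensus lineage — the consensus can only ever be the
LCA or a descendant of it, never off to the side.

## Hit filtering

Hard filters (defaults: e-value ≤ 1e-10, identity ≥ 97 %, coverage ≥ 100 %)
are applied per hit; query coverage is computed as
`100·(qend − qstart + 1)/qlen` from the 1-based inclusive alignment
coordinates rather than read from a tool-specific coverage column, so the
parser is independent of the search tool's output dialect. The e-value
cut is applied as a post-filter; setting it as a search parameter instead
would retain the same hits. The bitscore filter is then computed per query
on the hard-filtered set: hits within Δ (default 4) bits of that query's
best surviving bitscore are kept. Multi-taxid subject rows
(semicolon-separated `staxids`) expand to one hit per taxid before
dereplication.

Clusters whose hits are all filtered away are reported as "no hit"; they
never enter a composition, so composition proportions are fractions of
*assigned* reads. Yield accounting (`yield_fraction`, `staged_yields`)
captures the discarded reads separately.

## Compositions, thresholding, evaluation

The detection threshold keeps entries with proportion ≥ T (an entry at
exactly the 0.1 % operating point survives) and does **not** renormalise
the survivors — proportions remain interpretable as fractions of assigned
reads, and the benchmark applies the same convention on both sides.

Evaluation rolls both compositions to the target rank first. Entries whose
lineage has no node at that rank (assignments stuck above it) keep their
node, are flagged, and count as false positives at that rank — an
assignment at family rank cannot claim a genus-level true positive.
Confusion counts are aggregated over the whole sample set for the headline
metrics (that is the only way the published panel's aggregate table
arithmetic is reproducible), with per-sample rows also emitted. Undefined
ratios (e.g. precision with zero observed components) are reported as
absent, never as 0. Percent displays round half away from zero; raw
fractions are always retained in machine output.

"Average precision" here means the geometric mean √(P·R) of precision and
recall — the definition used in the validation literature this toolkit
follows — not the area under a precision-recall curve; the F-beta score is
the standard `(1+β²)PR/(β²P + R)` with β = 2 by default (recall twice as
important as precision). The threshold sweep evaluates aggregate confusion
on a grid from 0 to the largest observed proportion in steps of 0.0001
(0.01 % of total composition) and returns the smallest threshold attaining
the maximal F2. Recall is non-increasing along the grid; precision need
not be monotone.

Down-sampling follows a reproducibility convention designed so that any
laboratory re-running a size/replicate combination gets byte-identical
files: the seed is the decimal digits of the sample size concatenated with
the replicate number (size 1000, replicate 2 → seed 10002), the index set
is drawn once without replacement and applied to both mates, and output
preserves input order.

## Barcode resolution

Primer matching is ungapped sliding-window IUPAC matching: degenerate
primer positions match their expansion set, `N` in the target matches
nothing, and a window is reported when at least 80 % of the primer —
anchored at the 3' end, since 3' mismatches are what kill extension —
lies on the target with ≥ 65 % identity over the aligned span. These
permissive defaults emulate primer-site discovery tools; the thresholds
are exposed as parameters. A barcode is the sequence between *facing*
matches (forward primer upstream of the reverse primer's reverse
complement, or the mirror image on the other strand) within a maximum
product length (default 2000 bp); primer spans are removed and
minus-strand products are reverse-complemented, so extraction is exactly
strand-invariant (property-tested).

Pairwise identities come from end-to-end global alignment with match +2,
mismatch −4, gap open −20, gap extend −2 — heavy gap penalties suit
same-locus amplicon comparisons, where indels are rare and near-end gaps
should not be discounted. Identity is `identities / alignment columns`,
i.e. 1 − hamming/length with gap columns counted as differences, which
keeps the formula well-defined for unequal lengths. The scoring constants
are documented, not claimed to match any particular external aligner.

For the resolution summary, each barcode's neighbourhood is every set
member (itself included — a sequence is trivially within any identity
level of itself) with identity ≥ the level; the neighbourhood's unique
taxa vote at the 0.51 majority level, and the consensus node's rank is
recorded. The summary reports, per identity level, the percentage of
barcodes resolving at species-or-below and genus-or-below, plus per-taxid
barcode counts and the median barcode length. Consensus depth is
monotone in the identity level on well-separated barcode sets (shrinking a
neighbourhood removes only off-taxon votes); on pathological sets where a
shrinking neighbourhood drops the votes that supported a deep off-lineage
majority, depth can decrease — the property is asserted only on the
generator's references, which are separated by construction.

## Synthetic data generator

The generator emulates the structure of a metabarcoding validation panel,
not its chemistry. Defaults: 12 species, two per genus, two genera per
family under a single clade; 75 bp barcodes (the short 16S fragment that
motivates the resolution analysis) flanked by a degenerate primer pair;
read depth 5000 per sample (the recommended minimum sequencing depth, and
fast to simulate); three samples whose planted components sum to 99.9 %
with every sample containing a component at the 1 % reporting limit.
Sister species differ by `divergence` substitutions (default 3, i.e.
identity 0.96 — just below a 97 % clustering level; 0 makes siblings share
a barcode and collapses their resolution to genus). Reference records are
re-drawn on a deterministic sub-seed if a random flank happens to fake a
primer site, so extraction recovers exactly one barcode per record by
construction.

Each planted component becomes one read cluster (the largest is split in
two to exercise aggregation) whose hit table contains a perfect hit, a
second in-window hit to the same taxon, and one decoy per filter: identity
96.9 (just under the 97 boundary), bitscore 130 (outside the Δ = 4 window
of the 140-bit best), partial coverage, and a failing e-value. The 0.1 %
of depth left unplanted is spread over noise clusters assigned to
off-panel taxa in unplanted genera, each kept below the 0.05 % noise
floor — modelling the trace contaminations seen in real proficiency-test
material rather than per-base sequencing error. One decoy-only cluster per
sample must come out unassigned, exercising the "no hit" path and the
yield denominator.

What passing tests on this generator do show: the filter chain removes
exactly the planted decoy classes; the consensus vote, thresholding and
roll-up arithmetic are correct; planted proportions are recovered to
read-depth quantisation (|predicted − planted| ≤ 1/depth); and the sweep
separates sub-0.05 % noise from ≥ 1 % components. What they do not show:
robustness to real-world database mislabelling, chimeras, or denoising
artefacts — those stages are upstream of this toolkit's scope.

## Numerical and design choices

- Threshold comparisons (detection threshold, identity levels, consensus
  fraction) are all inclusive (≥), chosen so published operating points
  include their boundary.
- The sweep grid is `i·step` floats; tests compare grid points with a
  1e-9 tolerance rather than exact equality.
- On the 0.01 % grid with inclusive thresholding, the smallest
  noise-excluding threshold equals the noise ceiling rounded up to the
  next grid point; with noise strictly below 0.05 % the sweep optimum is
  therefore exactly 0.05 %, the closed left edge of the noise-to-signal
  gap.
- `consensus` compares `count/n >= level` in floating point; both sides
  are computed the same way in the implementation and the brute-force
  oracle, so boundary cases agree by construction.
- Empty inputs: empty vote lists, empty sample sets and zero read counts
  raise `ValueError`; an all-filtered cluster or an empty composition is a
  logged, legal outcome.
- Report percentages round half away from zero to integer percent.

## Known limitations

- The consensus vote is unweighted over unique taxa; bitscore- or
  count-weighted variants are deliberately not implemented.
- Primer matching is ungapped; a primer site interrupted by an indel in
  the reference is missed.
- The identity matrix is O(n²) global alignments — fine for desk-scale
  barcode sets, not for database-wide scans.
- Taxdump loading is linear-time and memory-resident; it is not tuned for
  the full multi-million-node NCBI dump.
- Conspecific probability and upstream read processing (merging,
  clustering, denoising, chimera removal) are out of scope.
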