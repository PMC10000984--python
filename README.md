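# consenstax

Taxonomy-aware consensus assignment and quantitative validation for DNA
metabarcoding, with an in-silico analysis of primer-pair resolution.

## The problem

Food-authenticity laboratories identify the animal species in a meat product
by amplicon sequencing of a short mitochondrial barcode (for the 16S rDNA
marker used as the running example here, ~75 bp between the primers) and
searching the resulting read clusters (OTUs or ASVs) against a large
reference database. Between the similarity search and the final report sit
several bespoke computational steps that decide what the laboratory actually
calls present, and at what proportion:

1. **Hit filtering.** Each cluster's tabular hits are hard-filtered on
   e-value (≤ 1e-10), percent identity (≥ 97) and query coverage (= 100),
   then post-filtered to the hits within Δ = 4 bits of the cluster's best
   bitscore.
2. **Consensus assignment.** The surviving hits' taxa are dereplicated to a
   unique-taxon set which votes on the NCBI taxonomy tree: the cluster is
   assigned the deepest node shared by at least a fraction *X* of the taxa
   (*X* = 0.51 is a strict majority vote; *X* = 1.0 is the last common
   ancestor). Ambiguous clusters therefore land at genus or above instead of
   being forced to a species.
3. **Composition and detection threshold.** Assigned read counts are summed
   per taxon; components below a detection threshold *T* (operating point
   0.1 % of assigned reads) are discarded as noise, without renormalising
   the remaining proportions.
4. **Validation.** Observed compositions are compared to the known
   compositions of reference samples at a chosen rank. The comparison is
   open-world: true positives, false positives and false negatives, from
   which precision = TP/(TP+FP), recall = TP/(TP+FN), the F2 score
   (recall weighted double) and the geometric mean √(P·R) are derived,
   together with per-sample Euclidean (L2) distances, per-component relative
   errors E = (predicted − expected)/expected, read-yield fractions, and the
   splitting level log10(clusters / expected components). A threshold sweep
   in 0.01 % increments locates the smallest *T* maximising F2 — this is how
   the 0.1 % operating point is derived from a validation panel.
5. **Barcode resolution.** Before any wet-lab work, a primer pair can be
   scored in silico: extract every inter-primer fragment from a reference
   collection (IUPAC-degenerate matching, 80 % coverage anchored at the
   primer 3' end, 65 % identity), dereplicate taxon-wise, compute global
   pairwise identities, and ask, for each barcode, at which rank a majority
   consensus over all neighbours within an identity level (e.g. 97 % or
   100 %) would land. The fraction of barcodes resolving at species or genus
   level predicts the marker's discriminatory power.

`consenstax` implements all of these stages as a library plus a thin CLI,
and ships a deterministic synthetic-data generator so the entire chain runs
and validates without any reference database or sequencing data.

## Worked example

```python
from consenstax import evaluate
from consenstax.fixtures import FixtureSpec, make_taxonomy, make_blast_data
from consenstax.pipeline import run_samples
from consenstax.benchmark import pr_threshold_sweep

spec = FixtureSpec(seed=1)                       # 12 taxa, 3 samples, depth 5000
tax = make_taxonomy(spec)
observed, expected = run_samples(make_blast_data(spec), tax)

comp = observed[0]
for taxid, e in sorted(comp.entries.items(), key=lambda kv: -kv[1].proportion):
    print(f"{taxid}  {tax.name(taxid):<22} {e.reads:>5} reads  {e.proportion:.2%}")

report = evaluate(expected, observed, tax, rank="genus", threshold=0.001)
print(f"precision={report.precision:.2f} recall={report.recall:.2f} F2={report.fbeta:.2f}")
sweep = pr_threshold_sweep(expected, observed, tax, rank="genus")
print(f"optimal detection threshold: {sweep.optimal_threshold:.2%}")
```

prints

```
1000  Genus_0 species_0       4495 reads  89.90%
1002  Genus_1 species_0        250 reads  5.00%
1004  Genus_2 species_0        200 reads  4.00%
1006  Genus_3 species_0         50 reads  1.00%
1008  Genus_4 species_0          2 reads  0.04%
1009  Genus_4 species_1          2 reads  0.04%
1010  Genus_5 species_0          1 reads  0.02%
precision=1.00 recall=1.00 F2=1.00
optimal detection threshold: 0.05%
```

The first sample's planted components (89.9 %, 5 %, 4 % and the 1 %
reporting-limit component) are recovered exactly; the three trace clusters
below 0.05 % are the generator's planted noise, which the 0.1 % detection
threshold removes, giving perfect precision and recall at the genus level.
The sweep then finds that any threshold from 0.05 % up to just below 1 %
would separate this noise from the signal, and reports the smallest one.

The same chain is available from the shell:

```bash
consenstax fixtures --seed 1 --out fx/
consenstax assign --hits fx/hits.tsv --counts fx/counts.tsv --taxdump fx/taxdump \
                  --threshold 0 --out observed.tsv
consenstax benchmark --expected fx/expected.tsv --observed observed.tsv \
                     --taxdump fx/taxdump --rank genus
consenstax sweep --expected fx/expected.tsv --observed observed.tsv --taxdump fx/taxdump
consenstax downsample --r1 fx/r1.fastq.gz --r2 fx/r2.fastq.gz --size 1000 --replicate 1 \
                      --out-r1 sub_r1.fastq --out-r2 sub_r2.fastq
```

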