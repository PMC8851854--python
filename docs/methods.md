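# Methods

## Annotation model

Proteomes are searched against profile-HMM databases with `hmmsearch`; the
package consumes the `--domtblout` domain table (one row per domain, the
protein as target and the HMM as query).  Each profile carries a curated
threshold in its spec table:

| field | meaning | default behaviour |
|---|---|---|
| `cutoff_score` | bit-score threshold | compared with `>=` (the `hmmsearch -T`/`--cut_nc` convention) |
| `score_type` | `full` or `domain` | selects the full-sequence or best-domain bit score |
| `cutoff_kind` | `suggested`, `nc`, `tc`, `evalue_fallback` | provenance of the cutoff |
| fallback E-value | for profiles without a curated score | `full_evalue <= 1e-5`, configurable |

Domain rows are collapsed per (protein, profile) keeping the row with the
maximum best-domain score; ties break by smaller independent E-value, then
smaller alignment start.  Both choices are deterministic tie-breaks, not
biology: any row would carry the same pass/fail decision in almost all
real tables.

**Database priority.** When two passing profiles from different databases
map to the same function on one protein, only the highest-priority
database wins (default order custom > kofam > tigrfam > pfam,
configurable).  A profile wins if it has top priority for at least one of
its functions; profiles passing on disjoint functions all win.  The
annotation table keeps every collapsed hit with `passed_threshold`,
`passed_motif` and `winning` flags, so downstream consumers can choose
between "all passing" and "priority winner" views.

**Motif validation.** Roughly twenty families are too similar for scores
alone (DsrC vs TusE is the canonical pair; both live in KO family K11179).
Profiles may reference a motif rule: a required conserved-residue window
over the 20 amino-acid letters plus wildcard `X`, optionally paired with a
forbidden motif diagnostic of the confounding family.  A hit passes when
the required motif occurs anywhere in the sequence (unanchored,
position-wise comparison) and the forbidden one does not.  Ambiguous or
rare residue codes (B, Z, J, U, O) fail every specific motif position — a
conservative choice, since a window containing an ambiguity code cannot be
confirmed to conserve the residue.  The shipped rule set contains the DsrC
motif; further family rules are user-supplied TSV rows, not invented here.
Validation recomputes `winning`, never resurrects a sub-threshold hit, and
is idempotent.

## Cutoff curation

To adjust noise/trusted cutoffs empirically: subsample query sequences
from a reference collection (10% of the collection, but at least 10
sequences, capped at the collection size; drawn without replacement from a
seeded generator), collect pairwise hmmsearch bit scores, rank them in
descending order, and set the cutoff to the mean of the endpoints of the
sharpest decreasing interval.  The interval is a consecutive pair of
ranked scores by default; a `window` parameter generalizes it to wider
spans with the same mean-of-endpoints rule.  Ties break toward the
higher-score pair, yielding the more conservative cutoff.  A series with
no decrease returns the common score flagged degenerate.  Retrieval of
reference sequences from external databases is out of scope; the CLI
consumes pre-computed two-column score tables.

## KEGG modules

Module DEFINITION strings parse with a recursive-descent grammar:
top-level space-separated units are steps; within a step `,` is OR, `+` is
AND, a `-`-prefixed component is optional (vacuously satisfiable), and
parentheses group.  Precedence, loosest to tightest: space, comma,
plus/minus.  Bare `--` units are gap steps and never enter the step count;
optional components never add steps either.  Nested module identifiers
evaluate as absent unless a memo of already-called modules is supplied.
Completeness is the fraction of counted steps whose expression is true
given the genome's KO set; a module is called present at completeness
`>= cutoff` with cutoff 0.75 by default.  The non-strict comparison is
deliberate so that a 4-step module with 3 satisfied steps (75%) is called
present at the default cutoff.  KO presence is taken from winning KOfam
rows; other databases feed modules only through explicit KO aliases in
the spec table.

## CAZymes and peptidases

dbCAN-style CAZy domain tables are filtered with the stock hmmscan-parser
conventions: per (protein, family) overlapping domain alignments on the
family HMM are merged; calls require merged HMM coverage >= 0.3 and a best
domain E-value <= 1e-5 for merged alignments longer than 80 residues
(1e-3 otherwise).  These are external parser conventions, not values
measured here, and all four knobs are arguments.  Peptidase/inhibitor
alignments against a MEROPS-pepunit-style database keep records with
E-value <= 1e-10, query coverage >= 80%, identity >= 50% and per-query rank
<= 1 (rank by bit score, ties by smaller E-value then subject id) —
boundaries inclusive.

## Coverage and abundance

Per-gene coverage is the mean per-base depth over the gene (1-based
inclusive gene coordinates; 0-based arrays internally).  From a sorted BAM
only primary alignments count (secondary/supplementary/unmapped excluded),
so multi-mapped reads contribute once.  Genome coverage C_g defaults to
the length-weighted mean of its genes' depths — equivalent to total mapped
bases over total gene length — with a simple-mean flag; the aggregation
choice only matters for genomes with strongly length-skewed depth.  A
step's relative abundance is 100 × (summed depth of genes winning
annotation to the step's profiles) / (summed depth of all genes).  RPKM
(reads / (kb of transcript × millions of mapped reads)) replaces DNA depth
in metatranscriptome mode; every downstream formula is unchanged, only the
meaning of C_g shifts from abundance to expression.

## Community metrics

MW-score and contribution percentage are exactly the two ratios shown in
the README.  Implementation is a vectorized matrix product; the test suite
pins it to an independent double-loop evaluation at 1e-12.  The
contribution table is emitted unrounded (so each present function's row
sums to exactly 100%); any rounding is presentation-layer.  Taxon groups
come from GTDB lineages at a configurable rank (default phylum), with
Proteobacteria always replaced by its subordinate classes at phylum rank
because that phylum is too broad to be one ecological unit; an unnamed
rank maps to `Unclassified_<deepest named rank>`.

The functional network contains one edge per (taxon group, unordered step
pair) where at least one member genome encodes both steps; the edge weight
is the mean of the two steps' group-summed gene coverages and the member
count is an attribute, a testable reduction of per-genome multi-edges.
Sankey flows accumulate genome coverage per (group, function) and conserve
into function → cycle totals by construction.  Sequential chains report,
per ordered step, the genome count and the coverage of those genomes as a
percentage of total community coverage (genome-based normalization; the
gene-sum alternative is available through the step-abundance table), plus
the count of genomes encoding both steps of each consecutive pair — the
single-organism hand-off candidates.

## Fixtures and what they show

The fixture generator plants a known genome × function presence matrix
(every chosen function in ≥ 1 genome, every genome with ≥ 1 function),
coverages ~ Uniform(1, 50) — a realistic MAG depth range — and writes
proteomes, domtblout tables whose scores clear (plants) or miss (decoys)
the profile cutoffs, a TusE-like decoy that passes the DsrC score cutoff
but lacks the motif, per-gene depth tables that realize the planted
coverages exactly, and a GTDB-style taxonomy including Proteobacteria
lineages.  Default shape: 5 genomes, 8 planted functions, 3 decoys per
genome — small enough that the full suite runs in seconds, large enough to
exercise every code path.  The fixtures emulate table *structure* and the
decision boundaries, not biology: scores are offset from cutoffs rather
than drawn from homology, sequences are random except for planted motif
windows, and depth is uniform within a genome.  Passing tests therefore
demonstrate correctness of parsing, thresholding, validation and the
community algebra — not annotation accuracy on real proteins, which
depends on the curated HMM databases that are deliberately not bundled.

## Template

The default template ships 31 cycling steps and 51 functions across the
carbon, nitrogen, sulfur and other-element cycles, named by the standard
step nomenclature (`C-S-07` methanogenesis, `N-S-09` anammox, `S-S-06`
sulfite reduction, ...), with a 63-profile spec table.  The profile-to-step
gene content is a compact default — real deployments should substitute
their curated template TSVs, which the loader validates (unique ids,
resolvable profile references; the 31/51 size check applies only to the
shipped default).

## Numerical and degenerate-input choices

- Bit-score comparisons are `>=`, E-value comparisons `<=`; all printed
  filter boundaries are inclusive.
- Zero total coverage, an empty proteome, an empty score series, an
  all-zero presence matrix, or a genome missing taxonomy/coverage raise
  configuration errors naming the offender rather than returning NaN.
- Functions with zero MW-score have undefined contribution rows and are
  emitted as NA.
- All pipeline outputs are sorted on stable keys and carry no timestamps,
  so reruns are byte-identical.

## Known limitations

- The real curated HMM databases, dbCAN/MEROPS data, and the live KEGG
  module database are not bundled; schema-compatible miniatures ship for
  tests and the loader accepts full user-supplied versions.
- Motif rules are exact/wildcard windows, not position-specific scoring.
- Gene calling, read mapping, homology search and taxonomy assignment are
  delegated to their standard tools; the package only orchestrates or
  consumes their outputs.
- The sequential-chain roster and the profile content of the default
  template are replaceable defaults, not a curated reference.
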