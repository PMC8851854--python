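# cycleprofiler

Functional trait and biogeochemical cycle profiling of microbial genomes
and communities.

Microbial ecologists working with sets of genomes — isolates,
metagenome-assembled genomes (MAGs) or single-cell genomes — routinely ask
two questions: *what can each organism do* (which metabolic pathways and
biogeochemical transformations does it encode), and *who does what in the
community* (how is each transformation distributed across taxa, weighted by
abundance). `cycleprofiler` answers both with a reproducible, fully
offline-testable workflow:

- **Genome scale** — validated protein annotation against profile-HMM
  databases with per-profile curated bit-score cutoffs (noise/trusted
  cutoffs or KOfam-suggested values, honoring the full-sequence vs
  best-domain score type), database-priority resolution (custom > KOfam >
  TIGRfam > Pfam), conserved-residue **motif validation** for confusable
  families (e.g. the DsrC motif `GPXKXXCXXXGXPXPXXCX`, X = any residue,
  which separates DsrC from TusE), KEGG **module completeness** (a module is
  present when ≥ 75% of its steps are satisfied, configurable), CAZyme and
  peptidase calls, and presence of 31 biogeochemical cycling steps / 51
  finer-grained functions.
- **Community scale** — per-gene read coverage (depth table or sorted BAM)
  aggregated to genome coverages C_g, step relative abundances, and the
  **MW-score** (metabolic weight score) machinery:

  ```
  MW(f)       =  Σ_g C_g · S(g,f)  /  Σ_{g,f'} C_g · S(g,f')
  Cperc(f,p)  =  100 · Σ_{g∈p} C_g · S(g,f)  /  Σ_g C_g · S(g,f)
  ```

  where S(g,f) ∈ {0,1} is presence of function f in genome g.  MW-scores
  sum to 1 over functions; contribution percentages sum to 100% over taxon
  groups for every present function.  Groups default to GTDB phyla, with
  Proteobacteria replaced by its classes.  The same layer builds per-group
  functional co-occurrence networks, Sankey flows (group → function →
  cycle) and sequential-transformation profiles (e.g. the denitrification
  chain), and accepts RPKM tables in place of DNA coverage for
  metatranscriptomes.

The package also implements the empirical **cutoff-curation** rule used to
adjust profile thresholds: rank pairwise hmmsearch scores and place the
cutoff at the mean of the sharpest decreasing interval.

## Worked example

```python
import pandas as pd
from cycleprofiler import CommunityProfile, mw_scores, contribution_percentages

profile = CommunityProfile(
    presence=pd.DataFrame([[1, 0], [1, 1]], index=["g1", "g2"], columns=["f1", "f2"]),
    coverage=pd.Series({"g1": 10.0, "g2": 30.0}),
    groups=pd.Series({"g1": "Nitrospirota", "g2": "Gammaproteobacteria"}),
)
print(mw_scores(profile))
print(contribution_percentages(profile))
```

prints

```
f1   0.5714
f2   0.4286

    Gammaproteobacteria  Nitrospirota
f1                 75.0          25.0
f2                100.0           0.0
```

Function f1 is encoded by both genomes, so its MW-score is
(10 + 30)/70 = 0.5714 of the community's coverage-weighted functional
capacity; g2's group contributes 30/40 = 75% of it.  More narrative
examples — annotation with motif validation, cutoff curation, module
completeness, and a full community-mode run on generated fixtures — live in
`examples/` (each prints its results and a one-line interpretation).

## Command line

```bash
profiler fixtures -o toy --seed 42            # deterministic toy inputs
profiler genome    -i toy -o out_g
profiler community -i toy -o out_c --depth toy/depth.tsv --tax toy/gtdbtk.tsv
profiler curate-cutoff scores.tsv             # sharpest-drop cutoff from a score TSV
```

Outputs are plain TSV (plus GraphML for the functional network) and are
byte-identical across reruns of the same inputs.

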