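"""Genome-mode and community-mode pipeline orchestration and output writers.

Genome mode profiles each input genome in isolation: validated protein
annotations, function/trait presence, KEGG module completeness, CAZyme and
peptidase calls, and per-genome plus community-wide cycle-step presence.
Community mode layers abundance on top: per-gene depths (from a depth table
or a sorted BAM) aggregate to genome coverages C_g, which drive step
relative abundances, MW-scores and contribution percentages, the per-group
functional network, Sankey flows and sequential-transformation profiles.
With the metatranscriptome flag the same machinery runs on RPKM-derived
values instead of DNA depth.

All outputs are TSV (GraphML for the network graph); re-running with the
same inputs and configuration is byte-identical.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from . import cazy, community, coverage, kegg
from .errors import ConfigError
from .hmm import annotate_proteome
from .templates import CycleTemplate, load_templates


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: Path
    output_dir: Path
    mode: str = "genome"                      # genome | community
    protein_extension: str = "faa"
    prodigal_mode: str = "meta"               # meta | single
    depth_table: Path | None = None
    bam_path: Path | None = None
    gene_intervals: Mapping[str, tuple[str, int, int]] | None = None
    taxonomy_table: Path | None = None
    omics: str = "metagenome"                 # metagenome | metatranscriptome
    module_cutoff: float = 0.75
    taxon_rank: str = "phylum"
    threads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if self.mode not in ("genome", "community"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not 0 < self.module_cutoff <= 1:
            raise ConfigError("module cutoff must be in (0, 1]")
        if self.mode == "community" and self.depth_table is None and self.bam_path is None:
            raise ConfigError("community mode requires a depth table or BAM coverage input")


def call_genes(nucleotide_fasta: Path, out_faa: Path, mode: str = "meta") -> Path:
    """Predict proteins from a nucleotide FASTA with Prodigal (meta or single)."""
    exe = shutil.which("prodigal")
    if exe is None:
        raise ConfigError("prodigal not found on PATH; supply .faa proteomes instead")
    subprocess.run(
        [exe, "-i", str(nucleotide_fasta), "-a", str(out_faa), "-p", mode, "-q"],
        check=True, capture_output=True,
    )
    return out_faa


def _discover_genomes(cfg: RunConfig) -> list[str]:
    faas = sorted(cfg.input_dir.glob(f"*.{cfg.protein_extension}"))
    nts = [p for p in sorted(cfg.input_dir.glob("*.fasta")) + sorted(cfg.input_dir.glob("*.fna"))
           if not p.with_suffix(f".{cfg.protein_extension}").exists()]
    for nt in nts:
        faas.append(call_genes(nt, nt.with_suffix(f".{cfg.protein_extension}"),
                               mode=cfg.prodigal_mode))
    genomes = sorted({p.stem for p in faas})
    if not genomes:
        raise ConfigError(f"no genome inputs (*.{cfg.protein_extension}) in {cfg.input_dir}")
    return genomes


def run_genome_mode(cfg: RunConfig, template: CycleTemplate | None = None) -> dict[str, Path]:
    """Run the genome-scale workflow; returns the output file manifest."""
    template = template or load_templates()
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    genomes = _discover_genomes(cfg)
    specs = template.profile_specs
    outputs: dict[str, Path] = {}

    annotations: dict[str, pd.DataFrame] = {}
    for g in genomes:
        faa = cfg.input_dir / f"{g}.{cfg.protein_extension}"
        domtbl = cfg.input_dir / f"{g}.domtblout"
        table = annotate_proteome(
            faa, specs, domtblout=domtbl if domtbl.exists() else None,
            hmm_db=None if domtbl.exists() else _require_hmm_db(cfg),
            motif_rules=template.motif_rules, genome_id=g, threads=cfg.threads,
        )
        annotations[g] = table
        p = cfg.output_dir / f"{g}.annotation.tsv"
        table.loc[table["winning"]].to_csv(p, sep="\t", index=False)
        outputs[f"annotation/{g}"] = p

    # trait (function presence) matrix over all template functions
    presence = function_presence(annotations, template)
    p = cfg.output_dir / "function_presence.tsv"
    presence.to_csv(p, sep="\t", index_label="genome_id")
    outputs["function_presence"] = p

    # KEGG module completeness from winning KOfam rows
    mod_rows, step_rows = [], []
    for g in genomes:
        kos = winning_kos(annotations[g], specs)
        for mid, defn in sorted(template.modules.items()):
            call = kegg.call_presence(kegg.module_completeness(defn, kos),
                                      cutoff=cfg.module_cutoff)
            mod_rows.append((g, mid, defn.name, call.n_steps, call.n_present,
                             call.completeness, call.present))
            for i, state in enumerate(call.step_states, start=1):
                step_rows.append((g, mid, i, state))
    p = cfg.output_dir / "module_presence.tsv"
    pd.DataFrame(mod_rows, columns=["genome_id", "module_id", "name", "n_steps",
                                    "n_present", "completeness", "present"]
                 ).to_csv(p, sep="\t", index=False)
    outputs["module_presence"] = p
    p = cfg.output_dir / "module_steps.tsv"
    pd.DataFrame(step_rows, columns=["genome_id", "module_id", "step_index", "satisfied"]
                 ).to_csv(p, sep="\t", index=False)
    outputs["module_steps"] = p

    # CAZymes and peptidases from pre-computed inputs, when present
    caz_rows, pep_rows = [], []
    for g in genomes:
        dbcan = cfg.input_dir / f"{g}.dbcan.domtblout"
        if dbcan.exists():
            for c in cazy.parse_dbcan_hits(dbcan.read_text().splitlines()):
                caz_rows.append((g, c.protein_id, c.family_id, c.evalue, c.covered_fraction))
        pep = cfg.input_dir / f"{g}.pep.tsv"
        if pep.exists():
            recs = cazy.read_alignment_table(pep.read_text().splitlines())
            for r in cazy.filter_peptidase_hits(recs):
                pep_rows.append((g, r.query_id, r.subject_id, r.percent_identity,
                                 r.evalue, r.query_coverage, r.bit_score))
    p = cfg.output_dir / "cazymes.tsv"
    pd.DataFrame(caz_rows, columns=["genome_id", "protein_id", "family_id",
                                    "evalue", "covered_fraction"]).to_csv(p, sep="\t", index=False)
    outputs["cazymes"] = p
    p = cfg.output_dir / "peptidases.tsv"
    pd.DataFrame(pep_rows, columns=["genome_id", "protein_id", "subject_id",
                                    "percent_identity", "evalue", "query_coverage",
                                    "bit_score"]).to_csv(p, sep="\t", index=False)
    outputs["peptidases"] = p

    # cycle-step presence, per genome and community-wide
    steps = step_presence(presence, template)
    p = cfg.output_dir / "step_presence.tsv"
    steps.to_csv(p, sep="\t", index_label="genome_id")
    outputs["step_presence"] = p
    summary = pd.DataFrame({
        "step_id": steps.columns,
        "n_genomes": steps.sum(axis=0).astype(int).values,
    })
    p = cfg.output_dir / "community_steps.tsv"
    summary.to_csv(p, sep="\t", index=False)
    outputs["community_steps"] = p
    return outputs


def _require_hmm_db(cfg: RunConfig) -> Path:
    db = cfg.input_dir / "profiles.hmm"
    if not db.exists():
        raise ConfigError(
            "no pre-computed domtblout found and no profiles.hmm database to search; "
            "supply per-genome <genome>.domtblout files or an HMM database"
        )
    return db


def winning_kos(table: pd.DataFrame, specs: Mapping[str, object]) -> set[str]:
    """KO set of a genome: winning rows from KOfam profiles."""
    out = set()
    for _, row in table.loc[table["winning"]].iterrows():
        spec = specs[row["profile_id"]]
        if getattr(spec, "database", "") == "kofam":
            out.add(row["profile_id"])
    return out


def function_presence(annotations: Mapping[str, pd.DataFrame],
                      template: CycleTemplate) -> pd.DataFrame:
    """Binary genome x function matrix from winning annotation rows."""
    fn_map = template.function_map
    genomes = sorted(annotations)
    data = {}
    for g in genomes:
        winners = set(annotations[g].loc[annotations[g]["winning"], "profile_id"])
        data[g] = {f: int(bool(profiles & winners)) for f, profiles in fn_map.items()}
    return pd.DataFrame.from_dict(data, orient="index")[
        [f.function_id for f in template.functions]
    ]


def step_presence(presence: pd.DataFrame, template: CycleTemplate) -> pd.DataFrame:
    """Binary genome x step matrix: a step is present when any of its functions is."""
    cols = {}
    for s in template.steps:
        fns = [f.function_id for f in template.functions if f.step_id == s.step_id]
        cols[s.step_id] = (presence[fns].sum(axis=1) > 0).astype(int)
    return pd.DataFrame(cols, index=presence.index)


def _load_gene_coverages(cfg: RunConfig) -> list[coverage.GeneCoverage]:
    if cfg.depth_table is not None:
        return coverage.read_depth_table(cfg.depth_table)
    if cfg.bam_path is None or cfg.gene_intervals is None:
        raise ConfigError("community mode needs a depth table, or a BAM plus gene intervals")
    genome_of = {gene: gene.split("_")[0] for gene in cfg.gene_intervals}
    return coverage.depth_from_bam(cfg.bam_path, cfg.gene_intervals, genome_of=genome_of)


def run_community_mode(cfg: RunConfig, template: CycleTemplate | None = None) -> dict[str, Path]:
    """Run the community-scale workflow on top of genome mode."""
    template = template or load_templates()
    outputs = run_genome_mode(cfg, template)

    genes = _load_gene_coverages(cfg)
    by_genome: dict[str, list[coverage.GeneCoverage]] = {}
    for gc in genes:
        by_genome.setdefault(gc.genome_id, []).append(gc)
    genome_cov = pd.Series({g: coverage.genome_coverage(gs).coverage
                            for g, gs in sorted(by_genome.items())}, dtype=float)
    p = cfg.output_dir / "genome_coverage.tsv"
    genome_cov.rename("coverage").to_csv(p, sep="\t", index_label="genome_id")
    outputs["genome_coverage"] = p

    if cfg.taxonomy_table is None:
        raise ConfigError("community mode requires a GTDB-Tk classification table")
    tax = pd.read_csv(cfg.taxonomy_table, sep="\t")
    tax_col = "classification"
    if tax_col not in tax.columns:
        raise ConfigError("taxonomy table must carry a 'classification' column")
    lineages = dict(zip(tax["user_genome"].astype(str), tax[tax_col].astype(str)))

    presence = pd.read_csv(outputs["function_presence"], sep="\t", index_col="genome_id")
    missing_tax = sorted(set(presence.index.astype(str)) - set(lineages))
    if missing_tax:
        raise ConfigError(f"genomes missing from the taxonomy table: {', '.join(missing_tax)}")
    groups = pd.Series({g: community.assign_taxon_group(lineages[g], rank=cfg.taxon_rank)
                        for g in presence.index})

    profile = community.CommunityProfile(
        presence=presence, coverage=genome_cov, groups=groups,
    )

    mw = community.mw_scores(profile)
    cperc = community.contribution_percentages(profile)
    # MW-score sheet: one column per function; first row the MW-score, then
    # one row per taxon group with its contribution percentage.
    sheet = pd.concat([mw.to_frame("MW-score").T, cperc.T])
    p = cfg.output_dir / "mw_scores.tsv"
    sheet.to_csv(p, sep="\t", index_label="row")
    outputs["mw_scores"] = p

    # step relative abundances from gene coverages
    annotations = {
        g: pd.read_csv(cfg.output_dir / f"{g}.annotation.tsv", sep="\t")
        for g in presence.index
    }
    all_ann = (pd.concat(annotations.values(), ignore_index=True)
               if annotations else pd.DataFrame())
    if not all_ann.empty:
        all_ann["winning"] = all_ann["winning"].astype(bool)
    step_map = template.step_map
    abund_rows = []
    for s in template.steps:
        val = coverage.step_relative_abundance(s.step_id, all_ann, genes, step_map)
        abund_rows.append((s.step_id, s.name, val))
    p = cfg.output_dir / "step_abundance.tsv"
    pd.DataFrame(abund_rows, columns=["step_id", "name", "relative_abundance_pct"]
                 ).to_csv(p, sep="\t", index=False)
    outputs["step_abundance"] = p

    # functional network over cycle steps
    steps_df = pd.read_csv(outputs["step_presence"], sep="\t", index_col="genome_id")
    step_cov = _step_gene_coverage(all_ann, genes, step_map, steps_df.index, steps_df.columns)
    edges, graph = community.build_functional_network(steps_df, groups, step_cov)
    p = cfg.output_dir / "network_edges.tsv"
    pd.DataFrame(
        [(e.step_a, e.step_b, e.group_id, e.weight, e.n_genomes) for e in edges],
        columns=["step_a", "step_b", "group", "weight", "n_genomes"],
    ).to_csv(p, sep="\t", index=False)
    outputs["network_edges"] = p
    p = cfg.output_dir / "network.graphml"
    nx.write_graphml(graph, p)
    outputs["network_graphml"] = p

    flows, group_sizes = community.sankey_flows(profile, template.cycle_map)
    p = cfg.output_dir / "sankey_flows.tsv"
    pd.DataFrame([(f.source, f.target, f.weight) for f in flows],
                 columns=["source", "target", "weight"]).to_csv(p, sep="\t", index=False)
    outputs["sankey_flows"] = p
    p = cfg.output_dir / "sankey_groups.tsv"
    group_sizes.rename("n_genomes").to_csv(p, sep="\t", index_label="group")
    outputs["sankey_groups"] = p

    chain_rows = []
    for chain_id, entries in sorted(template.chains.items()):
        letters = [e[0] for e in entries]
        chain_steps = [e[1] for e in entries]
        prof = community.sequential_profile(chain_id, chain_steps, steps_df,
                                            genome_cov, letters=letters)
        for letter, sid, n, a in zip(prof.letters, prof.steps, prof.n_genomes,
                                     prof.abundance_pct):
            chain_rows.append((chain_id, letter, sid, n, a))
    p = cfg.output_dir / "sequential_profiles.tsv"
    pd.DataFrame(chain_rows, columns=["chain_id", "letter", "step_id",
                                      "n_genomes", "abundance_pct"]
                 ).to_csv(p, sep="\t", index=False)
    outputs["sequential_profiles"] = p
    return outputs


def _step_gene_coverage(annotations: pd.DataFrame,
                        genes: Sequence[coverage.GeneCoverage],
                        step_map: Mapping[str, frozenset[str]],
                        genomes: pd.Index, steps: pd.Index) -> pd.DataFrame:
    """Genome x step sums of winning-gene coverage."""
    depth = {(g.genome_id, g.gene_id): g.mean_depth for g in genes}
    out = pd.DataFrame(0.0, index=genomes, columns=steps)
    if annotations.empty:
        return out
    for sid in steps:
        profiles = set(step_map[sid])
        rows = annotations.loc[annotations["winning"]
                               & annotations["profile_id"].isin(profiles)]
        for g, pid in sorted(set(zip(rows["genome_id"], rows["protein_id"]))):
            if g in out.index:
                out.at[g, sid] += depth.get((g, pid), 0.0)
    return out
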