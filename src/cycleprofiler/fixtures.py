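"""Deterministic synthetic fixture generation for offline pipeline runs.

Emulates, at toy scale, every input the profiler consumes: proteomes
(FASTA), hmmsearch domtblout tables consistent with a planted
genome x function presence matrix, per-gene depth tables realizing planted
genome coverages, a GTDB-Tk classification summary, peptidase alignment
tables, dbCAN-style domain tables, and a toy read mapping (SAM).  A truth
manifest records exactly what was planted so pipeline outputs can be
checked for exact recovery.

Everything is drawn from one ``numpy`` generator seeded by the caller, so a
given (seed, shape) pair always produces a byte-identical bundle.  What the
fixtures emulate — and what they do not (real HMM score distributions,
sequence homology, read error) — is documented in the package's methods
note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .templates import CycleTemplate, load_templates

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: GTDB-style lineages cycled over fixture genomes; includes Proteobacteria
#: entries so the phylum->class substitution is exercised.
LINEAGE_POOL = [
    "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Burkholderiales;f__Burkholderiaceae;g__Cupriavidus;s__",
    "d__Bacteria;p__Nitrospirota;c__Nitrospiria;o__Nitrospirales;f__Nitrospiraceae;g__Nitrospira;s__",
    "d__Bacteria;p__Desulfobacterota;c__Desulfovibrionia;o__Desulfovibrionales;f__Desulfovibrionaceae;g__Desulfovibrio;s__",
    "d__Archaea;p__Halobacteriota;c__Methanosarcinia;o__Methanosarcinales;f__Methanosarcinaceae;g__Methanosarcina;s__",
    "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Rhodobacterales;f__Rhodobacteraceae;g__Paracoccus;s__",
    "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides;s__",
]


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def sequence_matching_motif(rng: np.random.Generator, motif: str) -> str:
    """A concrete residue window satisfying a wildcard motif."""
    return "".join(
        rng.choice(list(AMINO_ACIDS)) if c == "X" else c for c in motif
    )


def format_domtblout_row(
    protein_id: str,
    profile_id: str,
    tlen: int,
    qlen: int,
    full_evalue: float,
    full_score: float,
    i_evalue: float,
    dom_score: float,
    hmm_from: int,
    hmm_to: int,
    ali_from: int,
    ali_to: int,
    dom_num: int = 1,
    dom_of: int = 1,
) -> str:
    """One data row in hmmsearch --domtblout column order."""
    return (
        f"{protein_id} - {tlen} {profile_id} - {qlen} "
        f"{full_evalue:.2g} {full_score:.1f} 0.1 {dom_num} {dom_of} "
        f"{i_evalue:.2g} {i_evalue:.2g} {dom_score:.1f} 0.1 "
        f"{hmm_from} {hmm_to} {ali_from} {ali_to} {ali_from} {ali_to} 0.95 -"
    )


DOMTBLOUT_HEADER = (
    "#                                                               --- full sequence ---"
    " -------------- this domain -------------   hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen"
    "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
    "  from    to  from    to  acc description of target\n"
)


@dataclass
class FixtureBundle:
    """Paths and planted truth of one generated fixture set."""

    root: Path
    genome_ids: list[str]
    function_ids: list[str]
    presence: dict[str, dict[str, int]]      # genome -> function -> 0/1
    coverages: dict[str, float]
    groups: dict[str, str]
    kos: dict[str, list[str]]                # genome -> planted KO profiles
    manifest_path: Path


def generate_fixtures(
    seed: int,
    out_dir: str | Path,
    n_genomes: int = 5,
    n_functions: int = 8,
    n_decoys: int = 3,
    template: CycleTemplate | None = None,
    plant_tuse_decoy: bool = True,
) -> FixtureBundle:
    """Write a deterministic toy community fixture bundle under ``out_dir``.

    Plants a random genome x function presence matrix (every chosen function
    in at least one genome, every genome with at least one function), genome
    coverages ~ Uniform(1, 50), and for each planted (genome, function) one
    protein whose domtblout hit passes the corresponding profile's cutoff.
    Decoy proteins carry sub-threshold hits; optionally one TusE-like decoy
    passes the DsrC profile's score cutoff but lacks the DsrC motif, so the
    motif-validation stage must reject it.  The recorded presence truth is
    the closure of the planted profiles over the template's function map
    (profiles shared between functions mark every mapped function present).
    """
    if n_genomes < 1:
        raise ConfigError("n_genomes must be >= 1")
    template = template or load_templates()
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome_ids = [f"g{i + 1:02d}" for i in range(n_genomes)]
    fn_pool = [f.function_id for f in template.functions]
    n_functions = min(n_functions, len(fn_pool))
    chosen = sorted(rng.choice(fn_pool, size=n_functions, replace=False))

    # planted assignment: redraw until no empty row/column
    while True:
        plant = rng.integers(0, 2, size=(n_genomes, n_functions))
        if plant.sum(axis=0).min() >= 1 and plant.sum(axis=1).min() >= 1:
            break

    fn_profiles = template.function_map
    specs = template.profile_specs
    coverages = {g: round(float(rng.uniform(1, 50)), 4) for g in genome_ids}
    groups = {}

    presence: dict[str, dict[str, int]] = {}
    kos: dict[str, list[str]] = {}
    depth_rows: list[tuple[str, str, int, float]] = []

    dsrc_profile = next((p for p, s in specs.items() if s.motif_rule_id == "DsrC"), None)

    for gi, g in enumerate(genome_ids):
        lineage = LINEAGE_POOL[gi % len(LINEAGE_POOL)]
        groups[g] = lineage
        proteins: dict[str, str] = {}
        dom_rows: list[str] = []
        planted_profiles: list[str] = []
        pnum = 0

        for fj, f in enumerate(chosen):
            if plant[gi, fj] != 1:
                continue
            profile = str(rng.choice(sorted(fn_profiles[f])))
            planted_profiles.append(profile)
            spec = specs[profile]
            pnum += 1
            pid = f"{g}_p{pnum:03d}"
            length = int(rng.integers(150, 400))
            seq = random_protein(rng, length)
            if spec.motif_rule_id == "DsrC":
                window = sequence_matching_motif(rng, template.motif_rules["DsrC"].required_motif)
                pos = int(rng.integers(0, length - len(window)))
                seq = seq[:pos] + window + seq[pos + len(window):]
            proteins[pid] = seq
            base = spec.cutoff_score if spec.cutoff_score is not None else 60.0
            score = base + float(rng.uniform(5, 60))
            qlen = int(rng.integers(120, 350))
            dom_rows.append(format_domtblout_row(
                pid, profile, tlen=length, qlen=qlen,
                full_evalue=1e-30, full_score=score, i_evalue=1e-28, dom_score=score - 1.0,
                hmm_from=1, hmm_to=qlen, ali_from=5, ali_to=min(length, qlen),
            ))

        # sub-threshold decoys plus one hit-free protein
        all_profiles = sorted(specs)
        for _ in range(n_decoys):
            pnum += 1
            pid = f"{g}_p{pnum:03d}"
            length = int(rng.integers(120, 300))
            proteins[pid] = random_protein(rng, length)
            profile = str(rng.choice(all_profiles))
            spec = specs[profile]
            if spec.cutoff_score is not None:
                score = spec.cutoff_score * float(rng.uniform(0.2, 0.8))
                ev = 1e-8
            else:
                score = 20.0
                ev = 1e-2  # misses the E-value fallback
            qlen = int(rng.integers(120, 350))
            dom_rows.append(format_domtblout_row(
                pid, profile, tlen=length, qlen=qlen,
                full_evalue=ev, full_score=score, i_evalue=ev, dom_score=score,
                hmm_from=1, hmm_to=qlen // 2, ali_from=3, ali_to=min(length, qlen // 2),
            ))
        pnum += 1
        proteins[f"{g}_p{pnum:03d}"] = random_protein(rng, int(rng.integers(100, 200)))

        if plant_tuse_decoy and gi == 0 and dsrc_profile is not None:
            spec = specs[dsrc_profile]
            pnum += 1
            pid = f"{g}_tusE"
            length = 180
            proteins[pid] = random_protein(rng, length)  # no DsrC motif
            score = (spec.cutoff_score or 60.0) + 25.0
            dom_rows.append(format_domtblout_row(
                pid, dsrc_profile, tlen=length, qlen=110,
                full_evalue=1e-25, full_score=score, i_evalue=1e-24, dom_score=score - 1.0,
                hmm_from=1, hmm_to=110, ali_from=10, ali_to=110,
            ))

        with open(out / f"{g}.faa", "w") as fh:
            for pid, seq in proteins.items():
                fh.write(f">{pid}\n{seq}\n")
        with open(out / f"{g}.domtblout", "w") as fh:
            fh.write(DOMTBLOUT_HEADER)
            fh.write("\n".join(dom_rows) + ("\n" if dom_rows else ""))
        _write_peptidase_fixture(out / f"{g}.pep.tsv", proteins, rng)
        _write_dbcan_fixture(out / f"{g}.dbcan.domtblout", proteins, rng)

        for pid, seq in proteins.items():
            depth_rows.append((g, pid, 3 * len(seq), coverages[g]))

        # truth: closure of planted profiles over the template's functions
        planted_set = set(planted_profiles)
        presence[g] = {
            f.function_id: int(bool(f.profile_ids & planted_set))
            for f in template.functions
        }
        kos[g] = sorted({p for p in planted_set
                         if specs[p].database == "kofam"})

    with open(out / "depth.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\tlength_bp\tmean_depth\n")
        for g, pid, ln, d in depth_rows:
            fh.write(f"{g}\t{pid}\t{ln}\t{d}\n")
    with open(out / "gtdbtk.tsv", "w") as fh:
        fh.write("user_genome\tclassification\n")
        for g in genome_ids:
            fh.write(f"{g}\t{groups[g]}\n")

    manifest = {
        "seed": seed,
        "genome_ids": genome_ids,
        "chosen_functions": list(chosen),
        "presence": presence,
        "coverages": coverages,
        "lineages": groups,
        "kos": kos,
    }
    manifest_path = out / "truth.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return FixtureBundle(
        root=out, genome_ids=genome_ids, function_ids=list(chosen),
        presence=presence, coverages=coverages, groups=groups, kos=kos,
        manifest_path=manifest_path,
    )


def _write_peptidase_fixture(path: Path, proteins: dict[str, str],
                             rng: np.random.Generator) -> None:
    """Two alignments vs a MEROPS-style subject set: one passing, one failing."""
    pids = sorted(proteins)
    rows = []
    q1 = pids[0]
    rows.append(f"{q1}\tMER0001234|C26.001\t{60 + float(rng.uniform(0, 30)):.1f}\t150\t10\t1\t1\t150\t1\t150\t1e-40\t250.0\t{85 + float(rng.uniform(0, 10)):.1f}")
    q2 = pids[min(1, len(pids) - 1)]
    rows.append(f"{q2}\tMER0005678|S01.151\t{30 + float(rng.uniform(0, 15)):.1f}\t120\t40\t3\t1\t120\t1\t120\t1e-12\t90.0\t{85 + float(rng.uniform(0, 10)):.1f}")
    path.write_text("\n".join(rows) + "\n")


def _write_dbcan_fixture(path: Path, proteins: dict[str, str],
                         rng: np.random.Generator) -> None:
    """Two CAZy-family domains: one passing the parser, one below coverage."""
    pids = sorted(proteins)
    q1 = pids[0]
    rows = [
        format_domtblout_row(q1, "GH5.hmm", tlen=len(proteins[q1]), qlen=150,
                             full_evalue=1e-30, full_score=180.0, i_evalue=1e-28,
                             dom_score=178.0, hmm_from=5, hmm_to=140,
                             ali_from=1, ali_to=136),
        format_domtblout_row(q1, "CBM50.hmm", tlen=len(proteins[q1]), qlen=200,
                             full_evalue=1e-4, full_score=20.0, i_evalue=1e-4,
                             dom_score=19.0, hmm_from=1, hmm_to=30,
                             ali_from=1, ali_to=30),
    ]
    path.write_text(DOMTBLOUT_HEADER + "\n".join(rows) + "\n")


def toy_read_mapping() -> tuple[str, dict[str, tuple[str, int, int]]]:
    """A 10-read toy SAM over one contig plus gene intervals.

    Includes one secondary and one supplementary alignment that depth
    computation must ignore.  Returns (sam_text, gene intervals in 1-based
    inclusive coordinates).
    """
    contig, clen, rlen = "contig1", 120, 20
    header = f"@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{contig}\tLN:{clen}\n"
    # (name, flag, 1-based pos)
    reads = [
        ("r1", 0, 1), ("r2", 0, 6), ("r3", 0, 11), ("r4", 16, 21),
        ("r5", 0, 41), ("r6", 0, 46), ("r7", 16, 61), ("r8", 0, 81),
        ("r9", 256, 15),   # secondary: excluded
        ("r10", 2048, 70),  # supplementary: excluded
    ]
    lines = [header.rstrip("\n")]
    for name, flag, pos in reads:
        seq = "A" * rlen
        lines.append(
            f"{name}\t{flag}\t{contig}\t{pos}\t60\t{rlen}M\t*\t0\t0\t{seq}\t{'I' * rlen}"
        )
    genes = {
        "geneA": (contig, 11, 40),
        "geneB": (contig, 51, 90),
    }
    return "\n".join(lines) + "\n", genes
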