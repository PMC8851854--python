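"""Profile-HMM annotation: domtblout parsing, score thresholding and hit selection.

Proteomes are searched against profile-HMM databases (KOfam, TIGRfam, Pfam,
custom metabolic profiles) with ``hmmsearch``.  Each profile carries a curated
bit-score cutoff — the KOfam-suggested value, or a noise/trusted cutoff
adjusted so that non-specific hits from closely related families are excluded
— together with the score type it applies to (full-sequence or best-domain
bit score).  Hits passing their profile's cutoff are then resolved across
databases: when two passing profiles from different databases target the same
function, the higher-priority database (custom curated profiles first) wins.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ParseError

#: Database priority used to resolve two passing profiles annotating the same
#: function on one protein.  Earlier entries take precedence.
DEFAULT_PRIORITY: tuple[str, ...] = ("custom", "kofam", "tigrfam", "pfam", "dbcan")

#: E-value threshold applied to profiles that ship without a curated bit-score
#: cutoff.
DEFAULT_FALLBACK_EVALUE = 1e-5

DATABASES = frozenset({"kofam", "tigrfam", "pfam", "custom", "dbcan"})

ANNOTATION_COLUMNS = [
    "genome_id",
    "protein_id",
    "profile_id",
    "full_score",
    "best_domain_score",
    "full_evalue",
    "i_evalue",
    "passed_threshold",
    "passed_motif",
    "winning",
]


@dataclass(frozen=True)
class HmmProfileSpec:
    """One profile's identity, curated cutoff and function mapping.

    ``cutoff_score`` is a bit score compared against the full-sequence or
    best-domain score depending on ``score_type``; profiles without a curated
    cutoff (``cutoff_score is None``) fall back to a full-sequence E-value
    threshold and must declare ``cutoff_kind='evalue_fallback'``.
    """

    profile_id: str
    database: str
    cutoff_score: float | None = None
    score_type: str = "full"
    cutoff_kind: str = "suggested"
    function_ids: frozenset[str] = field(default_factory=frozenset)
    motif_rule_id: str | None = None

    def __post_init__(self) -> None:
        if self.database not in DATABASES:
            raise ConfigError(f"unknown database {self.database!r} for profile {self.profile_id}")
        if self.score_type not in ("full", "domain"):
            raise ConfigError(f"score_type must be 'full' or 'domain', got {self.score_type!r}")
        if self.cutoff_score is None and self.cutoff_kind != "evalue_fallback":
            raise ConfigError(
                f"profile {self.profile_id}: no cutoff_score requires cutoff_kind='evalue_fallback'"
            )
        if self.cutoff_score is not None and self.cutoff_score < 0:
            raise ConfigError(f"profile {self.profile_id}: negative cutoff_score")


@dataclass(frozen=True)
class HmmHit:
    """One domain row of a HMMER3 ``--domtblout`` table (hmmsearch layout)."""

    protein_id: str
    genome_id: str
    profile_id: str
    full_score: float
    best_domain_score: float
    full_evalue: float
    i_evalue: float
    ali_from: int
    ali_to: int
    qlen: int
    tlen: int
    hmm_from: int = 0
    hmm_to: int = 0


def parse_domtblout(stream: Iterable[str], genome_id: str = "") -> list[HmmHit]:
    """Parse hmmsearch ``--domtblout`` lines into :class:`HmmHit` rows.

    One row per domain; no merging happens here.  In the hmmsearch layout the
    *target* is the protein sequence and the *query* is the HMM profile.
    Lines starting with ``#`` are comments.  Raises :class:`ParseError` naming
    the 1-based line number for malformed rows.
    """
    hits: list[HmmHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 23:
            raise ParseError(f"line {lineno}: expected >= 23 fields, got {len(fields)}")
        try:
            hit = HmmHit(
                protein_id=fields[0],
                genome_id=genome_id,
                profile_id=fields[3],
                tlen=int(fields[2]),
                qlen=int(fields[5]),
                full_evalue=float(fields[6]),
                full_score=float(fields[7]),
                i_evalue=float(fields[12]),
                best_domain_score=float(fields[13]),
                hmm_from=int(fields[15]),
                hmm_to=int(fields[16]),
                ali_from=int(fields[17]),
                ali_to=int(fields[18]),
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def apply_threshold(
    hit: HmmHit, spec: HmmProfileSpec, fallback_evalue: float = DEFAULT_FALLBACK_EVALUE
) -> bool:
    """Does ``hit`` pass its profile's curated threshold?

    Bit scores pass under ``>=`` (the ``hmmsearch -T``/``--cut_nc``
    convention); the E-value fallback passes under ``<=``.
    """
    if hit.profile_id != spec.profile_id:
        raise ConfigError(f"hit profile {hit.profile_id} does not match spec {spec.profile_id}")
    if spec.cutoff_score is None:
        return hit.full_evalue <= fallback_evalue
    score = hit.full_score if spec.score_type == "full" else hit.best_domain_score
    return score >= spec.cutoff_score


def _collapse_domains(hits: Sequence[HmmHit]) -> list[HmmHit]:
    """Per (genome, protein, profile), keep the single best domain row.

    Best = max best_domain_score; ties broken by smaller i_evalue, then
    smaller ali_from.
    """
    best: dict[tuple[str, str, str], HmmHit] = {}
    for h in hits:
        key = (h.genome_id, h.protein_id, h.profile_id)
        cur = best.get(key)
        if cur is None:
            best[key] = h
            continue
        a = (-h.best_domain_score, h.i_evalue, h.ali_from)
        b = (-cur.best_domain_score, cur.i_evalue, cur.ali_from)
        if a < b:
            best[key] = h
    return list(best.values())


def _compute_winning(table: pd.DataFrame, specs: Mapping[str, HmmProfileSpec],
                     priority: Sequence[str]) -> pd.Series:
    """Recompute the ``winning`` flag with database-priority conflict resolution.

    A row is eligible when it passed the threshold and was not rejected by a
    motif rule.  Among eligible profiles on one protein that map to the same
    function, only those from the highest-priority database win; a profile
    wins if it wins for at least one of its functions.
    """
    rank = {db: i for i, db in enumerate(priority)}
    eligible = table["passed_threshold"] & (table["passed_motif"] != False)  # noqa: E712
    winning = pd.Series(False, index=table.index)
    for (_, _), idx in table.groupby(["genome_id", "protein_id"]).groups.items():
        idx = [i for i in idx if eligible.loc[i]]
        if not idx:
            continue
        # best database rank per function across this protein's eligible rows
        best_rank: dict[str, int] = {}
        for i in idx:
            spec = specs[table.at[i, "profile_id"]]
            r = rank.get(spec.database, len(rank))
            for f in spec.function_ids:
                if r < best_rank.get(f, len(rank) + 1):
                    best_rank[f] = r
        for i in idx:
            spec = specs[table.at[i, "profile_id"]]
            r = rank.get(spec.database, len(rank))
            funcs = spec.function_ids
            if not funcs or any(best_rank[f] == r for f in funcs):
                winning.loc[i] = True
    return winning


def select_hits(
    hits: Sequence[HmmHit],
    specs: Mapping[str, HmmProfileSpec],
    fallback_evalue: float = DEFAULT_FALLBACK_EVALUE,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Collapse domain rows and build the validated annotation table.

    Returns a DataFrame with :data:`ANNOTATION_COLUMNS`; ``passed_motif`` is
    ``pd.NA`` everywhere (motif validation is a later stage) and ``winning``
    reflects threshold passing plus database-priority resolution.
    """
    unknown = sorted({h.profile_id for h in hits} - set(specs))
    if unknown:
        raise ConfigError(f"hits reference unknown profile ids: {', '.join(unknown)}")
    rows = []
    for h in _collapse_domains(hits):
        spec = specs[h.profile_id]
        rows.append(
            {
                "genome_id": h.genome_id,
                "protein_id": h.protein_id,
                "profile_id": h.profile_id,
                "full_score": h.full_score,
                "best_domain_score": h.best_domain_score,
                "full_evalue": h.full_evalue,
                "i_evalue": h.i_evalue,
                "passed_threshold": apply_threshold(h, spec, fallback_evalue),
                "passed_motif": pd.NA,
                "winning": False,
            }
        )
    table = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    if not table.empty:
        table = table.sort_values(["genome_id", "protein_id", "profile_id"]).reset_index(drop=True)
        table["winning"] = _compute_winning(table, specs, priority)
    return table


def _run_hmmsearch(proteome: Path, hmm_db: Path, threads: int) -> list[str]:
    exe = shutil.which("hmmsearch")
    if exe is None:
        raise ConfigError(
            "hmmsearch not found on PATH and no pre-computed domtblout supplied; "
            "install HMMER or pass a domtblout file"
        )
    with tempfile.NamedTemporaryFile(suffix=".domtblout", mode="r", delete=False) as tmp:
        out = tmp.name
    subprocess.run(
        [exe, "--cpu", str(threads), "--domtblout", out, str(hmm_db), str(proteome)],
        check=True,
        capture_output=True,
    )
    lines = Path(out).read_text().splitlines()
    Path(out).unlink()
    return lines


def annotate_proteome(
    proteome: str | Path,
    specs: Mapping[str, HmmProfileSpec],
    domtblout: str | Path | None = None,
    hmm_db: str | Path | None = None,
    motif_rules: Mapping[str, object] | None = None,
    genome_id: str | None = None,
    fallback_evalue: float = DEFAULT_FALLBACK_EVALUE,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    threads: int = 1,
) -> pd.DataFrame:
    """Annotate one proteome: hmmsearch (or pre-computed domtblout) -> thresholds -> motifs.

    ``proteome`` is a protein FASTA; ``domtblout`` a pre-computed hmmsearch
    table for it (preferred, fully offline), otherwise ``hmm_db`` is searched
    with HMMER.  Deterministic given fixed inputs.
    """
    from Bio import SeqIO

    from .motifs import validate_hits

    proteome = Path(proteome)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(proteome), "fasta")}
    if not seqs:
        raise ConfigError(f"empty proteome: {proteome}")
    gid = genome_id if genome_id is not None else proteome.stem
    if domtblout is not None:
        lines = Path(domtblout).read_text().splitlines()
    elif hmm_db is not None:
        lines = _run_hmmsearch(proteome, Path(hmm_db), threads)
    else:
        raise ConfigError("need either a pre-computed domtblout or an HMM database path")
    hits = parse_domtblout(lines, genome_id=gid)
    table = select_hits(hits, specs, fallback_evalue=fallback_evalue, priority=priority)
    if motif_rules:
        table = validate_hits(table, seqs, motif_rules, specs, priority=priority)
    return table
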