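"""Carbohydrate-active enzyme (CAZyme) and peptidase annotation.

CAZymes are annotated by searching proteomes against a dbCAN-style CAZy
family HMM database and filtering the domain table with the stock
hmmscan-parser conventions (coverage of the family HMM, alignment-length
dependent E-value).  Peptidases and their inhibitors are annotated by
filtering tabular protein alignments against a MEROPS-pepunit-style database
with the thresholds ``-k 1 -e 1e-10 --query-cover 80 --id 50``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError
from .hmm import parse_domtblout

_CAZY_FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)\d+(_\d+)?$")

#: Column order of the consumed tabular alignment (DIAMOND/BLAST outfmt 6
#: plus qcovhsp).
ALIGNMENT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qcovhsp",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One query-subject alignment with its per-query rank by bit score."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    query_coverage: float
    bit_score: float
    rank: int = 1


@dataclass(frozen=True)
class CazyCall:
    """One protein assigned to a CAZy family."""

    protein_id: str
    family_id: str
    evalue: float
    covered_fraction: float


def read_alignment_table(stream: Iterable[str]) -> list[AlignmentRecord]:
    """Read a 13-column tabular alignment and assign per-query ranks.

    Ranks order alignments of one query by descending bit score; ties broken
    by smaller E-value, then lexicographic subject id.
    """
    rows = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 13:
            raise ParseError(f"line {lineno}: expected 13 tab-separated fields, got {len(f)}")
        try:
            rows.append(dict(
                query_id=f[0], subject_id=f[1], percent_identity=float(f[2]),
                evalue=float(f[10]), bit_score=float(f[11]), query_coverage=float(f[12]),
            ))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return rank_alignments(rows)


def rank_alignments(rows: Sequence[dict]) -> list[AlignmentRecord]:
    """Turn raw alignment dicts into ranked :class:`AlignmentRecord` lists."""
    records: list[AlignmentRecord] = []
    df = pd.DataFrame(rows)
    if df.empty:
        return records
    for _, grp in df.groupby("query_id", sort=False):
        grp = grp.sort_values(
            ["bit_score", "evalue", "subject_id"], ascending=[False, True, True]
        )
        for rank, (_, r) in enumerate(grp.iterrows(), start=1):
            records.append(AlignmentRecord(
                query_id=r["query_id"], subject_id=r["subject_id"],
                percent_identity=r["percent_identity"], evalue=r["evalue"],
                query_coverage=r["query_coverage"], bit_score=r["bit_score"],
                rank=rank,
            ))
    return records


def filter_peptidase_hits(
    records: Sequence[AlignmentRecord],
    max_evalue: float = 1e-10,
    min_qcov: float = 80.0,
    min_id: float = 50.0,
    keep_k: int = 1,
) -> list[AlignmentRecord]:
    """Keep alignments passing the MEROPS search thresholds.

    Defaults mirror the search settings ``-k 1 -e 1e-10 --query-cover 80
    --id 50``; boundaries pass (>= for identity/coverage, <= for E-value).
    """
    return [
        r for r in records
        if r.evalue <= max_evalue
        and r.query_coverage >= min_qcov
        and r.percent_identity >= min_id
        and r.rank <= keep_k
    ]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def parse_dbcan_hits(
    stream: Iterable[str],
    evalue_long: float = 1e-5,
    evalue_short: float = 1e-3,
    long_aln: int = 80,
    min_cov: float = 0.3,
) -> list[CazyCall]:
    """Parse a CAZy-family hmmsearch domtblout into filtered family calls.

    Per (protein, family), overlapping domain alignments on the HMM are
    merged; the call is kept when the merged fraction of the family HMM
    covered is >= ``min_cov`` and the best domain E-value passes the
    alignment-length dependent threshold (``evalue_long`` for merged
    alignments longer than ``long_aln`` residues, else ``evalue_short``).
    These are the stock dbCAN hmmscan-parser defaults, fully configurable.
    The family id is the HMM name with any ``.hmm`` suffix stripped.
    """
    hits = parse_domtblout(stream)
    by_pair: dict[tuple[str, str], list] = {}
    for h in hits:
        family = h.profile_id.removesuffix(".hmm")
        by_pair.setdefault((h.protein_id, family), []).append(h)
    calls: list[CazyCall] = []
    for (protein, family), rows in sorted(by_pair.items()):
        hmm_len = rows[0].qlen
        merged = _merge_intervals([(h.hmm_from, h.hmm_to) for h in rows])
        aln_len = sum(hi - lo + 1 for lo, hi in merged)
        covered = aln_len / hmm_len
        evalue = min(h.i_evalue for h in rows)
        threshold = evalue_long if aln_len > long_aln else evalue_short
        if covered >= min_cov and evalue <= threshold:
            calls.append(CazyCall(protein_id=protein, family_id=family,
                                  evalue=evalue, covered_fraction=covered))
    return calls


def is_cazy_family(family_id: str) -> bool:
    """Does the id look like a CAZy family (GH/GT/PL/CE/AA/CBM + digits)?"""
    return _CAZY_FAMILY_RE.match(family_id) is not None
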