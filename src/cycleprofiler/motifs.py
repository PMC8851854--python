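"""Conserved-residue motif validation of annotation hits.

Some protein families are so similar in sequence that profile scores alone
cannot separate them even though their functions diverge — the classic case
is DsrC (dissimilatory sulfite reductase subunit C) versus TusE (a tRNA
thiouridine synthase component), both hit by KO family K11179.  DsrC carries
a diagnostic conserved-residue window, ``GPXKXXCXXXGXPXPXXCX`` (X = any
amino acid), that TusE lacks.  Hits on profiles carrying a motif rule are
kept only if the protein contains the required motif (and, when a forbidden
motif is configured for the confounding family, does not contain it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError

#: Residues treated as matching a wildcard position only: ambiguity/rare codes
#: fail any specific (non-X) motif position.
AMBIGUOUS = frozenset("BZJUO")

#: Diagnostic DsrC motif distinguishing it from TusE.
DSRC_MOTIF = "GPXKXXCXXXGXPXPXXCX"


@dataclass(frozen=True)
class MotifRule:
    """A required (and optionally forbidden) conserved-residue motif."""

    rule_id: str
    required_motif: str
    forbidden_motif: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.required_motif:
            raise ConfigError(f"rule {self.rule_id}: empty required motif")
        if self.forbidden_motif == "":
            object.__setattr__(self, "forbidden_motif", None)


def motif_matches(sequence: str, motif: str) -> bool:
    """Unanchored position-wise motif search; ``X`` matches any residue.

    A specific (non-X) motif position matches only the identical one-letter
    code; ambiguous residues (B, Z, J, U, O) in the sequence therefore fail
    every specific position.
    """
    if not motif:
        raise ConfigError("empty motif")
    m = len(motif)
    n = len(sequence)
    for start in range(n - m + 1):
        ok = True
        for j in range(m):
            p = motif[j]
            if p == "X":
                continue
            if sequence[start + j] != p:
                ok = False
                break
        if ok:
            return True
    return False


def validate_hits(
    table: pd.DataFrame,
    sequences: Mapping[str, str],
    rules: Mapping[str, MotifRule],
    specs: Mapping[str, object],
    priority: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Apply motif rules to an annotation table and recompute winners.

    Rows whose profile carries a ``motif_rule_id`` get
    ``passed_motif = required matches AND NOT forbidden matches``; rows
    without a rule keep ``passed_motif = NA`` (not applicable).  The
    operation is idempotent.
    """
    from .hmm import DEFAULT_PRIORITY, _compute_winning

    if priority is None:
        priority = DEFAULT_PRIORITY
    table = table.copy()
    for i in table.index:
        spec = specs[table.at[i, "profile_id"]]
        rule_id = getattr(spec, "motif_rule_id", None)
        if rule_id is None or rule_id == "":
            table.at[i, "passed_motif"] = pd.NA
            continue
        if rule_id not in rules:
            raise ConfigError(f"motif rule {rule_id!r} not found for profile {spec.profile_id}")
        rule = rules[rule_id]
        pid = table.at[i, "protein_id"]
        if pid not in sequences:
            raise ConfigError(f"protein sequence missing for motif-ruled hit: {pid}")
        seq = sequences[pid]
        passed = motif_matches(seq, rule.required_motif)
        if passed and rule.forbidden_motif is not None:
            passed = not motif_matches(seq, rule.forbidden_motif)
        table.at[i, "passed_motif"] = passed
    if not table.empty:
        table["winning"] = _compute_winning(table, specs, priority)
    return table
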