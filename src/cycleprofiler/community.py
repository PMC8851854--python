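"""Community-scale metrics: taxon grouping, MW-scores, contributions, networks.

The community layer treats the input genome set as a microbial community:
each genome g carries an abundance C_g (metagenomic coverage, or RPKM-based
expression in metatranscriptome mode) and a binary functional repertoire
S(g, f) over the template's functions.  From these it computes:

* **MW-score** (metabolic weight score) of a function f:

      MW(f) = sum_g C_g * S(g, f)  /  sum_{g, f'} C_g * S(g, f')

  the coverage-weighted fraction of the community's total functional
  capacity attributed to f; MW-scores sum to 1 over functions.

* **Contribution percentage** of a taxon group p to function f:

      Cperc(f, p) = 100 * sum_{g in p} C_g * S(g, f) / sum_g C_g * S(g, f)

  the group's coverage-weighted share of f's MW-score; sums to 100% over
  groups for every function with nonzero MW-score.

Genomes are grouped at the phylum level by default, except Proteobacteria,
which is replaced by its subordinate classes because of its breadth; any
GTDB rank down to genus may be used instead.

The module also derives per-group functional co-occurrence networks (an
edge between two cycling steps whenever a group member encodes both),
Sankey flows (taxon group -> function -> elemental cycle, weighted by
genome coverage), and sequential-transformation profiles (genome counts and
community-coverage percentages along an ordered chain of steps, e.g. the
denitrification series).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigError

GTDB_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


def parse_gtdb_lineage(lineage: str) -> dict[str, str]:
    """Split a GTDB lineage string into rank -> name (empty when unnamed)."""
    parts = [p.strip() for p in lineage.strip().split(";") if p.strip()]
    if not parts or not parts[0].startswith("d__"):
        raise ConfigError(f"unparseable GTDB lineage: {lineage!r}")
    names: dict[str, str] = {r: "" for r in GTDB_RANKS}
    for part in parts:
        for rank, prefix in zip(GTDB_RANKS, _PREFIXES):
            if part.startswith(prefix):
                names[rank] = part[len(prefix):]
                break
        else:
            raise ConfigError(f"unparseable lineage component {part!r} in {lineage!r}")
    return names


def assign_taxon_group(gtdb_lineage: str, rank: str = "phylum") -> str:
    """Taxon group of a genome at ``rank``, with the Proteobacteria substitution.

    At rank phylum, genomes classified as Proteobacteria are grouped by
    their class instead.  An unnamed rank yields
    ``Unclassified_<deepest named rank>``.
    """
    if rank not in ("phylum", "class", "order", "family", "genus"):
        raise ConfigError(f"unsupported grouping rank {rank!r}")
    names = parse_gtdb_lineage(gtdb_lineage)
    name = names[rank]
    if rank == "phylum" and name == "Proteobacteria":
        name = names["class"]
        if not name:
            return "Unclassified_Proteobacteria"
        return name
    if not name:
        deepest = ""
        for r in GTDB_RANKS[: GTDB_RANKS.index(rank)]:
            if names[r]:
                deepest = names[r]
        return f"Unclassified_{deepest}" if deepest else "Unclassified"
    return name


@dataclass
class CommunityProfile:
    """Genome x function presence matrix S joined with coverages and groups.

    ``presence`` is a binary DataFrame (genomes x functions); ``coverage``
    a Series of C_g indexed by genome; ``groups`` a Series mapping genome to
    taxon group.
    """

    presence: pd.DataFrame
    coverage: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        genomes = list(self.presence.index)
        missing_cov = set(genomes) - set(self.coverage.index)
        if missing_cov:
            raise ConfigError(f"genomes without coverage: {sorted(missing_cov)}")
        missing_grp = set(genomes) - set(self.groups.index)
        if missing_grp:
            raise ConfigError(f"genomes without taxon group: {sorted(missing_grp)}")
        vals = set(self.presence.to_numpy().ravel().tolist())
        if not vals <= {0, 1}:
            raise ConfigError("presence matrix must be binary (0/1)")
        self.coverage = self.coverage.loc[genomes].astype(float)
        self.groups = self.groups.loc[genomes]

    @property
    def genomes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def functions(self) -> list[str]:
        return list(self.presence.columns)


def mw_scores(profile: CommunityProfile) -> pd.Series:
    """MW-score per function: coverage-weighted presence over the community total."""
    weighted = profile.presence.mul(profile.coverage, axis=0)
    per_function = weighted.sum(axis=0)
    total = per_function.sum()
    if total <= 0:
        raise ConfigError("no function present or zero coverage: MW-scores undefined")
    return per_function / total


def contribution_percentages(profile: CommunityProfile) -> pd.DataFrame:
    """Contribution percentage of each taxon group to each function's MW-score.

    Returns functions x groups (%); functions whose MW-score is zero are
    reported as all-NA rows (undefined share of nothing).  Values are
    unrounded; per-function rows sum to exactly 100 for present functions.
    """
    weighted = profile.presence.mul(profile.coverage, axis=0)
    by_group = weighted.groupby(profile.groups, observed=True).sum()  # groups x functions
    totals = weighted.sum(axis=0)
    out = pd.DataFrame(index=profile.functions, columns=by_group.index, dtype=float)
    for f in profile.functions:
        if totals[f] > 0:
            out.loc[f] = 100.0 * by_group[f] / totals[f]
    return out


@dataclass(frozen=True)
class NetworkEdge:
    """Co-occurrence of two cycling steps within one taxon group."""

    step_a: str
    step_b: str
    group_id: str
    weight: float
    n_genomes: int


def build_functional_network(
    step_presence: pd.DataFrame,
    groups: pd.Series,
    step_coverage: pd.DataFrame,
) -> tuple[list[NetworkEdge], nx.MultiGraph]:
    """Per-group step co-occurrence network.

    ``step_presence``: binary genomes x steps; ``step_coverage``: genomes x
    steps gene-coverage sums.  One edge per (group, unordered step pair)
    with at least one member genome encoding both steps; its weight is the
    mean of the two steps' group-summed gene coverages, its ``n_genomes``
    the number of member genomes with both steps.  Node degree (number of
    connections) is attached as the node size attribute.
    """
    edges: list[NetworkEdge] = []
    steps = list(step_presence.columns)
    for group, members in step_presence.groupby(groups, observed=True).groups.items():
        sub = step_presence.loc[list(members)]
        cov = step_coverage.loc[list(members)].sum(axis=0)
        for a, b in itertools.combinations(steps, 2):
            both = int(((sub[a] == 1) & (sub[b] == 1)).sum())
            if both >= 1:
                edges.append(NetworkEdge(
                    step_a=a, step_b=b, group_id=str(group),
                    weight=float((cov[a] + cov[b]) / 2.0), n_genomes=both,
                ))
    graph = nx.MultiGraph()
    for e in edges:
        graph.add_edge(e.step_a, e.step_b, group=e.group_id,
                       weight=e.weight, n_genomes=e.n_genomes)
    degrees = dict(graph.degree())
    nx.set_node_attributes(graph, degrees, "degree")
    nx.set_node_attributes(graph, degrees, "size")
    return edges, graph


@dataclass(frozen=True)
class SankeyFlow:
    source: str
    target: str
    weight: float


def sankey_flows(
    profile: CommunityProfile,
    cycle_map: Mapping[str, str],
) -> tuple[list[SankeyFlow], pd.Series]:
    """Taxon group -> function -> cycle flows weighted by genome coverage.

    Each group->function flow accumulates the coverage of the group's
    genomes possessing the function; each function->cycle flow is the sum
    of its incoming group flows (conservation holds by construction).  Also
    returns the group genome counts used to scale the taxon column.
    """
    present_functions = [f for f in profile.functions if profile.presence[f].sum() > 0]
    unmapped = sorted(f for f in present_functions if f not in cycle_map)
    if unmapped:
        raise ConfigError(f"functions not mapped to a cycle: {', '.join(unmapped)}")
    flows: list[SankeyFlow] = []
    fn_totals: dict[str, float] = {}
    weighted = profile.presence.mul(profile.coverage, axis=0)
    by_group = weighted.groupby(profile.groups, observed=True).sum()
    for f in present_functions:
        for group in by_group.index:
            w = float(by_group.at[group, f])
            if w > 0:
                flows.append(SankeyFlow(source=str(group), target=f, weight=w))
                fn_totals[f] = fn_totals.get(f, 0.0) + w
    for f in present_functions:
        if f in fn_totals:
            flows.append(SankeyFlow(source=f, target=cycle_map[f], weight=fn_totals[f]))
    group_sizes = profile.groups.value_counts()
    return flows, group_sizes


@dataclass(frozen=True)
class SequentialChain:
    """Genome counts and coverage percentages along an ordered step chain."""

    chain_id: str
    steps: tuple[str, ...]
    letters: tuple[str, ...]
    n_genomes: tuple[int, ...]
    abundance_pct: tuple[float, ...]
    pair_genomes: tuple[int, ...]  # genomes possessing both steps of each consecutive pair


def sequential_profile(
    chain_id: str,
    chain_steps: Sequence[str],
    step_presence: pd.DataFrame,
    coverage: pd.Series,
    letters: Sequence[str] | None = None,
) -> SequentialChain:
    """Profile an ordered transformation chain (e.g. NO3- -> NO2- -> ... -> N2).

    Per step: the number of genomes encoding it and the summed coverage of
    those genomes as a percentage of total community coverage; per
    consecutive step pair: the number of genomes encoding both (potential
    single-organism hand-off of the intermediate).
    """
    unknown = [s for s in chain_steps if s not in step_presence.columns]
    if unknown:
        raise ConfigError(f"unknown step ids in chain {chain_id}: {', '.join(unknown)}")
    if letters is None:
        letters = tuple(chr(ord("A") + i) for i in range(len(chain_steps)))
    if len(set(letters)) != len(letters):
        raise ConfigError(f"chain {chain_id}: duplicate step letters")
    total_cov = float(coverage.loc[step_presence.index].sum())
    n_genomes, abundances = [], []
    for s in chain_steps:
        members = step_presence.index[step_presence[s] == 1]
        n_genomes.append(int(len(members)))
        abund = 100.0 * float(coverage.loc[members].sum()) / total_cov if total_cov > 0 else 0.0
        abundances.append(abund)
    pairs = []
    for a, b in zip(chain_steps[:-1], chain_steps[1:]):
        pairs.append(int(((step_presence[a] == 1) & (step_presence[b] == 1)).sum()))
    return SequentialChain(
        chain_id=chain_id, steps=tuple(chain_steps), letters=tuple(letters),
        n_genomes=tuple(n_genomes), abundance_pct=tuple(abundances),
        pair_genomes=tuple(pairs),
    )
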