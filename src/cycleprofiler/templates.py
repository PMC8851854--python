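"""Template loading and validation.

The default template ships with the package: 31 biogeochemical cycling
steps (carbon, nitrogen, sulfur and "other" element transformations, ids
following the ``<element>-S-<NN>`` convention) subdivided into 51
finer-grained functions, each linked to the profile-HMMs whose winning hits
evidence it, plus sequential-transformation chain skeletons, motif rules
and the profile-spec table.  Step and function names follow the standard
cycling nomenclature (e.g. "C-S-07 Methanogenesis", "N-S-09 Anammox"); the
profile assignments are a compact default set and are fully replaceable by
user-supplied template TSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigError
from .hmm import HmmProfileSpec
from .kegg import ModuleDefinition, parse_definition
from .motifs import MotifRule

DEFAULT_N_STEPS = 31
DEFAULT_N_FUNCTIONS = 51


@dataclass(frozen=True)
class CycleStep:
    step_id: str
    name: str
    cycle: str
    profile_ids: frozenset[str]


@dataclass(frozen=True)
class FunctionDef:
    function_id: str
    name: str
    category: str
    step_id: str
    profile_ids: frozenset[str]


@dataclass
class CycleTemplate:
    """Validated step/function/chain template joined to profile specs."""

    steps: list[CycleStep]
    functions: list[FunctionDef]
    chains: dict[str, list[tuple[str, str]]]  # chain_id -> [(letter, step_id)]
    profile_specs: dict[str, HmmProfileSpec]
    motif_rules: dict[str, MotifRule] = field(default_factory=dict)
    modules: dict[str, ModuleDefinition] = field(default_factory=dict)

    @property
    def step_map(self) -> dict[str, frozenset[str]]:
        return {s.step_id: s.profile_ids for s in self.steps}

    @property
    def function_map(self) -> dict[str, frozenset[str]]:
        return {f.function_id: f.profile_ids for f in self.functions}

    @property
    def cycle_map(self) -> dict[str, str]:
        """function_id -> elemental cycle / category."""
        return {f.function_id: f.category for f in self.functions}

    @property
    def steps_of_function(self) -> dict[str, str]:
        return {f.function_id: f.step_id for f in self.functions}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("cycleprofiler").joinpath("data", name)))


def read_profile_specs(path: str | Path) -> dict[str, HmmProfileSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    specs: dict[str, HmmProfileSpec] = {}
    for r in df.itertuples():
        if r.profile_id in specs:
            raise ConfigError(f"duplicate profile id {r.profile_id!r} in {path}")
        specs[r.profile_id] = HmmProfileSpec(
            profile_id=r.profile_id,
            database=r.database,
            cutoff_score=float(r.cutoff_score) if r.cutoff_score else None,
            score_type=r.score_type or "full",
            cutoff_kind=r.cutoff_kind or "suggested",
            function_ids=frozenset(x for x in r.function_ids.split(";") if x),
            motif_rule_id=r.motif_rule_id or None,
        )
    return specs


def read_motif_rules(path: str | Path) -> dict[str, MotifRule]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    rules: dict[str, MotifRule] = {}
    for r in df.itertuples():
        if r.rule_id in rules:
            raise ConfigError(f"duplicate motif rule {r.rule_id!r}")
        rules[r.rule_id] = MotifRule(
            rule_id=r.rule_id,
            required_motif=r.required_motif,
            forbidden_motif=r.forbidden_motif or None,
            description=getattr(r, "description", ""),
        )
    return rules


def read_modules(path: str | Path) -> dict[str, ModuleDefinition]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {
        r.module_id: parse_definition(r.definition, module_id=r.module_id, name=r.name)
        for r in df.itertuples()
    }


def load_templates(
    steps_path: str | Path | None = None,
    functions_path: str | Path | None = None,
    chains_path: str | Path | None = None,
    profile_specs_path: str | Path | None = None,
    motif_rules_path: str | Path | None = None,
    modules_path: str | Path | None = None,
) -> CycleTemplate:
    """Load and cross-validate the template set; ``None`` paths use defaults.

    The shipped default template must contain exactly 31 steps and 51
    functions; the size check is waived when a user supplies their own step
    or function tables.
    """
    is_default = steps_path is None and functions_path is None
    steps_path = steps_path or _data_path("cycle_steps.tsv")
    functions_path = functions_path or _data_path("functions.tsv")
    chains_path = chains_path or _data_path("chains.tsv")
    profile_specs_path = profile_specs_path or _data_path("profile_specs.tsv")
    motif_rules_path = motif_rules_path or _data_path("motif_rules.tsv")
    modules_path = modules_path or _data_path("modules.tsv")

    specs = read_profile_specs(profile_specs_path)
    rules = read_motif_rules(motif_rules_path)
    modules = read_modules(modules_path)

    sdf = pd.read_csv(steps_path, sep="\t", dtype=str).fillna("")
    steps = [
        CycleStep(r.step_id, r.name, r.cycle,
                  frozenset(x for x in r.profile_ids.split(";") if x))
        for r in sdf.itertuples()
    ]
    fdf = pd.read_csv(functions_path, sep="\t", dtype=str).fillna("")
    functions = [
        FunctionDef(r.function_id, r.name, r.category, r.step_id,
                    frozenset(x for x in r.profile_ids.split(";") if x))
        for r in fdf.itertuples()
    ]
    cdf = pd.read_csv(chains_path, sep="\t", dtype=str).fillna("")
    chains: dict[str, list[tuple[str, str]]] = {}
    for r in cdf.itertuples():
        chains.setdefault(r.chain_id, []).append((r.letter, r.step_id))

    # referential integrity
    step_ids = [s.step_id for s in steps]
    if len(set(step_ids)) != len(step_ids):
        dups = sorted({s for s in step_ids if step_ids.count(s) > 1})
        raise ConfigError(f"duplicate step ids: {', '.join(dups)}")
    fn_ids = [f.function_id for f in functions]
    if len(set(fn_ids)) != len(fn_ids):
        dups = sorted({f for f in fn_ids if fn_ids.count(f) > 1})
        raise ConfigError(f"duplicate function ids: {', '.join(dups)}")
    dangling = sorted(
        {p for s in steps for p in s.profile_ids if p not in specs}
        | {p for f in functions for p in f.profile_ids if p not in specs}
    )
    if dangling:
        raise ConfigError(f"template references profiles absent from the spec table: "
                          f"{', '.join(dangling)}")
    known_steps = set(step_ids)
    bad_fn_steps = sorted({f.step_id for f in functions if f.step_id not in known_steps})
    if bad_fn_steps:
        raise ConfigError(f"functions reference unknown steps: {', '.join(bad_fn_steps)}")
    bad_chain = sorted({sid for ch in chains.values() for _, sid in ch
                        if sid not in known_steps})
    if bad_chain:
        raise ConfigError(f"chains reference unknown steps: {', '.join(bad_chain)}")
    rule_ids = {spec.motif_rule_id for spec in specs.values() if spec.motif_rule_id}
    missing_rules = sorted(rule_ids - set(rules))
    if missing_rules:
        raise ConfigError(f"profile specs reference unknown motif rules: "
                          f"{', '.join(missing_rules)}")

    if is_default and (len(steps) != DEFAULT_N_STEPS or len(functions) != DEFAULT_N_FUNCTIONS):
        raise ConfigError(
            f"default template must have {DEFAULT_N_STEPS} steps and "
            f"{DEFAULT_N_FUNCTIONS} functions, found {len(steps)}/{len(functions)}"
        )
    return CycleTemplate(steps=steps, functions=functions, chains=chains,
                         profile_specs=specs, motif_rules=rules, modules=modules)
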