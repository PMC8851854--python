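"""Domtblout parsing, score thresholding and database-priority hit selection."""

import numpy as np
import pandas as pd
import pytest

from cycleprofiler import (
    ConfigError,
    HmmHit,
    HmmProfileSpec,
    ParseError,
    apply_threshold,
    parse_domtblout,
    select_hits,
)
from cycleprofiler.fixtures import DOMTBLOUT_HEADER, format_domtblout_row


def make_hit(protein="p1", genome="g1", profile="K00001", full=120.0, dom=118.0,
             fe=1e-20, ie=1e-18, afrom=5, ato=190, tlen=200, qlen=180):
    return HmmHit(protein_id=protein, genome_id=genome, profile_id=profile,
                  full_score=full, best_domain_score=dom, full_evalue=fe,
                  i_evalue=ie, ali_from=afrom, ali_to=ato, qlen=qlen, tlen=tlen)


def spec_of(profile="K00001", db="kofam", cutoff=100.0, stype="full",
            functions=("f1",), motif=None):
    return HmmProfileSpec(
        profile_id=profile, database=db, cutoff_score=cutoff, score_type=stype,
        cutoff_kind="suggested" if cutoff is not None else "evalue_fallback",
        function_ids=frozenset(functions), motif_rule_id=motif,
    )


class TestParseDomtblout:
    def test_comment_only_stream_is_empty(self):
        assert parse_domtblout(["# a comment", "#", ""]) == []

    def test_field_transcription(self):
        row = format_domtblout_row("p1", "K00001", tlen=200, qlen=180,
                                   full_evalue=1e-20, full_score=120.5,
                                   i_evalue=1e-18, dom_score=118.2,
                                   hmm_from=1, hmm_to=170, ali_from=5, ali_to=190)
        (hit,) = parse_domtblout([row], genome_id="g1")
        assert hit.protein_id == "p1" and hit.profile_id == "K00001"
        assert hit.full_score == 120.5 and hit.best_domain_score == 118.2
        assert (hit.ali_from, hit.ali_to) == (5, 190)
        assert (hit.tlen, hit.qlen) == (200, 180)
        assert hit.genome_id == "g1"

    def test_domain_rows_not_merged_at_parse_time(self):
        rows = [format_domtblout_row("p1", "K00001", 200, 180, 1e-20, 120.0,
                                     1e-10, s, 1, 50, 1, 60, dom_num=i, dom_of=3)
                for i, s in enumerate([40.0, 90.0, 70.0], start=1)]
        assert len(parse_domtblout(rows)) == 3

    @pytest.mark.parametrize("bad", ["p1 - x K00001", "too few fields"])
    def test_malformed_row_names_line(self, bad):
        good = format_domtblout_row("p1", "K00001", 200, 180, 1e-20, 120.0,
                                    1e-18, 118.0, 1, 170, 5, 190)
        with pytest.raises(ParseError, match="line 2"):
            parse_domtblout([good, bad])

    def test_non_numeric_score_is_parse_error(self):
        row = format_domtblout_row("p1", "K00001", 200, 180, 1e-20, 120.0,
                                   1e-18, 118.0, 1, 170, 5, 190).split()
        row[7] = "abc"
        with pytest.raises(ParseError, match="line 1"):
            parse_domtblout([" ".join(row)])


class TestApplyThreshold:
    def test_score_equal_to_cutoff_passes(self):
        assert apply_threshold(make_hit(full=100.0), spec_of(cutoff=100.0))

    def test_domain_score_type_ignores_full_score(self):
        hit = make_hit(full=200.0, dom=50.0)
        assert not apply_threshold(hit, spec_of(cutoff=100.0, stype="domain"))

    def test_evalue_fallback(self):
        spec = spec_of(cutoff=None)
        assert apply_threshold(make_hit(fe=1e-6), spec, fallback_evalue=1e-5)
        assert not apply_threshold(make_hit(fe=1e-4), spec, fallback_evalue=1e-5)

    def test_profile_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            apply_threshold(make_hit(profile="K99999"), spec_of())


class TestSelectHits:
    def test_empty_hit_list(self):
        assert select_hits([], {}).empty

    def test_custom_beats_kofam_on_shared_function(self):
        specs = {
            "K00001": spec_of("K00001", "kofam", 50.0, functions=("hyd",)),
            "HydA": spec_of("HydA", "custom", 50.0, functions=("hyd",)),
        }
        hits = [make_hit(profile="K00001", full=80.0, dom=80.0),
                make_hit(profile="HydA", full=90.0, dom=90.0)]
        table = select_hits(hits, specs).set_index("profile_id")
        assert bool(table.at["HydA", "winning"])
        assert not bool(table.at["K00001", "winning"])
        assert bool(table.at["K00001", "passed_threshold"])

    def test_domain_collapse_keeps_max_domain_score(self):
        hits = [make_hit(dom=s, full=120.0) for s in (40.0, 90.0, 70.0)]
        table = select_hits(hits, {"K00001": spec_of()})
        assert len(table) == 1
        assert table["best_domain_score"].iloc[0] == 90.0

    def test_unknown_profile_listed_in_error(self):
        with pytest.raises(ConfigError, match="K77777"):
            select_hits([make_hit(profile="K77777")], {"K00001": spec_of()})

    def test_non_conflicting_profiles_both_win(self):
        specs = {
            "K00001": spec_of("K00001", "kofam", 50.0, functions=("fa",)),
            "K00002": spec_of("K00002", "kofam", 50.0, functions=("fb",)),
        }
        hits = [make_hit(profile="K00001", full=80.0),
                make_hit(profile="K00002", full=80.0)]
        table = select_hits(hits, specs)
        assert table["winning"].all()


def naive_select(hits, specs, fallback=1e-5):
    """Independent one-pass oracle: group, collapse, compare per row."""
    groups = {}
    for h in hits:
        groups.setdefault((h.genome_id, h.protein_id, h.profile_id), []).append(h)
    rows = {}
    for key, hs in groups.items():
        best = sorted(hs, key=lambda h: (-h.best_domain_score, h.i_evalue, h.ali_from))[0]
        spec = specs[key[2]]
        if spec.cutoff_score is None:
            passed = best.full_evalue <= fallback
        elif spec.score_type == "full":
            passed = best.full_score >= spec.cutoff_score
        else:
            passed = best.best_domain_score >= spec.cutoff_score
        rows[key] = (best, passed)
    return rows


class TestSelectHitsProperties:
    def make_random_hits(self, rng, n, profiles):
        hits = []
        for _ in range(n):
            p = rng.choice(profiles)
            s = float(rng.uniform(10, 200))
            hits.append(make_hit(
                protein=f"p{int(rng.integers(0, 30))}",
                genome=f"g{int(rng.integers(0, 3))}",
                profile=p, full=s, dom=s * float(rng.uniform(0.5, 1.0)),
                fe=float(10.0 ** -rng.uniform(1, 30)),
                ie=float(10.0 ** -rng.uniform(1, 30)),
                afrom=int(rng.integers(1, 50)),
            ))
        return hits

    def test_matches_naive_filter_oracle(self, rng):
        specs = {
            "K00001": spec_of("K00001", "kofam", 100.0, functions=("f1",)),
            "K00002": spec_of("K00002", "kofam", 80.0, "domain", functions=("f2",)),
            "CustomA": spec_of("CustomA", "custom", 90.0, functions=("f1",)),
            "PF00001": spec_of("PF00001", "pfam", None, functions=("f3",)),
        }
        for _ in range(25):
            hits = self.make_random_hits(rng, int(rng.integers(1, 300)), list(specs))
            table = select_hits(hits, specs)
            oracle = naive_select(hits, specs)
            assert len(table) == len(oracle)
            for _, r in table.iterrows():
                best, passed = oracle[(r.genome_id, r.protein_id, r.profile_id)]
                assert r.passed_threshold == passed
                assert r.best_domain_score == best.best_domain_score

    def test_raising_cutoff_never_adds_winners(self, rng):
        base = {"K00001": spec_of("K00001", "kofam", 100.0)}
        raised = {"K00001": spec_of("K00001", "kofam", 130.0)}
        hits = self.make_random_hits(rng, 150, ["K00001"])
        w_base = select_hits(hits, base)
        w_raised = select_hits(hits, raised)
        winners = lambda t: set(t.loc[t.winning, "protein_id"])
        assert winners(w_raised) <= winners(w_base)

    def test_priority_is_noop_for_single_database_function(self, rng):
        specs = {"K00001": spec_of("K00001", "kofam", 100.0, functions=("solo",))}
        hits = self.make_random_hits(rng, 100, ["K00001"])
        table = select_hits(hits, specs)
        assert (table["winning"] == table["passed_threshold"]).all()
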