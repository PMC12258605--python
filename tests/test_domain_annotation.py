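"""Domain-hit parsing, annotation resolution, and NLR calling."""

import numpy as np
import pandas as pd
import pytest

from nlrscape.domain_annotation import (
    DomainHit,
    call_nlr_candidates,
    categorize_domain,
    classify_architecture,
    default_category_map,
    filter_alignment_hits,
    load_domtblout,
    merge_overlapping_intervals,
    resolve_competing_hits,
)
from nlrscape.io import write_domtblout
from nlrscape.synthetic_data import generate_domain_hits


def hit(gene="g1", profile="NACHT", source="sordariales_specific", start=100, end=250,
        evalue=1e-10, score=50.0):
    return DomainHit(gene, profile, source, start, end, evalue, score)


class TestLoadDomtblout:
    def make_file(self, tmp_path, hits_df):
        path = tmp_path / "hits.domtblout"
        write_domtblout(hits_df, path)
        return path

    def test_round_trip(self, tmp_path):
        hits = generate_domain_hits(
            None,
            {"g1": [("NACHT", "pfam_a", (10, 150), 1e-6)],
             "g2": [("Ank", "pfam_a", (5, 80)), ("WD40", "pfam_a", (100, 200))]},
            seed=0,
        )
        loaded = load_domtblout(self.make_file(tmp_path, hits), source="pfam_a")
        assert len(loaded) == 3
        g1 = loaded[loaded.gene_id == "g1"].iloc[0]
        assert (g1.aa_start, g1.aa_end) == (10, 150)
        assert g1.evalue == pytest.approx(1e-6)

    def test_comment_only_file_is_empty(self, tmp_path):
        path = tmp_path / "empty.domtblout"
        path.write_text("# nothing here\n# at all\n")
        assert load_domtblout(path).empty

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.domtblout"
        path.write_text("# header\ntoo few columns\n")
        with pytest.raises(ValueError, match="line 2"):
            load_domtblout(path)


class TestResolveCompetingHits:
    def test_same_source_nb_pair_squared_rule_pass(self):
        # 1e-10 < (1e-4)^2 = 1e-8: best retained
        calls = resolve_competing_hits(
            [hit(profile="NACHT", evalue=1e-10), hit(profile="NB-ARC", evalue=1e-4)]
        )
        assert list(calls.profile) == ["NACHT"]
        assert list(calls.status) == ["resolved"]

    def test_same_source_nb_pair_squared_rule_fail(self):
        # 1e-6 > (1e-4)^2 = 1e-8: NB competition left undetermined
        calls = resolve_competing_hits(
            [hit(profile="NACHT", evalue=1e-6), hit(profile="NB-ARC", evalue=1e-4)]
        )
        assert set(calls.status) == {"undetermined"}

    def test_non_nb_tie_keeps_all_as_multiple(self):
        calls = resolve_competing_hits(
            [hit(profile="Ank", evalue=1e-6), hit(profile="TPR", evalue=1e-4)]
        )
        assert set(calls.status) == {"multiple"}
        assert set(calls.profile) == {"Ank", "TPR"}

    def test_source_priority_wins_outright(self):
        # a weak curated-profile hit beats a strong Pfam-A hit on the region
        calls = resolve_competing_hits(
            [hit(profile="Ank", source="wojciechowski", evalue=1e-3),
             hit(profile="TPR", source="pfam_a", evalue=1e-30)]
        )
        assert list(calls.profile) == ["Ank"]

    def test_single_hit_unchanged(self):
        calls = resolve_competing_hits([hit()])
        assert list(calls.status) == ["resolved"]

    def test_non_overlapping_hits_do_not_compete(self):
        calls = resolve_competing_hits(
            [hit(profile="NACHT", start=1, end=100, evalue=1e-5),
             hit(profile="Ank", start=300, end=400, evalue=1e-4)]
        )
        assert len(calls) == 2
        assert set(calls.status) == {"resolved"}

    def test_decoy_evalue_ratio_from_generator(self):
        # (1e-12, 1e-5): 1e-12 < 1e-10, the strong hit survives
        hits = generate_domain_hits(
            None,
            {"g1": [("NACHT", "sordariales_specific", (50, 200), 1e-12),
                    ("NB-ARC", "sordariales_specific", (60, 210), 1e-5)]},
        )
        calls = resolve_competing_hits(hits)
        assert list(calls.profile) == ["NACHT"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(7)
        base = [
            hit(profile=p, source=s, start=st_, end=st_ + 120, evalue=ev)
            for p, s, st_, ev in [
                ("NACHT", "sordariales_specific", 100, 1e-12),
                ("NB-ARC", "sordariales_specific", 130, 1e-5),
                ("Ank", "pfam_a", 400, 1e-9),
                ("TPR", "pfam_a", 430, 1e-8),
            ]
        ]
        reference = resolve_competing_hits(base)
        for _ in range(10):
            perm = [base[i] for i in rng.permutation(len(base))]
            shuffled = resolve_competing_hits(perm)
            pd.testing.assert_frame_equal(reference, shuffled)

    def test_resolved_calls_monotone_in_overlap_fraction(self):
        """Within one profile source, lowering the overlap threshold only
        merges competition groups, so the number of cleanly resolved calls
        cannot grow."""
        rng = np.random.default_rng(3)
        hits = []
        for g in range(10):
            for _ in range(4):
                start = int(rng.integers(1, 300))
                hits.append(
                    hit(
                        gene=f"g{g}",
                        profile=str(rng.choice(["NACHT", "NB-ARC", "Ank", "TPR"])),
                        start=start,
                        end=start + int(rng.integers(50, 200)),
                        evalue=float(10.0 ** rng.uniform(-20, -3)),
                    )
                )
        resolved = []
        for f in (1.0, 0.75, 0.5, 0.25, 0.05):
            calls = resolve_competing_hits(hits, overlap_fraction=f)
            resolved.append((calls.status == "resolved").sum())
        assert all(a >= b for a, b in zip(resolved, resolved[1:]))


class TestCategorize:
    @pytest.mark.parametrize(
        "profile,category",
        [("sesA", "HeLo-like"), ("NAD1", "Goodbye-like"), ("Lipocalin_5", "Lipocalin_5")],
    )
    def test_merges_and_noncanonical_fallback(self, profile, category):
        assert categorize_domain(profile) == category

    def test_amyloid_profiles_pool(self):
        cm = default_category_map()
        assert cm.category("HET-s_218-289") == "amyloid"
        assert cm.category_class("HET-s_218-289") == "amyloid"

    def test_table_round_trip(self):
        cm = default_category_map()
        again = type(cm).from_table(cm.to_table())
        assert again.profile_to_category == cm.profile_to_category


class TestCallNLRCandidates:
    def calls_for(self, entries):
        hits = [hit(**e) for e in entries]
        return resolve_competing_hits(hits)

    def test_nb_plus_cterm_long_gene_is_candidate(self):
        calls = self.calls_for(
            [dict(profile="NACHT", start=100, end=250),
             dict(profile="Ank", start=300, end=400)]
        )
        assert call_nlr_candidates(calls, {"g1": 2400}) == {"g1"}

    def test_short_gene_rejected(self):
        calls = self.calls_for(
            [dict(profile="NACHT", start=100, end=250),
             dict(profile="Ank", start=300, end=400)]
        )
        assert call_nlr_candidates(calls, {"g1": 999}) == set()
        assert call_nlr_candidates(calls, {"g1": 1000}) == set()  # strictly > 1 kb
        assert call_nlr_candidates(calls, {"g1": 1001}) == {"g1"}

    def test_nb_only_rejected(self):
        calls = self.calls_for([dict(profile="NACHT", start=100, end=250)])
        assert call_nlr_candidates(calls, {"g1": 2400}) == set()

    def test_cterm_upstream_of_nb_rejected(self):
        calls = self.calls_for(
            [dict(profile="Ank", start=10, end=80),
             dict(profile="NACHT", start=100, end=250)]
        )
        assert call_nlr_candidates(calls, {"g1": 2400}) == set()

    def test_missing_gene_length_raises(self):
        calls = self.calls_for([dict(profile="NACHT", start=100, end=250)])
        with pytest.raises(KeyError):
            call_nlr_candidates(calls, {})


class TestClassifyArchitecture:
    def resolved(self, entries, gene="g1"):
        return resolve_competing_hits([hit(gene=gene, **e) for e in entries])

    def test_full_complement_is_tripartite(self):
        calls = self.resolved(
            [dict(profile="HeLo", start=5, end=80),
             dict(profile="NACHT", start=120, end=280),
             dict(profile="WD40", start=320, end=500)]
        )
        assert classify_architecture(calls, 520) == "tripartite"

    def test_nb_near_n_terminus_is_missing_n(self):
        calls = self.resolved(
            [dict(profile="NACHT", start=12, end=200),
             dict(profile="WD40", start=260, end=420)]
        )
        assert classify_architecture(calls, 450) == "missing-N"

    def test_two_canonical_nterm_categories_is_mixed(self):
        calls = self.resolved(
            [dict(profile="sesB", start=5, end=60),
             dict(profile="HeLo", start=80, end=140),
             dict(profile="NACHT", start=170, end=330),
             dict(profile="Ank", start=360, end=500)]
        )
        assert classify_architecture(calls, 520) == "mixed"

    def test_short_tail_with_no_cterm_call_is_missing_c(self):
        calls = self.resolved(
            [dict(profile="HeLo", start=5, end=80),
             dict(profile="NACHT", start=120, end=280)]
        )
        assert classify_architecture(calls, 300) == "missing-C"  # 20 aa tail

    def test_noncanonical_only_side(self):
        calls = self.resolved(
            [dict(profile="Lipocalin_5", start=5, end=80),
             dict(profile="NACHT", start=120, end=280),
             dict(profile="Ank", start=300, end=420)]
        )
        assert classify_architecture(calls, 460) == "non-canonical"


class TestIntervalsAndFilters:
    @pytest.mark.parametrize(
        "intervals,expected",
        [
            ([(1, 100), (50, 150)], [(1, 150)]),
            ([(1, 10), (20, 30)], [(1, 10), (20, 30)]),
            ([(1, 5), (5, 9), (8, 12), (20, 25)], [(1, 12), (20, 25)]),
            ([], []),
        ],
    )
    def test_merge_examples(self, intervals, expected):
        assert merge_overlapping_intervals(intervals) == expected

    def test_merge_agrees_with_covered_positions_oracle(self):
        from conftest import merge_intervals_oracle

        rng = np.random.default_rng(11)
        for _ in range(50):
            ivs = []
            for _ in range(rng.integers(1, 8)):
                s = int(rng.integers(1, 60))
                ivs.append((s, s + int(rng.integers(0, 20))))
            assert merge_overlapping_intervals(ivs) == merge_intervals_oracle(ivs)

    def test_alignment_hit_filters(self):
        hits = pd.DataFrame(
            {
                "start": [100, 100, 100, 5000],
                "end": [900, 900, 900, 5900],
                "score": [199.0, 500.0, 500.0, 500.0],
                "has_stop": [False, False, True, False],
                "has_frameshift": [False, False, False, False],
            }
        )
        kept = filter_alignment_hits(hits, nb_intervals=[(200, 400)])
        # score 199 fails the threshold; the stop-codon hit and the
        # non-overlapping hit fail their filters; one survives
        assert len(kept) == 1
        assert kept.iloc[0].score == 500.0 and kept.iloc[0].start == 100
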