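import numpy as np
import pytest

from pare_decay import (
    annotate_regions,
    condition_specificity,
    detect_prominent_sites,
    discover_motif_groups,
    exclude_mirna_sites,
    extract_flanks,
)
from pare_decay.degradome_io import SignatureMatrix, TranscriptAnnotation
from pare_decay.endo_cleavage import AnchoredFlank, CleavageGroup, CleavageSite
from pare_decay.mirna_targets import TargetHit
from pare_decay.motif import Motif


def _matrix(entries, lib="DW"):
    m = SignatureMatrix(lib)
    for tid, pos, c in entries:
        m.add(tid, pos, c)
    return m


def _site(tid, pos, lib="DW", count=100.0):
    return CleavageSite(tid, pos, count, count / 0.9, 50.0, 0.9, lib)


class TestDetectProminentSites:
    def test_dominant_spike_detected_with_stats(self):
        m = _matrix([("t1", 100, 200.0), ("t1", 40, 2.0), ("t1", 700, 1.0)])
        (site,) = detect_prominent_sites(m)
        assert site.position == 100
        assert site.fraction_of_total == pytest.approx(200 / 203)
        assert site.prominence_ratio == pytest.approx(100.0)

    def test_tied_maximum_disqualifies_transcript(self):
        m = _matrix([("t1", 10, 50.0), ("t1", 90, 50.0), ("t1", 30, 1.0)])
        assert detect_prominent_sites(m) == []

    def test_empty_matrix_gives_no_sites(self):
        assert detect_prominent_sites(SignatureMatrix("DW")) == []

    @pytest.mark.parametrize(
        "entries",
        [
            [("t1", 5, 8.0)],  # below min_count
            [("t1", 5, 30.0), ("t1", 9, 40.0)],  # fraction < 0.5 for runner? no: max 40/70=0.57 but ratio 40/30 < 5
            [("t1", 5, 12.0), ("t1", 9, 14.0)],  # ratio too small
        ],
    )
    def test_triple_rule_rejects_weak_candidates(self, entries):
        assert detect_prominent_sites(_matrix(entries)) == []

    def test_single_position_transcript_qualifies(self):
        (site,) = detect_prominent_sites(_matrix([("t1", 7, 15.0)]))
        assert site.fraction_of_total == 1.0 and site.prominence_ratio == np.inf

    def test_invariant_under_scaling_with_rescaled_min_count(self):
        entries = [("t1", 100, 200.0), ("t1", 40, 2.0), ("t2", 9, 30.0)]
        s1 = detect_prominent_sites(_matrix(entries), min_count=10)
        s2 = detect_prominent_sites(_matrix(entries).scaled(0.1), min_count=1)
        assert [(s.transcript_id, s.position) for s in s1] == [
            (s.transcript_id, s.position) for s in s2
        ]

    def test_at_most_one_site_per_transcript(self):
        m = _matrix([("t1", 10, 1000.0), ("t1", 20, 30.0), ("t1", 30, 1.0)])
        sites = detect_prominent_sites(m)
        assert len(sites) == 1 and sites[0].position == 10


class TestExcludeMirnaSites:
    def _hit(self, tid, pos):
        return TargetHit("m1", tid, pos - 11, pos + 9, 0.0, pos)

    def test_exact_overlap_removed(self):
        sites = [_site("t1", 50)]
        assert exclude_mirna_sites(sites, [self._hit("t1", 50)]) == []

    @pytest.mark.parametrize("dist,kept", [(1, False), (2, False), (3, True), (10, True)])
    def test_exclusion_radius(self, dist, kept):
        sites = [_site("t1", 50 + dist)]
        out = exclude_mirna_sites(sites, [self._hit("t1", 50)], window_nt=2)
        assert (len(out) == 1) is kept

    def test_other_transcript_not_affected(self):
        sites = [_site("t2", 50)]
        assert len(exclude_mirna_sites(sites, [self._hit("t1", 50)])) == 1

    def test_empty_hit_set_is_identity(self):
        sites = [_site("t1", 50)]
        assert exclude_mirna_sites(sites, []) == sites


class TestExtractFlanks:
    def test_window_coordinates_and_anchor(self):
        seq = "".join("ACGU"[i % 4] for i in range(200))
        flanks = extract_flanks([_site("t1", 100)], {"t1": seq})
        (f,) = flanks
        assert f.sequence == seq[89:115]  # positions 90..115 inclusive
        assert len(f.sequence) == 26 and f.anchor_offset == 10
        # first nt 3' of the cut is the site position itself
        assert f.sequence[10] == seq[99]

    def test_site_too_close_to_end_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            flanks = extract_flanks([_site("t1", 5)], {"t1": "ACGU" * 50})
        assert flanks == []

    def test_planted_motif_offset_constant_across_members(self, small_sim):
        _, ann, seq, pare, _, truth = small_sim
        sites = [_site(e.transcript_id, e.cut_position) for e in truth.endo_sites]
        flanks = extract_flanks(sites, seq)
        starts = {f.sequence[f.anchor_offset : f.anchor_offset + 9] for f in flanks}
        assert starts == {truth.endo_sites[0].consensus}


def _random_flanks(rng, n, motif=None, n_with=0, width=26, anchor=10):
    out = []
    for i in range(n):
        s = "".join(rng.choice(list("ACGU"), width))
        if motif and i < n_with:
            s = s[:anchor] + motif + s[anchor + len(motif) :]
        out.append(
            AnchoredFlank(site=_site(f"t{i}", 100), sequence=s, anchor_offset=anchor)
        )
    return out


class TestDiscoverMotifGroups:
    def test_planted_8mer_in_12_of_60_recovered(self, rng):
        flanks = _random_flanks(rng, 60, motif="GACGGUUC", n_with=12)
        groups = discover_motif_groups(flanks)
        assert len(groups) == 1
        (g,) = groups
        assert g.consensus == "GACGGUUC"
        assert len(g.members) == 12
        assert {s.transcript_id for s in g.members} == {f"t{i}" for i in range(12)}

    def test_five_member_group_dropped_at_default_min_size(self, rng):
        flanks = _random_flanks(rng, 60, motif="GACGGUUC", n_with=5)
        assert discover_motif_groups(flanks) == []

    def test_fewer_flanks_than_min_size_gives_empty(self, rng):
        flanks = _random_flanks(rng, 4, motif="GACGGUUC", n_with=4)
        assert discover_motif_groups(flanks) == []

    def test_random_flanks_rarely_form_groups(self):
        clean = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            if not discover_motif_groups(_random_flanks(rng, 60)):
                clean += 1
        assert clean >= 9

    def test_mixed_anchor_offsets_rejected(self, rng):
        flanks = _random_flanks(rng, 6)
        flanks[0] = AnchoredFlank(flanks[0].site, flanks[0].sequence, 9)
        with pytest.raises(ValueError):
            discover_motif_groups(flanks)

    def test_membership_is_a_partition(self, rng):
        flanks = _random_flanks(rng, 60, motif="GACGGUUC", n_with=12)
        # add a second planted motif on other members
        for i in range(20, 30):
            s = flanks[i].sequence
            flanks[i] = AnchoredFlank(
                flanks[i].site, s[:10] + "CCUUAAGGCC" + s[20:], 10
            )
        groups = discover_motif_groups(flanks)
        seen = [s.transcript_id for g in groups for s in g.members]
        assert len(seen) == len(set(seen))
        assert {g.consensus for g in groups} == {"GACGGUUC", "CCUUAAGGCC"}


def _group(members, consensus="ACGUACGU"):
    motif = Motif(consensus, np.full((len(consensus), 4), 0.25), list(range(len(members))), [10] * len(members), 1e-6, 20)
    return CleavageGroup("G1", motif, members)


class TestConditionSpecificity:
    def test_labels(self):
        dw = [_site("t1", 10, "DW"), _site("t2", 20, "DW")]
        dc = [_site("t3", 30, "DC"), _site("t1", 10, "DC")]
        g_dw = _group([_site("t2", 20)])
        g_dc = _group([_site("t3", 30)])
        g_sh = _group([_site("t1", 10), _site("t2", 20)])
        out = condition_specificity([g_dw, g_dc, g_sh], dw, dc)
        assert [g.condition_label for g in out] == ["DW_only", "DC_only", "shared"]

    def test_empty_group_list(self):
        assert condition_specificity([], [], []) == []


class TestAnnotateRegions:
    ANN = {"t1": TranscriptAnnotation("t1", 1000, 201, 700, 0)}

    def test_cds_start_is_cds(self):
        g = _group([_site("t1", 201)])
        groups, overall = annotate_regions([g], self.ANN)
        assert groups[0].region_distribution == {"utr5": 0.0, "cds": 1.0, "utr3": 0.0}

    def test_equal_three_way_split(self):
        g = _group([_site("t1", 150), _site("t1", 400), _site("t1", 900)])
        groups, overall = annotate_regions([g], self.ANN)
        assert groups[0].region_distribution == pytest.approx(
            {"utr5": 1 / 3, "cds": 1 / 3, "utr3": 1 / 3}
        )
        assert sum(overall.values()) == pytest.approx(1.0, abs=1e-12)

    def test_overall_equals_weighted_member_fractions(self):
        g1 = _group([_site("t1", 150), _site("t1", 400)])
        g2 = _group([_site("t1", 900), _site("t1", 950), _site("t1", 980)])
        groups, overall = annotate_regions([g1, g2], self.ANN)
        # recompute from scratch
        member_regions = ["utr5", "cds", "utr3", "utr3", "utr3"]
        for region in ("utr5", "cds", "utr3"):
            assert overall[region] == pytest.approx(member_regions.count(region) / 5)

    def test_missing_annotation_raises(self):
        g = _group([_site("tX", 10)])
        with pytest.raises(KeyError):
            annotate_regions([g], self.ANN)
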