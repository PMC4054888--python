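import statistics

import numpy as np
import pytest

from pare_decay import (
    MiRNA,
    align_mirna,
    categorize_hit,
    compare_conditions,
    normalize_library,
    scan_targets,
    transcript_abundance,
    build_abundance_table,
)
from pare_decay.degradome_io import SignatureMatrix

RC = str.maketrans("ACGU", "UGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


MIRNA = "ACGUACGUACGUACGGACGUA"  # 21 nt; position 15 (1-based) is G


class TestAlignMirna:
    def test_perfect_reverse_complement_scores_zero(self):
        assert align_mirna(MIRNA, revcomp(MIRNA)) == 0.0

    def test_single_wobble_outside_core_scores_half(self):
        # miRNA position 15 is G; pair it with U instead of C -> G:U wobble
        window = list(revcomp(MIRNA))
        window[21 - 15] = "U"
        assert align_mirna(MIRNA, "".join(window)) == 0.5

    def test_single_mismatch_in_core_scores_two(self):
        # miRNA position 5 is in the doubled 2-13 core; A there pairs U ->
        # replace with C for a plain mismatch
        assert MIRNA[4] == "A"
        window = list(revcomp(MIRNA))
        window[21 - 5] = "C"
        assert align_mirna(MIRNA, "".join(window)) == 2.0

    def test_window_length_must_match(self):
        with pytest.raises(ValueError):
            align_mirna(MIRNA, "ACGU")

    def test_alphabet_violation_rejected(self):
        with pytest.raises(ValueError):
            align_mirna(MIRNA, revcomp(MIRNA)[:-1] + "N")

    def test_mirna_dataclass_validates(self):
        with pytest.raises(ValueError):
            MiRNA("m", "ACGU")


class TestCategorizeHit:
    @pytest.mark.parametrize(
        "profile,site,expected",
        [
            ({1: 10.0, 2: 4.0, 3: 2.0}, 1, 0),  # unique maximum
            ({1: 10.0, 2: 4.0, 3: 2.0}, 2, 3),  # median of nonzero = 4 -> <= median
            ({1: 10.0, 2: 10.0, 3: 2.0}, 1, 1),  # tied maximum
            ({1: 10.0, 2: 6.0, 3: 2.0, 4: 1.5}, 2, 2),  # above median, below max
            ({1: 10.0, 2: 1.0}, 2, 4),  # single read
        ],
    )
    def test_rule_application(self, profile, site, expected):
        assert categorize_hit(profile, site) == expected

    def test_zero_count_site_rejected(self):
        with pytest.raises(ValueError):
            categorize_hit({1: 10.0}, 2)

    def test_agrees_with_bruteforce_on_random_profiles(self, rng):
        def brute(profile, site):
            nonzero = sorted(c for c in profile.values() if c > 0)
            count = profile[site]
            maximum = nonzero[-1]
            if count == maximum:
                return 0 if nonzero.count(maximum) == 1 else 1
            med = statistics.median(nonzero)
            if count > med:
                return 2
            if count > 1:
                return 3
            return 4

        for _ in range(1000):
            n = int(rng.integers(1, 12))
            profile = {
                int(p): float(c)
                for p, c in zip(
                    rng.choice(np.arange(1, 100), size=n, replace=False),
                    rng.integers(1, 30, size=n),
                )
            }
            site = list(profile)[int(rng.integers(0, n))]
            assert categorize_hit(profile, site) == brute(profile, site)


def _planted_scene(rng, n_transcripts=30, n_targets=5):
    """Random transcripts with perfect-complement sites and PARE spikes."""
    mirna = MIRNA
    transcripts, sigs, planted = {}, SignatureMatrix("DW"), []
    for i in range(n_transcripts):
        tid = f"t{i}"
        seq = "".join(rng.choice(list("ACGU"), 500))
        if i < n_targets:
            start0 = int(rng.integers(50, 400))
            seq = seq[:start0] + revcomp(mirna) + seq[start0 + 21 :]
            cut = start0 + 1 + 21 - 10  # 1-based
            sigs.add(tid, cut, 90.0)
            sigs.add(tid, cut + 37, 6.0)
            planted.append((tid, cut))
        transcripts[tid] = seq
    return {"m1": mirna}, transcripts, {"DW": sigs}, planted


class TestScanTargets:
    def test_planted_sites_recovered_exactly(self, rng):
        mirnas, transcripts, sigs, planted = _planted_scene(rng)
        hits = scan_targets(mirnas, transcripts, sigs)
        found = {(h.transcript_id, h.cleavage_position) for h in hits}
        assert found == set(planted)
        assert all(h.score == 0.0 for h in hits)

    def test_site_without_pare_evidence_is_not_reported(self, rng):
        mirnas, transcripts, sigs, planted = _planted_scene(rng)
        empty = {"DW": SignatureMatrix("DW")}
        assert scan_targets(mirnas, transcripts, empty) == []

    def test_score_cutoff_boundary(self, rng):
        # 4 undoubled mismatches + 1 undoubled wobble = 4.5 (kept);
        # 5 undoubled mismatches = 5.0 (dropped at the 4.5 default)
        mirna = MIRNA
        base = revcomp(mirna)
        # miRNA positions 14,16,17,18,19 are undoubled (window idx 21-i)
        def mutate(positions, wobble_at=None):
            w = list(base)
            for p in positions:
                m = mirna[p - 1]
                comp = {"A": "U", "U": "A", "C": "G", "G": "C"}[m]
                choices = [c for c in "ACGU" if c != comp]
                # avoid accidental wobble
                choices = [
                    c for c in choices
                    if not ((m == "G" and c == "U") or (m == "U" and c == "G"))
                ]
                w[21 - p] = choices[0]
            if wobble_at is not None:
                m = mirna[wobble_at - 1]
                w[21 - wobble_at] = "U" if m == "G" else "G"
            return "".join(w)

        kept_window = mutate([14, 16, 17, 18], wobble_at=15)
        dropped_window = mutate([1, 14, 16, 17, 18])
        assert align_mirna(mirna, kept_window) == 4.5
        assert align_mirna(mirna, dropped_window) == 5.0
        transcripts = {"k": "AAAA" + kept_window + "AAAA",
                       "d": "AAAA" + dropped_window + "AAAA"}
        sigs = SignatureMatrix("DW")
        for tid in transcripts:
            sigs.add(tid, 4 + 1 + 21 - 10, 50.0)
        hits = scan_targets({"m1": mirna}, transcripts, {"DW": sigs})
        assert {h.transcript_id for h in hits} == {"k"}


class TestCompareConditions:
    def test_arrows_follow_planted_directions(self, small_sim):
        _, ann, seq, pare, rna, truth = small_sim
        norm_dc, _ = normalize_library(pare["DC"], pare["DW"])
        norm = {"DW": pare["DW"], "DC": norm_dc}
        hits = scan_targets(truth.mirna_sequences, seq, norm)
        table = build_abundance_table(
            transcript_abundance(norm["DW"]), transcript_abundance(norm["DC"]),
            rna["RW"], rna["RC"],
        )
        out = compare_conditions(hits, table, truth.mirna_log2fc)
        by_tid = out.set_index("transcript").to_dict("index")
        arrows = {2.5: "up", 0.0: "unchanged", -2.5: "down"}
        for t in truth.mirna_targets:
            row = by_tid[t.transcript_id]
            # degradation product tracks the planted uncapped-abundance change
            assert row["de_change"] == arrows[truth.log2fc_d[t.transcript_id]]
            assert row["mirna_change"] == arrows[truth.mirna_log2fc[t.mirna_id]]

    def test_unchanged_everywhere_gives_dashes(self):
        import pandas as pd

        from pare_decay.mirna_targets import TargetHit

        hits = [TargetHit("m1", "t1", 10, 30, 0.0, 21,
                          reads={"DW": 20.0, "DC": 20.0}, categories={})]
        table = pd.DataFrame({"log2fc_r": [0.0]}, index=["t1"])
        out = compare_conditions(hits, table, {"m1": 0.0})
        row = out.iloc[0]
        assert (row.mirna_change, row.mrna_change, row.de_change) == (
            "unchanged", "unchanged", "unchanged",
        )

    def test_arrows_invariant_to_prior_library_scaling(self, small_sim):
        _, ann, seq, pare, rna, truth = small_sim
        norm_dc, _ = normalize_library(pare["DC"], pare["DW"])
        norm = {"DW": pare["DW"], "DC": norm_dc}
        hits1 = scan_targets(truth.mirna_sequences, seq, norm)
        # rescale both raw libraries, then re-normalize: arrows must not move
        scaled = {"DW": pare["DW"].scaled(3.0), "DC": pare["DC"].scaled(7.0)}
        renorm_dc, _ = normalize_library(scaled["DC"], scaled["DW"])
        hits2 = scan_targets(truth.mirna_sequences, seq,
                             {"DW": scaled["DW"], "DC": renorm_dc})
        table = build_abundance_table(
            transcript_abundance(norm["DW"]), transcript_abundance(norm["DC"]),
            rna["RW"], rna["RC"],
        )
        out1 = compare_conditions(hits1, table, truth.mirna_log2fc)
        out2 = compare_conditions(hits2, table, truth.mirna_log2fc)
        key = ["mirna", "transcript", "cleavage_pos"]
        merged = out1.merge(out2, on=key, suffixes=("_1", "_2"))
        assert len(merged) == len(out1)
        assert (merged["de_change_1"] == merged["de_change_2"]).all()
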