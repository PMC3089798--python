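"""DRE core scanning, PWM scoring, one-hot distance, conservation clustering."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahrcross.dre import (
    Pwm,
    build_pwm,
    cluster_orthologous_dres,
    dre_distance,
    extend_to_19mer,
    matrix_similarity,
    positional_conservation,
    scan_cores,
    scan_promoter,
    DreHit,
)
from ahrcross.io import FormatError, PromoterRecord
from ahrcross.simulate import (
    DRE_CONSENSUS_19MER,
    PlantedDre,
    generate_promoters,
    mutate_19mer,
    revcomp,
)
from .test_simulate import brute_force_core_scan

BASES = "ACGT"


def _record(seq, tss=0, species="mouse", gene="g", up=10000, down=1000):
    return PromoterRecord(species, gene, seq, tss, up, down)


class TestScanCores:
    def test_plus_strand_hit_center(self):
        hits = scan_cores(_record("AAGCGTGAA"))
        assert len(hits) == 1
        h = hits[0]
        assert (h.core_center, h.strand) == (4, "+")

    def test_minus_strand_hit_center(self):
        hits = scan_cores(_record("AACACGCAA"))
        assert len(hits) == 1
        assert (hits[0].core_center, hits[0].strand) == (4, "-")

    def test_n_never_matches(self):
        assert scan_cores(_record("AAGCGTNAA")) == []
        assert scan_cores(_record("GCGTGNNNNGCGTG"))[0].core_center == 2

    def test_window_bounds_respected(self):
        # core center at +3 with downstream window of 2 -> excluded
        rec = _record("AAAGCGTGAA", tss=2, down=2)
        assert scan_cores(rec) == []

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            seq = "".join(rng.choice(list(BASES), size=200))
            rec = _record(seq, tss=100)
            got = sorted((h.seq_start, h.strand) for h in scan_cores(rec))
            assert got == sorted(brute_force_core_scan(seq))

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list(BASES), size=300))
        rec = _record(seq, tss=150)
        mirrored = _record(revcomp(seq), tss=len(seq) - 1 - 150)
        fwd = sorted((h.seq_start, h.strand) for h in scan_cores(rec))
        rev = sorted(
            (len(seq) - (h.seq_start + 5), "+-"[h.strand == "+"])
            for h in scan_cores(mirrored)
        )
        assert fwd == rev


class TestExtend:
    def test_full_flank_19mer_carries_core(self):
        seq = "T" * 7 + "GCGTG" + "A" * 7
        (hit,) = scan_cores(_record(seq))
        dre = extend_to_19mer(hit, _record(seq))
        assert dre.seq19[7:12] == "GCGTG" and len(dre.seq19) == 19

    def test_insufficient_flank_dropped_with_warning(self):
        seq = "AAGCGTG" + "A" * 12  # only 2 bp of left flank
        (hit,) = scan_cores(_record(seq))
        with pytest.warns(UserWarning, match="insufficient flank"):
            assert extend_to_19mer(hit, _record(seq)) is None

    def test_minus_strand_reported_in_dre_orientation(self):
        core19 = DRE_CONSENSUS_19MER
        seq = "TTTT" + revcomp(core19) + "CCCC"
        rec = _record(seq)
        hits = [h for h in scan_cores(rec) if h.strand == "-"]
        dre = extend_to_19mer(hits[0], rec)
        assert dre.seq19 == core19
        # round trip: the reported 19-mer itself scans positive at 7..11
        assert dre.seq19[7:12] == "GCGTG"

    def test_mismatched_record_rejected(self):
        seq = "T" * 7 + "GCGTG" + "A" * 7
        (hit,) = scan_cores(_record(seq))
        with pytest.raises(ValueError, match="does not belong"):
            extend_to_19mer(hit, _record(seq, gene="other"))


class TestPwm:
    def test_identical_sequences_modal_probability(self):
        n = 8
        pwm = build_pwm([DRE_CONSENSUS_19MER] * n)
        expected = (n + 0.25) / (n + 1)
        idx = [BASES.index(b) for b in DRE_CONSENSUS_19MER]
        for i, bi in enumerate(idx):
            assert pwm.probs[bi, i] == pytest.approx(expected)

    def test_uniform_column_zero_information(self):
        probs = np.full((4, 19), 0.25)
        probs[:, 0] = [0.7, 0.1, 0.1, 0.1]  # one informative column
        pwm = Pwm(probs)
        assert pwm.weights[1:] == pytest.approx(0.0)
        assert pwm.weights[0] > 0

    def test_frequencies_match_brute_force_counts(self, rng):
        seqs = [
            "".join(rng.choice(list(BASES), size=19)) for _ in range(50)
        ]
        pwm = build_pwm(seqs, pseudocount=0.25)
        for i in range(19):
            for bi, b in enumerate(BASES):
                count = sum(s[i] == b for s in seqs)
                assert pwm.probs[bi, i] == pytest.approx(
                    (count + 0.25) / (50 + 1.0)
                )

    def test_bad_training_input_rejected(self):
        with pytest.raises(FormatError, match="length"):
            build_pwm(["ACGT", "ACGT"])
        with pytest.raises(FormatError, match=">= 2"):
            build_pwm([DRE_CONSENSUS_19MER])


class TestMatrixSimilarity:
    def test_consensus_scores_one(self, default_pwm):
        assert matrix_similarity(default_pwm.consensus, default_pwm) == pytest.approx(1.0)

    def test_worst_sequence_scores_zero(self, default_pwm):
        worst = "".join(
            BASES[default_pwm.probs[:, i].argmin()] for i in range(19)
        )
        assert matrix_similarity(worst, default_pwm) == pytest.approx(0.0)

    def test_all_57_single_mutants_decrease_and_match_oracle(self, default_pwm):
        pwm = default_pwm
        cons = pwm.consensus
        ms_cons = matrix_similarity(cons, pwm)
        for i in range(19):
            for b in BASES:
                if b == cons[i]:
                    continue
                mut = cons[:i] + b + cons[i + 1 :]
                ms = matrix_similarity(mut, pwm)
                assert ms < ms_cons
                # independent recomputation from raw matrix entries
                raw = sum(
                    pwm.weights[j] * pwm.probs[BASES.index(mut[j]), j]
                    for j in range(19)
                )
                expected = (raw - pwm.s_min) / (pwm.s_max - pwm.s_min)
                assert ms == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=19, max_size=19))
    def test_bounds_for_all_19mers(self, default_pwm, seq):
        assert 0.0 <= matrix_similarity(seq, default_pwm) <= 1.0

    def test_invalid_base_rejected(self, default_pwm):
        with pytest.raises(FormatError, match="invalid base"):
            matrix_similarity("N" * 19, default_pwm)


class TestDistance:
    def test_identity_and_single_mismatch(self):
        a = DRE_CONSENSUS_19MER
        assert dre_distance(a, a) == 0.0
        b = ("A" if a[0] != "A" else "C") + a[1:]
        assert dre_distance(a, b) == pytest.approx(math.sqrt(2))

    def test_threshold_admits_four_rejects_five_mismatches(self, rng):
        a = DRE_CONSENSUS_19MER
        m4 = mutate_19mer(a, 4, rng)
        m5 = mutate_19mer(a, 5, rng)
        assert dre_distance(a, m4) == pytest.approx(math.sqrt(8))  # 2.828 <= 3
        assert dre_distance(a, m4) <= 3.0
        assert dre_distance(a, m5) == pytest.approx(math.sqrt(10))  # 3.162 > 3
        assert dre_distance(a, m5) > 3.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=19, max_size=19),
            min_size=3, max_size=3,
        )
    )
    def test_metric_axioms(self, triple):
        a, b, c = triple
        assert dre_distance(a, b) == dre_distance(b, a)
        assert (dre_distance(a, b) == 0) == (a == b)
        assert dre_distance(a, c) <= dre_distance(a, b) + dre_distance(b, c) + 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(FormatError):
            dre_distance("ACGT", "ACGTA")


def _hit(species, gene, pos, seq19, strand="+"):
    return DreHit(species, gene, pos, strand, seq19)


class TestClustering:
    def test_similar_mouse_rat_cluster_human_singletons(self, rng):
        base = DRE_CONSENSUS_19MER
        hits = [
            _hit("mouse", "Gsta5", -5, base),
            _hit("rat", "Gsta5", -22, mutate_19mer(base, 2, rng)),
            _hit("human", "GSTA5", -480, mutate_19mer(base, 9, rng)),
            _hit("human", "GSTA5", 120, mutate_19mer(base, 8, rng)),
        ]
        clusters = cluster_orthologous_dres(hits, theta=3.0)
        orth = [c for c in clusters if c.orthologous]
        assert len(orth) == 1
        assert orth[0].species == {"mouse", "rat"}
        table, spread = positional_conservation(orth[0])
        assert spread == 17  # -5 vs -22

    def test_all_dissimilar_all_singletons(self, rng):
        seqs = ["".join(rng.choice(list(BASES), 19)) for _ in range(4)]
        hits = [_hit("mouse", "x", i * 30, s) for i, s in enumerate(seqs)]
        # random 19-mers are essentially always > 4 mismatches apart
        if min(
            dre_distance(a, b) for i, a in enumerate(seqs) for b in seqs[i + 1 :]
        ) > 3.0:
            clusters = cluster_orthologous_dres(hits, theta=3.0)
            assert all(len(c.members) == 1 for c in clusters)
            assert not any(c.orthologous for c in clusters)

    def test_three_species_within_theta_form_one_cluster(self, rng):
        base = DRE_CONSENSUS_19MER
        m1 = mutate_19mer(base, 1, rng)
        m2 = mutate_19mer(base, 1, rng)
        hits = [
            _hit("mouse", "g", -10, base),
            _hit("rat", "g", -12, m1),
            _hit("human", "g", -14, m2),
        ]
        # pairwise distances all <= sqrt(2*2) = 2 < 3
        clusters = cluster_orthologous_dres(hits, theta=3.0)
        assert len(clusters) == 1
        assert clusters[0].orthologous and len(clusters[0].species) == 3
        assert clusters[0].max_distance <= 3.0

    def test_theta_zero_only_exact_duplicates(self, rng):
        base = DRE_CONSENSUS_19MER
        hits = [
            _hit("mouse", "g", -10, base),
            _hit("rat", "g", -20, base),
            _hit("human", "g", -30, mutate_19mer(base, 1, rng)),
        ]
        clusters = cluster_orthologous_dres(hits, theta=0.0)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]

    def test_theta_infinite_single_cluster(self, rng):
        hits = [
            _hit("mouse", "g", i, "".join(rng.choice(list(BASES), 19)))
            for i in range(5)
        ]
        clusters = cluster_orthologous_dres(hits, theta=np.inf)
        assert len(clusters) == 1

    def test_input_order_invariance(self, rng):
        base = DRE_CONSENSUS_19MER
        hits = [
            _hit("mouse", "g", -5, base),
            _hit("rat", "g", -22, mutate_19mer(base, 2, rng)),
            _hit("human", "g", -480, mutate_19mer(base, 9, rng)),
        ]
        c1 = cluster_orthologous_dres(hits)
        c2 = cluster_orthologous_dres(hits[::-1])
        sig = lambda cs: sorted(
            tuple(sorted((h.species, h.core_center) for h in c.members)) for c in cs
        )
        assert sig(c1) == sig(c2)


class TestPositionalConservation:
    def test_single_member_zero_spread(self):
        cluster = cluster_orthologous_dres([_hit("mouse", "g", -7, DRE_CONSENSUS_19MER)])[0]
        _, spread = positional_conservation(cluster)
        assert spread == 0

    def test_symmetric_positions(self):
        hits = [
            _hit("mouse", "g", 10, DRE_CONSENSUS_19MER),
            _hit("rat", "g", -10, DRE_CONSENSUS_19MER),
        ]
        (cluster,) = cluster_orthologous_dres(hits)
        _, spread = positional_conservation(cluster)
        assert spread == 20


class TestScanPromoterIntegration:
    def test_planted_promoters_scored_and_filtered(self, default_pwm, rng):
        planted = [
            PlantedDre("mouse", "g1", -300, "+", DRE_CONSENSUS_19MER),
            PlantedDre("mouse", "g1", 50, "-", mutate_19mer(DRE_CONSENSUS_19MER, 3, rng)),
        ]
        (rec,), _ = generate_promoters(
            planted, upstream_bp=1000, downstream_bp=200, seed=12
        )
        hits = scan_promoter(rec, pwm=default_pwm)
        assert len(hits) == 2
        by_pos = {h.core_center: h for h in hits}
        assert by_pos[-300].ms == pytest.approx(1.0)
        assert by_pos[50].ms < 1.0
        strict = scan_promoter(rec, pwm=default_pwm, ms_min=0.999)
        assert [h.core_center for h in strict] == [-300]

    def test_plus_strand_only_mode(self, default_pwm, rng):
        planted = [
            PlantedDre("mouse", "g1", -300, "+", DRE_CONSENSUS_19MER),
            PlantedDre("mouse", "g1", 50, "-", DRE_CONSENSUS_19MER),
        ]
        (rec,), _ = generate_promoters(
            planted, upstream_bp=1000, downstream_bp=200, seed=13
        )
        hits = scan_promoter(rec, strand="plus")
        assert [h.strand for h in hits] == ["+"]
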