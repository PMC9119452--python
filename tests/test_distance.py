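"""K2P distances, matrices, group summaries and the barcoding gap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap.distance import (
    DistanceMatrix,
    barcode_gap,
    distance_matrix,
    group_summaries,
    k2p,
)
from barcodegap.synthetic_data import expected_k2p, _evolve
from conftest import k2p_oracle


def _seq_pair_with(P, Q, L):
    """Build two sequences realising exact transition/transversion counts."""
    n_ts, n_tv = round(P * L), round(Q * L)
    s1 = "A" * L
    s2 = "G" * n_ts + "C" * n_tv + "A" * (L - n_ts - n_tv)
    return s1, s2


class TestK2P:
    def test_identical_sequences_zero(self):
        pw = k2p("ACGT" * 140, "ACGT" * 140)
        assert pw.d == 0.0 and pw.P == 0.0 and pw.Q == 0.0

    def test_one_transition_in_530(self):
        s1 = "A" * 530
        s2 = "G" + "A" * 529
        pw = k2p(s1, s2)
        assert round(pw.d, 4) == 0.0019
        assert pw.d == pytest.approx(-0.5 * math.log(1 - 2 / 530), abs=1e-15)

    def test_closed_form_P01_Q005(self):
        s1, s2 = _seq_pair_with(0.1, 0.05, 1000)
        pw = k2p(s1, s2)
        assert pw.d == pytest.approx(
            -0.5 * math.log(0.75) - 0.25 * math.log(0.90), abs=1e-12
        )
        assert pw.d == pytest.approx(0.170181, abs=5e-7)

    def test_jukes_cantor_identity_when_Q_is_2P(self):
        # P=0.01, Q=0.02 -> JC with p=0.03: 0.030613...
        s1, s2 = _seq_pair_with(0.01, 0.02, 1000)
        pw = k2p(s1, s2)
        p = pw.P + pw.Q
        assert pw.d == pytest.approx(-0.75 * math.log(1 - 4 * p / 3), abs=1e-12)
        assert pw.d == pytest.approx(0.0306165, abs=5e-7)

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        pw = k2p("ACGT-N", "ACGAAN")
        assert pw.n_sites == 4  # gap and N columns excluded
        assert pw.Q == 0.25  # T->A transversion over 4 sites

    def test_saturation_flagged_not_raised(self):
        # 60% differing sites, all transitions: 1-2P-Q < 0
        s1 = "A" * 100
        s2 = "G" * 60 + "A" * 40
        pw = k2p(s1, s2)
        assert pw.saturated and math.isnan(pw.d)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError, match="length"):
            k2p("ACGT", "ACG")

    def test_no_comparable_sites_error(self):
        with pytest.raises(ValueError, match="comparable"):
            k2p("NNNN", "ACGT")

    def test_symmetry_exact(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGTN-"), size=60))
            b = "".join(rng.choice(list("ACGTN-"), size=60))
            if not any(
                x in "ACGT" and y in "ACGT" for x, y in zip(a, b)
            ):
                continue
            assert k2p(a, b) == k2p(b, a)

    def test_monotone_in_P_at_fixed_Q(self):
        L, Q = 1000, 0.1
        ds = [
            k2p(*_seq_pair_with(P, Q, L)).d
            for P in (0.0, 0.05, 0.1, 0.15, 0.2)
        ]
        assert all(a < b for a, b in zip(ds, ds[1:]))

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            a = "".join(rng.choice(list("ACGTN-"), size=50, p=[.23, .23, .23, .23, .05, .03]))
            b = "".join(rng.choice(list("ACGTN-"), size=50, p=[.23, .23, .23, .23, .05, .03]))
            P, Q, n, d = k2p_oracle(a, b)
            pw = k2p(a, b)
            assert (pw.P, pw.Q, pw.n_sites) == (P, Q, n)
            if d is None:
                assert pw.saturated
            else:
                assert pw.d == pytest.approx(d, abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 40), st.integers(0, 40), st.integers(1, 420))
def test_k2p_equals_oracle_property(n_ts, n_tv, n_same):
    s1 = "A" * (n_ts + n_tv + n_same)
    s2 = "G" * n_ts + "T" * n_tv + "A" * n_same
    P, Q, n, d = k2p_oracle(s1, s2)
    pw = k2p(s1, s2)
    assert pw.saturated == (d is None)
    if d is not None:
        assert abs(pw.d - d) < 1e-12


class TestDistanceMatrix:
    def test_three_haplotypes_symmetric(self):
        m = distance_matrix(
            [("a", "A" * 20), ("b", "A" * 19 + "T"), ("c", "A" * 18 + "TT")]
        )
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        assert m.get("a", "b") == m.get("b", "a") > 0

    def test_saturated_pair_flagged(self):
        s_far = "G" * 60 + "A" * 40
        m = distance_matrix([("a", "A" * 100), ("b", s_far), ("c", "A" * 100)])
        assert m.is_saturated("a", "b") and not m.is_saturated("a", "c")

    def test_estimator_consistency_at_large_L(self, rng):
        """Sequences evolved at true divergence 0.1 estimate d within 0.005."""
        L = 100_000
        anc = rng.integers(0, 4, size=L)
        der = _evolve(anc, 0.1, 2.0, rng)
        bases = np.array(list("AGCT"))
        d = k2p("".join(bases[anc]), "".join(bases[der])).d
        assert abs(d - 0.1) < 0.005

    def test_estimator_recovery_across_replicates(self, rng):
        """Mean estimated d within 3 SE of truth for t in {0.01, 0.05, 0.1}."""
        L, reps = 530, 200
        bases = np.array(list("AGCT"))
        for t in (0.01, 0.05, 0.1):
            est = []
            for _ in range(reps):
                anc = rng.integers(0, 4, size=L)
                der = _evolve(anc, t, 2.0, rng)
                est.append(k2p("".join(bases[anc]), "".join(bases[der])).d)
            se = np.std(est, ddof=1) / math.sqrt(reps)
            assert abs(np.mean(est) - t) < 3 * se + 1e-9

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            distance_matrix([("a", "AAAA"), ("a", "AAAT")])


class TestGroupSummaries:
    def _matrix(self):
        return distance_matrix(
            [
                ("g1A", "A" * 20), ("g1B", "A" * 19 + "G"),
                ("g2A", "C" * 20), ("g2B", "C" * 19 + "T"),
                ("solo", "G" * 10 + "A" * 10),
            ]
        )

    def test_single_haplotype_group_is_zero(self):
        m = self._matrix()
        summaries = group_summaries(
            m, {"g1A": "g1", "g1B": "g1", "g2A": "g2", "g2B": "g2",
                "solo": "g3"}
        )
        s3 = next(s for s in summaries if s.group_a == s.group_b == "g3")
        assert (s3.mean, s3.min, s3.max, s3.n_pairs) == (0, 0, 0, 0)

    def test_two_haplotype_group_single_pair(self):
        m = self._matrix()
        summaries = group_summaries(
            m, {"g1A": "g1", "g1B": "g1"}, exclude={"g2A", "g2B", "solo"}
        )
        (s,) = [s for s in summaries if s.within]
        assert s.mean == s.min == s.max == m.get("g1A", "g1B")
        assert s.n_pairs == 1

    def test_excluded_haplotypes_contribute_nothing(self):
        m = self._matrix()
        with_solo = group_summaries(
            m, {"g1A": "g1", "g1B": "g1", "g2A": "g2", "g2B": "g2",
                "solo": "g1"}
        )
        without = group_summaries(
            m, {"g1A": "g1", "g1B": "g1", "g2A": "g2", "g2B": "g2"},
            exclude={"solo"},
        )
        s_with = next(s for s in without if s.group_a == s.group_b == "g1")
        assert s_with.n_pairs == 1
        assert len(with_solo) == len(without) + 0  # g1 keeps both entries

    def test_unmapped_label_rejected(self):
        m = self._matrix()
        with pytest.raises(ValueError, match="solo"):
            group_summaries(m, {"g1A": "g1", "g1B": "g1", "g2A": "g2",
                                "g2B": "g2"})

    def test_unweighted_mean_over_pairs(self):
        m = distance_matrix(
            [("a", "A" * 10), ("b", "A" * 9 + "G"), ("c", "A" * 8 + "GG")]
        )
        (s,) = [
            s for s in group_summaries(m, {k: "g" for k in "abc"}) if s.within
        ]
        expected = (m.get("a", "b") + m.get("a", "c") + m.get("b", "c")) / 3
        assert s.mean == pytest.approx(expected, abs=1e-15)
        assert s.n_pairs == 3


class TestBarcodeGap:
    def _summary(self, g1, g2, lo, hi):
        from barcodegap.distance import GroupSummary

        return GroupSummary(g1, g2, (lo + hi) / 2, lo, hi, 1)

    def test_paper_style_gap_no_overlap(self):
        within = [self._summary("a", "a", 0.0, 0.0086)]
        between = [self._summary("a", "b", 0.0095, 0.2886)]
        gap = barcode_gap(within, between)
        assert not gap.overlap
        assert gap.within_range == (0.0, 0.0086)
        assert gap.between_range == (0.0095, 0.2886)

    def test_identical_ranges_overlap(self):
        within = [self._summary("a", "a", 0.0, 0.01)]
        between = [self._summary("a", "b", 0.0, 0.01)]
        assert barcode_gap(within, between).overlap

    def test_fold_ratio_infinite_when_within_zero(self):
        within = [self._summary("a", "a", 0.0, 0.0)]
        between = [self._summary("a", "b", 0.1, 0.2)]
        assert math.isinf(barcode_gap(within, between).fold_ratio)

    def test_planted_gap_on_simulated_groups(self, rng):
        """Groups with within ~0.002 and between ~0.2 separate cleanly."""
        bases = np.array(list("AGCT"))
        haps, group_map = [], {}
        anc = rng.integers(0, 4, size=530)
        for g in range(4):
            root = _evolve(anc, 0.1, 2.0, rng)  # pairwise ~0.2 between groups
            for v in range(2):
                var = _evolve(root, 0.001, 2.0, rng)
                name = f"g{g}h{v}"
                haps.append((name, "".join(bases[var])))
                group_map[name] = f"g{g}"
        summaries = group_summaries(distance_matrix(haps), group_map)
        within = [s for s in summaries if s.within]
        between = [s for s in summaries if not s.within]
        gap = barcode_gap(within, between)
        assert not gap.overlap and gap.fold_ratio > 10
        assert all(s.mean < 0.01 for s in within)
        assert all(s.mean > 0.01 for s in between)
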