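"""Profile-HMM engine: construction, DP scores vs enumeration, calibration,
search, and alignment round-trips."""

import math

import numpy as np
import pytest
import scipy.stats

from oracles import enumerate_path_scores
from conftest import random_small_profile
from ephscan.profilehmm import (
    Alignment,
    CalibrationError,
    DegenerateModelError,
    NotCalibratedError,
    align_to_profile,
    build_profile,
    calibrate,
    evalue,
    fit_evd,
    forward,
    profile_from_json,
    profile_to_json,
    search,
    trim_alignment,
    viterbi,
    viterbi_score,
)
from ephscan.seqs import AA_INDEX, AMINO_ACIDS, BACKGROUND, SequenceRecord


class TestBuildProfile:
    def test_unanimous_columns(self, tiny_profile):
        assert tiny_profile.M == 5
        for j, res in enumerate("ACDEF"):
            assert tiny_profile.match_emissions[j].argmax() == AA_INDEX[res]

    def test_all_gap_column_not_a_match_state(self):
        aln = Alignment((("a", "AC-DE"), ("b", "AC-DE")))
        prof = build_profile(aln, occupancy_threshold=0.5)
        assert prof.M == 4 and prof.match_columns == (0, 1, 3, 4)

    def test_hand_computed_emissions_with_unit_pseudocount(self):
        """Two-row column 'A'/'C': emission = (count + bg) / (2 + 1)."""
        aln = Alignment((("a", "A"), ("b", "C")))
        prof = build_profile(aln, pseudocount_weight=1.0)
        em = prof.match_emissions[0]
        expected_a = (1 + BACKGROUND[AA_INDEX["A"]]) / 3.0
        expected_c = (1 + BACKGROUND[AA_INDEX["C"]]) / 3.0
        expected_w = BACKGROUND[AA_INDEX["W"]] / 3.0
        assert math.isclose(em[AA_INDEX["A"]], expected_a, rel_tol=1e-12)
        assert math.isclose(em[AA_INDEX["C"]], expected_c, rel_tol=1e-12)
        assert math.isclose(em[AA_INDEX["W"]], expected_w, rel_tol=1e-12)

    def test_degenerate_when_no_column_passes(self):
        aln = Alignment((("a", "A---"), ("b", "-C--"), ("c", "--D-"), ("d", "---E")))
        with pytest.raises(DegenerateModelError):
            build_profile(aln, occupancy_threshold=0.5)

    def test_normalization_invariant_on_random_alignments(self, rng):
        for _ in range(30):
            prof = random_small_profile(rng)
            if prof is not None:
                prof.validate()


class TestViterbiForward:
    def test_self_match_visits_every_match_state(self, tiny_profile):
        score, path = viterbi(tiny_profile, "ACDEF")
        states = [s for s, _j, _i in path]
        assert states == ["M"] * 5
        assert score > 0

    def test_all_x_scores_nonpositive(self, tiny_profile):
        assert viterbi_score(tiny_profile, "XXXXX") <= 0

    def test_scores_equal_exhaustive_enumeration(self, rng):
        """Viterbi = max, Forward = log-sum over all legal paths (<=3 match
        states, sequences <=5), to 1e-9 relative."""
        checked = 0
        while checked < 60:
            prof = random_small_profile(rng)
            if prof is None:
                continue
            L = int(rng.integers(1, 6))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
            ref = enumerate_path_scores(prof, seq)
            if len(ref) == 0:
                continue
            v = viterbi_score(prof, seq)
            f = forward(prof, seq)
            assert math.isclose(v, ref.max(), rel_tol=1e-9, abs_tol=1e-9)
            assert math.isclose(
                f, float(np.logaddexp2.reduce(ref)), rel_tol=1e-9, abs_tol=1e-9
            )
            checked += 1

    def test_forward_dominates_viterbi(self, rng):
        for _ in range(20):
            prof = random_small_profile(rng)
            if prof is None:
                continue
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=5))
            assert forward(prof, seq) >= viterbi_score(prof, seq) - 1e-9

    def test_near_single_path_model_forward_close_to_viterbi(self):
        """With ~unanimous transitions and sharp emissions the path sum is
        dominated by the single best path."""
        rows = tuple((f"s{i}", "ACDEFGHIKL") for i in range(50))
        prof = build_profile(Alignment(rows), pseudocount_weight=1e-6)
        v = viterbi_score(prof, "ACDEFGHIKL")
        f = forward(prof, "ACDEFGHIKL")
        assert 0 <= f - v < 0.02

    def test_invalid_symbol_rejected(self, tiny_profile):
        with pytest.raises(ValueError):
            viterbi_score(tiny_profile, "AC*EF")


class TestCalibration:
    def test_deterministic_under_seed(self, tiny_profile):
        p1 = calibrate(tiny_profile, n_random=100, length=50, seed=4)
        p2 = calibrate(tiny_profile, n_random=100, length=50, seed=4)
        assert p1 == p2

    def test_parameter_recovery_from_known_gumbel(self):
        mu, lam = 5.0, 0.7
        samples = scipy.stats.gumbel_r.rvs(
            loc=mu, scale=1 / lam, size=10000, random_state=202
        )
        mu_hat, lam_hat = fit_evd(samples)
        assert abs(mu_hat - mu) <= 0.1
        assert abs(lam_hat - lam) <= 0.05

    def test_too_few_samples_rejected(self, tiny_profile):
        with pytest.raises(CalibrationError):
            calibrate(tiny_profile, n_random=50)


class TestEvalue:
    def test_closed_form_at_location(self, tiny_profile):
        calibrate(tiny_profile, n_random=100, length=50, seed=1)
        mu = tiny_profile.calibration.mu
        assert math.isclose(
            evalue(tiny_profile, mu, 1.0), 1 - math.exp(-1), rel_tol=1e-12
        )

    def test_monotone_and_vanishing(self, tiny_profile):
        calibrate(tiny_profile, n_random=100, length=50, seed=1)
        es = [evalue(tiny_profile, s, 100.0) for s in (0.0, 10.0, 50.0, 1e6)]
        assert es == sorted(es, reverse=True)
        assert es[-1] < 1e-12

    def test_linear_in_database_size(self, tiny_profile):
        calibrate(tiny_profile, n_random=100, length=50, seed=1)
        assert math.isclose(
            evalue(tiny_profile, 3.0, 200.0),
            2 * evalue(tiny_profile, 3.0, 100.0),
            rel_tol=1e-12,
        )

    def test_uncalibrated_profile_rejected(self, tiny_alignment):
        prof = build_profile(tiny_alignment)
        with pytest.raises(NotCalibratedError):
            evalue(prof, 1.0, 10.0)


def _family_profile(rng, M=40, nrow=6):
    cons = "".join(rng.choice(list(AMINO_ACIDS), size=M))
    rows = []
    for r in range(nrow):
        row = "".join(
            c
            if rng.random() > 0.1
            else AMINO_ACIDS[rng.integers(20)]
            for c in cons
        )
        rows.append((f"s{r}", row))
    aln = Alignment(tuple(rows))
    prof = build_profile(aln, name="fam")
    calibrate(prof, n_random=100, length=120, seed=5)
    return cons, aln, prof


class TestSearch:
    def test_training_sequences_self_recover(self, rng):
        _cons, aln, prof = _family_profile(rng)
        db = [SequenceRecord(rid, row.replace("-", "")) for rid, row in aln.rows]
        hits = search(prof, db, evalue_cutoff=0.01)
        assert {h.target for h in hits} == {rid for rid, _ in aln.rows}

    def test_two_planted_copies_give_two_hits(self, rng):
        cons, _aln, prof = _family_profile(rng)
        from ephscan.seqs import random_background_seq

        seq = (
            random_background_seq(30, rng)
            + cons
            + random_background_seq(40, rng)
            + cons
            + random_background_seq(30, rng)
        )
        hits = search(prof, [SequenceRecord("two", seq)], evalue_cutoff=0.01)
        assert len(hits) == 2
        a, b = sorted(hits, key=lambda h: h.start)
        assert a.end < b.start

    def test_empty_input_empty_output(self, rng):
        _c, _a, prof = _family_profile(rng)
        assert search(prof, [], evalue_cutoff=0.01) == []


class TestAlignToProfile:
    def test_column_count_and_identical_rows(self, rng):
        _c, aln, prof = _family_profile(rng)
        db = [SequenceRecord(rid, row.replace("-", "")) for rid, row in aln.rows]
        db += [SequenceRecord("dup_" + db[0].id, db[0].seq)]
        hits = search(prof, db, evalue_cutoff=0.01)
        realigned = align_to_profile(prof, hits)
        assert realigned.n_cols == prof.M
        rows = dict(realigned.rows)
        r1 = next(v for k, v in rows.items() if k.startswith(db[0].id))
        r2 = next(v for k, v in rows.items() if k.startswith("dup_"))
        assert r1 == r2

    def test_round_trip_profile_scores_stable(self, rng):
        """Rebuilding a profile from its own realigned hits changes
        self-search scores by < 5%."""
        _c, aln, prof = _family_profile(rng)
        db = [SequenceRecord(rid, row.replace("-", "")) for rid, row in aln.rows]
        hits = search(prof, db, evalue_cutoff=0.01)
        rebuilt = build_profile(align_to_profile(prof, hits), name="fam2")
        for rec in db:
            s1 = viterbi_score(prof, rec.seq)
            s2 = viterbi_score(rebuilt, rec.seq)
            assert abs(s2 - s1) <= 0.05 * abs(s1)

    def test_foreign_hit_rejected(self, rng, tiny_profile):
        _c, aln, prof = _family_profile(rng)
        db = [SequenceRecord(rid, row.replace("-", "")) for rid, row in aln.rows]
        hits = search(prof, db, evalue_cutoff=0.01)
        from ephscan.profilehmm import ConsistencyError

        with pytest.raises(ConsistencyError):
            align_to_profile(tiny_profile, hits)


class TestTrimAlignment:
    def test_zero_threshold_is_identity(self, tiny_alignment):
        assert trim_alignment(tiny_alignment, 0.0).rows == tiny_alignment.rows

    def test_sparse_column_removed_and_idempotent(self):
        rows = tuple(
            (f"s{i}", ("A" if i == 0 else "-") + "CDE") for i in range(10)
        )
        aln = Alignment(rows)
        t1 = trim_alignment(aln, 0.5)
        assert t1.n_cols == 3
        assert trim_alignment(t1, 0.5).rows == t1.rows

    def test_all_columns_removed_rejected(self, tiny_alignment):
        aln = Alignment((("a", "A--"), ("b", "-C-"), ("c", "--D")))
        with pytest.raises(DegenerateModelError):
            trim_alignment(aln, 0.9)


def test_profile_json_round_trip(tiny_profile):
    calibrate(tiny_profile, n_random=100, length=50, seed=2)
    clone = profile_from_json(profile_to_json(tiny_profile))
    assert clone.name == tiny_profile.name
    assert np.allclose(clone.match_emissions, tiny_profile.match_emissions)
    assert clone.calibration == tiny_profile.calibration
    assert viterbi_score(clone, "ACDEF") == viterbi_score(tiny_profile, "ACDEF")
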