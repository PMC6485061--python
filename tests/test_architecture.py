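"""Overlap resolution, CRD annotation, and the classification grammar."""

import numpy as np
import pytest

from oracles import resolve_overlaps_oracle
from ephscan.architecture import (
    annotate_crd,
    check_conserved_cysteines,
    classify,
    count_matrix,
    resolve_overlaps,
)
from ephscan.profilehmm import Alignment, DomainHit
from ephscan.synthdata import FamilySpec, evolve_member, make_consensus


def _hit(profile, start, end, ev=1e-6, bits=50.0, target="p1"):
    return DomainHit(
        profile=profile,
        target=target,
        start=start,
        end=end,
        bits=bits,
        evalue=ev,
        row="",
        match_map={},
    )


class TestResolveOverlaps:
    def test_disjoint_hits_both_kept(self):
        hits = [_hit("LBD", 1, 100), _hit("fn3", 150, 240)]
        assert len(resolve_overlaps(hits)) == 2

    def test_identical_interval_keeps_lower_evalue(self):
        a = _hit("LBD", 1, 100, ev=1e-10)
        b = _hit("fn3", 1, 100, ev=1e-3)
        kept = resolve_overlaps([b, a])
        assert kept == [a]

    def test_matches_brute_force_priority_oracle(self, rng):
        for _ in range(30):
            hits = []
            for k in range(int(rng.integers(2, 6))):
                s = int(rng.integers(1, 300))
                e = s + int(rng.integers(20, 120))
                hits.append(
                    _hit(f"d{k}", s, e, ev=float(rng.uniform(1e-12, 1e-2)),
                         bits=float(rng.uniform(10, 90)))
                )
            assert resolve_overlaps(hits) == resolve_overlaps_oracle(hits)


class TestAnnotateCRD:
    def test_wide_gap_becomes_crd(self):
        hits = [_hit("LBD", 1, 180), _hit("fn3", 300, 390)]
        assert annotate_crd(hits, 500) == (181, 299)

    def test_narrow_gap_absent(self):
        hits = [_hit("LBD", 1, 180), _hit("fn3", 191, 280)]
        assert annotate_crd(hits, 400) is None

    def test_no_lbd_absent(self):
        assert annotate_crd([_hit("fn3", 300, 390)], 500) is None


def _arch_hits(spec):
    """spec: list of (label, start, end)"""
    return [_hit(lab, s, e, ev=1e-8) for lab, s, e in spec]


class TestClassify:
    def test_canonical_full_receptor(self):
        hits = _arch_hits(
            [("LBD", 30, 210), ("fn3", 260, 350), ("fn3", 360, 450),
             ("kinase", 520, 770), ("SAM", 790, 850)]
        )
        call = classify("p", hits, 900, tm_segments=[(470, 492)])
        assert call.class_label == "EPH_FULL"
        assert call.crd == (211, 259)

    def test_proto_receptor_without_lbd(self):
        hits = _arch_hits([("fn3", 30, 120), ("kinase", 200, 450)])
        call = classify("p", hits, 500, tm_segments=[(140, 165)])
        assert call.class_label == "PROTO_EPH_LIKE"

    def test_partial_receptor_missing_kinase(self):
        hits = _arch_hits([("LBD", 25, 200), ("fn3", 230, 320)])
        assert classify("p", hits, 400).class_label == "EPH_PARTIAL"

    def test_ephrin_and_cupredoxin_and_other(self):
        rbd = _arch_hits([("ephrin_RBD", 20, 160)])
        assert classify("p", rbd, 200).class_label == "EPHRIN"
        cu = _arch_hits([("cupredoxin", 20, 150)])
        assert classify("p", cu, 200, copper_competent=True).class_label == "CUPREDOXIN"
        assert classify("p", cu, 200, copper_competent=False).class_label == "OTHER"
        assert classify("p", [], 200).class_label == "OTHER"

    def test_lbd_not_nterminal_is_partial(self):
        hits = _arch_hits([("kinase", 30, 280), ("LBD", 400, 580)])
        assert classify("p", hits, 600).class_label == "EPH_PARTIAL"

    def test_order_invariance(self, rng):
        hits = _arch_hits(
            [("LBD", 30, 210), ("fn3", 260, 350), ("kinase", 520, 770)]
        )
        labels = set()
        for _ in range(5):
            perm = list(hits)
            rng.shuffle(perm)
            labels.add(classify("p", perm, 800).class_label)
        assert labels == {"EPH_FULL"}


class TestCountMatrix:
    def test_empty_input_all_zero(self):
        mat = count_matrix([], {"p1": "cnidaria"})
        assert (mat.to_numpy() == 0).all()

    def test_total_equals_non_other_calls(self):
        calls = [
            classify("p1", _arch_hits([("ephrin_RBD", 20, 160)]), 200),
            classify("p2", _arch_hits([("LBD", 20, 180)]), 400),
            classify("p3", [], 300),
        ]
        lmap = {"p1": "a", "p2": "a", "p3": "b"}
        mat = count_matrix(calls, lmap)
        assert mat.to_numpy().sum() == 2

    def test_missing_lineage_rejected(self):
        calls = [classify("p1", _arch_hits([("ephrin_RBD", 20, 160)]), 200)]
        with pytest.raises(KeyError):
            count_matrix(calls, {"other": "a"})


class TestConservedCysteines:
    PAIRS = [(10, 25), (40, 55)]

    def _family_alignment(self, divergence=0.3, n=12):
        fixed = {c: "C" for pair in self.PAIRS for c in pair}
        cons = make_consensus("fam", 60, seed=3)
        rows = tuple(
            (f"m{i}", evolve_member(cons, divergence, 0.0, seed=i, fixed_sites=fixed).seq)
            for i in range(n)
        )
        return Alignment(rows)

    def test_reference_passes_all_pairs(self):
        aln = self._family_alignment(divergence=0.0, n=2)
        df = check_conserved_cysteines(aln, self.PAIRS)
        assert df["all_pairs"].all()

    def test_single_substitution_fails_only_that_pair(self):
        aln = self._family_alignment(divergence=0.0, n=1)
        rid, row = aln.rows[0]
        mutated = row[:10] + "S" + row[11:]
        df = check_conserved_cysteines(Alignment(((rid, mutated),)), self.PAIRS)
        assert not df.loc[rid, "pair_11_26"]
        assert df.loc[rid, "pair_41_56"]

    def test_generator_holds_bridges_under_divergence(self):
        df = check_conserved_cysteines(self._family_alignment(0.3), self.PAIRS)
        assert df["all_pairs"].all()

    def test_out_of_range_column_rejected(self):
        aln = self._family_alignment(0.0, n=2)
        with pytest.raises(ValueError):
            check_conserved_cysteines(aln, [(10, 400)])
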