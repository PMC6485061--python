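"""Generator contracts: determinism, identity calibration, planted signals."""

import numpy as np
import pytest

from ephscan.anchoring import call_gpi, hydropathy_profile, predict_gpi_charge, predict_gpi_omega
from ephscan.seqs import random_background_seq
from ephscan.synthdata import (
    FamilySpec,
    InvalidSpecError,
    PanelSpec,
    assemble_panel,
    classify_tokens,
    evolve_member,
    make_consensus,
    plant_gpi_signal,
    plant_tm,
    specs_from_json,
    specs_to_json,
)


class TestMakeConsensus:
    def test_deterministic_under_fixed_seed(self):
        a = make_consensus("LBD", 180, seed=1)
        b = make_consensus("LBD", 180, seed=1)
        assert a.seq == b.seq

    def test_different_seeds_differ(self):
        a = make_consensus("LBD", 180, seed=1)
        b = make_consensus("LBD", 180, seed=2)
        assert sum(x != y for x, y in zip(a.seq, b.seq)) > 0

    def test_short_length_rejected(self):
        with pytest.raises(InvalidSpecError):
            make_consensus("LBD", 10, seed=1)


class TestEvolveMember:
    def test_zero_divergence_is_identity(self):
        cons = make_consensus("f", 60, seed=3)
        assert evolve_member(cons, 0.0, 0.0, seed=9).seq == cons.seq

    def test_identity_calibration_matches_binomial_expectation(self):
        """Mean identity over replicates is 1 - divergence within 3 SE."""
        cons = make_consensus("f", 1000, seed=5)
        div, n_rep = 0.3, 100
        idents = []
        for k in range(n_rep):
            m = evolve_member(cons, div, 0.0, seed=k)
            idents.append(np.mean([a == b for a, b in zip(m.seq, cons.seq)]))
        se = np.sqrt(div * (1 - div) / 1000) / np.sqrt(n_rep)
        assert abs(np.mean(idents) - (1 - div)) < 3 * se

    def test_extreme_divergence_near_background_identity(self):
        cons = make_consensus("f", 1000, seed=6)
        m = evolve_member(cons, 0.94, 0.0, seed=1)
        ident = np.mean([a == b for a, b in zip(m.seq, cons.seq)])
        assert 0.0 < ident < 0.15

    def test_fixed_sites_held_invariant(self):
        cons = make_consensus("f", 100, seed=7)
        m = evolve_member(cons, 0.9, 0.0, seed=2, fixed_sites={10: "C", 50: "H"})
        assert m.seq[10] == "C" and m.seq[50] == "H"


class TestPlantTM:
    def test_c_terminal_window_hydropathy_and_position(self, rng):
        base = random_background_seq(200, rng)
        rec, (s, e) = plant_tm(base, "c_terminal", seed=4)
        window = rec.seq[s - 1 : e]
        assert len(window) == 21
        kd = hydropathy_profile(window, 21)
        assert kd[len(window) // 2] >= 1.6
        assert len(rec.seq) - e <= 40

    def test_internal_placement_far_from_terminus(self, rng):
        base = random_background_seq(200, rng)
        rec, (_s, e) = plant_tm(base, "internal", seed=4)
        assert len(rec.seq) - e >= 60

    def test_short_sequence_rejected(self):
        with pytest.raises(InvalidSpecError):
            plant_tm("ACDEFGHIKL", "c_terminal")


class TestPlantGPI:
    def test_signal_passes_both_heuristics(self, rng):
        base = random_background_seq(180, rng)
        rec, omega = plant_gpi_signal(base, seed=8)
        assert predict_gpi_omega(rec.seq) == omega
        assert predict_gpi_charge(rec.seq)
        assert call_gpi(rec.seq) == (True, omega)

    def test_stacks_with_planted_tm(self, rng):
        base = random_background_seq(180, rng)
        with_tm, (s, e) = plant_tm(base, "c_terminal", seed=1)
        rec, omega = plant_gpi_signal(with_tm, seed=2)
        assert rec.seq[s - 1 : e] == with_tm.seq[s - 1 : e]
        assert call_gpi(rec.seq)[0]

    def test_empty_input_yields_bare_signal(self):
        rec, omega = plant_gpi_signal("", seed=1)
        assert len(rec.seq) == 15 and omega == 1


def _panel(frag=0.0, decoys=0, seed=5):
    fams = [
        FamilySpec("LBD", 60, 2, 0.1, seed=1),
        FamilySpec("kinase", 60, 2, 0.1, seed=2),
    ]
    spec = PanelSpec(
        lineages=("a", "b"),
        architectures_per_lineage={
            "a": [("LBD kinase", 3, 0.1)],
            "b": [("LBD", 2, 0.1)],
        },
        fragment_fraction=frag,
        decoy_count=decoys,
        seed=seed,
    )
    return spec, fams


class TestAssemblePanel:
    def test_count_conservation(self):
        spec, fams = _panel(decoys=4)
        records, truth = assemble_panel(spec, fams)
        assert sum(len(v) for v in records.values()) == 3 + 2 + 4 == len(truth)

    def test_full_fragmentation_drops_a_domain_everywhere(self):
        spec, fams = _panel(frag=1.0)
        _records, truth = assemble_panel(spec, fams)
        multi = truth[truth.protein_id.str.startswith("a_")]
        for _, row in multi.iterrows():
            assert len(row["architecture"].split()) < 2

    def test_decoy_count_exact(self):
        spec, fams = _panel(decoys=7)
        _records, truth = assemble_panel(spec, fams)
        assert (truth["true_class"] == "decoy").sum() == 7

    def test_byte_identical_determinism(self):
        spec, fams = _panel(decoys=3)
        r1, t1 = assemble_panel(spec, fams)
        r2, t2 = assemble_panel(spec, fams)
        assert {k: [(x.id, x.seq) for x in v] for k, v in r1.items()} == {
            k: [(x.id, x.seq) for x in v] for k, v in r2.items()
        }
        assert t1.equals(t2)

    def test_unresolvable_token_rejected(self):
        spec, fams = _panel()
        bad = PanelSpec(
            lineages=("a",),
            architectures_per_lineage={"a": [("LBD nosuch", 1, 0.1)]},
            seed=1,
        )
        with pytest.raises(InvalidSpecError):
            assemble_panel(bad, fams)

    def test_spec_json_round_trip(self):
        spec, fams = _panel(decoys=2)
        p2, f2 = specs_from_json(specs_to_json(spec, fams))
        assert p2 == spec and f2 == fams


@pytest.mark.parametrize(
    "tokens, expected",
    [
        (["LBD", "fn3", "fn3", "TM", "kinase", "SAM"], "EPH_FULL"),
        (["fn3", "TM", "kinase"], "PROTO_EPH_LIKE"),
        (["LBD", "fn3"], "EPH_PARTIAL"),
        (["ephrin_RBD", "GPI"], "EPHRIN"),
        (["COPPER+"], "CUPREDOXIN"),
        (["COPPER-"], "OTHER"),
        (["kinase"], "OTHER"),
    ],
)
def test_truth_grammar(tokens, expected):
    assert classify_tokens(tokens) == expected
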