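"""Standard synthetic study panels.

These definitions fix the study conditions used throughout the test-suite
and the acceptance script: the six domain families of the Eph/ephrin system
(with invariant disulfide-bridge cysteines and copper-site residues), panels
of full-length/partial/proto receptors, ephrins of all four anchoring
subtypes, cupredoxins with intact or lost copper centres, decoy proteins,
and the tiered-divergence database used to exercise iterative search.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ephscan.profilehmm import Alignment
from ephscan.seqs import SequenceRecord, random_background_seq, write_fasta
from ephscan.synthdata import (
    DEFAULT_COPPER_SITES,
    COPPER_INTACT,
    FamilySpec,
    PanelSpec,
    assemble_panel,
    evolve_member,
    evolve_member_exact,
    make_consensus,
    make_seed_alignment,
    write_panel,
)

#: disulfide-bridge cysteine pairs, 0-based consensus columns
#: (receptor LBD: the C105-C115 / C70-C188 pattern folded into a 180-residue
#: consensus; ephrin RBD: C51-C92 / C80-C140 on a 140-residue consensus)
LBD_BRIDGE_PAIRS = ((104, 114), (69, 174))
RBD_BRIDGE_PAIRS = ((50, 91), (79, 139))

SEED_MEMBERS = 8
SEED_DIVERGENCE = 0.15


def default_families(seed: int = 11) -> list[FamilySpec]:
    """The six domain families with invariant structural sites."""
    lbd_fixed = {c: "C" for pair in LBD_BRIDGE_PAIRS for c in pair}
    rbd_fixed = {c: "C" for pair in RBD_BRIDGE_PAIRS for c in pair}
    cu_fixed = {DEFAULT_COPPER_SITES[k]: v for k, v in COPPER_INTACT.items()}
    return [
        FamilySpec("LBD", 180, SEED_MEMBERS, SEED_DIVERGENCE, seed=seed + 1,
                   fixed_sites=lbd_fixed),
        FamilySpec("fn3", 95, SEED_MEMBERS, SEED_DIVERGENCE, seed=seed + 2),
        FamilySpec("kinase", 250, SEED_MEMBERS, SEED_DIVERGENCE, seed=seed + 3),
        FamilySpec("SAM", 65, SEED_MEMBERS, SEED_DIVERGENCE, seed=seed + 4),
        FamilySpec("ephrin_RBD", 140, SEED_MEMBERS, SEED_DIVERGENCE, seed=seed + 5,
                   fixed_sites=rbd_fixed),
        FamilySpec("cupredoxin", 130, SEED_MEMBERS, SEED_DIVERGENCE, seed=seed + 6,
                   fixed_sites=cu_fixed),
    ]


RECEPTOR_FULL = "LBD fn3 fn3 TM kinase SAM"
RECEPTOR_PARTIAL = "LBD fn3"
RECEPTOR_PROTO = "fn3 TM kinase"
EPHRIN_B = "ephrin_RBD TM"
EPHRIN_A = "ephrin_RBD GPI"
EPHRIN_DUAL = "ephrin_RBD TM GPI"
EPHRIN_UNANCHORED = "ephrin_RBD"
CUPREDOXIN_PLUS = "COPPER+"
CUPREDOXIN_MINUS = "COPPER-"


def classification_panel(
    divergence: float = 0.0,
    fragment_fraction: float = 0.0,
    seed: int = 29,
    decoys: int = 12,
) -> PanelSpec:
    """Three-lineage panel covering every class of the grammar."""
    def archs(n_full, n_partial, n_proto, n_b, n_a, n_dual, n_un, n_cu_p, n_cu_m):
        out = []
        for arch, n in [
            (RECEPTOR_FULL, n_full), (RECEPTOR_PARTIAL, n_partial),
            (RECEPTOR_PROTO, n_proto), (EPHRIN_B, n_b), (EPHRIN_A, n_a),
            (EPHRIN_DUAL, n_dual), (EPHRIN_UNANCHORED, n_un),
            (CUPREDOXIN_PLUS, n_cu_p), (CUPREDOXIN_MINUS, n_cu_m),
        ]:
            if n:
                out.append((arch, n, divergence))
        return out

    return PanelSpec(
        lineages=("cnidaria", "porifera", "ctenophora"),
        architectures_per_lineage={
            "cnidaria": archs(3, 1, 1, 3, 1, 0, 1, 1, 1),
            "porifera": archs(2, 1, 1, 1, 1, 2, 1, 1, 1),
            "ctenophora": archs(1, 1, 0, 0, 1, 0, 1, 1, 0),
        },
        fragment_fraction=fragment_fraction,
        decoy_count=decoys,
        seed=seed,
    )


def anchoring_panel(divergence: float = 0.0, seed: int = 31) -> PanelSpec:
    """Ephrin-only panel with all four anchoring subtypes planted."""
    archs = [
        (EPHRIN_B, 6, divergence),
        (EPHRIN_A, 6, divergence),
        (EPHRIN_DUAL, 6, divergence),
        (EPHRIN_UNANCHORED, 6, divergence),
    ]
    return PanelSpec(
        lineages=("cnidaria", "porifera"),
        architectures_per_lineage={"cnidaria": archs, "porifera": archs},
        fragment_fraction=0.0,
        decoy_count=0,
        seed=seed,
    )


def tiered_database(
    seed: int,
    family: FamilySpec | None = None,
    members_per_tier: int = 12,
    decoys: int = 200,
) -> tuple[Alignment, list[SequenceRecord], dict[str, str]]:
    """Seed alignment plus a database of homolog tiers at exactly 60/40/25%
    identity to the family consensus, embedded in linker context, with
    background decoys. Returns (seed alignment, database, target -> tier
    map). Tier members are planted at the stated identity exactly (fixed
    substitution count) so each tier is homogeneous."""
    fam = family or FamilySpec("LBD", 180, SEED_MEMBERS, 0.10, seed=11)
    seed_aln = Alignment(tuple(make_seed_alignment(fam)))
    cons = make_consensus(fam.family_name, fam.consensus_length, fam.seed)
    rng = np.random.default_rng(seed)
    db: list[SequenceRecord] = []
    tiers: dict[str, str] = {}
    for div, tier in [(0.40, "id60"), (0.60, "id40"), (0.75, "id25")]:
        for k in range(members_per_tier):
            m = evolve_member_exact(cons, div, 0.01, seed=int(rng.integers(2**31)))
            seq = (
                random_background_seq(60, rng)
                + m.seq
                + random_background_seq(60, rng)
            )
            pid = f"{tier}_{k}"
            db.append(SequenceRecord(pid, seq))
            tiers[pid] = tier
    for d in range(decoys):
        db.append(
            SequenceRecord(
                f"decoy_{d}",
                random_background_seq(int(rng.integers(250, 450)), rng),
            )
        )
    return seed_aln, db, tiers


def expansion_panel(seed: int = 47) -> tuple[dict, "object", dict[str, str]]:
    """Panel mirroring the demosponge observation: one lineage carries three
    distinct LBD subfamilies but a single kinase family.

    Returns (records per lineage, truth table, lineage map).
    """
    rng = np.random.default_rng(seed)
    lineages = {"porifera": [], "cnidaria": [], "bilateria": []}
    lineage_map: dict[str, str] = {}
    kin_cons = make_consensus("kinase", 250, 77)
    sub_cons = [make_consensus(f"LBD_sub{i}", 180, 200 + i) for i in range(3)]

    def protein(pid, lin, lbd_cons, lbd_div, kin_div):
        lbd = evolve_member(lbd_cons, lbd_div, 0.0, seed=int(rng.integers(2**31)))
        kin = evolve_member(kin_cons, kin_div, 0.0, seed=int(rng.integers(2**31)))
        seq = (
            random_background_seq(25, rng)
            + lbd.seq
            + random_background_seq(40, rng)
            + kin.seq
            + random_background_seq(20, rng)
        )
        lineages[lin].append(SequenceRecord(pid, seq, lineage=lin))
        lineage_map[pid] = lin

    # porifera: 3 members of each LBD subfamily, all kinases from one family
    for i in range(3):
        for k in range(3):
            protein(f"por_s{i}_{k}", "porifera", sub_cons[i], 0.10, 0.10)
    # other lineages: one member per subfamily, deeper divergence, so each
    # porifera subfamily triple forms its own pure clade
    for lin, base in [("cnidaria", 0.35), ("bilateria", 0.45)]:
        for i in range(3):
            protein(f"{lin}_s{i}", lin, sub_cons[i], base, base)
    return lineages, None, lineage_map


def write_run_inputs(
    outdir: str | Path,
    panel: PanelSpec,
    families: list[FamilySpec],
    rounds: int = 1,
    master_seed: int = 17,
) -> Path:
    """Materialise a panel + per-family seed alignments + run-config JSON;
    returns the config path (everything under ``outdir``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = assemble_panel(panel, families)
    write_panel(records, truth, outdir / "panel")
    seed_paths = {}
    cu_reference = None
    for fam in families:
        aln = Alignment(tuple(make_seed_alignment(fam)))
        p = outdir / f"seed_{fam.family_name}.afa"
        aln.to_fasta(p)
        seed_paths[fam.family_name] = str(p)
        if fam.family_name == "cupredoxin":
            cu_reference = {
                "family": "cupredoxin",
                "reference_id": aln.rows[0][0],
                # seed rows are ungapped: residue number = consensus index + 1
                "annotations": {
                    name: idx + 1 for name, idx in DEFAULT_COPPER_SITES.items()
                },
            }
    config = {
        "seed_alignments": seed_paths,
        "inputs": {
            lin: str(outdir / "panel" / f"{lin}.fasta") for lin in panel.lineages
        },
        "output_dir": str(outdir / "out"),
        "rounds": rounds,
        "master_seed": master_seed,
    }
    if cu_reference:
        config["copper_reference"] = cu_reference
    cfg_path = outdir / "run.json"
    cfg_path.write_text(json.dumps(config, indent=2))
    return cfg_path
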