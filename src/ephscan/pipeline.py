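"""End-to-end orchestration: ORF extraction, per-family iterative searches,
architecture/anchoring/copper classification, count matrices, domain trees,
and a reproducible run report.

All randomness derives from one master seed; per-family calibration streams
are seeded from the master seed combined with a CRC of the family name, so
families are independent but every run with the same configuration is
byte-identical in its primary outputs (timings go to a separate file).
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ephscan import architecture as arch
from ephscan import phylo
from ephscan.anchoring import call_anchoring
from ephscan.copper import classify_copper_site, map_reference_columns
from ephscan.itersearch import iterative_search
from ephscan.profilehmm import (
    Alignment,
    DomainHit,
    build_profile,
    hits_to_tsv,
    profile_to_json,
    search,
    viterbi,
)
from ephscan.seqs import SequenceRecord, read_fasta

IUPAC_NT = set("ACGTUNRYSWKMBDHV")

#: domain families whose trees are compared for lineage expansions
TREE_FAMILIES = ("LBD", "kinase", "ephrin_RBD")


class AlphabetError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    seed_alignments: dict[str, str]  # family -> aligned FASTA path
    inputs: dict[str, str]  # lineage -> protein FASTA path
    output_dir: str
    rounds: int = 2
    evalue_cutoff: float = 0.01
    dedupe_threshold: float = 0.9
    min_clade_size: int = 3
    master_seed: int = 17
    n_calibration: int = 200
    copper_reference: dict | None = None  # {"family","reference_id","annotations"}

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        return cls(**doc)

    def validate(self) -> None:
        for p in list(self.seed_alignments.values()) + list(self.inputs.values()):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if not (0 < self.evalue_cutoff):
            raise ValueError("evalue_cutoff must be positive")


def _family_seed(master_seed: int, family: str) -> int:
    crc = zlib.crc32(family.encode())
    ss = np.random.SeedSequence([master_seed, crc])
    return int(np.random.default_rng(ss).integers(2**31))


def extract_orfs(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], list[str]]:
    """Six-frame translation; per record, the single longest stop-to-stop
    translated segment (ties: lowest frame index, then 5'-most position).

    Records whose every frame is stop-riddled down to the empty string are
    skipped with a warning.
    """
    proteins = []
    warned = []
    for rec in records:
        nt = rec.seq.upper().replace("U", "T")
        bad = set(nt) - IUPAC_NT
        if bad:
            raise AlphabetError(
                f"{rec.id}: non-nucleotide symbols {sorted(bad)!r}"
            )
        frames: list[str] = []
        rc = str(Seq(nt).reverse_complement())
        for strand_seq in (nt, rc):
            for off in (0, 1, 2):
                sub = strand_seq[off:]
                sub = sub[: len(sub) - len(sub) % 3]
                frames.append(str(Seq(sub).translate()) if sub else "")
        best: tuple[int, int, str] | None = None  # (-len, frame, segment)
        for f, tr in enumerate(frames):
            pos = 0
            for seg in tr.split("*"):
                if seg and (
                    best is None
                    or (-len(seg), f, pos) < (best[0], best[1], best[2])
                ):
                    best = (-len(seg), f, pos)
                    best_seg = seg
                pos += len(seg) + 1
        if best is None:
            warned.append(f"{rec.id}: no open reading frame")
            continue
        proteins.append(
            dataclasses.replace(rec, id=f"{rec.id}_orf", seq=best_seg)
        )
    return proteins, warned


def _copper_map_and_profile(config: RunConfig):
    ref = config.copper_reference
    if not ref:
        return None, None
    family = ref.get("family", "cupredoxin")
    aln = Alignment.from_fasta(config.seed_alignments[family])
    profile = build_profile(
        aln,
        pseudocount_weight=max(1.0, float(aln.n_rows)),
        name=family,
    )
    cmap = map_reference_columns(
        profile, aln, ref["reference_id"], {k: int(v) for k, v in ref["annotations"].items()}
    )
    return cmap, profile


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all outputs under config.output_dir.

    Returns the run report as a dict (also written as report.json).
    """
    config.validate()
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings_log: list[str] = []

    # load inputs
    database: list[SequenceRecord] = []
    lineage_map: dict[str, str] = {}
    for lineage in sorted(config.inputs):
        recs = read_fasta(config.inputs[lineage], lineage=lineage)
        database.extend(recs)
        for r in recs:
            lineage_map[r.id] = lineage
    seq_by_id = {r.id: r.seq for r in database}
    timings["load"] = time.time() - t_start

    # per-family iterative search; final hits from the last-round profile
    family_states = {}
    hits_by_protein: dict[str, list[DomainHit]] = {pid: [] for pid in seq_by_id}
    all_final_hits: dict[str, list[DomainHit]] = {}
    search_logs = {}
    for family in sorted(config.seed_alignments):
        t0 = time.time()
        seed_aln = Alignment.from_fasta(config.seed_alignments[family])
        state = iterative_search(
            seed_aln,
            database,
            rounds=config.rounds,
            evalue_cutoff=config.evalue_cutoff,
            dedupe_threshold=config.dedupe_threshold,
            seed=_family_seed(config.master_seed, family),
            name=family,
            n_calibration=config.n_calibration,
        )
        final_hits = search(state.profile, database, config.evalue_cutoff)
        family_states[family] = state
        all_final_hits[family] = final_hits
        search_logs[family] = state.log
        for h in final_hits:
            hits_by_protein[h.target].append(h)
        hits_to_tsv(final_hits, outdir / f"hits_{family}.tsv")
        (outdir / f"profile_{family}.json").write_text(
            profile_to_json(state.profile)
        )
        timings[f"search_{family}"] = time.time() - t0

    # anchoring
    t0 = time.time()
    anchoring_calls = {
        pid: call_anchoring(pid, seq_by_id[pid]) for pid in sorted(seq_by_id)
    }
    pd.DataFrame(
        [
            {
                "protein_id": a.protein_id,
                "tm_segments": ";".join(f"{s}-{e}" for s, e, _v in a.tm_segments),
                "votes": ";".join(str(v) for _s, _e, v in a.tm_segments),
                "c_terminal_tm": a.c_terminal_tm,
                "gpi": a.gpi,
                "omega_pos": a.omega_pos if a.omega_pos else "",
                "subtype": a.subtype,
            }
            for a in anchoring_calls.values()
        ]
    ).to_csv(outdir / "anchoring.tsv", sep="\t", index=False)
    timings["anchoring"] = time.time() - t0

    # copper verdicts for every protein with a cupredoxin-fold hit; rows come
    # from the seed-built profile so the reference-column map stays valid
    t0 = time.time()
    copper_verdicts: dict[str, str] = {}
    cmap, seed_cu_profile = _copper_map_and_profile(config)
    if cmap is not None:
        cu_family = config.copper_reference.get("family", "cupredoxin")
        targets = sorted({h.target for h in all_final_hits.get(cu_family, [])})
        calls = []
        for pid in targets:
            bits, path = viterbi(seed_cu_profile, seq_by_id[pid])
            match_map = {j: i for st, j, i in path if st == "M"}
            row = "".join(
                seq_by_id[pid][match_map[j]] if j in match_map else "-"
                for j in range(seed_cu_profile.M)
            )
            positions = sorted(match_map.values())
            hit = DomainHit(
                profile=cu_family,
                target=pid,
                start=positions[0] + 1,
                end=positions[-1] + 1,
                bits=bits,
                evalue=0.0,
                row=row,
                match_map=match_map,
            )
            calls.append(classify_copper_site(hit, cmap))
        copper_verdicts = {c.protein_id: c.verdict for c in calls}
        from ephscan.copper import copper_calls_to_frame

        copper_calls_to_frame(calls).to_csv(
            outdir / "copper.tsv", sep="\t", index=False
        )
    timings["copper"] = time.time() - t0

    # architecture classification
    t0 = time.time()
    calls = []
    for pid in sorted(seq_by_id):
        a = anchoring_calls[pid]
        verdict = copper_verdicts.get(pid)
        calls.append(
            arch.classify(
                pid,
                hits_by_protein[pid],
                len(seq_by_id[pid]),
                tm_segments=[(s, e) for s, e, _v in a.tm_segments],
                copper_competent=(verdict == "COPPER_COMPETENT")
                if verdict is not None
                else None,
            )
        )
    pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "architecture": ";".join(
                    f"{lab}:{s}-{e}" for lab, s, e, _ev in c.domains
                ),
                "crd": f"{c.crd[0]}-{c.crd[1]}" if c.crd else "",
                "class": c.class_label,
            }
            for c in calls
        ]
    ).to_csv(outdir / "architecture.tsv", sep="\t", index=False)
    matrix = arch.count_matrix(calls, lineage_map)
    matrix.to_csv(outdir / "count_matrix.tsv", sep="\t")
    timings["architecture"] = time.time() - t0

    # domain trees and lineage expansions
    t0 = time.time()
    trees = {}
    expansions_rows = []
    for family in TREE_FAMILIES:
        hits = all_final_hits.get(family, [])
        # one leaf per protein: the best (lowest-E) hit of that family
        best_per_target: dict[str, DomainHit] = {}
        for h in hits:
            cur = best_per_target.get(h.target)
            if cur is None or (h.evalue, h.start) < (cur.evalue, cur.start):
                best_per_target[h.target] = h
        if len(best_per_target) < 3:
            warnings_log.append(f"tree skipped for {family}: <3 hits")
            continue
        rows = tuple(
            (pid, best_per_target[pid].row) for pid in sorted(best_per_target)
        )
        aln = Alignment(rows)
        try:
            dm = phylo.distance_matrix(aln)
        except phylo.UndefinedDistanceError:
            warnings_log.append(f"tree skipped for {family}: undefined distance")
            continue
        tree = phylo.nj_tree(dm)
        trees[family] = tree
        (outdir / f"tree_{family}.nwk").write_text(phylo.to_newick(tree))
        for lin, clade in phylo.detect_expansions(
            tree, lineage_map, config.min_clade_size
        ):
            expansions_rows.append(
                {"family": family, "lineage": lin, "size": len(clade),
                 "leaves": ";".join(clade)}
            )
    pd.DataFrame(
        expansions_rows, columns=["family", "lineage", "size", "leaves"]
    ).to_csv(outdir / "expansions.tsv", sep="\t", index=False)

    contrast = None
    if "LBD" in trees and "kinase" in trees:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            contrast = phylo.compare_domain_trees(
                trees["LBD"],
                trees["kinase"],
                lineage_map,
                min_clade_size=config.min_clade_size,
            )
        contrast.to_csv(outdir / "domain_tree_contrast.tsv", sep="\t")
    timings["phylo"] = time.time() - t0

    report = {
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
        },
        "n_proteins": len(database),
        "per_family_rounds": search_logs,
        "class_counts": {
            c: int(sum(1 for call in calls if call.class_label == c))
            for c in arch.CLASSES
        },
        "warnings": warnings_log,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "timings.json").write_text(json.dumps(timings, indent=2))
    return report
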