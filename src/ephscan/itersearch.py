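"""Iterative profile search with redundancy removal.

Round 0 searches the database with a profile built from the seed alignment;
each subsequent round aligns newly accepted hit envelopes back onto the
profile, merges them into the alignment, rebuilds and recalibrates, and
searches again. Two rebuild rounds at E <= 0.01 are the defaults. Redundancy
is removed by greedy incremental identity clustering (longest-first, join the
first representative above the identity threshold), the same scheme used by
CD-HIT-style tools.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from Bio import Align

from ephscan.profilehmm import (
    Alignment,
    DomainHit,
    ProfileHMM,
    align_to_profile,
    build_profile,
    calibrate,
    search,
)
from ephscan.seqs import SequenceRecord


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -1.0
    return a


def pairwise_identity(a: str, b: str) -> float:
    """Identity of the optimal global alignment (match 1, mismatch 0,
    linear gap -1): matches / alignment length. Symmetric in its arguments."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


@dataclasses.dataclass(frozen=True)
class ClusterSet:
    """Greedy identity clusters; each representative is its cluster's longest
    member (ties broken by id)."""

    clusters: tuple[tuple[str, tuple[str, ...]], ...]
    identity_threshold: float

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]


def dedupe(sequences: list[SequenceRecord], identity_threshold: float) -> ClusterSet:
    """Greedy incremental clustering: sort by length descending; each sequence
    joins the first existing representative with identity >= threshold, else
    founds a new cluster."""
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must lie in (0, 1]")
    order = sorted(sequences, key=lambda r: (-len(r.seq), r.id))
    reps: list[SequenceRecord] = []
    members: list[list[str]] = []
    for rec in order:
        for k, rep in enumerate(reps):
            if pairwise_identity(rec.seq, rep.seq) >= identity_threshold:
                members[k].append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([])
    return ClusterSet(
        clusters=tuple(
            (rep.id, tuple(ms)) for rep, ms in zip(reps, members)
        ),
        identity_threshold=identity_threshold,
    )


@dataclasses.dataclass
class IterationState:
    """State of the iterative search after a given round (round 0 = seed)."""

    round_index: int
    profile: ProfileHMM
    accepted: dict[tuple[str, int, int], DomainHit]
    alignment: Alignment
    log: list[dict]
    #: accepted-hit keys already merged into (or judged redundant with) the alignment
    merged_keys: set[tuple[str, int, int]] = dataclasses.field(default_factory=set)

    @property
    def accepted_targets(self) -> set[str]:
        return {h.target for h in self.accepted.values()}


def _hit_key(h: DomainHit) -> tuple[str, int, int]:
    return (h.target, h.start, h.end)


def _project(alignment: Alignment, match_columns: tuple[int, ...]) -> Alignment:
    """Restrict an alignment to the profile's match columns so merged hit rows
    (one column per match state) stay width-consistent."""
    rows = tuple(
        (rid, "".join(row[c] for c in match_columns)) for rid, row in alignment.rows
    )
    return Alignment(rows)


def _accept(accepted: dict, new_hits: list[DomainHit]) -> dict:
    """Union new hits into the accepted set; a hit overlapping an already
    accepted envelope on the same target by more than half of the shorter
    envelope is the same discovery re-detected, not a new one."""
    accepted = dict(accepted)
    for h in new_hits:
        dup = any(
            h.target == t
            and min(h.end, e) - max(h.start, s) + 1
            > 0.5 * min(h.end - h.start, e - s)
            for (t, s, e) in accepted
        )
        if not dup:
            accepted[_hit_key(h)] = h
    return accepted


def _select_for_merge(
    state: IterationState,
    database: list[SequenceRecord],
    dedupe_threshold: float,
) -> tuple[list[DomainHit], set]:
    """Accepted hits not yet in the alignment whose envelope subsequences
    survive greedy dedupe against the rows already merged."""
    seq_by_id = {r.id: r.seq for r in database}
    merged_keys = set(state.merged_keys)
    candidates = [h for k, h in state.accepted.items() if k not in merged_keys]
    merged_seqs = [row.replace("-", "") for _rid, row in state.alignment.rows]
    to_merge: list[DomainHit] = []
    for h in sorted(candidates, key=lambda h: (-(h.end - h.start), h.target, h.start)):
        env = seq_by_id[h.target][h.start - 1 : h.end]
        merged_keys.add(_hit_key(h))
        if not env:
            continue
        redundant = any(
            pairwise_identity(env, m) >= dedupe_threshold for m in merged_seqs if m
        )
        if not redundant:
            to_merge.append(h)
            merged_seqs.append(env)
    return to_merge, merged_keys


def run_iteration(
    state: IterationState,
    database: list[SequenceRecord],
    evalue_cutoff: float = 0.01,
    dedupe_threshold: float = 0.9,
    occupancy_threshold: float = 0.5,
    calibration_seed: int | None = None,
    pseudocount_scale: float = 1.0,
) -> IterationState:
    """One rebuild-and-research round.

    Hits accepted in earlier rounds that are not yet part of the alignment
    (and that survive dedupe against it) are first merged in as envelope
    subsequences; the profile is rebuilt and recalibrated from the enlarged
    alignment; then the database is searched with the updated profile and
    new hits (E <= cutoff, not already accepted) join the accepted set.
    Rebuilt profiles use depth-proportional emission pseudocounts
    (pseudocount_scale x alignment rows): as the alignment accumulates
    divergent members, emissions soften toward the background, which is what
    lets later rounds reach remote homologs.
    """
    if state.profile.calibration is None:
        raise RuntimeError("profile must be calibrated")
    to_merge, merged_keys = _select_for_merge(state, database, dedupe_threshold)
    alignment = state.alignment
    profile = state.profile
    if to_merge:
        extra = align_to_profile(profile, to_merge)
        alignment = Alignment(state.alignment.rows + extra.rows)
        profile = build_profile(
            alignment,
            occupancy_threshold=occupancy_threshold,
            pseudocount_weight=max(1.0, pseudocount_scale * alignment.n_rows),
            name=profile.name,
        )
        alignment = _project(alignment, profile.match_columns)
        seed = (
            calibration_seed
            if calibration_seed is not None
            else state.profile.calibration.calibration_seed + 1
        )
        calibrate(
            profile,
            n_random=state.profile.calibration.n_calibration,
            seed=seed,
        )
    new_hits = search(profile, database, evalue_cutoff)
    accepted = _accept(state.accepted, new_hits)
    dropped = [
        k for k in state.accepted if k not in {_hit_key(h) for h in new_hits}
    ]
    entry = {
        "round": state.round_index + 1,
        "hits": len(new_hits),
        "accepted_total": len(accepted),
        "merged": len(to_merge),
        "dropped_below_cutoff": len(dropped),
        "calibration_seed": profile.calibration.calibration_seed,
    }
    return IterationState(
        round_index=state.round_index + 1,
        profile=profile,
        accepted=accepted,
        alignment=alignment,
        log=state.log + [entry],
        merged_keys=merged_keys,
    )


def iterative_search(
    seed_alignment: Alignment,
    database: list[SequenceRecord],
    rounds: int = 2,
    evalue_cutoff: float = 0.01,
    dedupe_threshold: float = 0.9,
    occupancy_threshold: float = 0.5,
    seed: int = 0,
    name: str = "profile",
    n_calibration: int = 200,
    pseudocount_scale: float = 1.0,
) -> IterationState:
    """Seed search (round 0) followed by ``rounds`` rebuild-and-research
    iterations; rounds=0 is a plain single-pass search."""
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    profile = build_profile(
        seed_alignment,
        occupancy_threshold=occupancy_threshold,
        pseudocount_weight=max(1.0, pseudocount_scale * seed_alignment.n_rows),
        name=name,
    )
    calibrate(profile, n_random=n_calibration, seed=seed)
    working = _project(seed_alignment, profile.match_columns)
    hits = search(profile, database, evalue_cutoff)
    accepted = {_hit_key(h): h for h in hits}
    state = IterationState(
        round_index=0,
        profile=profile,
        accepted=accepted,
        alignment=working,
        log=[
            {
                "round": 0,
                "hits": len(hits),
                "accepted_total": len(accepted),
                "merged": 0,
                "dropped_below_cutoff": 0,
                "calibration_seed": seed,
            }
        ],
    )
    for r in range(rounds):
        state = run_iteration(
            state,
            database,
            evalue_cutoff=evalue_cutoff,
            dedupe_threshold=dedupe_threshold,
            occupancy_threshold=occupancy_threshold,
            calibration_seed=seed + r + 1,
            pseudocount_scale=pseudocount_scale,
        )
    return state
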