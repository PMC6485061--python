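"""A self-contained profile hidden Markov model engine.

Builds a profile from an aligned protein family, scores sequences by Viterbi
and Forward in log2-odds against a background composition, calibrates
E-values by fitting an extreme-value (Gumbel) law to background scores, and
aligns accepted hits back onto match states.

Model architecture: match/insert/delete states with the seven transition
groups {M→M, M→I, M→D, I→M, I→I, D→M, D→D} plus begin entries {B→M1, B→D1};
no insert state after the last match. Alignment mode is *glocal*: the model
must be traversed begin→end while the sequence flanks are free (scored as
background, i.e. zero log-odds). Multiple domains per target are found by
iterated score-and-mask. Insert emissions are fixed to the background, so
inserted residues are log-odds neutral. Internally coordinates are 0-based
half-open; every reported coordinate is 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ephscan.seqs import AMINO_ACIDS, BACKGROUND, SequenceRecord, encode

PROB_FLOOR = 1e-9
_EULER_GAMMA = float(np.euler_gamma)


class DegenerateModelError(ValueError):
    """No usable match column survives the occupancy/trimming threshold."""


class CalibrationError(ValueError):
    pass


class NotCalibratedError(RuntimeError):
    pass


class ConsistencyError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Alignment:
    """A gapped multiple alignment: rows of (id, aligned string), gap '-'."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(self.rows) < 1:
            raise ValueError("alignment needs at least one row")
        ncol = len(self.rows[0][1])
        if ncol < 1:
            raise ValueError("alignment needs at least one column")
        for rid, row in self.rows:
            if len(row) != ncol:
                raise ValueError(f"row {rid!r} has inconsistent length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    def occupancy(self) -> np.ndarray:
        """Per-column fraction of non-gap characters."""
        arr = np.array([list(r) for _, r in self.rows])
        return (arr != "-").mean(axis=0)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        from Bio import SeqIO

        rows = tuple(
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        )
        return cls(rows)

    def to_fasta(self, path: str | Path) -> None:
        from ephscan.seqs import write_fasta

        write_fasta(
            [SequenceRecord(rid, row) for rid, row in self.rows], path, wrap=80
        )


@dataclasses.dataclass(frozen=True)
class EVDParams:
    """Gumbel location/scale fitted to background bit scores."""

    mu: float
    lam: float
    n_calibration: int
    calibration_seed: int

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclasses.dataclass(frozen=True)
class DomainHit:
    """One profile-vs-target match (coordinates 1-based inclusive)."""

    profile: str
    target: str
    start: int
    end: int
    bits: float
    evalue: float
    #: residue aligned to each match state ('-' where the state is deleted)
    row: str
    #: 0-based match-state index -> 0-based target position
    match_map: dict[int, int] = dataclasses.field(compare=False, hash=False)

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid envelope")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclasses.dataclass
class ProfileHMM:
    """Profile HMM over the 20-letter amino-acid alphabet.

    Transition arrays are indexed by source match/delete/insert state
    (length M-1); ``begin`` holds (B→M1, B→D1).
    """

    name: str
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (20,)
    background: np.ndarray  # (20,)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    begin: np.ndarray  # (2,)
    match_columns: tuple[int, ...] | None = None
    calibration: EVDParams | None = None

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, tol: float = 1e-9) -> None:
        assert self.M >= 1
        assert np.all(self.match_emissions > 0)
        assert np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=tol)
        assert np.allclose(self.insert_emissions.sum(), 1.0, atol=tol)
        assert abs(self.begin.sum() - 1.0) <= tol
        if self.M > 1:
            for a, b, c in [
                (self.t_mm, self.t_mi, self.t_md),
                (self.t_im, self.t_ii, None),
                (self.t_dm, self.t_dd, None),
            ]:
                group = a + b + (c if c is not None else 0)
                assert np.allclose(group, 1.0, atol=tol)
                assert np.all(a > 0) and np.all(b > 0)


def _floor_norm(v: np.ndarray) -> np.ndarray:
    v = np.maximum(v, PROB_FLOOR)
    if v.ndim == 1:
        return v / v.sum()
    return v / v.sum(axis=-1, keepdims=True)


def build_profile(
    alignment: Alignment,
    occupancy_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    name: str = "profile",
) -> ProfileHMM:
    """Estimate a profile from an alignment.

    Columns whose non-gap fraction is >= occupancy_threshold become match
    states. Match emissions are (observed counts + pseudocount_weight x
    background), normalised; transitions come from the observed state paths
    with Laplace (+1) smoothing per group. Insert emissions are fixed to the
    background.
    """
    if not (0 < occupancy_threshold <= 1):
        raise ValueError("occupancy_threshold must be in (0, 1]")
    occ = alignment.occupancy()
    match_cols = [c for c in range(alignment.n_cols) if occ[c] >= occupancy_threshold]
    if not match_cols:
        raise DegenerateModelError("no column passes the occupancy threshold")
    M = len(match_cols)
    col_to_state = {c: j for j, c in enumerate(match_cols)}
    match_set = set(match_cols)

    em_counts = np.zeros((M, 20))
    c_mm = np.zeros(max(M - 1, 1))
    c_mi = np.zeros_like(c_mm)
    c_md = np.zeros_like(c_mm)
    c_im = np.zeros_like(c_mm)
    c_ii = np.zeros_like(c_mm)
    c_dm = np.zeros_like(c_mm)
    c_dd = np.zeros_like(c_mm)
    c_begin = np.zeros(2)

    for _rid, row in alignment.rows:
        # decode the row into a state path (flanking inserts are ignored)
        path: list[tuple[str, int]] = []
        last_match_state = -1
        for c, ch in enumerate(row):
            if c in match_set:
                j = col_to_state[c]
                path.append(("M", j) if ch != "-" else ("D", j))
                last_match_state = j
                if ch != "-" and ch.upper() in AMINO_ACIDS:
                    em_counts[j, AMINO_ACIDS.index(ch.upper())] += 1
            elif ch != "-" and 0 <= last_match_state < M - 1:
                path.append(("I", last_match_state))
        if not path:
            continue
        c_begin[0 if path[0][0] == "M" else 1] += 1
        for (s0, j0), (s1, _j1) in zip(path, path[1:]):
            if s0 == "M" and j0 < M - 1:
                if s1 == "M":
                    c_mm[j0] += 1
                elif s1 == "I":
                    c_mi[j0] += 1
                else:
                    c_md[j0] += 1
            elif s0 == "I":
                if s1 == "M":
                    c_im[j0] += 1
                elif s1 == "I":
                    c_ii[j0] += 1
                # I->D is not part of the state graph; left uncounted
            elif s0 == "D" and j0 < M - 1:
                if s1 == "M":
                    c_dm[j0] += 1
                elif s1 == "D":
                    c_dd[j0] += 1

    em = _floor_norm(em_counts + pseudocount_weight * BACKGROUND[None, :])
    # Laplace-smoothed transition groups
    m_group = np.stack([c_mm, c_mi, c_md], axis=1) + 1.0
    m_group = _floor_norm(m_group)
    i_group = _floor_norm(np.stack([c_im, c_ii], axis=1) + 1.0)
    d_group = _floor_norm(np.stack([c_dm, c_dd], axis=1) + 1.0)
    begin = _floor_norm(c_begin + 1.0)

    prof = ProfileHMM(
        name=name,
        match_emissions=em,
        insert_emissions=BACKGROUND.copy(),
        background=BACKGROUND.copy(),
        t_mm=m_group[:, 0],
        t_mi=m_group[:, 1],
        t_md=m_group[:, 2],
        t_im=i_group[:, 0],
        t_ii=i_group[:, 1],
        t_dm=d_group[:, 0],
        t_dd=d_group[:, 1],
        begin=begin,
        match_columns=tuple(match_cols),
    )
    prof.validate()
    return prof


# ---------------------------------------------------------------------------
# dynamic programming


def _log_params(profile: ProfileHMM):
    lg = np.log2
    M = profile.M
    lmm, lmi, lmd = lg(profile.t_mm), lg(profile.t_mi), lg(profile.t_md)
    lim, lii = lg(profile.t_im), lg(profile.t_ii)
    ldm, ldd = lg(profile.t_dm), lg(profile.t_dd)
    lbm, lbd = lg(profile.begin[0]), lg(profile.begin[1])
    # entry[j]: B -> (D_0..D_{j-1}) -> M_j ; exitc[j]: M_j -> (D..) -> E
    cumdd = np.concatenate([[0.0], np.cumsum(ldd)]) if M > 1 else np.array([0.0])
    entry = np.empty(M)
    entry[0] = lbm
    for j in range(1, M):
        entry[j] = lbd + cumdd[j - 1] + ldm[j - 1]
    exitc = np.zeros(M)
    for j in range(M - 1):
        exitc[j] = lmd[j] + (cumdd[M - 1] - cumdd[j + 1])
    return lmm, lmi, lmd, lim, lii, ldm, ldd, entry, exitc


def _lodds(profile: ProfileHMM, eseq: np.ndarray) -> np.ndarray:
    me = np.log2(profile.match_emissions) - np.log2(profile.background)[None, :]
    lod = np.zeros((profile.M, len(eseq)))
    ok = eseq >= 0
    if ok.any():
        lod[:, ok] = me[:, eseq[ok]]
    return lod


def _viterbi_dp(profile: ProfileHMM, eseq: np.ndarray):
    """Glocal Viterbi over one (sub)sequence; returns (VM, VI, VD, params)."""
    M, L = profile.M, len(eseq)
    lmm, lmi, lmd, lim, lii, ldm, ldd, entry, exitc = _log_params(profile)
    lod = _lodds(profile, eseq)
    NEG = -np.inf
    VM = np.full((M, L), NEG)
    VI = np.full((M, L), NEG)
    VD = np.full((M, L), NEG)
    idx = np.arange(L, dtype=float)
    for j in range(M):
        if j == 0:
            VM[0] = lod[0] + entry[0]
        else:
            prevM = np.concatenate([[NEG], VM[j - 1, :-1]])
            prevI = np.concatenate([[NEG], VI[j - 1, :-1]])
            prevD = np.concatenate([[NEG], VD[j - 1, :-1]])
            best = np.maximum(
                entry[j],
                np.maximum(
                    prevM + lmm[j - 1],
                    np.maximum(prevI + lim[j - 1], prevD + ldm[j - 1]),
                ),
            )
            VM[j] = lod[j] + best
            VD[j] = np.maximum(VM[j - 1] + lmd[j - 1], VD[j - 1] + ldd[j - 1])
        if j < M - 1 and L > 1:
            # VI[j,i] = max(VM[j,i-1]+lmi, VI[j,i-1]+lii): a running max
            a = VM[j] - idx * lii[j]
            c = np.maximum.accumulate(a)
            VI[j, 1:] = lmi[j] + lii[j] * (idx[1:] - 1.0) + c[:-1]
    return VM, VI, VD, (lmm, lmi, lmd, lim, lii, ldm, ldd, entry, exitc, lod)


def viterbi_score(profile: ProfileHMM, seq: str | SequenceRecord) -> float:
    """Best glocal log2-odds bit score (no traceback)."""
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if not s:
        raise ValueError("empty sequence")
    eseq = encode(s)
    VM, _VI, _VD, params = _viterbi_dp(profile, eseq)
    exitc = params[8]
    return float(np.max(VM + exitc[:, None]))


def viterbi(
    profile: ProfileHMM, seq: str | SequenceRecord
) -> tuple[float, list[tuple[str, int, int | None]]]:
    """Best glocal path; returns (bits, path).

    Path entries are (state, match-state index, 0-based target position or
    None for delete states), in model order including entry/exit deletes.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if not s:
        raise ValueError("empty sequence")
    eseq = encode(s)
    VM, VI, VD, params = _viterbi_dp(profile, eseq)
    lmm, lmi, lmd, lim, lii, ldm, ldd, entry, exitc, lod = params
    M, L = profile.M, len(eseq)
    total = VM + exitc[:, None]
    j, i = np.unravel_index(int(np.argmax(total)), total.shape)
    score = float(total[j, i])
    if not np.isfinite(score):
        raise ValueError("no legal path")
    # exit deletes after the last match state
    tail = [("D", k, None) for k in range(j + 1, M)]
    rev: list[tuple[str, int, int | None]] = []
    state = "M"
    while True:
        if state == "M":
            rev.append(("M", j, i))
            cands: list[tuple[str, float]] = [("B", entry[j])]
            if j > 0 and i > 0:
                cands += [
                    ("M", VM[j - 1, i - 1] + lmm[j - 1]),
                    ("I", VI[j - 1, i - 1] + lim[j - 1]),
                    ("D", VD[j - 1, i - 1] + ldm[j - 1]),
                ]
            pick = max(cands, key=lambda kv: kv[1])[0]
            if pick == "B":
                rev.extend(("D", k, None) for k in range(j - 1, -1, -1))
                break
            j, i, state = j - 1, i - 1, pick
        elif state == "I":
            rev.append(("I", j, i))
            a = VM[j, i - 1] + lmi[j] if i > 0 else -np.inf
            b = VI[j, i - 1] + lii[j] if i > 0 else -np.inf
            state = "M" if a >= b else "I"
            i -= 1
        else:  # D
            rev.append(("D", j, None))
            a = VM[j - 1, i] + lmd[j - 1]
            b = VD[j - 1, i] + ldd[j - 1]
            state = "M" if a >= b else "D"
            j -= 1
    path = list(reversed(rev)) + tail
    return score, path


def forward(profile: ProfileHMM, seq: str | SequenceRecord) -> float:
    """Glocal Forward log2-odds bit score (log-sum over all legal paths)."""
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if not s:
        raise ValueError("empty sequence")
    eseq = encode(s)
    M, L = profile.M, len(eseq)
    lmm, lmi, lmd, lim, lii, ldm, ldd, entry, exitc = _log_params(profile)
    lod = _lodds(profile, eseq)
    NEG = -np.inf
    FM = np.full((M, L), NEG)
    FI = np.full((M, L), NEG)
    FD = np.full((M, L), NEG)
    idx = np.arange(L, dtype=float)
    for j in range(M):
        if j == 0:
            FM[0] = lod[0] + entry[0]
        else:
            prevM = np.concatenate([[NEG], FM[j - 1, :-1]])
            prevI = np.concatenate([[NEG], FI[j - 1, :-1]])
            prevD = np.concatenate([[NEG], FD[j - 1, :-1]])
            tot = np.logaddexp2(
                entry[j],
                np.logaddexp2(
                    prevM + lmm[j - 1],
                    np.logaddexp2(prevI + lim[j - 1], prevD + ldm[j - 1]),
                ),
            )
            FM[j] = lod[j] + tot
            FD[j] = np.logaddexp2(FM[j - 1] + lmd[j - 1], FD[j - 1] + ldd[j - 1])
        if j < M - 1 and L > 1:
            a = FM[j] - idx * lii[j]
            acc = np.logaddexp2.accumulate(a)
            FI[j, 1:] = lmi[j] + lii[j] * (idx[1:] - 1.0) + acc[:-1]
    total = FM + exitc[:, None]
    return float(np.logaddexp2.reduce(total, axis=None))


# ---------------------------------------------------------------------------
# calibration and search


def fit_evd(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: lambda = pi/(sigma*sqrt(6)),
    mu = mean - gamma/lambda."""
    scores = np.asarray(scores, dtype=float)
    sd = float(np.std(scores, ddof=1))
    if sd <= 0:
        raise CalibrationError("zero variance in calibration scores")
    lam = float(np.pi / (sd * np.sqrt(6.0)))
    mu = float(np.mean(scores) - _EULER_GAMMA / lam)
    return mu, lam


def calibrate(
    profile: ProfileHMM,
    n_random: int = 200,
    length: int = 400,
    seed: int = 0,
) -> EVDParams:
    """Fit the background-score extreme-value law and attach it to the profile."""
    if n_random < 100:
        raise CalibrationError("n_random must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.choice(20, size=(n_random, length), p=BACKGROUND)
    scores = np.array(
        [
            viterbi_score(profile, "".join(AMINO_ACIDS[i] for i in row))
            for row in idx
        ]
    )
    mu, lam = fit_evd(scores)
    params = EVDParams(mu=mu, lam=lam, n_calibration=n_random, calibration_seed=seed)
    profile.calibration = params
    return params


def evalue(profile: ProfileHMM, bit_score: float, database_size: float) -> float:
    """E = N * P(max background score >= s) under the fitted Gumbel law."""
    if profile.calibration is None:
        raise NotCalibratedError(f"profile {profile.name!r} is not calibrated")
    p = profile.calibration
    x = np.exp(-p.lam * (bit_score - p.mu))
    return float(database_size * -np.expm1(-x))


def _unmasked_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    segs = []
    start = None
    for i, m in enumerate(mask):
        if not m and start is None:
            start = i
        elif m and start is not None:
            segs.append((start, i))
            start = None
    if start is not None:
        segs.append((start, len(mask)))
    return segs


def _hit_from_path(
    profile: ProfileHMM,
    rec: SequenceRecord,
    bits: float,
    ev: float,
    path: list,
    offset: int,
) -> DomainHit:
    match_map = {j: offset + i for st, j, i in path if st == "M"}
    positions = sorted(match_map.values())
    row = "".join(
        rec.seq[match_map[j]] if j in match_map else "-" for j in range(profile.M)
    )
    return DomainHit(
        profile=profile.name,
        target=rec.id,
        start=positions[0] + 1,
        end=positions[-1] + 1,
        bits=bits,
        evalue=ev,
        row=row,
        match_map=match_map,
    )


def search(
    profile: ProfileHMM,
    sequences: list[SequenceRecord],
    evalue_cutoff: float = 0.01,
    database_size: float | None = None,
    max_hits_per_seq: int = 8,
) -> list[DomainHit]:
    """Best non-overlapping domain hits with E <= cutoff, per sequence, by
    iterated score-and-mask; sorted by E ascending."""
    if profile.calibration is None:
        raise NotCalibratedError(f"profile {profile.name!r} is not calibrated")
    N = float(database_size if database_size is not None else len(sequences))
    hits: list[DomainHit] = []
    for rec in sequences:
        if not rec.seq:
            continue
        mask = np.zeros(len(rec.seq), dtype=bool)
        for _ in range(max_hits_per_seq):
            best = None
            for s, e in _unmasked_segments(mask):
                if e - s < 1:
                    continue
                sub = rec.seq[s:e]
                bits, path = viterbi(profile, sub)
                if best is None or bits > best[0]:
                    best = (bits, path, s)
            if best is None:
                break
            bits, path, offset = best
            ev = evalue(profile, bits, N)
            if ev > evalue_cutoff:
                break
            hit = _hit_from_path(profile, rec, bits, ev, path, offset)
            hits.append(hit)
            mask[hit.start - 1 : hit.end] = True
            if mask.all():
                break
    hits.sort(key=lambda h: (h.evalue, h.target, h.start))
    return hits


def align_to_profile(profile: ProfileHMM, hits: list[DomainHit]) -> Alignment:
    """Match-column-anchored alignment of hits: one column per match state.

    Insert-state residues are excluded from columns (they are log-odds
    neutral and carry no column statistics).
    """
    rows = []
    for h in hits:
        if h.profile != profile.name or len(h.row) != profile.M:
            raise ConsistencyError(
                f"hit on {h.target!r} was not produced by profile {profile.name!r}"
            )
        rows.append((f"{h.target}/{h.start}-{h.end}", h.row))
    return Alignment(tuple(rows))


def trim_alignment(alignment: Alignment, min_occupancy: float) -> Alignment:
    """Drop columns whose non-gap fraction is below min_occupancy."""
    occ = alignment.occupancy()
    keep = [c for c in range(alignment.n_cols) if occ[c] >= min_occupancy]
    if not keep:
        raise DegenerateModelError("trimming removed every column")
    rows = tuple(
        (rid, "".join(row[c] for c in keep)) for rid, row in alignment.rows
    )
    return Alignment(rows)


# ---------------------------------------------------------------------------
# serialization


def profile_to_json(profile: ProfileHMM) -> str:
    doc = {
        "name": profile.name,
        "match_emissions": profile.match_emissions.tolist(),
        "insert_emissions": profile.insert_emissions.tolist(),
        "background": profile.background.tolist(),
        "transitions": {
            k: getattr(profile, k).tolist()
            for k in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
        },
        "begin": profile.begin.tolist(),
        "match_columns": list(profile.match_columns or []) or None,
        "calibration": (
            dataclasses.asdict(profile.calibration) if profile.calibration else None
        ),
    }
    return json.dumps(doc)


def profile_from_json(text: str) -> ProfileHMM:
    doc = json.loads(text)
    tr = doc["transitions"]
    cal = doc.get("calibration")
    prof = ProfileHMM(
        name=doc["name"],
        match_emissions=np.array(doc["match_emissions"]),
        insert_emissions=np.array(doc["insert_emissions"]),
        background=np.array(doc["background"]),
        t_mm=np.array(tr["t_mm"]),
        t_mi=np.array(tr["t_mi"]),
        t_md=np.array(tr["t_md"]),
        t_im=np.array(tr["t_im"]),
        t_ii=np.array(tr["t_ii"]),
        t_dm=np.array(tr["t_dm"]),
        t_dd=np.array(tr["t_dd"]),
        begin=np.array(doc["begin"]),
        match_columns=tuple(doc["match_columns"]) if doc.get("match_columns") else None,
        calibration=EVDParams(**cal) if cal else None,
    )
    return prof


def hits_to_tsv(hits: list[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("profile\ttarget\tstart\tend\tbits\tevalue\n")
        for h in hits:
            fh.write(
                f"{h.profile}\t{h.target}\t{h.start}\t{h.end}\t"
                f"{h.bits:.3f}\t{h.evalue:.3g}\n"
            )
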