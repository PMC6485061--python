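"""Membrane-anchoring calls: consensus TM helices, dual-heuristic GPI
prediction, and ephrin subtype assignment.

TM prediction emulates a consensus-of-predictors scheme: five sliding-window
Kyte–Doolittle sub-predictors (windows 15/17/19/21/23, threshold 1.6) vote
position-wise, and a consensus helix requires at least 3 of 5 votes over a
run of at least 15 residues. A helix is C-terminal when it ends within 40
residues of the terminus.

GPI anchoring is called only when two deliberately independent heuristics
agree (the dual-support rule): an omega-site motif scan near the C-terminus
and a composition test on the extreme tail. Subtypes follow the ephrin
convention — B: C-terminal TM without GPI; A: GPI without C-terminal TM;
DUAL: both; UNANCHORED: neither.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ephscan.seqs import KYTE_DOOLITTLE

TM_WINDOWS = (15, 17, 19, 21, 23)
TM_THRESHOLD = 1.6
TM_MIN_RUN = 15
TM_MIN_VOTES = 3
C_TERMINAL_WINDOW = 40

GPI_TAIL_THRESHOLD = 1.5
OMEGA_RESIDUES = set("SAGNDC")
SMALL_RESIDUES = set("AGSCNDT")
CHARGED_RESIDUES = set("DEKRH")

SUBTYPES = ("A", "B", "DUAL", "UNANCHORED")


@dataclasses.dataclass(frozen=True)
class AnchoringCall:
    protein_id: str
    tm_segments: tuple[tuple[int, int, int], ...]  # (start, end, votes), 1-based
    c_terminal_tm: bool
    gpi: bool
    omega_pos: int | None
    subtype: str


def hydropathy_profile(seq: str, window: int) -> np.ndarray:
    """Sliding-window mean Kyte–Doolittle hydropathy, one value per residue;
    terminal positions use truncated windows."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not (7 <= window <= 41):
        raise ValueError("window must lie in [7, 41]")
    vals = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq.upper()])
    n = len(vals)
    if n == 0:
        return vals
    half = window // 2
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (cs[hi] - cs[lo]) / (hi - lo)
    return out


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal True runs of at least min_len, as 0-based half-open intervals."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_len:
        runs.append((start, len(mask)))
    return runs


def predict_tm(seq: str) -> list[tuple[int, int, int]]:
    """Consensus TM segments as (start, end, votes), 1-based inclusive.

    Sequences shorter than 25 residues yield no call.
    """
    n = len(seq)
    if n < 25:
        return []
    votes = np.zeros(n, dtype=int)
    for w in TM_WINDOWS:
        hp = hydropathy_profile(seq, w)
        for s, e in _runs(hp >= TM_THRESHOLD, TM_MIN_RUN):
            votes[s:e] += 1
    segments = []
    for s, e in _runs(votes >= TM_MIN_VOTES, TM_MIN_RUN):
        segments.append((s + 1, e, int(votes[s:e].max())))
    return segments


def is_c_terminal(tm_segments: list[tuple[int, int, int]], length: int) -> bool:
    return any(length - end <= C_TERMINAL_WINDOW for _s, end, _v in tm_segments)


def predict_gpi_omega(seq: str) -> int | None:
    """Omega-site motif heuristic; returns the most C-terminal qualifying
    omega position (1-based) or None.

    An omega residue (small: S/A/G/N/D/C) in the last 40 residues with small
    residues at omega+1 and omega+2 qualifies when it is followed within 25
    residues by a hydrophobic stretch (window-11 mean >= 1.5) that reaches
    the terminus.
    """
    n = len(seq)
    if n < 14:
        return None
    seq = seq.upper()
    # t0 = earliest start such that every window-11 mean from there on is
    # above threshold (the tail stretch reaching the terminus)
    w = 11
    if n < w:
        return None
    means = np.array(
        [np.mean([KYTE_DOOLITTLE.get(c, 0.0) for c in seq[t : t + w]]) for t in range(n - w + 1)]
    )
    good = means >= GPI_TAIL_THRESHOLD
    t0 = None
    for t in range(len(good) - 1, -1, -1):
        if good[t]:
            t0 = t
        else:
            break
    if t0 is None:
        return None
    best = None
    for i in range(max(0, n - 40), n - 2):
        if (
            seq[i] in OMEGA_RESIDUES
            and seq[i + 1] in SMALL_RESIDUES
            and seq[i + 2] in SMALL_RESIDUES
            and t0 - i <= 25
        ):
            best = i + 1
    return best


def predict_gpi_charge(seq: str) -> bool:
    """Composition heuristic: an uncharged, hydrophobic extreme tail with a
    small-residue triplet in the last 40 residues."""
    n = len(seq)
    if n < 15:
        return False
    seq = seq.upper()
    tail15 = seq[-15:]
    if any(c in CHARGED_RESIDUES for c in tail15):
        return False
    tail12 = seq[-12:]
    if np.mean([KYTE_DOOLITTLE.get(c, 0.0) for c in tail12]) < GPI_TAIL_THRESHOLD:
        return False
    last40 = seq[-40:]
    return any(
        all(c in SMALL_RESIDUES for c in last40[i : i + 3])
        for i in range(len(last40) - 2)
    )


def call_gpi(seq: str) -> tuple[bool, int | None]:
    """GPI call: positive only when BOTH heuristics agree (dual-support)."""
    omega = predict_gpi_omega(seq)
    if omega is not None and predict_gpi_charge(seq):
        return True, omega
    return False, None


def classify_subtype(c_terminal_tm: bool, gpi: bool) -> str:
    if c_terminal_tm and gpi:
        return "DUAL"
    if c_terminal_tm:
        return "B"
    if gpi:
        return "A"
    return "UNANCHORED"


def call_anchoring(protein_id: str, seq: str) -> AnchoringCall:
    """Full anchoring call for one protein.

    When a GPI anchor is called, the hydrophobic stretch C-terminal of the
    omega site is the anchor propeptide (removed on anchoring), not a TM
    helix: TM segments are truncated at the omega position and kept only if
    a helix-length stretch remains upstream of it.
    """
    tm = predict_tm(seq)
    gpi, omega = call_gpi(seq)
    if gpi and omega is not None:
        tm = [
            (s, min(e, omega - 1), v)
            for s, e, v in tm
            if min(e, omega - 1) - s + 1 >= TM_MIN_RUN
        ]
    ct = is_c_terminal(tm, len(seq))
    return AnchoringCall(
        protein_id=protein_id,
        tm_segments=tuple(tm),
        c_terminal_tm=ct,
        gpi=gpi,
        omega_pos=omega,
        subtype=classify_subtype(ct, gpi),
    )
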