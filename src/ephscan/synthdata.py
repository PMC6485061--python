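"""Synthetic multi-lineage proteome panels with planted ground truth.

Every downstream stage (profile search, architecture grammar, anchoring,
copper-site scanning, trees) is validated against panels produced here:
protein families evolved from random consensus sequences at controlled
divergence, assembled into domain architectures with linkers, planted
transmembrane helices and GPI-anchor signals, fragmentary gene models, and
unrelated decoy proteins — together with a machine-readable truth table.

Architecture strings are whitespace-separated token lists. Tokens are either
declared family names (e.g. ``LBD fn3 fn3 TM kinase SAM``) or the special
tokens ``TM`` (a planted 21-residue hydrophobic helix), ``GPI`` (a C-terminal
omega-site + hydrophobic tail, always last), ``COPPER+`` / ``COPPER-`` (an
instance of the declared ``cupredoxin`` family with the copper-chelating
triad intact or substituted).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ephscan.seqs import (
    AMINO_ACIDS,
    BACKGROUND,
    SequenceRecord,
    random_background_seq,
    write_fasta,
)

SPECIAL_TOKENS = {"TM", "GPI", "COPPER+", "COPPER-"}

#: residues allowed in a planted TM helix
TM_RESIDUES = "LIVFAM"
#: hydrophobic tail of a planted GPI signal
GPI_TAIL_RESIDUES = "LIVF"
#: omega-site candidates planted by the generator (uncharged small residues)
GPI_OMEGA_RESIDUES = "SAGNC"
#: small residues planted at omega+1/omega+2
GPI_SMALL_RESIDUES = "AGST"
#: residues never allowed to form long runs inside linkers
_HYDROPHOBIC_RUN = set("LIVFM")

#: default copper-site reference columns used by panel cupredoxin families,
#: 0-based positions on the family consensus (names follow azurin numbering)
DEFAULT_COPPER_SITES = {"G45": 44, "H46": 45, "C112": 111, "H117": 116, "M121": 120}
COPPER_INTACT = {"G45": "G", "H46": "H", "C112": "C", "H117": "H", "M121": "M"}
COPPER_LOST = {"G45": "G", "H46": "Q", "C112": "S", "H117": "Q", "M121": "L"}


class InvalidSpecError(ValueError):
    """A family or panel specification violates its invariants."""


@dataclasses.dataclass(frozen=True)
class FamilySpec:
    """One synthetic protein domain family.

    fixed_sites maps 0-based consensus positions to residues held invariant
    during evolution (disulfide-bridge cysteines, copper-site residues).
    """

    family_name: str
    consensus_length: int
    n_members: int
    divergence: float
    indel_rate: float = 0.0
    seed: int = 0
    fixed_sites: dict[int, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.consensus_length < 30:
            raise InvalidSpecError("consensus_length must be >= 30")
        if not (0.0 <= self.divergence < 0.95):
            raise InvalidSpecError("divergence must lie in [0, 0.95)")
        if self.n_members < 1:
            raise InvalidSpecError("n_members must be >= 1")
        if not (0.0 <= self.indel_rate < 1.0):
            raise InvalidSpecError("indel_rate must lie in [0, 1)")
        for pos in self.fixed_sites:
            if not (0 <= pos < self.consensus_length):
                raise InvalidSpecError("fixed_sites position outside consensus")


@dataclasses.dataclass(frozen=True)
class PanelSpec:
    """A multi-lineage panel: per-lineage architecture counts plus decoys.

    architectures_per_lineage maps lineage -> list of
    (architecture string, count, divergence tier).
    """

    lineages: tuple[str, ...]
    architectures_per_lineage: dict[str, list[tuple[str, int, float]]]
    fragment_fraction: float = 0.0
    decoy_count: int = 0
    seed: int = 0
    decoy_length_range: tuple[int, int] = (150, 450)

    def __post_init__(self):
        if not (0.0 <= self.fragment_fraction <= 1.0):
            raise InvalidSpecError("fragment_fraction must lie in [0, 1]")
        if self.decoy_count < 0:
            raise InvalidSpecError("decoy_count must be >= 0")
        for lin in self.architectures_per_lineage:
            if lin not in self.lineages:
                raise InvalidSpecError(f"unknown lineage {lin!r}")


def _derived_rng(*entropy: int) -> np.random.Generator:
    """Deterministic per-item stream derived from a master seed."""
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def make_consensus(family_name: str, length: int, seed: int) -> SequenceRecord:
    """Random consensus drawn from the average amino-acid composition."""
    if length < 30:
        raise InvalidSpecError("consensus length must be >= 30")
    rng = _derived_rng(seed)
    return SequenceRecord(
        id=f"{family_name}_consensus", seq=random_background_seq(length, rng)
    )


def evolve_member(
    consensus: SequenceRecord | str,
    divergence: float,
    indel_rate: float,
    seed: int,
    fixed_sites: dict[int, str] | None = None,
    member_id: str = "member",
) -> SequenceRecord:
    """Evolve one family member from a consensus.

    Each non-fixed site is substituted independently with probability
    ``divergence``, always to a *different* residue (drawn from the background
    composition renormalised without the current residue), so the expected
    identity to the consensus is exactly ``1 - divergence``. Insertions and
    deletions each occur per site with probability ``indel_rate / 2``.
    """
    base = consensus.seq if isinstance(consensus, SequenceRecord) else consensus
    if not base:
        raise InvalidSpecError("consensus must be non-empty")
    fixed = dict(fixed_sites or {})
    rng = _derived_rng(seed)
    out: list[str] = []
    for i, ch in enumerate(base):
        if i in fixed:
            out.append(fixed[i])
            continue
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            pass  # deletion
        else:
            if rng.random() < divergence:
                j = AMINO_ACIDS.index(ch) if ch in AMINO_ACIDS else -1
                p = BACKGROUND.copy()
                if j >= 0:
                    p[j] = 0.0
                p /= p.sum()
                ch = AMINO_ACIDS[rng.choice(20, p=p)]
            out.append(ch)
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            out.append(AMINO_ACIDS[rng.choice(20, p=BACKGROUND)])
    return SequenceRecord(id=member_id, seq="".join(out))


def evolve_member_exact(
    consensus: SequenceRecord | str,
    divergence: float,
    indel_rate: float,
    seed: int,
    fixed_sites: dict[int, str] | None = None,
    member_id: str = "member",
) -> SequenceRecord:
    """Evolve one member at *exactly* the stated divergence.

    Exactly round(divergence x length) non-fixed sites, chosen uniformly,
    are substituted to a different residue; indels as in evolve_member.
    Used where a panel must realise an identity tier exactly (e.g. "the 25%
    identity tier") rather than in binomial expectation.
    """
    base = consensus.seq if isinstance(consensus, SequenceRecord) else consensus
    if not base:
        raise InvalidSpecError("consensus must be non-empty")
    fixed = dict(fixed_sites or {})
    rng = _derived_rng(seed)
    free = [i for i in range(len(base)) if i not in fixed]
    k = min(len(free), int(round(divergence * len(base))))
    subs = set(rng.choice(free, size=k, replace=False).tolist()) if k else set()
    out: list[str] = []
    for i, ch in enumerate(base):
        if i in fixed:
            out.append(fixed[i])
            continue
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            pass  # deletion
        else:
            if i in subs:
                j = AMINO_ACIDS.index(ch) if ch in AMINO_ACIDS else -1
                p = BACKGROUND.copy()
                if j >= 0:
                    p[j] = 0.0
                p /= p.sum()
                ch = AMINO_ACIDS[rng.choice(20, p=p)]
            out.append(ch)
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            out.append(AMINO_ACIDS[rng.choice(20, p=BACKGROUND)])
    return SequenceRecord(id=member_id, seq="".join(out))


def make_family(spec: FamilySpec) -> tuple[SequenceRecord, list[SequenceRecord]]:
    """Consensus plus n_members evolved members of one family."""
    cons = make_consensus(spec.family_name, spec.consensus_length, spec.seed)
    members = [
        evolve_member(
            cons,
            spec.divergence,
            spec.indel_rate,
            seed=int(_derived_rng(spec.seed, k + 1).integers(2**31)),
            fixed_sites=spec.fixed_sites,
            member_id=f"{spec.family_name}_m{k + 1}",
        )
        for k in range(spec.n_members)
    ]
    return cons, members


def make_seed_alignment(spec: FamilySpec) -> list[tuple[str, str]]:
    """An ungapped seed alignment of the family (members evolved without indels)."""
    spec0 = dataclasses.replace(spec, indel_rate=0.0)
    _, members = make_family(spec0)
    return [(m.id, m.seq) for m in members]


#: sampling weights for TM residues; planted helices draw only the strong
#: hydrophobics so a 21-mer clears every sliding-window threshold even when
#: flanked by charge-rich linkers
_TM_WEIGHTS = np.array([0.40, 0.30, 0.30, 0.0, 0.0, 0.0])  # L I V F A M


def _tm_helix(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(TM_RESIDUES), size=21, p=_TM_WEIGHTS))


def plant_tm(
    seq: SequenceRecord | str,
    position_mode: str = "c_terminal",
    seed: int = 0,
) -> tuple[SequenceRecord, tuple[int, int]]:
    """Insert a 21-residue hydrophobic helix; returns (record, 1-based interval).

    ``c_terminal`` places the helix so it ends within 40 residues of the
    terminus; ``internal`` places it at least 60 residues from the terminus
    (requires length >= 85).
    """
    rec = seq if isinstance(seq, SequenceRecord) else SequenceRecord("seq", seq)
    n = len(rec.seq)
    if n < 25:
        raise InvalidSpecError("sequence shorter than 25 residues")
    rng = _derived_rng(seed)
    tm = _tm_helix(rng)
    if position_mode == "c_terminal":
        p = max(0, n - 15)
    elif position_mode == "internal":
        if n < 85:
            raise InvalidSpecError("internal placement requires length >= 85")
        p = min(n // 3, n - 60)
    else:
        raise ValueError(f"unknown position_mode {position_mode!r}")
    new = rec.seq[:p] + tm + rec.seq[p:]
    return rec.with_seq(new), (p + 1, p + 21)


def _gpi_signal(rng: np.random.Generator) -> tuple[str, int]:
    """15-residue omega-site + hydrophobic tail; returns (signal, omega offset)."""
    omega = rng.choice(list(GPI_OMEGA_RESIDUES))
    small = "".join(rng.choice(list(GPI_SMALL_RESIDUES), size=2))
    tail = "".join(rng.choice(list(GPI_TAIL_RESIDUES), size=12))
    return omega + small + tail, 0


def plant_gpi_signal(
    seq: SequenceRecord | str, seed: int = 0
) -> tuple[SequenceRecord, int]:
    """Append an omega-site motif plus hydrophobic tail; returns (record, omega pos).

    The omega residue and the two following small residues are drawn from
    uncharged candidates only, so the planted signal satisfies both GPI
    heuristics (motif-based and composition-based) of the anchoring module.
    """
    rec = seq if isinstance(seq, SequenceRecord) else SequenceRecord("seq", seq)
    rng = _derived_rng(seed)
    signal, off = _gpi_signal(rng)
    new = rec.seq + signal
    return rec.with_seq(new), len(rec.seq) + 1 + off


def _linker(rng: np.random.Generator, lo: int = 15, hi: int = 60) -> str:
    """Background linker with no hydrophobic {L,I,V,F,M} run longer than 8
    and at least one charged residue in its last 10 positions (soluble
    termini never mimic a GPI propeptide tail)."""
    n = int(rng.integers(lo, hi + 1))
    polar = [a for a in AMINO_ACIDS if a not in _HYDROPHOBIC_RUN]
    out: list[str] = []
    run = 0
    for _ in range(n):
        ch = AMINO_ACIDS[rng.choice(20, p=BACKGROUND)]
        if ch in _HYDROPHOBIC_RUN:
            run += 1
            if run > 8:
                ch = polar[rng.integers(len(polar))]
                run = 0
        else:
            run = 0
        out.append(ch)
    tail = out[-10:]
    if not any(c in "DEKRH" for c in tail):
        out[-int(rng.integers(1, min(n, 10) + 1))] = "DEKR"[rng.integers(4)]
    return "".join(out)


def classify_tokens(tokens: list[str]) -> str:
    """Ground-truth class of an architecture token list (the grammar applied
    to planted domains rather than detected hits)."""
    doms = [t for t in tokens if t not in ("TM", "GPI")]
    has_tm = "TM" in tokens
    has_lbd = "LBD" in doms
    kin_idx = [i for i, t in enumerate(doms) if t == "kinase"]
    ect_idx = [i for i, t in enumerate(doms) if t in ("LBD", "fn3")]
    if has_lbd and doms[0] == "LBD" and kin_idx and (
        not ect_idx or max(kin_idx) > max(ect_idx)
    ):
        return "EPH_FULL"
    if kin_idx and "fn3" in doms and has_tm and not has_lbd:
        return "PROTO_EPH_LIKE"
    if has_lbd:
        return "EPH_PARTIAL"
    if "ephrin_RBD" in doms and not kin_idx:
        return "EPHRIN"
    if "COPPER+" in doms:
        return "CUPREDOXIN"
    return "OTHER"


def _subtype(c_terminal_tm: bool, gpi: bool) -> str:
    if c_terminal_tm and gpi:
        return "DUAL"
    if c_terminal_tm:
        return "B"
    if gpi:
        return "A"
    return "UNANCHORED"


def _truncate_tokens(
    tokens: list[str], rng: np.random.Generator
) -> list[str] | None:
    """Remove >=1 whole domain from a random terminus; None if ineligible."""
    dom_pos = [i for i, t in enumerate(tokens) if t != "GPI" and t != "TM"]
    if len(dom_pos) < 2:
        return None
    k = int(rng.integers(1, len(dom_pos)))  # domains removed
    if rng.random() < 0.5:  # N-terminal truncation
        return tokens[dom_pos[k - 1] + 1 :]
    return tokens[: dom_pos[len(dom_pos) - k]]


def _build_protein(
    pid: str,
    lineage: str,
    tokens: list[str],
    divergence: float,
    fam_specs: dict[str, FamilySpec],
    consensus: dict[str, SequenceRecord],
    rng: np.random.Generator,
) -> tuple[SequenceRecord, dict]:
    """Assemble one protein from tokens; returns (record, truth row)."""
    parts: list[str] = []
    domains: list[tuple[str, int, int]] = []
    tm_intervals: list[tuple[int, int]] = []
    copper_state = ""
    pos = 0

    def _append(s: str) -> tuple[int, int]:
        nonlocal pos
        start = pos + 1
        parts.append(s)
        pos += len(s)
        return start, pos

    has_gpi = tokens and tokens[-1] == "GPI"
    body = tokens[:-1] if has_gpi else tokens
    for j, tok in enumerate(body):
        last = j == len(body) - 1
        if tok == "TM":
            seg = _tm_helix(rng)
            tm_intervals.append(_append(seg))
        else:
            if tok in ("COPPER+", "COPPER-"):
                fs = fam_specs["cupredoxin"]
                state = COPPER_INTACT if tok == "COPPER+" else COPPER_LOST
                fixed = dict(fs.fixed_sites)
                fixed.update(
                    {DEFAULT_COPPER_SITES[name]: res for name, res in state.items()}
                )
                copper_state = tok
                fam = "cupredoxin"
            else:
                fs = fam_specs[tok]
                fixed = fs.fixed_sites
                fam = tok
            member = evolve_member(
                consensus[fam],
                divergence,
                fs.indel_rate,
                seed=int(rng.integers(2**31)),
                fixed_sites=fixed,
            )
            s, e = _append(member.seq)
            domains.append((fam, s, e))
        if not last:
            _append(_linker(rng))
        else:
            # trailing linker; kept short after a final TM so the helix stays
            # within 40 residues of the terminus (within 25 if a GPI follows)
            if tok == "TM":
                hi = 25 - 15 if has_gpi else 35
                _append(_linker(rng, 5, max(6, hi)))
            elif not has_gpi:
                _append(_linker(rng))
    if not body:
        _append(_linker(rng))
    omega_pos = -1
    if has_gpi:
        signal, off = _gpi_signal(rng)
        s, _ = _append(signal)
        omega_pos = s + off
    # leading linker before the first domain
    lead = _linker(rng)
    seq = lead + "".join(parts)
    shift = len(lead)
    domains = [(f, s + shift, e + shift) for f, s, e in domains]
    tm_intervals = [(s + shift, e + shift) for s, e in tm_intervals]
    if omega_pos > 0:
        omega_pos += shift
    total = len(seq)
    c_term_tm = any(total - e <= 40 for _, e in tm_intervals)
    row = {
        "protein_id": pid,
        "lineage": lineage,
        "architecture": " ".join(tokens),
        "true_class": classify_tokens(tokens),
        "tm_intervals": ";".join(f"{s}-{e}" for s, e in tm_intervals),
        "c_terminal_tm": c_term_tm,
        "gpi": has_gpi,
        "omega_pos": omega_pos,
        "subtype": _subtype(c_term_tm, has_gpi),
        "copper_state": copper_state,
        "domains": ";".join(f"{f}:{s}-{e}" for f, s, e in domains),
        "length": total,
    }
    return SequenceRecord(id=pid, seq=seq, lineage=lineage), row


def assemble_panel(
    panel_spec: PanelSpec, family_specs: list[FamilySpec]
) -> tuple[dict[str, list[SequenceRecord]], pd.DataFrame]:
    """Build the full panel: per-lineage records plus the truth table."""
    fam_map = {fs.family_name: fs for fs in family_specs}
    # validate tokens up front
    for lin, archs in panel_spec.architectures_per_lineage.items():
        for arch, _count, _div in archs:
            for tok in arch.split():
                if tok not in SPECIAL_TOKENS and tok not in fam_map:
                    raise InvalidSpecError(f"unresolvable token {tok!r} in {arch!r}")
                if tok in ("COPPER+", "COPPER-") and "cupredoxin" not in fam_map:
                    raise InvalidSpecError(
                        "COPPER tokens require a declared 'cupredoxin' family"
                    )
    consensus = {
        name: make_consensus(name, fs.consensus_length, fs.seed)
        for name, fs in fam_map.items()
    }

    # enumerate planned proteins deterministically
    plan: list[tuple[str, list[str], float]] = []  # (lineage, tokens, divergence)
    for lin in panel_spec.lineages:
        for arch, count, div in panel_spec.architectures_per_lineage.get(lin, []):
            for _ in range(count):
                plan.append((lin, arch.split(), div))

    # pick which eligible proteins get fragmented (exact fraction)
    eligible = [
        i
        for i, (_, toks, _) in enumerate(plan)
        if len([t for t in toks if t not in ("TM", "GPI")]) >= 2
    ]
    n_frag = int(round(panel_spec.fragment_fraction * len(eligible)))
    sel_rng = _derived_rng(panel_spec.seed, 999_983)
    frag_set = set(
        sel_rng.choice(eligible, size=n_frag, replace=False).tolist()
        if n_frag
        else []
    )

    records: dict[str, list[SequenceRecord]] = {lin: [] for lin in panel_spec.lineages}
    rows: list[dict] = []
    for idx, (lin, tokens, div) in enumerate(plan):
        rng = _derived_rng(panel_spec.seed, idx)
        toks = tokens
        if idx in frag_set:
            cut = _truncate_tokens(tokens, rng)
            if cut is not None:
                toks = cut
        pid = f"{lin}_{idx:04d}"
        rec, row = _build_protein(pid, lin, toks, div, fam_map, consensus, rng)
        records[lin].append(rec)
        rows.append(row)

    for d in range(panel_spec.decoy_count):
        lin = panel_spec.lineages[d % len(panel_spec.lineages)]
        rng = _derived_rng(panel_spec.seed, 1_000_000 + d)
        lo, hi = panel_spec.decoy_length_range
        seq = random_background_seq(int(rng.integers(lo, hi + 1)), rng)
        pid = f"{lin}_decoy{d:04d}"
        records[lin].append(SequenceRecord(id=pid, seq=seq, lineage=lin))
        rows.append(
            {
                "protein_id": pid,
                "lineage": lin,
                "architecture": "",
                "true_class": "decoy",
                "tm_intervals": "",
                "c_terminal_tm": False,
                "gpi": False,
                "omega_pos": -1,
                "subtype": "UNANCHORED",
                "copper_state": "",
                "domains": "",
                "length": len(seq),
            }
        )
    truth = pd.DataFrame(rows)
    return records, truth


def write_panel(
    records: dict[str, list[SequenceRecord]],
    truth: pd.DataFrame,
    outdir: str | Path,
) -> None:
    """One 80-column FASTA per lineage plus truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for lin, recs in records.items():
        write_fasta(recs, outdir / f"{lin}.fasta", wrap=80)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def specs_to_json(panel: PanelSpec, families: list[FamilySpec]) -> str:
    doc = {
        "panel": {
            "lineages": list(panel.lineages),
            "architectures_per_lineage": {
                lin: [[a, c, d] for a, c, d in archs]
                for lin, archs in panel.architectures_per_lineage.items()
            },
            "fragment_fraction": panel.fragment_fraction,
            "decoy_count": panel.decoy_count,
            "seed": panel.seed,
            "decoy_length_range": list(panel.decoy_length_range),
        },
        "families": [
            {
                "family_name": f.family_name,
                "consensus_length": f.consensus_length,
                "n_members": f.n_members,
                "divergence": f.divergence,
                "indel_rate": f.indel_rate,
                "seed": f.seed,
                "fixed_sites": {str(k): v for k, v in f.fixed_sites.items()},
            }
            for f in families
        ],
    }
    return json.dumps(doc, indent=2)


def specs_from_json(text: str) -> tuple[PanelSpec, list[FamilySpec]]:
    doc = json.loads(text)
    p = doc["panel"]
    panel = PanelSpec(
        lineages=tuple(p["lineages"]),
        architectures_per_lineage={
            lin: [(a, int(c), float(d)) for a, c, d in archs]
            for lin, archs in p["architectures_per_lineage"].items()
        },
        fragment_fraction=float(p.get("fragment_fraction", 0.0)),
        decoy_count=int(p.get("decoy_count", 0)),
        seed=int(p.get("seed", 0)),
        decoy_length_range=tuple(p.get("decoy_length_range", (150, 450))),
    )
    families = [
        FamilySpec(
            family_name=f["family_name"],
            consensus_length=int(f["consensus_length"]),
            n_members=int(f["n_members"]),
            divergence=float(f["divergence"]),
            indel_rate=float(f.get("indel_rate", 0.0)),
            seed=int(f.get("seed", 0)),
            fixed_sites={int(k): v for k, v in f.get("fixed_sites", {}).items()},
        )
        for f in doc["families"]
    ]
    return panel, families
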