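"""Domain-architecture calls and the Eph/ephrin classification grammar.

Per-protein domain hits are resolved into an ordered, non-overlapping
architecture; the cysteine-rich region (CRD) between the ligand-binding
domain and the first fibronectin repeat is annotated; and each protein
receives exactly one class label:

* ``EPH_FULL`` — LBD is the most N-terminal domain and a tyrosine-kinase
  domain lies C-terminal to every extracellular domain (SAM/PDZ absence
  never blocks the call: C-terminally truncated gene models are common).
* ``PROTO_EPH_LIKE`` — kinase + fn3 + TM present but no LBD (the receptor
  form seen in unicellular holozoans).
* ``EPH_PARTIAL`` — LBD present without a correctly placed kinase.
* ``EPHRIN`` — ephrin receptor-binding domain present, no kinase.
* ``CUPREDOXIN`` — cupredoxin-fold domain with a copper-competent site.
* ``OTHER`` — everything else.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from ephscan.profilehmm import Alignment, DomainHit

CLASSES = ("EPH_FULL", "EPH_PARTIAL", "PROTO_EPH_LIKE", "EPHRIN", "CUPREDOXIN", "OTHER")

#: canonical domain labels the grammar understands
LBD = "LBD"
FN3 = "fn3"
KINASE = "kinase"
SAM = "SAM"
EPHRIN_RBD = "ephrin_RBD"
CUPREDOXIN_DOM = "cupredoxin"

#: minimum LBD→fn3 gap that is annotated as the CRD
CRD_MIN_GAP = 40
#: a hit is discarded if it overlaps a better hit by more than this fraction
#: of the shorter envelope
OVERLAP_TOLERANCE = 0.10
#: the LBD counts as "N-terminal" only within this leading fraction
LBD_NTERM_FRACTION = 0.35


@dataclasses.dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    domains: tuple[tuple[str, int, int, float], ...]  # (label, start, end, E)
    crd: tuple[int, int] | None
    class_label: str
    has_lbd: bool
    has_kinase: bool
    has_tm: bool
    has_sam: bool


def resolve_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Greedy selection by ascending E-value (ties: higher bits, then leftmost
    start); a hit is kept iff it overlaps no kept hit by more than 10% of the
    shorter envelope. Returns kept hits sorted by start."""
    ranked = sorted(hits, key=lambda h: (h.evalue, -h.bits, h.start, h.profile))
    kept: list[DomainHit] = []
    for h in ranked:
        ok = True
        for k in kept:
            ov = min(h.end, k.end) - max(h.start, k.start) + 1
            shorter = min(h.end - h.start + 1, k.end - k.start + 1)
            if ov > OVERLAP_TOLERANCE * shorter:
                ok = False
                break
        if ok:
            kept.append(h)
    return sorted(kept, key=lambda h: h.start)


def annotate_crd(
    ordered_hits: list[DomainHit], sequence_length: int
) -> tuple[int, int] | None:
    """The gap between an LBD hit and the first following fn3 hit, when it is
    at least CRD_MIN_GAP residues wide."""
    lbd = next((h for h in ordered_hits if h.profile == LBD), None)
    if lbd is None:
        return None
    fn3 = next(
        (h for h in ordered_hits if h.profile == FN3 and h.start > lbd.end), None
    )
    if fn3 is None:
        return None
    gap = fn3.start - lbd.end - 1
    if gap < CRD_MIN_GAP:
        return None
    return (lbd.end + 1, fn3.start - 1)


def classify(
    protein_id: str,
    hits: list[DomainHit],
    sequence_length: int,
    tm_segments: list[tuple[int, int]] | None = None,
    copper_competent: bool | None = None,
) -> ArchitectureCall:
    """Resolve hits and apply the classification grammar.

    tm_segments are consensus TM intervals from the anchoring module;
    copper_competent is the copper module's verdict for the protein's
    cupredoxin-fold domain (None when no such domain was hit).
    """
    ordered = resolve_overlaps(hits)
    crd = annotate_crd(ordered, sequence_length)
    tm_segments = tm_segments or []

    labels = [h.profile for h in ordered]
    has_lbd = LBD in labels
    has_kin = KINASE in labels
    has_sam = SAM in labels
    has_tm = bool(tm_segments)
    has_fn3 = FN3 in labels
    has_rbd = EPHRIN_RBD in labels
    has_cupre = CUPREDOXIN_DOM in labels

    lbd_first = False
    kin_cterm = False
    if has_lbd:
        lbd_hit = next(h for h in ordered if h.profile == LBD)
        others = [h for h in ordered if h is not lbd_hit]
        lbd_first = (
            all(lbd_hit.start < h.start for h in others)
            and lbd_hit.start <= LBD_NTERM_FRACTION * sequence_length
        )
    if has_kin:
        ect_ends = [h.end for h in ordered if h.profile in (LBD, FN3)]
        kin_starts = [h.start for h in ordered if h.profile == KINASE]
        kin_cterm = not ect_ends or max(kin_starts) > max(ect_ends)

    if has_lbd and lbd_first and has_kin and kin_cterm:
        label = "EPH_FULL"
    elif has_kin and has_fn3 and has_tm and not has_lbd:
        label = "PROTO_EPH_LIKE"
    elif has_lbd:
        label = "EPH_PARTIAL"
    elif has_rbd and not has_kin:
        label = "EPHRIN"
    elif has_cupre and copper_competent:
        label = "CUPREDOXIN"
    else:
        label = "OTHER"

    return ArchitectureCall(
        protein_id=protein_id,
        domains=tuple((h.profile, h.start, h.end, h.evalue) for h in ordered),
        crd=crd,
        class_label=label,
        has_lbd=has_lbd,
        has_kinase=has_kin,
        has_tm=has_tm,
        has_sam=has_sam,
    )


def count_matrix(
    calls: list[ArchitectureCall], lineage_map: dict[str, str]
) -> pd.DataFrame:
    """Per-lineage counts of each non-OTHER class (the gene-count heat-map
    table). Raises KeyError for a protein without a lineage."""
    classes = [c for c in CLASSES if c != "OTHER"]
    lineages = sorted(set(lineage_map.values()))
    mat = pd.DataFrame(0, index=lineages, columns=classes, dtype=int)
    for call in calls:
        if call.protein_id not in lineage_map:
            raise KeyError(f"protein {call.protein_id!r} has no lineage")
        if call.class_label != "OTHER":
            mat.loc[lineage_map[call.protein_id], call.class_label] += 1
    mat.index.name = "lineage"
    return mat


def check_conserved_cysteines(
    domain_alignment: Alignment,
    reference_pairs: list[tuple[int, int]],
) -> pd.DataFrame:
    """Check disulfide-bridge cysteines at annotated match columns.

    reference_pairs are 0-based column-index pairs on the profile-anchored
    alignment. A sequence passes a pair iff both columns hold 'C'; the
    overall verdict requires every pair to pass.
    """
    ncol = domain_alignment.n_cols
    for a, b in reference_pairs:
        if not (0 <= a < ncol and 0 <= b < ncol):
            raise ValueError(f"reference column pair ({a}, {b}) outside alignment")
    rows = []
    for rid, row in domain_alignment.rows:
        status = {
            f"pair_{a + 1}_{b + 1}": (row[a] == "C" and row[b] == "C")
            for a, b in reference_pairs
        }
        status["sequence_id"] = rid
        status["all_pairs"] = all(v for k, v in status.items() if k.startswith("pair"))
        rows.append(status)
    df = pd.DataFrame(rows).set_index("sequence_id")
    return df
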