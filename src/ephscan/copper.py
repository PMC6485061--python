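"""Copper-binding-site scanning of cupredoxin-fold domains.

Cupredoxins chelate copper through an invariant cysteine and two conserved
histidines (azurin numbering C112, H46, H117), flanked by comparatively
variable G45 and M121. Ephrin-like members of the fold carry non-conservative
substitutions at these positions. This module maps azurin-numbered reference
annotations onto profile match states through an annotated reference row of
the profile's alignment, then classifies each aligned hit:

* ``COPPER_COMPETENT`` — H, C, H at the three required columns;
* ``COPPER_LOST`` — any other residue at one or more required columns;
* ``UNMAPPABLE`` — a required column is deleted in the hit.

Only the H/C/H triad is required; the variable positions are recorded but
never change the verdict.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from ephscan.profilehmm import Alignment, ConsistencyError, DomainHit, ProfileHMM

REQUIRED_SITES = ("H46", "C112", "H117")
EXPECTED = {"G45": "G", "H46": "H", "C112": "C", "H117": "H", "M121": "M"}


class UnmappableAnnotationError(ValueError):
    """An annotated residue falls outside the reference or in an insert."""


@dataclasses.dataclass(frozen=True)
class ReferenceColumnMap:
    """Named copper-site positions as 0-based match-state indices."""

    profile_name: str
    columns: dict[str, int]
    disulfide_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        idx = list(self.columns.values())
        if len(set(idx)) != len(idx):
            raise ValueError("reference columns must be distinct")


@dataclasses.dataclass(frozen=True)
class CopperCall:
    protein_id: str
    observed: dict[str, str]
    verdict: str  # COPPER_COMPETENT | COPPER_LOST | UNMAPPABLE


def map_reference_columns(
    profile: ProfileHMM,
    alignment: Alignment,
    reference_id: str,
    annotations: dict[str, int],
    disulfide_pairs: tuple[tuple[int, int], ...] = (),
) -> ReferenceColumnMap:
    """Convert 1-based residue numbers on an annotated reference row into
    match-state indices of the profile built from ``alignment``.

    The reference must be a row of the profile's source alignment, and every
    annotated residue must land in a match column (not an insert region).
    """
    row = next((r for rid, r in alignment.rows if rid == reference_id), None)
    if row is None:
        raise ConsistencyError(f"{reference_id!r} is not a row of the alignment")
    if profile.match_columns is None:
        raise ConsistencyError("profile does not record its source match columns")
    col_to_state = {c: j for j, c in enumerate(profile.match_columns)}
    # residue number -> alignment column of the reference row
    res_to_col: dict[int, int] = {}
    res = 0
    for c, ch in enumerate(row):
        if ch != "-":
            res += 1
            res_to_col[res] = c
    columns: dict[str, int] = {}
    for name, resnum in annotations.items():
        if resnum not in res_to_col:
            raise UnmappableAnnotationError(
                f"residue {resnum} beyond reference length {res}"
            )
        col = res_to_col[resnum]
        if col not in col_to_state:
            raise UnmappableAnnotationError(
                f"residue {resnum} ({name}) aligns to an insert region"
            )
        columns[name] = col_to_state[col]
    return ReferenceColumnMap(
        profile_name=profile.name, columns=columns, disulfide_pairs=disulfide_pairs
    )


def classify_copper_site(hit: DomainHit, column_map: ReferenceColumnMap) -> CopperCall:
    """Verdict for one aligned cupredoxin-fold hit (a pure function of the
    residues observed at the mapped columns)."""
    if hit.profile != column_map.profile_name:
        raise ConsistencyError(
            f"hit from profile {hit.profile!r} does not match map "
            f"{column_map.profile_name!r}"
        )
    observed = {name: hit.row[j] for name, j in column_map.columns.items()}
    required = [name for name in REQUIRED_SITES if name in column_map.columns]
    if any(observed[name] == "-" for name in required):
        verdict = "UNMAPPABLE"
    elif all(observed[name] == EXPECTED[name] for name in required):
        verdict = "COPPER_COMPETENT"
    else:
        verdict = "COPPER_LOST"
    return CopperCall(protein_id=hit.target, observed=observed, verdict=verdict)


def copper_calls_to_frame(calls: list[CopperCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"protein_id": c.protein_id, "verdict": c.verdict}
        row.update({f"site_{k}": v for k, v in sorted(c.observed.items())})
        rows.append(row)
    return pd.DataFrame(rows)
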