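"""Label editing-aware candidates against the standard ORF set.

Each candidate is compared, on the forward reference axis, with the ORFs a
standard (non-editing-aware) extractor returns on the same genome:

* ``sub`` — the candidate's interval is wholly contained in a standard ORF's;
* ``int`` — it partially overlaps at least one standard ORF;
* ``new`` — it overlaps no standard ORF at all.

Overlap is evaluated on closed 1-based intervals, by default restricted to
standard ORFs on the same strand (``strand_mode="same"``); frame is ignored.
A candidate with an exact standard counterpart is contained in it and is
therefore ``sub``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

from .scanner import OrfCandidate

LabelValue = Literal["sub", "int", "new"]
StrandMode = Literal["same", "any"]


@dataclass(frozen=True)
class OrfLabel:
    """sub/int/new classification plus the standard ORF justifying it."""

    value: LabelValue
    matched_standard_id: Optional[str] = None


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Length of the intersection of two closed intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def classify(
    candidate: OrfCandidate,
    standard_set: Sequence[OrfCandidate],
    strand_mode: StrandMode = "same",
) -> OrfLabel:
    """Classify one candidate against the standard ORF set.

    When several standard ORFs qualify, the one with the largest overlap is
    recorded; ties break toward the smallest start coordinate.  An empty
    standard set yields ``new``.
    """
    ci = candidate.fwd_interval
    best: Optional[OrfCandidate] = None
    best_ov = 0
    contained = False
    for std in standard_set:
        if strand_mode == "same" and std.strand != candidate.strand:
            continue
        ov = _overlap(ci, std.fwd_interval)
        if ov == 0:
            continue
        is_contained = std.fwd_interval[0] <= ci[0] and ci[1] <= std.fwd_interval[1]
        better = (
            best is None
            or (is_contained and not contained)
            or (is_contained == contained and ov > best_ov)
            or (is_contained == contained and ov == best_ov and std.fwd_interval[0] < best.fwd_interval[0])
        )
        if better:
            best, best_ov, contained = std, ov, is_contained
    if best is None:
        return OrfLabel("new")
    return OrfLabel("sub" if contained else "int", matched_standard_id=best.id or None)


def classify_all(
    candidates: Sequence[OrfCandidate],
    standard_set: Sequence[OrfCandidate],
    strand_mode: StrandMode = "same",
) -> List[OrfLabel]:
    return [classify(c, standard_set, strand_mode) for c in candidates]


def count_novel(
    candidates: Sequence[OrfCandidate], standard_set: Sequence[OrfCandidate]
) -> Tuple[int, int]:
    """(total, novel) where novel = candidates no standard tool would return.

    A candidate counts as novel when its exact genomic footprint
    (strand + forward interval) matches no standard ORF — i.e. it is not
    identically extractable without editing awareness.  This covers every
    ``int``/``new`` candidate and any ``sub`` candidate with different cut
    points.
    """
    standard_keys = {s.identity_key() for s in standard_set}
    novel = sum(1 for c in candidates if c.identity_key() not in standard_keys)
    return len(candidates), novel
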