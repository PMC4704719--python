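"""Classify input variants into the tracking status taxonomy.

Every input ID receives exactly one status.  ``UNCHANGED`` and ``MERGED``
variants go to the results file with their current coordinate; everything
else is routed to the error file:

* ``DELETED`` — withdrawn, never merged, not reactivated.
* ``INVALID`` — reached a withdrawn ID *through* a merge (submitters
  withdrew and merged the cluster).
* ``CHR_NOTON`` — no longer mapped to any current chromosome.
* ``NO_COORD`` — mapped to multiple contigs, or to a chromosome without an
  exact position.
* ``UNKNOWN`` — absent from every resource dataset.
* ``DUPLICATED`` — a later input resolving to a final ID already claimed by
  an earlier input in the same batch (e.g. the current and an early version
  of the same variant both queried).
* ``UNLIFTED`` — a coordinate input that no chain block covers during a
  build conversion (coordinate-mode runs only).

Reactivated IDs are live: they are never DELETED/INVALID and classify by
their position record like any active ID.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .merge_resolver import resolve
from .resource_io import REAL_CHROMS, CompiledResource, format_rs


class Status(enum.Enum):
    UNCHANGED = "UNCHANGED"
    MERGED = "MERGED"
    DELETED = "DELETED"
    INVALID = "INVALID"
    UNKNOWN = "UNKNOWN"
    CHR_NOTON = "CHR_NOTON"
    NO_COORD = "NO_COORD"
    DUPLICATED = "DUPLICATED"
    UNLIFTED = "UNLIFTED"


#: statuses written to the results file; all others go to the error file
OK_STATUSES = frozenset({Status.UNCHANGED, Status.MERGED})


@dataclass
class TrackedVariant:
    """One input variant's resolution outcome."""

    input_token: str
    input_id: Optional[int]
    final_id: Optional[int]
    status: Status
    chrom: Optional[str] = None
    pos1: Optional[int] = None
    chain: tuple[int, ...] = ()

    @property
    def ok(self) -> bool:
        return self.status in OK_STATUSES


def classify(input_id: int, resource: CompiledResource, input_token: str | None = None) -> TrackedVariant:
    """Apply the status decision cascade to one rs ID.

    Order: resolve merges first; then a live position record decides
    UNCHANGED/MERGED; then the problem chromosome codes; then deletion
    history (DELETED unmerged, INVALID merged); UNKNOWN otherwise.
    """
    token = input_token if input_token is not None else format_rs(input_id)
    r = resource.current_of.get(input_id, input_id)
    merged = r != input_id
    if merged:
        chain = resolve(input_id, resource.current_of).chain
    else:
        chain = (input_id,)

    rec = resource.positions.get(r)
    if rec is not None:
        if rec.chrom in REAL_CHROMS and rec.pos0 is not None:
            return TrackedVariant(
                input_token=token,
                input_id=input_id,
                final_id=r,
                status=Status.MERGED if merged else Status.UNCHANGED,
                chrom=rec.chrom,
                pos1=rec.pos0 + 1,
                chain=chain,
            )
        if rec.chrom == "NotOn":
            return TrackedVariant(token, input_id, r, Status.CHR_NOTON, chain=chain)
        # Multi, or a real chromosome with a blank position
        return TrackedVariant(token, input_id, r, Status.NO_COORD, chain=chain)

    if r in resource.deleted and r not in resource.reactivated:
        status = Status.INVALID if merged else Status.DELETED
        return TrackedVariant(token, input_id, r, status, chain=chain)

    return TrackedVariant(token, input_id, None, Status.UNKNOWN, chain=chain)


def track_batch(
    input_ids: Sequence[int], resource: CompiledResource, tokens: Sequence[str] | None = None
) -> list[TrackedVariant]:
    """Classify a batch in input order, reassigning later collisions.

    When two inputs resolve to the same final ID, the first keeps its
    classification and every subsequent one becomes DUPLICATED.
    """
    if tokens is None:
        tokens = [format_rs(rs) for rs in input_ids]
    out: list[TrackedVariant] = []
    seen_final: set[int] = set()
    for rs, token in zip(input_ids, tokens):
        tv = classify(rs, resource, input_token=token)
        if tv.final_id is not None:
            if tv.final_id in seen_final:
                tv = TrackedVariant(
                    input_token=token,
                    input_id=rs,
                    final_id=tv.final_id,
                    status=Status.DUPLICATED,
                    chain=tv.chain,
                )
            else:
                seen_final.add(tv.final_id)
        out.append(tv)
    return out


def status_counts(variants: Iterable[TrackedVariant]) -> dict[str, int]:
    """Per-status tallies plus a Total row; the run-summary table."""
    counts = {s.value: 0 for s in Status}
    total = 0
    for tv in variants:
        counts[tv.status.value] += 1
        total += 1
    counts["Total"] = total
    return counts
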