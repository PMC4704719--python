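"""Resolve historical rs IDs to their current ones by walking merge chains.

dbSNP merges identifiers pairwise and always folds the later (higher) number
into the earlier (lower) one, so an ID retired years ago may sit several
merge events away from its current name.  The recorded ``rsCurrent`` column
can itself be stale, so it is never trusted as the terminal answer here:
the authoritative resolution walks rsHigh→rsLow links transitively until an
ID with no further mapping is reached.  ``rsCurrent`` disagreements are only
logged.

``compile_resource`` precomputes the full transitive closure so that batch
lookups are a single dictionary access.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .resource_io import (
    CompiledResource,
    HistoryRecord,
    MergeEvent,
    PositionRecord,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResolutionResult:
    """Outcome of walking the merge chain from one input ID.

    ``chain`` lists the visited IDs, input first and final last.  On a
    cycle the walk truncates at the first revisit, ``cycle_detected`` is
    set, and the final ID is the smallest rs number on the cycle (merges go
    high→low in dbSNP, so the smallest member is the best canonical pick).
    """

    input_id: int
    final_id: int
    chain: tuple[int, ...]
    merged: bool
    cycle_detected: bool = False


def build_forward_map(events: Iterable[MergeEvent]) -> dict[int, int]:
    """Map each rs_high to its rs_low.

    dbSNP dumps are chronological, so when the same rs_high appears twice
    with different targets the last occurrence wins (a warning is logged).
    """
    fwd: dict[int, int] = {}
    for ev in events:
        prev = fwd.get(ev.rs_high)
        if prev is not None and prev != ev.rs_low:
            log.warning(
                "rs%d merged to both rs%d and rs%d; keeping the later event",
                ev.rs_high,
                prev,
                ev.rs_low,
            )
        fwd[ev.rs_high] = ev.rs_low
    return fwd


def resolve(rs: int, fwd: Mapping[int, int]) -> ResolutionResult:
    """Follow the forward map until an ID with no mapping is reached.

    Terminates on any input: a visited-set guard detects cycles, in which
    case the smallest rs number on the cycle is returned as final.
    """
    chain: list[int] = [rs]
    seen = {rs}
    cur = rs
    while cur in fwd:
        nxt = fwd[cur]
        if nxt in seen:
            # cycle: its members run from the first occurrence of nxt onward
            cycle = chain[chain.index(nxt) :]
            final = min(cycle)
            return ResolutionResult(
                input_id=rs,
                final_id=final,
                chain=tuple(chain),
                merged=final != rs,
                cycle_detected=True,
            )
        chain.append(nxt)
        seen.add(nxt)
        cur = nxt
    return ResolutionResult(
        input_id=rs,
        final_id=cur,
        chain=tuple(chain),
        merged=cur != rs,
    )


def compile_resource(
    events: Iterable[MergeEvent],
    history_records: Iterable[HistoryRecord],
    position_records: Iterable[PositionRecord],
    build_tag: str = "",
) -> CompiledResource:
    """Precompute current IDs for every historical ID plus history/positions.

    The result satisfies the idempotence invariant: no value of
    ``current_of`` is itself a key, so a compiled lookup equals a full
    chain walk.  Cycle members compile to the tie-break result and are
    counted in one summary log line.
    """
    events = list(events)
    fwd = build_forward_map(events)
    current_of: dict[int, int] = {}
    cycles = 0
    stale_current = 0
    for rs in fwd:
        res = resolve(rs, fwd)
        if res.final_id != rs:  # keep current_of free of self-entries
            current_of[rs] = res.final_id
        if res.cycle_detected:
            cycles += 1
    for ev in events:
        if current_of.get(ev.rs_high, ev.rs_high) != ev.rs_current:
            stale_current += 1
    if cycles:
        log.warning("forward map contains cycles; %d entries compiled via tie-break", cycles)
    if stale_current:
        log.info(
            "%d RsMergeArch rows carry a stale rsCurrent differing from the chain walk",
            stale_current,
        )

    deleted: set[int] = set()
    reactivated: set[int] = set()
    for rec in history_records:
        if rec.reactivated:
            reactivated.add(rec.rs_id)
            deleted.discard(rec.rs_id)
        else:
            if rec.rs_id not in reactivated:
                deleted.add(rec.rs_id)

    positions = {rec.rs_id: rec for rec in position_records}
    return CompiledResource(
        current_of=current_of,
        deleted=deleted,
        reactivated=reactivated,
        positions=positions,
        build_tag=build_tag,
    )
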