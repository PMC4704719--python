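"""Readers for the three dbSNP resource flat files and the compiled-resource format.

dbSNP distributes its identifier history as tab-delimited dumps:

* **RsMergeArch** — every merge event: a later-assigned rs number (rsHigh)
  folded into an earlier one (rsLow), with dbSNP's recorded current ID
  (rsCurrent, which may itself be stale).
* **SNPHistory** — withdrawn rs IDs; re-submitted ones carry a reactivation
  comment.
* **SNPChrPosOnRef** — chromosome/position of every rs ID on a reference
  assembly, with the special chromosome codes ``Multi`` (multiple contigs)
  and ``NotOn`` (no current chromosome).

All readers accept plain or gzip-compressed files (detected by magic bytes,
not extension), skip and count malformed lines, and preserve file order.
Positions in SNPChrPosOnRef are 0-based; this module is the only place that
convention is known — everything user-facing downstream is 1-based.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Optional, Union

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

# 0-based field indices into the dbSNP dumps.  RsMergeArch column order is
# rsHigh, rsLow, build_id, orien, create_time, last_updated_time, rsCurrent.
MERGE_RSHIGH_COL = 0
MERGE_RSLOW_COL = 1
MERGE_RSCURRENT_COL = 6

COMPILED_FORMAT_HEADER = "#rstrack-compiled v1"

#: Chromosome tokens that carry a genuine mappable location.  "PAR" and "Un"
#: do carry coordinates in dbSNP and are treated as real chromosomes.
REAL_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT", "PAR", "Un"])
#: Full closed vocabulary, including the problem codes.
KNOWN_CHROMS = REAL_CHROMS | {"Multi", "NotOn"}

_RS_RE = re.compile(r"^(?:rs)?(\d+)$", re.IGNORECASE)


def parse_rs(token: str) -> int:
    """Normalize an rs accession to its positive integer part.

    Accepts ``rs123``, ``RS123`` and bare ``123``.  Raises ``ValueError``
    for anything else (including zero and negatives).
    """
    m = _RS_RE.match(token.strip())
    if not m:
        raise ValueError(f"not an rs identifier: {token!r}")
    value = int(m.group(1))
    if value < 1:
        raise ValueError(f"rs number must be >= 1: {token!r}")
    return value


def format_rs(value: int) -> str:
    """Emit the canonical lowercase prefixed form, e.g. ``rs123``."""
    return f"rs{value}"


def normalize_chrom(token: str) -> str:
    """Map chromosome spellings onto the index vocabulary.

    ``chr1``/``1`` → ``1``; ``chrM``/``M``/``MT`` → ``MT``.  Tokens outside
    the known vocabulary are returned stripped of a ``chr`` prefix and
    logged once per distinct string by the callers that care.
    """
    t = token.strip()
    if t.lower().startswith("chr"):
        t = t[3:]
    if t.upper() in ("M", "MT"):
        return "MT"
    if t.upper() in ("X", "Y"):
        return t.upper()
    return t


@dataclass(frozen=True)
class MergeEvent:
    """One RsMergeArch row: rs_high was merged into rs_low."""

    rs_high: int
    rs_low: int
    rs_current: int


@dataclass(frozen=True)
class HistoryRecord:
    """A withdrawn rs ID, and whether it was later reactivated."""

    rs_id: int
    reactivated: bool


@dataclass(frozen=True)
class PositionRecord:
    """An rs ID's location per SNPChrPosOnRef; pos0 is 0-based, None if blank."""

    rs_id: int
    chrom: str
    pos0: Optional[int]


@dataclass
class CompiledResource:
    """Fully resolved old-ID→current-ID map plus history and positions.

    ``current_of`` holds entries only for IDs that changed, and is
    idempotent: no value is itself a key.  ``deleted`` holds withdrawn IDs
    that were never reactivated.
    """

    current_of: dict[int, int] = field(default_factory=dict)
    deleted: set[int] = field(default_factory=set)
    reactivated: set[int] = field(default_factory=set)
    positions: dict[int, PositionRecord] = field(default_factory=dict)
    build_tag: str = ""


def open_maybe_gzip(path: PathLike, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing gzip (by magic bytes)."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def _data_lines(handle: IO[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


def read_merge_arch(path: PathLike) -> list[MergeEvent]:
    """Read RsMergeArch rows as (rs_high, rs_low, rs_current) events.

    Lines whose ID fields do not parse as integers are skipped and logged
    with their line number.
    """
    events: list[MergeEvent] = []
    skipped = 0
    with open_maybe_gzip(path) as fh:
        for lineno, fields in _data_lines(fh):
            try:
                high = int(fields[MERGE_RSHIGH_COL])
                low = int(fields[MERGE_RSLOW_COL])
                cur = int(fields[MERGE_RSCURRENT_COL])
            except (IndexError, ValueError):
                skipped += 1
                log.warning("%s:%d: malformed RsMergeArch line, skipped", path, lineno)
                continue
            events.append(MergeEvent(rs_high=high, rs_low=low, rs_current=cur))
    if skipped:
        log.info("%s: skipped %d malformed lines", path, skipped)
    return events


def read_snp_history(path: PathLike) -> list[HistoryRecord]:
    """Read SNPHistory into one record per distinct rs ID.

    An ID is reactivated iff any of its lines carries the case-insensitive
    substring ``reactiv`` in the comment (final) field.
    """
    reactivated: dict[int, bool] = {}
    order: list[int] = []
    skipped = 0
    with open_maybe_gzip(path) as fh:
        for lineno, fields in _data_lines(fh):
            try:
                rs = int(fields[0])
            except (IndexError, ValueError):
                skipped += 1
                log.warning("%s:%d: malformed SNPHistory line, skipped", path, lineno)
                continue
            comment = fields[-1] if len(fields) > 1 else ""
            # dbSNP spells it both "reactivated" and "re-activated"
            marker = "reactiv" in comment.lower().replace("-", "")
            if rs not in reactivated:
                order.append(rs)
            reactivated[rs] = reactivated.get(rs, False) or marker
    if skipped:
        log.info("%s: skipped %d malformed lines", path, skipped)
    return [HistoryRecord(rs_id=rs, reactivated=reactivated[rs]) for rs in order]


def read_chr_pos(path: PathLike) -> list[PositionRecord]:
    """Read SNPChrPosOnRef rows (rs_id, chrom, 0-based position).

    A blank position field yields ``pos0=None``.  Chromosome strings outside
    the closed vocabulary are normalized (``chr`` prefix stripped, M→MT) and
    kept, with one log line per distinct unknown string.
    """
    records: list[PositionRecord] = []
    skipped = 0
    warned: set[str] = set()
    with open_maybe_gzip(path) as fh:
        for lineno, fields in _data_lines(fh):
            try:
                rs = int(fields[0])
                chrom_raw = fields[1]
            except (IndexError, ValueError):
                skipped += 1
                log.warning("%s:%d: malformed SNPChrPosOnRef line, skipped", path, lineno)
                continue
            pos_field = fields[2].strip() if len(fields) > 2 else ""
            if pos_field:
                try:
                    pos0: Optional[int] = int(pos_field)
                except ValueError:
                    skipped += 1
                    log.warning("%s:%d: non-integer position, skipped", path, lineno)
                    continue
                if pos0 < 0:
                    skipped += 1
                    log.warning("%s:%d: negative position, skipped", path, lineno)
                    continue
            else:
                pos0 = None
            chrom = chrom_raw.strip()
            if chrom not in KNOWN_CHROMS:
                chrom = normalize_chrom(chrom)
                if chrom not in KNOWN_CHROMS and chrom_raw not in warned:
                    warned.add(chrom_raw)
                    log.warning("%s: chromosome %r outside known vocabulary", path, chrom_raw)
            records.append(PositionRecord(rs_id=rs, chrom=chrom, pos0=pos0))
    if skipped:
        log.info("%s: skipped %d malformed lines", path, skipped)
    return records


class CompiledFormatError(RuntimeError):
    """Raised when a compiled-resource file has the wrong header/version."""


def write_compiled(resource: CompiledResource, path: PathLike) -> None:
    """Serialize a compiled resource (gzip tab-delimited, versioned header).

    Row layout: ``rs<TAB>current_rs<TAB>flags<TAB>chrom<TAB>pos0`` with empty
    trailing fields where absent.  Flags: D=deleted, R=reactivated.
    """
    keys = set(resource.current_of) | resource.deleted | resource.reactivated | set(
        resource.positions
    )
    with gzip.open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{COMPILED_FORMAT_HEADER} {resource.build_tag}\n")
        for rs in sorted(keys):
            cur = resource.current_of.get(rs, rs)
            flags = ""
            if rs in resource.deleted:
                flags += "D"
            if rs in resource.reactivated:
                flags += "R"
            rec = resource.positions.get(rs)
            chrom = rec.chrom if rec else ""
            pos = "" if rec is None or rec.pos0 is None else str(rec.pos0)
            fh.write(f"{rs}\t{cur}\t{flags}\t{chrom}\t{pos}\n")


def read_compiled(path: PathLike) -> CompiledResource:
    """Read back a compiled resource; fatal on a header/version mismatch."""
    resource = CompiledResource()
    with open_maybe_gzip(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(COMPILED_FORMAT_HEADER):
            raise CompiledFormatError(
                f"{path}: expected header {COMPILED_FORMAT_HEADER!r}, "
                f"found {header[:60]!r}"
            )
        resource.build_tag = header[len(COMPILED_FORMAT_HEADER) :].strip()
        for lineno, raw in enumerate(fh, start=2):
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise CompiledFormatError(f"{path}:{lineno}: expected 5 fields")
            rs = int(fields[0])
            cur = int(fields[1])
            if cur != rs:
                resource.current_of[rs] = cur
            if "D" in fields[2]:
                resource.deleted.add(rs)
            if "R" in fields[2]:
                resource.reactivated.add(rs)
            if fields[3]:
                pos0 = int(fields[4]) if fields[4] else None
                resource.positions[rs] = PositionRecord(rs_id=rs, chrom=fields[3], pos0=pos0)
    return resource
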