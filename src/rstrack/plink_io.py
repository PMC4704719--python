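"""PLINK .map/.bim marker file reading, in-place updating, and writing.

Marker files index the columns of a companion genotype matrix (.ped/.bed)
positionally, so the one hard rule here is conservation: the output always
has exactly the input's rows, in the input's order.  Markers that cannot be
tracked are kept verbatim and their IDs written to an exclusion list, which
feeds straight into a genotype tool's --exclude flag; dropping rows would
silently desynchronize the genotype data.

A marker whose ID parses as an rs accession is tracked by ID; anything else
(array probe names like ``exm-551``, ``.``) falls back to a coordinate
lookup, which is how rs IDs are recovered for probes that never had one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from . import coord_index
from .resource_io import CompiledResource, PathLike, format_rs, open_maybe_gzip, parse_rs
from .tracker_core import Status, TrackedVariant, classify

log = logging.getLogger(__name__)

FIELD_COUNT = {"map": 4, "bim": 6}


@dataclass(frozen=True)
class MarkerRecord:
    """One marker row; non-ID, non-position fields pass through verbatim."""

    chrom: str
    marker_id: str
    cm: str
    pos1: int
    a1: Optional[str] = None
    a2: Optional[str] = None

    def fields(self, kind: str) -> list[str]:
        base = [self.chrom, self.marker_id, self.cm, str(self.pos1)]
        if kind == "bim":
            base += [self.a1 or "0", self.a2 or "0"]
        return base


class MarkerFormatError(RuntimeError):
    pass


def read_markers(path: PathLike, kind: str) -> list[MarkerRecord]:
    """Read a whitespace-delimited map (4-col) or bim (6-col) file.

    A row with the wrong field count is fatal with its line number: a
    silently mangled marker file would desynchronize genotype data.
    """
    want = FIELD_COUNT[kind]
    records: list[MarkerRecord] = []
    with open_maybe_gzip(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != want:
                raise MarkerFormatError(
                    f"{path}:{lineno}: expected {want} fields for {kind}, found {len(fields)}"
                )
            try:
                pos1 = int(fields[3])
            except ValueError:
                raise MarkerFormatError(f"{path}:{lineno}: non-integer position {fields[3]!r}")
            rec = MarkerRecord(
                chrom=fields[0],
                marker_id=fields[1],
                cm=fields[2],
                pos1=pos1,
                a1=fields[4] if kind == "bim" else None,
                a2=fields[5] if kind == "bim" else None,
            )
            records.append(rec)
    return records


def update_markers(
    records: Sequence[MarkerRecord],
    resource: CompiledResource,
    position_index: coord_index.PositionIndex,
) -> tuple[list[MarkerRecord], list[str], list[int]]:
    """Rewrite IDs/coordinates of trackable markers; list the rest.

    Returns (updated records, excluded marker IDs, excluded row indices).
    Output row count and order always equal the input's.
    """
    # offset detection uses only the rows that will need coordinate fallback
    fallback_coords = []
    for rec in records:
        try:
            parse_rs(rec.marker_id)
        except ValueError:
            fallback_coords.append((rec.chrom, rec.pos1))
    offset = 0
    if fallback_coords:
        offset = coord_index.detect_base_offset(fallback_coords, position_index)

    updated: list[MarkerRecord] = []
    excluded: list[str] = []
    excluded_rows: list[int] = []
    seen_final: set[int] = set()
    for i, rec in enumerate(records):
        tv = _track_marker(rec, resource, position_index, offset)
        if tv is not None and tv.status in (Status.UNCHANGED, Status.MERGED):
            if tv.final_id in seen_final:  # duplicated final ID: keep first only
                excluded.append(rec.marker_id)
                excluded_rows.append(i)
                updated.append(rec)
                continue
            seen_final.add(tv.final_id)
            updated.append(
                replace(rec, marker_id=format_rs(tv.final_id), chrom=tv.chrom, pos1=tv.pos1)
            )
        else:
            excluded.append(rec.marker_id)
            excluded_rows.append(i)
            updated.append(rec)
    return updated, excluded, excluded_rows


def _track_marker(
    rec: MarkerRecord,
    resource: CompiledResource,
    position_index: coord_index.PositionIndex,
    offset: int,
) -> Optional[TrackedVariant]:
    try:
        rs = parse_rs(rec.marker_id)
    except ValueError:
        hits = coord_index.lookup(rec.chrom, rec.pos1, offset, position_index)
        if not hits:
            return None
        rs = hits[0]
    return classify(rs, resource, input_token=rec.marker_id)


def write_markers(records: Sequence[MarkerRecord], path: PathLike, kind: str) -> None:
    """Write tab-delimited markers, preserving field order and row count."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write("\t".join(rec.fields(kind)) + "\n")


def write_excluded(ids: Sequence[str], path: PathLike) -> None:
    """One marker ID per line, ready for a genotype tool's exclusion flag."""
    with open(path, "w", encoding="utf-8") as fh:
        for marker_id in ids:
            fh.write(marker_id + "\n")
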