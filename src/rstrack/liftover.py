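"""Point liftover between genome assemblies via UCSC chain files.

A chain file describes an alignment between a source ("target" in UCSC
jargon, t) and destination ("query", q) assembly as a header line::

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id

followed by ``size [dt dq]`` triplets giving ungapped block lengths and the
gaps after them on each side.  This module expands the triplets into
absolute ungapped blocks and maps single positions through them.  Variants
are points here, so no interval splitting is needed.  Where chains overlap
on the source, the higher-scoring chain wins (file order breaks score
ties), matching the UCSC convention.

All public positions are 1-based; the chain format itself is 0-based
half-open and that arithmetic stays inside this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from intervaltree import IntervalTree

from .resource_io import PathLike, normalize_chrom, open_maybe_gzip

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped aligned block, absolute coordinates, 0-based half-open.

    Negative-strand query coordinates are stored as-is (in reverse-strand
    space); ``lift_point`` flips them using ``q_size``.
    """

    t_chrom: str
    t_start: int
    t_end: int
    q_chrom: str
    q_start: int
    q_end: int
    q_strand: str
    q_size: int
    score: int
    order: int  # position of the parent chain in the file, for tie-breaks


class ChainFormatError(RuntimeError):
    pass


@dataclass
class ChainMap:
    """Blocks grouped by source chromosome, in interval trees for lookup."""

    trees: dict[str, IntervalTree]

    @property
    def blocks(self) -> list[ChainBlock]:
        out = []
        for tree in self.trees.values():
            out.extend(iv.data for iv in tree)
        return out


def parse_chain(path: PathLike) -> ChainMap:
    """Expand a UCSC chain file into ungapped blocks grouped by source chrom."""
    trees: dict[str, IntervalTree] = {}
    order = -1
    with open_maybe_gzip(path) as fh:
        lines = iter(enumerate(fh, start=1))
        for lineno, raw in lines:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] != "chain":
                raise ChainFormatError(f"{path}:{lineno}: expected chain header, got {line[:40]!r}")
            if len(fields) not in (12, 13):
                raise ChainFormatError(f"{path}:{lineno}: malformed chain header")
            try:
                score = int(fields[1])
                t_chrom = normalize_chrom(fields[2])
                t_strand = fields[4]
                t_start, t_end = int(fields[5]), int(fields[6])
                q_chrom = normalize_chrom(fields[7])
                q_size = int(fields[8])
                q_strand = fields[9]
                q_start, q_end = int(fields[10]), int(fields[11])
            except ValueError as exc:
                raise ChainFormatError(f"{path}:{lineno}: malformed chain header: {exc}")
            if t_strand != "+":
                raise ChainFormatError(f"{path}:{lineno}: source strand must be +")
            order += 1
            t_cur, q_cur = t_start, q_start
            tree = trees.setdefault(t_chrom, IntervalTree())
            done = False
            for blineno, braw in lines:
                bline = braw.strip()
                if not bline:
                    done = True  # blank line terminates the block list
                    break
                parts = bline.split()
                try:
                    size = int(parts[0])
                    dt = int(parts[1]) if len(parts) == 3 else 0
                    dq = int(parts[2]) if len(parts) == 3 else 0
                except (ValueError, IndexError):
                    raise ChainFormatError(f"{path}:{blineno}: malformed block line")
                if size > 0:
                    tree.addi(
                        t_cur,
                        t_cur + size,
                        ChainBlock(
                            t_chrom=t_chrom,
                            t_start=t_cur,
                            t_end=t_cur + size,
                            q_chrom=q_chrom,
                            q_start=q_cur,
                            q_end=q_cur + size,
                            q_strand=q_strand,
                            q_size=q_size,
                            score=score,
                            order=order,
                        ),
                    )
                t_cur += size + dt
                q_cur += size + dq
                if len(parts) == 1:  # final line of the chain has no gaps
                    done = True
                    break
            if not done:
                raise ChainFormatError(f"{path}: truncated block list in chain {order}")
    return ChainMap(trees=trees)


def lift_point(chrom: str, pos1: int, chains: ChainMap) -> Optional[tuple[str, int]]:
    """Map a 1-based point to the destination assembly; None if uncovered.

    Among covering blocks the highest chain score wins, then file order.
    Negative-strand blocks flip through the destination chromosome length.
    """
    c = normalize_chrom(chrom)
    tree = chains.trees.get(c)
    if tree is None:
        return None
    p = pos1 - 1
    hits = tree[p]
    if not hits:
        return None
    block: ChainBlock = min(hits, key=lambda iv: (-iv.data.score, iv.data.order)).data
    q0 = block.q_start + (p - block.t_start)
    if block.q_strand == "-":
        q0 = block.q_size - 1 - q0
    return block.q_chrom, q0 + 1
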