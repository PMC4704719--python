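"""Synthetic dbSNP resource fixtures with a constructive ground truth.

Real dbSNP dumps are tens of gigabytes; this generator emulates their
structure at test scale so every pipeline stage runs without a download.
Each simulated variant is assigned a *fate* up front — live, withdrawn,
reactivated, multi-contig, off-chromosome, coordinate-less, or entirely
absent — and a merge chain of configurable depth, and the three resource
files (RsMergeArch, SNPHistory, SNPChrPosOnRef) are then written to realize
that fate.  Because the expected status, final ID and coordinate of every
input are recorded *while the files are built*, the emitted truth table is
an oracle independent of the tracker itself: a recovery test compares the
tracker's output against construction, not against another run of the same
code.

Adversarial structure is available on demand: merge cycles (which never
occur in clean dbSNP dumps but must not hang the resolver) and a toy UCSC
chain file that shifts one synthetic assembly onto another, including a
negative-strand chain.

The same seed always yields byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .resource_io import format_rs

_CHROMS = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]

#: source-assembly positions are offset by this much in the fixture chain file
CHAIN_SHIFT = 1_000


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the simulated dbSNP snapshot.

    Fractions partition the variant pool; whatever they leave over is live
    variants with genuine coordinates.  ``max_chain_depth`` bounds the
    number of merge events per variant (depth drawn uniformly from
    0..max; 0 means never merged).
    """

    n_variants: int = 1000
    max_chain_depth: int = 3
    fraction_deleted: float = 0.05
    fraction_reactivated: float = 0.03
    fraction_multi: float = 0.02
    fraction_noton: float = 0.02
    fraction_blank_pos: float = 0.02
    fraction_unknown: float = 0.02
    cycle_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_deleted,
            self.fraction_reactivated,
            self.fraction_multi,
            self.fraction_noton,
            self.fraction_blank_pos,
            self.fraction_unknown,
        )
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("fate fractions must lie in [0,1] and jointly sum to <= 1")


@dataclass(frozen=True)
class TruthRow:
    """Constructive expectation for one input variant."""

    input_id: int
    status: str
    final_id: int | None
    chrom: str | None
    pos1: int | None


@dataclass
class Fixture:
    merge_path: Path
    history_path: Path
    pos_path: Path
    chain_path: Path
    input_path: Path
    truth_path: Path
    truth: list[TruthRow] = field(default_factory=list)


def generate(spec: FixtureSpec, out_dir: Path | str) -> Fixture:
    """Write the resource files, a toy chain file, and the truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    # rs numbers drawn without replacement from a bounded range so chains
    # can never collide by accident
    pool_size = spec.n_variants * (spec.max_chain_depth + 2) + 10 * (spec.cycle_count + 1)
    numbers = rng.sample(range(1, pool_size * 20), pool_size)
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        got = numbers[cursor : cursor + k]
        cursor += k
        return got

    fates = _assign_fates(spec, rng)

    merge_rows: list[tuple[int, int, int]] = []  # (high, low, current)
    history_rows: list[tuple[int, str]] = []  # (rs, comment)
    pos_rows: list[tuple[int, str, str]] = []  # (rs, chrom, pos field)
    truth: list[TruthRow] = []

    for fate in fates:
        depth = rng.randint(0, spec.max_chain_depth)
        if fate == "unknown":
            depth = 0
        ids = sorted(take(depth + 1), reverse=True)  # merges go high -> low
        head, final = ids[0], ids[-1]
        for high, low in zip(ids, ids[1:]):
            merge_rows.append((high, low, final))
        merged = depth > 0
        chrom = rng.choice(_CHROMS)
        pos0 = rng.randint(100, 10_000_000)

        if fate == "live":
            pos_rows.append((final, chrom, str(pos0)))
            status = "MERGED" if merged else "UNCHANGED"
            truth.append(TruthRow(head, status, final, chrom, pos0 + 1))
        elif fate == "deleted":
            history_rows.append((final, ""))
            status = "INVALID" if merged else "DELETED"
            truth.append(TruthRow(head, status, final, None, None))
        elif fate == "reactivated":
            history_rows.append((final, "Re-activation of cluster"))
            pos_rows.append((final, chrom, str(pos0)))
            status = "MERGED" if merged else "UNCHANGED"
            truth.append(TruthRow(head, status, final, chrom, pos0 + 1))
        elif fate == "multi":
            pos_rows.append((final, "Multi", ""))
            truth.append(TruthRow(head, "NO_COORD", final, None, None))
        elif fate == "noton":
            pos_rows.append((final, "NotOn", ""))
            truth.append(TruthRow(head, "CHR_NOTON", final, None, None))
        elif fate == "blank_pos":
            pos_rows.append((final, chrom, ""))
            truth.append(TruthRow(head, "NO_COORD", final, None, None))
        elif fate == "unknown":
            truth.append(TruthRow(head, "UNKNOWN", None, None, None))
        else:  # pragma: no cover
            raise AssertionError(fate)

    # adversarial merge cycles; their members carry no other records, so a
    # cycle head resolves (via the smallest-member tie-break) to UNKNOWN
    for _ in range(spec.cycle_count):
        a, b, c = sorted(take(3))
        merge_rows.append((b, c, a))
        merge_rows.append((c, b, a))
        truth.append(TruthRow(b, "UNKNOWN", None, None, None))

    fx = Fixture(
        merge_path=out_dir / "RsMergeArch.tsv",
        history_path=out_dir / "SNPHistory.tsv",
        pos_path=out_dir / "SNPChrPosOnRef.tsv",
        chain_path=out_dir / "toy.chain",
        input_path=out_dir / "input_ids.txt",
        truth_path=out_dir / "truth.tsv",
        truth=truth,
    )
    _write_merge(fx.merge_path, merge_rows)
    _write_history(fx.history_path, history_rows)
    _write_pos(fx.pos_path, pos_rows)
    _write_chain(fx.chain_path)
    fx.input_path.write_text("".join(format_rs(t.input_id) + "\n" for t in truth))
    _write_truth(fx.truth_path, truth)
    return fx


def _assign_fates(spec: FixtureSpec, rng: random.Random) -> list[str]:
    n = spec.n_variants
    counts = {
        "deleted": int(spec.fraction_deleted * n),
        "reactivated": int(spec.fraction_reactivated * n),
        "multi": int(spec.fraction_multi * n),
        "noton": int(spec.fraction_noton * n),
        "blank_pos": int(spec.fraction_blank_pos * n),
        "unknown": int(spec.fraction_unknown * n),
    }
    fates: list[str] = []
    for fate, k in counts.items():
        fates.extend([fate] * k)
    fates.extend(["live"] * (n - len(fates)))
    rng.shuffle(fates)
    return fates


def _write_merge(path: Path, rows: list[tuple[int, int, int]]) -> None:
    # dbSNP dump layout: rsHigh, rsLow, build, orien, created, updated, rsCurrent
    with open(path, "w") as fh:
        for high, low, cur in rows:
            fh.write(f"{high}\t{low}\t142\t0\t2014-01-01\t2014-06-01\t{cur}\n")


def _write_history(path: Path, rows: list[tuple[int, str]]) -> None:
    with open(path, "w") as fh:
        for rs, comment in rows:
            fh.write(f"{rs}\t2013-01-01\t142\t142\t{comment}\n")


def _write_pos(path: Path, rows: list[tuple[int, str, str]]) -> None:
    with open(path, "w") as fh:
        for rs, chrom, pos in rows:
            fh.write(f"{rs}\t{chrom}\t{pos}\n")


def _write_chain(path: Path) -> None:
    """Toy two-assembly chain: chr1/chr2 shifted +CHAIN_SHIFT, chr3 reversed.

    Every source position p on chr1/chr2 within [0, 20M) maps to
    p + CHAIN_SHIFT; chr3 maps through a negative-strand chain.
    """
    span = 20_000_000
    q_size = span + CHAIN_SHIFT
    with open(path, "w") as fh:
        for i, chrom in enumerate(("chr1", "chr2")):
            fh.write(
                f"chain 1000 {chrom} {span} + 0 {span} "
                f"{chrom} {q_size} + {CHAIN_SHIFT} {q_size} {i + 1}\n"
            )
            fh.write(f"{span}\n\n")
        fh.write(
            f"chain 900 chr3 {span} + 0 {span} chr3 {q_size} - 0 {span} 3\n"
        )
        fh.write(f"{span}\n\n")


def _write_truth(path: Path, truth: list[TruthRow]) -> None:
    with open(path, "w") as fh:
        fh.write("input_id\tstatus\tfinal_id\tchrom\tpos1\n")
        for t in truth:
            fh.write(
                "\t".join(
                    [
                        format_rs(t.input_id),
                        t.status,
                        format_rs(t.final_id) if t.final_id is not None else "",
                        t.chrom or "",
                        str(t.pos1) if t.pos1 is not None else "",
                    ]
                )
                + "\n"
            )


def read_truth(path: Path | str) -> list[TruthRow]:
    """Parse a truth table written by :func:`generate`."""
    rows: list[TruthRow] = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            tok_id, status, final, chrom, pos1 = line.rstrip("\n").split("\t")
            rows.append(
                TruthRow(
                    input_id=int(tok_id[2:]),
                    status=status,
                    final_id=int(final[2:]) if final else None,
                    chrom=chrom or None,
                    pos1=int(pos1) if pos1 else None,
                )
            )
    return rows
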