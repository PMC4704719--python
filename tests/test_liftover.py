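"""Chain parsing and point liftover against an exhaustive per-base oracle."""

import gzip

import pytest

from rstrack.liftover import ChainFormatError, lift_point, parse_chain

# one chain, one block: t[100,200) -> q[1100,1200), + strand
SIMPLE = "chain 100 chr1 1000 + 100 200 chr1 5000 + 1100 1200 1\n100\n\n"

# two 50-base blocks separated by a 10-base source-only gap (dt=10, dq=0)
GAPPED = "chain 100 chr1 1000 + 100 210 chr1 5000 + 1100 1200 1\n50\t10\t0\n50\n\n"

# negative-strand chain: q coordinates in reverse-strand space
NEG = "chain 80 chr2 1000 + 300 360 chr2 2000 - 400 460 2\n60\n\n"

# overlapping chains on the source: the higher-scoring one must win
OVERLAP = (
    "chain 900 chr3 1000 + 100 200 chr3 5000 + 3000 3100 1\n100\n\n"
    "chain 500 chr3 1000 + 150 250 chr3 5000 + 4000 4100 2\n100\n\n"
)


def brute_force_map(text):
    """Independent per-base table built straight from the chain triplets."""
    table = {}
    lines = iter(text.splitlines())
    for line in lines:
        if not line.startswith("chain"):
            continue
        f = line.split()
        score, t_chrom = int(f[1]), f[2].removeprefix("chr")
        t_cur = int(f[5])
        q_chrom, q_size, q_strand = f[7].removeprefix("chr"), int(f[8]), f[9]
        q_cur = int(f[10])
        for bline in lines:
            if not bline.strip():
                break
            parts = [int(x) for x in bline.split()]
            size = parts[0]
            for i in range(size):
                q0 = q_cur + i
                if q_strand == "-":
                    q0 = q_size - 1 - q0
                key = (t_chrom, t_cur + i + 1)  # 1-based
                if key not in table or score > table[key][0]:
                    table[key] = (score, q_chrom, q0 + 1)
            if len(parts) == 3:
                t_cur += size + parts[1]
                q_cur += size + parts[2]
            else:
                break
    return {k: (c, p) for k, (s, c, p) in table.items()}


def chain_file(tmp_path, text, name="test.chain"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParseChain:
    def test_single_block_expansion(self, tmp_path):
        cm = parse_chain(chain_file(tmp_path, SIMPLE))
        (block,) = cm.blocks
        assert (block.t_start, block.t_end) == (100, 200)
        assert (block.q_start, block.q_end) == (1100, 1200)
        assert block.q_strand == "+"

    def test_gap_arithmetic(self, tmp_path):
        cm = parse_chain(chain_file(tmp_path, GAPPED))
        blocks = sorted(cm.blocks, key=lambda b: b.t_start)
        first, second = blocks
        assert second.t_start == first.t_end + 10
        assert second.q_start == first.q_end

    def test_empty_file(self, tmp_path):
        assert parse_chain(chain_file(tmp_path, "")).blocks == []

    def test_gzipped_chain(self, tmp_path):
        p = tmp_path / "c.chain.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(SIMPLE)
        assert len(parse_chain(p).blocks) == 1

    def test_malformed_header_fatal(self, tmp_path):
        with pytest.raises(ChainFormatError):
            parse_chain(chain_file(tmp_path, "chain oops\n"))

    def test_truncated_block_list_fatal(self, tmp_path):
        text = "chain 100 chr1 1000 + 100 200 chr1 5000 + 1100 1200 1\n50\t10\t0"
        with pytest.raises(ChainFormatError, match="truncated"):
            parse_chain(chain_file(tmp_path, text))


class TestLiftPoint:
    def test_plus_strand_arithmetic(self, tmp_path):
        cm = parse_chain(chain_file(tmp_path, SIMPLE))
        assert lift_point("chr1", 150, cm) == ("1", 1150)

    def test_uncovered_position_absent(self, tmp_path):
        cm = parse_chain(chain_file(tmp_path, SIMPLE))
        assert lift_point("chr1", 50, cm) is None
        assert lift_point("chr9", 150, cm) is None

    def test_higher_score_wins_on_overlap(self, tmp_path):
        cm = parse_chain(chain_file(tmp_path, OVERLAP))
        # position 180 (1-based) is covered by both chains; score 900 wins
        assert lift_point("chr3", 180, cm) == ("3", 3000 + 179 - 100 + 1)

    @pytest.mark.parametrize("text", [SIMPLE, GAPPED, NEG, OVERLAP], ids=["simple", "gapped", "neg", "overlap"])
    def test_equals_per_base_oracle_everywhere(self, tmp_path, text):
        cm = parse_chain(chain_file(tmp_path, text))
        oracle = brute_force_map(text)
        for pos1 in range(1, 600):
            for chrom in ("1", "2", "3"):
                assert lift_point(chrom, pos1, cm) == oracle.get((chrom, pos1)), (chrom, pos1)

    @pytest.mark.parametrize("text", [SIMPLE, GAPPED, NEG], ids=["simple", "gapped", "neg"])
    def test_injective_within_chain(self, tmp_path, text):
        cm = parse_chain(chain_file(tmp_path, text))
        seen = {}
        for pos1 in range(1, 600):
            out = lift_point("chr1" if "chr1" in text else "chr2", pos1, cm)
            if out is not None:
                assert out not in seen, f"{pos1} and {seen[out]} collide on {out}"
                seen[out] = pos1
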