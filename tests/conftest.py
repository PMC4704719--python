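from pathlib import Path

import pytest

from rstrack import merge_resolver, resource_io

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toya_dir() -> Path:
    return DATA / "toyA"


@pytest.fixture(scope="session")
def toya(toya_dir) -> resource_io.CompiledResource:
    """The small hand-written dbSNP snapshot used across modules.

    Merge chains 1002→1001→1000 and 2001→2000; 3001→3000 where 3000 was
    withdrawn; 4000 withdrawn outright; 5000 withdrawn then reactivated
    (and mapped to chr3:42); 6000 on Multi; 7000 on NotOn.
    """
    return merge_resolver.compile_resource(
        resource_io.read_merge_arch(toya_dir / "RsMergeArch.tsv"),
        resource_io.read_snp_history(toya_dir / "SNPHistory.tsv"),
        resource_io.read_chr_pos(toya_dir / "SNPChrPosOnRef.tsv"),
        build_tag="toyA-hg19",
    )


@pytest.fixture(scope="session")
def toya_positions(toya_dir):
    return resource_io.read_chr_pos(toya_dir / "SNPChrPosOnRef.tsv")
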