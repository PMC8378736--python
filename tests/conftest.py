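import sys
from pathlib import Path

import numpy as np
import pysam
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from smallder import SampleRecord


@pytest.fixture
def bam_factory(tmp_path):
    """Write a small sorted+indexed BAM from (chrom, pos1, length) reads."""

    def make(
        name: str,
        reads: list[tuple[str, int, int]],
        chrom_lengths: dict[str, int] | None = None,
        condition: str = "",
    ) -> SampleRecord:
        chrom_lengths = chrom_lengths or {"chr1": 1000}
        chroms = list(chrom_lengths)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()],
        }
        path = tmp_path / f"{name}.bam"
        reads = sorted(reads, key=lambda r: (chroms.index(r[0]), r[1]))
        with pysam.AlignmentFile(str(path), "wb", header=header) as af:
            for i, (chrom, pos1, length) in enumerate(reads):
                a = pysam.AlignedSegment(af.header)
                a.query_name = f"r{i}"
                a.flag = 0
                a.reference_id = chroms.index(chrom)
                a.reference_start = pos1 - 1
                a.mapping_quality = 60
                a.cigarstring = f"{length}M"
                af.write(a)
        pysam.index(str(path))
        return SampleRecord(path, name, condition)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
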