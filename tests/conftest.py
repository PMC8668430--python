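"""Shared fixtures: synthetic read sets and toy SAM/BED builders."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from dimerseq import write_synthetic_reads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211)


@pytest.fixture(scope="session")
def synthetic_reads(tmp_path_factory):
    """Error-free full-structure reads: (fastq path, truth DataFrame)."""
    d = tmp_path_factory.mktemp("reads")
    fastq = d / "reads.fastq.gz"
    truth = write_synthetic_reads(
        fastq, d / "truth.tsv", n_cells=12, reads_per_cell=15, seq_error_rate=0.0, seed=7
    )
    return fastq, truth


def make_sam(path, references, records):
    """Write a SAM file from simple dict records.

    ``references``: list of (name, length). ``records``: dicts with keys
    qname, flag, ref, pos (0-based), cigar, and optional tags (dict).
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in references],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(header)
            a.query_name = r["qname"]
            a.flag = r.get("flag", 0)
            a.reference_id = [n for n, _ in references].index(r["ref"])
            a.reference_start = r["pos"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigarstring = r["cigar"]
            seq_len = sum(n for op, n in a.cigartuples or [] if op in (0, 1, 4, 7, 8))
            a.query_sequence = "A" * seq_len
            for tag, val in r.get("tags", {}).items():
                a.set_tag(tag, val)
            out.write(a)
    return path
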