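"""File-format glue: MTX triplets, alignment record streams, event tables."""

from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pysam
import scipy.io
import scipy.sparse as sp

from .dedup import CountMatrix
from .fusion import FusionEvent

__all__ = [
    "open_text_writer",
    "write_mtx",
    "read_mtx",
    "records_from_alignment",
    "write_events_tsv",
    "write_qc_json",
]


def open_text_writer(path) -> TextIO:
    """Text writer, gzip-compressed for ``.gz`` paths.

    Gzip members are written with a zeroed timestamp so that repeated
    runs with the same seed produce byte-identical files.
    """
    if str(path).endswith(".gz"):
        return _io.TextIOWrapper(gzip.GzipFile(str(path), "wb", mtime=0))
    return open(path, "w")


def write_mtx(cm: CountMatrix, outdir) -> None:
    """Write a Matrix Market triplet: matrix.mtx, features.tsv, barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(cm.matrix))
    (outdir / "features.tsv").write_text("".join(f"{f}\n" for f in cm.features))
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cm.cells))


def read_mtx(outdir) -> CountMatrix:
    outdir = Path(outdir)
    mat = sp.csr_matrix(scipy.io.mmread(str(outdir / "matrix.mtx")))
    features = (outdir / "features.tsv").read_text().splitlines()
    cells = (outdir / "barcodes.tsv").read_text().splitlines()
    return CountMatrix(matrix=mat, features=features, cells=cells)


def records_from_alignment(
    path, feature_tag: str = "XT"
) -> Iterator[tuple[str, str, str]]:
    """Yield (cell, feature, umi) from a SAM/BAM with header-embedded tags.

    Read names follow the extraction convention ``readid_BARCODE_UMI``;
    the feature is taken from ``feature_tag`` (falling back to the
    reference name, the transcriptome-alignment convention).  Unmapped,
    secondary and supplementary records are skipped.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            parts = rec.query_name.split("_")
            if len(parts) < 3:
                continue
            feature = (
                rec.get_tag(feature_tag) if rec.has_tag(feature_tag) else rec.reference_name
            )
            if feature is None:
                continue
            yield parts[-2], str(feature), parts[-1]


def write_events_tsv(events: Iterable[FusionEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tn_cells\tn_umis\tn_reads\n")
        for e in events:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{len(e.cells)}\t{e.n_umis}\t{e.n_reads}\n")


def write_qc_json(qc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
        fh.write("\n")
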