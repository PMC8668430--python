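"""Pipeline orchestration and dataset-level QC.

Runs extract -> correct -> count -> fusion with files on disk between
stages, so any stage can be re-run independently, and computes the QC
panel: poly(A) detection rate, perfect-complementarity fraction ``b``,
theoretical and measured base-calling accuracy, assignment fractions and
the number of cells passing the feature filter.  The barnyard summary
classifies cells of a mixed-species run by UMI purity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .correct import assign_all, build_whitelist
from .dedup import CountMatrix, count_matrix
from .dimer import measured_accuracy, theoretical_accuracy
from .extract import ReadLayout, extract_fastq, find_polyA
from .fusion import GeneModel, call_fusions
from .io import records_from_alignment, write_events_tsv, write_mtx, write_qc_json

__all__ = ["RunConfig", "BarnyardSummary", "run_pipeline", "barnyard"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serialized verbatim into the QC."""

    fastq: str
    outdir: str
    alignment: str | None = None  # SAM/BAM with feature tags, for counting
    bed: str | None = None  # gene model, for fusion calling
    handle: str = "AAGCAGTGGTATCAACGCAGAGTAC"
    polyT_min_len: int = 15
    handle_max_edits: int = 3
    edit_distance: int = 6
    expected_cells: int = 1000
    min_features: int = 200
    min_fusion_umis: int = 5
    feature_tag: str = "XT"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edit_distance", "expected_cells", "min_fusion_umis"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_features < 0:
            raise ValueError("min_features must be >= 0")

    @property
    def layout(self) -> ReadLayout:
        return ReadLayout(
            handle=self.handle,
            polyT_min_len=self.polyT_min_len,
            handle_max_edits=self.handle_max_edits,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _polyA_rate_fastq(path, layout: ReadLayout) -> float:
    n = hits = 0
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            n += 1
            s = entry.sequence.upper()
            if (
                find_polyA(s, min_len=layout.polyT_min_len, base="A") is not None
                or find_polyA(s, min_len=layout.polyT_min_len, base="T") is not None
            ):
                hits += 1
    return hits / n if n else 0.0


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and persists) the QC report.

    Counting and fusion calling run only when an alignment (and, for
    fusions, a gene BED) is configured; the extraction and correction
    stages always run.  Intermediates are kept under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    layout = config.layout
    qc: dict = {
        "tool_version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
    }

    # --- extract ---------------------------------------------------------
    try:
        structures, stats = extract_fastq(
            config.fastq, out / "extracted.fastq.gz", out / "rejected.tsv", layout
        )
    except Exception as exc:  # pragma: no cover - stage tagging only
        raise RuntimeError(f"[extract] stage failed: {exc}") from exc
    qc["n_reads"] = stats.n_reads
    qc["n_parsed"] = stats.n_parsed
    qc["parse_rate"] = stats.parse_rate
    qc["fail_counts"] = stats.fail_counts
    qc["polyA_detection_rate"] = _polyA_rate_fastq(config.fastq, layout)
    if not structures:
        raise RuntimeError("[extract] stage failed: no read parsed")

    # --- correct ---------------------------------------------------------
    try:
        barcodes = [s.barcode_seq for s in structures]
        acc = measured_accuracy(barcodes)
        wl = build_whitelist(structures, expected_cells=config.expected_cells)
        wl.to_tsv(out / "whitelist.tsv")
        results, summary = assign_all(structures, wl, max_edit=config.edit_distance)
    except Exception as exc:
        raise RuntimeError(f"[correct] stage failed: {exc}") from exc
    qc["b_perfect_complementarity"] = acc.b
    qc["theoretical_accuracy"] = acc.theoretical_accuracy
    qc["measured_accuracy"] = acc.measured_accuracy
    qc["fraction_perfect"] = summary.fraction_perfect
    qc["fraction_corrected"] = summary.fraction_corrected
    qc["fraction_unassigned"] = summary.fraction_unassigned
    qc["whitelist_size"] = len(wl)

    from .io import open_text_writer

    with open_text_writer(out / "corrected.fastq.gz") as fq, open(
        out / "assignments.tsv", "w"
    ) as tsv:
        tsv.write("read_id\tstatus\tbarcode\tedit_distance\n")
        for s, r in zip(structures, results):
            ed = "" if r.edit_distance_used is None else r.edit_distance_used
            tsv.write(f"{s.read_id}\t{r.status}\t{r.assigned_barcode or ''}\t{ed}\n")
            if r.assigned_barcode is not None:
                cdna = s.cdna_seq or "N"
                fq.write(
                    f"@{s.read_id}_{r.assigned_barcode}_{s.umi_seq}\n"
                    f"{cdna}\n+\n{'I' * len(cdna)}\n"
                )

    # --- count -----------------------------------------------------------
    if config.alignment:
        try:
            cm = count_matrix(
                records_from_alignment(config.alignment, config.feature_tag),
                min_features=config.min_features,
            )
            write_mtx(cm, out / "counts")
        except Exception as exc:
            raise RuntimeError(f"[count] stage failed: {exc}") from exc
        qc["n_cells_passing"] = len(cm.cells)
        qc["n_features"] = len(cm.features)
        qc["total_umis"] = int(cm.matrix.sum())

    # --- fusion ----------------------------------------------------------
    if config.alignment and config.bed:
        try:
            genes = GeneModel.from_bed(config.bed)
            with pysam.AlignmentFile(config.alignment, check_sq=False) as fh:
                events, counters = call_fusions(
                    fh, genes, min_umis=config.min_fusion_umis
                )
            write_events_tsv(events, out / "fusions.tsv")
        except Exception as exc:
            raise RuntimeError(f"[fusion] stage failed: {exc}") from exc
        qc["fusion_events"] = len(events)
        qc["fusion_counters"] = dict(counters)

    write_qc_json(qc, out / "qc.json")
    return qc


@dataclass
class BarnyardSummary:
    """Per-cell species purity and classification for a two-species run."""

    per_cell: pd.DataFrame  # columns: cell, <species...>, purity, label
    class_counts: dict[str, int] = field(default_factory=dict)
    purity_threshold: float = 0.9


def barnyard(
    cm: CountMatrix,
    species_of_feature: dict[str, str],
    purity_threshold: float = 0.9,
) -> BarnyardSummary:
    """Classify cells as pure one-species or mixed by UMI purity.

    Purity is the dominant species' share of the cell's UMIs (in [0.5, 1]
    for two species); cells at or above the threshold take the dominant
    species label, others are "mixed".  Cells with zero UMIs are excluded.
    """
    if not 0.5 < purity_threshold <= 1.0:
        raise ValueError("purity_threshold must lie in (0.5, 1]")
    species = sorted(set(species_of_feature.values()))
    masks = {
        sp_name: np.array([species_of_feature.get(f) == sp_name for f in cm.features])
        for sp_name in species
    }
    dense = np.asarray(cm.matrix.sum(axis=0)).ravel()  # noqa: F841 (total check below)
    rows = []
    for j, cell in enumerate(cm.cells):
        col = cm.matrix.getcol(j).toarray().ravel()
        sums = {sp_name: int(col[masks[sp_name]].sum()) for sp_name in species}
        total = sum(sums.values())
        if total == 0:
            continue
        top = max(species, key=lambda s: sums[s])
        purity = sums[top] / total
        label = top if purity >= purity_threshold else "mixed"
        rows.append({"cell": cell, **sums, "purity": purity, "label": label})
    per_cell = pd.DataFrame(rows)
    counts = per_cell["label"].value_counts().to_dict() if len(rows) else {}
    return BarnyardSummary(
        per_cell=per_cell, class_counts=counts, purity_threshold=purity_threshold
    )
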