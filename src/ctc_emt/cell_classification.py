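"""Cell-origin classification (tCTC / pNC / tNC) and per-cell QC.

Micromanipulated single cells carry two layers of evidence: the protein
panel used at picking time (epithelial/mesenchymal markers, CD45/CD31
exclusion markers) and the transcriptome.  A cell picked as a CTC on
protein can still express immune or endothelial transcripts, casting
doubt on its tumor origin; combining both layers yields three classes:

tCTC (true CTC)
    protein CTC-positive and every configured immune/endothelial marker
    transcript below the expression threshold (default < 4, on
    normalized counts);
pNC (potential normal cell)
    protein CTC-positive but at least one marker transcript at or above
    the threshold;
tNC (true normal cell)
    protein panel negative for both epithelial and mesenchymal markers
    (the protein rule dominates whatever the transcriptome shows).

QC retains cells with at least ``min_genes`` detected genes (default 800,
inclusive); transcriptome quality for low-throughput workflows is a
separate rule requiring at least 2 of the 3 housekeeping genes
(EEF1A1, ACTB, GAPDH).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .phenotyping import MarkerPanel, call_phenotype

HOUSEKEEPING_GENES = ("EEF1A1", "ACTB", "GAPDH")


class CellClassificationError(ValueError):
    """Raised for a contradictory protein panel (cancer marker together
    with an exclusion marker or DAPI signal)."""


@dataclass
class CellRecord:
    cell_id: str
    panel: MarkerPanel
    expr: Mapping[str, float] = field(default_factory=dict)
    n_genes_detected: int | None = None
    housekeeping_detected: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self) -> None:
        if self.n_genes_detected is None and self.expr:
            self.n_genes_detected = sum(1 for v in self.expr.values() if v > 0)


@dataclass
class ClassifierConfig:
    """Thresholds of the origin classifier and QC filters.

    ``immune_endo_markers`` is deliberately editable: the default ships
    the hematopoietic (PTPRC, encoding CD45) and endothelial (PECAM1,
    encoding CD31) transcripts, and any lineage list may be supplied.
    ``expr_threshold`` applies to normalized expression; a transcript is
    'expressed' at values ≥ threshold (strictly below passes as absent).
    """

    immune_endo_markers: tuple[str, ...] = ("PTPRC", "PECAM1")
    expr_threshold: float = 4.0
    min_genes: int = 800
    min_housekeeping: int = 2

    def validate(self) -> None:
        if self.expr_threshold <= 0 or self.min_genes <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.min_housekeeping <= len(HOUSEKEEPING_GENES):
            raise ValueError("min_housekeeping must be in 1..3")


def classify_origin(cell: CellRecord, cfg: ClassifierConfig | None = None) -> str:
    """Classify one cell as tCTC, pNC or tNC (see module docstring).

    Raises :class:`CellClassificationError` when the protein panel is
    contradictory: a cancer marker positive together with CD45/CD31 or a
    DAPI signal cannot be assigned an origin.
    """
    cfg = cfg or ClassifierConfig()
    cfg.validate()
    panel = cell.panel
    if not panel.epithelial_positive and not panel.mesenchymal_positive:
        return "tNC"
    call = call_phenotype(panel)
    if call.label == "not_CTC":
        raise CellClassificationError(
            f"cell {cell.cell_id}: contradictory panel ({call.reason})"
        )
    marker_expressed = any(
        cell.expr.get(g, 0.0) >= cfg.expr_threshold
        for g in cfg.immune_endo_markers
    )
    return "pNC" if marker_expressed else "tCTC"


def qc_filter(
    cells: Sequence[CellRecord], cfg: ClassifierConfig | None = None
) -> tuple[list[CellRecord], list[tuple[str, str]]]:
    """Retain cells with ≥ min_genes detected genes; log the rejected.

    Returns (retained cells, rejection log of (cell_id, reason)); the two
    always partition the input.
    """
    cfg = cfg or ClassifierConfig()
    cfg.validate()
    retained: list[CellRecord] = []
    rejected: list[tuple[str, str]] = []
    for cell in cells:
        n = cell.n_genes_detected
        if n is None:
            rejected.append((cell.cell_id, "n_genes_detected not available"))
        elif n >= cfg.min_genes:
            retained.append(cell)
        else:
            rejected.append(
                (cell.cell_id, f"{n} genes detected < {cfg.min_genes}")
            )
    return retained, rejected


def housekeeping_pass(
    cell: CellRecord, cfg: ClassifierConfig | None = None
) -> bool:
    """True when at least min_housekeeping of the 3 housekeeping genes
    (EEF1A1, ACTB, GAPDH) were detected in the control PCR."""
    cfg = cfg or ClassifierConfig()
    cfg.validate()
    return sum(bool(b) for b in cell.housekeeping_detected) >= cfg.min_housekeeping
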