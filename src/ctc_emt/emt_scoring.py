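"""Per-cell EMT scoring and quartile-based phenotype classes.

The EMT score of a cell contrasts a fixed mesenchymal gene panel (FN1,
CDH2, SERPINE1) with a fixed epithelial panel (KRT5, KRT7, KRT8, KRT18,
KRT19, EPCAM, CDH1) on reads-per-million (RPM) normalized expression:

    M = Σ_mesenchymal log10(RPM + 1)
    E = Σ_epithelial  log10(RPM + 1)
    score = (M − E) / n_total            (n_total = 10 by default)

Positive scores indicate a mesenchymal-leaning, negative an
epithelial-leaning transcriptome.  Within the scored CTC population the
score quartiles define phenotype classes: strictly below Q1 → eCTC,
strictly above Q3 → mCTC, otherwise intermediate.  Quartiles use linear
interpolation between order statistics (plotting position (k−1)/(n−1));
the convention is configurable because alternatives can shift tail
membership by a cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_MESENCHYMAL = ("FN1", "CDH2", "SERPINE1")
DEFAULT_EPITHELIAL = ("KRT5", "KRT7", "KRT8", "KRT18", "KRT19", "EPCAM", "CDH1")


@dataclass(frozen=True)
class EmtGenePanel:
    mesenchymal: tuple[str, ...] = DEFAULT_MESENCHYMAL
    epithelial: tuple[str, ...] = DEFAULT_EPITHELIAL

    def __post_init__(self) -> None:
        overlap = set(self.mesenchymal) & set(self.epithelial)
        if overlap:
            raise ValueError(f"panels must be disjoint; shared: {sorted(overlap)}")
        if not self.mesenchymal or not self.epithelial:
            raise ValueError("both panels must be non-empty")

    @property
    def n_total(self) -> int:
        return len(self.mesenchymal) + len(self.epithelial)


@dataclass
class EmtScore:
    cell_id: str
    m_sum: float
    e_sum: float
    score: float
    quartile_class: str | None = None  # eCTC | intermediate | mCTC


def rpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Add an ``"rpm"`` layer: count / cell total × 10⁶ per gene and cell."""
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"cells with zero total counts cannot be RPM-normalized: "
            f"{list(zero.index)}"
        )
    matrix.layers["rpm"] = matrix.counts / totals * 1e6
    return matrix


def emt_score(
    rpm: Mapping[str, float] | pd.Series,
    panel: EmtGenePanel | None = None,
    cell_id: str = "",
) -> EmtScore:
    """Score one cell from its RPM vector; missing panel genes count as 0."""
    panel = panel or EmtGenePanel()
    if isinstance(rpm, pd.Series):
        rpm = rpm.to_dict()
    missing = [g for g in (*panel.mesenchymal, *panel.epithelial) if g not in rpm]
    if missing:
        logger.warning(
            "cell %s: panel genes absent from matrix, scored as RPM 0: %s",
            cell_id or "<unnamed>", missing,
        )
    m_sum = float(sum(np.log10(rpm.get(g, 0.0) + 1.0) for g in panel.mesenchymal))
    e_sum = float(sum(np.log10(rpm.get(g, 0.0) + 1.0) for g in panel.epithelial))
    return EmtScore(cell_id=cell_id, m_sum=m_sum, e_sum=e_sum,
                    score=(m_sum - e_sum) / panel.n_total)


def score_cells(
    matrix: ExpressionMatrix, panel: EmtGenePanel | None = None
) -> pd.DataFrame:
    """EMT scores for every cell; RPM-normalizes first if needed.

    Returns a DataFrame indexed by cell id with m_sum, e_sum, score.
    """
    panel = panel or EmtGenePanel()
    if "rpm" not in matrix.layers:
        rpm_normalize(matrix)
    rpm = matrix.layers["rpm"]
    rows = [emt_score(rpm[c], panel, cell_id=c) for c in rpm.columns]
    return pd.DataFrame(
        {"m_sum": [r.m_sum for r in rows],
         "e_sum": [r.e_sum for r in rows],
         "score": [r.score for r in rows]},
        index=rpm.columns,
    )


def classify_by_quartiles(
    scores: Sequence[float] | pd.Series, method: str = "linear"
) -> tuple[list[str], float, float]:
    """Assign eCTC / intermediate / mCTC classes by score quartiles.

    Q1 and Q3 are computed over the supplied scores (the CTC population
    being classified) with the given quantile ``method`` (numpy
    convention name; default linear interpolation of order statistics).
    Labels use strict inequalities — score < Q1 → eCTC, score > Q3 →
    mCTC — so degenerate (all-equal) score sets yield all-intermediate.

    Returns (labels, Q1, Q3).
    """
    values = np.asarray(scores, dtype=float)
    if values.size < 4:
        raise ValueError("quartile classification needs at least 4 scores")
    q1, q3 = np.quantile(values, [0.25, 0.75], method=method)
    labels = [
        "eCTC" if s < q1 else ("mCTC" if s > q3 else "intermediate")
        for s in values
    ]
    return labels, float(q1), float(q3)


def score_and_classify(
    matrix: ExpressionMatrix,
    panel: EmtGenePanel | None = None,
    method: str = "linear",
) -> tuple[pd.DataFrame, dict]:
    """Score all cells, then classify by quartiles of those scores.

    Returns the per-cell table (m_sum, e_sum, score, quartile_class) and
    a small run report (panel, quantile convention, Q1, Q3).
    """
    panel = panel or EmtGenePanel()
    table = score_cells(matrix, panel)
    labels, q1, q3 = classify_by_quartiles(table["score"], method=method)
    table = table.copy()
    table["quartile_class"] = labels
    report = {
        "mesenchymal_panel": list(panel.mesenchymal),
        "epithelial_panel": list(panel.epithelial),
        "n_total": panel.n_total,
        "quantile_method": method,
        "q1": q1,
        "q3": q3,
    }
    return table, report
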