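"""EMT phenotype calling from immunofluorescence marker panels.

A putative circulating tumor cell (CTC) is scored on a seven-marker panel:
epithelial surface markers (EpCAM, E-cadherin), mesenchymal surface markers
(cell-surface vimentin, MCAM), the hematopoietic exclusion marker CD45, the
endothelial exclusion marker CD31, and nuclear DAPI (a viable, intact cell
shows no DAPI signal under these staining conditions, so DAPI positivity
marks a dead cell and excludes it).

The module also carries the small arithmetic helpers of the isolation
workflow: extrapolation of observed counts to a 5 mL blood volume,
enrichment/depletion and spike-in recovery metrics, and the qPCR
Cq-to-relative-quantity transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

PHENOTYPES = ("eCTC", "emCTC", "mCTC")

#: default last qPCR cycle considered quantifiable
DEFAULT_CQ_MAX = 35


@dataclass(frozen=True)
class MarkerPanel:
    """Thresholded (present/absent) immunofluorescence calls for one cell."""

    epcam: bool = False
    ecad: bool = False
    csvim: bool = False
    mcam: bool = False
    cd45: bool = False
    cd31: bool = False
    dapi: bool = False

    @property
    def epithelial_positive(self) -> bool:
        return self.epcam or self.ecad

    @property
    def mesenchymal_positive(self) -> bool:
        return self.csvim or self.mcam

    @property
    def excluded(self) -> bool:
        """True when an exclusion marker (CD45, CD31) or DAPI is positive."""
        return self.cd45 or self.cd31 or self.dapi


@dataclass(frozen=True)
class PhenotypeCall:
    label: str  # eCTC | emCTC | mCTC | not_CTC
    reason: str


def call_phenotype(panel: MarkerPanel) -> PhenotypeCall:
    """Assign the EMT phenotype of one cell from its marker panel.

    A CTC must lack CD45, CD31 and DAPI signal and show at least one
    cancer (epithelial or mesenchymal) marker.  Among CTCs, the label is
    eCTC for epithelial-only, mCTC for mesenchymal-only, and emCTC when
    both marker axes are positive.  The function is total: every panel
    maps to exactly one label.
    """
    if panel.excluded:
        pos = [m for m in ("cd45", "cd31", "dapi") if getattr(panel, m)]
        return PhenotypeCall("not_CTC", f"exclusion marker positive: {','.join(pos)}")
    epi = panel.epithelial_positive
    mes = panel.mesenchymal_positive
    if not epi and not mes:
        return PhenotypeCall("not_CTC", "no cancer marker positive")
    if epi and mes:
        return PhenotypeCall("emCTC", "epithelial and mesenchymal markers positive")
    if epi:
        return PhenotypeCall("eCTC", "epithelial markers only")
    return PhenotypeCall("mCTC", "mesenchymal markers only")


def scale_to_volume(observed_count: float, screened_fraction: float) -> float:
    """Extrapolate a count observed in a screened sample fraction to 5 mL.

    When only a portion of an enriched sample could be screened, the
    recorded count is scaled proportionally (``observed / fraction``);
    fractional results are legitimate and kept.
    """
    if not 0 < screened_fraction <= 1:
        raise ValueError(
            f"screened_fraction must be in (0, 1], got {screened_fraction}"
        )
    if observed_count < 0:
        raise ValueError("observed_count must be non-negative")
    return observed_count / screened_fraction


def enrichment_factor(cells_before: float, cells_after: float) -> float:
    """Fraction of PBMCs surviving the enrichment procedure.

    The companion depletion rate is ``1 - enrichment_factor``.
    """
    if cells_before <= 0:
        raise ValueError("cells_before must be positive")
    if cells_after < 0:
        raise ValueError("cells_after must be non-negative")
    return cells_after / cells_before


def depletion_rate(cells_before: float, cells_after: float) -> float:
    """PBMC depletion achieved by the enrichment procedure (1 − enrichment)."""
    return 1.0 - enrichment_factor(cells_before, cells_after)


def recovery_rate(recovered: float, spiked: float) -> float:
    """Fraction of spiked tumor cells recovered after the full isolation."""
    if spiked <= 0:
        raise ValueError("spiked must be positive")
    if recovered < 0:
        raise ValueError("recovered must be non-negative")
    if recovered > spiked:
        warnings.warn(
            f"recovered ({recovered}) exceeds spiked ({spiked}); rate > 1",
            stacklevel=2,
        )
    return recovered / spiked


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR quantification cycle; ``cq=None`` encodes 'undetected'."""

    cq: float | None
    cq_max: int = DEFAULT_CQ_MAX


def rq_from_cq(m: QpcrMeasurement) -> float:
    """Relative quantity RQ = 2^(CqMAX − Cq).

    Undetected reactions, and Cq beyond the last quantifiable cycle
    ``cq_max``, map to RQ = 0.
    """
    if m.cq_max <= 0:
        raise ValueError("cq_max must be a positive cycle number")
    if m.cq is None:
        return 0.0
    if m.cq <= 0:
        raise ValueError("detected Cq must be positive")
    if m.cq > m.cq_max:
        return 0.0
    return float(2.0 ** (m.cq_max - m.cq))


def call_phenotypes_frame(panels: pd.DataFrame) -> pd.DataFrame:
    """Vectorized phenotype calling over a cell table with boolean columns.

    ``panels`` must carry columns epcam, ecad, csvim, mcam, cd45, cd31,
    dapi.  Returns a copy with ``phenotype`` and ``reason`` columns added.
    """
    required = ("epcam", "ecad", "csvim", "mcam", "cd45", "cd31", "dapi")
    missing = [c for c in required if c not in panels.columns]
    if missing:
        raise ValueError(f"missing marker columns: {missing}")
    calls = [
        call_phenotype(MarkerPanel(**{c: bool(row[c]) for c in required}))
        for _, row in panels.iterrows()
    ]
    out = panels.copy()
    out["phenotype"] = [c.label for c in calls]
    out["reason"] = [c.reason for c in calls]
    return out


def summarize_positivity(
    counts: pd.DataFrame, phenotypes: Iterable[str] = PHENOTYPES
) -> Mapping[str, float]:
    """Cohort-level CTC positivity summary from per-patient phenotype counts.

    ``counts`` has one row per patient and one column per phenotype (counts
    per 5 mL; fractional extrapolated values allowed, any value > 0 marks
    the patient positive for that phenotype).

    Returns fractions of: overall CTC positivity, each single-phenotype-only
    pattern (e.g. ``mCTC_only``), and patients with two or more co-existing
    phenotypes (``mixed``).
    """
    phenotypes = tuple(phenotypes)
    missing = [p for p in phenotypes if p not in counts.columns]
    if missing:
        raise ValueError(f"missing phenotype columns: {missing}")
    pos = counts[list(phenotypes)] > 0
    n = len(counts)
    if n == 0:
        raise ValueError("empty cohort")
    n_pos_phenotypes = pos.sum(axis=1)
    out = {"n_patients": float(n), "positive": float((n_pos_phenotypes > 0).mean())}
    for p in phenotypes:
        only = pos[p] & (n_pos_phenotypes == 1)
        out[f"{p}_only"] = float(only.mean())
    out["mixed"] = float((n_pos_phenotypes >= 2).mean())
    return out
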