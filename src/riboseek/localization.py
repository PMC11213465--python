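"""Nuclear vs cytoplasmic RNA localization from FISH spots and fractionation qPCR.

Two independent quantifications of the same biological quantity:

* single-molecule FISH: per-cell nuclear and cytoplasmic spot counts; the
  aggregate cytoplasmic percentage is the median of per-cell percentages
  (robust to segmentation outliers); a pooled-spot estimate is also reported.
* subcellular fractionation + RT-qPCR: efficiency^(-ΔΔCt) relative
  quantification of the cytosolic vs nuclear fraction, with compartment
  controls (a Neat1-like nuclear transcript, a Gapdh-like cytosolic one)
  gating QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellSpotCounts",
    "QpcrMeasurement",
    "LocalizationResult",
    "fish_localization",
    "relative_quantification",
    "fractionation_localization",
]


@dataclass(frozen=True)
class CellSpotCounts:
    cell_id: str
    nuclear_spots: int
    cytoplasmic_spots: int

    def __post_init__(self) -> None:
        if self.nuclear_spots < 0 or self.cytoplasmic_spots < 0:
            raise ValueError("spot counts must be non-negative")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Target and reference Ct in one fraction; efficiency is fold per cycle."""

    target_ct: float
    reference_ct: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.target_ct) and math.isfinite(self.reference_ct)):
            raise ValueError("Ct values must be finite")
        if self.efficiency <= 1:
            raise ValueError("amplification efficiency must exceed 1")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


@dataclass
class LocalizationResult:
    method: str  # "fish" | "fractionation"
    percent_cytoplasmic: float
    n_cells: int = 0
    per_cell_percent: list[float] = field(default_factory=list)
    pooled_percent: float | None = None
    qc_flags: dict = field(default_factory=dict)

    @property
    def percent_nuclear(self) -> float:
        return 100.0 - self.percent_cytoplasmic

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "percent_cytoplasmic": self.percent_cytoplasmic,
            "percent_nuclear": self.percent_nuclear,
            "pooled_percent": self.pooled_percent,
            "n_cells": self.n_cells,
            "qc_flags": self.qc_flags,
        }


def fish_localization(
    cells: list[CellSpotCounts], min_cells: int = 100
) -> LocalizationResult:
    """Aggregate per-cell cytoplasmic percentages (median) across FISH cells.

    Cells with zero total spots are excluded from per-cell statistics and
    counted in QC.  A low-n flag is raised when fewer than ``min_cells``
    informative cells remain.
    """
    if not cells:
        raise ValueError("no cells provided")
    per_cell = []
    pooled_nuc = pooled_cyto = 0
    n_empty = 0
    for c in cells:
        total = c.nuclear_spots + c.cytoplasmic_spots
        if total == 0:
            n_empty += 1
            continue
        per_cell.append(100.0 * c.cytoplasmic_spots / total)
        pooled_nuc += c.nuclear_spots
        pooled_cyto += c.cytoplasmic_spots
    if not per_cell:
        raise ValueError("no cell with any spot")
    qc = {"n_zero_spot_cells": n_empty, "low_n": len(per_cell) < min_cells}
    return LocalizationResult(
        method="fish",
        percent_cytoplasmic=float(np.median(per_cell)),
        n_cells=len(per_cell),
        per_cell_percent=per_cell,
        pooled_percent=100.0 * pooled_cyto / (pooled_nuc + pooled_cyto),
        qc_flags=qc,
    )


def relative_quantification(a: QpcrMeasurement, b: QpcrMeasurement) -> float:
    """Fold-change of a relative to b: efficiency^(ΔCt_b - ΔCt_a)."""
    if a.efficiency != b.efficiency:
        raise ValueError("measurements must share an efficiency model")
    return a.efficiency ** (b.delta_ct - a.delta_ct)


def _percent_cyto(cyto: QpcrMeasurement, nuc: QpcrMeasurement) -> float:
    r = relative_quantification(cyto, nuc)
    return 100.0 * r / (1.0 + r)


def fractionation_localization(
    cyto: QpcrMeasurement,
    nuc: QpcrMeasurement,
    nuclear_controls: dict[str, tuple[QpcrMeasurement, QpcrMeasurement]],
    cytosolic_controls: dict[str, tuple[QpcrMeasurement, QpcrMeasurement]],
) -> LocalizationResult:
    """Cytoplasmic percentage from fractionation qPCR with control-based QC.

    Controls are supplied as name -> (cyto measurement, nuc measurement).
    QC fails when any nuclear control computes > 50% cytoplasmic or any
    cytosolic control < 50%.
    """
    if not nuclear_controls or not cytosolic_controls:
        raise ValueError("at least one nuclear and one cytosolic control required")
    pct = _percent_cyto(cyto, nuc)
    failed = {}
    for name, (c, n) in nuclear_controls.items():
        p = _percent_cyto(c, n)
        if p > 50.0:
            failed[name] = p
    for name, (c, n) in cytosolic_controls.items():
        p = _percent_cyto(c, n)
        if p < 50.0:
            failed[name] = p
    return LocalizationResult(
        method="fractionation",
        percent_cytoplasmic=pct,
        qc_flags={"controls_failed": failed, "qc_pass": not failed},
    )
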