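"""ddCt quantification of qRT-PCR validation plates.

Each target gene is multiplexed with a housekeeping reference (Gapdh in
the validation experiment).  Per arm, replicate Ct values are
aggregated (mean by default); then

    dCt_seed  = Ct_target_seed  - Ct_ref_seed
    dCt_ctrl  = Ct_target_ctrl  - Ct_ref_ctrl
    ddCt      = dCt_seed - dCt_ctrl
    log2FC    = -ddCt

assuming a doubling of product per cycle (amplification efficiency 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ValidationError

CT_RANGE = (0.0, 45.0)


@dataclass
class QpcrMeasurement:
    gene: str
    condition: str  # seed | control
    div: int
    ct_replicates: tuple[float, ...]
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.condition not in ("seed", "control"):
            raise ValidationError(f"condition must be seed/control, got {self.condition!r}")
        cts = tuple(float(c) for c in self.ct_replicates)
        if len(cts) < 1:
            raise ValidationError("at least one Ct replicate required")
        if any(not CT_RANGE[0] < c < CT_RANGE[1] for c in cts):
            raise ValidationError(f"Ct values must lie in {CT_RANGE}, got {cts}")
        self.ct_replicates = cts

    def aggregate(self, method: str = "mean") -> float:
        if method == "mean":
            return float(np.mean(self.ct_replicates))
        if method == "median":
            return float(np.median(self.ct_replicates))
        raise ValidationError(f"unknown aggregation {method!r}")

    @property
    def replicate_sd(self) -> float:
        return float(np.std(self.ct_replicates, ddof=1)) if len(self.ct_replicates) > 1 else 0.0


@dataclass
class DdctResult:
    gene: str
    div: int
    ddct: float
    log2fc: float
    warnings: list = field(default_factory=list)


def delta_delta_ct(
    target_seed: QpcrMeasurement,
    target_ctrl: QpcrMeasurement,
    ref_seed: QpcrMeasurement,
    ref_ctrl: QpcrMeasurement,
    agg: str = "mean",
    sd_cutoff: float = 0.5,
) -> DdctResult:
    """ddCt log2 fold change for one gene at one DIV.

    Raises when arms are mismatched in gene or DIV; flags (without
    failing) any arm whose replicate SD exceeds ``sd_cutoff`` cycles.
    """
    if target_seed.gene != target_ctrl.gene:
        raise ValidationError("target arms refer to different genes")
    if len({m.div for m in (target_seed, target_ctrl, ref_seed, ref_ctrl)}) != 1:
        raise ValidationError("all four arms must share the same DIV")
    if target_seed.condition != "seed" or ref_seed.condition != "seed":
        raise ValidationError("seed arms must have condition='seed'")
    if target_ctrl.condition != "control" or ref_ctrl.condition != "control":
        raise ValidationError("control arms must have condition='control'")

    warnings = [
        f"{m.gene}/{m.condition}: replicate SD {m.replicate_sd:.2f} > {sd_cutoff}"
        for m in (target_seed, target_ctrl, ref_seed, ref_ctrl)
        if m.replicate_sd > sd_cutoff
    ]
    d_seed = target_seed.aggregate(agg) - ref_seed.aggregate(agg)
    d_ctrl = target_ctrl.aggregate(agg) - ref_ctrl.aggregate(agg)
    ddct = d_seed - d_ctrl
    return DdctResult(target_seed.gene, target_seed.div, ddct, -ddct, warnings)


def read_plate(path) -> pd.DataFrame:
    """Read a qPCR plate CSV: gene, condition, div, well, ct, is_reference."""
    plate = pd.read_csv(path)
    required = {"gene", "condition", "div", "ct", "is_reference"}
    missing = required - set(plate.columns)
    if missing:
        raise ValidationError(f"plate CSV missing columns: {sorted(missing)}")
    return plate


def analyze_plate(
    plate: pd.DataFrame,
    reference: str = "Gapdh",
    agg: str = "mean",
    sd_cutoff: float = 0.5,
) -> pd.DataFrame:
    """ddCt log2FC for every (target gene, DIV) on a plate table."""

    def measurement(gene: str, condition: str, div: int) -> QpcrMeasurement:
        rows = plate[
            (plate["gene"] == gene) & (plate["condition"] == condition) & (plate["div"] == div)
        ]
        if rows.empty:
            raise ValidationError(f"missing arm: gene={gene}, condition={condition}, div={div}")
        return QpcrMeasurement(
            gene, condition, int(div), tuple(rows["ct"]), gene == reference
        )

    targets = sorted(set(plate.loc[~plate["is_reference"].astype(bool), "gene"]))
    if reference not in set(plate["gene"]):
        raise ValidationError(f"reference gene {reference!r} absent from plate")
    rows = []
    for gene in targets:
        for div in sorted(set(plate.loc[plate["gene"] == gene, "div"].astype(int))):
            result = delta_delta_ct(
                measurement(gene, "seed", div),
                measurement(gene, "control", div),
                measurement(reference, "seed", div),
                measurement(reference, "control", div),
                agg=agg,
                sd_cutoff=sd_cutoff,
            )
            rows.append(
                {
                    "gene": gene,
                    "div": div,
                    "log2fc": result.log2fc,
                    "ddct": result.ddct,
                    "sd_flag": "; ".join(result.warnings),
                }
            )
    return pd.DataFrame(rows)
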