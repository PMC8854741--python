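"""Monotone-trend classification against pathology and transcript-protein
concordance.

A feature's response profile is its seed - control log2 fold change at
each DIV (from the contrast table).  Pathology increases strictly with
DIV, so Spearman's rho between profile and pathology is +1 exactly when
the profile rises strictly over time, -1 when it falls strictly, and
anything else (including any tie) is non-monotone.  With three time
points the attainable rho values for tie-free profiles are
{-1, -0.5, 0.5, 1}.

Concordance restricts to transcript-significant genes with a mapped,
complete-case-quantified protein and classifies the joint direction
(up_up, down_down, up_down, down_up); a gene is *selected* when both
layers are strictly monotone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .matrix import ValidationError

QUADRANTS = ("up_up", "down_down", "up_down", "down_up")


@dataclass
class TrendProfile:
    feature_id: str
    profile: tuple[float, ...]
    rho: float
    trend_class: str  # up | down | non_monotone


def trend_classify(profile, pathology=None, feature_id: str = "") -> TrendProfile:
    """Classify a per-DIV profile as up / down / non-monotone.

    ``pathology`` defaults to the DIV ranks (only ranks matter for
    Spearman, so the imaging-derived curve gives identical results);
    when given it must be strictly increasing and the same length as
    the profile.
    """
    profile = np.asarray(profile, dtype=float)
    if pathology is None:
        pathology = np.arange(1.0, profile.size + 1.0)
    pathology = np.asarray(pathology, dtype=float)
    if profile.shape != pathology.shape:
        raise ValidationError("profile and pathology must have the same length")
    if profile.size < 3:
        raise ValidationError("profile needs at least 3 time points")
    if np.any(np.diff(pathology) <= 0):
        raise ValidationError("pathology must be strictly increasing")
    diffs = np.diff(profile)
    if np.all(diffs > 0):
        trend, rho = "up", 1.0
    elif np.all(diffs < 0):
        trend, rho = "down", -1.0
    elif np.all(profile == profile[0]):  # constant: rank correlation undefined
        trend, rho = "non_monotone", 0.0
    else:
        rho = float(spearmanr(profile, pathology).statistic)
        trend = "non_monotone"
    return TrendProfile(feature_id, tuple(profile.tolist()), float(rho), trend)


def trend_table(contrasts: pd.DataFrame, pathology: dict[int, float] | None = None) -> pd.DataFrame:
    """Per-feature trend classification of a contrast table.

    ``pathology`` optionally maps DIV -> pathology value (e.g. the
    imaging percent-of-final readout); by default DIV order is used.
    """
    rows = []
    for gene, grp in contrasts.sort_values("div").groupby("gene_id", sort=False):
        divs = grp["div"].to_numpy()
        path = np.array([pathology[d] for d in divs]) if pathology else None
        tp = trend_classify(grp["log2fc"].to_numpy(), path, feature_id=gene)
        row = {"feature_id": gene, "rho": tp.rho, "trend_class": tp.trend_class}
        for d, v in zip(divs, tp.profile):
            row[f"log2fc_div{d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _quadrant(rna_class: str, protein_class: str) -> str:
    if rna_class in ("up", "down") and protein_class in ("up", "down"):
        return f"{rna_class}_{protein_class}"
    return "none"


def concordance(
    rna_trends: pd.DataFrame,
    protein_trends: pd.DataFrame,
    mapping: pd.DataFrame,
    summaries: pd.DataFrame,
) -> pd.DataFrame:
    """Transcript-protein concordance records for significant genes.

    One row per transcript-significant gene: its mapped protein (if
    any), both rho values, the joint-direction quadrant, a ``selected``
    flag (both layers strictly monotone) and a reason code
    (``ok`` / ``unmapped`` / ``unquantified`` / ``non_monotone``).
    """
    if mapping["gene_id"].duplicated().any():
        dups = mapping.loc[mapping["gene_id"].duplicated(), "gene_id"].unique()
        raise ValidationError(f"duplicate mapping rows for gene(s): {list(dups[:5])}")
    gene_to_protein = dict(zip(mapping["gene_id"], mapping["protein_id"]))
    rna_by_gene = rna_trends.set_index("feature_id")
    prot_by_id = protein_trends.set_index("feature_id")

    rows = []
    sig_genes = summaries.loc[summaries["fdr_significant"], "gene_id"]
    for gene in sig_genes:
        rna_row = rna_by_gene.loc[gene]
        record = {
            "gene_id": gene,
            "protein_id": "",
            "rho_rna": float(rna_row["rho"]),
            "rho_protein": np.nan,
            "quadrant": "none",
            "selected": False,
            "reason": "",
        }
        protein_id = gene_to_protein.get(gene, "")
        if not protein_id:
            record["reason"] = "unmapped"
        elif protein_id not in prot_by_id.index:
            record["protein_id"] = protein_id
            record["reason"] = "unquantified"
        else:
            prot_row = prot_by_id.loc[protein_id]
            record["protein_id"] = protein_id
            record["rho_protein"] = float(prot_row["rho"])
            record["quadrant"] = _quadrant(rna_row["trend_class"], prot_row["trend_class"])
            if record["quadrant"] != "none":
                record["selected"] = True
                record["reason"] = "ok"
            else:
                record["reason"] = "non_monotone"
        rows.append(record)
    return pd.DataFrame(
        rows,
        columns=["gene_id", "protein_id", "rho_rna", "rho_protein", "quadrant", "selected", "reason"],
    )


def quadrant_counts(records: pd.DataFrame) -> dict[str, int]:
    """Counts over the four joint-direction quadrants (selected genes)."""
    selected = records[records["selected"]]
    counts = selected["quadrant"].value_counts().to_dict()
    return {q: int(counts.get(q, 0)) for q in QUADRANTS}
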