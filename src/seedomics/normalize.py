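"""Matrix preprocessing: quantile normalization (RNA), total-abundance
normalization and complete-case filtering (protein), and the imaging
inclusion readout transform.

The protein preparation order is fixed as complete-case filter ->
total-abundance normalization on linear scale -> log2 transform, after
which the protein matrix can be analysed with the same factorial
machinery as RNA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import AbundanceMatrix, ValidationError, design_for_matrix


def quantile_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Force every sample to share the mean empirical distribution.

    Each sample's sorted values are replaced by the across-sample mean
    of the order statistics; within-sample ranks are preserved.  Tied
    values within a sample receive the mean of the reference values at
    their tied ranks.
    """
    if m.has_missing:
        raise ValidationError(
            "quantile_normalize requires a complete matrix; run filter_complete first"
        )
    if m.data.shape[1] < 2:
        raise ValidationError("quantile_normalize needs >= 2 samples")
    values = m.values
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        # average rank (1-based); ties get the mean reference value over
        # the positions they occupy, which equals the mean of the
        # reference cumulative sums over the tied rank span
        ranks = rankdata(col, method="average")
        csum = np.concatenate([[0.0], np.cumsum(reference)])
        lo = rankdata(col, method="min").astype(int)
        hi = rankdata(col, method="max").astype(int)
        out[:, j] = (csum[hi] - csum[lo - 1]) / (hi - lo + 1)
    return AbundanceMatrix(
        pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids), m.scale
    )


def total_abundance_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample so its total abundance equals the mean total.

    Operates on linear-scale intensities; totals are computed over
    non-missing cells and missing cells stay missing.
    """
    if m.scale != "linear":
        raise ValidationError("total_abundance_normalize expects a linear-scale matrix")
    values = m.values
    if np.nanmin(values) < 0:
        raise ValidationError("linear abundances must be >= 0")
    totals = np.nansum(values, axis=0)
    zero = totals == 0
    if zero.any():
        raise ValidationError(
            f"sample(s) with zero total abundance: {list(m.sample_ids[zero])}"
        )
    factors = totals.mean() / totals
    return AbundanceMatrix(
        pd.DataFrame(values * factors, index=m.feature_ids, columns=m.sample_ids), "linear"
    )


def filter_complete(m: AbundanceMatrix, design: pd.DataFrame | None = None) -> AbundanceMatrix:
    """Keep only features measured in every sample of the design.

    With ``design`` given, completeness is assessed over the design's
    samples (which must all be matrix columns); otherwise over all
    columns.  Row order is preserved.
    """
    if design is not None:
        sub = m.subset_samples(design_for_matrix_ids(design, m))
    else:
        sub = m
    complete = ~sub.data.isna().any(axis=1)
    return AbundanceMatrix(m.data.loc[complete], m.scale)


def design_for_matrix_ids(design: pd.DataFrame, m: AbundanceMatrix) -> list[str]:
    ids = [s for s in design["sample_id"].astype(str)]
    absent = [s for s in ids if s not in m.data.columns]
    if absent:
        raise ValidationError(f"design samples absent from matrix: {absent[:5]}")
    return ids


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2 of a linear matrix; missing cells stay missing."""
    if m.scale != "linear":
        raise ValidationError("log2_transform expects a linear-scale matrix")
    values = m.values
    with np.errstate(divide="ignore"):
        out = np.log2(values)
    if np.isneginf(out).any():
        raise ValidationError("zero intensities cannot be log2-transformed")
    return AbundanceMatrix(
        pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids), "log2"
    )


def prepare_protein(m: AbundanceMatrix, design: pd.DataFrame | None = None) -> AbundanceMatrix:
    """Full protein preprocessing: complete-case -> total-normalize -> log2."""
    filtered = filter_complete(m, design)
    if design is not None:
        filtered = filtered.subset_samples(design_for_matrix_ids(design, filtered))
    return log2_transform(total_abundance_normalize(filtered))


def inclusion_readout(
    inclusion_counts,
    nuclei_counts,
    div,
    ref_div: int,
) -> dict[int, float]:
    """Percent-of-final imaging readout.

    Per well, the tau inclusion count is divided by the live-nuclei
    count; the ratios are averaged per DIV and expressed as percent of
    the reference-DIV mean ratio (the reference DIV reads exactly 100).
    """
    inclusion = np.asarray(inclusion_counts, dtype=float)
    nuclei = np.asarray(nuclei_counts, dtype=float)
    divs = np.asarray(div, dtype=int)
    if not inclusion.shape == nuclei.shape == divs.shape:
        raise ValidationError("inclusion, nuclei and div arrays must have equal length")
    if (nuclei <= 0).any():
        raise ValidationError("every well must have a positive live-nuclei count")
    ratios = inclusion / nuclei
    per_div = pd.Series(ratios).groupby(divs).mean()
    if ref_div not in per_div.index:
        raise ValidationError(f"reference DIV {ref_div} absent from data")
    ref = per_div.loc[ref_div]
    if ref == 0:
        raise ValidationError("reference DIV has zero mean inclusion ratio")
    out = (100.0 * per_div / ref).to_dict()
    out[ref_div] = 100.0
    return {int(k): float(v) for k, v in out.items()}
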