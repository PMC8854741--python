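"""Synthetic multi-omics generator for the seeded-neuron time course.

Emulates the statistical structure of a 2-treatment (tau seed vs
control) x 3-DIV factorial experiment with three biological replicates
per cell: gene-level log2 RNA abundances with plate batch effects, a
partially mapped protein layer on linear scale with missing cells, and
a ground-truth table recording each gene's response archetype so every
downstream stage can be scored against truth.

Response archetypes
-------------------
``null``
    no treatment effect at any DIV.
``monotone_up`` / ``monotone_down``
    seed - control log2 fold change grows in magnitude with pathology,
    following the exponential inclusion-formation curve and reaching
    +/- ``effect_size`` at the final DIV.
``late_only`` / ``early_only``
    effect confined to the last (respectively first) DIV, sign drawn
    at random per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix, ValidationError, write_design

ARCHETYPES = ("null", "monotone_up", "monotone_down", "late_only", "early_only")

DEFAULT_ARCHETYPE_FRACTIONS = {
    "null": 0.94,
    "monotone_up": 0.019,
    "monotone_down": 0.014,
    "late_only": 0.022,
    "early_only": 0.005,
}


def pathology_curve(
    div: int,
    div_levels: tuple[int, ...] = (3, 7, 14),
    first_fraction: float = 1.0,
) -> float:
    """Percent of final-DIV tau inclusion load at ``div``.

    The inclusion readout grows exponentially over the culture period
    and is normalized to the final time point, so the curve is
    ``100 * exp(k * (div - max(div_levels)))`` with ``k`` fixed so the
    first DIV evaluates to ``first_fraction`` percent (default 1%).
    Strictly increasing in ``div``; exactly 100 at the final DIV.
    """
    div_levels = tuple(div_levels)
    if div not in div_levels:
        raise ValidationError(f"div {div} not in div_levels {div_levels}")
    if not 0 < first_fraction < 100:
        raise ValidationError("first_fraction must lie in (0, 100)")
    d0, dmax = div_levels[0], div_levels[-1]
    if div == dmax:
        return 100.0
    if div == d0:
        return first_fraction
    k = math.log(first_fraction / 100.0) / (d0 - dmax)
    return 100.0 * math.exp(k * (div - dmax))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the study layout: 18,049 quantified genes, three
    independent samples per treatment x DIV combination at DIV 3/7/14,
    four culture plates, ~6% of genes responsive, a protein layer
    covering ~20% of genes with ~60% of mapped responsive genes
    concordant in direction, and a missingness rate that retains about
    half the proteins after complete-case filtering.
    """

    n_genes: int = 18049
    n_replicates: int = 3
    div_levels: tuple[int, ...] = (3, 7, 14)
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_FRACTIONS)
    )
    effect_size: float = 2.0
    residual_sd: float = 0.25
    plate_sd: float = 0.1
    n_plates: int = 4
    protein_fraction: float = 0.2
    concordant_fraction: float = 0.6
    protein_missing_rate: float = 0.035
    pathology_first_fraction: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.n_plates < 1:
            raise ValidationError("n_plates must be >= 1")
        levels = tuple(self.div_levels)
        if len(levels) < 2 or any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValidationError("div_levels must be strictly increasing with >= 2 levels")
        self.div_levels = levels
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise ValidationError(f"archetype_fractions has unknown archetypes: {sorted(unknown)}")
        fractions = {a: float(self.archetype_fractions.get(a, 0.0)) for a in ARCHETYPES}
        if any(not 0.0 <= f <= 1.0 for f in fractions.values()):
            raise ValidationError("archetype_fractions entries must lie in [0, 1]")
        if abs(sum(fractions.values()) - 1.0) > 1e-9:
            raise ValidationError("archetype_fractions must sum to 1")
        self.archetype_fractions = fractions
        for name in ("protein_fraction", "concordant_fraction", "protein_missing_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        for name in ("residual_sd", "plate_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class SimulatedExperiment:
    """Bundle returned by :func:`simulate_experiment`."""

    rna: AbundanceMatrix
    protein: AbundanceMatrix
    design: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    @property
    def mapping(self) -> pd.DataFrame:
        mapped = self.truth.loc[self.truth["protein_id"] != "", ["gene_id", "protein_id"]]
        return mapped.reset_index(drop=True)

    def rna_design(self) -> pd.DataFrame:
        return self.design[self.design["assay"] == "rna"].reset_index(drop=True)

    def protein_design(self) -> pd.DataFrame:
        return self.design[self.design["assay"] == "protein"].reset_index(drop=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.rna.to_tsv(outdir / "rna_log2.tsv")
        self.protein.to_tsv(outdir / "protein_linear.tsv")
        write_design(self.design, outdir / "design.csv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.mapping.to_csv(outdir / "mapping.tsv", sep="\t", index=False)


def _apportion(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n genes across archetypes."""
    quotas = {a: fractions[a] * n for a in ARCHETYPES}
    counts = {a: int(math.floor(q)) for a, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(ARCHETYPES, key=lambda a: quotas[a] - counts[a], reverse=True)
    for a in by_remainder[:short]:
        counts[a] += 1
    return counts


def _build_design(config: SimulationConfig, assay: str) -> pd.DataFrame:
    rows = []
    i = 0
    for div in config.div_levels:
        for treatment in ("seed", "control"):
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{assay}_{treatment}_d{div}_r{rep}",
                        "treatment": treatment,
                        "div": div,
                        "replicate": rep,
                        "plate": f"{assay}_P{i % config.n_plates + 1}",
                        "assay": assay,
                    }
                )
                i += 1
    return pd.DataFrame(rows)


def _true_profiles(config: SimulationConfig, archetypes: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """True per-DIV seed - control log2FC, genes x DIVs."""
    levels = config.div_levels
    curve = np.array(
        [pathology_curve(d, levels, config.pathology_first_fraction) / 100.0 for d in levels]
    )
    n = len(archetypes)
    fc = np.zeros((n, len(levels)))
    e = config.effect_size
    fc[archetypes == "monotone_up"] = e * curve
    fc[archetypes == "monotone_down"] = -e * curve
    late = archetypes == "late_only"
    early = archetypes == "early_only"
    fc[late, -1] = e * signs[late]
    fc[early, 0] = e * signs[early]
    return fc


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate RNA + protein matrices, design and ground truth.

    The observed value of gene g in sample s is
    ``baseline_g + true_fc_g(div_s) * [s is seeded] + plate_offset_{g, plate_s}
    + N(0, residual_sd)``.  Plate offsets are gene-specific draws from
    ``N(0, plate_sd)``.  Baselines sit on a 0.25 log2-unit grid so that
    noise-free cell-mean differences reproduce the true log2FC without
    floating-point residue.  The protein layer covers a random subset of
    genes (``protein_fraction``), shares or flips the transcript
    direction per ``concordant_fraction``, is exponentiated to linear
    scale, and has cells blanked completely at random.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(1, n + 1)])

    counts = _apportion(config.archetype_fractions, n)
    archetypes = np.concatenate([np.repeat(a, counts[a]) for a in ARCHETYPES])
    rng.shuffle(archetypes)
    signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    fc = _true_profiles(config, archetypes, signs)

    # protein mapping and direction
    mapped = rng.random(n) < config.protein_fraction
    responsive = archetypes != "null"
    concordant = rng.random(n) < config.concordant_fraction
    protein_sign = np.where(concordant, 1.0, -1.0)
    protein_fc = fc * protein_sign[:, None]
    protein_ids = np.where(mapped, np.char.add("P_", gene_ids), "")
    protein_direction = np.where(
        mapped & responsive, np.where(concordant, "concordant", "discordant"), ""
    )

    div_levels = config.div_levels

    def _assay_matrix(design: pd.DataFrame, base: np.ndarray, fc_assay: np.ndarray) -> np.ndarray:
        plates = design["plate"].to_numpy()
        plate_index = {p: i for i, p in enumerate(pd.unique(plates))}
        offsets = (
            rng.normal(0.0, config.plate_sd, size=(n, len(plate_index)))
            if config.plate_sd > 0
            else np.zeros((n, len(plate_index)))
        )
        noise = (
            rng.normal(0.0, config.residual_sd, size=(n, len(design)))
            if config.residual_sd > 0
            else np.zeros((n, len(design)))
        )
        div_col = {d: j for j, d in enumerate(div_levels)}
        values = np.empty((n, len(design)))
        for s, row in enumerate(design.itertuples(index=False)):
            effect = fc_assay[:, div_col[row.div]] if row.treatment == "seed" else 0.0
            values[:, s] = base + effect + offsets[:, plate_index[row.plate]] + noise[:, s]
        return values

    rna_design = _build_design(config, "rna")
    protein_design = _build_design(config, "protein")

    rna_base = rng.integers(16, 49, size=n) / 4.0
    rna_values = _assay_matrix(rna_design, rna_base, fc)
    rna = AbundanceMatrix(
        pd.DataFrame(rna_values, index=gene_ids, columns=rna_design["sample_id"]), "log2"
    )

    protein_base = rng.integers(40, 81, size=n) / 4.0
    protein_log2 = _assay_matrix(protein_design, protein_base, protein_fc)
    protein_linear = np.power(2.0, protein_log2)
    if config.protein_missing_rate > 0:
        miss = rng.random(protein_linear.shape) < config.protein_missing_rate
        protein_linear = np.where(miss, np.nan, protein_linear)
    keep = mapped
    protein = AbundanceMatrix(
        pd.DataFrame(
            protein_linear[keep],
            index=protein_ids[keep],
            columns=protein_design["sample_id"],
        ),
        "linear",
    )

    truth = pd.DataFrame({"gene_id": gene_ids, "archetype": archetypes})
    for j, d in enumerate(div_levels):
        truth[f"log2fc_div{d}"] = fc[:, j]
    truth["protein_id"] = protein_ids
    truth["protein_direction"] = protein_direction
    for j, d in enumerate(div_levels):
        truth[f"protein_log2fc_div{d}"] = np.where(mapped, protein_fc[:, j], 0.0)

    design = pd.concat([rna_design, protein_design], ignore_index=True)
    return SimulatedExperiment(rna, protein, design, truth, config)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "div_levels" in raw:
        raw["div_levels"] = tuple(raw["div_levels"])
    return SimulationConfig(**raw)
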