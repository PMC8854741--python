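"""Differential-expression statistics: oracles and invariants.

Independent oracles used here:
- hand ordinary-least-squares on a balanced toy table (cell means,
  pooled variance) for the factorial contrasts;
- scipy.stats.studentized_range for the Tukey tail probability;
- a literal Benjamini-Hochberg step-up loop for bh_fdr;
- statsmodels MixedLM for the plate random-intercept model;
- a brute-force double loop for the p* contrast-resolution rule.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range, t as t_dist

import seedomics
from seedomics import (
    AbundanceMatrix,
    SimulationConfig,
    ValidationError,
    bh_fdr,
    contrasts_per_gene,
    detect_plate_effect,
    resolve_significance,
    run_de,
    sidak_adjust,
    simulate_experiment,
    studentized_range_sf,
    tukey_adjust,
)
from conftest import make_design


def matrix_from(values, design):
    frame = pd.DataFrame(
        np.atleast_2d(values),
        index=[f"g{i}" for i in range(np.atleast_2d(values).shape[0])],
        columns=design["sample_id"],
    )
    return AbundanceMatrix(frame, "log2")


# ---------------------------------------------------------------------------
# studentized range / Tukey
# ---------------------------------------------------------------------------

class TestStudentizedRange:
    @pytest.mark.parametrize("df", [4, 12, 30])
    @pytest.mark.parametrize("t", [0.3, 1.0, 2.5, 4.0, 6.0])
    def test_k2_reduces_to_two_sided_t(self, t, df):
        mine = tukey_adjust([t], df, k_means=2)[0]
        assert mine == pytest.approx(2 * t_dist.sf(t, df), abs=1e-9)

    def test_t0_gives_p1(self):
        assert tukey_adjust([0.0], 12, k_means=6)[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k,df", [(6, 12), (6, 4), (6, 30), (3, 10)])
    def test_matches_scipy_oracle(self, k, df):
        q = np.array([0.2, 1.0, 2.0, 3.0 * np.sqrt(2), 6.0, 9.0])
        mine = studentized_range_sf(q, k, df)
        oracle = studentized_range.sf(q, k, df)
        np.testing.assert_allclose(mine, oracle, atol=1e-6)

    def test_t3_df12_k6_value(self):
        mine = tukey_adjust([3.0], 12, k_means=6)[0]
        oracle = float(studentized_range.sf(3.0 * np.sqrt(2), 6, 12))
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_monotone_decreasing_in_t(self):
        t = np.linspace(0, 8, 50)
        p = tukey_adjust(t, 12, k_means=6)
        assert (np.diff(p) <= 1e-12).all()

    def test_fwer_at_least_raw(self, rng):
        t = rng.normal(0, 2, size=200)
        p_raw = 2 * t_dist.sf(np.abs(t), 12)
        p_fwer = tukey_adjust(t, 12, k_means=6)
        assert (p_fwer >= p_raw - 1e-12).all()

    def test_nonfinite_t_rejected(self):
        with pytest.raises(ValidationError):
            tukey_adjust([np.nan], 12)

    def test_sidak_option(self):
        p = np.array([0.01, 0.2])
        np.testing.assert_allclose(sidak_adjust(p, 3), 1 - (1 - p) ** 3, rtol=1e-12)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

class TestContrastsPerGene:
    def test_null_identity(self):
        design = make_design(n_replicates=3)
        y = np.tile(np.repeat([5.0, 6.0, 7.0], 6), 1)  # same by DIV, no treatment effect
        # add replicate-level variation identical across treatments
        y = y + np.tile([0.1, -0.1, 0.0], 6)
        table = contrasts_per_gene(y, design)
        np.testing.assert_allclose(table["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["p_raw"], 1.0, atol=1e-12)

    def test_hand_ols_oracle_2x3x2(self, rng):
        """Balanced 2-replicate toy solved by explicit cell means / pooled RSS."""
        design = make_design(n_replicates=2, n_plates=1)
        y = rng.normal(0, 1, size=len(design))
        table = contrasts_per_gene(y, design)
        n, p = len(design), 6
        frame = design.assign(y=y)
        cell_means = frame.groupby(["treatment", "div"])["y"].mean()
        rss = ((frame["y"] - frame.groupby(["treatment", "div"])["y"].transform("mean")) ** 2).sum()
        s2 = rss / (n - p)
        for _, row in table.iterrows():
            fc = cell_means[("seed", row["div"])] - cell_means[("control", row["div"])]
            se = np.sqrt(s2 * (1 / 2 + 1 / 2))
            assert row["log2fc"] == pytest.approx(fc, abs=1e-10)
            assert row["se"] == pytest.approx(se, abs=1e-10)
            assert row["t"] == pytest.approx(fc / se, abs=1e-10)
            assert row["df"] == n - p
            assert row["p_raw"] == pytest.approx(2 * t_dist.sf(abs(fc / se), n - p), abs=1e-12)

    def test_low_noise_recovers_truth(self):
        config = SimulationConfig(
            n_genes=40,
            archetype_fractions={
                "null": 0.0,
                "monotone_up": 1.0,
                "monotone_down": 0.0,
                "late_only": 0.0,
                "early_only": 0.0,
            },
            effect_size=2.0,
            residual_sd=0.01,
            plate_sd=0.0,
            n_plates=1,
            rng_seed=4,
        )
        sim = simulate_experiment(config)
        design = sim.rna_design()
        for i, gene in enumerate(sim.truth["gene_id"]):
            table = contrasts_per_gene(sim.rna.values[i], design, gene_id=gene)
            truth = [sim.truth.loc[i, f"log2fc_div{d}"] for d in (3, 7, 14)]
            np.testing.assert_allclose(table["log2fc"], truth, atol=0.05)

    def test_zero_variance_rejected(self):
        design = make_design(n_replicates=3)
        with pytest.raises(ValidationError, match="degenerate"):
            contrasts_per_gene(np.zeros(len(design)), design)

    def test_missing_cell_named(self):
        design = make_design(n_replicates=3)
        broken = design[~((design["treatment"] == "seed") & (design["div"] == 7))]
        with pytest.raises(ValidationError, match="seed.*7"):
            contrasts_per_gene(np.zeros(len(broken)), broken)


class TestPlateEffect:
    def test_single_plate_returns_false(self):
        design = make_design(n_plates=1)
        assert detect_plate_effect(np.random.default_rng(0).normal(size=18), design) is False

    def test_size_under_null(self, rng):
        """With no plate effect the LRT should rarely fire (alpha = 0.05)."""
        design = make_design(n_plates=4)
        hits = sum(
            detect_plate_effect(rng.normal(0, 1, 18), design) for _ in range(200)
        )
        assert hits / 200 < 0.10

    def test_power_under_strong_plate_effect(self, rng):
        design = make_design(n_plates=4)
        plate_idx = design["plate"].astype("category").cat.codes.to_numpy()
        hits = 0
        for _ in range(100):
            offsets = rng.normal(0, 2.0, 4)
            y = rng.normal(0, 0.3, 18) + offsets[plate_idx]
            hits += detect_plate_effect(y, design)
        assert hits / 100 > 0.8

    def test_lrt_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLM

        design = make_design(n_plates=4)
        fit = seedomics.destats.FactorialFit(design)
        plate_idx = design["plate"].astype("category").cat.codes.to_numpy()
        for _ in range(5):
            y = rng.normal(0, 1, 18) + rng.normal(0, 1.0, 4)[plate_idx]
            stat, _ = fit.plate_lrt(y)
            frame = design.assign(y=y, cell=design["treatment"] + design["div"].astype(str))
            mixed = MixedLM.from_formula(
                "y ~ 0 + C(cell)", groups="plate", data=frame
            ).fit(reml=False)
            ols = sm.OLS(y, fit.X).fit()
            oracle = max(0.0, 2 * (mixed.llf - ols.llf))
            assert stat == pytest.approx(oracle, abs=1e-6)

    def test_mixed_contrasts_match_statsmodels_reml(self, rng):
        from statsmodels.regression.mixed_linear_model import MixedLM

        design = make_design(n_plates=4)
        fit = seedomics.destats.FactorialFit(design)
        plate_idx = design["plate"].astype("category").cat.codes.to_numpy()
        y = rng.normal(0, 1, 18) + rng.normal(0, 1.5, 4)[plate_idx]
        est, se, df_sat, lam = fit.mixed_contrasts(y)
        frame = design.assign(y=y, cell=design["treatment"] + design["div"].astype(str))
        mixed = MixedLM.from_formula("y ~ 0 + C(cell)", groups="plate", data=frame).fit(
            reml=True
        )
        # align cell order: statsmodels sorts C(cell) labels alphabetically
        labels = [f"C(cell)[{c}]" for c in sorted(frame["cell"].unique())]
        beta_sm = pd.Series(mixed.fe_params.values, index=labels)
        order = [f"C(cell)[{t}{d}]" for (t, d) in fit.cells]
        L = fit.L
        est_sm = L @ beta_sm[order].to_numpy()
        np.testing.assert_allclose(est, est_sm, atol=1e-6)
        # variance components agree
        lam_sm = mixed.cov_re.values[0, 0] / mixed.scale
        assert lam == pytest.approx(lam_sm, rel=1e-3)
        # SE against the model-based GLS covariance built directly from
        # statsmodels' own fitted variance parameters (statsmodels'
        # cov_params uses a numerically differentiated Hessian instead)
        Z = pd.get_dummies(design["plate"]).to_numpy(dtype=float)
        V = mixed.scale * (np.eye(len(design)) + lam_sm * (Z @ Z.T))
        cov_gls = np.linalg.inv(fit.X.T @ np.linalg.solve(V, fit.X))
        se_gls = np.sqrt(np.einsum("ij,jk,ik->i", L, cov_gls, L))
        np.testing.assert_allclose(se, se_gls, atol=1e-5)
        assert ((df_sat >= 1) & (df_sat <= fit.df_resid)).all()

    def test_satterthwaite_df_frozen_reference(self):
        """Mixed-model contrast SE and Satterthwaite df reproduce values
        computed independently with lmerTest + emmeans on the same data."""
        from seedomics import quantile_normalize

        config = SimulationConfig(
            n_genes=2000,
            archetype_fractions={"null": 1.0},
            residual_sd=0.25,
            plate_sd=0.0,
            n_plates=4,
            protein_fraction=0.0,
            rng_seed=1006,
        )
        sim = simulate_experiment(config)
        rna = quantile_normalize(sim.rna)
        fit = seedomics.destats.FactorialFit(sim.rna_design())
        est, se, df_sat, _ = fit.mixed_contrasts(rna.data.loc["g00100"].to_numpy())
        np.testing.assert_allclose(np.abs(est), [0.122, 0.103, 0.672], atol=5e-4)
        np.testing.assert_allclose(se, [0.0595, 0.0589, 0.0595], atol=5e-4)
        np.testing.assert_allclose(df_sat, [9.16, 9.08, 9.16], atol=0.01)


# ---------------------------------------------------------------------------
# BH and p*
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Literal step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.05]), [0.05])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_oracle_randomized(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.1, 1.5])

    def test_q_at_least_p_min_property(self, rng):
        p = rng.uniform(0, 1, 100)
        assert (bh_fdr(p) >= p - 1e-15).all()


def random_instance(rng, n_genes):
    """Random contrast/summary tables for p*-rule brute-force checks."""
    genes = [f"g{i}" for i in range(n_genes)]
    p_fwer = rng.uniform(0, 1, size=(n_genes, 3))
    # sprinkle small p-values so FDR-significant sets are non-trivial
    spike = rng.random(n_genes) < 0.3
    p_fwer[spike] *= 1e-3
    contrasts = pd.DataFrame(
        {
            "gene_id": np.repeat(genes, 3),
            "div": np.tile([3, 7, 14], n_genes),
            "p_fwer": p_fwer.ravel(),
        }
    )
    p_min = p_fwer.min(axis=1)
    summaries = pd.DataFrame({"gene_id": genes, "p_min": p_min, "q_fdr": bh_fdr(p_min)})
    return summaries, contrasts


def pstar_oracle(summaries, contrasts, alpha, strict):
    """Brute-force double loop over genes x contrasts."""
    passing = [
        row.p_min for row in summaries.itertuples() if row.q_fdr < alpha
    ]
    if not passing:
        return None, {g: [] for g in summaries["gene_id"]}
    p_star = max(passing)
    sig = {g: [] for g in summaries["gene_id"]}
    for row in contrasts.itertuples():
        hit = row.p_fwer < p_star if strict else row.p_fwer <= p_star
        if hit:
            sig[row.gene_id].append(row.div)
    return p_star, sig


class TestResolveSignificance:
    def test_three_gene_example(self):
        summaries = pd.DataFrame(
            {
                "gene_id": ["A", "B", "C"],
                "p_min": [0.001, 0.010, 0.200],
                "q_fdr": [0.003, 0.015, 0.200],
            }
        )
        contrasts = pd.DataFrame(
            {
                "gene_id": ["A", "A", "A", "B", "B", "B", "C", "C", "C"],
                "div": [3, 7, 14] * 3,
                "p_fwer": [0.001, 0.5, 0.009, 0.010, 0.02, 0.9, 0.2, 0.3, 0.4],
            }
        )
        p_star, summ, contr = resolve_significance(summaries, contrasts, alpha=0.05)
        assert p_star == pytest.approx(0.010)
        assert contr["significant"].tolist() == [
            True, False, True, True, False, False, False, False, False,
        ]
        assert summ.set_index("gene_id")["significant_divs"].to_dict() == {
            "A": [3, 14],
            "B": [3],
            "C": [],
        }

    def test_no_fdr_significant_gene(self):
        summaries = pd.DataFrame(
            {"gene_id": ["A"], "p_min": [0.5], "q_fdr": [0.5]}
        )
        contrasts = pd.DataFrame(
            {"gene_id": ["A"] * 3, "div": [3, 7, 14], "p_fwer": [0.5, 0.6, 0.7]}
        )
        p_star, summ, contr = resolve_significance(summaries, contrasts)
        assert p_star is None
        assert not contr["significant"].any()
        assert summ["significant_divs"].tolist() == [[]]

    @pytest.mark.parametrize("strict", [False, True])
    def test_matches_bruteforce_on_random_instances(self, rng, strict):
        for _ in range(60):
            summaries, contrasts = random_instance(rng, int(rng.integers(2, 40)))
            p_star, summ, contr = resolve_significance(
                summaries, contrasts, alpha=0.05, strict=strict
            )
            p_star_o, sig_o = pstar_oracle(summaries, contrasts, 0.05, strict)
            assert (p_star is None) == (p_star_o is None)
            if p_star is not None:
                assert p_star == p_star_o
            got = summ.set_index("gene_id")["significant_divs"].to_dict()
            assert got == {g: sorted(v) for g, v in sig_o.items()}

    def test_gene_mismatch_rejected(self):
        summaries = pd.DataFrame({"gene_id": ["A"], "p_min": [0.1], "q_fdr": [0.1]})
        contrasts = pd.DataFrame({"gene_id": ["B"], "div": [3], "p_fwer": [0.1]})
        with pytest.raises(ValidationError):
            resolve_significance(summaries, contrasts)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

class TestRunDe:
    def test_shape_contract(self, small_experiment):
        sim = small_experiment
        result = run_de(sim.rna, sim.rna_design())
        n = sim.config.n_genes
        assert len(result.contrasts) == 3 * n
        assert len(result.summaries) == n
        assert set(result.contrasts["div"]) == {3, 7, 14}
        assert (result.contrasts["p_fwer"] >= result.contrasts["p_raw"] - 1e-12).all()
        merged = result.summaries.merge(
            result.contrasts.groupby("gene_id")["p_fwer"].min().rename("check"),
            left_on="gene_id",
            right_index=True,
        )
        np.testing.assert_allclose(merged["p_min"], merged["check"], atol=1e-15)
        assert (merged["q_fdr"] >= merged["p_min"] - 1e-15).all()

    def test_single_spiked_gene_is_the_only_discovery(self, rng):
        design = make_design(n_plates=1)
        n_genes = 120
        values = rng.normal(8.0, 0.2, size=(n_genes, len(design)))
        seed14 = (
            (design["treatment"] == "seed") & (design["div"] == 14)
        ).to_numpy()
        values[0, seed14] += 6.0  # huge effect, tiny noise
        m = matrix_from(values, design)
        result = run_de(m, design)
        sig = result.summaries[result.summaries["fdr_significant"]]
        assert sig["gene_id"].tolist() == ["g0"]
        assert result.summaries.loc[0, "significant_divs"] == [14]

    def test_matches_per_gene_contrast_function(self, small_experiment):
        sim = small_experiment
        result = run_de(sim.rna, sim.rna_design(), plate_policy="never")
        gene = sim.truth["gene_id"].iloc[5]
        single = contrasts_per_gene(
            sim.rna.data.loc[gene].to_numpy(), sim.rna_design(), gene_id=gene
        )
        bulk = result.contrasts[result.contrasts["gene_id"] == gene].reset_index()
        np.testing.assert_allclose(bulk["log2fc"], single["log2fc"], atol=1e-12)
        np.testing.assert_allclose(bulk["se"], single["se"], atol=1e-12)
        np.testing.assert_allclose(bulk["p_raw"], single["p_raw"], atol=1e-12)

    def test_zero_variance_gene_dropped_not_fatal(self):
        design = make_design(n_plates=1)
        values = np.vstack(
            [np.full(len(design), 5.0), np.random.default_rng(0).normal(8, 1, len(design))]
        )
        result = run_de(matrix_from(values, design), design)
        assert result.log["n_dropped_zero_variance"] == 1
        assert len(result.summaries) == 1

    def test_sidak_family_less_conservative_than_tukey6(self, small_experiment):
        sim = small_experiment
        tukey = run_de(sim.rna, sim.rna_design(), family="tukey6", plate_policy="never")
        sidak = run_de(sim.rna, sim.rna_design(), family="sidak3", plate_policy="never")
        assert (
            sidak.contrasts["p_fwer"] <= tukey.contrasts["p_fwer"] + 1e-9
        ).all()

    def test_run_log_counts(self, small_experiment):
        sim = small_experiment
        result = run_de(sim.rna, sim.rna_design())
        assert result.log["n_genes"] == sim.config.n_genes
        assert result.log["n_fdr_significant"] == int(
            result.summaries["fdr_significant"].sum()
        )
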