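"""Per-gene factorial differential expression with the contrast-resolution
procedure.

For each gene the model is

    log2 abundance ~ treatment + DIV + treatment:DIV

fitted by ordinary least squares, or — when a plate batch effect is
detected by a likelihood-ratio test of the plate random-intercept
variance component — by the corresponding linear mixed model.  The
seed - control difference of model-predicted (estimated marginal) cell
means is reported at each DIV with its SE, t statistic and two-sided p.

Multiplicity is handled in two tiers:

1. within gene, the three per-DIV contrasts are adjusted to a
   family-wise error rate by a Tukey (studentized-range) procedure over
   the six treatment x DIV cell means;
2. across genes, each gene's minimum FWER-adjusted p is carried into a
   Benjamini-Hochberg step-up, controlling the FDR at ``alpha``.

Individual significant contrasts are then resolved by the p* rule: p*
is the largest per-gene minimum FWER p among FDR-significant genes, and
a contrast is called significant when its FWER p is at or below p*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2, norm, t as t_dist
from statsmodels.stats.multitest import multipletests

from .matrix import AbundanceMatrix, ValidationError, design_for_matrix

logger = logging.getLogger(__name__)

DIV_ORDER_COLS = ["gene_id", "div", "log2fc", "se", "t", "df", "p_raw", "p_fwer"]


# ---------------------------------------------------------------------------
# studentized-range tail probability
# ---------------------------------------------------------------------------

def studentized_range_sf(q, k: int, df: float, n_nodes: int = 120) -> np.ndarray:
    """P(Q(k, df) >= q) by Gauss-Legendre quadrature, vectorized over q.

    Uses the classical double-integral representation of the range of k
    standard normals scaled by an independent chi; the difference of
    powers in the integrand is evaluated through ``expm1``/``log1p`` so
    small tail probabilities keep relative accuracy.
    """
    if k < 2:
        raise ValidationError("k_means must be >= 2")
    if df <= 0:
        raise ValidationError("df must be > 0")
    q = np.asarray(q, dtype=float)
    if not np.isfinite(q).all():
        raise ValidationError("non-finite studentized-range quantile")
    scalar = q.ndim == 0
    q = np.atleast_1d(q)

    # outer variable: s = sqrt(chi2_df / df)
    s_lo = np.sqrt(chi2.ppf(1e-16, df) / df)
    s_hi = np.sqrt(chi2.isf(1e-16, df) / df)
    xs, ws = np.polynomial.legendre.leggauss(n_nodes)
    s = 0.5 * (s_hi - s_lo) * xs + 0.5 * (s_hi + s_lo)
    ws = ws * 0.5 * (s_hi - s_lo)
    log_fs = (
        (df / 2.0) * np.log(df / 2.0)
        - gammaln(df / 2.0)
        + np.log(2.0)
        + (df - 1.0) * np.log(s)
        - df * s * s / 2.0
    )
    outer_w = ws * np.exp(log_fs)

    # inner variable: location u of the maximum
    xu, wu = np.polynomial.legendre.leggauss(n_nodes)
    u = 9.0 * xu
    inner_w = 9.0 * wu * norm.pdf(u)
    log_phi = norm.logcdf(u)
    phi = norm.cdf(u)
    km1 = k - 1

    out = np.empty_like(q, dtype=float)
    for i0 in range(0, q.size, 128):
        qc = np.maximum(q[i0 : i0 + 128], 0.0)[:, None, None]
        b = norm.cdf(u[None, None, :] - qc * s[None, :, None])
        ratio = np.clip(b / phi[None, None, :], 0.0, 1.0)
        # Phi(u)^{k-1} - (Phi(u) - Phi(u - q s))^{k-1}, cancellation-free
        with np.errstate(divide="ignore"):
            term = np.exp(km1 * log_phi)[None, None, :] * (
                -np.expm1(km1 * np.log1p(-ratio))
            )
        inner = np.einsum("j,qsj->qs", inner_w, term)
        out[i0 : i0 + 128] = k * np.einsum("s,qs->q", outer_w, inner)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def tukey_adjust(t_values, df: float, k_means: int = 6) -> np.ndarray:
    """Tukey FWER adjustment: P(Q(k_means, df) >= sqrt(2) |t|)."""
    t_values = np.asarray(t_values, dtype=float)
    if not np.isfinite(t_values).all():
        raise ValidationError("non-finite t statistic passed to tukey_adjust")
    return studentized_range_sf(np.sqrt(2.0) * np.abs(t_values), k_means, df)


def sidak_adjust(p_raw, m: int = 3) -> np.ndarray:
    """Sidak FWER adjustment for a family of m independent contrasts."""
    p_raw = np.asarray(p_raw, dtype=float)
    return -np.expm1(m * np.log1p(-p_raw))


# ---------------------------------------------------------------------------
# factorial design machinery
# ---------------------------------------------------------------------------

class FactorialFit:
    """Shared per-design machinery for the 2 x |DIV| factorial model.

    Precomputes the cell-mean design matrix, the per-DIV seed - control
    contrast vectors, and the eigendecomposition of the plate incidence
    used by the profiled-likelihood mixed model, so that per-gene work
    reduces to small dense linear algebra.  :meth:`for_design` caches
    instances (and their simulated LRT null) per design layout.
    """

    _cache: dict = {}

    @classmethod
    def for_design(cls, design: pd.DataFrame) -> "FactorialFit":
        key = tuple(
            map(tuple, design[["treatment", "div", "plate"]].itertuples(index=False))
        )
        if key not in cls._cache:
            if len(cls._cache) > 32:  # keep the cache tiny
                cls._cache.clear()
            cls._cache[key] = cls(design)
        return cls._cache[key]

    def __init__(self, design: pd.DataFrame):
        self.design = design
        self.div_levels = tuple(sorted(design["div"].unique()))
        cells = [(t, d) for d in self.div_levels for t in ("seed", "control")]
        self.cells = cells
        index = {c: i for i, c in enumerate(cells)}
        n = len(design)
        p = len(cells)
        counts = design.groupby(["treatment", "div"]).size()
        for t in ("seed", "control"):
            for d in self.div_levels:
                if counts.get((t, d), 0) < 2:
                    raise ValidationError(
                        f"design cell treatment={t}, div={d} has fewer than 2 replicates"
                    )
        X = np.zeros((n, p))
        for i, row in enumerate(design.itertuples(index=False)):
            X[i, index[(row.treatment, row.div)]] = 1.0
        self.X = X
        self.n, self.p = n, p
        self.XtX_inv = np.linalg.inv(X.T @ X)
        self.pinv = self.XtX_inv @ X.T
        L = np.zeros((len(self.div_levels), p))
        for j, d in enumerate(self.div_levels):
            L[j, index[("seed", d)]] = 1.0
            L[j, index[("control", d)]] = -1.0
        self.L = L
        self.contrast_var_ols = np.einsum("ij,jk,ik->i", L, self.XtX_inv, L)
        self.df_resid = n - p

        plates = design["plate"].to_numpy()
        self.plate_levels = pd.unique(plates)
        self.n_plates = len(self.plate_levels)
        Z = np.zeros((n, self.n_plates))
        plate_index = {pl: i for i, pl in enumerate(self.plate_levels)}
        for i, pl in enumerate(plates):
            Z[i, plate_index[pl]] = 1.0
        eigvals, Q = np.linalg.eigh(Z @ Z.T)
        self.eig = np.maximum(eigvals, 0.0)
        self.Q = Q
        self.Xt = Q.T @ X

    # -- OLS --------------------------------------------------------------
    def ols_contrasts(self, Y: np.ndarray):
        """Vectorized OLS cell-means fit; Y is genes x samples."""
        beta = Y @ self.pinv.T
        resid = Y - beta @ self.X.T
        rss = np.einsum("ij,ij->i", resid, resid)
        s2 = rss / self.df_resid
        est = beta @ self.L.T
        se = np.sqrt(s2[:, None] * self.contrast_var_ols[None, :])
        return est, se, s2

    # -- mixed model ------------------------------------------------------
    def _neg2_profile(self, lam: float, yt: np.ndarray, reml: bool):
        w = 1.0 + lam * self.eig
        Xw = self.Xt / w[:, None]
        XtWX = self.Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - self.Xt @ beta
        rss = float(np.sum(r * r / w))
        if reml:
            dof = self.n - self.p
            val = (
                dof * np.log(2.0 * np.pi * rss / dof)
                + np.sum(np.log(w))
                + np.linalg.slogdet(XtWX)[1]
                + dof
            )
        else:
            val = self.n * np.log(2.0 * np.pi * rss / self.n) + np.sum(np.log(w)) + self.n
        return val, beta, XtWX, rss

    def _profile_lambda(self, yt: np.ndarray, reml: bool) -> float:
        f0 = self._neg2_profile(0.0, yt, reml)[0]
        res = minimize_scalar(
            lambda loglam: self._neg2_profile(np.exp(loglam), yt, reml)[0],
            bounds=(-12.0, 10.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if res.fun < f0:
            return float(np.exp(res.x))
        return 0.0

    def plate_lrt_stat(self, y: np.ndarray) -> float:
        """ML likelihood-ratio statistic for the plate variance component."""
        yt = self.Q.T @ y
        f0 = self._neg2_profile(0.0, yt, reml=False)[0]
        lam = self._profile_lambda(yt, reml=False)
        return max(0.0, f0 - self._neg2_profile(lam, yt, reml=False)[0])

    def null_lrt_quantiles(self, n_sims: int = 2000, seed: int = 0) -> np.ndarray:
        """Exact finite-sample null distribution of the plate LRT.

        Under H0 (no plate variance) the LRT statistic is pivotal: its
        distribution depends on the design (X, Z) only, not on the
        fixed effects or the noise scale, so it can be simulated once
        per design from standard-normal responses and reused for every
        gene.  Cached on the instance.
        """
        if getattr(self, "_null_lrt", None) is None or len(self._null_lrt) < n_sims:
            rng = np.random.default_rng(seed)
            stats = np.array(
                [self.plate_lrt_stat(rng.standard_normal(self.n)) for _ in range(n_sims)]
            )
            self._null_lrt = np.sort(stats)
        return self._null_lrt

    def plate_lrt(self, y: np.ndarray, null: str = "exact"):
        """Plate variance-component LRT: (statistic, p).

        ``null="exact"`` compares against the design-specific simulated
        null distribution (add-one empirical tail probability);
        ``null="mixture"`` uses the asymptotic boundary mixture
        0.5*chi2_0 + 0.5*chi2_1, which is anticonservative at these
        sample sizes.
        """
        stat = self.plate_lrt_stat(y)
        if null == "mixture":
            p = 0.5 * float(chi2.sf(stat, 1)) if stat > 0 else 1.0
        elif null == "exact":
            ref = self.null_lrt_quantiles()
            p = (np.sum(ref >= stat) + 1.0) / (len(ref) + 1.0)
        else:
            raise ValidationError("null must be 'exact' or 'mixture'")
        return stat, p

    def mixed_contrasts(self, y: np.ndarray):
        """REML plate random-intercept fit.

        Returns per-DIV contrast estimates, SEs, Satterthwaite degrees
        of freedom and the fitted variance ratio.  The Satterthwaite df
        approximates the distribution of each contrast's variance
        estimate from the curvature of the REML criterion in the
        variance components (the approach of lmerTest/emmeans); with no
        fitted plate variance it reduces to the residual df.
        """
        yt = self.Q.T @ y
        lam = self._profile_lambda(yt, reml=True)
        _, beta, XtWX, rss = self._neg2_profile(lam, yt, reml=True)
        s2 = rss / (self.n - self.p)
        cov = s2 * np.linalg.inv(XtWX)
        est = self.L @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", self.L, cov, self.L))
        df = self._satterthwaite_df(yt, np.array([s2, lam * s2]))
        return est, se, df, lam

    # Satterthwaite machinery: theta = (sigma2_resid, sigma2_plate)
    def _reml_crit_theta(self, theta: np.ndarray, yt: np.ndarray) -> float:
        s2e, s2p = theta
        w = s2e + s2p * self.eig
        Xw = self.Xt / w[:, None]
        XtWX = self.Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - self.Xt @ beta
        return float(np.sum(np.log(w)) + np.linalg.slogdet(XtWX)[1] + np.sum(r * r / w))

    def _contrast_var_theta(self, theta: np.ndarray) -> np.ndarray:
        s2e, s2p = theta
        w = s2e + s2p * self.eig
        XtWX = self.Xt.T @ (self.Xt / w[:, None])
        C = np.linalg.inv(XtWX)
        return np.einsum("ij,jk,ik->i", self.L, C, self.L)

    def _satterthwaite_df(self, yt: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """df_j = 2 g_j^2 / (grad g_j' A grad g_j), A = REML vcov of theta."""
        if theta[1] <= 0:
            return np.full(self.L.shape[0], float(self.df_resid))
        eps = 1e-5 * np.maximum(np.abs(theta), 1e-8)
        # observed information: Hessian of 0.5 * reml criterion
        H = np.zeros((2, 2))
        for a in range(2):
            for b in range(a, 2):
                pp, pm, mp, mm = (theta.copy() for _ in range(4))
                pp[a] += eps[a]; pp[b] += eps[b]
                pm[a] += eps[a]; pm[b] -= eps[b]
                mp[a] -= eps[a]; mp[b] += eps[b]
                mm[a] -= eps[a]; mm[b] -= eps[b]
                H[a, b] = H[b, a] = (
                    self._reml_crit_theta(pp, yt)
                    - self._reml_crit_theta(pm, yt)
                    - self._reml_crit_theta(mp, yt)
                    + self._reml_crit_theta(mm, yt)
                ) / (8.0 * eps[a] * eps[b])
        try:
            A = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.full(self.L.shape[0], float(self.df_resid))
        g = self._contrast_var_theta(theta)
        grad = np.zeros((2, self.L.shape[0]))
        for a in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[a] += eps[a]
            tm[a] -= eps[a]
            grad[a] = (self._contrast_var_theta(tp) - self._contrast_var_theta(tm)) / (2 * eps[a])
        denom = np.einsum("aj,ab,bj->j", grad, A, grad)
        df = np.where(denom > 0, 2.0 * g * g / np.maximum(denom, 1e-300), self.df_resid)
        # clamp to a sane range: at least 1, at most the residual df
        return np.clip(df, 1.0, float(self.df_resid))


def detect_plate_effect(
    y, design: pd.DataFrame, alpha: float = 0.05, null: str = "exact"
) -> bool:
    """True iff the plate random-intercept LRT rejects at ``alpha``.

    With a single plate the variance component is unidentifiable and
    the function returns False with a logged note.
    """
    fit = FactorialFit.for_design(design)
    if fit.n_plates < 2:
        logger.info("single plate in design; plate effect not identifiable")
        return False
    _, p = fit.plate_lrt(np.asarray(y, dtype=float), null=null)
    return p < alpha


def contrasts_per_gene(
    y,
    design: pd.DataFrame,
    use_mixed: bool = False,
    gene_id: str = "gene",
) -> pd.DataFrame:
    """Seed - control contrast at each DIV for a single gene.

    Returns one row per DIV with the estimated-marginal-mean difference
    (log2FC), SE, t, residual df and two-sided raw p.  In the balanced
    fixed-effects case the log2FC equals the difference of cell means.
    """
    fit = FactorialFit.for_design(design)
    y = np.asarray(y, dtype=float)
    if y.shape != (fit.n,):
        raise ValidationError(f"expected {fit.n} sample values, got {y.shape}")
    if use_mixed:
        est, se, df, _ = fit.mixed_contrasts(y)
    else:
        est, se_mat, s2 = fit.ols_contrasts(y[None, :])
        if s2[0] <= 0 or not np.all(np.isfinite(se_mat)) or np.any(se_mat == 0):
            raise ValidationError(f"zero residual variance for gene {gene_id} (degenerate fit)")
        est, se = est[0], se_mat[0]
        df = np.full(len(est), float(fit.df_resid))
    if np.any(se == 0):
        raise ValidationError(f"zero residual variance for gene {gene_id} (degenerate fit)")
    t_stat = est / se
    p_raw = 2.0 * t_dist.sf(np.abs(t_stat), df)
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "div": list(fit.div_levels),
            "log2fc": est,
            "se": se,
            "t": t_stat,
            "df": df,
            "p_raw": p_raw,
            "p_fwer": np.nan,
        }
    )


def empirical_log2fc(m: AbundanceMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-DIV seed - control difference of raw cell means.

    Model-free companion to :func:`run_de` for trend screening: no
    variance estimate is involved, so it also works on noise-free data
    where the factorial fit is degenerate.
    """
    design = design_for_matrix(design, m)
    fit = FactorialFit.for_design(design)
    est, _, _ = fit.ols_contrasts(m.values)
    divs = list(fit.div_levels)
    return pd.DataFrame(
        {
            "gene_id": np.repeat(np.asarray(m.feature_ids), len(divs)),
            "div": np.tile(divs, len(m.feature_ids)),
            "log2fc": est.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# across-gene multiplicity
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy()
    if np.any((p_values < 0) | (p_values > 1) | ~np.isfinite(p_values)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p_values, method="fdr_bh")[1]


def resolve_significance(
    summaries: pd.DataFrame,
    contrasts: pd.DataFrame,
    alpha: float = 0.05,
    strict: bool = False,
):
    """Apply the p* contrast-resolution rule.

    p* is the maximum per-gene minimum FWER p among genes whose BH
    q-value is below ``alpha``.  A contrast is significant when its
    FWER p is <= p* (or strictly < p* with ``strict=True``).  When no
    gene passes the FDR cut, p* is undefined (None) and no contrast is
    significant.

    Returns ``(p_star, summaries, contrasts)`` where the summary table
    gains ``fdr_significant`` and ``significant_divs`` columns and the
    contrast table gains a boolean ``significant`` column.
    """
    summaries = summaries.copy()
    contrasts = contrasts.copy()
    if set(summaries["gene_id"]) != set(contrasts["gene_id"]):
        raise ValidationError("summaries and contrasts must cover the same genes")
    summaries["fdr_significant"] = summaries["q_fdr"] < alpha
    passing = summaries.loc[summaries["fdr_significant"], "p_min"]
    if passing.empty:
        p_star = None
        contrasts["significant"] = False
    else:
        p_star = float(passing.max())
        if strict:
            contrasts["significant"] = contrasts["p_fwer"] < p_star
        else:
            contrasts["significant"] = contrasts["p_fwer"] <= p_star
    sig = (
        contrasts[contrasts["significant"]]
        .groupby("gene_id")["div"]
        .apply(lambda s: sorted(s.tolist()))
    )
    summaries["significant_divs"] = summaries["gene_id"].map(sig)
    summaries["significant_divs"] = summaries["significant_divs"].apply(
        lambda v: v if isinstance(v, list) else []
    )
    return p_star, summaries, contrasts


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    contrasts: pd.DataFrame
    summaries: pd.DataFrame
    p_star: float | None
    log: dict


def run_de(
    m: AbundanceMatrix,
    design: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "tukey6",
    pstar_strict: bool = False,
    plate_policy: str = "auto",
) -> DEResult:
    """Full differential-expression pass over a normalized matrix.

    ``plate_policy``: ``"auto"`` runs the plate LRT per gene and uses
    the mixed fit where it rejects; ``"never"`` forces OLS; ``"always"``
    forces the mixed fit.  ``family``: ``"tukey6"`` (studentized range
    over the six cell means) or ``"sidak3"`` (Sidak over the three
    contrasts).
    """
    if family not in ("tukey6", "sidak3"):
        raise ValidationError("family must be 'tukey6' or 'sidak3'")
    if m.has_missing:
        raise ValidationError("run_de requires a complete matrix; filter first")
    design = design_for_matrix(design, m)
    fit = FactorialFit.for_design(design)
    Y = m.values
    genes = np.asarray(m.feature_ids)

    est, se, s2 = fit.ols_contrasts(Y)
    degenerate = (s2 <= 0) | ~np.isfinite(s2)
    if degenerate.any():
        for g in genes[degenerate]:
            logger.warning("dropping gene %s: zero residual variance", g)
    keep = ~degenerate
    genes, Y, est, se = genes[keep], Y[keep], est[keep], se[keep]

    mixed_flags = np.zeros(len(genes), dtype=bool)
    dfs = np.full(est.shape, float(fit.df_resid))
    if plate_policy == "always":
        mixed_flags[:] = fit.n_plates >= 2
    elif plate_policy == "auto" and fit.n_plates >= 2:
        for i in range(len(genes)):
            _, p = fit.plate_lrt(Y[i])
            mixed_flags[i] = p < 0.05
    for i in np.flatnonzero(mixed_flags):
        est[i], se[i], dfs[i], _ = fit.mixed_contrasts(Y[i])

    t_stat = est / se
    p_raw = 2.0 * t_dist.sf(np.abs(t_stat), dfs)
    if family == "tukey6":
        p_fwer = np.empty_like(p_raw)
        ols_rows = ~mixed_flags
        if ols_rows.any():  # common residual df: one vectorized pass
            p_fwer[ols_rows] = tukey_adjust(
                t_stat[ols_rows].ravel(), float(fit.df_resid), k_means=6
            ).reshape(-1, est.shape[1])
        for i in np.flatnonzero(mixed_flags):  # per-contrast Satterthwaite df
            for j in range(est.shape[1]):
                p_fwer[i, j] = tukey_adjust([t_stat[i, j]], dfs[i, j], k_means=6)[0]
    else:
        p_fwer = sidak_adjust(p_raw.ravel(), m=p_raw.shape[1]).reshape(p_raw.shape)
    p_fwer = np.maximum(p_fwer, p_raw)  # guard quadrature round-off at p ~ 1

    divs = list(fit.div_levels)
    contrasts = pd.DataFrame(
        {
            "gene_id": np.repeat(genes, len(divs)),
            "div": np.tile(divs, len(genes)),
            "log2fc": est.ravel(),
            "se": se.ravel(),
            "t": t_stat.ravel(),
            "df": dfs.ravel(),
            "p_raw": p_raw.ravel(),
            "p_fwer": p_fwer.ravel(),
        }
    )

    p_min = p_fwer.min(axis=1)
    q = bh_fdr(p_min)
    best = np.argmin(p_fwer, axis=1)
    direction = np.where(est[np.arange(len(genes)), best] >= 0, "up", "down")
    summaries = pd.DataFrame(
        {"gene_id": genes, "p_min": p_min, "q_fdr": q, "direction": direction}
    )
    p_star, summaries, contrasts = resolve_significance(
        summaries, contrasts, alpha=alpha, strict=pstar_strict
    )

    sig_per_div = (
        contrasts[contrasts["significant"]].groupby("div")["gene_id"].nunique().to_dict()
    )
    log = {
        "alpha": alpha,
        "family": family,
        "pstar_strict": pstar_strict,
        "p_star": p_star,
        "n_genes": int(len(genes)),
        "n_dropped_zero_variance": int(degenerate.sum()),
        "n_mixed_model_genes": int(mixed_flags.sum()),
        "n_fdr_significant": int(summaries["fdr_significant"].sum()),
        "n_significant_per_div": {int(k): int(v) for k, v in sig_per_div.items()},
    }
    logger.info("run_de: %s", log)
    return DEResult(contrasts, summaries, p_star, log)
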