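"""SNP-set association tests: the Rasch-score test and its comparators.

The primary test regresses a binary or quantitative trait on the per-subject
multi-marker Rasch genetic score (logistic or linear model, likelihood-ratio
inference on the score term).  The comparators operate on per-SNP p-values
from a linear trend test:

* **minP** — the smallest per-SNP p-value, reported without multiplicity
  correction.  Deliberately biased; serves as a negative control.
* **Fisher** — T = -2 * sum(ln p_i) against chi-square(2m); **Brown**'s
  scaled chi-square adjusts the reference distribution for dependence using
  a polynomial approximation of cov(-2 ln p_i, -2 ln p_j) in the genotype
  correlation.
* **GATES** — extended Simes procedure; the effective number of independent
  tests is derived from eigenvalues of the p-value correlation matrix,
  approximated from genotype correlation by a sixth-order polynomial.
* **SKAT** — variance-component score test with a (weighted) linear kernel;
  the null distribution is a mixture of chi-squares handled by moment
  matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "TraitVector",
    "AssociationResult",
    "PValueVector",
    "snp_trend_test",
    "trend_test_counts",
    "per_snp_pvalues",
    "score_association",
    "minp_combine",
    "fisher_combine",
    "gates_combine",
    "skat_test",
    "genotype_correlation",
    "results_table",
]

_P_FLOOR = np.finfo(float).tiny  # smallest positive normal; clamp for p = 0


@dataclass
class TraitVector:
    """Per-subject outcome with optional covariates.

    ``family`` is ``"binary"`` (0 = control, 1 = case) or ``"quantitative"``.
    """

    values: np.ndarray
    family: str = "binary"
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trait must be a vector")
        if self.family not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait family {self.family!r}")
        if self.family == "binary":
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, [0.0, 1.0])):
                raise ValueError("binary trait must be coded 0/1")
            if uniq.size < 2:
                raise ValueError("binary trait must contain both classes")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.values.size:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != self.values.size:
                raise ValueError("covariate rows must match trait length")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class AssociationResult:
    method: str
    statistic: float
    p_value: float
    effect: float | None = None
    df: float | None = None
    converged: bool = True
    note: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


@dataclass
class PValueVector:
    """Per-SNP p-values with an optional genotype correlation matrix."""

    p: np.ndarray
    corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size == 0:
            raise ValueError("empty p-value vector")
        if np.any(self.p <= 0):
            warnings.warn("p-values of 0 clamped to the smallest positive normal")
            self.p = np.maximum(self.p, _P_FLOOR)
        if np.any(self.p > 1):
            raise ValueError("p-values above 1")
        if self.corr is not None:
            self.corr = np.asarray(self.corr, dtype=float)
            if self.corr.shape != (self.p.size, self.p.size):
                raise ValueError("correlation matrix shape mismatch")
            if not np.allclose(self.corr, self.corr.T, atol=1e-8):
                raise ValueError("correlation matrix must be symmetric")


def _as_pvec(p, corr=None) -> PValueVector:
    if isinstance(p, PValueVector):
        return p
    return PValueVector(np.atleast_1d(p), corr)


def genotype_correlation(values: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of genotype dosages (the LD summary used
    by GATES and Brown).  Constant columns get zero off-diagonal correlation."""
    v = np.asarray(values, dtype=float)
    sd = v.std(axis=0)
    keep = sd > 0
    m = v.shape[1]
    corr = np.eye(m)
    if keep.sum() >= 2:
        sub = np.corrcoef(v[:, keep], rowvar=False)
        corr[np.ix_(keep, keep)] = sub
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# per-SNP tests


def trend_test_counts(controls: np.ndarray, cases: np.ndarray) -> AssociationResult:
    """Cochran-Armitage trend test from a 2x3 genotype count table.

    ``controls``/``cases`` are counts of genotypes 0, 1, 2; scores (0, 1, 2)
    weight the additive trend.  Two-sided p from the chi-square(1) reference.
    """
    controls = np.asarray(controls, dtype=float)
    cases = np.asarray(cases, dtype=float)
    t = np.arange(controls.size, dtype=float)
    n_x = controls + cases
    n_tot = n_x.sum()
    r_tot = cases.sum()
    num = n_tot * (t @ cases) - r_tot * (t @ n_x)
    den = r_tot * (n_tot - r_tot) * (n_tot * (t**2 @ n_x) - (t @ n_x) ** 2)
    if den <= 0:
        return AssociationResult(
            "trend", 0.0, 1.0, converged=False, note="degenerate table"
        )
    z2 = n_tot * num**2 / den
    return AssociationResult("trend", float(z2), float(stats.chi2.sf(z2, 1)), df=1)


def snp_trend_test(genotypes_one_snp: np.ndarray, trait: TraitVector) -> AssociationResult:
    """Single-SNP trend test of association.

    Binary traits: Cochran-Armitage trend test (score test on the additive
    0/1/2 coding).  Quantitative traits: two-sided t-test on the slope of a
    simple linear regression of the trait on the dosage.
    """
    g = np.asarray(genotypes_one_snp, dtype=float)
    if g.size != trait.n:
        raise ValueError("genotype and trait lengths differ")
    if np.all(g == g[0]):
        return AssociationResult(
            "trend", 0.0, 1.0, converged=False, note="constant genotype"
        )
    if trait.family == "binary":
        y = trait.values
        cats = int(g.max()) + 1
        cases = np.bincount(g[y == 1].astype(int), minlength=cats)
        controls = np.bincount(g[y == 0].astype(int), minlength=cats)
        return trend_test_counts(controls, cases)
    res = stats.linregress(g, trait.values)
    return AssociationResult(
        "trend",
        float(res.slope / res.stderr) ** 2 if res.stderr > 0 else 0.0,
        float(res.pvalue),
        effect=float(res.slope),
        df=1,
    )


def per_snp_pvalues(data: GenotypeMatrix, trait: TraitVector) -> PValueVector:
    """Trend-test p-values for every SNP plus the genotype correlation."""
    p = np.array(
        [snp_trend_test(data.values[:, j], trait).p_value for j in range(data.n_items)]
    )
    return PValueVector(p, genotype_correlation(data.values))


# ---------------------------------------------------------------------------
# score regression


def _logistic_score_test(score, y, X_null) -> tuple[float, float]:
    """Rao score test for adding ``score`` to a fitted null logistic model."""
    null = sm.GLM(y, X_null, family=sm.families.Binomial()).fit()
    mu = null.fittedvalues
    v = mu * (1 - mu)
    u = score @ (y - mu)
    xv = X_null.T * v
    info_ss = score @ (v * score)
    info_sx = xv @ score
    info_xx = X_null.T @ (v[:, None] * X_null)
    var = info_ss - info_sx @ np.linalg.solve(info_xx, info_sx)
    if var <= 0:
        return 0.0, 1.0
    stat = u * u / var
    return float(stat), float(stats.chi2.sf(stat, 1))


def score_association(score: np.ndarray, trait: TraitVector) -> AssociationResult:
    """Association of the Rasch genetic score with the trait.

    Binary traits: logistic regression of case status on the score (plus any
    covariates), p-value from the likelihood-ratio test on the score term.
    Quantitative traits: ordinary least squares, likewise LRT.  Perfect
    separation falls back to the Rao score test, flagged in ``note``.
    """
    score = np.asarray(score, dtype=float)
    if score.size != trait.n:
        raise ValueError("score and trait lengths differ")
    if not np.all(np.isfinite(score)):
        raise ValueError("score contains non-finite values")
    if np.allclose(score, score[0]):
        return AssociationResult(
            "rasch", 0.0, 1.0, converged=True, note="constant score"
        )
    n = trait.n
    X_null = np.ones((n, 1))
    if trait.covariates is not None:
        X_null = np.column_stack([X_null, trait.covariates])
        if np.linalg.matrix_rank(X_null) < X_null.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
    X_full = np.column_stack([X_null, score])
    y = trait.values
    if trait.family == "quantitative":
        full = sm.OLS(y, X_full).fit()
        null = sm.OLS(y, X_null).fit()
        lr = 2.0 * (full.llf - null.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), 1))
        return AssociationResult(
            "rasch", float(max(lr, 0.0)), max(p, _P_FLOOR),
            effect=float(full.params[-1]), df=1,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(y, X_full).fit(disp=0, maxiter=100)
            null = sm.Logit(y, X_null).fit(disp=0, maxiter=100)
            separated = not (
                full.mle_retvals.get("converged", False)
                and np.all(np.abs(full.params) < 1e3)
            )
        except Exception:
            separated = True
        if separated:
            stat, p = _logistic_score_test(score, y, X_null)
            return AssociationResult(
                "rasch", stat, max(p, _P_FLOOR), df=1, converged=True,
                note="perfect separation; Rao score test fallback",
            )
    lr = 2.0 * (full.llf - null.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), 1))
    return AssociationResult(
        "rasch", float(max(lr, 0.0)), max(p, _P_FLOOR),
        effect=float(full.params[-1]), df=1,
    )


# ---------------------------------------------------------------------------
# p-value combiners


def minp_combine(p, corr=None) -> AssociationResult:
    """Smallest per-SNP p-value, no multiplicity correction (negative control)."""
    pv = _as_pvec(p, corr)
    pmin = float(pv.p.min())
    return AssociationResult("minp", pmin, pmin)


#: Brown (1975) polynomial approximation of cov(-2 ln p_i, -2 ln p_j) as a
#: function of the (genotype) correlation r.
_BROWN_COEF = (3.263, 0.710, 0.027)


def _brown_cov(r: np.ndarray) -> np.ndarray:
    a = np.abs(r)
    return _BROWN_COEF[0] * a + _BROWN_COEF[1] * a**2 + _BROWN_COEF[2] * a**3


def fisher_combine(p, corr=None, adjust: str = "none") -> AssociationResult:
    """Fisher's combination T = -2 sum(ln p_i), optionally Brown-adjusted.

    Unadjusted: T ~ chi-square(2m) under independence.  ``adjust="brown"``
    rescales to c * chi-square(df) with c = Var(T) / (2 E(T)) and
    df = 2 E(T)^2 / Var(T), Var(T) = 4m + 2 sum_{i<j} cov_ij from the
    declared polynomial in |r_ij|.
    """
    pv = _as_pvec(p, corr)
    m = pv.p.size
    t_stat = float(-2.0 * np.log(pv.p).sum())
    if adjust == "none":
        return AssociationResult(
            "fisher", t_stat, max(float(stats.chi2.sf(t_stat, 2 * m)), _P_FLOOR),
            df=2 * m,
        )
    if adjust != "brown":
        raise ValueError(f"unknown adjustment {adjust!r}")
    corr_m = pv.corr if pv.corr is not None else np.eye(m)
    iu = np.triu_indices(m, 1)
    cov_sum = float(_brown_cov(corr_m[iu]).sum())
    mean_t = 2.0 * m
    var_t = 4.0 * m + 2.0 * cov_sum
    c = var_t / (2.0 * mean_t)
    df = 2.0 * mean_t**2 / var_t
    p_out = max(float(stats.chi2.sf(t_stat / c, df)), _P_FLOOR)
    return AssociationResult("brown", t_stat, p_out, df=df)


#: GATES (Li et al. 2011) sixth-order polynomial approximating the
#: correlation between trend-test p-values from the genotype correlation r.
_GATES_COEF = (0.2982, -0.0127, 0.0588, 0.0099, 0.6281, -0.0009)


def _gates_pval_corr(r: np.ndarray) -> np.ndarray:
    c6, c5, c4, c3, c2, c1 = _GATES_COEF
    return c6 * r**6 + c5 * r**5 + c4 * r**4 + c3 * r**3 + c2 * r**2 + c1 * r


def _effective_tests(pcorr: np.ndarray) -> float:
    """Effective number of independent tests: m - sum_{lambda>1}(lambda - 1)."""
    lam = np.linalg.eigvalsh(pcorr)
    if np.any(lam < -1e-8):
        warnings.warn("non-PSD p-value correlation; eigenvalues clipped at 0")
    lam = np.clip(lam, 0.0, None)
    m = pcorr.shape[0]
    return float(m - np.sum(lam[lam > 1] - 1.0))


def gates_combine(p, corr=None) -> AssociationResult:
    """Gene-based association by the extended Simes procedure (GATES).

    P_gene = min_j [ m_e * p_(j) / m_e(j) ] over the ascending p-values,
    where m_e is the effective number of independent tests of all m SNPs and
    m_e(j) that of the top j SNPs, both from eigenvalues of the p-value
    correlation matrix (identity assumed when no correlation is given).
    Under an identity correlation this is exactly the Simes combination;
    highly correlated significant SNPs count less.
    """
    pv = _as_pvec(p, corr)
    m = pv.p.size
    corr_m = pv.corr if pv.corr is not None else np.eye(m)
    order = np.argsort(pv.p, kind="stable")
    p_sorted = pv.p[order]
    pcorr = _gates_pval_corr(corr_m[np.ix_(order, order)])
    np.fill_diagonal(pcorr, 1.0)
    me_all = _effective_tests(pcorr)
    best = np.inf
    for j in range(1, m + 1):
        me_j = _effective_tests(pcorr[:j, :j]) if j < m else me_all
        best = min(best, me_all * p_sorted[j - 1] / me_j)
    p_out = min(max(float(best), _P_FLOOR), 1.0)
    return AssociationResult("gates", p_out, p_out, df=me_all)


# ---------------------------------------------------------------------------
# SKAT


def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Moment-matching tail probability for Q = sum lam_i chi2_1 (Liu 2009).

    Matches mean, variance and skewness/kurtosis to a (noncentral)
    chi-square; accurate to Monte-Carlo precision for common-variant kernels.
    """
    lam = lam[lam > 1e-12 * max(lam.max(), 1.0)]
    c1, c2, c3, c4 = (float(np.sum(lam**k)) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    mu_q, sigma_q = c1, np.sqrt(2.0 * c2)
    mu_x, sigma_x = df + delta, np.sqrt(2.0 * (df + 2.0 * delta))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, df, delta)) if delta > 0 else float(
        stats.chi2.sf(t, df)
    )


def skat_test(
    data: GenotypeMatrix,
    trait: TraitVector,
    weights: str | np.ndarray = "flat",
) -> AssociationResult:
    """SNP-set Kernel Association Test with a weighted linear kernel.

    Q = (y - mu)' G W G' (y - mu) where mu comes from the null model
    (intercept plus covariates).  The null distribution of Q is a mixture of
    chi-squares with the eigenvalues of the projected kernel as weights;
    the p-value uses moment matching.  ``weights="flat"`` suits common
    variants; ``weights="beta"`` applies Beta(1, 25) density weights on MAF,
    upweighting rare variants.
    """
    g = np.asarray(data.values, dtype=float)
    n, m = g.shape
    if trait.n != n:
        raise ValueError("trait length does not match genotype matrix")
    if isinstance(weights, str):
        if weights == "flat":
            w = np.ones(m)
        elif weights == "beta":
            maf = np.minimum(data.minor_allele_freq(), 1 - data.minor_allele_freq())
            w = stats.beta.pdf(maf, 1.0, 25.0)
        else:
            raise ValueError(f"unknown weight scheme {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,):
            raise ValueError("weight vector length mismatch")
    X = np.ones((n, 1))
    if trait.covariates is not None:
        X = np.column_stack([X, trait.covariates])
    y = trait.values
    if trait.family == "binary":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        mu = null.fittedvalues
        v = mu * (1 - mu)
    else:
        null = sm.OLS(y, X).fit()
        mu = null.fittedvalues
        v = np.full(n, float(null.scale))
    if not np.all(np.isfinite(mu)):
        raise RuntimeError("null model fitting failed")
    resid = y - mu
    gw = g * w[None, :]
    q_stat = float((resid @ gw) @ (gw.T @ resid))
    # eigenvalues of W^1/2 G' P0 G W^1/2 without forming the n x n projector:
    # G'P0G = G'VG - (G'VX)(X'VX)^-1(X'VG)
    gv = gw.T * v
    gtv_g = gv @ gw
    gtv_x = gv @ X
    xtv_x = X.T @ (v[:, None] * X)
    a_mat = gtv_g - gtv_x @ np.linalg.solve(xtv_x, gtv_x.T)
    lam = np.clip(np.linalg.eigvalsh(a_mat), 0.0, None)
    if lam.max() <= 0:
        return AssociationResult("skat", q_stat, 1.0, converged=False,
                                 note="degenerate kernel")
    p = min(max(_liu_pvalue(q_stat, lam), _P_FLOOR), 1.0)
    return AssociationResult("skat", q_stat, p, df=float(np.sum(lam > 1e-10)))


def results_table(results: list[AssociationResult]):
    """Serialize a list of results to a tidy DataFrame (tab-separable)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "method": r.method,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "effect": r.effect,
                "df": r.df,
                "converged": r.converged,
                "note": r.note,
            }
            for r in results
        ]
    )
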