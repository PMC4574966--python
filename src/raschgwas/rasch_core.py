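"""Partial Credit Model estimation and the multi-marker Rasch genetic score.

A set of bi-allelic SNPs coded 0/1/2 is treated as a set of polytomous items
of an item-response model.  The Partial Credit Model (PCM) gives the
probability of subject *n* scoring category *x* on item *i* as

    Pr(X_ni = x) = exp( sum_{k<=x} (beta_n - tau_ki) )
                   / sum_{j=0..m_i} exp( sum_{k<=j} (beta_n - tau_ki) )

with the convention that the k = 0 term contributes zero.  ``beta_n`` is the
latent "genetic load" of subject n and ``tau_ki`` the difficulty of reaching
category k of item i.  Item thresholds are estimated by Conditional Maximum
Likelihood (CML), which conditions on each subject's raw score (the sum of
their item responses, a sufficient statistic for beta) and therefore needs
the elementary symmetric functions of the item category terms.  Person
abilities are then obtained by maximum likelihood given the thresholds: the
ability of raw score r solves  sum_i E[X_i | beta] = r.

The per-subject ability is the multi-marker Rasch genetic score used
downstream for association testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "ItemThresholds",
    "AbilityTable",
    "PCMFit",
    "RaschFitError",
    "pcm_category_probs",
    "elementary_symmetric",
    "fit_pcm_cml",
    "person_abilities",
    "rasch_score",
    "simulate_pcm_responses",
]


class RaschFitError(RuntimeError):
    """Raised when a score is requested from a fit that did not converge."""


@dataclass
class ItemThresholds:
    """Ragged per-item threshold parameters tau[i][k], k = 1..m_i, in logits.

    The identification constraint is that the sum of all thresholds over
    items and categories equals zero (the model is invariant to adding a
    common constant to every beta and every tau).
    """

    tau: list[np.ndarray]
    normalization: str = "sum_zero"

    def __post_init__(self) -> None:
        self.tau = [np.asarray(t, dtype=float) for t in self.tau]
        flat = np.concatenate(self.tau) if self.tau else np.array([])
        if flat.size and not np.all(np.isfinite(flat)):
            raise ValueError("non-finite threshold")

    @property
    def n_items(self) -> int:
        return len(self.tau)

    @property
    def item_maxima(self) -> list[int]:
        return [len(t) for t in self.tau]


@dataclass
class AbilityTable:
    """Raw-score to ability mapping.

    ``beta[r]`` is the ability assigned to raw score ``raw_scores[r]``;
    abilities are strictly increasing in the raw score.  The extreme raw
    scores 0 and sum(m_i), where the likelihood has no maximum, are handled
    by pseudo-scores and flagged.
    """

    raw_scores: np.ndarray
    beta: np.ndarray
    extreme_flags: np.ndarray


@dataclass
class PCMFit:
    thresholds: ItemThresholds | None
    loglik_conditional: float
    converged: bool
    n_iterations: int
    reason: str | None = None
    #: original column indices of the items used in the fit
    item_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    #: per used item, sorted array of the observed raw category codes; the
    #: fitted categories are their consecutive recodes 0..m_i
    category_maps: list[np.ndarray] = field(default_factory=list)
    #: (item_id, reason) for items excluded from the fit
    dropped_items: list[tuple[str, str]] = field(default_factory=list)
    #: (item_id, description) for items whose categories were collapsed
    recodes: list[tuple[str, str]] = field(default_factory=list)


def pcm_category_probs(beta: float, tau_i: np.ndarray) -> np.ndarray:
    """Category probabilities of one PCM item at ability ``beta``.

    Parameters
    ----------
    beta
        Person ability in logits.
    tau_i
        Thresholds tau_ki for k = 1..m_i.

    Returns
    -------
    Probability vector of length ``m_i + 1`` summing to one.
    """
    tau_i = np.asarray(tau_i, dtype=float)
    if not np.isfinite(beta) or not np.all(np.isfinite(tau_i)):
        raise ValueError("pcm_category_probs requires finite beta and tau")
    # cumulative sums sum_{k<=x}(beta - tau_k); the k=0 term is zero
    cum = np.concatenate([[0.0], np.cumsum(beta - tau_i)])
    cum -= cum.max()  # softmax stabilisation
    e = np.exp(cum)
    return e / e.sum()


def elementary_symmetric(eps: list[np.ndarray]) -> np.ndarray:
    """Elementary symmetric functions gamma_r of PCM category terms.

    ``eps[i][x] = exp(-sum_{k<=x} tau_ki)`` with ``eps[i][0] = 1``.
    ``gamma_r`` is the sum over all response patterns with total raw score r
    of the product of their eps terms, computed by the stable summation
    (item-by-item convolution) recursion.
    """
    eps = [np.asarray(e, dtype=float) for e in eps]
    for e in eps:
        if np.any(e <= 0) or not np.all(np.isfinite(e)):
            raise ValueError("eps terms must be positive and finite")
    gamma = np.array([1.0])
    for e in eps:
        gamma = np.convolve(gamma, e)
    return gamma


def _scaled_esf_parts(eps: list[np.ndarray]):
    """Scaled forward/backward ESF products for stable likelihood/gradient.

    Each item's eps vector is divided by its maximum; returns the scaled
    full ESF, per-item leave-one-out scaled ESFs, the scaled eps vectors and
    the total log scale such that
    ``log gamma_r = log(gamma_scaled[r]) + log_scale_total``.
    """
    m = len(eps)
    scales = np.array([e.max() for e in eps])
    u = [e / s for e, s in zip(eps, scales)]
    fwd = [np.array([1.0])]
    for e in u:
        fwd.append(np.convolve(fwd[-1], e))
    bwd = [np.array([1.0])] * (m + 1)
    for i in range(m - 1, -1, -1):
        bwd[i] = np.convolve(u[i], bwd[i + 1])
    gamma_scaled = fwd[m]
    excl = [np.convolve(fwd[i], bwd[i + 1]) for i in range(m)]
    return gamma_scaled, excl, u, float(np.sum(np.log(scales)))


def _leave_two_out(u: list[np.ndarray]):
    """Scaled ESFs excluding every pair of items (upper triangle dict).

    Built from contiguous products P[a..b] so no deconvolution is needed.
    """
    m = len(u)
    # P[a][b] = convolution of u[a..b]; ragged upper-triangular table
    P = [[None] * m for _ in range(m)]
    for a in range(m):
        P[a][a] = u[a]
        for b in range(a + 1, m):
            P[a][b] = np.convolve(P[a][b - 1], u[b])
    one = np.array([1.0])

    def seg(a, b):
        return P[a][b] if a <= b else one

    out = {}
    for i in range(m):
        for j in range(i + 1, m):
            g = np.convolve(seg(0, i - 1), seg(i + 1, j - 1))
            g = np.convolve(g, seg(j + 1, m - 1))
            out[(i, j)] = g
    return out


def _prepare_items(data: GenotypeMatrix):
    """Recode item categories to consecutive observed values; drop constants."""
    keep: list[int] = []
    cat_maps: list[np.ndarray] = []
    dropped: list[tuple[str, str]] = []
    recodes: list[tuple[str, str]] = []
    for j in range(data.n_items):
        col = data.values[:, j]
        obs = np.unique(col)
        if obs.size < 2:
            dropped.append((data.item_ids[j], "constant item (single observed value)"))
            continue
        keep.append(j)
        cat_maps.append(obs)
        if not np.array_equal(obs, np.arange(obs.size)):
            recodes.append(
                (data.item_ids[j], f"categories {obs.tolist()} -> {list(range(obs.size))}")
            )
    return np.array(keep, dtype=int), cat_maps, dropped, recodes


def _recode(values: np.ndarray, item_index: np.ndarray, cat_maps: list[np.ndarray]) -> np.ndarray:
    cols = []
    for j, obs in zip(item_index, cat_maps):
        cols.append(np.searchsorted(obs, values[:, j]))
    return np.column_stack(cols)


def fit_pcm_cml(
    data: GenotypeMatrix,
    grad_tol: float = 1e-6,
    max_iter: int = 100,
) -> PCMFit:
    """Estimate PCM item thresholds by Conditional Maximum Likelihood.

    Subjects with extreme raw scores (0 or the maximum) carry no conditional
    information and contribute nothing to the likelihood.  Items observed at
    a single value are dropped; items with gaps in their observed categories
    are collapsed to consecutive codes (both recorded on the returned fit).
    The gauge freedom (a common shift of all thresholds) is removed by the
    sum-zero normalization.
    """
    if data.has_missing:
        raise ValueError(
            "fit_pcm_cml requires complete data; impute missing genotypes first"
        )
    item_index, cat_maps, dropped, recodes = _prepare_items(data)

    def _failed(reason: str) -> PCMFit:
        return PCMFit(
            thresholds=None,
            loglik_conditional=np.nan,
            converged=False,
            n_iterations=0,
            reason=reason,
            item_index=item_index,
            category_maps=cat_maps,
            dropped_items=dropped,
            recodes=recodes,
        )

    if item_index.size < 2:
        return _failed("fewer than 2 usable items after dropping constant items")

    x = _recode(data.values, item_index, cat_maps)
    m_i = np.array([obs.size - 1 for obs in cat_maps])
    total = int(m_i.sum())
    raw = x.sum(axis=1)
    if not np.any((raw > 0) & (raw < total)):
        return _failed("no subject with a non-extreme raw score")

    # sufficient statistics
    counts = [np.bincount(x[:, i], minlength=m + 1) for i, m in enumerate(m_i)]
    score_counts = np.bincount(raw, minlength=total + 1).astype(float)
    # cumulative counts: N_{i,k} = # responses >= k, k = 1..m_i
    ncum = [c[::-1].cumsum()[::-1][1:].astype(float) for c in counts]

    offsets = np.concatenate([[0], np.cumsum(m_i)])
    n_par = offsets[-1]

    def unpack(theta: np.ndarray) -> list[np.ndarray]:
        return [theta[offsets[i] : offsets[i + 1]] for i in range(len(m_i))]

    n_items_used = len(m_i)

    def evaluate(theta: np.ndarray, want_hess: bool = False):
        """Penalized negative conditional log-likelihood, gradient, Hessian.

        The Hessian uses first and second ESF derivatives (leave-one-out and
        leave-two-out scaled ESFs); the quadratic gauge penalty adds a
        rank-one all-ones block.  The objective is convex: log gamma_r is a
        log-sum-exp of linear functions of tau.
        """
        taus = unpack(theta)
        cumtaus = [np.concatenate([[0.0], np.cumsum(t)]) for t in taus]
        eps = [np.exp(-c) for c in cumtaus]
        gamma_s, excl, u, log_scale = _scaled_esf_parts(eps)
        log_gamma = np.log(gamma_s) + log_scale
        nll = sum(c @ ct for c, ct in zip(counts, cumtaus))
        nll += score_counts @ log_gamma
        grad = np.empty(n_par)
        # D[i][k-1](r) = (dgamma_r/dtau_ki) / gamma_r up to sign; tails are
        # the upper parts of u_i entering the ESF derivative
        D: list[list[np.ndarray]] = []
        tails: list[list[np.ndarray]] = []
        for i in range(n_items_used):
            Di, Ti = [], []
            for k in range(1, m_i[i] + 1):
                tail = np.zeros_like(u[i])
                tail[k:] = u[i][k:]
                A = np.convolve(tail, excl[i]) / gamma_s
                Di.append(A)
                Ti.append(tail)
                grad[offsets[i] + k - 1] = ncum[i][k - 1] - score_counts @ A
            D.append(Di)
            tails.append(Ti)
        s = theta.sum()
        nll += 0.5 * s * s
        grad += s
        if not want_hess:
            return nll, grad, None
        H = np.empty((n_par, n_par))
        for i in range(n_items_used):
            for k in range(1, m_i[i] + 1):
                for k2 in range(k, m_i[i] + 1):
                    val = score_counts @ (D[i][k2 - 1] - D[i][k - 1] * D[i][k2 - 1])
                    a, b = offsets[i] + k - 1, offsets[i] + k2 - 1
                    H[a, b] = H[b, a] = val
        l2o = _leave_two_out(u)
        for i in range(n_items_used):
            for j in range(i + 1, n_items_used):
                g2 = l2o[(i, j)]
                for k in range(1, m_i[i] + 1):
                    for l in range(1, m_i[j] + 1):
                        Bg = (
                            np.convolve(np.convolve(tails[i][k - 1], tails[j][l - 1]), g2)
                            / gamma_s
                        )
                        val = score_counts @ (Bg - D[i][k - 1] * D[j][l - 1])
                        a, b = offsets[i] + k - 1, offsets[j] + l - 1
                        H[a, b] = H[b, a] = val
        H += 1.0  # gauge penalty curvature
        return nll, grad, H

    # damped Newton on the convex penalized objective
    theta = np.zeros(n_par)
    nit = 0
    for nit in range(1, max_iter + 1):
        nll, grad, hess = evaluate(theta, want_hess=True)
        if np.max(np.abs(grad)) <= grad_tol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(hess + 1e-8 * np.eye(n_par), grad)
        t, desc = 1.0, float(grad @ step)
        cand, nll_c = theta, nll
        while t > 1e-10:
            cand = np.clip(theta - t * step, -30.0, 30.0)
            nll_c = evaluate(cand)[0]
            if np.isfinite(nll_c) and nll_c <= nll - 1e-4 * t * desc:
                break
            t /= 2.0
        theta = cand
    _, grad, _ = evaluate(theta)
    if not np.all(np.isfinite(theta)) or np.max(np.abs(grad)) > grad_tol:
        return _failed(
            f"CML did not converge within {max_iter} iterations "
            f"(max |gradient| = {np.max(np.abs(grad)):.2e})"
        )
    theta = theta - theta.mean()  # exact sum-zero recentring (gauge move)
    taus = [t.copy() for t in unpack(theta)]
    # conditional log-likelihood at the recentred optimum (penalty is zero)
    loglik = -float(evaluate(theta)[0])
    return PCMFit(
        thresholds=ItemThresholds(taus),
        loglik_conditional=loglik,
        converged=True,
        n_iterations=nit,
        item_index=item_index,
        category_maps=cat_maps,
        dropped_items=dropped,
        recodes=recodes,
    )


def _expected_score(beta: float, taus: list[np.ndarray]) -> float:
    return float(
        sum(np.arange(len(t) + 1) @ pcm_category_probs(beta, t) for t in taus)
    )


class _ExpectedScore:
    """Vectorised sum_i E[X_i | beta] over items with padded category grids."""

    def __init__(self, taus: list[np.ndarray]):
        m_max = max(len(t) for t in taus)
        n_items = len(taus)
        # C[i][x] = sum_{k<=x} tau_ki, padded with +inf so exp() vanishes
        self.C = np.full((n_items, m_max + 1), np.inf)
        self.X = np.arange(m_max + 1, dtype=float)[None, :]
        for i, t in enumerate(taus):
            self.C[i, : len(t) + 1] = np.concatenate([[0.0], np.cumsum(t)])

    def __call__(self, beta: float) -> float:
        logit = beta * self.X - self.C
        logit -= logit.max(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            p = np.exp(logit)
        p /= p.sum(axis=1, keepdims=True)
        return float((p * self.X).sum())


def _solve_ability(target: float, esc: _ExpectedScore) -> float:
    """Solve sum_i E[X_i | beta] = target for beta (strictly monotone)."""
    lo, hi = -40.0, 40.0
    f = lambda b: esc(b) - target
    flo, fhi = f(lo), f(hi)
    while flo > 0:
        lo -= 40.0
        flo = f(lo)
    while fhi < 0:
        hi += 40.0
        fhi = f(hi)
    try:
        return float(brentq(f, lo, hi, xtol=1e-10))
    except Exception as exc:  # pragma: no cover - defensive
        raise RaschFitError(f"ability solve failed for raw score {target}: {exc}")


def person_abilities(
    data: GenotypeMatrix,
    fit: PCMFit,
    extreme_shift: float = 0.25,
) -> tuple[AbilityTable, np.ndarray]:
    """Maximum-likelihood person abilities given fitted thresholds.

    Every attainable raw score r in 1..S-1 (S = sum of item maxima) receives
    the ability solving the expected-score equation sum_i E[X_i | beta] = r;
    subjects sharing a raw score share an ability (sufficiency).  The
    extreme raw scores 0 and S, where no maximum exists, are assigned the
    solutions at pseudo-scores ``extreme_shift`` and ``S - extreme_shift``
    and flagged.
    """
    if not fit.converged:
        raise RaschFitError(f"cannot score from a non-converged fit: {fit.reason}")
    taus = fit.thresholds.tau
    total = sum(len(t) for t in taus)
    raw_scores = np.arange(total + 1)
    beta = np.empty(total + 1)
    flags = np.zeros(total + 1, dtype=bool)
    esc = _ExpectedScore(taus)
    for r in raw_scores:
        if r == 0:
            beta[r] = _solve_ability(extreme_shift, esc)
            flags[r] = True
        elif r == total:
            beta[r] = _solve_ability(total - extreme_shift, esc)
            flags[r] = True
        else:
            beta[r] = _solve_ability(float(r), esc)
    table = AbilityTable(raw_scores=raw_scores, beta=beta, extreme_flags=flags)
    x = _recode(data.values, fit.item_index, fit.category_maps)
    scores = beta[x.sum(axis=1)]
    return table, scores


def rasch_score(data: GenotypeMatrix, extreme_shift: float = 0.25) -> np.ndarray:
    """One multi-marker Rasch genetic score per subject.

    Composition of :func:`fit_pcm_cml` and :func:`person_abilities`;
    deterministic given the data.  Raises :class:`RaschFitError` when the
    CML fit fails (too few usable items, no informative subjects, or
    non-convergence).
    """
    fit = fit_pcm_cml(data)
    if not fit.converged:
        raise RaschFitError(fit.reason or "PCM fit failed")
    _, scores = person_abilities(data, fit, extreme_shift=extreme_shift)
    return scores


def simulate_pcm_responses(
    thresholds: ItemThresholds,
    abilities: np.ndarray,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Draw a response matrix from a PCM with known thresholds.

    Used for parameter-recovery checks: each subject's category on each item
    is multinomial with :func:`pcm_category_probs` probabilities.
    """
    abilities = np.asarray(abilities, dtype=float)
    n = abilities.size
    out = np.empty((n, thresholds.n_items), dtype=np.int16)
    for i, tau in enumerate(thresholds.tau):
        cum = np.concatenate([[0.0], np.cumsum(-tau)])  # beta-independent part
        logits = abilities[:, None] * np.arange(len(tau) + 1)[None, :] + cum[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        cdf = p.cumsum(axis=1)
        u = rng.random(n)
        out[:, i] = (u[:, None] > cdf).sum(axis=1)
    return GenotypeMatrix(out)
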