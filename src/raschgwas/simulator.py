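"""Case-control genotype simulation and Monte-Carlo power studies.

Genotype frequencies follow Wright's inbreeding model: with allele
frequencies p_a and 1 - p_a and consanguinity coefficient F,

    p0 = p_a^2 + F p_a (1 - p_a)
    p1 = 2 p_a (1 - p_a) (1 - F)
    p2 = (1 - p_a)^2 + F p_a (1 - p_a)

(F = 0 gives Hardy-Weinberg proportions).  Disease risk acts through
penetrances f_i = Pr(disease | genotype i) parameterised by the relative
risks RR_i = f_i / f_0 and the population prevalence K_p; under the additive
mode RR_1 = (RR_2 + 1) / 2.  Bayes' rule then yields the case and control
genotype frequencies

    pD_i = f_i p_i / K_p          pH_i = (1 - f_i) p_i / (1 - K_p)

from which case-control panels are drawn directly.

Three dependence designs are provided: independent SNPs; and LD blocks of
moderate (r^2 in 0.4-0.7) or strong (r^2 in 0.8-1.0) linkage disequilibrium,
where each disease susceptibility locus (DSL) carries passenger SNPs drawn
from a synthetic two-locus haplotype pool with a controlled target r^2.
False-positive rate and power of any registered set-level test are estimated
as #(p <= alpha) / B over B simulated replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from .association import TraitVector, score_association, per_snp_pvalues
from .genotypes import GenotypeMatrix
from .rasch_core import RaschFitError, rasch_score

__all__ = [
    "SNPSpec",
    "ScenarioConfig",
    "PenetranceSet",
    "HaplotypePool",
    "SimulationReport",
    "genotype_freqs",
    "penetrances",
    "case_control_freqs",
    "simulate_scenario1",
    "build_haplotype_pool",
    "simulate_ld_scenario",
    "simulate",
    "monte_carlo_rate",
    "monte_carlo_rates",
    "reports_to_table",
    "METHODS",
]

#: realized r^2 ranges of the LD designs
LD_RANGES = {"moderate": (0.4, 0.7), "strong": (0.8, 1.0)}


@dataclass
class SNPSpec:
    """One simulated SNP: allele frequency, inbreeding, and disease risk."""

    p_a: float
    F: float = 0.0
    RR2: float = 1.0
    mode: str = "additive"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_a < 1.0:
            raise ValueError("allele frequency must lie in (0, 1)")
        if self.RR2 < 1.0:
            raise ValueError("RR2 must be >= 1")
        if self.mode != "additive":
            raise ValueError("only the additive inheritance mode is supported")


@dataclass
class ScenarioConfig:
    """Study design of one simulation scenario.

    Defaults are the reference design: 500 cases / 500 controls, prevalence
    0.05, a set of 24 SNPs of which 12 are disease susceptibility loci.
    """

    n_cases: int = 500
    n_controls: int = 500
    prevalence: float = 0.05
    n_snps: int = 24
    n_dsl: int = 12
    ld_mode: str = "independent"
    seed: int = 0
    maf_low: float = 0.1
    maf_high: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_dsl > self.n_snps:
            raise ValueError("n_dsl cannot exceed n_snps")
        if self.ld_mode not in ("independent",) + tuple(LD_RANGES):
            raise ValueError(f"unknown ld_mode {self.ld_mode!r}")
        if self.ld_mode != "independent" and self.n_snps <= self.n_dsl:
            raise ValueError("LD scenarios need passenger SNPs (n_snps > n_dsl)")


@dataclass
class PenetranceSet:
    """Genotype penetrances and the induced case/control frequencies."""

    f: np.ndarray  # (f0, f1, f2)
    pD: np.ndarray
    pH: np.ndarray


@dataclass
class HaplotypePool:
    """Synthetic two-locus haplotype pool generating controlled LD blocks.

    For every passenger (non-DSL) SNP the pool holds the haplotype
    frequencies linking it to its DSL, the implied 3x3 joint genotype table
    under random union of haplotypes, and the population r^2 realized by the
    construction.  It stands in for diplotype resampling from a real panel
    while preserving the controlled-LD design.
    """

    ld_mode: str
    dsl_of: np.ndarray  # passenger -> index of its DSL
    hap_freqs: list[np.ndarray]  # per passenger: freqs of (AB, Ab, aB, ab)
    joint: list[np.ndarray]  # per passenger: 3x3 P(g_dsl, g_passenger)
    r2: np.ndarray  # per passenger: population r^2 with its DSL

    def conditional(self, b: int) -> np.ndarray:
        """P(passenger genotype | DSL genotype) for passenger b (3x3 rows)."""
        j = self.joint[b]
        marg = j.sum(axis=1, keepdims=True)
        return j / marg


@dataclass
class SimulationReport:
    method: str
    ld_mode: str
    rr: float
    B: int
    alpha: float
    rate: float
    se: float
    n_failed: int = 0
    reliable: bool = True


# ---------------------------------------------------------------------------
# single-SNP population model


def genotype_freqs(spec: SNPSpec) -> np.ndarray:
    """Genotype frequencies (p0, p1, p2) under Wright's inbreeding model."""
    pa, F = spec.p_a, spec.F
    het = pa * (1.0 - pa)
    p = np.array(
        [pa**2 + F * het, 2.0 * het * (1.0 - F), (1.0 - pa) ** 2 + F * het]
    )
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"genotype frequencies out of [0, 1] for {spec}")
    return p


def penetrances(freqs: np.ndarray, K_p: float, RR2: float, mode: str = "additive") -> PenetranceSet:
    """Closed-form penetrances under the additive relative-risk model.

    f0 = K_p / (p0 + RR1 p1 + RR2 p2) with RR1 = (RR2 + 1) / 2, f1 = RR1 f0,
    f2 = RR2 f0; the population prevalence identity sum_i f_i p_i = K_p holds
    exactly.  Case and control genotype frequencies follow by Bayes' rule.
    """
    if mode != "additive":
        raise ValueError("only the additive inheritance mode is supported")
    if RR2 < 1.0:
        raise ValueError("RR2 must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    rr1 = (RR2 + 1.0) / 2.0
    rr = np.array([1.0, rr1, RR2])
    f0 = K_p / float(rr @ freqs)
    f = rr * f0
    if f[2] > 1.0:
        raise ValueError(
            f"penetrance f2 = {f[2]:.4f} > 1 for K_p={K_p}, RR2={RR2}, freqs={freqs}"
        )
    pD = f * freqs / K_p
    pH = (1.0 - f) * freqs / (1.0 - K_p)
    return PenetranceSet(f=f, pD=pD, pH=pH)


def case_control_freqs(pen: PenetranceSet) -> tuple[np.ndarray, np.ndarray]:
    """Case (pD) and control (pH) genotype frequency vectors of a fit."""
    return pen.pD, pen.pH


# ---------------------------------------------------------------------------
# scenario simulation


def _draw_genotypes(rng, pD, pH, n_cases, n_controls) -> np.ndarray:
    col = np.empty(n_cases + n_controls, dtype=np.int16)
    col[:n_cases] = rng.choice(3, size=n_cases, p=pD)
    col[n_cases:] = rng.choice(3, size=n_controls, p=pH)
    return col


def _snp_ids(config: ScenarioConfig) -> list[str]:
    ids = [f"dsl{i}" for i in range(config.n_dsl)]
    ids += [f"null{i}" for i in range(config.n_snps - config.n_dsl)]
    return ids


def simulate_scenario1(
    config: ScenarioConfig,
    rr_dsl: float,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TraitVector]:
    """Independent-SNP case-control panel.

    Each SNP gets its own allele frequency drawn uniformly from
    ``[maf_low, maf_high]``; DSLs carry relative risk ``rr_dsl``, the
    remaining SNPs RR = 1.  Cases are drawn from pD, controls from pH,
    independently across SNPs.  The first ``n_cases`` subjects are the cases.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_cases + config.n_controls
    values = np.empty((n, config.n_snps), dtype=np.int16)
    for j in range(config.n_snps):
        rr = rr_dsl if j < config.n_dsl else 1.0
        spec = SNPSpec(p_a=rng.uniform(config.maf_low, config.maf_high), RR2=rr)
        pen = penetrances(genotype_freqs(spec), config.prevalence, rr)
        values[:, j] = _draw_genotypes(rng, pen.pD, pen.pH, config.n_cases, config.n_controls)
    trait = TraitVector(
        np.concatenate([np.ones(config.n_cases), np.zeros(config.n_controls)])
    )
    return GenotypeMatrix(values, item_ids=_snp_ids(config)), trait


def _two_locus_joint(q_a: float, q_b: float, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype frequencies and 3x3 joint genotype table at correlation r.

    ``q`` are the frequencies of the counted alleles; D = r * sqrt(prod of
    allele variances) with positive coupling.  Random union of two
    independent haplotypes gives the joint genotype distribution.
    """
    d = r * np.sqrt(q_a * (1 - q_a) * q_b * (1 - q_b))
    hap = np.array(
        [
            q_a * q_b + d,  # AB
            q_a * (1 - q_b) - d,  # Ab
            (1 - q_a) * q_b - d,  # aB
            (1 - q_a) * (1 - q_b) + d,  # ab
        ]
    )
    if np.any(hap < -1e-12):
        raise ValueError(f"infeasible haplotype frequencies at r={r}")
    hap = np.clip(hap, 0.0, None)
    hap /= hap.sum()
    alleles = np.array([(1, 1), (1, 0), (0, 1), (0, 0)])
    joint = np.zeros((3, 3))
    for h1 in range(4):
        for h2 in range(4):
            ga = alleles[h1, 0] + alleles[h2, 0]
            gb = alleles[h1, 1] + alleles[h2, 1]
            joint[ga, gb] += hap[h1] * hap[h2]
    return hap, joint


def build_haplotype_pool(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    dsl_freqs: np.ndarray | None = None,
) -> HaplotypePool:
    """Synthetic haplotype pool for the LD scenarios.

    Each passenger SNP is attached to a DSL (round-robin) with a target r^2
    drawn uniformly from the scenario's range.  Targets keep a small margin
    (0.035) from any open boundary of the range so that finite-panel sample
    r^2, which fluctuates around the target, stays inside the declared range
    (r^2 = 1 is a closed boundary: sample r^2 cannot exceed it).  The
    passenger's allele frequency is pinned to its DSL's so that every target
    up to r^2 = 1 is attainable (the two-locus D constraint).
    """
    if config.ld_mode not in LD_RANGES:
        raise ValueError(f"ld_mode {config.ld_mode!r} has no LD range")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = LD_RANGES[config.ld_mode]
    margin = 0.035
    lo += margin
    if hi < 1.0:
        hi -= margin
    n_pass = config.n_snps - config.n_dsl
    if dsl_freqs is None:
        dsl_freqs = rng.uniform(config.maf_low, config.maf_high, size=config.n_dsl)
    dsl_of = np.arange(n_pass) % config.n_dsl
    haps, joints, r2s = [], [], []
    for b in range(n_pass):
        q = 1.0 - dsl_freqs[dsl_of[b]]  # frequency of the counted allele
        r2 = rng.uniform(lo, hi)
        hap, joint = _two_locus_joint(q, q, np.sqrt(r2))
        haps.append(hap)
        joints.append(joint)
        r2s.append(r2)
    return HaplotypePool(
        ld_mode=config.ld_mode,
        dsl_of=dsl_of,
        hap_freqs=haps,
        joint=joints,
        r2=np.array(r2s),
    )


def simulate_ld_scenario(
    config: ScenarioConfig,
    rr_dsl: float,
    pool: HaplotypePool,
    rng: np.random.Generator | None = None,
    dsl_freqs: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, TraitVector]:
    """LD-block case-control panel.

    DSL genotypes are drawn from the case/control frequencies exactly as in
    the independent scenario; every passenger SNP is then filled by sampling
    from the pool's conditional genotype distribution given its DSL —
    disease status acts on passengers only through the DSL, so the block
    inherits the pool's LD and the null propagates when rr_dsl = 1.
    """
    if pool.ld_mode != config.ld_mode:
        raise ValueError(
            f"pool built for ld_mode {pool.ld_mode!r} but config requests "
            f"{config.ld_mode!r}"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_cases + config.n_controls
    n_pass = config.n_snps - config.n_dsl
    if pool.dsl_of.size != n_pass:
        raise ValueError("pool passenger count does not match config")
    if dsl_freqs is None:
        # recover each DSL's allele frequency from its first passenger block
        dsl_freqs = np.empty(config.n_dsl)
        for b in range(n_pass):
            q = pool.hap_freqs[b][0] + pool.hap_freqs[b][1]
            dsl_freqs[pool.dsl_of[b]] = 1.0 - q
    values = np.empty((n, config.n_snps), dtype=np.int16)
    for j in range(config.n_dsl):
        spec = SNPSpec(p_a=float(dsl_freqs[j]), RR2=rr_dsl)
        pen = penetrances(genotype_freqs(spec), config.prevalence, rr_dsl)
        values[:, j] = _draw_genotypes(rng, pen.pD, pen.pH, config.n_cases, config.n_controls)
    for b in range(n_pass):
        cond = pool.conditional(b)
        g_dsl = values[:, pool.dsl_of[b]]
        u = rng.random(n)
        cdf = cond.cumsum(axis=1)
        values[:, config.n_dsl + b] = (u[:, None] > cdf[g_dsl]).sum(axis=1)
    trait = TraitVector(
        np.concatenate([np.ones(config.n_cases), np.zeros(config.n_controls)])
    )
    ids = [f"dsl{i}" for i in range(config.n_dsl)]
    ids += [f"ld{b}_dsl{pool.dsl_of[b]}" for b in range(n_pass)]
    return GenotypeMatrix(values, item_ids=ids), trait


def simulate(
    config: ScenarioConfig,
    rr_dsl: float,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TraitVector]:
    """Dispatch on ``config.ld_mode``; LD scenarios draw a fresh pool."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.ld_mode == "independent":
        return simulate_scenario1(config, rr_dsl, rng)
    pool = build_haplotype_pool(config, rng)
    return simulate_ld_scenario(config, rr_dsl, pool, rng)


# ---------------------------------------------------------------------------
# method registry and Monte-Carlo estimation


def _p_rasch(data: GenotypeMatrix, trait: TraitVector, cache: dict) -> float:
    score = rasch_score(data)
    return score_association(score, trait).p_value


def _pvec(data, trait, cache):
    if "pvec" not in cache:
        cache["pvec"] = per_snp_pvalues(data, trait)
    return cache["pvec"]


def _p_minp(data, trait, cache):
    return assoc.minp_combine(_pvec(data, trait, cache)).p_value


def _p_gates(data, trait, cache):
    return assoc.gates_combine(_pvec(data, trait, cache)).p_value


def _p_fisher(data, trait, cache):
    return assoc.fisher_combine(_pvec(data, trait, cache)).p_value


def _p_brown(data, trait, cache):
    return assoc.fisher_combine(_pvec(data, trait, cache), adjust="brown").p_value


def _p_skat(data, trait, cache):
    return assoc.skat_test(data, trait).p_value


#: set-level tests usable with :func:`monte_carlo_rates`
METHODS = {
    "rasch": _p_rasch,
    "minp": _p_minp,
    "gates": _p_gates,
    "fisher": _p_fisher,
    "brown": _p_brown,
    "skat": _p_skat,
}

#: fraction of failed replicates above which a report is marked unreliable
MAX_FAILURE_FRACTION = 0.02


def monte_carlo_rates(
    methods: list[str],
    config: ScenarioConfig,
    rr_dsl: float,
    B: int,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> dict[str, SimulationReport]:
    """Estimate #(p <= alpha) / B for several tests on shared replicates.

    Under rr_dsl = 1 the rate is the false-positive rate, under rr_dsl > 1
    the power.  A replicate where a method fails (e.g. a non-convergent PCM
    fit) is excluded from that method's denominator; reports with more than
    2% failures are flagged unreliable.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    for m in methods:
        if m not in METHODS:
            raise KeyError(f"unknown method {m!r}; choose from {sorted(METHODS)}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    hits = {m: 0 for m in methods}
    failed = {m: 0 for m in methods}
    for _ in range(B):
        data, trait = simulate(config, rr_dsl, rng)
        cache: dict = {}
        for m in methods:
            try:
                p = METHODS[m](data, trait, cache)
            except (RaschFitError, np.linalg.LinAlgError, RuntimeError):
                failed[m] += 1
                continue
            if p <= alpha:
                hits[m] += 1
    out = {}
    for m in methods:
        n_ok = B - failed[m]
        rate = hits[m] / n_ok if n_ok else np.nan
        se = float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else np.nan
        out[m] = SimulationReport(
            method=m,
            ld_mode=config.ld_mode,
            rr=rr_dsl,
            B=B,
            alpha=alpha,
            rate=float(rate),
            se=se,
            n_failed=failed[m],
            reliable=failed[m] <= MAX_FAILURE_FRACTION * B,
        )
    return out


def monte_carlo_rate(
    method: str,
    config: ScenarioConfig,
    rr_dsl: float,
    B: int,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> SimulationReport:
    """Single-method convenience wrapper around :func:`monte_carlo_rates`."""
    return monte_carlo_rates([method], config, rr_dsl, B, alpha, rng)[method]


def reports_to_table(reports: list[SimulationReport]) -> pd.DataFrame:
    """Tab-separable table (method, scenario, rr, B, alpha, rate, SE, ...)."""
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "scenario": r.ld_mode,
                "rr": r.rr,
                "B": r.B,
                "alpha": r.alpha,
                "rate": r.rate,
                "se": r.se,
                "n_failed": r.n_failed,
                "reliable": r.reliable,
            }
            for r in reports
        ]
    )
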