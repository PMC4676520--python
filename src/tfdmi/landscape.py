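"""Fitness landscape, fixation rates and the analytic stationary theory.

Malthusian fitness is a truncated quadratic in the mismatch number r,

    F(r) = -kappa_F * r**2 / 2       for r <= r*,
    F(r) = INVIABLE                  for r >  r*,

where the inviable branch is a typed sentinel (never a floating -inf), so
that fixation rates of lethal mutants are exact zeros.  Evolution in the
monomorphic (weak-mutation) regime is an origin-fixation process whose
per-position substitution rate follows Kimura's diploid fixation probability,

    k = 2 mu0 Ne (1 - e^(-2 dF)) / (1 - e^(-4 Ne dF)),

with the neutral limit k = mu0.  The stationary distribution over mismatch
classes balances fitness against sequence entropy S(r) = ln Omega(r) through
the free fitness Phi(r) = F(r) + S(r)/(4 Ne):

    p(r) = exp(4 Ne Phi(r)) / Z     on r in {0..r*}.

Note on exactness: with the full Kimura form the rate ratio is
k(dF)/k(-dF) = exp((4 Ne - 2) dF), so the chain's exact stationary law uses
exponent 4 Ne - 2; with the scaled (diffusion) form
k = mu0 * 4 Ne dF / (1 - e^(-4 Ne dF)) the exponent 4 Ne is exact.  The two
differ at O(dF), invisible whenever fitness effects are weak.  Analytic
functions here default to the 4 Ne convention; ``exponent_shift=-2`` selects
the law that is exactly stationary for full-form rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .genotype import BindingModel, sequence_entropy

__all__ = [
    "INVIABLE",
    "SelectionParams",
    "EquilibriumDistribution",
    "fitness",
    "fitness_delta",
    "kimura_position_rate",
    "per_mutant_rate",
    "fixation_factor",
    "free_fitness",
    "equilibrium_distribution",
    "mean_substitution_rate",
    "class_rates",
    "detailed_balance_residual",
]


class _Inviable:
    """Sentinel for fitness beyond the cliff; fixation rate of such mutants is 0."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "INVIABLE"


INVIABLE = _Inviable()


@dataclass(frozen=True)
class SelectionParams:
    """Population-genetic scale of the landscape.

    kappa_F : curvature of the fitness landscape (Malthusian units per mismatch^2)
    Ne      : effective population size (diploid; 2 Ne gene copies)
    mu0     : per-position mutation rate per generation
    """

    kappa_F: float
    Ne: float
    mu0: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa_F < 0:
            raise ValueError("kappa_F must be non-negative")
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")

    @property
    def scaled_size(self) -> float:
        """Dimensionless scaled population size 4 Ne kappa_F."""
        return 4.0 * self.Ne * self.kappa_F

    @classmethod
    def from_scaled(cls, scaled_size: float, Ne: float = 1000.0, mu0: float = 1.0) -> "SelectionParams":
        """Build from the scaled size 4 Ne kappa_F, back-solving kappa_F at fixed Ne."""
        if scaled_size < 0:
            raise ValueError("scaled_size must be non-negative")
        return cls(kappa_F=scaled_size / (4.0 * Ne), Ne=Ne, mu0=mu0)


def fitness(r: int, m: BindingModel, s: SelectionParams) -> float | _Inviable:
    """Malthusian fitness of mismatch class r; INVIABLE beyond the cliff."""
    if not 0 <= r <= m.ell:
        raise ValueError(f"r={r} outside [0, ell={m.ell}]")
    if r > m.r_star:
        return INVIABLE
    return -0.5 * s.kappa_F * r * r


def fitness_delta(r_from: int, r_to: int, m: BindingModel, s: SelectionParams) -> float | _Inviable:
    """dF = F(r_to) - F(r_from); INVIABLE if the target class is beyond the cliff."""
    if r_to > m.r_star:
        return INVIABLE
    return -0.5 * s.kappa_F * (r_to * r_to - r_from * r_from)


def kimura_position_rate(delta_F: float | _Inviable, s: SelectionParams, form: str = "full") -> float:
    """Per-position substitution rate for a fitness change delta_F.

    form="full"   : k = 2 mu0 Ne (1-e^(-2 dF)) / (1-e^(-4 Ne dF))
    form="scaled" : k = mu0 * 4 Ne dF / (1-e^(-4 Ne dF))   (weak-effect form)

    Returns mu0 exactly in the neutral limit and 0 for INVIABLE.  Numerically
    stable for |4 Ne dF| up to far beyond +-700 and near zero (series branch
    below |4 Ne dF| = 1e-8).
    """
    if isinstance(delta_F, _Inviable):
        return 0.0
    x = 4.0 * s.Ne * delta_F
    if form == "scaled":
        if abs(x) < 1e-8:
            return s.mu0 * (1.0 + 0.5 * x)
        if x < -700.0:
            return s.mu0 * (-x) * math.exp(x)
        return s.mu0 * x / (-math.expm1(-x))
    if form != "full":
        raise ValueError(f"unknown rate form {form!r}")
    if abs(x) < 1e-8:
        # first-order series of (1-e^(-2dF))/(1-e^(-4Ne dF))
        return s.mu0 * (1.0 + (2.0 * s.Ne - 1.0) * delta_F)
    if x < -700.0:
        # denominator 1-e^(-x) ~ -e^(-x); numerator 1-e^(-2dF) = -expm1(-2dF)
        log_num = -2.0 * delta_F if -2.0 * delta_F > 30.0 else math.log(math.expm1(-2.0 * delta_F))
        arg = log_num + x
        return 2.0 * s.mu0 * s.Ne * (math.exp(arg) if arg > -745.0 else 0.0)
    num = -math.expm1(-2.0 * delta_F)
    den = -math.expm1(-x)
    return 2.0 * s.mu0 * s.Ne * num / den


def fixation_factor(delta_F: float | _Inviable, s: SelectionParams, form: str = "full") -> float:
    """Kimura fixation probability pi(dF) = k(dF) / (2 mu0 Ne); 1/(2 Ne) when neutral."""
    return kimura_position_rate(delta_F, s, form) / (2.0 * s.mu0 * s.Ne)


def per_mutant_rate(delta_F: float | _Inviable, s: SelectionParams, form: str = "full") -> float:
    """Fixation rate of one specific single-letter mutant: k(dF)/3.

    The per-position mutation supply 2 mu0 Ne is spread over the 3 alternative
    letters at that position.
    """
    return kimura_position_rate(delta_F, s, form) / 3.0


def free_fitness(r: int, m: BindingModel, s: SelectionParams) -> float:
    """Phi(r) = F(r) + S(r)/(4 Ne); defined only on viable classes."""
    f = fitness(r, m, s)
    if isinstance(f, _Inviable):
        raise ValueError(f"free fitness undefined beyond the cliff (r={r} > r*={m.r_star})")
    return f + sequence_entropy(r, m) / (4.0 * s.Ne)


@dataclass(frozen=True)
class EquilibriumDistribution:
    """Stationary law over mismatch classes.

    p     : probability per class, length ell+1 (zero beyond r*)
    log_Z : log partition function, log sum_r exp(4 Ne Phi(r))
    phi   : free fitness per viable class, length r*+1
    """

    p: np.ndarray
    log_Z: float
    phi: np.ndarray
    r_star: int

    @property
    def mean_r(self) -> float:
        return float(np.dot(np.arange(self.p.size), self.p))

    def mean_dG(self, m: BindingModel) -> float:
        return m.delta_eps * self.mean_r


def equilibrium_distribution(
    m: BindingModel, s: SelectionParams, exponent_shift: float = 0.0
) -> EquilibriumDistribution:
    """Stationary distribution p(r) ∝ Omega(r) exp(4 Ne F(r)) on r in {0..r*}.

    Computed in log space (entropy via log-gamma), so arbitrarily large ell and
    4 Ne kappa_F are safe.  ``exponent_shift=-2`` yields the law exactly
    stationary under full-form Kimura rates (see module docstring).
    """
    rs = m.r_star
    a = 4.0 * s.Ne + exponent_shift
    r = np.arange(rs + 1)
    S = np.array([sequence_entropy(int(ri), m) for ri in r])
    F = -0.5 * s.kappa_F * r.astype(float) ** 2
    logw = S + a * F
    log_Z = float(logsumexp(logw))
    p = np.zeros(m.ell + 1)
    p[: rs + 1] = np.exp(logw - log_Z)
    p[: rs + 1] /= p[: rs + 1].sum()  # guard rounding
    phi = F + S / (4.0 * s.Ne)
    return EquilibriumDistribution(p=p, log_Z=log_Z, phi=phi, r_star=rs)


def class_rates(m: BindingModel, s: SelectionParams, form: str = "full") -> dict[str, np.ndarray | float]:
    """Per-mutant and total fixation rates aggregated by mismatch class.

    For a genotype in class r there are 2r mutants lowering r (rate k_down[r]
    each), 4r preserving it (rate mu0/3 each) and 6(ell-r) raising it (rate
    k_up[r] each, zero at the cliff).  Returns arrays over r = 0..r*:
    ``k_down``, ``k_up`` (per mutant), scalar ``k_same`` and the genotype
    total ``K``.
    """
    rs = m.r_star
    k_down = np.zeros(rs + 1)
    k_up = np.zeros(rs + 1)
    for r in range(rs + 1):
        if r > 0:
            k_down[r] = per_mutant_rate(fitness_delta(r, r - 1, m, s), s, form)
        if r < rs:
            k_up[r] = per_mutant_rate(fitness_delta(r, r + 1, m, s), s, form)
    k_same = s.mu0 / 3.0
    r = np.arange(rs + 1)
    K = 2 * r * k_down + 4 * r * k_same + 6 * (m.ell - r) * k_up
    return {"k_down": k_down, "k_up": k_up, "k_same": k_same, "K": K}


def mean_substitution_rate(
    m: BindingModel,
    s: SelectionParams,
    form: str = "full",
    p: np.ndarray | None = None,
) -> float:
    """Analytic mean per-site substitution rate, in units of mu0.

    <k> = (2 Ne mu0 / 3 ell) * sum_{r=0}^{r*} p(r) [ r (pi_-(r) + 1/Ne)
                                                     + 3 (ell - r) pi_+(r) ],

    where pi_-/pi_+ are Kimura fixation probabilities for r -> r-1 / r -> r+1
    (pi_+(r*) = 0 at the cliff) and the 1/Ne term carries the 4r within-class
    neutral mutants.  With kappa_F = 0 and the cliff removed this is exactly
    mu0; with the cliff it is mu0 (1 - p(r*) (ell - r*)/ell).
    """
    rs = m.r_star
    if p is None:
        p = equilibrium_distribution(m, s).p
    total = 0.0
    for r in range(rs + 1):
        pi_minus = fixation_factor(fitness_delta(r, r - 1, m, s), s, form) if r > 0 else 0.0
        pi_plus = fixation_factor(fitness_delta(r, r + 1, m, s), s, form) if r < rs else 0.0
        total += p[r] * (r * (pi_minus + 1.0 / s.Ne) + 3.0 * (m.ell - r) * pi_plus)
    return (2.0 * s.Ne / (3.0 * m.ell)) * total


def detailed_balance_residual(
    m: BindingModel,
    s: SelectionParams,
    form: str = "scaled",
    p: np.ndarray | None = None,
) -> float:
    """Max relative imbalance |p(r) k(r->r+1) - p(r+1) k(r+1->r)| over classes.

    Class-level fluxes use mutant counts (6(ell-r) up, 2(r+1) down) times the
    per-mutant rate.  With the stationary law matched to the rate form
    (exponent 4 Ne for "scaled", 4 Ne - 2 for "full") the residual vanishes to
    round-off; a perturbed ``p`` serves as a negative control.
    """
    rates = class_rates(m, s, form)
    if p is None:
        shift = -2.0 if form == "full" else 0.0
        p = equilibrium_distribution(m, s, exponent_shift=shift).p
    rs = m.r_star
    worst = 0.0
    for r in range(rs):
        up = p[r] * 6 * (m.ell - r) * rates["k_up"][r]
        down = p[r + 1] * 2 * (r + 1) * rates["k_down"][r + 1]
        denom = max(up, down)
        if denom > 0:
            worst = max(worst, abs(up - down) / denom)
    return worst
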