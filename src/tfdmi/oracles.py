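"""Independent brute-force oracles on tiny instances.

These enumerate the complete sequence-pair state space (feasible for ell <= 3)
and compute stationary laws and DMI first-passage probabilities by linear
algebra, with no reliance on the lumped mismatch-class picture or on the
Monte Carlo engines.  The main implementation must match them exactly (for
analytic quantities) or within Monte Carlo error (for simulations).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.sparse as sp
from scipy.stats import poisson

from .genotype import BindingModel
from .landscape import SelectionParams, fitness_delta, per_mutant_rate

__all__ = [
    "enumerate_pairs",
    "brute_force_degeneracy",
    "exact_stationary",
    "exact_PI_curve",
]

_MAX_ELL = 3


def enumerate_pairs(ell: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All 4**(2 ell) (protein, dna) code tuples."""
    if ell > _MAX_ELL:
        raise ValueError(f"enumeration limited to ell <= {_MAX_ELL}")
    seqs = list(itertools.product(range(4), repeat=ell))
    return [(p, d) for p in seqs for d in seqs]


def _r(p: tuple[int, ...], d: tuple[int, ...]) -> int:
    return sum(a != b for a, b in zip(p, d))


def brute_force_degeneracy(m: BindingModel) -> np.ndarray:
    """Omega(r) for r = 0..ell by explicit enumeration of all pairs."""
    counts = np.zeros(m.ell + 1, dtype=np.int64)
    for p, d in enumerate_pairs(m.ell):
        counts[_r(p, d)] += 1
    return counts


def _one_step_targets(p: tuple[int, ...], d: tuple[int, ...]):
    """Yield all 6*ell single-letter neighbours of a pair."""
    ell = len(p)
    for pos in range(ell):
        for letter in range(4):
            if letter != p[pos]:
                yield (p[:pos] + (letter,) + p[pos + 1 :], d)
            if letter != d[pos]:
                yield (p, d[:pos] + (letter,) + d[pos + 1 :])


def exact_stationary(m: BindingModel, s: SelectionParams, form: str = "scaled") -> np.ndarray:
    """Stationary distribution over r of the full sequence-pair chain, ell <= 3.

    Builds the complete fixation-rate generator over all viable pairs, solves
    the global balance equations and aggregates by mismatch class.
    """
    if m.ell > _MAX_ELL:
        raise ValueError(f"exact_stationary limited to ell <= {_MAX_ELL}")
    rs = m.r_star
    pairs = [g for g in enumerate_pairs(m.ell) if _r(*g) <= rs]
    index = {g: i for i, g in enumerate(pairs)}
    n = len(pairs)
    Q = np.zeros((n, n))
    for g in pairs:
        i = index[g]
        r_from = _r(*g)
        for tgt in _one_step_targets(*g):
            r_to = _r(*tgt)
            if r_to > rs:
                continue
            rate = per_mutant_rate(fitness_delta(r_from, r_to, m, s), s, form)
            Q[i, index[tgt]] += rate
            Q[i, i] -= rate
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    out = np.zeros(m.ell + 1)
    for g, i in index.items():
        out[_r(*g)] += pi[i]
    return out


def exact_PI_curve(
    m: BindingModel,
    s: SelectionParams,
    r0: int,
    grid: np.ndarray,
    form: str = "full",
    tol: float = 1e-10,
) -> np.ndarray:
    """Exact first-passage P_I(t) of the joint two-lineage chain at ell = 2.

    State space: ordered pairs of viable genotype pairs (g1, g2); any
    substitution producing a hybrid with h12 > r* or h21 > r* is routed to a
    single absorbing DMI state.  The transient distribution is propagated by
    uniformization with Poisson tail truncated below ``tol``; initial law is
    uniform over ancestors of class ``r0``, duplicated.
    """
    if m.ell != 2:
        raise ValueError("the joint-chain oracle is built for ell = 2")
    rs = m.r_star
    if not 0 <= r0 <= rs:
        raise ValueError("r0 must be a viable class")
    viable = [g for g in enumerate_pairs(2) if _r(*g) <= rs]
    joint = [(g1, g2) for g1 in viable for g2 in viable]
    index = {st: i for i, st in enumerate(joint)}
    n = len(joint)

    rows, cols, vals = [], [], []
    absorb = np.zeros(n)
    diag = np.zeros(n)
    for st in joint:
        g1, g2 = st
        i = index[st]
        for lineage in (0, 1):
            g = st[lineage]
            r_from = _r(*g)
            for tgt in _one_step_targets(*g):
                r_to = _r(*tgt)
                if r_to > rs:
                    continue
                rate = per_mutant_rate(fitness_delta(r_from, r_to, m, s), s, form)
                if rate <= 0.0:
                    continue
                new = (tgt, g2) if lineage == 0 else (g1, tgt)
                (p1, d1), (p2, d2) = new
                h12 = _r(p1, d2)
                h21 = _r(p2, d1)
                diag[i] += rate
                if h12 > rs or h21 > rs:
                    absorb[i] += rate
                else:
                    rows.append(i)
                    cols.append(index[new])
                    vals.append(rate)
    lam = float(diag.max())
    if lam <= 0.0:
        return np.zeros(len(grid))
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n, n)) / lam
    stay = 1.0 - diag / lam  # probability of the uniformized self-loop
    x0 = np.zeros(n)
    anc = [g for g in viable if _r(*g) == r0]
    for g in anc:
        x0[index[(g, g)]] += 1.0 / len(anc)

    t_end = float(np.max(grid))
    kmax = int(poisson.isf(tol * 0.1, lam * t_end)) + 2
    survival = np.empty(kmax + 1)
    x = x0.copy()
    survival[0] = x.sum()
    for k in range(1, kmax + 1):
        x = stay * x + P.T @ x
        survival[k] = x.sum()
    ks = np.arange(kmax + 1)
    out = np.empty(len(grid))
    for j, t in enumerate(np.asarray(grid, dtype=float)):
        w = poisson.pmf(ks, lam * t)
        # tail survival is sandwiched in [0, survival[kmax]]; its Poisson mass is < tol
        out[j] = 1.0 - float(np.dot(w, survival)) - float(poisson.sf(kmax, lam * t)) * survival[kmax]
    return np.clip(out, 0.0, 1.0)
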