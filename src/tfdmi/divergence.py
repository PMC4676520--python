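"""Allopatric divergence experiment: hybrid incompatibilities and time to RI.

A common-ancestor TF-TFBS pair (binding energy drawn from the stationary
distribution) is duplicated into two lineages that evolve independently under
origin-fixation dynamics.  At each substitution the two hybrid pairings are
scored by their Hamming distances h12 = dH(protein_1, dna_2) and
h21 = dH(protein_2, dna_1); a Dobzhansky-Muller incompatibility (DMI) arises
the first time either exceeds the viability threshold r*.  From replicate
first-passage times the probability P_I(t) of a DMI is estimated, the genome
is modelled as M independent interacting pairs through
P_RI(t) = 1 - (1 - P_I(t))**M, and the time to reproductive isolation t* is
read off as the first crossing of P_I = 1/M.

Two replicate engines are provided: an object-level one
(:func:`run_replicate`) built on :mod:`tfdmi.engine`, which can record hybrid
trajectories and a non-absorbing "instantaneous presence" DMI convention; and
a vectorized bulk engine (:func:`simulate_pairs`) that runs up to millions of
replicate pairs as a synchronized numpy sweep.  Both are sequence-level and
exactly equivalent in law; the bulk engine is validated against the small-ell
exact chain oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import LineageState, _decode_index, mutant_rates
from .genotype import (
    BindingModel,
    TFGenotype,
    hamming_distance,
    random_genotype_at_distance,
)
from .landscape import SelectionParams, class_rates, equilibrium_distribution

__all__ = [
    "AncestorSample",
    "HybridState",
    "DMIRecord",
    "DMICurve",
    "RISummary",
    "BulkResult",
    "hybrid_state",
    "sample_ancestor",
    "run_replicate",
    "simulate_pairs",
    "dmi_curve",
    "log_grid",
    "estimate_PI",
    "prob_RI",
    "time_to_RI",
    "TStarResult",
    "hybrid_energy_stats",
    "early_slope",
    "loglog_curvature",
    "min_substitutions_to_DMI",
]


# --------------------------------------------------------------------------
# ancestors and hybrids

@dataclass(frozen=True)
class AncestorSample:
    genotype: TFGenotype
    r0: int
    mode: str  # "equilibrium" | "fixed-r" | "user"


@dataclass(frozen=True)
class HybridState:
    """Hamming distances and binding energies of the two hybrid pairings."""

    h12: int
    h21: int
    dG12: float
    dG21: float


def hybrid_state(g1: TFGenotype, g2: TFGenotype, m: BindingModel) -> HybridState:
    """Score the hybrids: protein of lineage 1 with dna of lineage 2 and vice versa."""
    h12 = hamming_distance(g1.protein, g2.dna)
    h21 = hamming_distance(g2.protein, g1.dna)
    return HybridState(h12=h12, h21=h21, dG12=m.delta_eps * h12, dG21=m.delta_eps * h21)


def sample_ancestor(
    m: BindingModel,
    s: SelectionParams,
    mode: str = "equilibrium",
    rng: np.random.Generator | None = None,
    genotype: TFGenotype | None = None,
) -> AncestorSample:
    """Draw the common ancestor.

    mode="equilibrium": r0 from the stationary law, then uniform within class.
    mode="fixed-r":     r0 = round of the stationary mean (narrow-ancestor variant).
    mode="user":        validate a supplied genotype (viability enforced).
    """
    if mode == "user":
        if genotype is None:
            raise ValueError("user mode requires a genotype")
        r0 = genotype.mismatches
        if r0 > m.r_star:
            raise ValueError(f"user ancestor has r0={r0} > r*={m.r_star} (inviable)")
        return AncestorSample(genotype=genotype, r0=r0, mode=mode)
    if rng is None:
        raise ValueError("equilibrium/fixed-r modes require an rng")
    eq = equilibrium_distribution(m, s)
    if mode == "equilibrium":
        r0 = int(rng.choice(m.ell + 1, p=eq.p))
    elif mode == "fixed-r":
        r0 = int(round(eq.mean_r))
    else:
        raise ValueError(f"unknown ancestor mode {mode!r}")
    g = random_genotype_at_distance(r0, m, rng)
    return AncestorSample(genotype=g, r0=r0, mode=mode)


# --------------------------------------------------------------------------
# object-level replicate

@dataclass
class DMIRecord:
    """Outcome of one replicate pair of diverging lineages."""

    first_passage_time: float  # math.inf when censored
    which_hybrid: str | None  # "12" | "21" | "both" | None
    substitutions_at_dmi: int | None
    r0: int
    t_max: float
    trajectory: list[tuple[float, int, int]] | None = None  # (t, h12, h21)
    params: dict = field(default_factory=dict)

    @property
    def censored(self) -> bool:
        return not math.isfinite(self.first_passage_time)


def run_replicate(
    ancestor: AncestorSample | TFGenotype,
    t_max: float,
    m: BindingModel,
    s: SelectionParams,
    rng: np.random.Generator,
    form: str = "full",
    mode: str = "first_passage",
    record_hybrids: bool = False,
) -> DMIRecord:
    """Evolve one duplicated-ancestor pair of lineages to ``t_max``.

    Hybrid distances are recomputed only at substitution events (they change
    only then, by at most one).  With mode="first_passage" the run stops at
    the first DMI; with mode="instantaneous" it continues to ``t_max`` and the
    trajectory records the presence of a DMI over time.
    """
    if mode not in ("first_passage", "instantaneous"):
        raise ValueError(f"unknown DMI mode {mode!r}")
    g0 = ancestor.genotype if isinstance(ancestor, AncestorSample) else ancestor
    r0 = g0.mismatches
    if r0 > m.r_star:
        raise ValueError("ancestor is inviable")
    L1 = LineageState.from_genotype(g0)
    L2 = L1.copy()
    h12 = h21 = r0
    traj = [(0.0, h12, h21)] if (record_hybrids or mode == "instantaneous") else None
    t = 0.0
    n_subs = 0
    fp = math.inf
    which = None
    rs = m.r_star
    while True:
        # merge the two independent lineages on one clock: total rate K1+K2
        L1.time = L2.time = t
        rates1 = mutant_rates(L1, m, s, form)
        rates2 = mutant_rates(L2, m, s, form)
        K1, K2 = float(rates1.sum()), float(rates2.sum())
        K = K1 + K2
        if K <= 0.0:
            t = t_max
            break
        dt = rng.standard_exponential() / K
        if t + dt > t_max:
            t = t_max
            break
        t += dt
        if rng.random() * K < K1:
            lineage, rates, state, other = 1, rates1, L1, L2
        else:
            lineage, rates, state, other = 2, rates2, L2, L1
        cum = np.cumsum(rates)
        idx = int(np.searchsorted(cum, rng.random() * float(cum[-1]), side="right"))
        idx = min(idx, rates.size - 1)
        locus, pos, letter = _decode_index(idx, state, m.ell)
        seq = state.protein if locus == 0 else state.dna
        old = int(seq[pos])
        seq[pos] = letter
        state.n_substitutions[locus] += 1
        n_subs += 1
        # incremental hybrid update
        if lineage == 1:
            if locus == 0:  # protein_1 vs dna_2
                h12 += int(letter != other.dna[pos]) - int(old != other.dna[pos])
            else:  # dna_1 vs protein_2
                h21 += int(other.protein[pos] != letter) - int(other.protein[pos] != old)
        else:
            if locus == 0:  # protein_2 vs dna_1
                h21 += int(letter != other.dna[pos]) - int(old != other.dna[pos])
            else:  # dna_2 vs protein_1
                h12 += int(other.protein[pos] != letter) - int(other.protein[pos] != old)
        if traj is not None:
            traj.append((t, h12, h21))
        if (h12 > rs or h21 > rs) and not math.isfinite(fp):
            fp = t
            which = "both" if (h12 > rs and h21 > rs) else ("12" if h12 > rs else "21")
            if mode == "first_passage":
                break
    subs_at = n_subs if math.isfinite(fp) else None
    return DMIRecord(
        first_passage_time=fp,
        which_hybrid=which,
        substitutions_at_dmi=subs_at,
        r0=r0,
        t_max=t_max,
        trajectory=traj,
        params={"ell": m.ell, "delta_eps": m.delta_eps, "delta_eps_ns": m.delta_eps_ns,
                "r_star": m.r_star, "kappa_F": s.kappa_F, "Ne": s.Ne, "mu0": s.mu0},
    )


# --------------------------------------------------------------------------
# vectorized bulk engine

@dataclass
class BulkResult:
    """Replicate-pair sweep output.

    first_passage : per-pair DMI first-passage time (inf = censored)
    r0            : per-pair ancestor mismatch class
    occupancy     : time-weighted occupancy of r pooled over lineages (or None)
    counts        : accepted substitutions, shape (n, 2 lineages, 2 loci) (or None)
    """

    first_passage: np.ndarray
    r0: np.ndarray
    t_max: float
    n_pairs: int
    occupancy: np.ndarray | None = None
    counts: np.ndarray | None = None


def _select_kth_true(mask: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Per row, index of the (k+1)-th True entry of a boolean matrix."""
    cs = np.cumsum(mask, axis=1)
    hit = mask & (cs == (k + 1)[:, None])
    return hit.argmax(axis=1)


def simulate_pairs(
    n_pairs: int,
    t_max: float,
    m: BindingModel,
    s: SelectionParams,
    rng: np.random.Generator,
    ancestor_mode: str = "equilibrium",
    r0: int | None = None,
    form: str = "full",
    track_dmi: bool = True,
    collect_occupancy: bool = False,
    collect_counts: bool = False,
) -> BulkResult:
    """Vectorized sweep of replicate allopatric pairs.

    All pairs advance together: each round draws the next substitution (or
    censoring) of every still-active pair, applies it, updates the lineage
    and hybrid mismatch counts incrementally, and absorbs pairs whose hybrids
    cross the cliff (when ``track_dmi``).  ``r0`` forces a common ancestor
    class; otherwise the ancestor follows ``ancestor_mode`` as in
    :func:`sample_ancestor`.  With ``track_dmi=False`` the sweep doubles as a
    bulk single-lineage simulator (per-lineage statistics are unaffected by
    hybrid bookkeeping).
    """
    ell, rs = m.ell, m.r_star
    tables = class_rates(m, s, form)
    K_of_r = tables["K"]
    kd, ku, ks = tables["k_down"], tables["k_up"], float(tables["k_same"])

    if r0 is not None:
        if not 0 <= r0 <= rs:
            raise ValueError("forced r0 must be a viable class")
        r0v = np.full(n_pairs, r0, dtype=np.int64)
    else:
        eq = equilibrium_distribution(m, s)
        if ancestor_mode == "equilibrium":
            r0v = rng.choice(ell + 1, size=n_pairs, p=eq.p).astype(np.int64)
        elif ancestor_mode == "fixed-r":
            r0v = np.full(n_pairs, int(round(eq.mean_r)), dtype=np.int64)
        else:
            raise ValueError(f"unknown ancestor mode {ancestor_mode!r}")

    P1 = rng.integers(0, 4, size=(n_pairs, ell), dtype=np.uint8)
    D1 = P1.copy()
    ranks = np.argsort(rng.random((n_pairs, ell)), axis=1)
    mism = ranks < r0v[:, None]
    offs = rng.integers(1, 4, size=(n_pairs, ell), dtype=np.uint8)
    D1[mism] = (D1[mism] + offs[mism]) % 4
    P2, D2 = P1.copy(), D1.copy()

    r1 = r0v.copy()
    r2 = r0v.copy()
    h12 = r0v.copy()
    h21 = r0v.copy()
    t = np.zeros(n_pairs)
    fp = np.full(n_pairs, np.inf)
    occ = np.zeros(rs + 1) if collect_occupancy else None
    counts = np.zeros((n_pairs, 2, 2), dtype=np.int64) if collect_counts else None

    active = np.arange(n_pairs)
    while active.size:
        Kt = K_of_r[r1[active]] + K_of_r[r2[active]]
        dt = np.full(active.size, np.inf)
        nz = Kt > 0.0
        if nz.any():
            dt[nz] = rng.standard_exponential(int(nz.sum())) / Kt[nz]
        t_new = t[active] + dt
        if occ is not None:
            dt_eff = np.minimum(t_new, t_max) - t[active]
            np.add.at(occ, r1[active], dt_eff)
            np.add.at(occ, r2[active], dt_eff)
        cens = t_new >= t_max
        t[active] = np.where(cens, t_max, t_new)
        active = active[~cens]
        if active.size == 0:
            break

        a = active
        K1 = K_of_r[r1[a]]
        first = rng.random(a.size) * (K1 + K_of_r[r2[a]]) < K1
        for lineage, rows in ((1, a[first]), (2, a[~first])):
            if rows.size == 0:
                continue
            if lineage == 1:
                P, D, rl = P1, D1, r1
            else:
                P, D, rl = P2, D2, r2
            rb = rl[rows]
            w_down = 2 * rb * kd[rb]
            w_same = 4 * rb * ks
            w_up = 6 * (ell - rb) * ku[rb]
            u = rng.random(rows.size) * (w_down + w_same + w_up)
            cls = np.where(u < w_down, 0, np.where(u < w_down + w_same, 1, 2))
            on_protein = rng.random(rows.size) < 0.5

            mismatch = P[rows] != D[rows]
            kpos = np.empty(rows.size, dtype=np.int64)
            lo = cls < 2
            if lo.any():
                kpos[lo] = (rng.random(int(lo.sum())) * rb[lo]).astype(np.int64)
            if (~lo).any():
                kpos[~lo] = (rng.random(int((~lo).sum())) * (ell - rb[~lo])).astype(np.int64)
            pos = np.empty(rows.size, dtype=np.int64)
            if lo.any():
                pos[lo] = _select_kth_true(mismatch[lo], kpos[lo])
            if (~lo).any():
                pos[~lo] = _select_kth_true(~mismatch[~lo], kpos[~lo])

            rr = np.arange(rows.size)
            cur = np.where(on_protein, P[rows, pos], D[rows, pos]).astype(np.int64)
            par = np.where(on_protein, D[rows, pos], P[rows, pos]).astype(np.int64)
            new = np.empty(rows.size, dtype=np.int64)
            c0 = cls == 0
            new[c0] = par[c0]
            c1 = cls == 1
            if c1.any():
                lt = np.arange(4)
                cand = (lt[None, :] != cur[c1, None]) & (lt[None, :] != par[c1, None])
                pick = rng.integers(0, 2, size=int(c1.sum()))
                new[c1] = _select_kth_true(cand, pick)
            c2 = cls == 2
            if c2.any():
                new[c2] = (cur[c2] + rng.integers(1, 4, size=int(c2.sum()))) % 4

            # apply and update mismatch counters incrementally
            old = cur
            d_own = (new != par).astype(np.int64) - (old != par).astype(np.int64)
            rl[rows] += d_own
            if lineage == 1:
                oP, oD = P2, D2
            else:
                oP, oD = P1, D1
            other_partner = np.where(on_protein, oD[rows, pos], oP[rows, pos]).astype(np.int64)
            d_hyb = (new != other_partner).astype(np.int64) - (old != other_partner).astype(np.int64)
            # lineage1 protein or lineage2 dna -> h12; otherwise h21
            to_h12 = on_protein if lineage == 1 else ~on_protein
            h12[rows[to_h12]] += d_hyb[to_h12]
            h21[rows[~to_h12]] += d_hyb[~to_h12]

            prot_rows = rows[on_protein]
            P[prot_rows, pos[on_protein]] = new[on_protein].astype(np.uint8)
            dna_rows = rows[~on_protein]
            D[dna_rows, pos[~on_protein]] = new[~on_protein].astype(np.uint8)
            if counts is not None:
                counts[prot_rows, lineage - 1, 0] += 1
                counts[dna_rows, lineage - 1, 1] += 1

        if track_dmi:
            hit = (h12[a] > rs) | (h21[a] > rs)
            if hit.any():
                rows = a[hit]
                fp[rows] = t[rows]
                active = a[~hit]
            else:
                active = a
        else:
            active = a

    return BulkResult(
        first_passage=fp, r0=r0v, t_max=t_max, n_pairs=n_pairs, occupancy=occ, counts=counts
    )


# --------------------------------------------------------------------------
# curve estimation

def log_grid(t_max: float, t_min: float = 1e-4, points_per_decade: int = 50) -> np.ndarray:
    """Log-spaced time grid from ``t_min`` to ``t_max``."""
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    n = max(2, int(math.ceil(points_per_decade * math.log10(t_max / t_min))) + 1)
    return np.geomspace(t_min, t_max, n)


@dataclass
class DMICurve:
    """Estimated P_I(t) with Wilson 95% bounds on a time grid."""

    t: np.ndarray
    p: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_events: np.ndarray
    n_replicates: int
    params: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "P_I": self.p, "ci_lo": self.ci_lo,
             "ci_hi": self.ci_hi, "n_events": self.n_events}
        )


def _wilson(k: np.ndarray, n: int, z: float = 1.959963984540054) -> tuple[np.ndarray, np.ndarray]:
    phat = k / n
    denom = 1.0 + z * z / n
    centre = phat + z * z / (2 * n)
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    lo = np.minimum((centre - half) / denom, phat)  # guard rounding at k=0 / k=n
    hi = np.maximum((centre + half) / denom, phat)
    return np.clip(lo, 0.0, 1.0), np.clip(hi, 0.0, 1.0)


def estimate_PI(records, grid: np.ndarray, n: int | None = None, t_max: float | None = None) -> DMICurve:
    """Empirical first-passage P_I(t) on a grid, with Wilson 95% intervals.

    ``records`` is either an array of first-passage times (inf = censored) or
    a list of :class:`DMIRecord` with common parameters.  Censored replicates
    contribute zero up to their horizon; the grid must not extend past it.
    """
    params: dict = {}
    if len(records) and isinstance(records[0], DMIRecord):
        params = records[0].params
        for rec in records:
            if rec.params != params:
                raise ValueError("records carry mixed parameters")
        t_max = records[0].t_max if t_max is None else t_max
        times = np.array([rec.first_passage_time for rec in records])
        n = len(records)
    else:
        times = np.asarray(records, dtype=float)
        n = times.size if n is None else n
    if n < 1:
        raise ValueError("need at least one replicate")
    grid = np.asarray(grid, dtype=float)
    if t_max is not None and grid[-1] > t_max * (1 + 1e-12):
        raise ValueError("grid extends beyond the simulation horizon")
    finite = np.sort(times[np.isfinite(times)])
    k = np.searchsorted(finite, grid, side="right")
    p = k / n
    lo, hi = _wilson(k.astype(float), n)
    return DMICurve(t=grid, p=p, ci_lo=lo, ci_hi=hi, n_events=k, n_replicates=n, params=dict(params))


def prob_RI(p, M: float, short_time: bool = False) -> np.ndarray:
    """P_RI = 1 - (1 - P_I)**M over M interaction partners.

    ``short_time=True`` uses the small-P_I form 1 - exp(-M P_I).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    arr = p.p if isinstance(p, DMICurve) else np.asarray(p, dtype=float)
    if short_time:
        return -np.expm1(-M * arr)
    clipped = np.clip(arr, 0.0, 1.0)
    out = -np.expm1(M * np.log1p(-np.where(clipped < 1.0, clipped, 0.0)))
    return np.where(clipped < 1.0, out, 1.0)


@dataclass(frozen=True)
class TStarResult:
    t_star: float | None
    ci: tuple[float, float] | None
    reached: bool
    threshold: float
    M: float


def _crossing(t: np.ndarray, p: np.ndarray, threshold: float) -> float | None:
    idx = np.nonzero(p >= threshold)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0 or p[i - 1] <= 0.0:
        return float(t[i])
    # log-log interpolation between the bracketing grid points
    lt0, lt1 = math.log(t[i - 1]), math.log(t[i])
    lp0, lp1 = math.log(p[i - 1]), math.log(p[i])
    if lp1 == lp0:
        return float(t[i])
    frac = (math.log(threshold) - lp0) / (lp1 - lp0)
    return float(math.exp(lt0 + frac * (lt1 - lt0)))


def time_to_RI(
    curve: DMICurve,
    M: float = 1e5,
    first_passage: np.ndarray | None = None,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> TStarResult:
    """First crossing time of P_I(t) = 1/M, with a bootstrap CI when times are given.

    Returns ``reached=False`` (and no extrapolation) if the curve never
    reaches the threshold within its horizon.  The bootstrap resamples the
    per-replicate first-passage counts multinomially over the grid bins.
    """
    threshold = 1.0 / M
    t_star = _crossing(curve.t, curve.p, threshold)
    if t_star is None:
        return TStarResult(t_star=None, ci=None, reached=False, threshold=threshold, M=M)
    ci = None
    if first_passage is not None and n_boot > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        n = curve.n_replicates
        times = np.asarray(first_passage, dtype=float)
        finite = times[np.isfinite(times)]
        # bin at grid resolution: counts in (-inf, t_0], (t_0, t_1], ..., censored
        binned = np.searchsorted(curve.t, finite, side="left")
        cnt = np.bincount(np.minimum(binned, curve.t.size - 1), minlength=curve.t.size)
        cnt = np.append(cnt, n - finite.size)
        draws = rng.multinomial(n, cnt / n, size=n_boot)
        stars = []
        for d in draws:
            cum = np.cumsum(d[: curve.t.size]) / n
            c = _crossing(curve.t, cum, threshold)
            if c is not None:
                stars.append(c)
        if len(stars) >= max(2, n_boot // 2):
            ci = (float(np.percentile(stars, 2.5)), float(np.percentile(stars, 97.5)))
    return TStarResult(t_star=t_star, ci=ci, reached=True, threshold=threshold, M=M)


def dmi_curve(
    n_pairs: int,
    t_max: float,
    m: BindingModel,
    s: SelectionParams,
    rng: np.random.Generator,
    grid: np.ndarray | None = None,
    **kwargs,
) -> tuple[DMICurve, BulkResult]:
    """Convenience wrapper: bulk simulation + P_I estimation on a log grid."""
    if grid is None:
        grid = log_grid(t_max)
    res = simulate_pairs(n_pairs, t_max, m, s, rng, **kwargs)
    curve = estimate_PI(res.first_passage, grid, n=n_pairs, t_max=t_max)
    curve.params = {
        "ell": m.ell, "delta_eps": m.delta_eps, "delta_eps_ns": m.delta_eps_ns,
        "r_star": m.r_star, "kappa_F": s.kappa_F, "Ne": s.Ne, "mu0": s.mu0,
        "scaled_size": s.scaled_size, "n_replicates": n_pairs, "t_max": t_max,
    }
    return curve, res


# --------------------------------------------------------------------------
# trajectory statistics and diagnostics

def hybrid_energy_stats(records: list[DMIRecord], grid: np.ndarray, m: BindingModel) -> dict[str, np.ndarray]:
    """Mean and variance of hybrid binding energies versus time.

    Evaluates each recorded step-function trajectory on ``grid`` and returns
    per-grid-point statistics of max(dG12, dG21) and of each hybrid pairing.
    """
    if not records or any(rec.trajectory is None for rec in records):
        raise ValueError("hybrid trajectories were not recorded")
    grid = np.asarray(grid, dtype=float)
    g12 = np.empty((len(records), grid.size))
    g21 = np.empty((len(records), grid.size))
    for i, rec in enumerate(records):
        tr = np.asarray(rec.trajectory, dtype=float)
        idx = np.searchsorted(tr[:, 0], grid, side="right") - 1
        idx = np.clip(idx, 0, tr.shape[0] - 1)
        g12[i] = m.delta_eps * tr[idx, 1]
        g21[i] = m.delta_eps * tr[idx, 2]
    gmax = np.maximum(g12, g21)
    return {
        "t": grid,
        "mean_dG_max": gmax.mean(axis=0), "var_dG_max": gmax.var(axis=0, ddof=1),
        "mean_dG12": g12.mean(axis=0), "var_dG12": g12.var(axis=0, ddof=1),
        "mean_dG21": g21.mean(axis=0), "var_dG21": g21.var(axis=0, ddof=1),
    }


def _curve_points(curve: DMICurve, min_events: int = 10, max_p: float = 0.05):
    keep = (curve.n_events >= min_events) & (curve.p < max_p) & (curve.p > 0)
    # drop duplicated plateau points (same event count) to de-correlate
    ev = curve.n_events[keep]
    first = np.ones(ev.size, dtype=bool)
    first[1:] = ev[1:] != ev[:-1]
    t = curve.t[keep][first]
    p = curve.p[keep][first]
    w = ev[first].astype(float)
    return t, p, w


def early_slope(curve: DMICurve, min_events: int = 10, max_p: float = 0.05) -> float:
    """Weighted least-squares slope of log P_I vs log t over the early regime.

    Uses grid points with at least ``min_events`` DMI events and P_I below
    ``max_p`` (weights proportional to event counts).  A quadratic early
    regime returns a slope near 2.
    """
    t, p, w = _curve_points(curve, min_events, max_p)
    if t.size < 3:
        raise ValueError("too few informative points for a slope estimate")
    coeff = np.polyfit(np.log(t), np.log(p), 1, w=np.sqrt(w))
    return float(coeff[0])


def loglog_curvature(curve: DMICurve, min_events: int = 10, max_p: float = 0.5) -> tuple[float, float]:
    """Quadratic coefficient (and its standard error) of log P_I vs log t.

    A single power law gives zero curvature; the delayed large-population
    regime shows significantly negative curvature.
    """
    t, p, w = _curve_points(curve, min_events, max_p)
    if t.size < 5:
        raise ValueError("too few informative points for a curvature estimate")
    coeff, cov = np.polyfit(np.log(t), np.log(p), 2, w=np.sqrt(w), cov=True)
    return float(coeff[0]), float(math.sqrt(cov[0, 0]))


# --------------------------------------------------------------------------
# minimum substitutions to a DMI

def min_substitutions_to_DMI(m: BindingModel, max_depth: int = 3) -> int | None:
    """Smallest number of accepted substitutions (across both lineages) yielding a DMI.

    Exhaustive iterative-deepening search over all ordered, viability-
    respecting substitution histories of up to ``max_depth`` steps, from one
    canonical ancestor per viable mismatch class (sufficient by the position-
    permutation and alphabet-relabelling symmetry of the map).  Returns None
    if no DMI is reachable within ``max_depth`` steps.
    """
    ell, rs = m.ell, m.r_star
    if rs >= ell:
        return None  # no cliff, no DMI possible

    def dfs(P1, D1, P2, D2, remaining: int) -> bool:
        for lineage in (0, 1):
            P, D = (P1, D1) if lineage == 0 else (P2, D2)
            for locus_seq, partner in ((P, D), (D, P)):
                for pos in range(ell):
                    old = locus_seq[pos]
                    for letter in range(4):
                        if letter == old:
                            continue
                        locus_seq[pos] = letter
                        r = sum(a != b for a, b in zip(P, D))
                        if r <= rs:
                            h12 = sum(a != b for a, b in zip(P1, D2))
                            h21 = sum(a != b for a, b in zip(P2, D1))
                            if h12 > rs or h21 > rs:
                                locus_seq[pos] = old
                                return True
                            if remaining > 1 and dfs(P1, D1, P2, D2, remaining - 1):
                                locus_seq[pos] = old
                                return True
                        locus_seq[pos] = old
        return False

    for depth in range(1, max_depth + 1):
        for r0 in range(rs + 1):
            P = [0] * ell
            D = [1] * r0 + [0] * (ell - r0)
            if dfs(P, D, list(P), list(D), depth):
                return depth
    return None
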