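"""Origin-fixation Gillespie engine for a single monomorphic lineage.

In the weak-mutation regime the population is a single fixed (protein, dna)
sequence pair.  Each step computes the fixation rates of all 6*ell one-step
mutants (3 alternative letters x 2 loci x ell positions), picks one in
proportion to its rate, and advances time by an Exp(K) waiting time where K
is the total rate.  Time is measured in units of mu0*t (set mu0=1 to work in
these units directly).

Because fitness depends on sequences only through the mismatch count r, the
6*ell rates take at most three distinct values (restore / preserve / break a
match); :func:`class_rate_summary` exposes this O(1) bookkeeping, and
:func:`mutant_rates` the explicit per-mutant table.  The r-marginal of the
process is itself a birth-death chain, built by :func:`lumped_r_chain_rates`,
whose stationary vector reproduces the analytic equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotype import ALPHABET, BindingModel, TFGenotype, array_to_seq, seq_to_array
from .landscape import SelectionParams, class_rates

__all__ = [
    "CENSORED",
    "LineageState",
    "SubstitutionEvent",
    "mutant_rates",
    "class_rate_summary",
    "gillespie_step",
    "evolve_until",
    "lumped_r_chain_rates",
    "stationary_of_generator",
]


class _Censored:
    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "CENSORED"


CENSORED = _Censored()

_LOCI = ("protein", "dna")


@dataclass
class LineageState:
    """Currently fixed genotype of one lineage, with its clock and counters."""

    protein: np.ndarray
    dna: np.ndarray
    time: float = 0.0
    n_substitutions: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))

    @classmethod
    def from_genotype(cls, g: TFGenotype, time: float = 0.0) -> "LineageState":
        return cls(protein=seq_to_array(g.protein), dna=seq_to_array(g.dna), time=time)

    def to_genotype(self) -> TFGenotype:
        return TFGenotype(array_to_seq(self.protein), array_to_seq(self.dna))

    def copy(self) -> "LineageState":
        return LineageState(
            protein=self.protein.copy(),
            dna=self.dna.copy(),
            time=self.time,
            n_substitutions=self.n_substitutions.copy(),
        )

    @property
    def r(self) -> int:
        return int(np.count_nonzero(self.protein != self.dna))


@dataclass(frozen=True)
class SubstitutionEvent:
    time: float
    locus: str  # "protein" | "dna"
    position: int
    from_letter: str
    to_letter: str
    r_before: int
    r_after: int


def class_rate_summary(
    state: LineageState, m: BindingModel, s: SelectionParams, form: str = "full"
) -> dict[str, float]:
    """Constant-size summary of the mutant rate table for the current class r."""
    r = state.r
    rates = class_rates(m, s, form)
    k_down = float(rates["k_down"][r]) if r > 0 else 0.0
    k_up = float(rates["k_up"][r])
    k_same = float(rates["k_same"])
    return {
        "r": r,
        "k_down": k_down,
        "k_same": k_same,
        "k_up": k_up,
        "n_down": 2 * r,
        "n_same": 4 * r,
        "n_up": 6 * (m.ell - r),
        "K": 2 * r * k_down + 4 * r * k_same + 6 * (m.ell - r) * k_up,
    }


def mutant_rates(
    state: LineageState, m: BindingModel, s: SelectionParams, form: str = "full"
) -> np.ndarray:
    """Fixation rates of all 6*ell one-step mutants, recomputed from scratch.

    Index layout: locus-major (protein then dna), then position, then the 3
    alternative letters in ascending alphabet order:
    ``idx = locus*3*ell + pos*3 + k``.  Entries whose target class exceeds r*
    are exactly zero.
    """
    summary = class_rate_summary(state, m, s, form)
    ell = m.ell
    rates = np.empty(6 * ell)
    seqs = (state.protein, state.dna)
    for locus in (0, 1):
        seq, partner = seqs[locus], seqs[1 - locus]
        for pos in range(ell):
            cur, par = int(seq[pos]), int(partner[pos])
            base = locus * 3 * ell + pos * 3
            k = 0
            for letter in range(4):
                if letter == cur:
                    continue
                if cur == par:
                    rate = summary["k_up"]
                elif letter == par:
                    rate = summary["k_down"]
                else:
                    rate = summary["k_same"]
                rates[base + k] = rate
                k += 1
    return rates


def _decode_index(idx: int, state: LineageState, ell: int) -> tuple[int, int, int]:
    """Map a rate-table index back to (locus, position, new_letter_code)."""
    locus, rem = divmod(idx, 3 * ell)
    pos, k = divmod(rem, 3)
    cur = int((state.protein if locus == 0 else state.dna)[pos])
    letters = [c for c in range(4) if c != cur]
    return locus, pos, letters[k]


def gillespie_step(
    state: LineageState,
    m: BindingModel,
    s: SelectionParams,
    rng: np.random.Generator,
    t_horizon: float = math.inf,
    form: str = "full",
):
    """Advance the lineage by one substitution (or censor at the horizon).

    Draws the waiting time as -ln(u)/K with u uniform on (0,1) (exponential
    with rate K), picks a mutant with probability rate/K, applies it in place
    and returns the :class:`SubstitutionEvent`.  If K = 0 (every mutant
    inviable) or the waiting time overshoots ``t_horizon``, time is advanced
    to the horizon and :data:`CENSORED` is returned.
    """
    rates = mutant_rates(state, m, s, form)
    K = float(rates.sum())
    if K <= 0.0:
        state.time = min(t_horizon, math.inf)
        return CENSORED
    dt = rng.standard_exponential() / K
    if state.time + dt > t_horizon:
        state.time = t_horizon
        return CENSORED
    state.time += dt
    cum = np.cumsum(rates)
    idx = int(np.searchsorted(cum, rng.random() * K, side="right"))
    idx = min(idx, rates.size - 1)
    locus, pos, letter = _decode_index(idx, state, m.ell)
    seq = state.protein if locus == 0 else state.dna
    r_before = state.r
    from_letter = ALPHABET[int(seq[pos])]
    seq[pos] = letter
    r_after = state.r
    if r_after > m.r_star:  # pragma: no cover - guarded by zero rates
        raise RuntimeError("lineage stepped beyond the viability cliff")
    state.n_substitutions[locus] += 1
    return SubstitutionEvent(
        time=state.time,
        locus=_LOCI[locus],
        position=pos,
        from_letter=from_letter,
        to_letter=ALPHABET[letter],
        r_before=r_before,
        r_after=r_after,
    )


def evolve_until(
    state: LineageState,
    t_end: float,
    m: BindingModel,
    s: SelectionParams,
    rng: np.random.Generator,
    form: str = "full",
) -> list[SubstitutionEvent]:
    """Run the lineage to time ``t_end``; returns the substitution trajectory."""
    if t_end < state.time:
        raise ValueError("t_end precedes the current lineage time")
    events: list[SubstitutionEvent] = []
    while True:
        ev = gillespie_step(state, m, s, rng, t_horizon=t_end, form=form)
        if ev is CENSORED:
            break
        events.append(ev)
    return events


def lumped_r_chain_rates(m: BindingModel, s: SelectionParams, form: str = "full") -> np.ndarray:
    """Generator matrix of the exact r-marginal birth-death chain on {0..r*}.

    Up-rate 6(ell-r) * k_up(r), down-rate 2r * k_down(r); within-class moves
    do not change r and so do not enter the generator.
    """
    rates = class_rates(m, s, form)
    rs = m.r_star
    Q = np.zeros((rs + 1, rs + 1))
    for r in range(rs + 1):
        if r < rs:
            Q[r, r + 1] = 6 * (m.ell - r) * rates["k_up"][r]
        if r > 0:
            Q[r, r - 1] = 2 * r * rates["k_down"][r]
        Q[r, r] = -Q[r].sum()
    return Q


def stationary_of_generator(Q: np.ndarray) -> np.ndarray:
    """Stationary probability vector of a CTMC generator (rows sum to zero)."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
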