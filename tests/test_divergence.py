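"""Allopatric divergence: ancestors, hybrids, DMI detection, P_I, t*."""

import itertools
import math

import numpy as np
import pytest

from tfdmi import (
    BindingModel,
    SelectionParams,
    TFGenotype,
    equilibrium_distribution,
    hybrid_state,
    min_substitutions_to_DMI,
    prob_RI,
    random_genotype_at_distance,
    run_replicate,
    sample_ancestor,
    simulate_pairs,
    time_to_RI,
)
from tfdmi.divergence import DMICurve, estimate_PI, hybrid_energy_stats, log_grid
from tfdmi.oracles import exact_PI_curve


def scaled(size, Ne=1000.0):
    return SelectionParams.from_scaled(size, Ne=Ne)


class TestAncestorSampling:
    def test_equilibrium_mean_matches_analytic(self, model10, rng):
        s = scaled(0.04)
        res = simulate_pairs(20_000, 0.0, model10, s, rng)
        mean_expected = equilibrium_distribution(model10, s).mean_r
        se = res.r0.std(ddof=1) / np.sqrt(res.r0.size)
        assert abs(res.r0.mean() - mean_expected) < 3 * se

    def test_large_population_mode_at_optimum(self, model10, rng):
        s = scaled(40.0)
        draws = [sample_ancestor(model10, s, "equilibrium", rng).r0 for _ in range(300)]
        assert np.bincount(draws).argmax() == 0

    def test_fixed_r_is_deterministic(self, model10, rng):
        s = scaled(0.04)
        r0s = {sample_ancestor(model10, s, "fixed-r", rng).r0 for _ in range(10)}
        assert len(r0s) == 1

    def test_user_ancestor_viability_enforced(self, model10, rng):
        bad = random_genotype_at_distance(7, model10, rng)
        with pytest.raises(ValueError):
            sample_ancestor(model10, scaled(0.04), "user", genotype=bad)


class TestWorkedExample:
    """Compensatory divergence of an ell=5 pair with one ancestral mismatch."""

    M5 = BindingModel(ell=5)

    def test_hybrids_gain_mismatches(self):
        anc = TFGenotype("ATCGC", "ATAGC")
        g1 = TFGenotype("TTAGC", "ATAGC")  # two protein substitutions
        g2 = TFGenotype("ATCGA", "ATCGC")  # two dna substitutions
        assert anc.mismatches == g1.mismatches == g2.mismatches == 1
        hs = hybrid_state(g1, g2, self.M5)
        assert (hs.h12, hs.h21) == (2, 2)
        assert hs.dG12 == hs.dG21 == 6.0
        # no DMI as long as the threshold admits two mismatches
        assert hs.h12 <= BindingModel(ell=5, r_star_override=2).r_star

    def test_replayed_in_replicate_runner(self, rng):
        anc = TFGenotype("ATCGC", "ATAGC")
        rec = run_replicate(anc, 0.0, self.M5, scaled(0.04), rng)
        assert rec.censored and rec.trajectory is None
        assert rec.r0 == 1


class TestRunReplicate:
    def test_zero_horizon_censors(self, model10, rng):
        anc = sample_ancestor(model10, scaled(0.04), "equilibrium", rng)
        rec = run_replicate(anc, 0.0, model10, scaled(0.04), rng, record_hybrids=True)
        assert rec.censored
        assert rec.trajectory == [(0.0, anc.r0, anc.r0)]

    def test_hybrid_steps_bounded_and_first_passage_consistent(self, model10, rng):
        s = scaled(0.04)
        for _ in range(20):
            anc = sample_ancestor(model10, s, "equilibrium", rng)
            rec = run_replicate(anc, 5.0, model10, s, rng, record_hybrids=True)
            tr = np.asarray(rec.trajectory)
            assert (np.abs(np.diff(tr[:, 1])) <= 1).all()
            assert (np.abs(np.diff(tr[:, 2])) <= 1).all()
            if not rec.censored:
                assert max(tr[-1, 1], tr[-1, 2]) == model10.r_star + 1
                assert rec.first_passage_time == tr[-1, 0]
                assert rec.which_hybrid in ("12", "21", "both")
                assert rec.substitutions_at_dmi >= 2

    def test_monte_carlo_matches_exact_chain(self, rng):
        # ell=2 joint two-lineage chain: bulk engine vs matrix-exponential oracle
        m = BindingModel(ell=2)
        s = scaled(0.4)
        n = 10_000
        res = simulate_pairs(n, 5.0, m, s, rng, r0=1)
        grid = np.geomspace(0.05, 5.0, 20)
        mc = estimate_PI(res.first_passage, grid, n=n, t_max=5.0)
        exact = exact_PI_curve(m, s, r0=1, grid=grid)
        # exact binomial envelopes, family-wise 99% across the grid
        from scipy.stats import binom

        alpha = 0.01 / (2 * grid.size)
        counts = mc.p * n
        assert (counts >= binom.ppf(alpha, n, exact)).all()
        assert (counts <= binom.isf(alpha, n, exact)).all()


class TestEstimatePI:
    def test_all_censored_is_zero(self):
        curve = estimate_PI(np.full(50, np.inf), np.array([0.1, 1.0]), t_max=1.0)
        assert (curve.p == 0).all() and (curve.n_events == 0).all()

    def test_step_function(self):
        curve = estimate_PI(np.ones(10), np.array([0.5, 1.0, 2.0]), t_max=2.0)
        np.testing.assert_array_equal(curve.p, [0.0, 1.0, 1.0])

    def test_monotone_and_bounded(self, model10, rng):
        res = simulate_pairs(2000, 1.0, model10, scaled(0.04), rng)
        curve = estimate_PI(res.first_passage, log_grid(1.0), n=2000, t_max=1.0)
        assert (np.diff(curve.p) >= 0).all()
        assert (curve.ci_lo <= curve.p).all() and (curve.p <= curve.ci_hi).all()

    def test_grid_beyond_horizon_rejected(self):
        with pytest.raises(ValueError):
            estimate_PI(np.ones(5), np.array([0.5, 3.0]), t_max=1.0)

    def test_mixed_parameters_rejected(self, model10, rng):
        s1, s2 = scaled(0.04), scaled(4.0)
        anc = sample_ancestor(model10, s1, "equilibrium", rng)
        r1 = run_replicate(anc, 0.5, model10, s1, rng)
        r2 = run_replicate(anc, 0.5, model10, s2, rng)
        with pytest.raises(ValueError):
            estimate_PI([r1, r2], np.array([0.1]))


class TestProbRI:
    def test_endpoints(self):
        assert prob_RI(np.array([0.0]), M=1e5)[0] == 0.0
        assert prob_RI(np.array([1.0]), M=1e5)[0] == 1.0

    def test_threshold_value(self):
        # P_I = 1/M: P_RI = 1-(1-1e-5)^1e5 ~ 1 - 1/e
        val = prob_RI(np.array([1e-5]), M=1e5)[0]
        assert val == pytest.approx(1 - (1 - 1e-5) ** 1e5, rel=1e-10)
        assert val == pytest.approx(0.632, abs=2e-3)

    def test_short_time_form(self):
        p = np.array([1e-7, 1e-6])
        np.testing.assert_allclose(
            prob_RI(p, M=1e5, short_time=True), -np.expm1(-1e5 * p), rtol=1e-12
        )


class TestTimeToRI:
    def synthetic_quadratic(self):
        t = np.geomspace(1e-4, 1e-1, 200)
        return DMICurve(t=t, p=t**2, ci_lo=t**2, ci_hi=t**2,
                        n_events=np.full(t.size, 1000), n_replicates=10**6)

    def test_closed_form_crossing(self):
        ts = time_to_RI(self.synthetic_quadratic(), M=1e5)
        assert ts.reached
        assert ts.t_star == pytest.approx(math.sqrt(1e-5), rel=1e-3)

    def test_monotone_in_M(self):
        curve = self.synthetic_quadratic()
        stars = [time_to_RI(curve, M=M).t_star for M in (1e3, 1e4, 1e5)]
        assert stars[0] > stars[1] > stars[2]

    def test_no_crossing_is_explicit(self):
        t = np.array([0.1, 1.0])
        curve = DMICurve(t=t, p=np.zeros(2), ci_lo=np.zeros(2), ci_hi=np.zeros(2),
                         n_events=np.zeros(2, dtype=int), n_replicates=100)
        ts = time_to_RI(curve, M=1e5)
        assert not ts.reached and ts.t_star is None


class TestHybridEnergyStats:
    def test_fixed_ancestor_has_zero_initial_variance(self, model10, rng):
        s = scaled(20.0)
        g = random_genotype_at_distance(1, model10, rng)
        recs = [run_replicate(g, 5.0, model10, s, rng, mode="instantaneous")
                for _ in range(30)]
        stats = hybrid_energy_stats(recs, np.array([0.0, 5.0]), model10)
        assert stats["var_dG_max"][0] == 0.0

    def test_variance_grows_linearly_at_large_N(self, model10):
        rng = np.random.default_rng(77)
        s = scaled(20.0)
        recs = [run_replicate(sample_ancestor(model10, s, "equilibrium", rng),
                              40.0, model10, s, rng, mode="instantaneous")
                for _ in range(300)]
        grid = np.linspace(2.0, 40.0, 15)
        v = hybrid_energy_stats(recs, grid, model10)["var_dG_max"]
        A = np.vstack([grid, np.ones_like(grid)]).T
        coef, *_ = np.linalg.lstsq(A, v, rcond=None)
        r2 = 1 - ((v - A @ coef) ** 2).sum() / ((v - v.mean()) ** 2).sum()
        assert coef[0] > 0 and r2 > 0.95


class TestMinSubstitutionsToDMI:
    def test_default_model_needs_two(self, model10):
        assert min_substitutions_to_DMI(model10) == 2

    @pytest.mark.parametrize("ell", [2, 3, 10])
    def test_never_below_two(self, ell):
        # one substitution leaves each hybrid equal to a parent or the ancestor
        assert min_substitutions_to_DMI(BindingModel(ell=ell)) >= 2

    def test_no_cliff_no_dmi(self):
        assert min_substitutions_to_DMI(BindingModel(ell=4, r_star_override=4)) is None

    def test_matches_independent_enumeration_ell2(self):
        # brute force over explicit genotype states, no symmetry shortcut
        m = BindingModel(ell=2)
        rs = m.r_star
        letters = "ACGT"
        seqs = ["".join(p) for p in itertools.product(letters, repeat=2)]
        ancestors = [TFGenotype(p, d) for p in seqs for d in seqs
                     if TFGenotype(p, d).mismatches <= rs]

        def moves(g):
            for locus in (0, 1):
                seq = g.protein if locus == 0 else g.dna
                for pos in range(2):
                    for c in letters:
                        if c == seq[pos]:
                            continue
                        new = seq[:pos] + c + seq[pos + 1:]
                        cand = TFGenotype(new, g.dna) if locus == 0 else TFGenotype(g.protein, new)
                        if cand.mismatches <= rs:
                            yield cand

        def dmi(g1, g2):
            hs = hybrid_state(g1, g2, m)
            return hs.h12 > rs or hs.h21 > rs

        best = None
        for anc in ancestors:
            frontier = {(anc.protein, anc.dna, anc.protein, anc.dna)}
            for depth in range(1, 3):
                nxt = set()
                for p1, d1, p2, d2 in frontier:
                    g1, g2 = TFGenotype(p1, d1), TFGenotype(p2, d2)
                    for cand in moves(g1):
                        if dmi(cand, g2):
                            best = depth if best is None else min(best, depth)
                        nxt.add((cand.protein, cand.dna, p2, d2))
                    for cand in moves(g2):
                        if dmi(g1, cand):
                            best = depth if best is None else min(best, depth)
                        nxt.add((p1, d1, cand.protein, cand.dna))
                if best is not None and best <= depth:
                    break
                frontier = nxt
            if best == 1:
                break
        assert best == min_substitutions_to_DMI(m) == 2
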