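"""FSP solver: generator structure, oracle equivalence, diagnostics."""

import numpy as np
import pytest
import scipy.linalg
import scipy.stats

from fspburst import fsp
from fspburst.models import (
    Condition,
    GeneModel,
    GeneRateParams,
    GeneTopology,
    InhibitorMap,
    SignalParams,
)

from conftest import constitutive_model, tv_distance


def _rates(topology, params):
    return {
        "edges": {e: params.k[e] for e in topology.edges},
        "alpha": {i: params.alpha[i] for i in range(topology.n_states)},
        "delta": params.delta,
    }


@pytest.fixture(scope="module")
def small_gene():
    """3-state gene with O(10) copy numbers; dim 93 at max_count=30."""
    top = GeneTopology(3, (1, 2), "enhance")
    params = GeneRateParams(
        k={(0, 1): 2e-3, (1, 0): 1e-3, (1, 2): 5e-4, (2, 1): 2e-3},
        b=5e-3,
        alpha=(1e-4, 2e-3, 8e-3),
        delta=1e-3,
    )
    return GeneModel(topology=top, params=params)


class TestGenerator:
    def test_columns_sum_nonpositive_with_boundary_deficit(self, small_gene):
        space = fsp.StateSpace(3, 30)
        A = fsp.build_generator(small_gene.topology,
                                _rates(small_gene.topology, small_gene.params),
                                space)
        col = np.asarray(A.sum(axis=0)).ravel()
        assert np.all(col <= 1e-14)
        # deficit only where transcription leaves the top bin
        for g in range(3):
            j = space.index(g, 30)
            assert col[j] == pytest.approx(-small_gene.params.alpha[g])
        off = A.toarray().copy()
        np.fill_diagonal(off, 0.0)
        assert off.min() >= 0.0

    def test_columns_sum_zero_without_transcription(self):
        top = GeneTopology(2, (0, 1), "enhance")
        params = GeneRateParams(k={(0, 1): 1e-3, (1, 0): 2e-3}, b=0.0,
                                alpha=(0.0, 0.0), delta=1e-3)
        A = fsp.build_generator(top, _rates(top, params), fsp.StateSpace(2, 5))
        assert np.allclose(np.asarray(A.sum(axis=0)).ravel(), 0.0)

    def test_negative_rate_rejected(self, small_gene):
        rates = _rates(small_gene.topology, small_gene.params)
        rates["delta"] = -1.0
        with pytest.raises(ValueError):
            fsp.build_generator(small_gene.topology, rates, fsp.StateSpace(3, 5))

    def test_frozen_generator_matches_matrix_exponential(self, small_gene):
        """With the signal switched off, FSP equals expm(A t) p0 (dense oracle)."""
        gm = small_gene
        frozen = GeneRateParams(k=gm.params.k, b=0.0, alpha=gm.params.alpha,
                                delta=gm.params.delta)
        space = fsp.StateSpace(3, 30)
        times = np.array([0.0, 200.0, 1000.0, 3000.0])
        p0 = np.zeros(space.dim)
        p0[space.index(0, 0)] = 1.0
        sol = fsp.fsp_solve(gm.topology, frozen, None, "none",
                            SignalParams(1e-3, 1e-3), times, init=p0,
                            max_count=30, tol=1e-6, rtol=1e-10, atol=1e-14)
        A = fsp.build_generator(gm.topology, _rates(gm.topology, frozen),
                                space).toarray()
        # truncation sink appended to make the oracle conservative too
        Aaug = np.zeros((space.dim + 1, space.dim + 1))
        Aaug[:space.dim, :space.dim] = A
        Aaug[space.dim, :space.dim] = -A.sum(axis=0)
        for t, p_fsp, sink in zip(times, sol.prob, sol.sink_mass):
            oracle = scipy.linalg.expm(Aaug * t) @ np.r_[p0, 0.0]
            assert tv_distance(p_fsp.ravel(), oracle[:-1]) < 1e-6
            assert sink == pytest.approx(oracle[-1], abs=1e-9)


class TestStationary:
    def test_constitutive_limit_is_poisson(self):
        gm = constitutive_model(alpha=1e-2, delta=1e-4)  # alpha/delta = 100
        pi = fsp.stationary_distribution(gm.topology, gm.params, max_count=300)
        marg = pi.reshape(2, 301).sum(axis=0)
        ref = scipy.stats.poisson.pmf(np.arange(301), 100.0)
        assert tv_distance(marg, ref) < 1e-6

    def test_gene_state_marginal_matches_birth_death_ratios(self, cm1):
        """Detailed balance: pi_{i+1}/pi_i = k_{i,i+1}/k_{i+1,i} at s=0."""
        g = cm1.genes["tnfa"]
        pi = fsp.stationary_distribution(g.topology, g.params, g.inhibitors,
                                         "none", max_count=1500)
        states = pi.reshape(3, 1501).sum(axis=1)
        k = g.params.k
        ref = np.array([1.0, k[(0, 1)] / k[(1, 0)],
                        (k[(0, 1)] / k[(1, 0)]) * (k[(1, 2)] / k[(2, 1)])])
        ref /= ref.sum()
        assert states == pytest.approx(ref, abs=1e-6)
        assert states == pytest.approx([0.9921, 0.0026, 0.0053], abs=2e-4)

    def test_stationary_mean_matches_first_moment_identity(self, cm1):
        """E[x] = sum_i alpha_i pi_i / delta ~ 19.6 for TNF-a, no drug."""
        g = cm1.genes["tnfa"]
        pi = fsp.stationary_distribution(g.topology, g.params, g.inhibitors,
                                         "none", max_count=1500)
        pim = pi.reshape(3, 1501)
        mean = float(pim.sum(axis=0) @ np.arange(1501))
        states = pim.sum(axis=1)
        expected = float(np.dot(g.params.alpha, states)) / g.params.delta
        assert mean == pytest.approx(expected, rel=1e-6)
        assert mean == pytest.approx(19.6, abs=0.1)

    def test_degenerate_chain_rejected(self):
        top = GeneTopology(2, (0, 1), "enhance")
        params = GeneRateParams(k={(0, 1): 0.0, (1, 0): 0.0}, b=0.0,
                                alpha=(0.0, 0.0), delta=1e-3)
        with pytest.raises(ValueError):
            fsp.stationary_distribution(top, params, max_count=5)


class TestSolve:
    def test_zero_transcription_keeps_mrna_at_zero(self, small_gene):
        gm = small_gene
        silent = GeneRateParams(k=gm.params.k, b=gm.params.b,
                                alpha=(0.0, 0.0, 0.0), delta=gm.params.delta)
        space = fsp.StateSpace(3, 10)
        p0 = np.zeros(space.dim)
        p0[space.index(0, 0)] = 1.0
        sol = fsp.fsp_solve(gm.topology, silent, None, "none",
                            SignalParams(1e-3, 1e-3),
                            [0.0, 500.0, 2000.0], init=p0, max_count=10)
        marg = fsp.marginal_mrna(sol)
        assert marg[:, 0] == pytest.approx(1.0, abs=1e-8)
        assert np.all(sol.sink_mass <= 1e-12)

    def test_constitutive_transient_is_poisson_immigration_death(self):
        """Mean 100(1-e^{-delta t}) and Poisson law at every time (closed form)."""
        gm = constitutive_model(alpha=1e-2, delta=1e-4)
        space = fsp.StateSpace(2, 300)
        p0 = np.zeros(space.dim)
        p0[space.index(0, 0)] = 1.0
        times = np.array([0.0, 3000.0, 10000.0, 30000.0])
        sol = fsp.fsp_solve(gm.topology, gm.params, None, "none",
                            SignalParams(1e-3, 1e-3), times, init=p0,
                            max_count=300, tol=1e-8, rtol=1e-10, atol=1e-14)
        mean, _ = fsp.moments(sol)
        lam = 100.0 * (1.0 - np.exp(-1e-4 * times))
        assert mean == pytest.approx(lam, abs=1e-4)
        marg = fsp.marginal_mrna(sol)
        for ti in range(len(times)):
            ref = scipy.stats.poisson.pmf(np.arange(301), lam[ti])
            assert tv_distance(marg[ti], ref) < 1e-6

    def test_probability_conservation_and_sink_monotonicity(self, cm1_scaled):
        sol = fsp.solve_gene(cm1_scaled, "tnfa", "none",
                             [0.0, 1800.0, 3600.0, 7200.0, 14400.0],
                             max_count=64, tol=1e-2)
        totals = sol.prob.sum(axis=(1, 2)) + sol.sink_mass
        assert totals == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(sol.sink_mass) >= -1e-12)
        assert sol.sink_mass[-1] <= 1e-2

    def test_adaptive_expansion_until_sink_below_tol(self, cm1_scaled):
        sol = fsp.solve_gene(cm1_scaled, "tnfa", "none", [0.0, 3600.0],
                             max_count=8, tol=1e-6)
        assert sol.expansions >= 1
        assert sol.space.max_count > 8
        assert sol.sink_mass[-1] <= 1e-6

    def test_truncation_failure_reports_achieved_bound(self, cm1_scaled):
        with pytest.raises(fsp.FSPTruncationError) as err:
            fsp.solve_gene(cm1_scaled, "tnfa", "none", [0.0, 3600.0],
                           max_count=4, max_count_ceiling=8, tol=1e-9)
        assert err.value.achieved > 1e-9

    def test_invalid_times_rejected(self, small_gene):
        gm = small_gene
        with pytest.raises(ValueError):
            fsp.fsp_solve(gm.topology, gm.params, None, "none",
                          SignalParams(1e-3, 1e-3), [100.0, 200.0], max_count=10)


class TestDiagnostics:
    def test_point_mass_marginals_and_moments(self, small_gene):
        space = fsp.StateSpace(3, 10)
        prob = np.zeros((1, 3, 11))
        prob[0, 1, 5] = 1.0
        sol = fsp.FSPSolution(times=np.array([0.0]), prob=prob,
                              sink_mass=np.zeros(1), space=space,
                              alpha=(0.0, 0.0, 1.0), tol=1e-4)
        marg = fsp.marginal_mrna(sol)
        assert marg[0, 5] == 1.0 and marg.sum() == 1.0
        occ = fsp.state_occupancy(sol)
        assert occ[0] == pytest.approx([0.0, 1.0, 0.0])
        mean, sd = fsp.moments(sol)
        assert mean[0] == 5.0 and sd[0] == 0.0
        # alpha = (0,0,1): mean transcription rate equals P(G2)
        assert fsp.mean_transcription_rate(sol)[0] == occ[0, 2]

    def test_initial_occupancy_equals_stationary_marginal(self, cm1_scaled):
        g = cm1_scaled.genes["tnfa"]
        sol = fsp.solve_gene(cm1_scaled, "tnfa", "none", [0.0, 600.0],
                             max_count=64, tol=1e-2)
        pi = fsp.stationary_distribution(g.topology, g.params, g.inhibitors,
                                         "none", max_count=64)
        assert fsp.state_occupancy(sol)[0] == pytest.approx(
            pi.reshape(3, 65).sum(axis=1), abs=1e-9)

    def test_tsv_export_roundtrip(self, cm1_scaled, tmp_path):
        sol = fsp.solve_gene(cm1_scaled, "tnfa", "none", [0.0, 600.0],
                             max_count=64, tol=1e-2)
        path = tmp_path / "sol.tsv"
        sol.to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "time_s\tstate_or_count\tprobability"
        assert len(lines) == 1 + 2 * (3 + 65)
        sol.diagnostics_json(tmp_path / "diag.json")
        assert (tmp_path / "diag.json").stat().st_size > 0
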