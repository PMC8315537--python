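"""Admixture Gibbs sampler, model-order selection and diversity statistics."""

import numpy as np
import pandas as pd
import pytest

from dartpop import (
    McmcConfig,
    SimConfig,
    align_clusters,
    assign_membership,
    estimate_LK,
    evanno_deltaK,
    expected_heterozygosity,
    generate_collection,
    net_nucleotide_distance,
    run_admixture,
)
from dartpop.markers import MISSING, MarkerMatrix


def _snp(grid, **kw):
    grid = np.asarray(grid, dtype=np.int8)
    kw.setdefault("marker_ids", [f"m{i}" for i in range(grid.shape[0])])
    kw.setdefault("sample_ids", [f"s{j}" for j in range(grid.shape[1])])
    return MarkerMatrix(platform="snp", scores=grid, **kw)


class TestSampler:
    def test_k1_q_is_exactly_one(self, rng):
        m = _snp(rng.integers(-1, 3, size=(40, 12)))
        res = run_admixture(m, 1, McmcConfig(burn_in=50, mcmc=100), seed=1)
        assert np.all(res.Q == 1.0)

    def test_k1_matches_closed_form_dirichlet_posterior(self, rng):
        """At K=1 the allele-frequency posterior is Beta(lambda + alt,
        lambda + ref) in closed form; the sampler's posterior means must
        agree within Monte-Carlo error."""
        grid = rng.integers(-1, 3, size=(50, 30))
        m = _snp(grid)
        lam = 1.0
        res = run_admixture(m, 1, McmcConfig(burn_in=500, mcmc=5000, lambda_=lam), seed=2)
        valid = grid != MISSING
        alt = np.where(valid, grid, 0).sum(axis=1)
        tot = 2 * valid.sum(axis=1)
        closed = (lam + alt) / (2 * lam + tot)
        assert np.abs(res.P[0] - closed).max() < 0.02

    def test_seeded_runs_bit_reproducible(self, rng):
        m = _snp(rng.integers(0, 3, size=(30, 10)))
        cfg = McmcConfig(burn_in=20, mcmc=40)
        a = run_admixture(m, 2, cfg, seed=7)
        b = run_admixture(m, 2, cfg, seed=7)
        assert np.array_equal(a.Q, b.Q) and np.array_equal(a.lnL_trace, b.lnL_trace)

    def test_q_rows_on_simplex(self, rng):
        m = _snp(rng.integers(-1, 3, size=(30, 15)))
        res = run_admixture(m, 3, McmcConfig(burn_in=30, mcmc=60), seed=3)
        assert np.allclose(res.Q.sum(axis=1), 1.0, atol=1e-8)
        assert res.P.min() >= 0 and res.P.max() <= 1

    def test_recovers_two_founder_ancestry(self):
        cfg = SimConfig(
            n_accessions=60, n_landrace=30, n_improved=15, n_snp=300, n_silico=50,
            clone_groups=(), n_replicates=1, alpha_admix=0.05, fst=0.3, seed=31,
        )
        snp, _, truth = generate_collection(cfg)
        m = snp.select_samples(truth.accession_ids)
        res = run_admixture(m, 2, McmcConfig(burn_in=400, mcmc=800), seed=5)
        perm = align_clusters(res.Q, truth.Q_true)
        assert np.abs(res.Q[:, perm] - truth.Q_true).mean() < 0.1

    def test_clone_pair_posteriors_agree(self, rng):
        col = rng.integers(0, 3, size=200).astype(np.int8)
        others = rng.integers(0, 3, size=(200, 20)).astype(np.int8)
        m = _snp(np.column_stack([col, col, others]))
        res = run_admixture(m, 2, McmcConfig(burn_in=300, mcmc=600), seed=9)
        assert np.abs(res.Q[0] - res.Q[1]).sum() < 0.05

    def test_non_snp_input_rejected(self, rng):
        from dartpop.markers import MarkerMatrix

        m = MarkerMatrix("silico", rng.integers(0, 2, size=(10, 4)).astype(np.int8),
                         [f"m{i}" for i in range(10)], [f"s{j}" for j in range(4)])
        with pytest.raises(ValueError, match="codominant"):
            run_admixture(m, 2, McmcConfig(burn_in=10, mcmc=10), seed=1)


class TestEstimateLK:
    def test_constant_trace(self):
        assert estimate_LK([-50.0, -50.0, -50.0]) == pytest.approx(-50.0)

    def test_two_point_formula(self):
        # mean -101, sample variance 2 -> L = -102
        assert estimate_LK([-100.0, -102.0]) == pytest.approx(-102.0)

    def test_definition_on_longer_trace(self, rng):
        t = rng.normal(-1000, 5, size=200)
        assert estimate_LK(t) == pytest.approx(t.mean() - t.var(ddof=1) / 2, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            estimate_LK([-1.0, np.nan])


class TestEvanno:
    def _table(self, means, sds, runs=3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for K, (mu, sd) in enumerate(zip(means, sds), start=1):
            offs = rng.normal(0, 1, size=runs)
            offs = (offs - offs.mean()) / offs.std(ddof=1) * sd
            for r, o in enumerate(offs):
                rows.append({"K": K, "run": r, "L": mu + o})
        return pd.DataFrame(rows)

    def test_formula_arithmetic(self):
        # means -1000, -800, -780 with sd 2 at K=2 -> |20 - 200| / 2 = 90
        tab = self._table([-1000, -800, -780], [2.0, 2.0, 2.0])
        out, best = evanno_deltaK(tab)
        assert out.loc[out["K"] == 2, "delta_K"].iloc[0] == pytest.approx(90.0)
        assert best == 2

    def test_linear_L_gives_zero(self):
        tab = self._table([-900, -800, -700, -600], [1.0] * 4)
        out, _ = evanno_deltaK(tab)
        interior = out.dropna(subset=["delta_K"])
        assert np.allclose(interior["delta_K"], 0.0, atol=1e-9)

    def test_zero_sd_reported_inf(self):
        rows = [{"K": K, "run": r, "L": float(-100 * K if K != 2 else -150)} for K in (1, 2, 3) for r in (0, 1)]
        with pytest.warns(UserWarning, match="zero across-run sd"):
            out, best = evanno_deltaK(pd.DataFrame(rows))
        assert np.isinf(out.loc[out["K"] == 2, "delta_K"]).all()

    def test_needs_three_consecutive_K(self):
        with pytest.raises(ValueError):
            evanno_deltaK(pd.DataFrame([{"K": 1, "run": 0, "L": -1.0}, {"K": 1, "run": 1, "L": -1.1},
                                        {"K": 3, "run": 0, "L": -2.0}, {"K": 3, "run": 1, "L": -2.1}]))


class TestDiversity:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (np.full(10, 0.5), 0.5),
            (np.array([0.0, 1.0, 0.0]), 0.0),
            (np.array([0.5, 0.9]), 0.34),
        ],
    )
    def test_expected_heterozygosity(self, p, expected):
        assert expected_heterozygosity(p) == pytest.approx(expected)

    def test_net_distance_identical_is_zero(self, rng):
        p = rng.uniform(size=50)
        assert net_nucleotide_distance(p, p) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "p1,p2,expected",
        [(np.array([1.0]), np.array([0.0]), 1.0), (np.array([0.8]), np.array([0.2]), 0.36)],
    )
    def test_net_distance_closed_form(self, p1, p2, expected):
        assert net_nucleotide_distance(p1, p2) == pytest.approx(expected)


class TestMembership:
    def test_fully_assigned_and_admixed(self):
        labels, props = assign_membership(np.array([[0.995, 0.005], [0.60, 0.40]]), 0.01)
        assert labels == ["subpop1", "admixed"]

    def test_proportions_are_column_means(self):
        _, props = assign_membership(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert props == pytest.approx([0.5, 0.5])

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            assign_membership(np.array([[1.0, 0.0]]), 0.7)

    def test_alignment_invariance(self, rng):
        Q = rng.dirichlet([0.5, 0.5, 0.5], size=20)
        perm = [2, 0, 1]
        back = align_clusters(Q[:, perm], Q)
        assert np.allclose(Q[:, perm][:, back], Q)
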