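"""Weir-Cockerham F_ST, I-splines, GDM fitting and candidate classification."""

import numpy as np
import pandas as pd
import pytest

from invadapt import synthetic as syn
from invadapt import turnover as tv


# ---------------------------------------------------------------------------
# an independent textbook Weir-Cockerham (1984) oracle, scalar arithmetic
# ---------------------------------------------------------------------------

def wc_theta_oracle(pop_calls):
    """Multi-SNP two-population theta from raw genotype lists.

    ``pop_calls``: list of 2 arrays (individuals x SNPs, -1 missing).
    Ratio of sums of the a, b, c components over SNPs.
    """
    num = den = 0.0
    n_snps = pop_calls[0].shape[1]
    for j in range(n_snps):
        stats = []
        for calls in pop_calls:
            col = calls[:, j]
            obs = col[col >= 0]
            n_i = len(obs)
            p_i = obs.sum() / (2 * n_i)
            h_i = (obs == 1).sum() / n_i
            stats.append((n_i, p_i, h_i))
        (n1, p1, h1), (n2, p2, h2) = stats
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def _geno(pop_sizes, freqs, seed, n_snps=1):
    """GenotypeMatrix with per-population binomial draws at given freqs."""
    rng = np.random.default_rng(seed)
    blocks, pops = [], []
    for k, (n, f) in enumerate(zip(pop_sizes, freqs)):
        blocks.append(rng.binomial(2, f, size=(n, n_snps)).astype(np.int8))
        pops += [f"pop{k}"] * n
    calls = np.vstack(blocks)
    return syn.GenotypeMatrix(
        calls=calls,
        individual_ids=[f"i{k}" for k in range(len(pops))],
        populations=np.array(pops),
        locus_ids=np.zeros(n_snps, dtype=int),
        positions=np.arange(n_snps),
    )


class TestWeirCockerham:
    def test_equal_frequencies_give_zero(self):
        G = _geno([200, 200], [0.5, 0.5], seed=1, n_snps=5)
        m = tv.fst_for_snp_set(G, np.arange(5), min_n=5)
        assert m.fst[0, 1] < 0.02  # floored at 0, near 0 for large n

    def test_fixed_difference_gives_one(self):
        calls = np.vstack([np.zeros((10, 1)), np.full((10, 1), 2)]).astype(np.int8)
        G = syn.GenotypeMatrix(
            calls=calls, individual_ids=[f"i{k}" for k in range(20)],
            populations=np.array(["a"] * 10 + ["b"] * 10),
            locus_ids=np.zeros(1, int), positions=np.zeros(1, int),
        )
        m = tv.fst_for_snp_set(G, [0], min_n=5)
        assert m.fst[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("pop_sizes,freqs,n_snps", [
        ([10, 10], [0.2, 0.8], 1),
        ([15, 8], [0.3, 0.6], 3),
        ([12, 20, 7], [0.1, 0.5, 0.9], 2),
        ([9, 9, 9, 9], [0.2, 0.4, 0.6, 0.8], 3),
    ])
    def test_matches_textbook_oracle(self, pop_sizes, freqs, n_snps):
        G = _geno(pop_sizes, freqs, seed=42, n_snps=n_snps)
        m = tv.fst_for_snp_set(G, np.arange(n_snps), min_n=2)
        pops = m.populations
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                ci = G.calls[G.populations == pops[i]]
                cj = G.calls[G.populations == pops[j]]
                expected = max(wc_theta_oracle([ci, cj]), 0.0)
                assert m.fst[i, j] == pytest.approx(expected, abs=1e-10)

    def test_small_populations_excluded(self):
        G = _geno([10, 3, 10], [0.2, 0.5, 0.8], seed=3)
        m = tv.fst_for_snp_set(G, [0], min_n=5)
        assert m.populations == ["pop0", "pop2"]

    def test_rescaling_bounds_and_symmetry(self, cline_genotypes):
        G, _ = cline_genotypes
        out = tv.wc_fst_per_locus(G, loci=pd.unique(G.locus_ids)[:5], min_n=5)
        for m in out.values():
            assert np.allclose(m.fst, m.fst.T)
            assert np.allclose(np.diag(m.fst), 0)
            assert m.rescaled.min() >= 0 and m.rescaled.max() <= 1


class TestIsplineBasis:
    def test_zero_at_minimum_one_at_maximum(self):
        x = np.linspace(-2, 5, 50)
        B = tv.ispline_basis(x, 3)
        np.testing.assert_allclose(B[0], 0, atol=1e-12)
        np.testing.assert_allclose(B[-1], 1, atol=1e-12)

    def test_monotone_nondecreasing(self, rng):
        x = np.sort(rng.normal(size=100))
        B = tv.ispline_basis(x, 3)
        assert (np.diff(B, axis=0) >= -1e-12).all()

    def test_matches_numeric_integration_oracle(self):
        # basis i is the normalized integral of the degree-1 B-spline (hat)
        # on the same knots: check midpoints against brute-force quadrature
        knots = np.array([0.0, 0.4, 1.0])
        xs = np.array([0.2, 0.4, 0.7])
        B = tv.ispline_basis(xs, knots=knots)
        from scipy.interpolate import BSpline

        t = np.r_[knots[0], knots, knots[-1]]
        grid = np.linspace(0, 1, 20001)
        for i in range(3):
            c = np.zeros(3)
            c[i] = 1.0
            hat = BSpline(t, c, 1, extrapolate=False)(grid)
            hat = np.nan_to_num(hat)
            cum = np.cumsum(hat) * (grid[1] - grid[0])
            cum /= cum[-1]
            for x, got in zip(xs, B[:, i]):
                want = cum[int(round(x / (grid[1] - grid[0])))]
                assert got == pytest.approx(want, abs=1e-3)

    def test_values_outside_span_clamped(self):
        knots = np.array([0.0, 0.5, 1.0])
        B = tv.ispline_basis(np.array([-5.0, 5.0]), knots=knots)
        np.testing.assert_allclose(B[0], 0, atol=1e-12)
        np.testing.assert_allclose(B[1], 1, atol=1e-12)

    def test_insufficient_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            tv.ispline_basis(np.array([1.0, 1.0, 1.0]), 3)


@pytest.fixture(scope="module")
def sites():
    rng = np.random.default_rng(5)
    n = 40
    env = pd.DataFrame(
        {"PRJ": rng.uniform(0, 1, n), "MTP": rng.uniform(0, 1, n)},
        index=[f"p{i}" for i in range(n)],
    )
    coords = pd.DataFrame(
        {"lon": rng.uniform(0, 10, n), "lat": rng.uniform(0, 10, n)},
        index=env.index,
    )
    return env, coords


def _simulate_dissim(env, coef, intercept=0.1, noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    Z, iu, knots = tv._pair_design(env, None, list(env.columns), False, 3)
    eta = intercept + Z[:, 1:] @ np.concatenate([coef[c] for c in env.columns])
    y = 1 - np.exp(-eta)
    y = np.clip(y + rng.normal(0, noise, y.shape), 0, 0.999)
    return tv._square_from_pairs(y, len(env))


class TestGdmFit:
    def test_constant_zero_dissimilarity(self, sites):
        env, _ = sites
        m = tv.fit_gdm(np.zeros((len(env), len(env))), env)
        assert all(np.allclose(v, 0) for v in m.coefs.values())
        assert m.pct_deviance == 0.0

    def test_parameter_recovery_single_predictor(self, sites):
        env, _ = sites
        true = {"PRJ": np.array([0.4, 0.3, 0.3]), "MTP": np.zeros(3)}
        M = _simulate_dissim(env, true, seed=1)
        m = tv.fit_gdm(M, env)
        assert m.pct_deviance > 90
        assert m.turnover("PRJ") == pytest.approx(1.0, rel=0.10)
        assert m.turnover("MTP") < 0.1

    def test_random_dissimilarity_sits_at_floor(self, sites):
        env, _ = sites
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 1, size=(len(env) * (len(env) - 1)) // 2)
        m = tv.fit_gdm(tv._square_from_pairs(y, len(env)), env)
        assert m.pct_deviance < 2.0

    def test_fitted_dissimilarities_stay_in_unit_interval(self, sites):
        env, coords = sites
        true = {"PRJ": np.array([1.0, 1.0, 1.0]), "MTP": np.array([0.5, 0.0, 0.5])}
        m = tv.fit_gdm(_simulate_dissim(env, true, seed=3), env,
                       coords=coords, include_geography=True)
        assert (m.fitted >= 0).all() and (m.fitted < 1).all()
        assert all((v >= 0).all() for v in m.coefs.values())

    def test_out_of_range_dissimilarity_rejected(self, sites):
        env, _ = sites
        M = np.full((len(env), len(env)), 1.5)
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            tv.fit_gdm(M, env)

    def test_too_few_pairs_rejected(self):
        env = pd.DataFrame({"PRJ": [0.1, 0.5, 0.9, 0.2]})
        with pytest.raises(ValueError, match="pairs"):
            tv.fit_gdm(np.zeros((4, 4)), env)


class TestPartialTurnover:
    def test_zero_coefficients_zero_turnover(self, sites):
        env, _ = sites
        m = tv.fit_gdm(np.zeros((len(env), len(env))), env)
        assert tv.partial_turnover(m, "PRJ") == 0.0

    def test_turnover_is_coefficient_sum(self, sites):
        env, _ = sites
        m = tv.fit_gdm(_simulate_dissim(env, {"PRJ": np.array([0.2, 0.1, 0.1]),
                                              "MTP": np.zeros(3)}, seed=4), env)
        assert tv.partial_turnover(m, "PRJ") == pytest.approx(
            float(np.sum(m.coefs["PRJ"])))

    def test_unknown_predictor_rejected(self, sites):
        env, _ = sites
        m = tv.fit_gdm(np.zeros((len(env), len(env))), env)
        with pytest.raises(KeyError):
            tv.partial_turnover(m, "nope")


class TestReferenceGroup:
    def test_structure_only_reference_is_near_floor(self, null_genotypes):
        G, _ = null_genotypes
        ref = tv.reference_group_gdm(G, G.pop_env, G.pop_coords,
                                     n_ref=200, seed=1)
        assert ref.pct_deviance < 5.0
        for p in ref.predictors:
            assert ref.turnover(p) < 0.3

    def test_reference_stable_across_seeds(self, null_genotypes):
        G, _ = null_genotypes
        a = tv.reference_group_gdm(G, G.pop_env, G.pop_coords, n_ref=200, seed=2)
        b = tv.reference_group_gdm(G, G.pop_env, G.pop_coords, n_ref=200, seed=3)
        assert abs(a.pct_deviance - b.pct_deviance) < 5.0


class TestClassification:
    @pytest.fixture(scope="class")
    @staticmethod
    def models(cline_genotypes):
        G, truth = cline_genotypes
        causal_idx = [G.snp_ids.index(s) for s in truth.causal_snp_ids]
        causal_loci = sorted(set(G.locus_ids[causal_idx]))
        ref = tv.reference_group_gdm(G, G.pop_env, G.pop_coords, n_ref=200, seed=9)
        out = {}
        for locus in causal_loci[:4]:
            idx = np.flatnonzero(G.locus_ids == locus)
            m = tv.fst_for_snp_set(G, idx, min_n=5, locus=locus)
            out[locus] = tv.fit_gdm(m, G.pop_env, coords=G.pop_coords,
                                    include_geography=True)
        return out, ref

    def test_planted_loci_become_candidates_with_right_predictor(self, models):
        locus_models, ref = models
        tab = tv.classify_candidates(locus_models, ref)
        cand = tab[tab.status == "candidate"]
        assert len(cand) >= 0.8 * len(tab)
        assert (cand["winner"] == "PRJ").all()

    def test_low_deviance_locus_is_not_candidate(self, sites, models):
        env, coords = sites
        _, ref = models
        # structureless locus: %GDM below the reference floor fails C1
        rng = np.random.default_rng(11)
        y = rng.uniform(0, 1, size=(len(env) * (len(env) - 1)) // 2)
        weak = tv.fit_gdm(tv._square_from_pairs(y, len(env)), _ref_env(env, ref),
                          coords=coords, include_geography=True)
        tab = tv.classify_candidates({"weak": weak}, ref)
        assert tab.iloc[0]["status"] != "candidate"


def _ref_env(env, ref):
    """Extend a site table to the reference model's predictor roster."""
    out = env.copy()
    rng = np.random.default_rng(0)
    for p in ref.predictors:
        if p not in out.columns and p != tv.GEOGRAPHY:
            out[p] = rng.uniform(0, 1, len(out))
    return out[[p for p in ref.predictors if p != tv.GEOGRAPHY]]


class TestTurnoverMap:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted(sites):
        env, _ = sites
        true = {"PRJ": np.array([0.4, 0.3, 0.3]), "MTP": np.zeros(3)}
        return tv.fit_gdm(_simulate_dissim(env, true, seed=6), env)

    def test_constant_raster_constant_map(self, fitted):
        env = syn.EnvStack({"PRJ": np.full((12, 12), 0.5)})
        m, n_clamped = tv.predict_turnover_map(fitted, env, "PRJ")
        assert np.ptp(m) == 0.0

    def test_monotone_raster_monotone_map(self, fitted):
        grad = np.tile(np.linspace(0, 1, 20), (5, 1))
        env = syn.EnvStack({"PRJ": grad})
        m, _ = tv.predict_turnover_map(fitted, env, "PRJ")
        assert (np.diff(m, axis=1) >= -1e-12).all()

    def test_range_equals_partial_turnover(self, fitted):
        lo, hi = fitted.knots["PRJ"][0], fitted.knots["PRJ"][-1]
        env = syn.EnvStack({"PRJ": np.array([[lo, hi]] * 10)})
        m, _ = tv.predict_turnover_map(fitted, env, "PRJ")
        assert np.ptp(m) == pytest.approx(tv.partial_turnover(fitted, "PRJ"))

    def test_out_of_gradient_cells_counted(self, fitted):
        env = syn.EnvStack({"PRJ": np.array([[-10.0, 0.5, 10.0]] * 4)})
        _, n_clamped = tv.predict_turnover_map(fitted, env, "PRJ")
        assert n_clamped == 8

    def test_unknown_predictor_rejected(self, fitted):
        env = syn.EnvStack({"PRJ": np.zeros((10, 10))})
        with pytest.raises(KeyError):
            tv.predict_turnover_map(fitted, env, "XXX")


class TestDiagnostics:
    def test_generated_data_fit_nearly_perfectly(self, sites):
        env, _ = sites
        true = {"PRJ": np.array([0.5, 0.5, 0.5]), "MTP": np.zeros(3)}
        m = tv.fit_gdm(_simulate_dissim(env, true, noise=0.005, seed=7), env)
        d = tv.observed_vs_predicted(m)
        assert d["pearson"] > 0.95

    def test_shuffled_dissimilarities_decorrelate(self, sites):
        env, _ = sites
        rng = np.random.default_rng(8)
        y = rng.uniform(0, 0.8, size=(len(env) * (len(env) - 1)) // 2)
        m = tv.fit_gdm(tv._square_from_pairs(y, len(env)), env)
        d = tv.observed_vs_predicted(m)
        assert abs(d["pearson"]) < 0.3 or np.isnan(d["pearson"])

    def test_deterministic(self, sites):
        env, _ = sites
        M = _simulate_dissim(env, {"PRJ": np.array([0.3, 0.2, 0.1]),
                                   "MTP": np.zeros(3)}, seed=9)
        a = tv.observed_vs_predicted(tv.fit_gdm(M, env))
        b = tv.observed_vs_predicted(tv.fit_gdm(M, env))
        np.testing.assert_array_equal(a["predicted"], b["predicted"])


def test_population_allele_frequencies(cline_genotypes):
    G, truth = cline_genotypes
    j = G.snp_ids.index(truth.causal_snp_ids[0])
    tab = tv.population_allele_frequencies(G, [j])
    assert tab.shape == (len(pd.unique(G.populations)), 1)
    assert ((tab >= 0) & (tab <= 1)).all().all()
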