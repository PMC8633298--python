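"""Posterior summaries: variance shares, enrichment, PIP, PPWV, credible sets."""

import numpy as np
import pandas as pd
import pytest

import bayesrrc as b
from bayesrrc.annotate import MarkerGrouping, RegionSet
from bayesrrc.results import BayesRRCResults, evaluate_calls, ppwv, region_variance_shares
from bayesrrc.samples import PosteriorSamples


def make_samples(beta_draws, categories=None, n_groups=1, group_index=None):
    """Hand-built container from a dense (n_draws, p) effect matrix."""
    beta_draws = np.asarray(beta_draws, dtype=float)
    n_draws, p = beta_draws.shape
    bidx, bval, bcomp, indptr = [], [], [], [0]
    for d in range(n_draws):
        nz = np.flatnonzero(beta_draws[d])
        bidx.extend(nz)
        bval.extend(beta_draws[d, nz])
        bcomp.extend([1] * len(nz))
        indptr.append(indptr[-1] + len(nz))
    cats = np.asarray(categories) if categories is not None else np.full(p, "all")
    gi = np.asarray(group_index) if group_index is not None else np.zeros(p, dtype=int)
    labels = [(c, "common", "low") for c in dict.fromkeys(cats)] if categories is not None \
        else [("all",) * 3] * n_groups
    grouping = MarkerGrouping(cats, np.full(p, "common"), np.full(p, "low"), gi, labels)
    return PosteriorSamples(
        chain=np.zeros(n_draws, dtype=int), iteration=np.arange(n_draws),
        mu=np.zeros(n_draws), sigma2_eps=np.full(n_draws, 0.5),
        sigma2_G=np.full((n_draws, max(gi) + 1), 0.1),
        pi=np.full((n_draws, max(gi) + 1, 5), 0.2),
        beta_idx=bidx, beta_val=bval, beta_comp=bcomp, indptr=indptr,
        grouping=grouping, marker_ids=np.array([f"m{j}" for j in range(p)]),
        marker_sds=np.ones(p),
    )


def make_results(samples):
    class _Shim:
        pass

    model = _Shim()
    model.mixture = b.MixtureSpec()
    return BayesRRCResults(model, samples, None)


class TestVariancePartition:
    def test_single_draw_hand_arithmetic(self):
        res = make_results(make_samples([[0.1, 0.2]]))
        df = res.variance_partition("category")
        assert np.isclose(df[df.unit == "all"]["mean"].iloc[0], 0.05)

    def test_all_zero_draws(self):
        res = make_results(make_samples(np.zeros((4, 3))))
        df = res.variance_partition("category")
        assert (df["mean"] == 0).all()

    def test_h2_draws_match_partition_total(self, fitted_small):
        res = fitted_small["res"]
        total = res.variance_partition("category").iloc[-1]["mean"]
        assert np.isclose(total, res.h2_draws().mean())


class TestEnrichment:
    def test_hand_arithmetic(self):
        # one draw: group A holds 2 of 4 in-model markers and 0.8 of the
        # variance -> enrichment 0.8 / 0.5 = 1.6
        beta = np.zeros((1, 8))
        beta[0, [0, 1]] = np.sqrt([0.5, 0.3])   # A: variance 0.8
        beta[0, [4, 5]] = np.sqrt([0.1, 0.1])   # B: variance 0.2
        cats = np.array(["A"] * 4 + ["B"] * 4)
        res = make_results(make_samples(beta, categories=cats))
        df = res.enrichment("category").set_index("unit")
        assert np.isclose(df.loc["A", "enrichment_mean"], 1.6)
        assert np.isclose(df.loc["B", "enrichment_mean"], 0.4)

    def test_uniform_effects_enrichment_one(self):
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.1, size=(50, 40))
        cats = np.array(["A"] * 20 + ["B"] * 20)
        res = make_results(make_samples(beta, categories=cats))
        df = res.enrichment("category")
        assert np.allclose(df["enrichment_mean"], 1.0, atol=0.15)

    def test_weighted_mean_identity(self):
        # per draw, enrichment weighted by in-model marker shares equals 1
        rng = np.random.default_rng(1)
        beta = rng.normal(0, 0.1, size=(1, 30)) * (rng.random((1, 30)) < 0.5)
        cats = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        s = make_samples(beta, categories=cats)
        idx = s.beta_idx
        var_tot = (s.beta_val**2).sum()
        weighted = 0.0
        for cat in "ABC":
            members = np.flatnonzero(cats == cat)
            in_model = np.isin(idx, members)
            if not in_model.any():
                continue
            vshare = (s.beta_val[in_model] ** 2).sum() / var_tot
            mshare = in_model.sum() / len(idx)
            weighted += (vshare / mshare) * mshare
        assert np.isclose(weighted, 1.0)


class TestPip:
    def test_counting(self):
        beta = np.zeros((200, 2))
        beta[:190, 0] = 0.1
        res = make_results(make_samples(beta))
        pip = res.pip()
        assert pip[0] == 0.95 and pip[1] == 0.0

    def test_perfect_ld_pair_splits_pip(self):
        # two identical markers carrying one causal signal: each enters the
        # model about half the time, their PIPs summing to ~1
        rng = np.random.default_rng(2)
        n = 2000
        g_col = rng.integers(0, 3, size=n).astype(np.int8)
        geno = np.column_stack([g_col, g_col]).astype(np.int8)
        panel = b.GenotypePanel(geno, np.array(["a", "b"]),
                                np.array([0, 1000]), np.array([1, 1]),
                                np.full(2, 0.3), np.array([0, 0]))
        x = (g_col - g_col.mean()) / g_col.std()
        y = 0.3 * x + rng.standard_normal(n) * np.sqrt(1 - 0.09)
        # label switching between the twin markers mixes slowly within one
        # chain; pooling several chains symmetrizes the split
        res = b.BayesRRC(y, panel).fit(n_iter=3000, burn_in=500, seed=3,
                                       n_chains=4)
        pip = res.pip()
        assert 0.8 < pip.sum() < 1.25
        assert pip.min() > 0.15 and pip.max() < 0.9

    def test_all_chains_criterion(self):
        beta = np.zeros((100, 1))
        beta[:, 0] = 0.1
        s = make_samples(beta)
        s.chain = np.repeat([0, 1], 50)
        res = make_results(s)
        pooled, flag = res.pip(level=0.95)
        assert pooled[0] == 1.0 and flag[0]


class TestRegionShares:
    def region_set(self, members):
        return RegionSet([f"r{i}" for i in range(len(members))], members, "test", {})

    def test_hand_split(self):
        s = make_samples([[0.1, 0.2]])
        shares = region_variance_shares(s, self.region_set([[0], [1]]))
        np.testing.assert_allclose(shares, [[0.2, 0.8]])

    def test_tiling_shares_sum_to_one(self):
        rng = np.random.default_rng(3)
        beta = rng.normal(0, 0.1, (20, 12)) * (rng.random((20, 12)) < 0.4)
        s = make_samples(beta)
        shares = region_variance_shares(s, self.region_set([[0, 1, 2, 3], [4, 5, 6, 7], [8, 9, 10, 11]]))
        nonzero = np.abs(beta).sum(axis=1) > 0
        np.testing.assert_allclose(shares[nonzero].sum(axis=1), 1.0)

    def test_region_covering_all_markers(self):
        rng = np.random.default_rng(4)
        beta = rng.normal(size=(5, 6))
        s = make_samples(beta)
        shares = region_variance_shares(s, self.region_set([list(range(6))]))
        np.testing.assert_allclose(shares, 1.0)

    def test_empty_region_share_zero(self):
        s = make_samples([[0.1, 0.2]])
        shares = region_variance_shares(s, self.region_set([[0, 1], []]))
        assert shares[0, 1] == 0.0


class TestPpwv:
    def region_set(self):
        return RegionSet(["r0"], [[0]], "test", {})

    def test_counting(self):
        shares = np.array([[2e-5], [0.5e-5], [3e-5], [0.0]])
        df = ppwv(shares, self.region_set(), theta=1e-5)
        assert df["ppwv"].iloc[0] == 0.5

    def test_always_exceeding_gives_one(self):
        df = ppwv(np.full((10, 1), 1e-3), self.region_set(), theta=1e-5)
        assert df["ppwv"].iloc[0] == 1.0

    def test_monotone_in_theta_and_order_invariant(self):
        rng = np.random.default_rng(5)
        shares = rng.random((50, 1)) * 1e-4
        r = self.region_set()
        vals = [ppwv(shares, r, theta=t)["ppwv"].iloc[0] for t in (1e-6, 1e-5, 1e-4)]
        assert vals[0] >= vals[1] >= vals[2]
        shuffled = shares[rng.permutation(50)]
        assert ppwv(shuffled, r, theta=1e-5)["ppwv"].iloc[0] == vals[1]

    def test_theta_rejected_nonpositive(self):
        with pytest.raises(ValueError):
            ppwv(np.ones((2, 1)), self.region_set(), theta=0)


class TestCredibleSet:
    def test_connected_cluster_retained(self, fitted_small):
        # construct a fake region over one LD block of the fitted panel:
        # within-block R^2 is high, so the whole block should be kept
        res = fitted_small["res"]
        panel = fitted_small["panel"]
        truth = fitted_small["truth"]
        causal = truth.causal_indices[0]
        block = np.flatnonzero(panel.block == panel.block[causal])
        regions = RegionSet(["blk"], [block.tolist()], "ld_block", {})
        cs = res.credible_set(regions, "blk", purity_r2=0.01)
        assert set(cs["marker"]) == set(block)

    def test_two_clusters_separated(self):
        # two sub-clusters (high R^2 within, low across): the set must stay
        # inside the top-PIP marker's cluster
        rng = np.random.default_rng(6)
        n = 3000
        base1 = rng.integers(0, 3, n).astype(np.int8)
        base2 = rng.integers(0, 3, n).astype(np.int8)
        flip = rng.random((n, 2)) < 0.03
        geno = np.column_stack([
            base1, np.where(flip[:, 0], rng.integers(0, 3, n), base1),
            base2, np.where(flip[:, 1], rng.integers(0, 3, n), base2),
        ]).astype(np.int8)
        panel = b.GenotypePanel(geno, np.array(["a1", "a2", "b1", "b2"]),
                                np.arange(4) * 1000, np.ones(4, dtype=int),
                                np.full(4, 0.3), np.array([0, 0, 1, 1]))
        x = (base1 - base1.mean()) / base1.std()
        y = 0.35 * x + rng.standard_normal(n)
        y = (y - y.mean()) / y.std()
        model = b.BayesRRC(y, panel)
        model.panel = panel
        res = model.fit(n_iter=1500, burn_in=300, seed=7)
        regions = RegionSet(["all"], [[0, 1, 2, 3]], "ld_block", {})
        cs = res.credible_set(regions, "all", purity_r2=0.8)
        assert set(cs["marker"]) == {0, 1}

    def test_singleton_when_no_pure_pair(self, fitted_small):
        res = fitted_small["res"]
        panel = fitted_small["panel"]
        # markers from three different blocks: mutual R^2 ~ 0
        picks = [0, 15, 25]
        regions = RegionSet(["mix"], [picks], "ld_block", {})
        cs = res.credible_set(regions, "mix", purity_r2=0.9)
        assert len(cs) == 1


class TestAlleleScale:
    def test_unit_sd_unchanged(self):
        s = make_samples([[0.1, 0.0]])
        res = make_results(s)
        df = res.allele_effects()
        assert np.isclose(df["beta_allele"].iloc[0], df["beta_std"].iloc[0])

    def test_binomial_sd_arithmetic(self):
        s = make_samples([[0.02]])
        s.marker_sds = np.array([np.sqrt(2 * 0.01 * 0.99)])
        res = make_results(s)
        df = res.allele_effects()
        assert np.isclose(df["beta_allele"].iloc[0], 0.02 / 0.14071, atol=1e-4)

    def test_rare_marker_larger_allele_effect(self):
        s = make_samples([[0.1, 0.1]])
        s.marker_sds = np.array([np.sqrt(2 * 0.01 * 0.99), np.sqrt(2 * 0.4 * 0.6)])
        df = make_results(s).allele_effects()
        assert df["beta_allele"].iloc[0] > df["beta_allele"].iloc[1]


class TestEvaluateCalls:
    def regions(self):
        return RegionSet(["a", "b", "c", "d"], [[0], [1], [2], [3]], "test", {})

    def table(self, probs):
        return pd.DataFrame({"region_id": list("abcd"), "ppwv": probs})

    def test_perfect_calls(self):
        ev = evaluate_calls(self.table([1.0, 1.0, 0.0, 0.0]), self.regions(), [0, 1])
        assert ev["fdr"] == 0.0 and np.isclose(ev["auprc"], 1.0)

    def test_trapezoid_hand_computation(self):
        # ranked probs: causal, null, causal, null ->
        # precision at recall 0.5 = 1, at recall 1.0 = 2/3
        ev = evaluate_calls(self.table([0.9, 0.8, 0.7, 0.1]), self.regions(), [0, 2])
        # points: (r,p) = (0,1), (0.5,1), (0.5,0.5), (1,2/3), (1,0.5)
        # trapezoid over the recall path: 0.5*1 + 0*(...) + 0.5*(0.5+2/3)/2
        expected = 0.5 * 1.0 + 0.5 * (0.5 + 2 / 3) / 2
        assert np.isclose(ev["auprc"], expected)

    def test_fdr_counts_null_calls(self):
        ev = evaluate_calls(self.table([1.0, 0.99, 0.99, 0.0]), self.regions(), [0])
        assert np.isclose(ev["fdr"], 2 / 3)

    def test_no_causal_regions_recall_undefined(self):
        ev = evaluate_calls(self.table([0.5] * 4), self.regions(), [])
        assert ev.get("recall_undefined") and np.isnan(ev["auprc"])
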