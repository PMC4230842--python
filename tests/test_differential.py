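import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from crossmeth import betabinom, differential, diagnostics
from crossmeth.differential import Comparison, DmrCandidate
from crossmeth.io import Region, SampleKey
from conftest import make_table

SPECIES = "sim"


def key(tissue, treatment, rep=0):
    return SampleKey(SPECIES, tissue, treatment, rep)


class TestComparison:
    def test_only_single_factor_differences_allowed(self):
        with pytest.raises(ValueError):
            Comparison(key("root", "control23"), key("shoot", "cold4"))
        with pytest.raises(ValueError):
            Comparison(key("root", "control23"), key("root", "control23"))

    def test_sanctioned_set_has_two_axes(self):
        keys = [key(t, tr) for t in ("root", "shoot") for tr in ("control23", "cold4")]
        comps = differential.sanctioned_comparisons(keys)
        assert len(comps) == 4
        assert sum(c.axis == "tissue" for c in comps) == 2
        assert sum(c.axis == "treatment" for c in comps) == 2


class TestDmps:
    def _tables(self, recs_a, recs_b):
        return (
            make_table(recs_a, key=key("root", "control23")),
            make_table(recs_b, key=key("shoot", "control23")),
        )

    def test_identical_counts_give_p_one(self):
        ta, tb = self._tables(
            [("chr1", 10, "+", "CG", 10, 5)], [("chr1", 10, "+", "CG", 10, 5)]
        )
        comp = Comparison(ta.key, tb.key)
        res = differential.call_dmps(comp, ta, tb)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_prefilter_skips_low_rate_sites(self):
        ta, tb = self._tables(
            [("chr1", 10, "+", "CG", 20, 3)], [("chr1", 10, "+", "CG", 20, 2)]
        )  # rates 0.15 and 0.10
        comp = Comparison(ta.key, tb.key)
        res = differential.call_dmps(comp, ta, tb)
        assert not res["tested"].iloc[0] and np.isnan(res["p"].iloc[0])

    def test_swap_symmetry(self):
        ta, tb = self._tables(
            [("chr1", 10, "+", "CG", 10, 8)], [("chr1", 10, "+", "CG", 10, 1)]
        )
        comp = Comparison(ta.key, tb.key)
        fwd = differential.call_dmps(comp, ta, tb)
        rev = differential.call_dmps(Comparison(tb.key, ta.key), tb, ta)
        assert fwd["p"].iloc[0] == pytest.approx(rev["p"].iloc[0])
        assert fwd["direction"].iloc[0] == -rev["direction"].iloc[0]

    @given(
        n1=st.integers(1, 15), n2=st.integers(1, 15),
        k1=st.integers(0, 15), k2=st.integers(0, 15),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_fisher_matches_enumeration_oracle(self, n1, n2, k1, k2):
        k1, k2 = min(k1, n1), min(k2, n2)
        p_impl = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])[1]
        p_oracle = diagnostics.fisher_two_sided_oracle(k1, n1, k2, n2)
        assert p_impl == pytest.approx(p_oracle, abs=1e-9)


class TestCandidates:
    def _mk(self, intervals_by_sample, sites):
        """intervals: dict tissue/treatment label -> list of (start, end)."""
        mrs = {}
        tables = {}
        for (tissue, treatment), ivs in intervals_by_sample.items():
            k = key(tissue, treatment)
            mrs[k] = [Region("chr1", s, e) for s, e in ivs]
            tables[k] = make_table(
                [("chr1", p, "+", "CG", 10, 5) for p in sites], key=k
            )
        return mrs, tables

    ALL = [("root", "control23"), ("root", "cold4"), ("shoot", "control23"), ("shoot", "cold4")]

    def test_identical_mr_sets_give_no_candidates(self):
        mrs, tables = self._mk({c: [(100, 200)] for c in self.ALL}, range(100, 200, 10))
        assert differential.select_dmr_candidates(mrs, tables) == []

    def test_single_sample_mr_becomes_candidate(self):
        ivs = {c: [] for c in self.ALL}
        ivs[("root", "control23")] = [(100, 200)]
        mrs, tables = self._mk(ivs, range(100, 200, 10))
        cands = differential.select_dmr_candidates(mrs, tables)
        assert len(cands) == 1
        assert (cands[0].start, cands[0].end) == (100, 200)
        assert len(cands[0].present_in) == 1

    def test_min_cytosine_filter(self):
        ivs = {c: [] for c in self.ALL}
        ivs[("root", "control23")] = [(100, 200)]
        mrs, tables = self._mk(ivs, [110, 120, 130])  # only 3 shared sites
        assert differential.select_dmr_candidates(mrs, tables, min_c=4) == []

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_candidate_intervals_match_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ivs = {}
        for c in self.ALL:
            n = rng.integers(0, 4)
            regs = []
            for _ in range(n):
                s = int(rng.integers(0, 400))
                regs.append((s, s + int(rng.integers(10, 120))))
            ivs[c] = regs
        mrs, tables = self._mk(ivs, range(1, 601, 5))
        cands = differential.select_dmr_candidates(mrs, tables, min_c=1)
        # oracle: per-base presence profile scan
        cover = {c: np.zeros(700, dtype=bool) for c in self.ALL}
        for c, regs in ivs.items():
            for s, e in regs:
                cover[c][s:e] = True
        profile = np.stack([cover[c] for c in self.ALL])
        n_pres = profile.sum(axis=0)
        discordant = (n_pres > 0) & (n_pres < 4)
        base_in_cand = np.zeros(700, dtype=bool)
        for cand in cands:
            base_in_cand[cand.start : cand.end] = True
        # every candidate base is discordant, and every discordant base
        # containing a shared covered site with the same pattern is covered
        assert not (base_in_cand & ~discordant).any()
        for p in np.arange(1, 601, 5):
            if discordant[p - 1]:  # site p occupies base p-1
                assert base_in_cand[p - 1]


class TestBetabinomLrt:
    def test_identical_samples_give_lod_near_zero(self):
        rng = np.random.default_rng(40)
        n = np.maximum(rng.poisson(20, 30), 1)
        k = rng.binomial(n, 0.3)
        ctx = np.zeros(30, dtype=np.int64)
        lod, df, p = differential.betabinom_lrt([(k, n, ctx), (k, n, ctx)])
        assert lod < 1.0 and df == 2
        assert p > 0.1

    def test_null_type_one_error_controlled(self):
        frac = diagnostics.dmr_null_type1(n_regions=400, seed=41)
        assert frac <= 0.10

    def test_strong_difference_detected(self):
        rng = np.random.default_rng(42)
        n = np.maximum(rng.poisson(20, 20), 1)
        ka = rng.binomial(n, 0.8)
        kb = rng.binomial(n, 0.1)
        ctx = np.zeros(20, dtype=np.int64)
        _, _, p = differential.betabinom_lrt([(ka, n, ctx), (kb, n, ctx)])
        assert p < 1e-6

    def test_df_counts_contexts(self):
        rng = np.random.default_rng(43)
        n = np.maximum(rng.poisson(20, 30), 1)
        k = rng.binomial(n, 0.4)
        ctx = np.repeat([0, 1, 2], 10)
        _, df, _ = differential.betabinom_lrt([(k, n, ctx), (k, n, ctx)])
        assert df == 6


class TestGroupAndConfirm:
    ALL = [("root", "control23"), ("root", "cold4"), ("shoot", "control23"), ("shoot", "cold4")]

    def _tables(self, rate_by_combo, n_sites=20, cov=30, seed=44):
        rng = np.random.default_rng(seed)
        tables = {}
        for combo in self.ALL:
            k = key(*combo)
            rate = rate_by_combo[combo]
            recs = []
            for i in range(n_sites):
                n = max(int(rng.poisson(cov)), 1)
                recs.append(
                    ("chr1", 100 + 10 * i, "+", "CG", n, int(rng.binomial(n, rate)))
                )
            tables[k] = make_table(recs, key=k)
        return tables

    def _cand(self):
        return DmrCandidate("chr1", 95, 300, frozenset(), 20)

    def test_all_null_pairs_give_one_group_filtered(self):
        tables = self._tables({c: 0.3 for c in self.ALL})
        res = differential.group_and_confirm(self._cand(), tables)
        assert res.status == "filtered" and len(res.groups) == 1

    def test_tissue_split_groups_and_confirms(self):
        rates = {c: (0.75 if c[0] == "shoot" else 0.05) for c in self.ALL}
        tables = self._tables(rates)
        res = differential.group_and_confirm(self._cand(), tables)
        assert len(res.groups) == 2
        tissues = [sorted({k.tissue for k in g}) for g in res.groups]
        assert sorted(map(tuple, tissues)) == [("root",), ("shoot",)]
        assert res.p < 1e-6
        assert res.n_sig_samples == 4

    def test_injected_tissue_dmrs_recovered(self):
        study = diagnostics.run_study(
            genome_length=20_000, n_dmrs=5, seed=45, hmm_max_iter=10
        )
        assert study["injected_dmr_recall"] >= 0.8
        assert study["dmr_specificity"] >= 0.9


class TestStoreyFdr:
    def test_uniform_pvalues_give_pi0_near_one(self):
        rng = np.random.default_rng(46)
        p = rng.uniform(size=10_000)
        q = differential.storey_fdr(p)
        # with pi0 ~ 1 the q-values approximately equal BH
        bh = multipletests(p, method="fdr_bh")[1]
        ratio = np.median(q / bh)
        assert 0.9 <= ratio <= 1.0 + 1e-9

    def test_pi0_one_reduces_to_bh_exactly(self):
        rng = np.random.default_rng(47)
        p = rng.uniform(size=500) ** 1.5
        q = differential.storey_fdr(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh)

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(48)
        p = rng.beta(0.4, 1.0, size=3000)
        q = differential.storey_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_small_m_falls_back_to_bh_with_warning(self):
        p = np.linspace(0.01, 0.9, 20)
        with pytest.warns(UserWarning, match="pi0 = 1"):
            q = differential.storey_fdr(p)
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            differential.storey_fdr(np.array([0.5, 1.2]))


class TestResolveOverlaps:
    def test_disjoint_regions_all_kept(self):
        regs = [(Region("chr1", 0, 10), 1), (Region("chr1", 20, 30), 2)]
        assert len(differential.resolve_overlaps(regs)) == 2

    def test_higher_weight_wins(self):
        regs = [(Region("chr1", 0, 10), 3), (Region("chr1", 5, 15), 1)]
        kept = differential.resolve_overlaps(regs)
        assert len(kept) == 1 and kept[0][1] == 3

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_bruteforce_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        regs = []
        for _ in range(n):
            s = int(rng.integers(0, 100))
            regs.append((Region("chr1", s, s + int(rng.integers(5, 40))),
                         int(rng.integers(1, 5))))
        kept = differential.resolve_overlaps(regs)
        # independent brute force over all subsets
        from itertools import combinations as comb

        best = None
        for r in range(0, n + 1):
            for subset in comb(range(n), r):
                items = [regs[i] for i in subset]
                if any(
                    a[0].overlaps(b[0]) for a, b in comb(items, 2)
                ):
                    continue
                k = differential._subset_key(items)
                if best is None or k > best:
                    best = k
        assert differential._subset_key(kept) == best
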