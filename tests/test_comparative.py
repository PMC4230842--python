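import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossmeth import comparative, diagnostics, simulate
from crossmeth.io import GenomicFeature, Region

SPECIES = ["crub", "alyr", "atha"]


def aligned_frame(rows):
    """rows: (ctx1, ctx2, ctx3, status1, status2, status3)."""
    data = {}
    for j, sp in enumerate(SPECIES):
        data[f"chrom_{sp}"] = ["chr1"] * len(rows)
        data[f"pos_{sp}"] = np.arange(1, len(rows) + 1) * 10
        data[f"strand_{sp}"] = ["+"] * len(rows)
        data[f"context_{sp}"] = [r[j] for r in rows]
    aligned = pd.DataFrame(data)
    statuses = pd.DataFrame(
        {f"status_{sp}": [r[3 + j] for r in rows] for j, sp in enumerate(SPECIES)}
    )
    return aligned, statuses


class TestMatchContext:
    def test_identical_cg_kept(self):
        assert comparative.match_context(("CG", "CG", "CG"))

    def test_h_substitution_same_label_kept(self):
        # CHH with H=A vs H=T in different species keeps the CHH label
        assert comparative.match_context(("CHH", "CHH", "CHH"))

    def test_context_transition_excluded(self):
        assert not comparative.match_context(("CHH", "CHH", "CHG"))


class TestClassify:
    M, U, X = "methylated", "unmethylated", "untestable"

    def test_class_definitions(self):
        aligned, statuses = aligned_frame(
            [
                ("CG", "CG", "CG", self.M, self.M, self.M),  # conserved3
                ("CG", "CG", "CG", self.U, self.M, self.U),  # gain alyr
                ("CG", "CG", "CG", self.M, self.M, self.U),  # loss atha
                ("CG", "CG", "CG", self.U, self.U, self.U),  # unmethylated
                ("CHH", "CHH", "CHG", self.M, self.M, self.M),  # excluded
                ("CG", "CG", "CG", self.M, self.X, self.M),  # untestable
            ]
        )
        out, tally = comparative.classify_sites(aligned, statuses, SPECIES)
        assert list(out["cons_class"]) == [
            "conserved3", "gain:alyr", "loss:atha", "unmethylated",
            "excluded", "untestable",
        ]
        assert tally["conserved3"] == 1 and tally["gain:alyr"] == 1
        assert tally["loss:atha"] == 1 and tally["shared2"] == 1
        assert tally["excluded"] == 1 and tally["untestable"] == 1

    def test_classes_partition_kept_testable_sites(self, small_catalogue):
        aligned, truth = simulate.simulate_alignment_map(
            small_catalogue, SPECIES, divergence=0.1, seed=50
        )
        _, tally = comparative.classify_sites(aligned, truth.statuses, SPECIES)
        total_kept = (
            tally["conserved3"] + tally["shared2"] + tally["unmethylated"]
            + sum(tally[f"gain:{sp}"] for sp in SPECIES)
        )
        n_all = len(aligned)
        assert total_kept + tally["excluded"] + tally["untestable"] == n_all
        assert sum(tally[f"loss:{sp}"] for sp in SPECIES) == tally["shared2"]

    def test_recovers_generator_tally_exactly(self):
        r = diagnostics.classification_check(n_sites=5000, seed=51)
        assert r["tally_mismatches"] == 0
        assert r["exclusion_set_symmetric_difference"] == 0


class TestGainDensity:
    def test_ratio_values(self):
        aligned, statuses = aligned_frame(
            [("CG", "CG", "CG", "methylated", "unmethylated", "unmethylated")] * 3
            + [("CG", "CG", "CG", "methylated", "methylated", "unmethylated")]
        )
        out, _ = comparative.classify_sites(aligned, statuses, SPECIES)
        dens = comparative.gain_density(out, "crub", window=10_000)
        assert len(dens) == 1
        assert dens["density"].iloc[0] == pytest.approx(0.75)

    def test_windows_without_events_omitted(self):
        aligned, statuses = aligned_frame(
            [("CG", "CG", "CG", "unmethylated", "unmethylated", "unmethylated")]
        )
        out, _ = comparative.classify_sites(aligned, statuses, SPECIES)
        assert comparative.gain_density(out, "crub").empty

    def test_matches_direct_recount(self, small_catalogue):
        aligned, truth = simulate.simulate_alignment_map(
            small_catalogue, SPECIES, divergence=0.0, seed=52
        )
        out, _ = comparative.classify_sites(aligned, truth.statuses, SPECIES)
        dens = comparative.gain_density(out, "crub", window=500)
        sub = out[out["cons_class"].str.match("gain:|loss:")]
        for row in dens.itertuples():
            w = (sub[f"pos_crub"] - 1) // 500 * 500 == row.window_start
            gains = sub.loc[w, "cons_class"].str.startswith("gain:").sum()
            total = int(w.sum())
            assert row.gains == gains and row.gains + row.losses == total


class TestGeneBodyAndFeatureRates:
    def _calls(self, rows):
        df = pd.DataFrame(
            rows, columns=["chrom", "pos", "context", "rate", "testable", "is_methylated"]
        )
        return df

    def test_gene_body_fraction(self):
        rows = [("chr1", p, "CG", 0.5, True, p <= 50) for p in range(10, 210, 10)]
        calls = self._calls(rows)
        # gene spans bases [0, 200): 20 testable CG, 5 methylated
        assert comparative.gene_body_methylation(0, 200, "chr1", calls) == 0.25

    def test_gene_without_testable_cg_undefined(self):
        calls = self._calls([("chr1", 10, "CHH", 0.5, True, True)])
        assert np.isnan(comparative.gene_body_methylation(0, 100, "chr1", calls))

    def test_feature_rate_includes_zeros(self):
        calls = self._calls(
            [("chr1", p, "CG", r, True, r > 0.5) for p, r in
             [(10, 0.0), (20, 0.0), (30, 1.0), (40, 1.0)]]
        )
        feats = [GenomicFeature("chr1", 0, 100, "+", "gene", "g1")]
        assert comparative.feature_methylation_rate(feats, calls, "CG") == 0.5

    def test_empty_feature_undefined_and_normalization(self):
        calls = self._calls([("chr1", 10, "CG", 0.6, True, True)])
        feats = [GenomicFeature("chr2", 0, 100, "+", "gene", "g1")]
        assert np.isnan(comparative.feature_methylation_rate(feats, calls, "CG"))
        feats2 = [GenomicFeature("chr1", 0, 100, "+", "gene", "g1")]
        assert comparative.feature_methylation_rate(
            feats2, calls, "CG", normalize_to=0.3
        ) == pytest.approx(2.0)


class TestAnnotate:
    FEATS = [
        GenomicFeature("chr1", 100, 200, "+", "exon", "g1"),
        GenomicFeature("chr1", 200, 300, "+", "intron", "g1"),
        GenomicFeature("chr1", 220, 240, "+", "TE"),
        GenomicFeature("chr1", 400, 500, "+", "upstream1kb", "g2"),
    ]

    def test_precedence_te_over_intron(self):
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [150, 230, 260]})
        labels = comparative.annotate_sites(sites, self.FEATS)
        assert list(labels) == ["exon", "TE", "intron"]

    def test_outside_all_features_is_intergenic(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [1000, 50]})
        assert list(comparative.annotate_sites(sites, self.FEATS)) == [
            "intergenic", "intergenic",
        ]

    def test_every_site_gets_exactly_one_label(self):
        rng = np.random.default_rng(53)
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(1, 600, size=200)}
        )
        labels = comparative.annotate_sites(sites, self.FEATS)
        assert len(labels) == 200 and labels.notna().all()


class TestOrthologOverlap:
    def _setup(self, seed=54, n=100):
        rng = np.random.default_rng(seed)
        orthologs = pd.DataFrame(
            {sp: [f"{sp}_g{i}" for i in range(n)] for sp in SPECIES}
        )
        genes = {}
        regions = {}
        for sp in SPECIES:
            genes[sp] = pd.DataFrame(
                {
                    "gene_id": orthologs[sp],
                    "chrom": "chr1",
                    "start": np.arange(n) * 1000,
                    "end": np.arange(n) * 1000 + 500,
                }
            )
            picks = rng.choice(n, size=10, replace=False)
            regions[sp] = [Region("chr1", int(i * 1000 + 10), int(i * 1000 + 20)) for i in picks]
        return orthologs, genes, regions

    def test_pairwise_p_matches_tail_oracle(self):
        orthologs, genes, regions = self._setup()
        rep = comparative.ortholog_overlap_tests(
            regions, orthologs, genes, n_permutations=10, seed=1
        )
        for row in rep.pairwise.itertuples():
            Ka = rep.per_species_counts[row.species_a]
            nb = rep.per_species_counts[row.species_b]
            oracle = diagnostics.hypergeom_tail_oracle(row.observed, 100, Ka, nb)
            assert row.p_hypergeom == pytest.approx(oracle, abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        p = float(stats.hypergeom.sf(-1, 100, 1, 1))
        assert p == 1.0

    def test_identical_regions_everywhere_exceed_permutations(self):
        orthologs, genes, _ = self._setup()
        shared = [Region("chr1", 10, 20), Region("chr1", 1010, 1020)]
        regions = {sp: shared for sp in SPECIES}
        rep = comparative.ortholog_overlap_tests(
            regions, orthologs, genes, n_permutations=200, seed=2
        )
        assert rep.observed_three_way == 2
        assert rep.perm_max_three_way <= rep.observed_three_way

    def test_permutation_reproducible_under_seed(self):
        orthologs, genes, regions = self._setup()
        a = comparative.ortholog_overlap_tests(
            regions, orthologs, genes, n_permutations=50, seed=3
        )
        b = comparative.ortholog_overlap_tests(
            regions, orthologs, genes, n_permutations=50, seed=3
        )
        assert (a.perm_max_two_way, a.perm_max_three_way) == (
            b.perm_max_two_way, b.perm_max_three_way,
        )

    def test_requires_positive_permutations(self):
        orthologs, genes, regions = self._setup()
        with pytest.raises(ValueError):
            comparative.ortholog_overlap_tests(
                regions, orthologs, genes, n_permutations=0
            )
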