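"""CAZyme filtering, summaries, architectures and differential features."""

import numpy as np
import pandas as pd
import pytest

from magforge import cazyme_profiling as cz
from magforge.errors import MagforgeError


def _hits(rows):
    return pd.DataFrame(rows, columns=["gene_id", "family", "clazz",
                                       "qstart", "qend", "evalue",
                                       "query_coverage"])


class TestFilterDomainHits:
    @pytest.mark.parametrize("evalue, coverage, kept", [
        (1e-10, 0.9, False),   # fails the e-value gate
        (1e-20, 0.30, False),  # fails the coverage gate
        (1e-20, 0.50, True),   # passes both
        (1e-15, 0.35, True),   # inclusive boundaries
    ])
    def test_gates(self, evalue, coverage, kept):
        hits = _hits([("g1", "GH5", "GH", 1, 100, evalue, coverage)])
        assert len(cz.filter_domain_hits(hits)) == (1 if kept else 0)

    def test_overlap_resolution_keeps_lower_evalue(self):
        hits = _hits([
            ("g1", "GH5", "GH", 1, 100, 1e-30, 0.9),
            ("g1", "GH6", "GH", 40, 140, 1e-20, 0.9),   # >50% overlap, worse
            ("g1", "CBM4", "CBM", 150, 250, 1e-25, 0.9),
        ])
        out = cz.filter_domain_hits(hits)
        assert sorted(out["family"]) == ["CBM4", "GH5"]

    def test_small_overlap_retained(self):
        hits = _hits([
            ("g1", "GH5", "GH", 1, 100, 1e-30, 0.9),
            ("g1", "GH6", "GH", 60, 200, 1e-20, 0.9),  # 41/100 < 50% of shorter
        ])
        assert len(cz.filter_domain_hits(hits)) == 2

    def test_idempotent(self, complete_community):
        _, bundle, _ = complete_community
        once = cz.filter_domain_hits(bundle.domains)
        twice = cz.filter_domain_hits(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSummaries:
    def test_density_arithmetic(self):
        hits = _hits([(f"g{i}", "GH5", "GH", 1, 100, 1e-30, 0.9)
                      for i in range(50)])
        sizes = pd.Series({"A": 2_000_000})
        g2g = pd.Series({f"g{i}": "A" for i in range(50)})
        summary = cz.summarize_cazymes(hits, sizes, g2g)
        assert summary.per_genome.loc["A", ("per_mb", "GH")] == 25.0

    def test_genome_without_cazymes_has_zero_density(self):
        hits = _hits([("g0", "GH5", "GH", 1, 100, 1e-30, 0.9)])
        sizes = pd.Series({"A": 1e6, "B": 1e6})
        summary = cz.summarize_cazymes(hits, sizes, pd.Series({"g0": "A"}))
        assert (summary.per_genome.loc["B", "per_mb"] == 0).all()

    def test_group_mean_density(self):
        hits = _hits([(f"a{i}", "GH5", "GH", 1, 100, 1e-30, 0.9)
                      for i in range(10)]
                     + [(f"b{i}", "GH5", "GH", 1, 100, 1e-30, 0.9)
                        for i in range(30)])
        sizes = pd.Series({"A": 1e6, "B": 1e6})
        g2g = pd.Series({**{f"a{i}": "A" for i in range(10)},
                         **{f"b{i}": "B" for i in range(30)}})
        summary = cz.summarize_cazymes(hits, sizes, g2g,
                                       grouping={"A": "T", "B": "T"})
        assert summary.per_group.loc["T", "GH"] == 20.0

    def test_class_fractions_sum_to_one(self, complete_community):
        _, bundle, _ = complete_community
        filtered = cz.filter_domain_hits(bundle.domains)
        g2g = bundle.genes.set_index("gene_id")["genome_id"]
        summary = cz.summarize_cazymes(filtered, bundle.genome_sizes(), g2g)
        assert summary.class_fractions["domain_fraction"].sum() == \
            pytest.approx(1.0)
        assert summary.class_fractions["gene_fraction"].sum() == \
            pytest.approx(1.0)

    def test_zero_size_genome_rejected(self):
        with pytest.raises(MagforgeError):
            cz.summarize_cazymes(_hits([]), pd.Series({"A": 0}), pd.Series())


class TestArchitectures:
    def test_appended_fraction(self):
        # 10 CBM48 domains, 4 on proteins that also carry GH13_9
        rows = [(f"m{i}", "CBM48", "CBM", 1, 100, 1e-30, 0.9)
                for i in range(10)]
        rows += [(f"m{i}", "GH13_9", "GH", 120, 220, 1e-30, 0.9)
                 for i in range(4)]
        report = cz.modular_architectures(_hits(rows))
        assert report.multidomain_genes == [f"m{i}" for i in range(4)]
        cooc = report.cooccurrence.set_index(["family_a", "family_b"])
        assert cooc.loc[("CBM48", "GH13_9"), "appended_fraction"] == \
            pytest.approx(0.4)

    def test_single_domain_gene_excluded(self):
        report = cz.modular_architectures(
            _hits([("g1", "GH5", "GH", 1, 100, 1e-30, 0.9)]))
        assert report.multidomain_genes == []

    def test_tandem_cohesins_flag_scaffoldin(self):
        rows = [("s1", "cohesin", "cohesin", 1 + i * 150, 100 + i * 150,
                 1e-30, 0.9) for i in range(3)]
        rows.append(("s2", "cohesin", "cohesin", 1, 100, 1e-30, 0.9))
        report = cz.modular_architectures(_hits(rows))
        assert report.scaffoldin_candidates == ["s1"]

    def test_planted_structures_recovered(self, complete_community):
        _, bundle, truth = complete_community
        filtered = cz.filter_domain_hits(bundle.domains)
        report = cz.modular_architectures(filtered)
        assert truth.scaffoldin_genes == set(report.scaffoldin_candidates)
        assert truth.multidomain_genes <= set(report.multidomain_genes)


class TestSecretory:
    @pytest.mark.parametrize("n_flagged, expected", [(4, 0.4), (0, 0.0),
                                                     (10, 1.0)])
    def test_fractions(self, n_flagged, expected):
        hits = _hits([(f"g{i}", "GH5", "GH", 1, 100, 1e-30, 0.9)
                      for i in range(10)])
        signals = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n_flagged)],
            "secretory": [True] * n_flagged,
            "mode": ["either"] * n_flagged})
        g2g = pd.Series({f"g{i}": "A" for i in range(10)})
        out = cz.secretory_fractions(hits, signals, g2g)
        assert out.set_index("unit").loc["A", "fraction"] == \
            pytest.approx(expected)

    def test_planted_secretory_genes_recovered(self, complete_community):
        _, bundle, truth = complete_community
        filtered = cz.filter_domain_hits(bundle.domains)
        flagged = set(bundle.signals[bundle.signals["secretory"]]["gene_id"])
        caz_genes = set(filtered["gene_id"])
        assert flagged & caz_genes == truth.secretory_genes & caz_genes


class TestDifferentialFeatures:
    def test_tpm_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(30, 8)) + 1)
        lengths = pd.Series(rng.integers(300, 3000, size=30),
                            index=counts.index)
        tpm = cz.tpm_normalize(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_planted_enriched_feature_detected(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(100, size=(20, 16)).astype(float),
            index=[f"f{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(16)])
        counts.iloc[0, 8:] *= 8
        lengths = pd.Series(1000, index=counts.index)
        groups = pd.Series(["x"] * 8 + ["y"] * 8, index=counts.columns)
        out = cz.differential_features(counts, lengths, groups)
        row = out.set_index("feature").loc["f0"]
        assert row["significant"]
        assert row["tpm_mean_y"] > row["tpm_mean_x"]

    def test_undersized_group_rejected(self):
        counts = pd.DataFrame(np.ones((5, 3)),
                              columns=["s1", "s2", "s3"])
        groups = pd.Series(["x", "x", "y"], index=counts.columns)
        with pytest.raises(MagforgeError):
            cz.differential_features(counts, pd.Series(1000,
                                                       index=counts.index),
                                     groups)


class TestBGCSummary:
    def test_counts_and_frequencies(self):
        bgc = pd.DataFrame({
            "genome_id": ["a", "a", "b", "c"],
            "cluster_id": ["c1", "c2", "c3", "c4"],
            "bgc_family": ["NRPS", "NRPS", "NRPS", "terpene"]})
        grouping = {"a": "X", "b": "X", "c": "Y"}
        table, freqs = cz.summarize_bgcs(bgc, grouping)
        assert table.loc["NRPS", "X"] == 3
        assert freqs["NRPS"] == pytest.approx(0.75)
        assert freqs.sum() == pytest.approx(1.0)

    def test_empty_table(self):
        table, freqs = cz.summarize_bgcs(pd.DataFrame(
            columns=["genome_id", "cluster_id", "bgc_family"]), {})
        assert table.empty and freqs.empty
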