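"""Generator contracts: determinism, geometry, surface values, count model,
ground-truth consistency and on-disk round trips."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regenmeth.exceptions import ContextError, SizingError, ValidationError
from regenmeth.meth_io import read_cytosine_report
from regenmeth.simulate import (
    SimConfig,
    _surface_vector,
    build_genome,
    generate_dataset,
    methylation_surface,
    read_gene_bed,
    sample_counts,
    write_dataset,
)


class TestConfig:
    def test_defaults_validate(self):
        SimConfig().validate()

    def test_rejects_decreasing_well_floors(self):
        with pytest.raises(ValidationError):
            SimConfig(well_floor_by_quartile=(0.5, 0.3, 0.2, 0.1)).validate()

    def test_rejects_out_of_range_probability(self):
        with pytest.raises(ValidationError):
            SimConfig(cpg_background_meth=1.2).validate()


class TestBuildGenome:
    def test_zero_genes_gives_background_only_sites(self):
        cfg = SimConfig(n_genes=0, chrom_length=50_000)
        genes, sites = build_genome(cfg, np.random.default_rng(0))
        assert genes.empty
        assert (sites["context"] == "CpG").sum() > 0

    def test_same_seed_is_byte_identical(self):
        cfg = SimConfig(n_genes=10, chrom_length=60_000)
        g1, s1 = build_genome(cfg, np.random.default_rng(42))
        g2, s2 = build_genome(cfg, np.random.default_rng(42))
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_island_cpg_count_matches_density_times_width(self):
        # 1 site / 10 bp over +/-250 bp -> ~50 sites per island
        cfg = SimConfig(n_genes=400, n_chromosomes=2, chrom_length=500_000,
                        cpg_island_density=0.1, cpg_background_density=0.02)
        genes, sites = build_genome(cfg, np.random.default_rng(7))
        cpg = sites[sites["context"] == "CpG"]
        counts = []
        for _, g in genes.iterrows():
            sub = cpg[(cpg["chrom"] == g["chrom"])
                      & (abs(cpg["pos"] - g["tss"]) <= 250)]
            counts.append(len(sub))
        mean = np.mean(counts)
        expected = 0.1 * 501
        tol = 3 * np.sqrt(expected / len(genes))  # Poisson error of the mean
        assert mean == pytest.approx(expected, abs=tol)

    def test_context_consistent_with_trinucleotide(self):
        from regenmeth.meth_io import classify_context

        cfg = SimConfig(n_genes=5, chrom_length=30_000)
        _, sites = build_genome(cfg, np.random.default_rng(1))
        sample = sites.sample(200, random_state=0)
        assert all(
            classify_context(t) == c
            for t, c in zip(sample["trinucleotide"], sample["context"])
        )

    def test_overfull_chromosome_raises(self):
        cfg = SimConfig(n_genes=100, chrom_length=10_000, n_chromosomes=1)
        with pytest.raises(SizingError):
            build_genome(cfg, np.random.default_rng(0))


class TestMethylationSurface:
    CFG = SimConfig()

    def test_far_field_is_background(self):
        gene = {"tss": 50_000, "strand": "+", "chrom": "chr1"}
        p = methylation_surface(gene, 40_000, "CpG", "regenerative_control", self.CFG,
                                quartile="Q1")
        assert p == pytest.approx(self.CFG.cpg_background_meth)

    def test_tss_of_unaffected_q1_gene_is_near_floor(self):
        gene = {"tss": 50_000, "strand": "+", "chrom": "chr1"}
        p = methylation_surface(gene, 50_000, "CpG", "regenerative_control", self.CFG,
                                quartile="Q1")
        assert p <= self.CFG.well_floor_by_quartile[0] + 0.1 + 1e-12

    def test_noncpg_is_baseline_times_injury_multiplier(self):
        p = methylation_surface(None, 1000, "CHH", "regenerative_injured", self.CFG)
        assert p == pytest.approx(0.010 * 2.8)
        p = methylation_surface(None, 1000, "CHG", "regenerative_control", self.CFG)
        assert p == pytest.approx(0.010)

    def test_well_floors_order_the_surface(self):
        gene = {"tss": 50_000, "strand": "+", "chrom": "chr1"}
        depths = [
            methylation_surface(gene, 50_400, "CpG", "regenerative_control", self.CFG,
                                quartile=q)
            for q in ("Q1", "Q2", "Q3", "Q4")
        ]
        assert depths == sorted(depths)

    def test_promoter_effect_applies_only_when_injured(self):
        gene = {"tss": 50_000, "strand": "+", "chrom": "chr1"}
        kwargs = dict(quartile="Q2", effect_sign=1)
        ctl = methylation_surface(gene, 50_000, "CpG", "regenerative_control",
                                  self.CFG, **kwargs)
        inj = methylation_surface(gene, 50_000, "CpG", "regenerative_injured",
                                  self.CFG, **kwargs)
        assert inj > ctl

    def test_unknown_context_rejected(self):
        with pytest.raises(ContextError):
            methylation_surface(None, 0, "CNN", "regenerative_control", self.CFG)


class TestSampleCounts:
    def test_poisson_coverage_mean(self):
        cfg = SimConfig(n_replicates=1)
        rng = np.random.default_rng(2)
        _, total = sample_counts(np.full(100_000, 0.5), cfg, rng)
        assert total.mean() == pytest.approx(15.0, abs=0.05)

    def test_large_coverage_recovers_probability(self):
        cfg = SimConfig(coverage_mean=5000, n_replicates=1, replicate_dispersion=0.0)
        rng = np.random.default_rng(3)
        meth, total = sample_counts(np.full(200, 0.5), cfg, rng)
        assert (meth.sum() / total.sum()) == pytest.approx(0.5, abs=0.01)

    def test_dispersion_inflates_across_replicate_variance(self):
        # beta-binomial variance factor (1 + (n-1)phi) vs plain binomial
        rng = np.random.default_rng(4)
        cfg0 = SimConfig(replicate_dispersion=0.0, n_replicates=1, coverage_mean=50)
        cfg1 = SimConfig(replicate_dispersion=0.05, n_replicates=1, coverage_mean=50)
        m0, t0 = sample_counts(np.full(30_000, 0.5), cfg0, rng)
        m1, t1 = sample_counts(np.full(30_000, 0.5), cfg1, rng)
        v0 = np.var(m0[t0 > 0] / t0[t0 > 0])
        v1 = np.var(m1[t1 > 0] / t1[t1 > 0])
        assert v1 > 1.5 * v0

    def test_meth_never_exceeds_total(self, small_dataset):
        for t in small_dataset.samples[:2]:
            assert (t.df["meth"] + t.df["unmeth"] >= 0).all()
            assert (t.df["meth"] <= t.df["meth"] + t.df["unmeth"]).all()


class TestGroundTruth:
    def test_hyper_fraction_within_exact_binomial_bounds(self, small_dataset):
        truth = small_dataset.truth
        affected = truth[truth["effect_sign"] != 0]
        k = int((affected["effect_sign"] == 1).sum())
        res = stats.binomtest(k, len(affected), small_dataset.config.hyper_fraction)
        assert res.pvalue >= 0.01

    def test_every_gene_appears_exactly_once(self, small_dataset):
        assert small_dataset.truth["gene_id"].is_unique
        assert len(small_dataset.truth) == len(small_dataset.genes)

    def test_zero_coupling_keeps_de_independent_of_effect(self):
        cfg = SimConfig(n_genes=40, chrom_length=120_000, dmr_de_coupling=0.0, seed=5)
        ds = generate_dataset(cfg)
        t = ds.truth
        de_given_affected = (t[t["effect_sign"] != 0]["de_direction"] != "none").mean()
        de_overall = (t["de_direction"] != "none").mean()
        assert abs(de_given_affected - de_overall) < 0.35  # loose, small n

    def test_full_coupling_forces_concordant_de(self):
        cfg = SimConfig(n_genes=40, chrom_length=120_000, dmr_de_coupling=1.0, seed=5)
        ds = generate_dataset(cfg)
        t = ds.truth
        hyper = t[t["effect_sign"] == 1]
        assert (hyper["de_direction"] == "up").all()


class TestSurfaceRecovery:
    def test_control_cpg_percent_recovers_surface_average(self, small_dataset):
        """Measured genome-wide %CpG of a control regenerative replicate
        matches the coverage-independent surface mean within 0.5 points."""
        cfg = small_dataset.config
        sites = pd.concat(
            [
                small_dataset.samples[0].df.loc[lambda d: (d["context"] == "CpG")
                                                & (d["strand"] == "+"),
                                                ["chrom", "pos", "context"]],
            ],
            ignore_index=True,
        )
        sites["strand"] = "+"
        sites["trinucleotide"] = "CGA"
        expected = _surface_vector(
            sites, small_dataset.genes, small_dataset.truth,
            "regenerative_control", cfg,
        ).mean() * 100
        df = small_dataset.samples[0].df
        cpg = df[df["context"] == "CpG"]
        measured = 100 * cpg["meth"].sum() / (cpg["meth"].sum() + cpg["unmeth"].sum())
        assert measured == pytest.approx(expected, abs=0.5)

    def test_noncpg_tissue_ratio_recovered(self, small_dataset):
        def noncpg_pct(condition):
            t = [s for s in small_dataset.samples if s.condition == condition][0]
            sub = t.df[t.df["context"] != "CpG"]
            return sub["meth"].sum() / (sub["meth"].sum() + sub["unmeth"].sum())

        ratio = noncpg_pct("nonregenerative_control") / noncpg_pct("regenerative_control")
        expected = 0.028 / 0.010
        assert ratio == pytest.approx(expected, rel=0.10)


class TestWriteDataset:
    def test_round_trip_through_meth_io(self, small_dataset, tmp_path):
        write_dataset(small_dataset, tmp_path)
        sample = small_dataset.samples[0]
        back = read_cytosine_report(
            tmp_path / f"{sample.sample_id}.CpG_report.txt",
            sample.sample_id, sample.condition,
        )
        pd.testing.assert_frame_equal(back.df, sample.df)

    def test_manifest_seed_reproduces_identical_files(self, tmp_path):
        cfg = SimConfig(n_genes=8, chrom_length=40_000, seed=13)
        m1 = write_dataset(generate_dataset(cfg), tmp_path / "a")
        m2 = write_dataset(generate_dataset(SimConfig(**{**cfg.__dict__})), tmp_path / "b")
        assert m1["seed"] == 13
        assert m1["files"] == m2["files"]  # identical sha256 for every file

    def test_bed_has_one_record_per_gene(self, tmp_path):
        cfg = SimConfig(n_genes=8, chrom_length=40_000, seed=13)
        ds = generate_dataset(cfg)
        write_dataset(ds, tmp_path)
        bed = read_gene_bed(tmp_path / "genes.bed")
        assert len(bed) == 8
        pd.testing.assert_frame_equal(
            bed, ds.genes[["gene_id", "chrom", "strand", "tss"]], check_dtype=False
        )

    def test_manifest_config_echo_is_json(self, small_dataset, tmp_path):
        write_dataset(small_dataset, tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["config"]["n_genes"] == small_dataset.config.n_genes
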