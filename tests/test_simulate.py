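import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from lofburden.genes import read_gff3
from lofburden.simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_dataset,
    simulate_expression,
    simulate_gene_annotation,
    simulate_heterogeneity_study,
    simulate_lof_variants,
    simulate_population,
    write_vcf,
)


class TestConfigValidation:
    def test_too_many_subpops_rejected(self):
        with pytest.raises(ValueError, match="n_subpops"):
            SimulationConfig(n_accessions=5, n_subpops=10).validate()

    def test_bad_h2_rejected(self):
        with pytest.raises(ValueError, match="h2"):
            SimulationConfig(h2=1.5).validate()

    def test_improper_distribution_rejected(self):
        with pytest.raises(ValueError, match="proper"):
            SimulationConfig(transcripts_per_gene={1: 0.5}).validate()


class TestPopulation:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_accessions=50, n_snps=100, seed=7)
        G1, l1, K1 = simulate_population(cfg)
        G2, l2, K2 = simulate_population(cfg)
        pd.testing.assert_frame_equal(G1, G2)
        pd.testing.assert_frame_equal(K1, K2)

    def test_no_structure_when_divergence_zero(self):
        """With one panmictic population, between-half allele-frequency
        differences collapse to binomial sampling noise."""
        cfg = SimulationConfig(n_accessions=400, n_snps=500, n_subpops=1,
                               fst_like_divergence=0.0, seed=1)
        G, _, _ = simulate_population(cfg)
        half = 200
        f1 = G.iloc[:half].mean(axis=0) / 2
        f2 = G.iloc[half:].mean(axis=0) / 2
        pooled = G.mean(axis=0) / 2
        expected_sd = np.sqrt(2 * pooled * (1 - pooled) / half)
        z = (f1 - f2) / expected_sd.replace(0, np.nan)
        assert abs(z.std() - 1.0) < 0.15

    def test_two_subpops_separate_on_pc1(self):
        cfg = SimulationConfig(n_accessions=200, n_snps=1000, n_subpops=2,
                               fst_like_divergence=0.3, seed=2)
        G, labels, _ = simulate_population(cfg)
        X = G.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        pc1 = Xc @ Vt[0]
        assert silhouette_score(pc1[:, None], labels.to_numpy()) > 0.5

    def test_genotypes_are_homozygous_codes(self):
        G, _, _ = simulate_population(SimulationConfig(n_accessions=30, n_snps=50, seed=3))
        assert set(np.unique(G.to_numpy())) <= {0, 2}


class TestGeneAnnotation:
    def test_gene_spans_pairwise_disjoint(self):
        cfg = SimulationConfig(n_genes=500, n_chromosomes=5, n_expressed_genes=50, seed=4)
        genes = simulate_gene_annotation(cfg)
        by_chrom = {}
        for g in genes.values():
            by_chrom.setdefault(g.chromosome, []).append(g.span)
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_cds_lengths_divisible_by_three(self):
        genes = simulate_gene_annotation(SimulationConfig(n_genes=50, n_expressed_genes=10, seed=5))
        for g in genes.values():
            for t in g.transcripts:
                assert t.spliced_cds_length % 3 == 0

    def test_round_trips_through_gff3(self, tmp_path):
        from lofburden.genes import write_gff3

        cfg = SimulationConfig(n_genes=30, n_expressed_genes=10, seed=6)
        genes = simulate_gene_annotation(cfg)
        path = tmp_path / "g.gff3"
        write_gff3(genes.values(), str(path))
        back = read_gff3(str(path))
        assert set(back) == set(genes)
        for gid in genes:
            assert [t.cds_intervals for t in back[gid].transcripts] == [
                t.cds_intervals for t in genes[gid].transcripts
            ]

    def test_multi_transcript_genes_share_gene_id(self):
        cfg = SimulationConfig(n_genes=60, n_expressed_genes=10, transcripts_per_gene={2: 1.0}, seed=7)
        genes = simulate_gene_annotation(cfg)
        for g in genes.values():
            assert len(g.transcripts) == 2
            assert all(t.transcript_id.startswith(g.gene_id) for t in g.transcripts)


class TestLofVariants:
    def test_truth_burden_is_or_of_carriers(self):
        cfg = SimulationConfig(n_accessions=100, n_genes=60, n_expressed_genes=10, seed=8)
        genes = simulate_gene_annotation(cfg)
        acc = [f"acc{i:04d}" for i in range(100)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            variants, truth = simulate_lof_variants(genes, acc, cfg)
        lof = truth.variant_truth[truth.variant_truth["is_lof"]]
        for gid in truth.true_burden.columns:
            vids = lof[lof["gene_id"] == gid]["variant_id"]
            expected = np.zeros(100, dtype=np.int8)
            for vid in vids:
                expected |= truth.variant_carriers[vid].astype(np.int8)
            np.testing.assert_array_equal(truth.true_burden[gid].to_numpy(), expected)

    def test_class_proportions_realized(self):
        """Requested annotation-class shares are matched within 2 points."""
        cfg = SimulationConfig(
            n_accessions=50, n_genes=3000, n_chromosomes=5, n_expressed_genes=10,
            lof_alleles_per_gene={3: 1.0}, decoy_rate=0.0,
            class_proportions={"frameshift_variant": 0.45, "stop_gained": 0.25,
                               "stop_lost": 0.30},
            seed=9,
        )
        genes = simulate_gene_annotation(cfg)
        acc = [f"acc{i:04d}" for i in range(50)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            variants, _ = simulate_lof_variants(genes, acc, cfg)
        notes = pd.Series([v.truth_note.split(":")[-1] for v in variants])
        frac = notes.value_counts(normalize=True)
        assert abs(frac["frameshift_variant"] - 0.45) < 0.02
        assert abs(frac["stop_gained"] - 0.25) < 0.02

    def test_monomorphic_request_warns_and_excluded(self):
        cfg = SimulationConfig(
            n_accessions=20, n_genes=30, n_expressed_genes=5, lof_alleles_per_gene={1: 1.0},
            lof_freq_beta=(0.05, 200.0), decoy_rate=0.0, seed=10,
        )
        genes = simulate_gene_annotation(cfg)
        acc = [f"a{i}" for i in range(20)]
        with pytest.warns(UserWarning, match="zero carriers"):
            variants, truth = simulate_lof_variants(genes, acc, cfg)
        mono = truth.variant_truth[truth.variant_truth["note"].str.startswith("monomorphic")]
        assert len(mono) > 0
        assert not mono["is_lof"].any()


class TestExpression:
    def make_truth(self, n=200, seed=11, h2=0.3):
        cfg = SimulationConfig(n_accessions=n, n_snps=400, seed=seed, h2=h2)
        G, labels, K = simulate_population(cfg)
        rng = np.random.default_rng(seed)
        burden = pd.DataFrame(
            (rng.random((n, 5)) < 0.2).astype(np.int8),
            index=G.index, columns=[f"g{j}" for j in range(5)],
        )
        truth = GroundTruth(
            true_burden=burden, variant_carriers={}, variant_truth=pd.DataFrame(),
            true_effects=[], variance_components={}, realized_h2={},
            subpop_labels=labels,
        )
        return cfg, truth, K

    def test_deterministic_under_seed(self):
        cfg, truth, K = self.make_truth()
        e1 = simulate_expression(truth, K, cfg, ["g0", "g1"], [])
        e2 = simulate_expression(truth, K, cfg, ["g0", "g1"], [])
        pd.testing.assert_frame_equal(e1, e2)

    def test_h2_one_rejected(self):
        cfg, truth, K = self.make_truth(h2=1.0)
        with pytest.raises(ValueError, match="h2"):
            simulate_expression(truth, K, cfg, ["g0"], [])

    def test_unknown_causal_gene_rejected(self):
        cfg, truth, K = self.make_truth()
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_expression(truth, K, cfg, ["g0"], [("nope", "g0", 1.0)])

    def test_planted_effect_shifts_carriers(self):
        cfg, truth, K = self.make_truth(h2=0.2)
        expr = simulate_expression(truth, K, cfg, ["g1"], [("g0", "g1", 3.0)])
        x = truth.true_burden["g0"].astype(bool)
        y = expr["g1"]
        assert y[x].mean() - y[~x].mean() > 1.0

    def test_heritability_targeting_across_replicates(self):
        """Mean realized var(u)/(var(u)+var(e)) tracks the configured h2."""
        for h2 in (0.2, 0.6):
            realized = []
            for seed in range(25):
                cfg, truth, K = self.make_truth(n=500, seed=100 + seed, h2=h2)
                simulate_expression(truth, K, cfg, ["g0"], [])
                realized.append(truth.realized_h2["g0"])
            assert abs(np.mean(realized) - h2) < 0.05


class TestHeterogeneityStudy:
    def test_alleles_are_disjoint_and_burden_is_union(self):
        study = simulate_heterogeneity_study(seed=0)
        for gid in study.collapsed.columns:
            alleles = [a for a, g in study.allele_of.items() if g == gid]
            stack = study.uncollapsed[alleles].to_numpy()
            assert (stack.sum(axis=1) <= 1).all()  # mutually exclusive carriers
            np.testing.assert_array_equal(
                study.collapsed[gid].to_numpy(), stack.max(axis=1)
            )
            assert study.collapsed[gid].mean() == pytest.approx(0.08, abs=1e-9)


class TestDatasetBundle:
    def test_files_written_and_deterministic(self, small_dataset, tmp_path):
        ds, out = small_dataset
        for fname in ["variants.vcf", "deletions.tsv", "deletions.vcf",
                      "genes.gff3", "genotypes.tsv", "kinship.tsv",
                      "expression.tsv", "true_burden.tsv", "truth.json"]:
            assert (out / fname).exists()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds2 = simulate_dataset(ds.config)
        pd.testing.assert_frame_equal(ds.truth.true_burden, ds2.truth.true_burden)
        pd.testing.assert_frame_equal(ds.expression, ds2.expression)

    def test_deletion_tsv_and_vcf_agree(self, small_dataset):
        from cyvcf2 import VCF

        from lofburden.annotation import read_deletions_tsv, read_deletions_vcf

        ds, out = small_dataset
        acc = list(VCF(str(out / "deletions.vcf")).samples)
        tsv = {d.variant_id: d for d in read_deletions_tsv(str(out / "deletions.tsv"), acc)}
        vcf = {d.variant_id: d for d in read_deletions_vcf(str(out / "deletions.vcf"))}
        assert set(tsv) == set(vcf)
        for vid in tsv:
            assert tsv[vid].interval == vcf[vid].interval
            np.testing.assert_array_equal(tsv[vid].carriers, vcf[vid].carriers)
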