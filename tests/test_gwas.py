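"""VCF parsing, QC filters, meta-analysis arithmetic and the two-mode scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fedres.glm import GLMSpec, fit_irls
from fedres.gwas import (
    GenotypeStudy,
    GwasError,
    Variant,
    gwas_scan,
    meta_fixed_effect,
    read_vcf_genotypes,
    results_to_frame,
    variant_filters,
    write_vcf_genotypes,
)
from fedres.synthetic import default_genotype_truth, gen_genotype_study
from tests.conftest import build_session

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
)


def write_vcf_text(tmp_path, body, name="t.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestVcfReading:
    def test_dosage_is_the_alt_allele_count(self, tmp_path):
        path = write_vcf_text(tmp_path, "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
        study = read_vcf_genotypes(path)
        assert study.samples == ["S1", "S2", "S3"]
        assert study.dosages[:, 0].tolist() == [0.0, 1.0, 2.0]

    def test_missing_and_phased_calls(self, tmp_path):
        path = write_vcf_text(tmp_path, "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t./.\t0|1\t1|1\n")
        study = read_vcf_genotypes(path)
        assert np.isnan(study.dosages[0, 0])
        assert study.dosages[1, 0] == 1.0  # phase is ignored
        assert study.dosages[2, 0] == 2.0

    def test_multiallelic_record_rejected_by_name(self, tmp_path):
        path = write_vcf_text(tmp_path, "1\t150\trs9\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
        with pytest.raises(GwasError, match="1:150"):
            read_vcf_genotypes(path)

    def test_record_without_gt_rejected(self, tmp_path):
        body = "1\t100\trs1\tA\tG\t.\t.\t.\tDP\t3\t5\t7\n"
        path = tmp_path / "nogt.vcf"
        path.write_text(
            VCF_HEADER.replace(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
            )
            + body
        )
        with pytest.raises(GwasError, match="GT"):
            read_vcf_genotypes(path)

    def test_write_read_round_trip(self, tmp_path):
        import dataclasses

        truth = dataclasses.replace(
            default_genotype_truth(seed=1, n_variants=30, n_causal=2),
            geno_missing_rate=0.05,
        )
        (study, _pheno), = gen_genotype_study((40,), 30, truth)
        path = write_vcf_genotypes(study, tmp_path / "rt.vcf")
        reread = read_vcf_genotypes(path)
        assert reread.samples == study.samples
        assert [v.id for v in reread.variants] == [v.id for v in study.variants]
        np.testing.assert_array_equal(reread.dosages, study.dosages)


class TestVariantFilters:
    def test_monomorphic_variant_removed(self):
        study = GenotypeStudy(
            samples=["a", "b"],
            variants=[Variant("1", 1, "A", "G", "rs1"), Variant("1", 2, "A", "G", "rs2")],
            dosages=np.array([[0.0, 1.0], [0.0, 1.0]]),
        )
        kept = variant_filters(study, maf_min=0.01, missing_max=1.0)
        assert kept.variant_ids == ["rs2"]

    def test_noop_bounds_are_the_identity(self):
        truth = default_genotype_truth(seed=2, n_variants=25)
        (study, _), = gen_genotype_study((30,), 25, truth)
        kept = variant_filters(study, maf_min=0.0, missing_max=1.0)
        assert kept.variant_ids == study.variant_ids

    def test_keep_set_matches_brute_force(self):
        rng = np.random.default_rng(3)
        n, m = 80, 40
        dosages = rng.binomial(2, rng.uniform(0.0, 0.5, m), size=(n, m)).astype(float)
        dosages[rng.random((n, m)) < 0.1] = np.nan
        study = GenotypeStudy(
            samples=[f"s{i}" for i in range(n)],
            variants=[Variant("1", j + 1, "A", "G", f"rs{j}") for j in range(m)],
            dosages=dosages,
        )
        maf_min, missing_max = 0.05, 0.08
        kept = set(variant_filters(study, maf_min, missing_max).variant_ids)
        # brute force, one variant at a time
        expected = set()
        for j in range(m):
            col = dosages[:, j]
            called = col[~np.isnan(col)]
            freq = called.mean() / 2 if len(called) else 0.0
            maf = min(freq, 1 - freq)
            miss = np.isnan(col).mean()
            if maf >= maf_min and miss <= missing_max:
                expected.add(f"rs{j}")
        assert kept == expected

    def test_bad_bounds_rejected(self):
        study = GenotypeStudy(["a"], [Variant("1", 1, "A", "G", "rs1")], [[0.0]])
        with pytest.raises(GwasError):
            variant_filters(study, maf_min=0.7)


class TestMetaFixedEffect:
    def test_equal_weight_closed_form(self):
        beta, se, p = meta_fixed_effect([(1.0, 1.0), (3.0, 1.0)])
        assert beta == pytest.approx(2.0, abs=1e-12)
        assert se == pytest.approx(2.0**-0.5, abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_single_study_is_the_identity(self):
        beta, se, _ = meta_fixed_effect([(0.7, 0.2)])
        assert beta == pytest.approx(0.7, abs=1e-15)
        assert se == pytest.approx(0.2, abs=1e-15)

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(4)
        estimates = [(rng.normal(), float(rng.uniform(0.1, 2.0))) for _ in range(5)]
        beta, se, _ = meta_fixed_effect(estimates)
        w = [1.0 / s**2 for _, s in estimates]
        expected_beta = sum(wi * b for wi, (b, _) in zip(w, estimates)) / sum(w)
        assert beta == pytest.approx(expected_beta, abs=1e-12)
        assert se == pytest.approx(sum(w) ** -0.5, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(GwasError):
            meta_fixed_effect([])
        with pytest.raises(GwasError):
            meta_fixed_effect([(1.0, 0.0)])

    @settings(derandomize=True, max_examples=50)
    @given(
        estimates=st.lists(
            st.tuples(
                st.floats(-5, 5), st.floats(0.05, 3.0)
            ),
            min_size=2,
            max_size=8,
        )
    )
    def test_pooling_tightens_and_stays_in_the_hull(self, estimates):
        """Adding a study strictly shrinks the pooled SE, and the pooled
        estimate lies within the convex hull of the study estimates."""
        betas = [b for b, _ in estimates]
        pooled_beta, pooled_se, _ = meta_fixed_effect(estimates)
        assert min(betas) - 1e-9 <= pooled_beta <= max(betas) + 1e-9
        _, se_fewer, _ = meta_fixed_effect(estimates[:-1])
        assert pooled_se < se_fewer


def _geno_session(studies, **kwargs):
    return build_session([{"G": g, "P": p} for g, p in studies], **kwargs)


class TestScan:
    def test_single_node_federated_equals_local_scan(self):
        truth = default_genotype_truth(seed=5, n_variants=30, n_causal=2)
        studies = gen_genotype_study((120,), 30, truth)
        session = _geno_session(studies)
        rows = gwas_scan(session, GLMSpec("y ~ 1"), mode="federated")
        study, pheno = studies[0]
        for row in rows:
            if row.status != "ok":
                continue
            j = study.variant_ids.index(row.variant.id)
            d = study.dosages[:, j]
            mask = np.isfinite(d)
            X = np.column_stack([np.ones(mask.sum()), d[mask]])
            local = fit_irls(pheno["y"].to_numpy()[mask], X, "gaussian")
            assert row.beta == pytest.approx(local["coefficients"][1], rel=1e-8)
            assert row.se == pytest.approx(local["standard_errors"][1], rel=1e-8)

    def test_unharmonised_variant_lists_rejected(self):
        truth = default_genotype_truth(seed=6, n_variants=20)
        studies = gen_genotype_study((60, 60), 20, truth)
        g1, p1 = studies[1]
        studies[1] = (g1.subset_variants(np.arange(19)), p1)
        with pytest.raises(GwasError, match="harmonis"):
            gwas_scan(_geno_session(studies), GLMSpec("y ~ 1"), mode="meta")

    def test_rows_keep_variant_order_and_flag_filtered(self):
        truth = default_genotype_truth(seed=7, n_variants=40, n_causal=2)
        studies = gen_genotype_study((200, 200), 40, truth)
        session = _geno_session(studies)
        rows = gwas_scan(session, GLMSpec("y ~ 1"), mode="federated", maf_min=0.2)
        assert [r.variant.id for r in rows] == studies[0][0].variant_ids
        statuses = {r.status for r in rows}
        assert "filtered" in statuses and "ok" in statuses
        filtered = [r for r in rows if r.status == "filtered"]
        assert all(np.isnan(r.beta) for r in filtered)

    def test_cross_mode_agreement_on_causal_variants(self):
        truth = default_genotype_truth(seed=8, n_variants=60, n_causal=3)
        studies = gen_genotype_study((600, 600, 600), 60, truth)
        session = _geno_session(studies)
        fed = {r.variant.id: r.beta for r in gwas_scan(session, GLMSpec("y ~ 1"), mode="federated") if r.status == "ok"}
        meta = {r.variant.id: r.pooled_beta for r in gwas_scan(session, GLMSpec("y ~ 1"), mode="meta")}
        for vid in truth.causal_effects:
            assert meta[vid] == pytest.approx(fed[vid], rel=0.02)

    def test_results_table_columns(self):
        truth = default_genotype_truth(seed=9, n_variants=10)
        studies = gen_genotype_study((100,), 10, truth)
        rows = gwas_scan(_geno_session(studies), GLMSpec("y ~ 1"), mode="meta")
        frame = results_to_frame(rows)
        assert list(frame.columns) == ["chrom", "pos", "id", "beta", "se", "p", "n", "maf", "status", "k"]

    def test_invalid_mode_rejected(self):
        truth = default_genotype_truth(seed=9, n_variants=5)
        studies = gen_genotype_study((50,), 5, truth)
        with pytest.raises(GwasError, match="mode"):
            gwas_scan(_geno_session(studies), GLMSpec("y ~ 1"), mode="bayesian")
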