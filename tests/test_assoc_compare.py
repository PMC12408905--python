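"""QC filters, exact HWE test, GWAS OLS, permutation eQTL, agreement."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cfcomp as c
from cfcomp.assoc_compare import hwe_exact_p, inverse_normal_transform
from cfcomp.synthetic_data import MISSING

from conftest import toy_matrix


# ---------------------------------------------------------------------------
# Exact HWE test vs a full-enumeration rational-arithmetic oracle
# ---------------------------------------------------------------------------


def hwe_oracle(n_homref, n_het, n_homalt):
    """Exact-fraction enumeration of the conditional heterozygote distribution."""
    n = n_homref + n_het + n_homalt
    n_alt = n_het + 2 * n_homalt
    n_rare = min(n_alt, 2 * n - n_alt)
    denom = comb(2 * n, n_rare)
    probs = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        homr = (n_rare - h) // 2
        homc = n - h - homr
        if homc < 0:
            continue
        # multinomial genotype configurations carrying 2^h phased hets
        num = Fraction(
            comb(n, h) * comb(n - h, homr) * (2**h), denom
        )
        probs[h] = num
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHweExact:
    def test_symmetric_counts_give_high_p(self):
        p = hwe_exact_p(25, 50, 25)
        assert p == pytest.approx(hwe_oracle(25, 50, 25), abs=1e-9)
        assert p > 0.5

    def test_monomorphic_is_one(self):
        assert hwe_exact_p(100, 0, 0) == 1.0

    def test_all_heterozygote_extreme(self):
        p = hwe_exact_p(0, 100, 0)
        assert p == pytest.approx(hwe_oracle(0, 100, 0), rel=1e-6)
        assert p < 1e-5

    def test_matches_enumeration_on_all_small_triples(self):
        """Every count triple with total <= 20 agrees with the oracle."""
        for n in range(1, 21):
            for homr in range(n + 1):
                for het in range(n - homr + 1):
                    homa = n - homr - het
                    assert hwe_exact_p(homr, het, homa) == pytest.approx(
                        hwe_oracle(homr, het, homa), abs=1e-9
                    ), (homr, het, homa)

    def test_matches_enumeration_on_random_triples_up_to_50(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            homr = int(rng.integers(0, n + 1))
            het = int(rng.integers(0, n - homr + 1))
            homa = n - homr - het
            assert hwe_exact_p(homr, het, homa) == pytest.approx(
                hwe_oracle(homr, het, homa), abs=1e-9
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)


# ---------------------------------------------------------------------------
# Inverse-normal transform
# ---------------------------------------------------------------------------


class TestINT:
    def test_blom_offsets(self):
        x = np.array([3.0, 1.0, 2.0])
        got = inverse_normal_transform(x)
        exp = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        assert np.allclose(got, exp)

    def test_ties_get_average_rank_and_nan_preserved(self):
        x = np.array([1.0, 1.0, 5.0, np.nan])
        got = inverse_normal_transform(x)
        assert got[0] == got[1]
        assert np.isnan(got[3])


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


class TestQcFilter:
    def test_constructed_fixture_one_failure_per_rule(self):
        """6 SNPs: one fails each filter, three pass; the log attributes them."""
        n = 100
        rng = np.random.default_rng(1)

        def hwe_geno(p, size):
            return rng.binomial(2, p, size=size).astype(np.int8)

        cols = []
        # passers at MAF ~0.3
        for _ in range(3):
            cols.append(hwe_geno(0.3, n))
        # MAF failure: ~0.04 (may drift, enforce by construction)
        low = np.zeros(n, dtype=np.int8)
        low[:8] = 1  # MAF 0.04 exactly
        cols.append(low)
        # HWE failure: all heterozygotes at MAF 0.5
        cols.append(np.ones(n, dtype=np.int8))
        # missingness failure: 15% missing
        m = hwe_geno(0.3, n)
        m[:15] = MISSING
        cols.append(m)
        g = toy_matrix(np.column_stack(cols))
        kept, log = c.qc_filter(g)
        assert kept.n_variants == 3
        assert log["n_fail_maf"] == 1
        assert log["n_fail_hwe"] == 1
        assert log["n_fail_missing"] == 1

    def test_indels_and_multiallelic_set_aside(self):
        g = toy_matrix(
            np.ones((40, 2), dtype=int),
            vclass=["SNP", "INDEL"],
        )
        kept, log = c.qc_filter(g, maf_min=0.0, hwe_p_min=0.0, miss_max=1.0)
        assert log["n_not_snp"] == 1


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def gwas_cohort():
    return c.generate_cohort(300, 400, seed=70, genome_length=10**6)


class TestGwasLinear:
    def test_matches_statsmodels_ols_oracle(self, gwas_cohort):
        """Beta/SE/P equal an independent full-design OLS fit to 1e-8."""
        import statsmodels.api as sm

        truth = gwas_cohort
        g = truth.as_matrix()
        ph = c.generate_phenotypes(truth, [5], [0.4], 0.2, seed=71)
        covs = c.generate_covariates(300, truth.samples, seed=72)
        res = c.gwas_linear(g, ph.iloc[:, 0], covs, n_pcs=2)

        # oracle: rebuild the identical design and fit each SNP with statsmodels
        y = inverse_normal_transform(ph.iloc[:, 0].to_numpy())
        from cfcomp.assoc_compare import _build_covariates

        C, _ = _build_covariates(g, covs, 2, list(truth.samples))
        for j in [0, 5, 17, 123]:
            x = g.dosages[:, j].astype(float)
            X = np.column_stack([C, x])
            fit = sm.OLS(y, X).fit()
            row = res.table[res.table["pos"] == g.variants["pos"].iloc[j]].iloc[0]
            assert row["beta"] == pytest.approx(fit.params[-1], abs=1e-8)
            assert row["se"] == pytest.approx(fit.bse[-1], abs=1e-8)
            assert row["p"] == pytest.approx(fit.pvalues[-1], abs=1e-8)

    def test_per_snp_missing_matches_complete_case_oracle(self, gwas_cohort):
        import statsmodels.api as sm

        truth = gwas_cohort
        d = truth.genotypes.copy()
        d[:30, 7] = MISSING
        g = c.GenotypeMatrix(
            samples=list(truth.samples),
            variants=truth.variants[["chrom", "pos", "ref", "alt", "vclass", "multiallelic"]].copy(),
            dosages=d,
        )
        ph = c.generate_phenotypes(truth, [5], [0.4], 0.2, seed=73)
        res = c.gwas_linear(g, ph.iloc[:, 0], None, n_pcs=0)
        y = inverse_normal_transform(ph.iloc[:, 0].to_numpy())
        mask = d[:, 7] != MISSING
        X = np.column_stack([np.ones(mask.sum()), d[mask, 7].astype(float)])
        fit = sm.OLS(y[mask], X).fit()
        row = res.table[res.table["pos"] == g.variants["pos"].iloc[7]].iloc[0]
        assert row["beta"] == pytest.approx(fit.params[-1], abs=1e-8)
        assert row["n"] == mask.sum()

    def test_null_phenotype_p_uniform(self, gwas_cohort):
        ph = c.generate_phenotypes(gwas_cohort, [], [], 0.0, seed=74)
        res = c.gwas_linear(gwas_cohort.as_matrix(), ph.iloc[:, 0], None, n_pcs=0)
        assert stats.kstest(res.table["p"], "uniform").pvalue > 0.01
        frac = (res.table["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(res.table))
        assert abs(frac - 0.05) < 3 * se

    def test_planted_beta_recovered_against_matched_oracle(self):
        """Estimated beta agrees with the generating value after the
        inverse-normal transform, via a matched direct least-squares fit."""
        truth = c.generate_cohort(
            500, 100, maf_distribution=lambda rng, k: np.full(k, 0.3), seed=75,
            genome_length=10**6,
        )
        ph = c.generate_phenotypes(truth, [0], [0.5], 0.3, seed=76)
        res = c.gwas_linear(truth.as_matrix(), ph.iloc[:, 0], None, n_pcs=0)
        row = res.table[res.table["pos"] == truth.variants["pos"].iloc[0]].iloc[0]
        # matched oracle: direct OLS of the same transformed phenotype
        y = inverse_normal_transform(ph.iloc[:, 0].to_numpy())
        x = truth.genotypes[:, 0].astype(float)
        oracle = stats.linregress(x, y)
        assert row["beta"] == pytest.approx(oracle.slope, abs=1e-8)
        # and the untransformed fit recovers the planted 0.5 within 3 SE
        raw = stats.linregress(x, ph.iloc[:, 0].to_numpy())
        assert abs(raw.slope - 0.5) < 3 * raw.stderr

    def test_constant_dosage_snp_skipped(self):
        d = np.ones((50, 2), dtype=np.int8)
        d[:, 1] = np.tile([0, 1], 25)
        g = toy_matrix(d)
        rng = np.random.default_rng(77)
        ph = pd.Series(rng.normal(size=50), index=g.samples)
        res = c.gwas_linear(g, ph, None, n_pcs=0)
        assert len(res.table) == 1
        assert any("zero-variance" in reason for _, reason in res.skipped)


# ---------------------------------------------------------------------------
# cis-eQTL
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def eqtl_truth():
    return c.generate_cohort(150, 500, seed=80, genome_length=2_000_000)


class TestCisEqtl:
    def test_null_genes_empirical_p_uniform(self, eqtl_truth):
        expr, ann = c.generate_expression(
            eqtl_truth, c.CisConfig(egene_fraction=0.0), 120, seed=81,
            genome_length=2_000_000,
        )
        res = c.cis_eqtl(
            eqtl_truth.as_matrix(), expr, ann, n_perm=200,
            n_geno_pcs=0, n_expr_pcs=0, seed=82,
        )
        assert stats.kstest(res.genes["empirical_p"], "uniform").pvalue > 0.01

    def test_planted_egene_hits_permutation_floor(self, eqtl_truth):
        expr, ann = c.generate_expression(
            eqtl_truth, c.CisConfig(egene_fraction=1.0, beta=1.0, noise_sd=0.5),
            5, seed=83, genome_length=2_000_000,
        )
        res = c.cis_eqtl(
            eqtl_truth.as_matrix(), expr, ann, n_perm=500,
            n_geno_pcs=0, n_expr_pcs=0, seed=84,
        )
        # only genes whose causal variant passes the MAF filter are detectable
        maf = eqtl_truth.as_matrix().maf()
        detectable = ann[ann["is_egene"] & (maf[ann["causal_variant"]] >= 0.01)]
        got = res.genes.set_index("gene_id").loc[detectable["gene_id"]]
        assert len(got) >= 3
        assert (got["empirical_p"] == 1 / 501).all()
        assert got["significant"].all()

    def test_zero_window_skips_every_gene(self, eqtl_truth):
        expr, ann = c.generate_expression(
            eqtl_truth, c.CisConfig(egene_fraction=0.0), 5, seed=85,
            genome_length=2_000_000,
        )
        with pytest.raises(ValueError):
            c.cis_eqtl(eqtl_truth.as_matrix(), expr, ann, window=0, n_perm=10, seed=86)

    def test_permutation_determinism(self, eqtl_truth):
        expr, ann = c.generate_expression(
            eqtl_truth, c.CisConfig(egene_fraction=0.5), 10, seed=87,
            genome_length=2_000_000,
        )
        a = c.cis_eqtl(eqtl_truth.as_matrix(), expr, ann, n_perm=100, seed=88)
        b = c.cis_eqtl(eqtl_truth.as_matrix(), expr, ann, n_perm=100, seed=88)
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_single_variant_gene_empirical_converges_to_analytic(self):
        """Empirical P ~ nominal P for one cis variant under Gaussian noise."""
        truth = c.generate_cohort(
            100, 1, maf_distribution=lambda rng, k: np.full(k, 0.4), seed=89,
            genome_length=1000,
        )
        rng = np.random.default_rng(90)
        expr = pd.DataFrame(
            rng.normal(size=(1, 100)), index=pd.Index(["G0000"], name="gene_id"),
            columns=truth.samples,
        )
        ann = pd.DataFrame({"gene_id": ["G0000"], "chrom": "chr1", "tss": [500], "strand": "+"})
        res = c.cis_eqtl(
            truth.as_matrix(), expr, ann, n_perm=10_000,
            n_geno_pcs=0, n_expr_pcs=0, seed=91,
        )
        g = res.genes.iloc[0]
        assert abs(g["empirical_p"] - g["nominal_p"]) < 0.02


# ---------------------------------------------------------------------------
# Benjamini-Hochberg and agreement
# ---------------------------------------------------------------------------


def bh_bruteforce(pvals):
    """Textbook step-up BH adjusted P-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBHAndAgreement:
    def test_bh_qvalues_match_bruteforce_exactly(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(92)
        p = np.concatenate([rng.uniform(size=50), rng.uniform(size=10) * 1e-4])
        _, q, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, bh_bruteforce(p), atol=1e-12)
        # monotone in p
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_identical_summaries_unit_r2(self, gwas_cohort):
        ph = c.generate_phenotypes(gwas_cohort, [5], [0.4], 0.2, seed=93)
        res = c.gwas_linear(gwas_cohort.as_matrix(), ph.iloc[:, 0], None, n_pcs=0)
        ag = c.agreement(res, res)
        assert ag.r2_neglog10_p == pytest.approx(1.0)
        assert ag.r2_beta == pytest.approx(1.0)
        assert ag.n_a_unique == 0 and ag.n_b_unique == 0

    def test_three_point_hand_computation(self):
        from cfcomp.assoc_compare import AssocSummary

        def mk(neglogs, betas):
            return AssocSummary(
                table=pd.DataFrame(
                    {
                        "chrom": "chr1",
                        "pos": [1, 2, 3],
                        "ref": "A",
                        "alt": "G",
                        "beta": betas,
                        "se": 0.1,
                        "p": 10.0 ** (-np.asarray(neglogs)),
                    }
                )
            )

        ag = c.agreement(mk([1, 2, 3], [0.1, 0.2, 0.3]), mk([1, 2, 4], [0.1, 0.2, 0.3]))
        x, y = np.array([1, 2, 3.0]), np.array([1, 2, 4.0])
        brute = (np.corrcoef(x, y)[0, 1]) ** 2
        assert ag.r2_neglog10_p == pytest.approx(brute, abs=1e-12)

    def test_swapped_alleles_harmonized_with_sign_flip(self):
        from cfcomp.assoc_compare import AssocSummary

        a = AssocSummary(
            table=pd.DataFrame(
                {"chrom": "chr1", "pos": [1, 2], "ref": ["A", "C"], "alt": ["G", "T"],
                 "beta": [0.5, -0.2], "se": 0.1, "p": [0.01, 0.5]}
            )
        )
        b = AssocSummary(
            table=pd.DataFrame(
                {"chrom": "chr1", "pos": [1, 2], "ref": ["A", "T"], "alt": ["G", "C"],
                 "beta": [0.5, 0.2], "se": 0.1, "p": [0.01, 0.5]}
            )
        )
        ag = c.agreement(a, b)
        assert ag.n_overlap == 2 and ag.n_allele_flipped == 1
        assert ag.r2_beta == pytest.approx(1.0)

    def test_empty_overlap_rejected(self):
        from cfcomp.assoc_compare import AssocSummary

        a = AssocSummary(table=pd.DataFrame(
            {"chrom": "chr1", "pos": [1], "ref": "A", "alt": "G", "beta": [1.0], "se": 0.1, "p": [0.5]}))
        b = AssocSummary(table=pd.DataFrame(
            {"chrom": "chr1", "pos": [9], "ref": "A", "alt": "G", "beta": [1.0], "se": 0.1, "p": [0.5]}))
        with pytest.raises(ValueError):
            c.agreement(a, b)
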