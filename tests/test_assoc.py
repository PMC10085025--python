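"""Association machinery: PCA, nested-model scan, multiple testing,
effect sizes, and the pairwise epistasis check."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import logit

from mitonuclear import assoc, popgen_sim as ps, snp_table as st
from mitonuclear.snp_table import MISSING, SNPTable


def table_from_matrix(geno: np.ndarray, spacing: int = 10_000) -> SNPTable:
    """geno: (n_variants, n_strains)."""
    n_var = geno.shape[0]
    return SNPTable(
        variants=pd.DataFrame(
            {
                "chrom": "chrI",
                "pos": (np.arange(n_var) + 1) * spacing,
                "ref": "A",
                "alt": "C",
            }
        ),
        genotypes=geno.astype(np.int8),
        strains=[f"S{i + 1:04d}" for i in range(geno.shape[1])],
    )


def phenotype_frame(table: SNPTable, mitotypes, y_fn) -> pd.DataFrame:
    """One row per strain x mitotype with response from y_fn(g_row, mito)."""
    rows = []
    for mt in mitotypes:
        for i, sid in enumerate(table.strains):
            rows.append(
                {
                    "strain_id": sid,
                    "mitotype": mt,
                    "petite_pct": y_fn(table.genotypes[:, i], mt),
                }
            )
    return pd.DataFrame(rows)


class TestGenotypePca:
    def test_scores_orthogonal(self, rng):
        geno = rng.integers(0, 2, size=(80, 40)).astype(np.int8)
        scores, _ = assoc.genotype_pca(geno.T.astype(float), k=5)
        gram = scores.to_numpy().T @ scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_pc1_separates_structured_populations(self, tiny_map):
        panel = ps.simulate_founders(40, 2, tiny_map, F=0.3, seed=5)
        scores, _ = assoc.genotype_pca(panel.haplotypes.astype(float), k=2)
        labels = (panel.population == "P2").astype(float)
        corr = np.corrcoef(scores["PC1"], labels)[0, 1]
        assert abs(corr) > 0.9

    def test_constant_matrix_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="rank"):
            scores, _ = assoc.genotype_pca(np.ones((6, 10)), k=3)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-8)


class TestScanMitonuclear:
    MITOS = ["RC1", "RC2", "RC3"]

    def test_additive_phenotype_has_null_interaction(self, rng):
        geno = rng.integers(0, 2, size=(6, 30))
        table = table_from_matrix(geno)
        mito_eff = {"RC1": 0.0, "RC2": 4.0, "RC3": 9.0}
        phen = phenotype_frame(
            table, self.MITOS, lambda g, mt: 5.0 + 3.0 * g[2] + mito_eff[mt]
        )
        res = assoc.scan_mitonuclear(phen, table)
        row = res.iloc[2]
        assert row["stat_int"] == pytest.approx(0.0, abs=1e-6)
        assert row["p_int"] == pytest.approx(1.0)
        assert row["p_main"] < 1e-10

    def test_pure_interaction_detected(self, rng):
        geno = rng.integers(0, 2, size=(4, 40))
        table = table_from_matrix(geno)
        phen = phenotype_frame(
            table, self.MITOS,
            lambda g, mt: 5.0 + (8.0 * g[1] if mt == "RC3" else 0.0)
            + 0.001 * g[[0, 2, 3]].sum(),
        )
        # add tiny noise so residuals are nonzero but the signal dominates
        rng2 = np.random.default_rng(0)
        phen["petite_pct"] += rng2.normal(0, 0.01, len(phen))
        res = assoc.scan_mitonuclear(phen, table)
        assert res.iloc[1]["p_int"] < 1e-10
        assert res.iloc[1]["df_int"] == 2

    def test_monomorphic_flagged(self):
        geno = np.array([[0, 0, 0, 0, 0, 0], [0, 1, 0, 1, 0, 1]])
        table = table_from_matrix(geno)
        phen = phenotype_frame(table, ["RC1", "RC2"], lambda g, mt: 5.0 + g[1])
        phen["petite_pct"] += np.random.default_rng(1).normal(0, 0.1, len(phen))
        res = assoc.scan_mitonuclear(phen, table)
        assert res.iloc[0]["status"] == "monomorphic"
        assert np.isnan(res.iloc[0]["p_main"])
        assert res.iloc[1]["status"] == "ok"

    def test_collinear_with_conditioning_flagged(self, rng):
        g = rng.integers(0, 2, 20)
        table = table_from_matrix(np.vstack([g, g]))
        phen = phenotype_frame(table, ["RC1", "RC2"], lambda gg, mt: 5.0 + gg[0])
        phen["petite_pct"] += np.random.default_rng(2).normal(0, 0.1, len(phen))
        spec = assoc.ModelSpec(conditioning_snps=[0])
        res = assoc.scan_mitonuclear(phen, table, spec)
        assert res.iloc[1]["status"] == "collinear"

    def test_allele_absent_in_one_mitotype_reduces_df(self, rng):
        """Missing calls confined to one mitotype make an allele unobserved
        there; the interaction fit drops the inestimable contrast."""
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1] * 3)
        table = table_from_matrix(g[: 24].reshape(1, 24))
        phen = phenotype_frame(table, self.MITOS, lambda gg, mt: 5.0)
        phen["petite_pct"] = np.random.default_rng(3).normal(5, 1, len(phen))
        # mark carriers missing in RC3 only
        tab = table_from_matrix(table.genotypes.copy())
        carrier_cols = np.nonzero(tab.genotypes[0] == 1)[0]
        # build per-row missingness by duplicating the variant per mitotype is
        # not possible; instead give RC3 rows a distinct strain set
        phen_rc3 = phen["mitotype"] == "RC3"
        phen.loc[phen_rc3 & phen["strain_id"].isin(
            [tab.strains[c] for c in carrier_cols]
        ), "petite_pct"] = np.nan
        phen = phen.dropna()
        res = assoc.scan_mitonuclear(phen, tab)
        assert res.iloc[0]["status"] == "reduced_df"
        assert res.iloc[0]["df_int"] == 1

    def test_single_mitotype_level_rejected(self, rng):
        geno = rng.integers(0, 2, size=(2, 10))
        table = table_from_matrix(geno)
        phen = phenotype_frame(table, ["RC1"], lambda g, mt: 5.0)
        with pytest.raises(ValueError, match="mitotype levels"):
            assoc.scan_mitonuclear(phen, table)

    def test_matches_statsmodels_anova(self, rng):
        """Gaussian nested F-tests agree with statsmodels OLS compare_f_test
        on the same designs (independent route through a fitted model)."""
        geno = rng.integers(0, 2, size=(3, 25))
        table = table_from_matrix(geno)
        phen = phenotype_frame(table, self.MITOS, lambda g, mt: 0.0)
        phen["petite_pct"] = rng.normal(10, 2, len(phen))
        res = assoc.scan_mitonuclear(phen, table)
        mito_d = pd.get_dummies(phen["mitotype"], drop_first=True, dtype=float)
        for v in range(3):
            g = geno[v, [table.strains.index(s) for s in phen["strain_id"]]]
            X0 = sm.add_constant(mito_d)
            X1 = X0.copy(); X1["g"] = g
            X2 = X1.copy()
            for c in mito_d.columns:
                X2[f"g:{c}"] = g * mito_d[c]
            m0 = sm.OLS(phen["petite_pct"], X0).fit()
            m1 = sm.OLS(phen["petite_pct"], X1).fit()
            m2 = sm.OLS(phen["petite_pct"], X2).fit()
            f_main, p_main, _ = m1.compare_f_test(m0)
            f_int, p_int, _ = m2.compare_f_test(m1)
            assert res.iloc[v]["stat_main"] == pytest.approx(f_main, rel=1e-8)
            assert res.iloc[v]["p_main"] == pytest.approx(p_main, rel=1e-8)
            assert res.iloc[v]["stat_int"] == pytest.approx(f_int, rel=1e-8)
            assert res.iloc[v]["p_int"] == pytest.approx(p_int, rel=1e-8)

    @pytest.mark.parametrize("with_interaction", [True, False])
    def test_binomial_family_on_logit_scale_truth(self, rng, with_interaction):
        """Counts generated from a single logit-scale effect: the binomial
        LRT flags the interaction only when the effect is RC3-specific; a
        purely additive main effect keeps the interaction test null. (The
        model must contain every real effect: unmodelled loci create
        extra-binomial dispersion that inflates the chi-square LRT.)"""
        geno = rng.integers(0, 2, size=(1, 60))
        table = table_from_matrix(geno)
        rows = []
        rng2 = np.random.default_rng(11)
        for mt in self.MITOS:
            for i, sid in enumerate(table.strains):
                eta = logit(0.05) + 1.5 * geno[0, i] * (mt == "RC3" or not with_interaction)
                k = rng2.binomial(500, 1 / (1 + np.exp(-eta)))
                rows.append(
                    {"strain_id": sid, "mitotype": mt,
                     "petite_count": k, "total_count": 500}
                )
        phen = pd.DataFrame(rows)
        spec = assoc.ModelSpec(family="binomial")
        res = assoc.scan_mitonuclear(phen, table, spec)
        assert res.iloc[0]["p_main"] < 1e-8
        if with_interaction:
            assert res.iloc[0]["p_int"] < 1e-8
        else:
            assert res.iloc[0]["p_int"] > 1e-3

    def test_interaction_never_increases_residual_deviance(self, rng):
        geno = rng.integers(0, 2, size=(10, 30))
        table = table_from_matrix(geno)
        phen = phenotype_frame(table, self.MITOS, lambda g, mt: 0.0)
        phen["petite_pct"] = rng.normal(10, 3, len(phen))
        res = assoc.scan_mitonuclear(phen, table)
        ok = res["status"] == "ok"
        assert (res.loc[ok, "stat_main"] >= 0).all()
        assert (res.loc[ok, "stat_int"] >= 0).all()


class TestMitonuclearAnova:
    def test_factorial_background_interaction(self, rng):
        rows = []
        for bg in ["parental", "deletion"]:
            for mt in ["RC1", "RC2"]:
                for rep in range(6):
                    y = 10.0
                    if bg == "deletion" and mt == "RC2":
                        y += 8.0  # background effect only with one mitotype
                    rows.append(
                        {"background": bg, "mitotype": mt,
                         "petite_pct": y + rng.normal(0, 0.5)}
                    )
        phen = pd.DataFrame(rows)
        out = assoc.mitonuclear_anova(phen, "background")
        assert out["p_int"] < 1e-6


class TestAdjustPvalues:
    def test_bonferroni_threshold_genomewide(self):
        res = assoc.adjust_pvalues(np.full(24_955, 0.5), "bonferroni", alpha=0.05)
        assert float(f"{res.threshold:.1e}") == pytest.approx(2.0e-6)

    def test_bh_hand_example(self):
        res = assoc.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(res.adjusted, 0.04)

    def test_storey_pi0_one_equals_bh(self, rng):
        p = rng.uniform(0, 1, 500)
        bh = assoc.adjust_pvalues(p, "bh")
        storey = assoc.adjust_pvalues(p, "storey", pi0=1.0)
        assert np.allclose(bh.adjusted, storey.adjusted)

    def test_storey_estimates_pi0_below_one_with_signal(self, rng):
        p = np.concatenate([rng.uniform(0, 1, 800), rng.uniform(0, 1e-4, 200)])
        res = assoc.adjust_pvalues(p, "storey")
        assert 0 < res.pi0 < 1.0

    def test_adjusted_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 300)
        for method in ["bonferroni", "bh", "storey"]:
            adj = assoc.adjust_pvalues(p, method).adjusted
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()

    def test_nan_passthrough(self):
        res = assoc.adjust_pvalues([0.01, np.nan, 0.5], "bh")
        assert np.isnan(res.adjusted[1])
        assert not np.isnan(res.adjusted[0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assoc.adjust_pvalues([], "bh")


class TestEffectSizeDelta:
    def test_formula(self):
        # f0=0.6 with mean 10%, f1=0.4 with mean 5% -> |6 - 2| = 4
        g = np.array([0, 0, 0, 1, 1])
        y = np.array([10.0, 10, 10, 5, 5])
        f0, f1 = 0.6, 0.4
        assert f0 * 10 - f1 * 5 == pytest.approx(4.0)
        assert assoc.effect_size_delta(g, y) == pytest.approx(4.0)

    def test_balanced_products_cancel(self):
        g = np.array([0, 1])
        y = np.array([10.0, 10.0])
        assert assoc.effect_size_delta(g, y) == pytest.approx(0.0)

    def test_monomorphic_undefined(self):
        assert np.isnan(assoc.effect_size_delta([1, 1, 1], [1.0, 2.0, 3.0]))

    def test_matches_brute_force_from_replicate_counts(self, small_collection):
        """Delta from strain means equals a brute-force regrouping that
        recomputes allele-class means from the raw replicate counts."""
        freqs = small_collection.genotypes.mean(axis=0)
        v = int(np.argmin(np.abs(freqs - 0.5)))
        arch = ps.PhenotypeArchitecture(
            baseline=float(logit(0.08)), main_effects={v: 0.8}
        )
        counts = ps.simulate_petite_counts(
            small_collection, arch, ps.AssayDesign(300, 3), seed=9
        )
        from mitonuclear.pheno import strain_petite_means

        means = strain_petite_means(counts)
        strain_means = means.groupby("strain_id")["petite_pct"].mean()
        table = st.from_collection(small_collection)
        delta = assoc.effect_size_delta(
            table.genotypes[v], strain_means.reindex(table.strains).to_numpy()
        )
        # brute force: group strains by allele, average per-strain means
        per_strain = {}
        for sid, grp in counts.groupby("strain_id"):
            per_strain[sid] = (100.0 * grp["petite_count"] / grp["total_count"]).groupby(
                grp["mitotype"]
            ).mean().mean()
        alleles = {s: table.genotypes[v, i] for i, s in enumerate(table.strains)}
        cls = {a: [per_strain[s] for s in table.strains if alleles[s] == a] for a in (0, 1)}
        f1 = len(cls[1]) / (len(cls[0]) + len(cls[1]))
        brute = abs((1 - f1) * np.mean(cls[0]) - f1 * np.mean(cls[1]))
        assert delta == pytest.approx(brute)


class TestPairwiseEpistasis:
    def make_inputs(self, rng, n=80):
        geno = rng.integers(0, 2, size=(4, n))
        geno[3] = geno[0]  # perfect LD with SNP 0
        table = table_from_matrix(geno)
        phen = pd.DataFrame(
            {
                "strain_id": table.strains,
                "mitotype": "RC1",
                "petite_pct": np.zeros(n),
            }
        )
        return geno, table, phen

    def test_additive_phenotype_null(self, rng):
        geno, table, phen = self.make_inputs(rng)
        phen["petite_pct"] = 3.0 * geno[0] + 2.0 * geno[1] + rng.normal(0, 0.01, len(phen))
        out = assoc.pairwise_epistasis_scan(phen, table, focal_snps=[0], snps=[1])
        assert out.iloc[0]["p_int"] > 0.01

    def test_xor_phenotype_detected(self, rng):
        geno, table, phen = self.make_inputs(rng)
        phen["petite_pct"] = 10.0 * np.logical_xor(geno[0], geno[1]) + rng.normal(
            0, 0.01, len(phen)
        )
        out = assoc.pairwise_epistasis_scan(phen, table, focal_snps=[0], snps=[1])
        assert out.iloc[0]["p_int"] < 1e-10

    def test_self_and_perfect_ld_flagged(self, rng):
        geno, table, phen = self.make_inputs(rng)
        phen["petite_pct"] = rng.normal(0, 1, len(phen))
        out = assoc.pairwise_epistasis_scan(phen, table, focal_snps=[0])
        by_snp = out.set_index("snp")
        assert by_snp.loc[0, "status"] == "self"
        assert by_snp.loc[3, "status"] == "perfect_ld"

    def test_null_type_i_error_calibrated(self, rng):
        """Interaction p-values roughly uniform for independent null SNPs."""
        n = 200
        geno = rng.integers(0, 2, size=(60, n))
        table = table_from_matrix(geno)
        phen = pd.DataFrame(
            {
                "strain_id": table.strains,
                "mitotype": "RC1",
                "petite_pct": rng.normal(10, 2, n),
            }
        )
        out = assoc.pairwise_epistasis_scan(phen, table, focal_snps=[0])
        p = out["p_int"].dropna()
        frac = (p < 0.05).mean()
        from scipy import stats as sps

        lo, hi = np.array(sps.binom.interval(0.99, len(p), 0.05)) / len(p)
        assert lo <= frac <= hi
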