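"""qCML dispersion, NB exact test, effect sizes and multiplicity."""
import shutil
import subprocess
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylrad.diffmethyl import (
    MethylDiffModel,
    adjust_pvalues,
    call_dms,
    compute_logfc_logcpm,
    conditional_log_likelihood,
    equalize_libraries,
    estimate_common_dispersion,
    exact_test,
)
from methylrad.simulate import (
    SimConfig, abstract_catalog, assign_methylation_states, simulate_counts,
)
from methylrad.sites import CountMatrix


def masks(n1, n2):
    g = np.array([True] * n1 + [False] * n2)
    return [g, ~g]


def sim_matrix(seed=0, n_sites=2000, phi=0.2, frac=0.0, **kw):
    cfg = SimConfig(seed=seed, dispersion=phi, frac_differential=frac, **kw)
    truth = assign_methylation_states(abstract_catalog(n_sites), cfg)
    return simulate_counts(truth, cfg), truth


class TestEqualize:
    def test_equal_libraries_identity(self):
        counts = np.array([[4.0, 4, 4, 1, 1, 1], [10, 10, 10, 10, 10, 10]])
        libs = np.full(6, 100.0)
        pseudo, common = equalize_libraries(counts, libs, masks(3, 3), 0.1)
        assert common == pytest.approx(100.0)
        assert np.allclose(pseudo, counts, atol=1e-8)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(8.0, size=(300, 6)).astype(float)
        libs = counts.sum(axis=0)
        pseudo, _ = equalize_libraries(counts, libs, masks(3, 3), 0.1)
        doubled = counts.copy()
        doubled[:, 0] *= 2
        libs2 = libs.copy()
        libs2[0] *= 2
        pseudo2, _ = equalize_libraries(doubled, libs2, masks(3, 3), 0.1)
        # doubling a sample's counts and library leaves its quantiles in
        # place; pseudo-counts move only through the common-size shift
        # (geometric mean x 2^(1/6)) and the small group-proportion update
        assert np.corrcoef(pseudo[:, 0], pseudo2[:, 0])[0, 1] > 0.995
        ratio = np.median(pseudo2[:, 0][pseudo[:, 0] > 0]
                          / pseudo[:, 0][pseudo[:, 0] > 0])
        assert ratio == pytest.approx(2 ** (1 / 6), rel=0.05)

    def test_zeros_stay_zero(self):
        counts = np.zeros((5, 6))
        pseudo, _ = equalize_libraries(counts, np.full(6, 10.0), masks(3, 3), 0.2)
        assert np.allclose(pseudo, 0.0, atol=1e-9)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            equalize_libraries(np.ones((2, 6)), np.zeros(6), masks(3, 3), 0.1)


class TestDispersion:
    def test_recovery_at_phi_02(self):
        m, _ = sim_matrix(seed=21, phi=0.2)
        pseudo, _ = equalize_libraries(
            m.counts.values.astype(float), m.library_sizes.values.astype(float),
            masks(3, 3), 0.2,
        )
        phi_hat = estimate_common_dispersion(pseudo, masks(3, 3))
        assert 0.15 <= phi_hat <= 0.25

    def test_poisson_boundary(self):
        m, _ = sim_matrix(seed=22, phi=0.0)
        phi_hat = MethylDiffModel(m).fit().dispersion.common
        assert phi_hat <= 0.02

    def test_equal_counts_single_site_monotone(self):
        pseudo = np.array([[7.0, 7, 7, 7, 7, 7]])
        grid = np.logspace(-6, 1, 40)
        ll = [conditional_log_likelihood(pseudo, masks(3, 3), p) for p in grid]
        assert all(a >= b - 1e-9 for a, b in zip(ll[:-1], ll[1:]))
        assert estimate_common_dispersion(pseudo, masks(3, 3)) <= 1e-4

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_common_dispersion(np.zeros((4, 6)), masks(3, 3))


class TestExactTest:
    def test_poisson_limit_ten_vs_zero(self):
        pseudo = np.array([[10.0, 0.0]])
        p = exact_test(pseudo, masks(1, 1), 0.0)
        assert p[0] == pytest.approx(2 * 0.5**10, abs=1e-12)

    def test_equal_group_sums_p_one(self):
        pseudo = np.array([[5.0, 5, 5, 5, 5, 5]])
        assert exact_test(pseudo, masks(3, 3), 0.3)[0] == 1.0

    def test_zero_total_p_one(self):
        assert exact_test(np.zeros((1, 6)), masks(3, 3), 0.2)[0] == 1.0

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        pseudo = rng.poisson(6.0, size=(200, 6)).astype(float)
        g = masks(3, 3)
        p1 = exact_test(pseudo, g, 0.15)
        p2 = exact_test(pseudo, [g[1], g[0]], 0.15)
        assert np.allclose(p1, p2)

    def test_binomial_oracle_small_grid(self):
        """phi=0 agreement with an independent binomial-conditional
        enumeration (full exhaustive grid lives in the acceptance suite)."""
        for n1, n2 in [(1, 1), (2, 3), (3, 3)]:
            for z in (1, 7, 20):
                rows = np.zeros((z + 1, n1 + n2))
                rows[:, 0] = np.arange(z + 1)
                rows[:, n1] = z - np.arange(z + 1)
                p_impl = exact_test(rows, masks(n1, n2), 0.0)
                q = n1 / (n1 + n2)
                pmf = np.array(
                    [math.comb(z, k) * q**k * (1 - q) ** (z - k)
                     for k in range(z + 1)]
                )
                for k in range(z + 1):
                    lower, upper = pmf[: k + 1].sum(), pmf[k:].sum()
                    p_oracle = min(1.0, 2 * min(lower, upper))
                    assert p_impl[k] == pytest.approx(p_oracle, abs=1e-9)


class TestEffectSizes:
    def test_logfc_closed_form(self):
        counts = np.array([[4.0, 4, 4, 1, 1, 1]])
        libs = np.full(6, 1000.0)
        logfc, _ = compute_logfc_logcpm(counts, libs, masks(3, 3), prior=1e-9)
        assert logfc[0] == pytest.approx(2.0, abs=1e-6)

    def test_identical_groups_zero(self):
        counts = np.array([[7.0, 3, 5, 7, 3, 5]])
        logfc, _ = compute_logfc_logcpm(counts, np.full(6, 100.0), masks(3, 3))
        assert logfc[0] == 0.0

    def test_male_high_site_has_negative_logfc(self):
        # counts male (30,15,6) vs female (5,0,4): reported as logFC -2.67,
        # fixing the sign convention (female relative to male)
        counts = np.array([[5.0, 0, 4, 30, 15, 6]])  # female first
        logfc, _ = compute_logfc_logcpm(counts, np.full(6, 1e4, float),
                                        masks(3, 3))
        assert logfc[0] < 0


class TestAdjust:
    def test_bonferroni_closed_form(self):
        assert np.allclose(adjust_pvalues([0.01, 0.02], "bonferroni"),
                           [0.02, 0.04])

    def test_bh_step_up(self):
        assert np.allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh"), [0.04] * 4
        )

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_bonferroni_dominates_bh(self, pvals):
        bonf = adjust_pvalues(pvals, "bonferroni")
        bh = adjust_pvalues(pvals, "bh")
        assert (bonf >= bh - 1e-12).all()

    def test_empty_and_unknown(self):
        assert adjust_pvalues([], "bh").size == 0
        with pytest.raises(ValueError):
            adjust_pvalues([0.1], "holm")


class TestModelResults:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted():
        m, truth = sim_matrix(seed=30, n_sites=1500, phi=0.15, frac=0.1)
        return m, truth, MethylDiffModel(m).fit()

    def test_direction_tallies_partition_dms(self, fitted):
        _, _, res = fitted
        tallies = res.direction_tallies()
        assert sum(tallies.values()) == len(res.dms())

    def test_direction_matches_logfc_sign(self, fitted):
        _, _, res = fitted
        t = res.table
        assert ((t.logFC > 0) == (t.direction == "higher-in-female")).all()

    def test_no_dms_when_alpha_tiny(self, fitted):
        m, _, _ = fitted
        res = MethylDiffModel(m, alpha=1e-12).fit()
        assert len(res.dms()) == 0

    def test_bonferroni_subset_of_bh(self, fitted):
        m, _, _ = fitted
        bh = MethylDiffModel(m, adjust="bh").fit()
        bonf = MethylDiffModel(m, adjust="bonferroni").fit()
        assert set(bonf.dms().index) <= set(bh.dms().index)

    def test_group_swap_antisymmetry(self, fitted):
        m, _, res = fitted
        swapped_groups = m.groups.map({"female": "male", "male": "female"})
        m2 = CountMatrix(counts=m.counts, groups=swapped_groups)
        res2 = MethylDiffModel(m2).fit()
        assert np.allclose(res2.table.logFC, -res.table.logFC)
        assert np.allclose(res2.table.PValue, res.table.PValue)

    def test_summary_and_table_shape(self, fitted):
        m, _, res = fitted
        s = res.summary()
        assert "common dispersion" in s and "DMSs" in s
        t = res.to_table()
        for col in ("site", "logFC", "logCPM", "PValue", "adjP", "direction"):
            assert col in t.columns
        assert len(t) == res.n_sites

    def test_from_dataframe_constructor(self, fitted):
        m, _, res = fitted
        res2 = MethylDiffModel.from_dataframe(m.counts, m.groups).fit()
        assert np.allclose(res2.table.PValue, res.table.PValue)

    def test_empirical_fdr_controlled(self, fitted):
        m, truth, res = fitted
        t = truth.set_index(["contig", "pos", "strand"])
        true_d = t.loc[res.table.index, "differential"].values
        sig = res.table.significant.values
        if sig.sum():
            assert (~true_d[sig]).mean() <= 0.10


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestEdgeRCrossCheck:
    """edgeR (the reference qCML implementation) as independent oracle."""

    def test_dispersion_and_pvalue_ranking_agree(self, tmp_path):
        m, _ = sim_matrix(seed=77, n_sites=400, phi=0.25, frac=0.1)
        csv = tmp_path / "counts.csv"
        m.counts.reset_index(drop=True).to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            f"""
            counts <- as.matrix(read.csv('{csv}'))
            suppressMessages(library(edgeR))
            grp <- factor(c('male','male','male','female','female','female'),
                          levels=c('male','female'))
            d <- DGEList(counts=counts, group=grp)
            d <- estimateCommonDisp(d)
            et <- exactTest(d)
            out <- data.frame(disp=d$common.dispersion, p=et$table$PValue)
            write.csv(out, '{tmp_path}/out.csv', row.names=FALSE)
            """
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        out = pd.read_csv(tmp_path / "out.csv")
        res = MethylDiffModel(m).fit()
        assert res.dispersion.common == pytest.approx(out.disp[0], rel=0.15)
        rho = pd.Series(res.table.PValue.values).corr(
            pd.Series(out.p.values), method="spearman"
        )
        assert rho > 0.99
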