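import itertools

import numpy as np
import pandas as pd
import pytest

from gptrainsel import (
    MarkerPanel,
    MixedModelSpec,
    QTLSet,
    SyntheticPanelConfig,
    TraitData,
    additive_relationship,
    fit_prediction_model,
    gaussian_kernel,
    gwas_scan,
    li_ji_threshold,
    loco_kinships,
    predict_blup,
    reml_fit,
    select_qtl,
    simulate_panel,
    simulate_trait,
    tune_theta,
)
from gptrainsel.models import _reml_neg2_profile


def small_dataset(seed=17, sizes=(15, 15), n_markers=300):
    cfg = SyntheticPanelConfig(subpop_sizes=sizes, fst=0.2, n_markers=n_markers,
                               n_chromosomes=3, seed=seed)
    panel, assign = simulate_panel(cfg)
    trait, qtl, g = simulate_trait(panel, 2, 0.3, 0.7, seed=seed)
    return panel, assign, trait


def spec_for(panel, trait, kernels, ids=None):
    ids = ids or panel.genotype_ids
    y = trait.aligned(ids)
    gi = panel.genotype_index(ids)
    z = np.zeros((len(ids), panel.n_genotypes))
    z[np.arange(len(ids)), gi] = 1.0
    return MixedModelSpec(y, np.ones((len(ids), 1)), z, kernels, panel.genotype_ids)


def henderson_mme(spec, vc):
    """Independent oracle: solve Henderson's mixed-model equations directly."""
    y, x, z = spec.y, spec.X, spec.Z
    n = y.size
    blocks = []
    zs = []
    for label, k in spec.kernels:
        g = vc.sigma2[label] * k + 1e-8 * np.eye(k.shape[0])
        blocks.append(np.linalg.inv(g))
        zs.append(z)
    r_inv = np.eye(n) / vc.sigma2_e
    zz = np.hstack(zs)
    ginv = np.zeros((zz.shape[1], zz.shape[1]))
    off = 0
    for b in blocks:
        m = b.shape[0]
        ginv[off:off + m, off:off + m] = b
        off += m
    top = np.hstack([x.T @ r_inv @ x, x.T @ r_inv @ zz])
    bottom = np.hstack([zz.T @ r_inv @ x, zz.T @ r_inv @ zz + ginv])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([x.T @ r_inv @ y, zz.T @ r_inv @ y])
    sol = np.linalg.solve(lhs, rhs)
    beta = sol[:x.shape[1]]
    u = sol[x.shape[1]:]
    m = spec.Z.shape[1]
    g_total = sum(u[i * m:(i + 1) * m] for i in range(len(spec.kernels)))
    return beta, g_total


class TestREML:
    def test_spectral_path_matches_grid_maximization(self):
        panel, _, trait = small_dataset()
        a = additive_relationship(panel)
        spec = spec_for(panel, trait, [("g", a.values)])
        vc = reml_fit(spec)
        m = spec.record_kernels()[0][1]
        d, u = np.linalg.eigh((m + m.T) / 2)
        d = np.clip(d, 0, None)
        yt, xt = u.T @ spec.y, u.T @ spec.X
        grid = np.linspace(-4, 4, 1000)  # ratio grid 1e-4..1e4
        vals = [_reml_neg2_profile(g, d, yt, xt)[0] for g in grid]
        best = grid[int(np.argmin(vals))]
        fitted_ratio = np.log10(next(iter(vc.sigma2.values())) / vc.sigma2_e)
        assert abs(fitted_ratio - best) <= (grid[1] - grid[0]) + 1e-9

    def test_optimum_beats_random_ratios(self):
        panel, _, trait = small_dataset(seed=5)
        a = additive_relationship(panel)
        spec = spec_for(panel, trait, [("g", a.values)])
        vc = reml_fit(spec)
        m = spec.record_kernels()[0][1]
        d, u = np.linalg.eigh((m + m.T) / 2)
        d = np.clip(d, 0, None)
        yt, xt = u.T @ spec.y, u.T @ spec.X
        best = _reml_neg2_profile(
            np.log10(next(iter(vc.sigma2.values())) / vc.sigma2_e), d, yt, xt)[0]
        rng = np.random.default_rng(0)
        for lr in rng.uniform(-5, 5, 50):
            assert best <= _reml_neg2_profile(lr, d, yt, xt)[0] + 1e-6

    def test_identity_kernel_flagged_degenerate(self):
        rng = np.random.default_rng(3)
        n = 30
        ids = [f"g{i}" for i in range(n)]
        spec = MixedModelSpec(rng.normal(size=n), np.ones((n, 1)), np.eye(n),
                              [("g", np.eye(n))], ids)
        vc = reml_fit(spec)
        assert vc.degenerate

    def test_identical_kernels_flagged_degenerate(self):
        panel, _, trait = small_dataset(seed=9)
        a = additive_relationship(panel)
        spec = spec_for(panel, trait, [("g1", a.values), ("g2", a.values)])
        vc = reml_fit(spec)
        assert vc.degenerate

    def test_too_few_records_fatal(self):
        ids = [f"g{i}" for i in range(5)]
        spec = MixedModelSpec(np.arange(5.0), np.ones((5, 1)), np.eye(5),
                              [("g", np.eye(5))], ids)
        with pytest.raises(ValueError, match="10 records"):
            reml_fit(spec)


class TestBLUP:
    @pytest.mark.parametrize("n_kernels", [1, 2])
    def test_matches_henderson_mme(self, n_kernels):
        cfg = SyntheticPanelConfig(subpop_sizes=(15, 15), fst=0.2, n_markers=200,
                                   n_chromosomes=2, seed=31)
        panel, _ = simulate_panel(cfg)
        trait, _, _ = simulate_trait(panel, 2, 0.3, 0.6, seed=31)
        kernels = [("a", additive_relationship(panel).values)]
        if n_kernels == 2:
            kernels.append(("k", gaussian_kernel(panel, 1.0).values))
        train = panel.genotype_ids[:22]
        spec = spec_for(panel, trait, kernels, ids=train)
        vc = reml_fit(spec)
        preds = predict_blup(spec, vc)
        beta, g = henderson_mme(spec, vc)
        np.testing.assert_allclose(preds.to_numpy(), beta[0] + g, atol=1e-6)

    def test_zero_genetic_variance_predicts_intercept(self):
        panel, _, trait = small_dataset(seed=13)
        a = additive_relationship(panel)
        spec = spec_for(panel, trait, [("g", a.values)])
        from gptrainsel import VarianceComponents
        vc = VarianceComponents(sigma2={"g": 0.0}, sigma2_e=1.0, loglik=0.0)
        preds = predict_blup(spec, vc)
        assert np.allclose(preds.to_numpy(), preds.iloc[0])

    def test_training_blups_shrink_toward_mean(self):
        rng = np.random.default_rng(8)
        n = 25
        ids = [f"g{i}" for i in range(n)]
        y = rng.normal(size=n)
        spec = MixedModelSpec(y, np.ones((n, 1)), np.eye(n), [("g", np.eye(n))], ids)
        from gptrainsel import VarianceComponents
        vc = VarianceComponents(sigma2={"g": 1.0}, sigma2_e=1.0, loglik=0.0)
        preds = predict_blup(spec, vc)
        beta0 = preds.to_numpy().mean()
        g_hat = preds.to_numpy() - beta0
        resid = y - y.mean()
        assert (np.abs(g_hat) <= np.abs(resid) + 1e-8).all()


class TestGWAS:
    def test_pvalues_invariant_to_marker_and_genotype_order(self):
        panel, _, trait = small_dataset(seed=23, sizes=(20, 20))
        loco = loco_kinships(panel)
        base = gwas_scan(panel, trait, loco, panel.genotype_ids)
        perm = np.random.default_rng(1).permutation(panel.n_markers)
        shuffled = panel.subset(markers=perm)
        p2 = gwas_scan(shuffled, trait, loco_kinships(shuffled), panel.genotype_ids)
        np.testing.assert_allclose(base.loc[p2.index].to_numpy(), p2.to_numpy(),
                                   atol=1e-6)
        gperm = np.random.default_rng(2).permutation(panel.n_genotypes)
        gp = panel.subset(genotypes=gperm)
        p3 = gwas_scan(gp, trait, loco_kinships(gp), gp.genotype_ids)
        np.testing.assert_allclose(base.to_numpy(), p3.to_numpy(), atol=1e-6)

    def test_marker_monomorphic_within_training_has_missing_p(self):
        panel, _, trait = small_dataset(seed=2)
        d = panel.dosage.copy()
        d[:-1, 0] = 2
        d[-1, 0] = 0  # polymorphic overall, monomorphic within training
        p2 = MarkerPanel(panel.genotype_ids, panel.marker_ids, panel.chromosome,
                         panel.position_cM, d)
        train = p2.genotype_ids[:-1]
        pv = gwas_scan(p2, trait, loco_kinships(p2), train)
        assert np.isnan(pv.iloc[0])


class TestLiJi:
    @staticmethod
    def orthogonal_panel(K=10):
        # full 2^4 factorial: centered columns are mutually orthogonal
        rows = np.array(list(itertools.product([0, 2], repeat=4)))
        cols = []
        for subset in itertools.combinations(range(4), 1):
            cols.append(rows[:, subset[0]])
        for subset in itertools.combinations(range(4), 2):
            cols.append((rows[:, subset[0]] + rows[:, subset[1]]) % 4 // 2 * 2)
        for subset in itertools.combinations(range(4), 3):
            cols.append((rows[:, subset[0]] + rows[:, subset[1]] + rows[:, subset[2]]) % 4 // 2 * 2)
        dosage = np.stack(cols[:K], axis=1).astype(np.int8)
        return MarkerPanel([f"g{i}" for i in range(16)],
                           [f"m{j}" for j in range(K)],
                           np.array(["1"] * K, dtype=object),
                           np.arange(K, dtype=float), dosage)

    def test_independent_markers_give_meff_k(self):
        panel = self.orthogonal_panel(10)
        corr = np.corrcoef(panel.dosage.astype(float), rowvar=False)
        assert np.allclose(corr, np.eye(10), atol=1e-12)  # construction check
        thr = li_ji_threshold(panel, 0.01)
        assert thr == pytest.approx(1 - 0.99 ** (1 / 10), rel=1e-10)
        assert thr == pytest.approx(1.0045e-3, rel=1e-3)

    def test_duplicated_pairs_halve_meff(self):
        base = self.orthogonal_panel(5)
        dosage = np.repeat(base.dosage, 2, axis=1)
        panel = MarkerPanel(base.genotype_ids, [f"m{j}" for j in range(10)],
                            np.array(["1"] * 10, dtype=object),
                            np.arange(10, dtype=float), dosage)
        thr = li_ji_threshold(panel, 0.01)
        assert thr == pytest.approx(1 - 0.99 ** (1 / 5), rel=1e-9)

    def test_single_marker_threshold_is_alpha(self):
        panel = self.orthogonal_panel(2).subset(markers=[0, 1])
        # two duplicated? no: two orthogonal -> M_eff 2; use per-chromosome
        # single-marker path instead
        single = MarkerPanel(panel.genotype_ids, ["m0", "m1"],
                             np.array(["1", "2"], dtype=object),
                             np.array([0.0, 0.0]), panel.dosage)
        thr = li_ji_threshold(single.subset(markers=[0, 1]), 0.01)
        # one marker per chromosome: M_eff = 2 -> 1-(0.99)^(1/2)
        assert thr == pytest.approx(1 - 0.99 ** 0.5, rel=1e-9)

    def test_threshold_within_sidak_bonferroni_bounds(self, struct_panel):
        panel, _ = struct_panel
        thr = li_ji_threshold(panel, 0.01)
        assert 0.01 / panel.n_markers <= thr <= 0.01


class TestSelectQTL:
    def make_map(self):
        cfg = SyntheticPanelConfig(subpop_sizes=(10, 10), n_markers=40,
                                   n_chromosomes=2, seed=4)
        panel, _ = simulate_panel(cfg)
        return panel

    def test_empty_when_nothing_significant(self):
        panel = self.make_map()
        pv = pd.Series(0.5, index=panel.marker_ids)
        assert len(select_qtl(pv, 1e-3, panel)) == 0

    def test_nearby_peaks_collapse_to_strongest(self):
        panel = self.make_map()
        pv = pd.Series(0.5, index=panel.marker_ids)
        chrom = panel.chromosome[0]
        same = np.flatnonzero(panel.chromosome == chrom)
        near = [j for j in same
                if abs(panel.position_cM[j] - panel.position_cM[same[0]]) <= 10]
        pv.iloc[near[0]] = 1e-6
        pv.iloc[near[1]] = 1e-4
        qtl = select_qtl(pv, 1e-3, panel)
        assert qtl.marker_ids == [panel.marker_ids[near[0]]]

    def test_distant_peaks_both_kept(self):
        panel = self.make_map()
        pv = pd.Series(0.5, index=panel.marker_ids)
        chrom = panel.chromosome[0]
        same = np.flatnonzero(panel.chromosome == chrom)
        far_pair = None
        for i in same:
            for j in same:
                if abs(panel.position_cM[i] - panel.position_cM[j]) > 45:
                    far_pair = (i, j)
        i, j = far_pair
        pv.iloc[i] = 1e-6
        pv.iloc[j] = 1e-5
        qtl = select_qtl(pv, 1e-3, panel)
        assert len(qtl) == 2

    def test_forced_markers_always_included(self):
        panel = self.make_map()
        pv = pd.Series(0.5, index=panel.marker_ids)
        qtl = select_qtl(pv, 1e-3, panel, forced_markers=[panel.marker_ids[3]])
        assert qtl.marker_ids == [panel.marker_ids[3]]


class TestPredictionModels:
    def test_qgblup_with_no_qtl_reduces_to_gblup(self):
        panel, _, trait = small_dataset(seed=41)
        train = panel.genotype_ids[:24]
        a = additive_relationship(panel)
        g1 = fit_prediction_model("GBLUP", trait, panel, train, A=a)
        g2 = fit_prediction_model("QGBLUP", trait, panel, train, qtl=QTLSet(), A=a)
        np.testing.assert_allclose(g1.predictions.to_numpy(),
                                   g2.predictions.to_numpy(), atol=1e-10)

    def test_qtl_model_with_empty_set_fatal(self):
        panel, _, trait = small_dataset(seed=43)
        with pytest.raises(ValueError, match="empty QTL set"):
            fit_prediction_model("QTL", trait, panel, panel.genotype_ids, qtl=QTLSet())

    def test_all_models_cover_every_genotype(self):
        panel, _, trait = small_dataset(seed=47)
        train = panel.genotype_ids[:24]
        qtl = QTLSet(marker_ids=[panel.marker_ids[0]],
                     chromosomes=[str(panel.chromosome[0])],
                     positions=[float(panel.position_cM[0])])
        for model in ("QTL", "GBLUP", "QGBLUP", "RKHS"):
            res = fit_prediction_model(model, trait, panel, train, qtl=qtl, theta=1.0)
            assert list(res.predictions.index) == panel.genotype_ids
            assert np.isfinite(res.predictions.to_numpy()).all()


class TestTuneTheta:
    def test_single_value_grid_returned_without_cv(self, tiny_panel):
        trait = TraitData("t", pd.Series(np.arange(5.0), index=tiny_panel.genotype_ids))
        assert tune_theta(trait, tiny_panel, tiny_panel.genotype_ids, [0.7]) == 0.7

    def test_tiny_training_set_fatal(self, tiny_panel):
        trait = TraitData("t", pd.Series(np.arange(5.0), index=tiny_panel.genotype_ids))
        with pytest.raises(ValueError, match="too small"):
            tune_theta(trait, tiny_panel, tiny_panel.genotype_ids, [0.5, 1.0])

    def test_tie_goes_to_smallest_theta(self, monkeypatch):
        panel, _, trait = small_dataset(seed=3)
        import gptrainsel.models as mdl
        # force every theta to identical ability: predict_blup -> constant map
        monkeypatch.setattr(mdl, "reml_fit", lambda spec: mdl.VarianceComponents(
            sigma2={spec.kernels[0][0]: 0.0}, sigma2_e=1.0, loglik=0.0))
        theta = tune_theta(trait, panel, panel.genotype_ids[:20], [0.5, 1.0, 2.0])
        assert theta == 0.5
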