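"""Moderated model: classical-t limits, shrinkage fixed points, BH, DMS calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpgdiff import BetaMatrix, DifferentialMethylationModel, SpikeConfig, beta_to_m, bh_adjust, generate_annotation, generate_cohort
from cpgdiff.core import ValidationError
from cpgdiff.diffmeth import estimate_prior


def brute_force_bh(p):
    """Independent BH oracle: q_i = min over candidate thresholds t >= p_i of t*m/#{p<=t}."""
    p = np.asarray(p, float)
    m = len(p)
    out = np.empty(m)
    for i, pi in enumerate(p):
        candidates = [t * m / np.sum(p <= t) for t in p if t >= pi]
        out[i] = min(1.0, min(candidates))
    return out


def _mmatrix_from(values: np.ndarray, groups, pair_ids=None):
    samples = [f"s{i}" for i in range(values.shape[1])]
    md = pd.DataFrame(
        {"group": groups, "pair_id": pair_ids if pair_ids is not None else [None] * len(samples)},
        index=pd.Index(samples, name="sample"),
    )
    from cpgdiff.preprocess import MMatrix

    return MMatrix(pd.DataFrame(values, index=[f"cg{i}" for i in range(values.shape[0])], columns=samples), md)


class TestModeratedFit:
    def test_unshrunk_equals_classical_paired_t(self):
        rng = np.random.default_rng(0)
        n_pairs = 6
        M = rng.normal(size=(200, 2 * n_pairs))
        groups = ["tumor"] * n_pairs + ["control"] * n_pairs
        pairs = [f"P{i}" for i in range(n_pairs)] * 2
        m = _mmatrix_from(M, groups, pairs)
        res = DifferentialMethylationModel(m, design="paired").fit(shrink=False)
        t_ref, p_ref = stats.ttest_rel(M[:, :n_pairs], M[:, n_pairs:], axis=1)
        assert np.max(np.abs(res.tvalues.to_numpy() - t_ref)) < 1e-10
        assert np.max(np.abs(res.pvalues.to_numpy() - p_ref)) < 1e-10

    def test_unshrunk_equals_classical_two_sample_t(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(200, 11))
        groups = ["tumor"] * 5 + ["control"] * 6
        m = _mmatrix_from(M, groups)
        res = DifferentialMethylationModel(m, design="unpaired").fit(shrink=False)
        t_ref, p_ref = stats.ttest_ind(M[:, :5], M[:, 5:], axis=1, equal_var=True)
        assert np.max(np.abs(res.tvalues.to_numpy() - t_ref)) < 1e-10
        assert np.max(np.abs(res.pvalues.to_numpy() - p_ref)) < 1e-10

    def test_identical_variances_shrink_to_common_value(self):
        """Identical s2_g across probes: d0 -> inf and every posterior variance
        equals s2_g times the chi-square log-bias factor (d/2)/exp(digamma(d/2)),
        which tends to 1 as the residual df grow."""
        from scipy.special import digamma

        rng = np.random.default_rng(2)
        base = rng.normal(size=8)
        M = np.tile(base, (50, 1))
        signs = rng.choice([-1.0, 1.0], size=50)
        M = M * signs[:, None]  # same variance, varying sign/mean
        M = M + rng.normal(size=(50, 1))  # per-probe offset, variance unchanged
        groups = ["tumor"] * 4 + ["control"] * 4
        pairs = [f"P{i}" for i in range(4)] * 2
        m = _mmatrix_from(M, groups, pairs)
        res = DifferentialMethylationModel(m, design="paired").fit()
        assert np.isinf(res.df_prior)
        d = 3.0  # 4 pairs -> 3 residual df
        factor = (d / 2.0) / np.exp(digamma(d / 2.0))
        assert np.allclose(res.s2_post.to_numpy(), res.sigma2.to_numpy() * factor, rtol=1e-8)

    def test_infinite_prior_df_shrinks_fully(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(100, 10))
        m = _mmatrix_from(M, ["tumor"] * 5 + ["control"] * 5)
        res = DifferentialMethylationModel(m, design="unpaired").fit(prior_df=np.inf)
        assert np.allclose(res.s2_post.to_numpy(), res.s2_prior)

    def test_s2_post_between_prior_and_observed(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(300, 10)) * rng.uniform(0.5, 2.0, size=(300, 1))
        m = _mmatrix_from(M, ["tumor"] * 5 + ["control"] * 5)
        res = DifferentialMethylationModel(m, design="unpaired").fit()
        lo = np.minimum(res.sigma2, res.s2_prior)
        hi = np.maximum(res.sigma2, res.s2_prior)
        assert ((res.s2_post >= lo - 1e-12) & (res.s2_post <= hi + 1e-12)).all()
        assert res.df_prior > 0

    def test_prior_recovers_known_hyperparameters(self):
        """Sampling variances from the scaled-inverse-chi2 prior recovers (d0, s02)."""
        rng = np.random.default_rng(5)
        d0_true, s02_true, d_g = 8.0, 0.5, 7
        sigma2 = d0_true * s02_true / rng.chisquare(d0_true, size=20_000)
        s2 = sigma2 * rng.chisquare(d_g, size=20_000) / d_g
        d0, s02 = estimate_prior(s2, np.full(20_000, float(d_g)))
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s02 == pytest.approx(s02_true, rel=0.05)

    def test_paired_and_unpaired_agree_without_pair_effects(self):
        rng = np.random.default_rng(6)
        M = rng.normal(size=(50, 12))
        groups = ["tumor"] * 6 + ["control"] * 6
        pairs = [f"P{i}" for i in range(6)] * 2
        coef_paired = DifferentialMethylationModel(_mmatrix_from(M, groups, pairs), design="paired").fit().coef
        coef_unpaired = DifferentialMethylationModel(_mmatrix_from(M, groups), design="unpaired").fit().coef
        assert np.allclose(coef_paired.to_numpy(), coef_unpaired.to_numpy(), atol=1e-12)

    def test_design_size_requirements(self):
        rng = np.random.default_rng(7)
        M = rng.normal(size=(10, 2))
        with pytest.raises(ValidationError):
            DifferentialMethylationModel(_mmatrix_from(M, ["tumor", "control"], ["P1", "P1"]), design="paired")
        with pytest.raises(ValidationError):
            DifferentialMethylationModel(_mmatrix_from(M, ["tumor", "control"]), design="unpaired")

    def test_summary_mentions_design_and_prior(self):
        rng = np.random.default_rng(8)
        M = rng.normal(size=(20, 10))
        res = DifferentialMethylationModel(_mmatrix_from(M, ["tumor"] * 5 + ["control"] * 5), design="unpaired").fit()
        text = res.summary()
        assert "unpaired" in text and "prior df" in text


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
            ([0.3], [0.3]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        p = rng.uniform(size=500)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValidationError):
            bh_adjust([-0.1])

    def test_series_index_preserved(self):
        s = pd.Series([0.01, 0.5], index=["a", "b"])
        q = bh_adjust(s)
        assert list(q.index) == ["a", "b"]


class TestCallDMS:
    def test_direction_from_delta_beta(self, small_cohort):
        _, _, beta, truth = small_cohort
        paired = beta.subset_samples([s for s in beta.samples if beta.metadata.loc[s, "pair_id"] is not None])
        res = DifferentialMethylationModel(beta_to_m(paired), design="paired").fit()
        dms = res.call_dms(paired, alpha=0.05)
        assert len(dms) > 0
        assert ((dms.records["delta_beta"] < 0) == (dms.records["direction"] == "hypo")).all()
        assert (dms.records["adj_p"] < 0.05).all()

    def test_high_power_spikes_all_called(self):
        ann = generate_annotation(1000, seed=20)
        cfg = SpikeConfig(
            n_probes=1000, n_spiked_dms=50, delta_beta_effect=0.30, noise_sd=0.05, global_hypo_shift=0.0, seed=20
        )
        beta, truth = generate_cohort(ann, cfg)
        paired = beta.subset_samples([s for s in beta.samples if beta.metadata.loc[s, "pair_id"] is not None])
        res = DifferentialMethylationModel(beta_to_m(paired), design="paired").fit()
        dms = res.call_dms(paired, alpha=0.05)
        assert set(truth.spiked_probes) <= set(dms.probe_ids)

    def test_alpha_validation(self, small_cohort):
        _, _, beta, _ = small_cohort
        paired = beta.subset_samples([s for s in beta.samples if beta.metadata.loc[s, "pair_id"] is not None])
        res = DifferentialMethylationModel(beta_to_m(paired), design="paired").fit()
        with pytest.raises(ValidationError):
            res.call_dms(paired, alpha=1.5)

    def test_null_pvalues_approximately_uniform(self):
        """Pooled moderated p-values under the global null pass a KS uniformity check."""
        pooled = []
        for rep in range(5):
            ann = generate_annotation(1000, seed=100 + rep)
            cfg = SpikeConfig(n_probes=1000, n_spiked_dms=0, n_dmr_blocks=0, global_hypo_shift=0.0, seed=100 + rep)
            beta, _ = generate_cohort(ann, cfg)
            paired = beta.subset_samples([s for s in beta.samples if beta.metadata.loc[s, "pair_id"] is not None])
            res = DifferentialMethylationModel(beta_to_m(paired), design="paired").fit()
            pooled.append(res.pvalues.to_numpy())
        ks = stats.kstest(np.concatenate(pooled), "uniform")
        assert ks.pvalue > 0.01
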