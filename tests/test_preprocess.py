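"""Probe filtering, beta/M transform, covariate residualization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cpgdiff import BetaMatrix, beta_to_m, filter_probes, m_to_beta, residualize_covariates
from cpgdiff.core import ValidationError
from cpgdiff.preprocess import MMatrix, pca_covariate_screen
from conftest import make_annotation


class TestBetaMTransform:
    @pytest.mark.parametrize(
        "beta,expected",
        [
            (0.5, 0.0),  # symmetry point
            (0.8, 2.0),  # log2(4)
            (0.2, -2.0),
        ],
    )
    def test_known_values(self, beta, expected):
        assert beta_to_m(np.array([beta])) == pytest.approx(expected, abs=1e-12)

    def test_boundary_clipped_at_epsilon(self):
        # beta=0 clips to eps=1e-3: M = log2(0.001/0.999)
        expected = math.log2(0.001 / 0.999)
        assert expected == pytest.approx(-9.96434, abs=1e-4)
        assert beta_to_m(np.array([0.0]), epsilon=1e-3)[0] == pytest.approx(expected, abs=1e-12)

    def test_invalid_epsilon(self):
        with pytest.raises(ValidationError):
            beta_to_m(np.array([0.5]), epsilon=0.7)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1 - 1e-3))
    def test_round_trip_property(self, x):
        assert m_to_beta(beta_to_m(np.array([x]))) == pytest.approx(x, abs=1e-12)

    def test_matrix_interface_preserves_shape(self, tiny_beta):
        m = beta_to_m(tiny_beta)
        assert isinstance(m, MMatrix)
        assert list(m.probe_ids) == list(tiny_beta.probe_ids)
        assert list(m.samples) == list(tiny_beta.samples)
        back = m_to_beta(m)
        clipped = tiny_beta.values.clip(1e-3, 1 - 1e-3)
        assert np.allclose(back.to_numpy(), clipped.to_numpy(), atol=1e-12)


class TestFilterProbes:
    def _setup(self):
        rows = []
        for i in range(10):
            rows.append(
                {
                    "probe_id": f"cg{i}",
                    "chromosome": "chrX" if i >= 8 else "chr1",
                    "snp": i in (0, 1),
                    "cpg": i != 2,
                }
            )
        ann = make_annotation(rows)
        values = pd.DataFrame(
            np.full((10, 4), 0.5), index=[f"cg{i}" for i in range(10)], columns=["a", "b", "c", "d"]
        )
        md = pd.DataFrame(
            {"group": ["tumor", "tumor", "control", "control"]},
            index=pd.Index(["a", "b", "c", "d"], name="sample"),
        )
        return BetaMatrix(values, md), ann

    def test_reason_tallies_and_precedence(self):
        beta, ann = self._setup()
        filtered, report = filter_probes(beta, ann)
        assert report.n_removed_snp == 2
        assert report.n_removed_noncpg == 1
        assert report.n_removed_sex_chrom == 2
        assert report.n_retained == 5
        assert filtered.n_probes == 5

    def test_detection_failure_removed_first(self):
        beta, ann = self._setup()
        det = pd.DataFrame(np.zeros((10, 4)), index=beta.probe_ids, columns=beta.samples)
        det.loc["cg0"] = 0.9  # SNP probe also failing detection -> counted under detection
        det.loc["cg5", "a"] = 0.9
        filtered, report = filter_probes(beta, ann, detection_p=det)
        assert report.n_removed_detection == 2
        assert report.n_removed_snp == 1  # cg1 only
        assert "cg5" in report.removed["detection"]

    def test_keep_sex_chrom_flag(self):
        beta, ann = self._setup()
        filtered, report = filter_probes(beta, ann, keep_sex_chrom=True)
        assert report.n_removed_sex_chrom == 0
        assert "cg8" in list(filtered.probe_ids)

    def test_idempotent(self):
        beta, ann = self._setup()
        once, _ = filter_probes(beta, ann)
        twice, report2 = filter_probes(once, ann)
        assert twice.n_probes == once.n_probes
        assert report2.n_removed_snp == report2.n_removed_noncpg == report2.n_removed_sex_chrom == 0

    def test_detection_shape_mismatch(self):
        beta, ann = self._setup()
        det = pd.DataFrame(np.zeros((9, 4)), index=list(beta.probe_ids)[:9], columns=beta.samples)
        with pytest.raises(ValidationError, match="mismatch"):
            filter_probes(beta, ann, detection_p=det)


class TestResidualization:
    def _m(self, values, samples=None):
        samples = samples or [f"s{i}" for i in range(values.shape[1])]
        md = pd.DataFrame({"group": ["tumor"] * len(samples)}, index=pd.Index(samples, name="sample"))
        return MMatrix(pd.DataFrame(values, index=[f"cg{i}" for i in range(values.shape[0])], columns=samples), md)

    def test_exact_linear_fit_gives_zero_residuals(self):
        age = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = self._m((2.0 * age + 1.0).reshape(1, -1))
        cov = pd.DataFrame({"age": age}, index=m.samples)
        out = residualize_covariates(m, cov)
        assert np.allclose(out.values.to_numpy(), 0.0, atol=1e-10)

    def test_orthogonal_covariate_changes_nothing_but_centering(self):
        rng = np.random.default_rng(0)
        cov_vec = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        M = np.vstack([rng.normal(size=6) for _ in range(5)])
        M = M - M.mean(axis=1, keepdims=True)
        # project out the covariate direction so M is orthogonal to it
        M = M - np.outer(M @ cov_vec / (cov_vec @ cov_vec), cov_vec)
        m = self._m(M)
        cov = pd.DataFrame({"x": cov_vec}, index=m.samples)
        out = residualize_covariates(m, cov)
        assert np.allclose(out.values.to_numpy(), M, atol=1e-10)

    def test_residuals_uncorrelated_with_covariates(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(20, 12))
        m = self._m(M)
        cov = pd.DataFrame({"age": rng.normal(size=12), "afp": rng.normal(size=12)}, index=m.samples)
        out = residualize_covariates(m, cov)
        R = out.values.to_numpy()
        for c in cov.columns:
            x = cov[c] - cov[c].mean()
            assert np.max(np.abs(R @ x.to_numpy())) < 1e-10

    def test_projection_idempotent(self):
        rng = np.random.default_rng(2)
        m = self._m(rng.normal(size=(10, 8)))
        cov = pd.DataFrame({"age": rng.normal(size=8)}, index=m.samples)
        once = residualize_covariates(m, cov)
        twice = residualize_covariates(once, cov)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-10)

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(3)
        m = self._m(rng.normal(size=(5, 6)))
        x = rng.normal(size=6)
        cov = pd.DataFrame({"a": x, "b": 2 * x}, index=m.samples)
        with pytest.raises(ValidationError, match="rank"):
            residualize_covariates(m, cov)

    def test_pca_screen_flags_driving_covariate(self):
        rng = np.random.default_rng(4)
        cov_vec = rng.normal(size=10)
        M = np.outer(rng.normal(size=50), cov_vec) + rng.normal(scale=0.05, size=(50, 10))
        m = self._m(M)
        cov = pd.DataFrame({"batch": cov_vec}, index=m.samples)
        screen = pca_covariate_screen(m, cov, n_components=2)
        assert abs(screen.loc["PC1", "batch"]) > 0.9
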