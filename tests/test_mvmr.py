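"""Multivariable MR: instrument assembly and the joint IVW fit."""
import numpy as np
import pytest

from mrkit import assemble_mvmr_set, ivw, mvmr_ivw, simulate_mvmr
from mrkit.mvmr import MVMRRecord, MVMRSet
from mrkit.simulate import MVMRSimulationConfig

from conftest import make_dataset, make_harmonized


def _mv_set(X, y, sy, labels=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = labels or [f"exp{i + 1}" for i in range(X.shape[1])]
    recs = [
        MVMRRecord(f"rs{j}", X[j], np.full(X.shape[1], 0.01), float(y[j]), float(sy[j]))
        for j in range(X.shape[0])
    ]
    return MVMRSet("outcome", labels, recs)


def mvmr_normal_equations_oracle(X, y, sy):
    W = np.diag(1.0 / np.asarray(sy) ** 2)
    xtwx = X.T @ W @ X
    params = np.linalg.solve(xtwx, X.T @ W @ y)
    resid = y - X @ params
    rss_w = float(resid @ W @ resid)
    scale = max(1.0, rss_w / (X.shape[0] - X.shape[1]))
    se = np.sqrt(np.diag(np.linalg.inv(xtwx)) * scale)
    return params, se


class TestAssemble:
    def _exposures(self):
        rows1 = [dict(vid=v, ea="A", oa="G", beta=0.1) for v in "abcde"]
        rows2 = [dict(vid=v, ea="A", oa="G", beta=0.05) for v in "abcde"]
        return make_dataset(rows1, "e1"), make_dataset(rows2, "e2")

    def test_union_under_full_coverage(self):
        e1, e2 = self._exposures()
        outcome = make_dataset([dict(vid=v, ea="A", oa="G") for v in "abcde"], "out")
        mv = assemble_mvmr_set([e1, e2], outcome, [["a", "b", "c"], ["c", "d"]])
        assert [r.variant_id for r in mv.records] == ["a", "b", "c", "d"]

    def test_variant_absent_in_one_exposure_excluded_with_reason(self):
        e1, e2 = self._exposures()
        e2.associations.pop("b")
        outcome = make_dataset([dict(vid=v, ea="A", oa="G") for v in "abcde"], "out")
        mv = assemble_mvmr_set([e1, e2], outcome, [["a", "b", "c"], ["c", "d"]])
        assert [r.variant_id for r in mv.records] == ["a", "c", "d"]
        assert ("b", "absent in e2") in mv.audit

    def test_alignment_flips_sign_onto_primary_allele(self):
        e1 = make_dataset([dict(vid=v, ea="A", oa="G", beta=0.1) for v in "abcd"], "e1")
        e2 = make_dataset([dict(vid=v, ea="G", oa="A", beta=0.05, eaf=0.3) for v in "abcd"], "e2")
        outcome = make_dataset([dict(vid=v, ea="A", oa="G", beta=0.02) for v in "abcd"], "out")
        mv = assemble_mvmr_set([e1, e2], outcome, [list("abcd"), list("abcd")])
        assert mv.records[0].beta_exposures[1] == pytest.approx(-0.05)
        assert mv.records[0].beta_outcome == pytest.approx(0.02)

    def test_under_identified_is_hard_error(self):
        e1 = make_dataset([dict(vid=v, ea="A", oa="G") for v in "ab"], "e1")
        e2 = make_dataset([dict(vid=v, ea="A", oa="G") for v in "ab"], "e2")
        outcome = make_dataset([dict(vid=v, ea="A", oa="G") for v in "ab"], "out")
        with pytest.raises(ValueError, match="under-identified"):
            assemble_mvmr_set([e1, e2], outcome, [["a"], ["b"]])

    def test_palindromic_dropped(self):
        e1 = make_dataset(
            [dict(vid="p", ea="A", oa="T")] + [dict(vid=v, ea="A", oa="G") for v in "abc"], "e1"
        )
        e2 = make_dataset(
            [dict(vid="p", ea="A", oa="T")] + [dict(vid=v, ea="A", oa="G") for v in "abc"], "e2"
        )
        outcome = make_dataset(
            [dict(vid="p", ea="A", oa="T")] + [dict(vid=v, ea="A", oa="G") for v in "abc"], "out"
        )
        ids = list("abcp")
        mv = assemble_mvmr_set([e1, e2], outcome, [ids, ids])
        assert ("p", "palindromic") in mv.audit


class TestMVMRIVW:
    def test_exact_linear_system_recovered(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.05, 0.3, size=(6, 2))
        y = X @ np.array([0.3, 0.2])
        est = mvmr_ivw(_mv_set(X, y, [0.01] * 6))
        np.testing.assert_allclose(est.theta, [0.3, 0.2], rtol=1e-10)
        assert np.all(np.isfinite(est.se))

    def test_zero_co_exposure_reduces_to_univariable_ivw(self, rng):
        bx = rng.uniform(0.05, 0.3, 8)
        by = rng.normal(0, 0.03, 8)
        sy = rng.uniform(0.01, 0.05, 8)
        X = np.column_stack([bx, np.zeros(8)])
        est = mvmr_ivw(_mv_set(X, by, sy))
        uni = ivw(make_harmonized(bx, by, sy))
        assert est.theta[0] == pytest.approx(uni.theta, rel=1e-9)
        assert est.theta[1] == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.uniform(0.05, 0.3, size=(8, 2))
        y = rng.normal(0, 0.05, 8)
        sy = rng.uniform(0.01, 0.05, 8)
        est = mvmr_ivw(_mv_set(X, y, sy))
        params, se = mvmr_normal_equations_oracle(X, y, sy)
        np.testing.assert_allclose(est.theta, params, rtol=1e-8)
        np.testing.assert_allclose(est.se, se, rtol=1e-8)

    def test_collinear_exposures_hard_error_names_them(self, rng):
        x = rng.uniform(0.05, 0.3, 6)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="exp1, exp2"):
            mvmr_ivw(_mv_set(X, rng.normal(0, 0.05, 6), [0.01] * 6))

    def test_orthogonal_co_exposure_leaves_primary_unchanged(self, rng):
        bx = rng.uniform(0.05, 0.3, 10)
        sy = rng.uniform(0.01, 0.05, 10)
        w = 1.0 / sy**2
        raw = rng.normal(0, 0.1, 10)
        x2 = raw - bx * (np.sum(w * bx * raw) / np.sum(w * bx * bx))  # weighted-orthogonal
        y = rng.normal(0, 0.05, 10)
        joint = mvmr_ivw(_mv_set(np.column_stack([bx, x2]), y, sy))
        uni = ivw(make_harmonized(bx, y, sy))
        assert joint.theta[0] == pytest.approx(uni.theta, rel=1e-8)

    def test_scale_equivariance_per_column(self, rng):
        X = rng.uniform(0.05, 0.3, size=(8, 2))
        y = rng.normal(0, 0.05, 8)
        sy = rng.uniform(0.01, 0.05, 8)
        base = mvmr_ivw(_mv_set(X, y, sy))
        X2 = X.copy()
        X2[:, 1] *= 3.0
        scaled = mvmr_ivw(_mv_set(X2, y, sy))
        assert scaled.theta[0] == pytest.approx(base.theta[0], rel=1e-9)
        assert scaled.theta[1] == pytest.approx(base.theta[1] / 3.0, rel=1e-9)

    def test_results_frame_shape(self, rng):
        X = rng.uniform(0.05, 0.3, size=(8, 2))
        est = mvmr_ivw(_mv_set(X, rng.normal(0, 0.05, 8), [0.02] * 8))
        frame = est.to_frame()
        assert list(frame["exposure"]) == ["exp1", "exp2"]
        assert frame.loc[0, "adjusted_for"] == "exp2"
        np.testing.assert_allclose(frame["or"], np.exp(est.theta))


class TestEndToEnd:
    def test_simulated_direct_effects_recovered(self):
        cfg = MVMRSimulationConfig(thetas=(0.3, 0.2), seed=11)
        exposures, outcome, truth = simulate_mvmr(cfg)
        inst = [ds.variant_ids() for ds in exposures]
        mv = assemble_mvmr_set(exposures, outcome, inst)
        est = mvmr_ivw(mv)
        for i in range(2):
            assert abs(est.theta[i] - truth["thetas"][i]) < 3 * est.se[i]

    def test_confounded_univariable_biased_but_mvmr_recenters(self):
        """With theta1 = 0 and a confounder loading on exposure 1 and the
        outcome, univariable IVW on exposure-1 instruments is biased away
        from zero; including a confounder-proxy co-exposure re-centers the
        direct effect near zero."""
        uni_est, mv_est = [], []
        for seed in range(40):
            cfg = MVMRSimulationConfig(
                thetas=(0.0, 0.0),
                gamma_means=(0.08, 0.0),
                gamma_sds=(0.02, 1e-4),
                confounder_loadings=(1.0, 1.0),
                confounder_outcome=1.0,
                n_variants=50,
                seed=seed,
            )
            exposures, outcome, _ = simulate_mvmr(cfg)
            from mrkit.summary_io import harmonize

            hs = harmonize(exposures[0], outcome)
            uni_est.append(ivw(hs).theta)
            mv = assemble_mvmr_set(exposures, outcome, [ds.variant_ids() for ds in exposures])
            mv_est.append(mvmr_ivw(mv).theta[0])
        assert abs(np.mean(uni_est)) > 5 * abs(np.mean(mv_est))
        assert abs(np.mean(mv_est)) < 0.05
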