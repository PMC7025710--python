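import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gada_discrim.cohort_model import Group, IndicatorVector
from gada_discrim.discriminant import (
    DiscriminantModel,
    FisherFunctions,
    ModelArtifact,
    canonical_correlation_from_eigenvalue,
    fisher_classify,
    fit_canonical_lda,
    load_published_model,
    select_by_loading,
    two_stage_fit,
    wilks_from_eigenvalue,
)
from gada_discrim.errors import DomainError, SingularCovarianceError


def random_problem(seed, n1=30, n2=40, p=3, delta_scale=1.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(p, p))
    cov = a @ a.T + p * np.eye(p)
    mu1 = rng.normal(size=p) * delta_scale
    mu2 = rng.normal(size=p) * delta_scale
    x1 = rng.multivariate_normal(mu1, cov, n1)
    x2 = rng.multivariate_normal(mu2, cov, n2)
    X = np.vstack([x1, x2])
    groups = [Group.GADA_POS] * n1 + [Group.T2DM] * n2
    return X, groups


class TestIdentities:
    def test_published_eigenvalue_reproduces_printed_stats(self):
        assert round(wilks_from_eigenvalue(1.106), 3) == 0.475
        assert round(canonical_correlation_from_eigenvalue(1.106), 3) == 0.725

    @pytest.mark.parametrize("seed", range(8))
    def test_lambda_and_canonical_r_identities(self, seed):
        X, groups = random_problem(seed)
        model = fit_canonical_lda(X, groups)
        assert model.wilks_lambda == pytest.approx(1.0 / (1.0 + model.eigenvalue), abs=1e-10)
        assert model.canonical_correlation**2 == pytest.approx(
            model.eigenvalue / (1.0 + model.eigenvalue), abs=1e-10
        )
        assert np.all(np.abs(model.loadings) <= 1.0 + 1e-12)
        assert sum(model.priors.values()) == pytest.approx(1.0)

    def test_identical_groups_null_model(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(20, 3))
        X = np.vstack([block, block])
        groups = [Group.GADA_POS] * 20 + [Group.T2DM] * 20
        model = fit_canonical_lda(X, groups)
        assert model.eigenvalue == 0.0
        assert model.wilks_lambda == 1.0
        assert np.allclose(model.loadings, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_predictor_equals_point_biserial(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = 25, 35
        x = np.concatenate([rng.normal(1, 1, n1), rng.normal(0, 1, n2)])
        groups = [Group.GADA_POS] * n1 + [Group.T2DM] * n2
        model = fit_canonical_lda(x[:, None], groups)
        y = np.array([1.0] * n1 + [0.0] * n2)
        r = abs(np.corrcoef(x, y)[0, 1])
        assert model.canonical_correlation == pytest.approx(r, abs=1e-10)
        assert model.wilks_lambda == pytest.approx(1 - r**2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_score_separation_identity(self, seed):
        X, groups = random_problem(seed, n1=28, n2=44)
        model = fit_canonical_lda(X, groups)
        n1, n2 = 28, 44
        diff = model.raw_coefficients @ (
            model.group_means[Group.GADA_POS] - model.group_means[Group.T2DM]
        )
        # w'(mu1-mu2) = sqrt(d' S_w^-1 d); eigenvalue = n1 n2 / (n (n-2)) * that squared
        expected = np.sqrt(model.eigenvalue * (n1 + n2) * (n1 + n2 - 2) / (n1 * n2))
        assert diff == pytest.approx(expected, abs=1e-10)

    def test_score_has_unit_pooled_variance(self):
        X, groups = random_problem(11)
        model = fit_canonical_lda(X, groups)
        scores = X @ model.raw_coefficients
        mask = np.array([g is Group.GADA_POS for g in groups])
        s1 = scores[mask] - scores[mask].mean()
        s2 = scores[~mask] - scores[~mask].mean()
        pooled = (s1 @ s1 + s2 @ s2) / (len(scores) - 2)
        assert pooled == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_affine_rescaling_invariance(self, seed):
        X, groups = random_problem(seed, p=4)
        scale = np.array([2.5, 0.1, 40.0, 1.0])
        shift = np.array([-3.0, 10.0, 0.0, 5.0])
        m1 = fit_canonical_lda(X, groups)
        m2 = fit_canonical_lda(X * scale + shift, groups)
        assert np.allclose(m1.std_coefficients, m2.std_coefficients, atol=1e-8)
        assert np.allclose(m1.loadings, m2.loadings, atol=1e-8)
        assert m1.eigenvalue == pytest.approx(m2.eigenvalue, rel=1e-8)
        pred1 = [fisher_classify(m1.fisher, x).predicted for x in X]
        pred2 = [fisher_classify(m2.fisher, x).predicted for x in X * scale + shift]
        assert pred1 == pred2


class TestAgainstReferenceImplementation:
    def test_direction_and_predictions_match_sklearn(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X, groups = random_problem(21, n1=40, n2=60, p=4)
        y = np.array([1 if g is Group.GADA_POS else 0 for g in groups])
        n1, n2 = int(y.sum()), int((1 - y).sum())
        priors = {Group.GADA_POS: n1 / len(y), Group.T2DM: n2 / len(y)}
        model = fit_canonical_lda(X, groups, priors=priors)
        ref = sklearn.LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        # canonical direction is parallel to the reference discriminant direction
        w_ref = ref.coef_.ravel()
        cosine = w_ref @ model.raw_coefficients / (
            np.linalg.norm(w_ref) * np.linalg.norm(model.raw_coefficients)
        )
        assert abs(cosine) == pytest.approx(1.0, abs=1e-8)
        ours = [fisher_classify(model.fisher, x).predicted is Group.GADA_POS for x in X]
        assert np.array_equal(np.array(ours), ref.predict(X).astype(bool))

    @pytest.mark.parametrize("seed", range(6))
    def test_fisher_equals_mahalanobis_nearest_centroid(self, seed):
        X, groups = random_problem(seed, n1=15, n2=18, p=3)
        priors = {Group.GADA_POS: 0.3, Group.T2DM: 0.7}
        model = fit_canonical_lda(X, groups, priors=priors)
        C1 = X[:15] - X[:15].mean(axis=0)
        C2 = X[15:] - X[15:].mean(axis=0)
        s_w = (C1.T @ C1 + C2.T @ C2) / (len(X) - 2)
        s_w_inv = np.linalg.inv(s_w)
        for x in X:
            # oracle: argmin Mahalanobis distance with prior offset
            d = {
                g: (x - model.group_means[g]) @ s_w_inv @ (x - model.group_means[g])
                - 2 * np.log(priors[g])
                for g in (Group.GADA_POS, Group.T2DM)
            }
            oracle = min(d, key=d.get)
            assert fisher_classify(model.fisher, x).predicted is oracle

    def test_parameter_recovery_direction(self):
        rng = np.random.default_rng(33)
        p = 4
        cov = np.eye(p) + 0.3
        delta = np.array([1.0, -0.5, 0.25, 0.0])
        w_true = np.linalg.solve(cov, delta)
        angles = {}
        for n in (500, 5000):
            x1 = rng.multivariate_normal(delta, cov, n)
            x2 = rng.multivariate_normal(np.zeros(p), cov, n)
            model = fit_canonical_lda(
                np.vstack([x1, x2]), [Group.GADA_POS] * n + [Group.T2DM] * n
            )
            cosine = w_true @ model.raw_coefficients / (
                np.linalg.norm(w_true) * np.linalg.norm(model.raw_coefficients)
            )
            angles[n] = np.degrees(np.arccos(np.clip(abs(cosine), -1, 1)))
        assert angles[500] < 15.0
        assert angles[5000] < 6.0
        assert angles[5000] < angles[500]


def _mock_model(variables, loadings):
    k = len(variables)
    return DiscriminantModel(
        variables=tuple(variables),
        raw_coefficients=np.zeros(k),
        std_coefficients=np.zeros(k),
        loadings=np.asarray(loadings, dtype=float),
        wilks_lambda=0.5,
        eigenvalue=1.0,
        canonical_correlation=0.7,
        chi2=0.0,
        chi2_df=k,
        p_value=1.0,
        fisher=FisherFunctions(tuple(variables), {}, {}),
        priors={Group.GADA_POS: 0.5, Group.T2DM: 0.5},
        group_means={},
        counts={},
    )


class TestSelection:
    def test_strict_threshold(self):
        model = _mock_model("abcde", [0.63, -0.47, 0.43, 0.30, -0.11])
        sel = select_by_loading(model, 0.3)
        assert sel.retained == ["a", "b", "c"]
        assert sel.dropped == {"d": 0.30, "e": -0.11}

    def test_zero_threshold_keeps_all(self):
        model = _mock_model("abcde", [0.63, -0.47, 0.43, 0.30, -0.11])
        assert select_by_loading(model, 0.0).retained == list("abcde")

    def test_family_retained_as_unit(self):
        model = _mock_model(["a1", "a2", "b"], [0.5, 0.05, 0.1])
        sel = select_by_loading(model, 0.3, families={"a1": "fam", "a2": "fam"})
        assert sel.retained == ["a1", "a2"]
        assert "b" in sel.dropped


class TestTwoStage:
    def test_idempotent_when_all_above_threshold(self):
        X, groups = random_problem(40, n1=200, n2=200, p=2, delta_scale=3.0)
        frame = pd.DataFrame(X, columns=["u", "v"])
        result = two_stage_fit(frame, groups, threshold=0.01)
        assert result.model is result.stage1
        assert result.selection.dropped == {}

    def test_null_columns_dropped_and_refit_differs(self):
        rng = np.random.default_rng(41)
        n = 300
        effect = np.concatenate([rng.normal(1.5, 1, n), rng.normal(0, 1, n)])
        null1 = rng.normal(size=2 * n)
        null2 = rng.normal(size=2 * n)
        frame = pd.DataFrame({"effect": effect, "null1": null1, "null2": null2})
        groups = [Group.GADA_POS] * n + [Group.T2DM] * n
        result = two_stage_fit(frame, groups)
        assert result.model.variables == ("effect",)
        assert set(result.selection.dropped) == {"null1", "null2"}
        # refit loadings recomputed on the retained set
        assert result.model.loadings.shape == (1,)
        assert result.stage1.loadings.shape == (3,)

    def test_all_dropped_is_an_error(self):
        rng = np.random.default_rng(42)
        frame = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        groups = [Group.GADA_POS] * 20 + [Group.T2DM] * 20
        with pytest.raises(DomainError):
            two_stage_fit(frame, groups, threshold=0.999)


class TestDegenerateInputs:
    def test_singular_names_collinear_column(self):
        rng = np.random.default_rng(50)
        a = rng.normal(size=40)
        frame = pd.DataFrame({"a": a, "twice_a": 2 * a})
        groups = [Group.GADA_POS] * 20 + [Group.T2DM] * 20
        with pytest.raises(SingularCovarianceError):
            fit_canonical_lda(frame, groups)

    def test_constant_column_named(self):
        rng = np.random.default_rng(51)
        frame = pd.DataFrame({"a": rng.normal(size=40), "const": np.ones(40)})
        groups = [Group.GADA_POS] * 20 + [Group.T2DM] * 20
        with pytest.raises(SingularCovarianceError) as excinfo:
            fit_canonical_lda(frame, groups)
        assert "const" in excinfo.value.columns

    def test_too_few_members(self):
        with pytest.raises(DomainError):
            fit_canonical_lda(np.zeros((3, 1)), [Group.GADA_POS, Group.T2DM, Group.T2DM])

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            fit_canonical_lda(np.zeros((4, 1)), ["GADA_POS", "T2DM", "OTHER", "T2DM"])

    def test_bad_priors(self):
        X, groups = random_problem(52)
        with pytest.raises(DomainError):
            fit_canonical_lda(X, groups, priors={Group.GADA_POS: 0.7, Group.T2DM: 0.7})


class TestFisherClassify:
    def test_published_constants_at_reference_profile(self):
        artifact = load_published_model()
        score = fisher_classify(artifact.fisher, [0, 0, 0, 0, 0, 0, 0])
        assert score.score_gada == pytest.approx(-7.917)
        assert score.score_t2dm == pytest.approx(-3.764)
        assert score.predicted is Group.T2DM

    def test_hand_summed_bmi_only(self):
        artifact = load_published_model()
        score = fisher_classify(artifact.fisher, [0, 0, 1, 0, 0, 0, 0])
        assert score.delta == pytest.approx(-0.494, abs=1e-9)
        assert score.predicted is Group.T2DM

    def test_hand_summed_bmi_plus_hba1c(self):
        artifact = load_published_model()
        score = fisher_classify(artifact.fisher, [0, 0, 1, 0, 0, 1, 0])
        assert score.delta == pytest.approx(1.037, abs=1e-9)
        assert score.predicted is Group.GADA_POS

    def test_indicator_vector_input(self):
        artifact = load_published_model()
        iv = IndicatorVector(0, 0, 1, 0, 0, 1, 0)
        assert fisher_classify(artifact.fisher, iv).delta == pytest.approx(1.037, abs=1e-9)

    def test_length_mismatch(self):
        artifact = load_published_model()
        with pytest.raises(DomainError):
            fisher_classify(artifact.fisher, [0, 1])

    def test_tie_goes_to_reference_group(self):
        fisher = FisherFunctions(
            ("x",),
            {Group.GADA_POS: np.array([1.0]), Group.T2DM: np.array([1.0])},
            {Group.GADA_POS: 0.0, Group.T2DM: 0.0},
        )
        assert fisher_classify(fisher, [1.0]).predicted is Group.T2DM


class TestArtifact:
    def test_save_load_round_trip(self, tmp_path):
        X, groups = random_problem(60, p=3)
        model = fit_canonical_lda(X, groups, variables=("a", "b", "c"))
        artifact = ModelArtifact.from_model(model, {"a": 1.0})
        path = tmp_path / "model.json"
        artifact.save(path)
        back = ModelArtifact.load(path)
        assert back.variables == artifact.variables
        assert back.cutoffs == artifact.cutoffs
        assert np.allclose(
            back.fisher.coefficients[Group.GADA_POS],
            artifact.fisher.coefficients[Group.GADA_POS],
        )
        assert back.eigenvalue == pytest.approx(artifact.eigenvalue)

    def test_published_artifact_contents(self):
        artifact = load_published_model()
        assert artifact.name == "published"
        assert artifact.cutoffs == {"tg": 98.0, "hba1c": 8.6, "hdl": 46.0}
        assert artifact.fisher.constants[Group.GADA_POS] == -7.917
        assert artifact.fisher.constants[Group.T2DM] == -3.764
        assert artifact.eigenvalue == 1.106
        assert round(wilks_from_eigenvalue(artifact.eigenvalue), 3) == artifact.wilks_lambda
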