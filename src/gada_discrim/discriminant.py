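"""Two-group canonical linear discriminant analysis.

Implements the two-group closed form: the canonical weight vector is
proportional to S_w^{-1} (mu_1 - mu_2) with S_w the pooled within-group
covariance on n - 2 degrees of freedom, normalized so the pooled
within-group variance of the discriminant score is 1 and oriented so the
case group scores higher.  From the same decomposition come:

* standardized coefficients  = raw weights x pooled within-group SDs,
* structure-matrix loadings  = pooled within-group correlations between each
  predictor and the discriminant score,
* the eigenvalue of S_w^{-1} S_b, Wilks' lambda = 1/(1 + eigenvalue) and the
  canonical correlation sqrt(eigenvalue/(1 + eigenvalue)),
* per-group Fisher classification functions
  f_g(x) = mu_g' S_w^{-1} x - 1/2 mu_g' S_w^{-1} mu_g + ln(prior_g),
  assigning each record to the group with the larger score.

Variable selection retains predictors whose structure loading exceeds 0.3 in
absolute value (strictly); the two-stage fit runs the full model, applies the
selection (optionally by variable family), and refits on the survivors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import Group, IndicatorVector
from .errors import DomainError, SingularCovarianceError

LOADING_THRESHOLD = 0.3


def wilks_from_eigenvalue(eigenvalue: float) -> float:
    """Two-group identity: Wilks' lambda = 1 / (1 + eigenvalue)."""
    if eigenvalue < 0:
        raise DomainError(f"eigenvalue must be nonnegative, got {eigenvalue}")
    return 1.0 / (1.0 + eigenvalue)


def canonical_correlation_from_eigenvalue(eigenvalue: float) -> float:
    """Two-group identity: canonical r = sqrt(eigenvalue / (1 + eigenvalue))."""
    if eigenvalue < 0:
        raise DomainError(f"eigenvalue must be nonnegative, got {eigenvalue}")
    return float(np.sqrt(eigenvalue / (1.0 + eigenvalue)))


@dataclass
class FisherFunctions:
    """Per-group linear classification functions over named predictors."""

    variables: tuple
    coefficients: dict  # Group -> np.ndarray aligned to variables
    constants: dict  # Group -> float

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "coefficients": {g.value: np.asarray(c, dtype=float).tolist() for g, c in self.coefficients.items()},
            "constants": {g.value: float(c) for g, c in self.constants.items()},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "FisherFunctions":
        return cls(
            variables=tuple(data["variables"]),
            coefficients={Group(g): np.asarray(c, dtype=float) for g, c in data["coefficients"].items()},
            constants={Group(g): float(c) for g, c in data["constants"].items()},
        )


@dataclass
class FisherScore:
    score_gada: float
    score_t2dm: float

    @property
    def delta(self) -> float:
        return self.score_gada - self.score_t2dm

    @property
    def predicted(self) -> Group:
        # tie goes to the reference group
        return Group.GADA_POS if self.delta > 0 else Group.T2DM


@dataclass
class DiscriminantModel:
    variables: tuple
    raw_coefficients: np.ndarray
    std_coefficients: np.ndarray
    loadings: np.ndarray
    wilks_lambda: float
    eigenvalue: float
    canonical_correlation: float
    chi2: float
    chi2_df: int
    p_value: float
    fisher: FisherFunctions
    priors: dict  # Group -> prior probability
    group_means: dict  # Group -> np.ndarray
    counts: dict  # Group -> n

    def loading_of(self, variable: str) -> float:
        return float(self.loadings[self.variables.index(variable)])


def _find_collinear(within_centered: np.ndarray, variables: Sequence[str]) -> tuple:
    """Columns involved in a rank deficiency, via pivoted QR."""
    _, rmat = np.linalg.qr(within_centered)
    diag = np.abs(np.diag(rmat))
    tol = max(within_centered.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [variables[j] for j in range(len(variables)) if j < diag.size and diag[j] <= tol]
    # constant columns never show variance at all
    const = [variables[j] for j in range(len(variables)) if np.allclose(within_centered[:, j], 0.0)]
    return tuple(dict.fromkeys(const + bad))


def fit_canonical_lda(
    X: Union[np.ndarray, pd.DataFrame],
    groups: Sequence,
    priors: Optional[Mapping] = None,
    variables: Optional[Sequence[str]] = None,
) -> DiscriminantModel:
    """Fit the two-group canonical discriminant model.

    ``groups`` holds :class:`Group` labels (or their string values); priors
    default to equal (0.5/0.5).  Raises :class:`SingularCovarianceError` when
    the pooled within-group covariance is not invertible, naming the
    offending columns.
    """
    if isinstance(X, pd.DataFrame):
        variables = tuple(X.columns) if variables is None else tuple(variables)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        variables = tuple(variables) if variables is not None else tuple(f"x{j}" for j in range(X.shape[1]))
    if X.ndim != 2 or X.shape[1] != len(variables):
        raise DomainError("X must be 2-D with one column per variable")

    labels = [Group(g) for g in groups]
    if len(labels) != X.shape[0]:
        raise DomainError("groups must align with the rows of X")
    mask1 = np.array([g is Group.GADA_POS for g in labels])
    mask2 = np.array([g is Group.T2DM for g in labels])
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise DomainError(f"each group needs >= 2 members, got ({n1}, {n2})")
    n, p = n1 + n2, len(variables)

    X1, X2 = X[mask1], X[mask2]
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    C1, C2 = X1 - mu1, X2 - mu2
    within = np.vstack([C1, C2])
    s_w = (C1.T @ C1 + C2.T @ C2) / (n - 2)

    if np.linalg.matrix_rank(s_w) < p:
        cols = _find_collinear(within, variables)
        raise SingularCovarianceError(
            f"pooled within-group covariance is singular; suspect columns: {list(cols)}", cols
        )

    d = mu1 - mu2
    w_raw = np.linalg.solve(s_w, d)
    mahalanobis_sq = float(d @ w_raw)  # d' S_w^-1 d >= 0

    within_sd = np.sqrt(np.diag(s_w))
    if mahalanobis_sq <= 1e-12:
        # identical group means: null discriminant
        w = np.zeros(p)
        eigenvalue = 0.0
        loadings = np.zeros(p)
    else:
        w = w_raw / np.sqrt(mahalanobis_sq)  # w' S_w w = 1, w'd > 0
        eigenvalue = (n1 * n2) / (n * (n - 2)) * mahalanobis_sq
        loadings = (s_w @ w) / within_sd

    wilks = wilks_from_eigenvalue(eigenvalue)
    can_r = canonical_correlation_from_eigenvalue(eigenvalue)
    # Bartlett's chi-square approximation for H0: no group separation
    chi2 = -(n - 1 - (p + 2) / 2.0) * np.log(wilks) if wilks > 0 else float("inf")
    p_value = float(stats.chi2.sf(chi2, p))

    if priors is None:
        priors = {Group.GADA_POS: 0.5, Group.T2DM: 0.5}
    else:
        priors = {Group(g): float(v) for g, v in priors.items()}
        total = sum(priors.values())
        if not np.isclose(total, 1.0):
            raise DomainError(f"priors must sum to 1, got {total}")

    s_w_inv = np.linalg.inv(s_w)
    coefficients, constants = {}, {}
    for group, mu in ((Group.GADA_POS, mu1), (Group.T2DM, mu2)):
        coef = s_w_inv @ mu
        coefficients[group] = coef
        constants[group] = float(-0.5 * mu @ coef + np.log(priors[group]))

    return DiscriminantModel(
        variables=variables,
        raw_coefficients=w,
        std_coefficients=w * within_sd,
        loadings=loadings,
        wilks_lambda=float(wilks),
        eigenvalue=float(eigenvalue),
        canonical_correlation=float(can_r),
        chi2=float(chi2),
        chi2_df=p,
        p_value=p_value,
        fisher=FisherFunctions(variables=variables, coefficients=coefficients, constants=constants),
        priors=priors,
        group_means={Group.GADA_POS: mu1, Group.T2DM: mu2},
        counts={Group.GADA_POS: n1, Group.T2DM: n2},
    )


@dataclass
class SelectionResult:
    retained: list
    dropped: dict  # variable -> loading
    threshold: float


def select_by_loading(
    model: DiscriminantModel,
    threshold: float = LOADING_THRESHOLD,
    families: Optional[Mapping[str, str]] = None,
) -> SelectionResult:
    """Retain variables with |structure loading| strictly above ``threshold``.

    With ``families`` (variable -> family name), a family is retained as a
    unit when any of its members exceeds the threshold — the convention used
    for the age and BMI bin dummies, which travel together.
    """
    families = dict(families or {})
    family_of = {v: families.get(v, v) for v in model.variables}
    family_max: dict[str, float] = {}
    for v, loading in zip(model.variables, model.loadings):
        fam = family_of[v]
        family_max[fam] = max(family_max.get(fam, 0.0), abs(float(loading)))

    retained, dropped = [], {}
    for v, loading in zip(model.variables, model.loadings):
        if family_max[family_of[v]] > threshold:
            retained.append(v)
        else:
            dropped[v] = float(loading)
    return SelectionResult(retained=retained, dropped=dropped, threshold=threshold)


@dataclass
class TwoStageResult:
    model: DiscriminantModel
    stage1: DiscriminantModel
    selection: SelectionResult


def two_stage_fit(
    X: pd.DataFrame,
    groups: Sequence,
    threshold: float = LOADING_THRESHOLD,
    priors: Optional[Mapping] = None,
    families: Optional[Mapping[str, str]] = None,
) -> TwoStageResult:
    """Fit on all candidates, drop low-loading variables, refit on survivors.

    The refit recomputes loadings on the retained set, so they generally
    differ from the stage-1 values.
    """
    if not isinstance(X, pd.DataFrame):
        raise DomainError("two_stage_fit needs a named design matrix (DataFrame)")
    stage1 = fit_canonical_lda(X, groups, priors=priors)
    selection = select_by_loading(stage1, threshold=threshold, families=families)
    if not selection.retained:
        raise DomainError("no variable exceeded the loading threshold; nothing to refit")
    if list(selection.retained) == list(X.columns):
        return TwoStageResult(model=stage1, stage1=stage1, selection=selection)
    final = fit_canonical_lda(X[selection.retained], groups, priors=priors)
    return TwoStageResult(model=final, stage1=stage1, selection=selection)


def fisher_classify(fisher: FisherFunctions, iv) -> FisherScore:
    """Score a record's indicators with the per-group classification functions.

    ``iv`` may be an :class:`IndicatorVector` (matched to the function's
    variables by name) or a plain sequence aligned to ``fisher.variables``.
    """
    if isinstance(iv, IndicatorVector):
        mapping = iv.as_dict()
        try:
            x = np.array([mapping[v] for v in fisher.variables], dtype=float)
        except KeyError as exc:
            raise DomainError(f"indicator vector lacks variable {exc.args[0]!r}")
    else:
        x = np.asarray(iv, dtype=float)
        if x.shape != (len(fisher.variables),):
            raise DomainError(
                f"expected {len(fisher.variables)} indicator values, got shape {x.shape}"
            )
    score = {
        g: float(fisher.coefficients[g] @ x + fisher.constants[g])
        for g in (Group.GADA_POS, Group.T2DM)
    }
    return FisherScore(score_gada=score[Group.GADA_POS], score_t2dm=score[Group.T2DM])


# ---------------------------------------------------------------------------
# Model artifact (JSON serialization)
# ---------------------------------------------------------------------------


@dataclass
class ModelArtifact:
    """Self-contained scoring artifact: Fisher functions plus encoding cutoffs."""

    variables: tuple
    fisher: FisherFunctions
    cutoffs: dict  # variable -> cutoff value, for the *_ge_cut indicators
    std_coefficients: Optional[list] = None
    loadings: Optional[list] = None
    eigenvalue: Optional[float] = None
    wilks_lambda: Optional[float] = None
    canonical_correlation: Optional[float] = None
    priors: Optional[dict] = None
    name: str = "derived"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "variables": list(self.variables),
            "fisher": self.fisher.to_dict(),
            "cutoffs": {k: float(v) for k, v in self.cutoffs.items()},
            "std_coefficients": self.std_coefficients,
            "loadings": self.loadings,
            "eigenvalue": self.eigenvalue,
            "wilks_lambda": self.wilks_lambda,
            "canonical_correlation": self.canonical_correlation,
            "priors": {g.value: v for g, v in self.priors.items()} if self.priors else None,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelArtifact":
        priors = data.get("priors")
        return cls(
            variables=tuple(data["variables"]),
            fisher=FisherFunctions.from_dict(data["fisher"]),
            cutoffs=dict(data["cutoffs"]),
            std_coefficients=data.get("std_coefficients"),
            loadings=data.get("loadings"),
            eigenvalue=data.get("eigenvalue"),
            wilks_lambda=data.get("wilks_lambda"),
            canonical_correlation=data.get("canonical_correlation"),
            priors={Group(g): float(v) for g, v in priors.items()} if priors else None,
            name=data.get("name", "derived"),
        )

    @classmethod
    def load(cls, path) -> "ModelArtifact":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_model(cls, model: DiscriminantModel, cutoffs: Mapping[str, float], name: str = "derived") -> "ModelArtifact":
        return cls(
            variables=model.variables,
            fisher=model.fisher,
            cutoffs=dict(cutoffs),
            std_coefficients=np.asarray(model.std_coefficients, dtype=float).tolist(),
            loadings=np.asarray(model.loadings, dtype=float).tolist(),
            eigenvalue=model.eigenvalue,
            wilks_lambda=model.wilks_lambda,
            canonical_correlation=model.canonical_correlation,
            priors=model.priors,
            name=name,
        )


def load_published_model() -> ModelArtifact:
    """The published coefficients and cutoffs, shipped with the package."""
    text = resources.files("gada_discrim").joinpath("data/published_model.json").read_text()
    return ModelArtifact.from_dict(json.loads(text))
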