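"""Two-group synthetic cohort generator.

The published study reports only marginal summaries per group (mean +/- SD
for continuous variables, bin percentages for age and BMI, prevalences for
binary flags).  This module generates cohorts whose marginals emulate those
summaries so that the full pipeline can be exercised without patient data.

Joint dependence between continuous variables is a Gaussian copula with a
user-supplied latent correlation matrix.  The default correlations
(TG~HDL -0.4, BMI~TG +0.3, BMI~HDL -0.3, all others 0) are assumptions, not
published values.

Two generation modes:

``MOMENT_MATCH``
    Each continuous marginal is a floor-truncated normal whose parent
    parameters are solved so that the *truncated* mean and SD equal the
    published ones exactly; triglycerides use a moment-matched lognormal
    (sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2).

``BIN_CALIBRATED``
    Age and BMI bins are drawn first from the published bin proportions and
    values are drawn conditionally within the bin, so bin frequencies match
    the published table in expectation (mean/SD then only approximate).
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
from scipy import optimize, stats

from .cohort_model import Cohort, Gender, Group, PatientRecord
from .errors import ConfigError

#: Continuous variables in latent-correlation order.
CONTINUOUS_VARS = (
    "age_onset",
    "bmi",
    "total_chol",
    "tg",
    "hdl",
    "hba1c",
    "gpt",
    "creatinine",
)

#: Lower truncation floors (physiology / eligibility).
FLOORS = {
    "age_onset": 20.0,
    "hba1c": 4.0,
    "bmi": 0.0,
    "total_chol": 0.0,
    "tg": 0.0,
    "hdl": 0.0,
    "gpt": 0.0,
    "creatinine": 0.0,
}

#: Bin edges for the calibrated mode (right edge of last bin is +inf).
AGE_BIN_EDGES = (20.0, 30.0, 50.0, np.inf)
BMI_BIN_EDGES = (0.0, 23.0, 25.0, np.inf)


class SimMode(str, enum.Enum):
    MOMENT_MATCH = "MOMENT_MATCH"
    BIN_CALIBRATED = "BIN_CALIBRATED"


@dataclass
class GroupSpec:
    """Marginal summaries for one group."""

    n: int
    continuous: dict  # variable -> (mean, sd)
    bin_probs: dict  # {"age": (p1,p2,p3), "bmi": (p1,p2,p3)}
    binary_prevalence: dict  # {"male","smoking","statin","fibrate"} -> proportion
    tg_lognormal: bool = True

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"group size must be >= 1, got {self.n}")
        for var, (mean, sd) in self.continuous.items():
            if sd <= 0:
                raise ConfigError(f"{var}: sd must be > 0, got {sd}")
            if mean <= FLOORS.get(var, 0.0) and var != "age_onset":
                raise ConfigError(f"{var}: mean {mean} below floor")
        for key, probs in self.bin_probs.items():
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigError(f"bin_probs[{key!r}] must be 3 nonnegative values summing to 1")
        for key, p in self.binary_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"binary_prevalence[{key!r}] must be in [0,1], got {p}")


@dataclass
class SimConfig:
    gada: GroupSpec
    t2dm: GroupSpec
    correlation: np.ndarray  # over CONTINUOUS_VARS, latent Gaussian copula
    seed: int = 0
    mode: SimMode = SimMode.MOMENT_MATCH

    def validate(self) -> None:
        self.gada.validate()
        self.t2dm.validate()
        corr = np.asarray(self.correlation, dtype=float)
        k = len(CONTINUOUS_VARS)
        if corr.shape != (k, k):
            raise ConfigError(f"correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ConfigError("correlation matrix must have a unit diagonal")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise ConfigError("correlation matrix is not positive definite")

    def to_dict(self) -> dict:
        def spec_dict(spec: GroupSpec) -> dict:
            return {
                "n": spec.n,
                "continuous": {k: list(v) for k, v in spec.continuous.items()},
                "bin_probs": {k: list(v) for k, v in spec.bin_probs.items()},
                "binary_prevalence": dict(spec.binary_prevalence),
                "tg_lognormal": spec.tg_lognormal,
            }

        return {
            "gada": spec_dict(self.gada),
            "t2dm": spec_dict(self.t2dm),
            "correlation": np.asarray(self.correlation, dtype=float).tolist(),
            "seed": int(self.seed),
            "mode": self.mode.value,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        def spec(d: Mapping) -> GroupSpec:
            return GroupSpec(
                n=int(d["n"]),
                continuous={k: tuple(v) for k, v in d["continuous"].items()},
                bin_probs={k: tuple(v) for k, v in d["bin_probs"].items()},
                binary_prevalence=dict(d["binary_prevalence"]),
                tg_lognormal=bool(d.get("tg_lognormal", True)),
            )

        return cls(
            gada=spec(data["gada"]),
            t2dm=spec(data["t2dm"]),
            correlation=np.asarray(data["correlation"], dtype=float),
            seed=int(data.get("seed", 0)),
            mode=SimMode(data.get("mode", "MOMENT_MATCH")),
        )

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_correlation() -> np.ndarray:
    """Assumed latent correlations; everything not listed is 0."""
    corr = np.eye(len(CONTINUOUS_VARS))
    idx = {v: i for i, v in enumerate(CONTINUOUS_VARS)}
    for a, b, r in (("tg", "hdl", -0.4), ("bmi", "tg", 0.3), ("bmi", "hdl", -0.3)):
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return corr


def default_config(seed: int = 0, mode: SimMode = SimMode.MOMENT_MATCH) -> SimConfig:
    """Config populated from the published per-group summary table."""
    gada = GroupSpec(
        n=152,
        continuous={
            "age_onset": (37.6, 12.6),
            "bmi": (21.7, 3.8),
            "total_chol": (184.0, 46.9),
            "tg": (82.9, 65.2),
            "hdl": (58.0, 18.7),
            "hba1c": (10.5, 3.2),
            "gpt": (25.1, 18.7),
            "creatinine": (0.8, 0.2),
        },
        bin_probs={"age": (0.316, 0.493, 0.191), "bmi": (0.750, 0.105, 0.145)},
        binary_prevalence={"male": 0.487, "smoking": 0.217, "statin": 0.033, "fibrate": 0.007},
    )
    t2dm = GroupSpec(
        n=358,
        continuous={
            "age_onset": (50.4, 11.7),
            "bmi": (26.8, 4.5),
            "total_chol": (194.4, 41.9),
            "tg": (162.2, 119.9),
            "hdl": (42.7, 10.5),
            "hba1c": (8.2, 2.3),
            "gpt": (35.2, 29.2),
            "creatinine": (0.8, 0.2),
        },
        bin_probs={"age": (0.050, 0.372, 0.578), "bmi": (0.173, 0.196, 0.631)},
        binary_prevalence={"male": 0.564, "smoking": 0.179, "statin": 0.017, "fibrate": 0.014},
    )
    return SimConfig(gada=gada, t2dm=t2dm, correlation=default_correlation(), seed=seed, mode=mode)


# ---------------------------------------------------------------------------
# Marginal machinery
# ---------------------------------------------------------------------------


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _truncated_moments(mu: float, sigma: float, floor: float) -> tuple[float, float]:
    alpha = (floor - mu) / sigma
    lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)
    mean = mu + sigma * lam
    var = sigma**2 * (1.0 + alpha * lam - lam**2)
    return mean, float(np.sqrt(var))


@lru_cache(maxsize=None)
def matched_truncnorm_params(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose floor-truncated normal has the target moments.

    Falls back to (mean, sd) when truncation is negligible (floor more than
    eight parent SDs below the mean) or when the solver fails to improve.
    """
    if (floor - mean) / sd < -8.0:
        return mean, sd

    def objective(params):
        mu, log_sigma = params
        m, s = _truncated_moments(mu, float(np.exp(log_sigma)), floor)
        return [m - mean, s - sd]

    sol = optimize.root(objective, [mean, np.log(sd)], method="hybr")
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    if not sol.success or not np.all(np.isfinite([mu, sigma])):
        return mean, sd
    return mu, sigma


def _truncnorm_quantile(u: np.ndarray, mu: float, sigma: float, floor: float) -> np.ndarray:
    qlo = stats.norm.cdf((floor - mu) / sigma)
    return mu + sigma * stats.norm.ppf(qlo + u * (1.0 - qlo))


def _bin_calibrated_quantile(
    u: np.ndarray, mean: float, sd: float, probs, edges
) -> np.ndarray:
    """Draw from published bin probabilities, then within-bin from the base normal."""
    probs = np.asarray(probs, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(probs)])
    cum[-1] = 1.0
    out = np.empty_like(u)
    for k in range(len(probs)):
        mask = (u >= cum[k]) & (u < cum[k + 1]) if k < len(probs) - 1 else u >= cum[k]
        if not np.any(mask):
            continue
        v = (u[mask] - cum[k]) / max(cum[k + 1] - cum[k], 1e-300)
        qlo = stats.norm.cdf((edges[k] - mean) / sd)
        qhi = stats.norm.cdf((edges[k + 1] - mean) / sd) if np.isfinite(edges[k + 1]) else 1.0
        q = np.clip(qlo + v * (qhi - qlo), 1e-12, 1.0 - 1e-12)
        out[mask] = mean + sd * stats.norm.ppf(q)
    return out


def _generate_group(rng: np.random.Generator, spec: GroupSpec, corr: np.ndarray, mode: SimMode, group: Group) -> list:
    n = spec.n
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(CONTINUOUS_VARS))) @ chol.T
    u = stats.norm.cdf(z)

    values: dict[str, np.ndarray] = {}
    for j, var in enumerate(CONTINUOUS_VARS):
        mean, sd = spec.continuous[var]
        floor = FLOORS[var]
        if var == "tg" and spec.tg_lognormal:
            mu, sigma = lognormal_params(mean, sd)
            values[var] = np.exp(mu + sigma * z[:, j])
        elif mode is SimMode.BIN_CALIBRATED and var in ("age_onset", "bmi"):
            key, edges = ("age", AGE_BIN_EDGES) if var == "age_onset" else ("bmi", BMI_BIN_EDGES)
            values[var] = _bin_calibrated_quantile(u[:, j], mean, sd, spec.bin_probs[key], edges)
        else:
            mu, sigma = matched_truncnorm_params(mean, sd, floor)
            values[var] = _truncnorm_quantile(u[:, j], mu, sigma, floor)

    flags = {
        key: rng.random(n) < spec.binary_prevalence[key]
        for key in ("male", "smoking", "statin", "fibrate")
    }

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                group=group,
                gender=Gender.M if flags["male"][i] else Gender.F,
                smoking=bool(flags["smoking"][i]),
                statin=bool(flags["statin"][i]),
                fibrate=bool(flags["fibrate"][i]),
                **{var: float(values[var][i]) for var in CONTINUOUS_VARS},
            )
        )
    return records


def generate_cohort(cfg: SimConfig) -> Cohort:
    """Deterministic (per seed) synthetic cohort: cases first, then references."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    corr = np.asarray(cfg.correlation, dtype=float)
    records = _generate_group(rng, cfg.gada, corr, cfg.mode, Group.GADA_POS)
    records += _generate_group(rng, cfg.t2dm, corr, cfg.mode, Group.T2DM)
    return Cohort(records=records, provenance=f"synthetic:{cfg.content_hash()}:seed={cfg.seed}")
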