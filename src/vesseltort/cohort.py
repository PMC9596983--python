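"""Synthetic patient cohorts with the statistical structure of a
flow-diverter ISS study.

One row per patient: demographics, comorbidities, aneurysm/procedure
features and parent-artery tortuosity metrics, plus binary outcomes
``co`` (complete occlusion) and ``iss`` (in-stent stenosis).  Continuous
features are drawn from two-parameter families moment-matched to published
cohort summaries (lognormal for strictly positive skewed metrics - the
curvature summaries have SD exceeding the mean, implying strong right
skew - normal otherwise, logit-normal for DM which lives in (0, 1)).

ISS is generated from a logistic model on a chosen coefficient map; the
intercept is calibrated on the realized sample so the expected prevalence
equals the requested one.  Default coefficients encode the reported effect
directions: risk increases with maximum curvature and hypertension and
decreases with DM.  CO is drawn independently at its marginal prevalence
(no covariate was associated with CO).
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.special import expit, logit

__all__ = [
    "CONTINUOUS_FEATURES",
    "BINARY_FEATURES",
    "DEFAULT_ISS_COEF",
    "make_cohort",
]

# name -> (mean, sd, family); units: years, kg/m^2, cm, mm, 1/mm as relevant
CONTINUOUS_FEATURES: dict[str, tuple[float, float, str]] = {
    "age": (54.2, 9.2, "normal"),
    "bmi": (25.1, 3.7, "normal"),
    "height": (161.5, 7.0, "normal"),
    "aneurysm_neck": (6.2, 2.8, "lognormal"),
    "max_diameter": (9.4, 4.7, "lognormal"),
    "parent_artery_diameter": (3.8, 0.7, "normal"),
    "mean_curvature": (0.6, 0.5, "lognormal"),
    "max_curvature": (5.3, 8.9, "lognormal"),
    "mean_torsion": (12.4, 4.2, "lognormal"),
    "max_torsion": (45.4, 16.2, "lognormal"),
    "dm": (0.5, 0.2, "logitnormal"),
    "path_length": (23.9, 9.5, "lognormal"),
}

#: derived continuous columns (not drawn independently)
DERIVED_FEATURES = ("range_curvature", "range_torsion", "straight_distance")

# name -> prevalence
BINARY_FEATURES: dict[str, float] = {
    "female": 0.758,
    "hypertension": 0.435,
    "diabetes": 0.081,
    "hyperlipidemia": 0.387,
    "allergy": 0.113,
    "smoking": 0.210,
    "alcohol": 0.145,
    "symptomatic": 0.581,
    "ruptured": 0.048,
    "ped_coiling": 0.484,
    "ped_flex": 0.597,
    "multiple_ped": 0.129,
    "balloon_angioplasty": 0.226,
    "parent_stenosis": 0.048,
}

#: natural-scale logistic coefficients for the ISS outcome; the maximum
#: curvature coefficient is ln(1.084) per 1/mm, the DM coefficient ln(0.01)
#: per unit DM, hypertension a positive log-odds bump
DEFAULT_ISS_COEF: dict[str, float] = {
    "max_curvature": float(np.log(1.084)),
    "dm": float(np.log(0.01)),
    "hypertension": 0.9,
}

CO_PREVALENCE = 0.79


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _logitnormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a logit-normal by Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def moments(p):
        mu, log_sigma = p
        x = expit(mu + np.exp(log_sigma) * nodes)
        m = np.dot(weights, x)
        v = np.dot(weights, (x - m) ** 2)
        return [m - mean, np.sqrt(v) - sd]

    res = least_squares(moments, x0=[logit(mean), np.log(max(2.2 * sd, 1e-3))])
    mu, log_sigma = res.x
    return float(mu), float(np.exp(log_sigma))


def _draw_continuous(name: str, n: int, rng: np.random.Generator) -> np.ndarray:
    mean, sd, family = CONTINUOUS_FEATURES[name]
    if family == "normal":
        return rng.normal(mean, sd, n)
    if family == "lognormal":
        mu, sigma = _lognormal_params(mean, sd)
        return rng.lognormal(mu, sigma, n)
    if family == "logitnormal":
        mu, sigma = _logitnormal_params(mean, sd)
        return expit(rng.normal(mu, sigma, n))
    raise ValueError(family)


def make_cohort(
    n: int = 62,
    iss_prevalence: float = 0.355,
    coef: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
    co_prevalence: float = CO_PREVALENCE,
) -> pd.DataFrame:
    """Simulate a per-patient cohort table with binary ``iss``/``co`` outcomes.

    Parameters
    ----------
    n:
        Number of patients (>= 20 so the downstream inference is usable).
    iss_prevalence:
        Target expected ISS fraction; the logistic intercept is solved on
        the realized sample so the mean predicted risk equals this value.
    coef:
        Natural-scale logistic coefficients per feature; defaults to
        :data:`DEFAULT_ISS_COEF`.  An empty map gives a null cohort.
    seed:
        Seed for all randomness; same seed, same table.
    """
    if n < 20:
        raise ValueError("n must be at least 20")
    if not 0.0 < iss_prevalence < 1.0:
        raise ValueError("iss_prevalence must lie in (0, 1)")
    use_coef = DEFAULT_ISS_COEF if coef is None else dict(coef)
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for name in CONTINUOUS_FEATURES:
        cols[name] = _draw_continuous(name, n, rng)
    # minimum curvature/torsion along a vessel is essentially zero, so the
    # range summaries coincide with the maxima (as the clinical tables show)
    cols["range_curvature"] = cols["max_curvature"].copy()
    cols["range_torsion"] = cols["max_torsion"].copy()
    cols["straight_distance"] = cols["dm"] * cols["path_length"]
    for name, prev in BINARY_FEATURES.items():
        cols[name] = (rng.uniform(size=n) < prev).astype(int)

    unknown = set(use_coef) - set(cols)
    if unknown:
        raise ValueError(f"coefficients on ungenerated features: {sorted(unknown)}")
    eta = np.zeros(n)
    for name, beta in use_coef.items():
        eta += beta * cols[name]

    def excess(c: float) -> float:
        return float(expit(eta + c).mean()) - iss_prevalence

    intercept = brentq(excess, -50.0, 50.0)
    p_iss = expit(eta + intercept)
    cols["iss"] = (rng.uniform(size=n) < p_iss).astype(int)
    cols["co"] = (rng.uniform(size=n) < co_prevalence).astype(int)
    return pd.DataFrame(cols)
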