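"""Maximum-likelihood degree-distribution fitting and AIC model selection.

Candidate families are normal, Poisson, exponential, gamma and lognormal.
Degree samples are counts, but the continuous families are fitted with
their densities directly (no continuity correction): the point of the
exercise is to ask which textbook family best summarises a degree
histogram, and the normal routinely appears as the Poisson's limit.
Zero counts are permitted for the exponential (its density at 0 is
finite); gamma and lognormal require strictly positive samples and are
reported as unavailable otherwise.

AIC = 2k - 2 log L with k the number of free parameters.  The normal
sigma is the 1/n MLE (not the unbiased variant) so the AIC identity holds
exactly; standard errors come from the observed information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = ["FitResult", "fit_candidates", "select_aic", "aic_table", "params_table"]

FAMILY_ORDER = ("normal", "poisson", "exponential", "gamma", "lognormal")
_N_PARAMS = {"normal": 2, "poisson": 1, "exponential": 1, "gamma": 2, "lognormal": 2}


@dataclass
class FitResult:
    """One candidate family's MLE fit to a degree sample."""

    family: str
    params: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    loglik: float = math.nan
    aic: float = math.nan
    n: int = 0
    available: bool = True
    message: str = ""

    @property
    def k(self) -> int:
        return _N_PARAMS[self.family]


def _unavailable(family: str, n: int, message: str) -> FitResult:
    return FitResult(family=family, n=n, available=False, message=message)


def _finish(family: str, n: int, params: dict, se: dict, loglik: float) -> FitResult:
    return FitResult(
        family=family,
        params=params,
        se=se,
        loglik=loglik,
        aic=2.0 * _N_PARAMS[family] - 2.0 * loglik,
        n=n,
    )


def _fit_normal(x: np.ndarray) -> FitResult:
    n = x.size
    mu = float(x.mean())
    sigma = float(math.sqrt(np.mean((x - mu) ** 2)))
    if sigma == 0.0:
        return _unavailable("normal", n, "degenerate sample (zero variance)")
    loglik = float(stats.norm.logpdf(x, mu, sigma).sum())
    se = {"mean": sigma / math.sqrt(n), "sd": sigma / math.sqrt(2 * n)}
    return _finish("normal", n, {"mean": mu, "sd": sigma}, se, loglik)


def _fit_poisson(x: np.ndarray) -> FitResult:
    n = x.size
    if np.any(x != np.floor(x)) or np.any(x < 0):
        return _unavailable("poisson", n, "sample is not non-negative integer")
    rate = float(x.mean())
    loglik = float(stats.poisson.logpmf(x.astype(int), rate).sum())
    se = {"mean": math.sqrt(rate / n) if rate > 0 else 0.0}
    return _finish("poisson", n, {"mean": rate}, se, loglik)


def _fit_exponential(x: np.ndarray) -> FitResult:
    n = x.size
    if np.any(x < 0) or x.mean() <= 0:
        return _unavailable("exponential", n, "needs non-negative sample with mean > 0")
    rate = float(1.0 / x.mean())
    # log L = n log(rate) - rate * sum(x): depends on the data only through the mean
    loglik = float(n * math.log(rate) - rate * x.sum())
    se = {"rate": rate / math.sqrt(n)}
    return _finish("exponential", n, {"rate": rate}, se, loglik)


def _fit_gamma(x: np.ndarray) -> FitResult:
    n = x.size
    if np.any(x <= 0):
        return _unavailable("gamma", n, "needs strictly positive sample")
    try:
        shape, _, scale = stats.gamma.fit(x, floc=0.0)
    except Exception as exc:  # pragma: no cover - scipy failure path
        return _unavailable("gamma", n, f"MLE failed: {exc}")
    loglik = float(stats.gamma.logpdf(x, shape, scale=scale).sum())
    # observed information per observation: [[psi'(a), 1/theta], [1/theta, a/theta^2]]
    info = n * np.array(
        [
            [special.polygamma(1, shape), 1.0 / scale],
            [1.0 / scale, shape / scale**2],
        ]
    )
    cov = np.linalg.inv(info)
    se = {"shape": math.sqrt(cov[0, 0]), "scale": math.sqrt(cov[1, 1])}
    return _finish("gamma", n, {"shape": shape, "scale": scale}, se, loglik)


def _fit_lognormal(x: np.ndarray) -> FitResult:
    n = x.size
    if np.any(x <= 0):
        return _unavailable("lognormal", n, "needs strictly positive sample")
    logs = np.log(x)
    mu = float(logs.mean())
    sigma = float(math.sqrt(np.mean((logs - mu) ** 2)))
    if sigma == 0.0:
        return _unavailable("lognormal", n, "degenerate sample (zero variance)")
    loglik = float(stats.norm.logpdf(logs, mu, sigma).sum() - logs.sum())
    se = {"log_mean": sigma / math.sqrt(n), "log_sd": sigma / math.sqrt(2 * n)}
    return _finish("lognormal", n, {"log_mean": mu, "log_sd": sigma}, se, loglik)


_FITTERS = {
    "normal": _fit_normal,
    "poisson": _fit_poisson,
    "exponential": _fit_exponential,
    "gamma": _fit_gamma,
    "lognormal": _fit_lognormal,
}


def fit_candidates(sample, families=FAMILY_ORDER) -> list[FitResult]:
    """Fit every candidate family to a degree sample by maximum likelihood."""
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("sample must be 1-d with at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample must be finite")
    unknown = set(families) - set(FAMILY_ORDER)
    if unknown:
        raise ValueError(f"unknown families {sorted(unknown)}")
    return [_FITTERS[f](x) for f in FAMILY_ORDER if f in families]


def select_aic(fits: list[FitResult]) -> FitResult:
    """Fit with minimal AIC; ties go to fewer parameters, then family order."""
    avail = [f for f in fits if f.available]
    if not avail:
        raise ValueError("no candidate distribution could be fitted")
    return min(avail, key=lambda f: (f.aic, f.k, FAMILY_ORDER.index(f.family)))


def aic_table(fits_by_sample: dict[str, list[FitResult]]):
    """AIC per (family, sample) in the layout of a model-comparison table."""
    import pandas as pd

    rows = {}
    for name, fits in fits_by_sample.items():
        rows[name] = {f.family: (f.aic if f.available else math.nan) for f in fits}
    return pd.DataFrame(rows).reindex(list(FAMILY_ORDER))


def params_table(fits_by_sample: dict[str, list[FitResult]]):
    """Selected family and its parameter estimates (with SEs) per sample."""
    import pandas as pd

    records = []
    for name, fits in fits_by_sample.items():
        best = select_aic(fits)
        records.append(
            {
                "sample": name,
                "family": best.family,
                "params": "; ".join(
                    f"{k}={v:.4g} ({best.se.get(k, math.nan):.2g})"
                    for k, v in best.params.items()
                ),
                "aic": best.aic,
            }
        )
    return pd.DataFrame.from_records(records)
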