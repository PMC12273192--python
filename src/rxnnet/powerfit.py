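"""Discrete heavy-tail fitting, k_min selection and likelihood-ratio tests.

Degree distributions of reaction networks are integer-valued and heavy
tailed.  This module fits the discrete (zeta) power law

    P(k) = k^(-gamma) / zeta(gamma, k_min),    k >= k_min,

by maximum likelihood, selects the tail start ``k_min`` by minimizing the
Kolmogorov-Smirnov distance between the empirical and fitted tail CCDFs,
fits five alternative tail families (truncated power law, log-normal,
positive log-normal, exponential, stretched exponential), and compares
fitted families with the Vuong normalized log-likelihood-ratio test.

Continuous alternatives are discretized by the probability mass they place
on unit intervals centred at the integers: ``P(k) = F(k + 1/2) -
F(k - 1/2)``, renormalized over ``k >= k_min``.  The truncated power law is
defined directly on the integers, ``P(k) proportional to k^(-gamma)
exp(-rate k)``, normalized by direct summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp, zeta

__all__ = [
    "FAMILIES",
    "FitError",
    "DegreeSample",
    "TailFit",
    "LRTestResult",
    "degree_sample",
    "empirical_ccdf",
    "fit_power_law",
    "fit_alternative",
    "select_kmin",
    "compare",
]

FAMILIES = (
    "power_law",
    "truncated_power_law",
    "lognormal",
    "lognormal_positive",
    "exponential",
    "stretched_exponential",
)

_GAMMA_BOUNDS = (1.0 + 1e-9, 20.0)
_TPL_RATE_BOUNDS = (3e-5, 20.0)


class FitError(ValueError):
    """A tail fit could not be performed on the given sample."""


@dataclass
class DegreeSample:
    """An integer degree sample with its provenance."""

    values: np.ndarray
    direction: str = "out"  # {'in', 'out'}
    node_scope: str = "all"  # {'all', 'molecules', 'reactions'}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)


def degree_sample(net, direction: str = "out", node_scope: str = "all") -> DegreeSample:
    """Degree sample of a bipartite :class:`~rxnnet.graphs.ReactionNetwork`."""
    from .graphs import MOLECULE, REACTION

    g = net.graph
    scopes = {"all": None, "molecules": MOLECULE, "reactions": REACTION}
    if node_scope not in scopes:
        raise ValueError(f"unknown node_scope {node_scope!r}")
    want = scopes[node_scope]
    deg_view = g.in_degree() if direction == "in" else g.out_degree()
    values = [d for (n, d) in deg_view if want is None or g.nodes[n]["kind"] == want]
    return DegreeSample(np.asarray(values), direction=direction, node_scope=node_scope)


@dataclass
class TailFit:
    """A fitted tail family on the observations at or above ``kmin``."""

    family: str
    params: dict[str, float]
    kmin: int
    loglik: float
    ks_distance: float
    n_tail: int
    tail: np.ndarray = field(repr=False)

    def logpmf(self, k) -> np.ndarray:
        """Log probability mass of the fitted family at integer ``k >= kmin``."""
        k = np.asarray(k, dtype=np.float64)
        return _family_logpmf(self.family, self.params, self.kmin, k)

    def ccdf(self, k) -> np.ndarray:
        """Fitted tail CCDF ``P(K >= k)`` at integer ``k >= kmin``."""
        k = np.asarray(k, dtype=np.float64)
        return _family_ccdf(self.family, self.params, self.kmin, k)

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "kmin": self.kmin,
            "loglik": self.loglik,
            "ks_distance": self.ks_distance,
            "n_tail": self.n_tail,
        }


@dataclass(frozen=True)
class LRTestResult:
    """Vuong test between two tail fits of the same sample."""

    family_a: str
    family_b: str
    R: float
    p_value: float
    preferred: str


# ---------------------------------------------------------------------------
# Family log-pmfs and CCDFs
# ---------------------------------------------------------------------------


def _family_logpmf(family: str, params: dict, kmin: int, k: np.ndarray) -> np.ndarray:
    if family == "power_law":
        g = params["gamma"]
        return -g * np.log(k) - np.log(zeta(g, kmin))
    if family == "exponential":
        lam = params["rate"]
        return np.log1p(-np.exp(-lam)) - lam * (k - kmin)
    if family == "truncated_power_law":
        g, lam = params["gamma"], params["rate"]
        return -g * np.log(k) - lam * k - _tpl_log_norm(g, lam, kmin)
    if family in ("lognormal", "lognormal_positive"):
        mu, sigma = params["mu"], params["sigma"]
        upper = stats.norm.sf((np.log(k + 0.5) - mu) / sigma)
        lower = stats.norm.sf((np.log(k - 0.5) - mu) / sigma)
        norm = stats.norm.sf((np.log(kmin - 0.5) - mu) / sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(lower - upper) - np.log(norm)
    if family == "stretched_exponential":
        lam, beta = params["rate"], params["shape"]
        upper = np.exp(-((lam * (k + 0.5)) ** beta))
        lower = np.exp(-((lam * (k - 0.5)) ** beta))
        norm = np.exp(-((lam * (kmin - 0.5)) ** beta))
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(lower - upper) - np.log(norm)
    raise FitError(f"unknown family {family!r}")


def _family_ccdf(family: str, params: dict, kmin: int, k: np.ndarray) -> np.ndarray:
    if family == "power_law":
        g = params["gamma"]
        return zeta(g, k) / zeta(g, kmin)
    if family == "exponential":
        lam = params["rate"]
        return np.exp(-lam * (k - kmin))
    if family == "truncated_power_law":
        g, lam = params["gamma"], params["rate"]
        log_norm = _tpl_log_norm(g, lam, kmin)
        out = np.empty_like(k, dtype=np.float64)
        for i, kk in enumerate(np.atleast_1d(k)):
            out.flat[i] = np.exp(_tpl_log_norm(g, lam, int(kk)) - log_norm)
        return out
    if family in ("lognormal", "lognormal_positive"):
        mu, sigma = params["mu"], params["sigma"]
        return stats.norm.sf((np.log(k - 0.5) - mu) / sigma) / stats.norm.sf(
            (np.log(kmin - 0.5) - mu) / sigma
        )
    if family == "stretched_exponential":
        lam, beta = params["rate"], params["shape"]
        return np.exp(-((lam * (k - 0.5)) ** beta) + (lam * (kmin - 0.5)) ** beta)
    raise FitError(f"unknown family {family!r}")


def _tpl_log_norm(gamma: float, rate: float, kmin: int) -> float:
    """log sum_{k>=kmin} k^-gamma e^(-rate k), by summation with a tail bound."""
    n_terms = min(int(40.0 / rate) + 16, 2_000_000)
    ks = np.arange(kmin, kmin + n_terms, dtype=np.float64)
    return float(logsumexp(-gamma * np.log(ks) - rate * ks))


# ---------------------------------------------------------------------------
# Empirical quantities
# ---------------------------------------------------------------------------


def _as_values(sample) -> np.ndarray:
    if isinstance(sample, DegreeSample):
        return sample.values
    return np.asarray(sample, dtype=np.int64)


def empirical_ccdf(sample) -> list[tuple[int, float]]:
    """``(k, P(K >= k))`` at each observed value, decreasing in probability."""
    values = _as_values(sample)
    if values.size == 0:
        raise FitError("empty sample")
    uniq, counts = np.unique(values, return_counts=True)
    ccdf = 1.0 - np.concatenate(([0.0], np.cumsum(counts[:-1]))) / values.size
    return [(int(k), float(p)) for k, p in zip(uniq, ccdf)]


def _tail(values: np.ndarray, kmin: int) -> np.ndarray:
    tail = values[values >= kmin]
    if tail.size == 0:
        raise FitError("empty tail")
    if tail.size < 10:
        raise FitError(f"tail has only {tail.size} observations (need >= 10)")
    if np.unique(tail).size < 2:
        raise FitError("degenerate tail")
    return tail


def _ks_distance(tail: np.ndarray, fit_ccdf) -> float:
    uniq, counts = np.unique(tail, return_counts=True)
    emp = 1.0 - np.concatenate(([0.0], np.cumsum(counts[:-1]))) / tail.size
    return float(np.max(np.abs(emp - fit_ccdf(uniq.astype(np.float64)))))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_power_law(sample, kmin: int) -> TailFit:
    """Discrete power-law MLE on the observations at or above ``kmin``.

    Maximizes ``sum_i [-gamma log k_i] - n log zeta(gamma, kmin)`` by
    bounded scalar optimization of ``gamma`` on (1, 20].
    """
    values = _as_values(sample)
    tail = _tail(values, kmin)
    n = tail.size
    sum_log = float(np.sum(np.log(tail)))

    def nll(g: float) -> float:
        return n * np.log(zeta(g, kmin)) + g * sum_log

    res = optimize.minimize_scalar(nll, bounds=_GAMMA_BOUNDS, method="bounded", options={"xatol": 1e-6})
    gamma = float(res.x)
    params = {"gamma": gamma}
    fit = TailFit(
        family="power_law",
        params=params,
        kmin=kmin,
        loglik=-float(res.fun),
        ks_distance=0.0,
        n_tail=n,
        tail=np.sort(tail),
    )
    fit.ks_distance = _ks_distance(tail, fit.ccdf)
    return fit


def _optimize_family(nll, x0_list, bounds) -> optimize.OptimizeResult:
    best = None
    for x0 in x0_list:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("optimizer failed to converge from all starts")
    return best


def fit_alternative(sample, family: str, kmin: int) -> TailFit:
    """Discrete MLE of an alternative tail family at fixed ``kmin``."""
    if family == "power_law":
        return fit_power_law(sample, kmin)
    if family not in FAMILIES:
        raise FitError(f"unknown family {family!r}")

    values = _as_values(sample)
    tail = _tail(values, kmin)
    n = tail.size
    kf = tail.astype(np.float64)

    if family == "exponential":
        # geometric tail: closed-form MLE
        m = float(np.mean(kf))
        lam = float(np.log1p(1.0 / (m - kmin))) if m > kmin else 20.0
        params = {"rate": lam}
    else:
        params = _fit_multiparam(family, kf, kmin, n)

    loglik = float(np.sum(_family_logpmf(family, params, kmin, kf)))
    fit = TailFit(
        family=family,
        params=params,
        kmin=kmin,
        loglik=loglik,
        ks_distance=0.0,
        n_tail=n,
        tail=np.sort(tail),
    )
    fit.ks_distance = _ks_distance(tail, fit.ccdf)
    return fit


def _fit_multiparam(family: str, kf: np.ndarray, kmin: int, n: int) -> dict[str, float]:
    logk = np.log(kf)
    mu0, s0 = float(np.mean(logk)), max(float(np.std(logk)), 0.05)

    if family in ("lognormal", "lognormal_positive"):
        lo_mu = 0.0 if family == "lognormal_positive" else -20.0

        def nll(x):
            p = {"mu": x[0], "sigma": x[1]}
            lp = _family_logpmf(family, p, kmin, kf)
            return np.inf if not np.all(np.isfinite(lp)) else -float(np.sum(lp))

        starts = [(max(mu0, lo_mu), s0), (max(mu0 + 1.0, lo_mu), 2 * s0), (lo_mu if lo_mu > -20 else mu0 - 1.0, s0 + 0.5)]
        res = _optimize_family(nll, starts, bounds=[(lo_mu, 50.0), (1e-3, 50.0)])
        return {"mu": float(res.x[0]), "sigma": float(res.x[1])}

    if family == "stretched_exponential":

        def nll(x):
            lam, beta = np.exp(x)
            p = {"rate": lam, "shape": beta}
            lp = _family_logpmf(family, p, kmin, kf)
            return np.inf if not np.all(np.isfinite(lp)) else -float(np.sum(lp))

        lam0 = 1.0 / max(float(np.mean(kf)), 1.0)
        starts = [(np.log(lam0), np.log(b)) for b in (0.3, 0.7, 1.2)]
        res = _optimize_family(nll, starts, bounds=[(-18.0, 4.0), (-3.0, 1.6)])
        lam, beta = np.exp(res.x)
        return {"rate": float(lam), "shape": float(beta)}

    if family == "truncated_power_law":

        def nll(x):
            g, lam = x[0], np.exp(x[1])
            p = {"gamma": g, "rate": lam}
            lp = _family_logpmf(family, p, kmin, kf)
            return np.inf if not np.all(np.isfinite(lp)) else -float(np.sum(lp))

        g0 = 1.0 + n / max(float(np.sum(np.log(kf / (kmin - 0.5)))), 1e-9)
        lam_lo, lam_hi = np.log(_TPL_RATE_BOUNDS[0]), np.log(_TPL_RATE_BOUNDS[1])
        starts = [(min(max(g0, 0.1), 19.0), np.log(1e-3)), (2.0, np.log(1e-2)), (1.2, np.log(1e-4))]
        starts = [(g, max(min(l, lam_hi), lam_lo)) for g, l in starts]
        res = _optimize_family(nll, starts, bounds=[(0.05, 20.0), (lam_lo, lam_hi)])
        return {"gamma": float(res.x[0]), "rate": float(np.exp(res.x[1]))}

    raise FitError(f"unknown family {family!r}")  # pragma: no cover


def select_kmin(sample, kmin_candidates: Iterable[int] | None = None) -> TailFit:
    """Power-law fit at the KS-optimal tail start.

    Scans candidate ``kmin`` values (default ``[1, 100]`` intersected with
    the observed support), fits at each, and returns the fit minimizing the
    KS distance between empirical and fitted tail CCDFs.  Ties break toward
    the smaller ``kmin`` (the larger tail).
    """
    values = _as_values(sample)
    if values.size == 0:
        raise FitError("empty sample")
    support_min = int(values[values > 0].min()) if np.any(values > 0) else 1
    support_max = int(values.max())
    if kmin_candidates is None:
        kmin_candidates = range(max(1, support_min), min(100, support_max) + 1)

    best: TailFit | None = None
    for kmin in kmin_candidates:
        try:
            fit = fit_power_law(values, int(kmin))
        except FitError:
            continue
        if best is None or fit.ks_distance < best.ks_distance:
            best = fit
    if best is None:
        raise FitError("no kmin candidate leaves a fittable tail (>= 10 points, non-degenerate)")
    return best


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


def compare(fit_a: TailFit, fit_b: TailFit, significance: float = 0.05) -> LRTestResult:
    """Vuong normalized log-likelihood-ratio test between two fits.

    ``R = (L_a - L_b) / (sigma sqrt(n))`` with ``sigma`` the standard
    deviation of the per-observation log-likelihood differences; the
    two-sided p-value comes from the standard normal.  The sign of ``R``
    picks the preferred family when significant, otherwise the result is
    inconclusive.
    """
    if fit_a.kmin != fit_b.kmin:
        raise ValueError("fits compare different kmin values")
    if fit_a.n_tail != fit_b.n_tail or not np.array_equal(fit_a.tail, fit_b.tail):
        raise ValueError("fits were computed on different samples")

    d = fit_a.logpmf(fit_a.tail) - fit_b.logpmf(fit_b.tail)
    n = d.size
    sd = float(np.std(d))
    if sd == 0.0:
        return LRTestResult(fit_a.family, fit_b.family, 0.0, 1.0, "inconclusive")
    R = float(np.sum(d) / (sd * np.sqrt(n)))
    p = float(2.0 * stats.norm.sf(abs(R)))
    if p < significance:
        preferred = fit_a.family if R > 0 else fit_b.family
    else:
        preferred = "inconclusive"
    return LRTestResult(fit_a.family, fit_b.family, R, p, preferred)
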