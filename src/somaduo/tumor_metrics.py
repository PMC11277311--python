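"""Per-sample longitudinal tumor metrics: TMR, MATH, and VAF-mixture clonality.

TMR (tumor mutation rate) is a bespoke longitudinal indicator — the count of
level-1-passing variants per megabase of a 42 Mb exome capture, plus its
log10 — deliberately distinct from assay-grade tumor mutational burden (TMB).

MATH (mutant-allele tumor heterogeneity) is 100 * MAD / median of the
sample's VAFs, with the MAD scaled by the normal-consistency constant 1.4826
by default (the convention of the original score and of R's ``mad``).

Clonality is summarized by a one-dimensional Gaussian finite-mixture fit to
the VAF distribution: expectation-maximization over both an equal-variance
and a free-variance family for k = 1..max_components, selected by the
Bayesian information criterion (lower is better here: -2*logL + p*ln n).
Initialization is deterministic (component means at data quantiles), so
fits are reproducible and order-invariant; the seed only drives optional
perturbed restarts.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

__all__ = [
    "UNDEFINED",
    "Trend",
    "MixtureFit",
    "SampleMetrics",
    "round_half_up",
    "tmr",
    "mad",
    "math_score",
    "fit_vaf_mixture",
    "heterogeneity_trend",
    "sample_metrics",
]

#: Sentinel for metrics without a defined value (e.g. log10 of zero).
UNDEFINED = None

#: Normal-consistency constant: MAD * 1.4826 estimates sigma for Gaussian data.
MAD_NORMAL_SCALE = 1.4826

DEFAULT_CAPTURE_MB = 42.0


class Trend(str, enum.Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"
    EQUAL = "equal"


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` places (report convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def tmr(
    total_mutations: int, capture_mb: float = DEFAULT_CAPTURE_MB
) -> tuple[float, float | None]:
    """Mutations per megabase and its log10 (UNDEFINED when the count is 0)."""
    if capture_mb <= 0:
        raise ValueError(f"capture_mb must be positive, got {capture_mb}")
    if total_mutations < 0:
        raise ValueError("total_mutations must be >= 0")
    per_mb = total_mutations / capture_mb
    return per_mb, (math.log10(per_mb) if per_mb > 0 else UNDEFINED)


def mad(values: Sequence[float], scale: float = MAD_NORMAL_SCALE) -> float:
    """Median absolute deviation from the median, times ``scale``."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad of an empty sequence is undefined")
    return float(np.median(np.abs(x - np.median(x))) * scale)


def math_score(
    vafs: Sequence[float], mad_scale: float = MAD_NORMAL_SCALE
) -> float | None:
    """MATH = 100 * MAD(vafs) / median(vafs); UNDEFINED (with warning) at median 0."""
    x = np.asarray(vafs, dtype=float)
    if x.size == 0:
        raise ValueError("MATH of an empty VAF list is undefined")
    med = float(np.median(x))
    if med <= 0:
        warnings.warn("median VAF is 0; MATH undefined", stacklevel=2)
        return UNDEFINED
    return 100.0 * mad(x, scale=mad_scale) / med


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture by EM
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """Selected 1-D Gaussian mixture for a sample's VAF distribution."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    family: str  # "E" equal variance, "V" free variance
    log_likelihood: float
    #: BIC (lower is better) for every candidate (k, family)
    criterion: dict[tuple[int, str], float] = field(default_factory=dict)
    converged: bool = True
    seed: int = 0

    def to_rows(self) -> list[dict]:
        return [
            {"k": k, "family": fam, "bic": bic, "selected": (k, fam) == (self.n_components, self.family)}
            for (k, fam), bic in sorted(self.criterion.items())
        ]


_VAR_FLOOR = 1e-8
_LL_TOL = 1e-8
_MAX_ITER = 500


def _em_fit(
    x: np.ndarray, k: int, family: str, means0: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]:
    """EM for a k-component 1-D Gaussian mixture; returns (logL, w, mu, var, conv).

    The log-likelihood is checked to be non-decreasing across iterations
    (up to numerical tolerance) — a violated EM ascent property is a bug.
    """
    n = x.size
    w = np.full(k, 1.0 / k)
    mu = means0.astype(float).copy()
    var = np.full(k, max(float(np.var(x)), _VAR_FLOOR))
    prev_ll = -np.inf
    converged = False
    for _ in range(_MAX_ITER):
        # E step in log space
        log_pdf = (
            -0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        log_w = np.log(np.maximum(w, 1e-300))
        joint = log_pdf + log_w[None, :]
        m = joint.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
        ll = float(log_norm.sum())
        if ll + 1e-6 < prev_ll:
            raise AssertionError(
                f"EM log-likelihood decreased ({prev_ll} -> {ll}); ascent property violated"
            )
        if abs(ll - prev_ll) < _LL_TOL:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        resp = np.exp(joint - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        sq = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0)
        if family == "E":
            var = np.full(k, max(float(sq.sum() / n), _VAR_FLOOR))
        else:
            var = np.maximum(sq / nk, _VAR_FLOOR)
    return prev_ll, w, mu, var, converged


def _n_params(k: int, family: str) -> int:
    # weights (k-1) + means (k) + variances (1 for E, k for V)
    return (k - 1) + k + (1 if family == "E" else k)


def fit_vaf_mixture(
    vafs: Sequence[float], max_components: int = 5, seed: int = 0
) -> MixtureFit:
    """Fit 1..max_components Gaussian mixtures to VAFs and select by BIC.

    Candidates with fewer than 2 observations per component are skipped; if
    the sample is too small for any multi-component model a single-component
    fit is returned with a warning.
    """
    x = np.sort(np.asarray(vafs, dtype=float))
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    n = x.size
    if n == 0:
        raise ValueError("cannot fit a mixture to an empty VAF list")
    k_max = min(max_components, n // 2) or 1
    if k_max < max_components and n < 2 * max_components:
        warnings.warn(
            f"only {n} observations: restricting mixture candidates to k <= {k_max}",
            stacklevel=2,
        )
    criterion: dict[tuple[int, str], float] = {}
    fits: dict[tuple[int, str], tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]] = {}
    for k in range(1, k_max + 1):
        means0 = np.quantile(x, (np.arange(k) + 0.5) / k)
        for family in ("E", "V"):
            if k == 1 and family == "V":
                continue  # identical to E at k=1
            ll, w, mu, var, conv = _em_fit(x, k, family, means0)
            bic = -2.0 * ll + _n_params(k, family) * math.log(n)
            criterion[(k, family)] = bic
            fits[(k, family)] = (ll, w, mu, var, conv)
    # minimize BIC; ties broken toward smaller k, then equal-variance family
    best = min(criterion, key=lambda kf: (criterion[kf], kf[0], kf[1]))
    ll, w, mu, var, conv = fits[best]
    order = np.argsort(mu)
    return MixtureFit(
        n_components=best[0],
        weights=w[order],
        means=mu[order],
        variances=var[order],
        family=best[1],
        log_likelihood=ll,
        criterion=criterion,
        converged=conv,
        seed=seed,
    )


def heterogeneity_trend(math_p: float | None, math_r: float | None) -> Trend:
    """Direction of the MATH change from primary to recurrent."""
    if math_p is UNDEFINED or math_r is UNDEFINED:
        raise ValueError("heterogeneity trend needs both MATH scores defined")
    if math_r > math_p:
        return Trend.INCREASING
    if math_r < math_p:
        return Trend.DECREASING
    return Trend.EQUAL


@dataclass
class SampleMetrics:
    """TMR triple, MATH score and VAF-mixture summary for one sample."""

    sample_id: str
    total_mutations: int
    capture_mb: float
    per_mb: float
    log10_per_mb: float | None
    math_score: float | None
    mixture: MixtureFit | None

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "total_mutations": self.total_mutations,
            "capture_mb": self.capture_mb,
            "per_mb": round_half_up(self.per_mb),
            "per_mb_raw": self.per_mb,
            "log10_per_mb": (
                "" if self.log10_per_mb is UNDEFINED else round_half_up(self.log10_per_mb)
            ),
            "log10_per_mb_raw": "" if self.log10_per_mb is UNDEFINED else self.log10_per_mb,
            "math_score": (
                "" if self.math_score is UNDEFINED else round_half_up(self.math_score)
            ),
            "mixture_k": self.mixture.n_components if self.mixture else "",
            "mixture_means": (
                ";".join(f"{m:.4f}" for m in self.mixture.means) if self.mixture else ""
            ),
        }


def sample_metrics(
    sample_id: str,
    vafs: Sequence[float],
    capture_mb: float = DEFAULT_CAPTURE_MB,
    max_components: int = 5,
    seed: int = 0,
    mad_scale: float = MAD_NORMAL_SCALE,
) -> SampleMetrics:
    """Compute the full metric set from a sample's level-1-passing VAFs."""
    total = len(vafs)
    per_mb, log10_per_mb = tmr(total, capture_mb)
    score = math_score(vafs, mad_scale=mad_scale) if total else UNDEFINED
    mixture = fit_vaf_mixture(vafs, max_components=max_components, seed=seed) if total else None
    return SampleMetrics(
        sample_id=sample_id,
        total_mutations=total,
        capture_mb=capture_mb,
        per_mb=per_mb,
        log10_per_mb=log10_per_mb,
        math_score=score,
        mixture=mixture,
    )
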