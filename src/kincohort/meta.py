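"""DerSimonian-Laird random-effects pooling of penetrance estimates.

Published per-study penetrance is reported as a point estimate with a 95%
confidence interval on the percent scale.  Each study's standard error is
recovered from its CI width on a chosen transform scale (logit by default:
penetrance is a proportion and the source intervals are strongly
asymmetric on the raw scale), the between-study variance tau^2 comes from
the DerSimonian-Laird moment estimator, and heterogeneity is tested with
Cochran's Q against chi^2 on k-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["StudyEstimate", "MetaResult", "se_from_ci", "dl_pool", "SCALES"]

SCALES = ("logit", "log", "identity")

_Z = float(stats.norm.ppf(0.975))  # 1.959964...


@dataclass(frozen=True)
class StudyEstimate:
    """One study's penetrance estimate with 95% CI, on the 0-100 scale."""

    study: str
    estimate: float
    ci_low: float
    ci_high: float
    age_interval: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.estimate
                <= self.ci_high <= 100.0):
            raise ValueError(
                f"study {self.study!r}: require 0 <= ci_low <= estimate "
                f"<= ci_high <= 100, got "
                f"({self.ci_low}, {self.estimate}, {self.ci_high})"
            )


@dataclass
class MetaResult:
    """Pooled estimate with CI (0-100 scale) plus heterogeneity summaries."""

    pooled: float
    ci_low: float
    ci_high: float
    Q: float
    df: int
    p_het: float
    tau2: float
    weights: np.ndarray  # normalized random-effects weights
    scale: str
    k: int


def _transform(scale: str):
    if scale == "logit":
        return (lambda x: np.log(x / (1.0 - x))), stats.logistic.cdf
    if scale == "log":
        return np.log, np.exp
    if scale == "identity":
        # theta lives on the percent scale; back-transform is a no-op
        return (lambda x: x * 100.0), (lambda x: x)
    raise ValueError(f"unknown scale {scale!r}; choose from {SCALES}")


def se_from_ci(est: StudyEstimate, scale: str = "logit") -> tuple[float, float]:
    """Transformed point estimate and standard error from a 95% CI.

    The SE is the full CI width on the transformed scale divided by
    2 x z_0.975; asymmetric intervals are thereby averaged rather than
    taken at their wider half.
    """
    fwd, _ = _transform(scale)
    if scale in ("logit", "log"):
        for name, v in (("ci_low", est.ci_low), ("estimate", est.estimate),
                        ("ci_high", est.ci_high)):
            if v <= 0.0 or (scale == "logit" and v >= 100.0):
                raise ValueError(
                    f"study {est.study!r}: {name}={v} is at the boundary of "
                    f"the {scale} scale; apply a continuity adjustment to "
                    f"the transcribed interval first"
                )
    theta = float(fwd(est.estimate / 100.0))
    se = float((fwd(est.ci_high / 100.0) - fwd(est.ci_low / 100.0)) / (2 * _Z))
    return theta, se


def dl_pool(studies: Sequence[StudyEstimate], scale: str = "logit") -> MetaResult:
    """DerSimonian-Laird random-effects pooling of >= 2 study estimates.

    Fixed-effect weights w0_i = 1/se_i^2 give Cochran's Q; the moment
    estimator tau^2 = max(0, (Q - (k-1)) / (sum w0 - sum w0^2 / sum w0))
    then yields random-effects weights 1/(se_i^2 + tau^2).  The pooled
    estimate and its 95% CI are back-transformed to the 0-100 scale.
    """
    k = len(studies)
    if k < 2:
        raise ValueError("DerSimonian-Laird pooling needs at least 2 studies")
    fwd, back = _transform(scale)
    th, se = map(np.asarray, zip(*(se_from_ci(s, scale) for s in studies)))
    if np.any(se == 0):
        if np.ptp(th) > 0:
            raise ValueError("zero-width CI with discordant estimates")
        common = float(back(th[0])) * (100.0 if scale != "identity" else 1.0)
        return MetaResult(pooled=common, ci_low=common, ci_high=common,
                          Q=0.0, df=k - 1, p_het=1.0, tau2=0.0,
                          weights=np.full(k, 1.0 / k), scale=scale, k=k)

    w0 = 1.0 / se**2
    theta_fixed = float(np.sum(w0 * th) / np.sum(w0))
    Q = float(np.sum(w0 * (th - theta_fixed) ** 2))
    df = k - 1
    denom = np.sum(w0) - np.sum(w0**2) / np.sum(w0)
    tau2 = max(0.0, (Q - df) / denom)
    w = 1.0 / (se**2 + tau2)
    pooled_t = float(np.sum(w * th) / np.sum(w))
    half = _Z / np.sqrt(np.sum(w))
    p_het = float(stats.chi2.sf(Q, df))

    def _back(x: float) -> float:
        v = float(back(x))
        return v if scale == "identity" else 100.0 * v

    return MetaResult(pooled=_back(pooled_t),
                      ci_low=_back(pooled_t - half),
                      ci_high=_back(pooled_t + half),
                      Q=Q, df=df, p_het=p_het, tau2=float(tau2),
                      weights=w / np.sum(w), scale=scale, k=k)
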