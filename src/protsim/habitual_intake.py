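"""Habitual (usual) intake estimation from short-term recall data.

Daily intakes observed on a handful of recall days scatter around each
person's long-run habitual intake, so the distribution of 2-day means is
wider than the habitual distribution.  This module removes that
within-person variance with the standard one-part usual-intake model:

1. transform pooled daily intakes to approximate normality (Box-Cox
   exponent chosen from a fixed grid by profile likelihood);
2. split the transformed-scale variance into between- and within-person
   components (closed-form method of moments, exact for the balanced
   two-day design);
3. shrink each person's transformed mean toward the population mean by
   ``sqrt(s2_b / (s2_b + s2_w / n_i))``;
4. back-transform with a bias correction: the habitual value is the
   expectation of the inverse transform over the within-person noise,
   evaluated by 9-point Gauss-Hermite quadrature.

This is a simplified re-implementation of the approach taken by
usual-intake programs such as SPADE: one-part only (suitable for
nutrients consumed daily by essentially everyone, such as protein), no
age-trend modelling, no bootstrap uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Box-Cox exponent grid searched by :func:`select_transform`.
LAMBDA_GRID = np.round(np.arange(0.0, 1.01, 0.1), 1)

#: Gauss-Hermite quadrature order for the back-transformation integral.
GH_ORDER = 9


@dataclass(frozen=True)
class TransformSpec:
    """Box-Cox power transform with an optional pre-shift to admit zeros."""

    lmbda: float
    shift: float = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.asarray(x, dtype=float) + self.shift
        if np.any(y <= 0):
            raise ValueError("transform requires strictly positive shifted values")
        if self.lmbda == 0:
            return np.log(y)
        return (y ** self.lmbda - 1.0) / self.lmbda

    def inverse(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.lmbda == 0:
            y = np.exp(t)
        else:
            # clip at the domain boundary lambda*t + 1 >= 0
            y = np.maximum(self.lmbda * t + 1.0, 0.0) ** (1.0 / self.lmbda)
        return np.maximum(y - self.shift, 0.0)


@dataclass(frozen=True)
class VarianceComponents:
    """Transformed-scale mean and variance split."""

    mu: float
    sigma2_between: float
    sigma2_within: float

    def __post_init__(self) -> None:
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variance components must be >= 0")


@dataclass
class HabitualDistribution:
    """Per-person habitual intake estimates on the original scale."""

    values: np.ndarray
    weights: np.ndarray
    person_ids: np.ndarray
    transform: TransformSpec
    components: VarianceComponents

    def percentiles(self, probs=None) -> pd.Series:
        """Weighted percentiles of the habitual distribution (p1..p99 default)."""
        if probs is None:
            probs = np.arange(1, 100)
        probs = np.asarray(probs, dtype=float)
        order = np.argsort(self.values)
        v = self.values[order]
        w = self.weights[order]
        cdf = (np.cumsum(w) - 0.5 * w) / np.sum(w)
        out = np.interp(probs / 100.0, cdf, v)
        return pd.Series(out, index=[f"p{int(p)}" for p in probs])

    def weighted_mean(self) -> float:
        return float(np.average(self.values, weights=self.weights))


def select_transform(daily_values: np.ndarray) -> TransformSpec:
    """Pick the Box-Cox exponent maximising the profile log-likelihood.

    The exponent comes from the fixed grid {0, 0.1, ..., 1}; the shift is
    0 when all values are positive, else half the smallest positive value.
    """
    x = np.asarray(daily_values, dtype=float)
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError("cannot select a transform: all daily values are zero")
    if positive.size < 20:
        raise ValueError(
            f"need at least 20 positive daily values, have {positive.size}"
        )
    shift = 0.0 if np.all(x > 0) else float(positive.min()) / 2.0
    y = x + shift
    lls = [stats.boxcox_llf(lm, y) for lm in LAMBDA_GRID]
    best = LAMBDA_GRID[int(np.argmax(lls))]
    return TransformSpec(lmbda=float(best), shift=shift)


def fit_variance_components(
    person_ids: np.ndarray, values: np.ndarray
) -> VarianceComponents:
    """Method-of-moments variance split of a transformed person-day table.

    For the balanced two-day design: the within-person variance is the
    mean over persons of (d1 - d2)^2 / 2; the between-person variance is
    the sample variance of person means minus within/2, floored at 0.
    Unequal day counts (>= 2 each) are handled by the pooled within-person
    variance and a mean(1/n_i) correction.
    """
    df = pd.DataFrame({"person": person_ids, "value": values})
    g = df.groupby("person")["value"]
    means = g.mean()
    counts = g.count()
    if len(means) < 2:
        raise ValueError("need at least 2 persons to split the variance")
    if (counts < 2).any():
        raise ValueError("every person needs at least 2 recall days")

    # pooled within-person variance; for n_i = 2 this is mean((d1-d2)^2/2)
    ss_within = ((df["value"] - df["person"].map(means)) ** 2).sum()
    sigma2_within = float(ss_within / (counts - 1).sum())

    var_means = float(means.var(ddof=1))
    correction = sigma2_within * float((1.0 / counts).mean())
    sigma2_between = max(0.0, var_means - correction)
    return VarianceComponents(
        mu=float(means.mean()),
        sigma2_between=sigma2_between,
        sigma2_within=sigma2_within,
    )


def shrink_person_means(
    components: VarianceComponents,
    person_means: np.ndarray,
    n_days: np.ndarray | int,
) -> np.ndarray:
    """Shrink transformed person means toward the population mean.

    t_i = mu + c_i (m_i - mu) with
    c_i = sqrt(s2_b / (s2_b + s2_w / n_i)); when the between-person
    variance is zero everyone collapses to mu.
    """
    m = np.asarray(person_means, dtype=float)
    n = np.broadcast_to(np.asarray(n_days, dtype=float), m.shape)
    s2b, s2w = components.sigma2_between, components.sigma2_within
    if s2b == 0:
        return np.full_like(m, components.mu)
    c = np.sqrt(s2b / (s2b + s2w / n))
    return components.mu + c * (m - components.mu)


def back_transform_habitual(
    transform: TransformSpec,
    components: VarianceComponents,
    transformed_habituals: np.ndarray,
) -> np.ndarray:
    """Bias-corrected back-transformation to the original scale.

    habitual_i = E[ g^{-1}(t_i + e) ],  e ~ N(0, sigma2_within),
    evaluated with 9-point Gauss-Hermite quadrature.  For the identity
    transform (lambda = 1) this collapses to g^{-1}(t_i) exactly; for the
    log transform it equals the lognormal mean exp(t_i + s2_w/2) - shift.
    """
    t = np.asarray(transformed_habituals, dtype=float)
    sigma = float(np.sqrt(components.sigma2_within))
    if sigma == 0:
        return transform.inverse(t)
    nodes, weights = np.polynomial.hermite.hermgauss(GH_ORDER)
    shifts = np.sqrt(2.0) * sigma * nodes  # (GH_ORDER,)
    vals = transform.inverse(t[:, None] + shifts[None, :])
    return vals @ (weights / np.sqrt(np.pi))


def estimate_habitual_distribution(
    person_ids: np.ndarray,
    day_values: np.ndarray,
    weights: np.ndarray | None = None,
) -> HabitualDistribution:
    """Full pipeline: transform, variance split, shrinkage, back-transform.

    ``person_ids`` / ``day_values`` form a long person-day table (2 or
    more days per person); ``weights`` are per-person analysis weights
    aligned with the order of first appearance of each person.
    Deterministic given its input.
    """
    person_ids = np.asarray(person_ids)
    day_values = np.asarray(day_values, dtype=float)
    transform = select_transform(day_values)
    transformed = transform.forward(day_values)
    components = fit_variance_components(person_ids, transformed)

    df = pd.DataFrame({"person": person_ids, "t": transformed})
    g = df.groupby("person", sort=False)["t"]
    order = g.mean().index.to_numpy()
    means = g.mean().to_numpy()
    counts = g.count().to_numpy()

    shrunk = shrink_person_means(components, means, counts)
    habitual = back_transform_habitual(transform, components, shrunk)

    if weights is None:
        w = np.ones(len(order))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != order.shape:
            raise ValueError("weights must align with the persons in the table")
        if np.any(w <= 0):
            raise ValueError("analysis weights must be > 0")
    return HabitualDistribution(
        values=habitual,
        weights=w,
        person_ids=order,
        transform=transform,
        components=components,
    )


def fraction_below(
    distribution: HabitualDistribution,
    cutoff_per_kg: float,
    body_weights_kg: np.ndarray | None = None,
    *,
    per_kg: bool = False,
) -> float:
    """Analysis-weighted proportion with habitual intake below the cut-off.

    With ``per_kg=False`` the habitual values are g/d and are divided by
    ``body_weights_kg`` before comparison; with ``per_kg=True`` they are
    already on the g/kg BW/d scale and body weights are not needed.
    """
    if per_kg:
        per_kg_values = distribution.values
    else:
        if body_weights_kg is None:
            raise ValueError("g/d mode needs body weights")
        bw = np.asarray(body_weights_kg, dtype=float)
        if bw.shape != distribution.values.shape:
            raise ValueError("body weights must align with habitual values")
        per_kg_values = distribution.values / bw
    below = per_kg_values < cutoff_per_kg
    return float(np.average(below, weights=distribution.weights))
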