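"""Effect-size computation and pooling.

Implements the estimators the evidence maps are built on:

* Hedges' g — small-sample-corrected standardized mean difference, with
  the correction factor ``J = 1 - 3 / (4 df - 1)`` for ``df = n1 + n2 - 2``.
* Block-diagonal sampling variance–covariance matrices under an assumed
  within-cluster sampling correlation ``rho`` (default 0.5).
* Fixed-effect GLS pooling — the weighted mean ``(1' V^-1 y) / (1' V^-1 1)``
  with standard error ``sqrt(1 / (1' V^-1 1))`` and a Wald 95% interval.
* DerSimonian–Laird random effects (method-of-moments tau^2).
* Cluster-robust (sandwich) variance with a CR1-type ``m/(m-1)`` small-sample
  factor and a t(m-1) reference distribution.
* Leave-one-cluster-out sensitivity tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Dataset, EffectRecord, RawOutcome, ValidationError

Z975 = stats.norm.ppf(0.975)


class DegenerateInputError(ValueError):
    """Input carries no usable variation (e.g., identical constant groups)."""


class ParameterError(ValueError):
    """A tuning parameter is outside its admissible range."""


@dataclass
class PooledEstimate:
    """A weighted mean effect with its uncertainty and the counts behind it."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_studies: int
    n_effects: int
    method: str
    tau2: float | None = None
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_studies": self.n_studies,
            "n_effects": self.n_effects,
            "method": self.method,
        }


@dataclass
class VCVMatrix:
    """Sampling variance–covariance matrix, block-diagonal by cluster.

    Within a cluster ``cov(i, j) = rho * sqrt(vi * vj)``; across clusters
    zero.  The diagonal equals the effects' sampling variances, so the
    matrix is positive definite for ``0 <= rho < 1``.
    """

    labels: list[str]
    values: np.ndarray
    rho: float
    clusters: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def hedges_g(raw: RawOutcome) -> tuple[float, float]:
    """Hedges' g and its sampling variance from two-group summaries.

    Pooled SD ``s_p = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2))``,
    ``d = (m1 - m2) / s_p``, ``g = J d`` with ``J = 1 - 3/(4 df - 1)``, and
    ``vg = J^2 ((n1+n2)/(n1 n2) + d^2 / (2 df))``.
    """
    n1, n2 = raw.n1, raw.n2
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * raw.s1**2 + (n2 - 1) * raw.s2**2) / df)
    if sp == 0:
        raise DegenerateInputError("pooled SD is zero (identical constant groups)")
    d = (raw.m1 - raw.m2) / sp
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    vg = j**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * df))
    return g, vg


def fill_effect_sizes(dataset: Dataset) -> Dataset:
    """Compute yi/vi via Hedges' g for every effect that only has raw outcomes."""
    for e in dataset.effects:
        if e.yi is None or e.vi is None:
            if e.raw is None:
                raise ValidationError(
                    f"effect {e.effect_id!r} has neither yi/vi nor raw outcomes"
                )
            e.yi, e.vi = hedges_g(e.raw)
    return dataset


def build_vcv(
    effects: list[EffectRecord],
    cluster_by: str = "study_id",
    rho: float = 0.5,
) -> VCVMatrix:
    """Block-diagonal sampling VCV under within-cluster correlation ``rho``."""
    if not 0.0 <= rho < 1.0:
        raise ParameterError(f"rho must be in [0, 1), got {rho}")
    vis = np.array([_require_vi(e) for e in effects], dtype=float)
    clusters = [_cluster_label(e, cluster_by) for e in effects]
    sd = np.sqrt(vis)
    same = np.equal.outer(np.array(clusters, dtype=object), np.array(clusters, dtype=object))
    values = rho * np.outer(sd, sd) * same
    np.fill_diagonal(values, vis)
    return VCVMatrix(
        labels=[e.effect_id for e in effects],
        values=values,
        rho=rho,
        clusters=clusters,
    )


def pool_fixed_gls(y: np.ndarray, vcv: VCVMatrix, n_studies: int | None = None) -> PooledEstimate:
    """Multivariate fixed-effect (GLS) pooled mean with Wald 95% CI.

    With ``rho = 0`` this reduces exactly to the inverse-variance weighted
    mean with ``se = sqrt(1 / sum(1/vi))``.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(vcv.values, dtype=float)
    if y.shape[0] != v.shape[0]:
        raise ValueError("y is not aligned with the VCV labels")
    ones = np.ones(len(y))
    try:
        vinv_1 = np.linalg.solve(v, ones)
        vinv_y = np.linalg.solve(v, y)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "sampling VCV is singular; try a smaller rho"
        ) from exc
    denom = float(ones @ vinv_1)
    if denom <= 0:
        raise np.linalg.LinAlgError("sampling VCV is not positive definite; try a smaller rho")
    estimate = float(ones @ vinv_y) / denom
    se = math.sqrt(1.0 / denom)
    m = n_studies if n_studies is not None else len(set(vcv.clusters)) or 1
    return PooledEstimate(
        estimate=estimate,
        se=se,
        ci_low=estimate - Z975 * se,
        ci_high=estimate + Z975 * se,
        n_studies=m,
        n_effects=len(y),
        method="fixed_gls",
    )


def pool_random_dl(
    y: np.ndarray, v: np.ndarray, n_studies: int | None = None
) -> PooledEstimate:
    """DerSimonian–Laird random-effects pooled mean with Wald 95% CI."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = len(y)
    if k < 2:
        raise ValueError("random-effects pooling needs >= 2 effects (heterogeneity undefined)")
    w = 1.0 / v
    ybar = float(w @ y / w.sum())
    q = float(w @ (y - ybar) ** 2)
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / c)
    wstar = 1.0 / (v + tau2)
    estimate = float(wstar @ y / wstar.sum())
    se = math.sqrt(1.0 / wstar.sum())
    return PooledEstimate(
        estimate=estimate,
        se=se,
        ci_low=estimate - Z975 * se,
        ci_high=estimate + Z975 * se,
        n_studies=n_studies if n_studies is not None else k,
        n_effects=k,
        method="random_dl",
        tau2=tau2,
    )


def robust_variance(y: np.ndarray, vcv: VCVMatrix) -> PooledEstimate:
    """Cluster-robust (sandwich) pooled estimate.

    The point estimate is the fixed-effect GLS mean.  The variance uses
    scalar weights ``w_i`` equal to the row sums of ``V^-1``:
    ``se^2 = m/(m-1) * sum_c (sum_{i in c} w_i e_i)^2 / (sum_i w_i)^2``
    with residuals ``e_i = y_i - estimate``; the 95% CI uses the t
    distribution with ``m - 1`` degrees of freedom for ``m`` clusters.
    """
    clusters = vcv.clusters
    uniq = list(dict.fromkeys(clusters))
    m = len(uniq)
    if m < 2:
        raise ValueError(
            "cluster-robust variance needs >= 2 clusters "
            "(between-cluster replication assumption violated)"
        )
    base = pool_fixed_gls(y, vcv)
    y = np.asarray(y, dtype=float)
    w = np.linalg.solve(vcv.values, np.ones(len(y)))  # row sums of V^-1
    e = y - base.estimate
    cl = np.array(clusters, dtype=object)
    num = sum(float(np.sum(w[cl == c] * e[cl == c])) ** 2 for c in uniq)
    se2 = (m / (m - 1)) * num / float(w.sum()) ** 2
    se = math.sqrt(se2)
    tcrit = float(stats.t.ppf(0.975, m - 1))
    return PooledEstimate(
        estimate=base.estimate,
        se=se,
        ci_low=base.estimate - tcrit * se,
        ci_high=base.estimate + tcrit * se,
        n_studies=m,
        n_effects=len(y),
        method="robust",
        degenerate=(se == 0.0),
    )


def pool_effects(
    effects: list[EffectRecord],
    method: str = "fixed_gls",
    rho: float = 0.5,
    cluster_by: str = "study_id",
) -> PooledEstimate:
    """Pool a list of effects by the named method.

    Single-effect input passes through as its own estimate and standard
    error.  ``robust`` falls back to fixed GLS when only one cluster is
    available (the sandwich is undefined there).
    """
    if not effects:
        raise ValueError("no effects to pool")
    y = np.array([_require_yi(e) for e in effects], dtype=float)
    n_studies = len({e.study_id for e in effects})
    if len(effects) == 1:
        vi = _require_vi(effects[0])
        se = math.sqrt(vi)
        return PooledEstimate(
            estimate=float(y[0]),
            se=se,
            ci_low=float(y[0]) - Z975 * se,
            ci_high=float(y[0]) + Z975 * se,
            n_studies=1,
            n_effects=1,
            method="single_effect",
        )
    if method == "random_dl":
        v = np.array([_require_vi(e) for e in effects], dtype=float)
        return pool_random_dl(y, v, n_studies=n_studies)
    vcv = build_vcv(effects, cluster_by=cluster_by, rho=rho)
    if method == "fixed_gls":
        return pool_fixed_gls(y, vcv, n_studies=n_studies)
    if method == "robust":
        if len(set(vcv.clusters)) < 2:
            return pool_fixed_gls(y, vcv, n_studies=n_studies)
        return robust_variance(y, vcv)
    raise ParameterError(f"unknown pooling method {method!r}")


def leave_one_cluster_out(
    dataset: Dataset,
    cluster_by: str = "author_cluster",
    method: str = "fixed_gls",
    rho: float = 0.5,
) -> pd.DataFrame:
    """Pooled estimate without each cluster vs the cluster alone.

    One row per held-out cluster: the configured pooling method applied to
    the complement and to the cluster's own effects.  Used to gauge the
    influence of dominant research groups.
    """
    fill_effect_sizes(dataset)
    labels = [_cluster_label(e, cluster_by) for e in dataset.effects]
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("leave-one-cluster-out needs >= 2 clusters")
    rows = []
    for c in uniq:
        inside = [e for e, l in zip(dataset.effects, labels) if l == c]
        outside = [e for e, l in zip(dataset.effects, labels) if l != c]
        rest = pool_effects(outside, method=method, rho=rho)
        own = pool_effects(inside, method=method, rho=rho)
        rows.append(
            {
                "cluster": c,
                "estimate_without": rest.estimate,
                "se_without": rest.se,
                "ci_low_without": rest.ci_low,
                "ci_high_without": rest.ci_high,
                "n_effects_without": rest.n_effects,
                "estimate_own": own.estimate,
                "se_own": own.se,
                "n_effects_own": own.n_effects,
            }
        )
    return pd.DataFrame(rows)


def _require_vi(e: EffectRecord) -> float:
    if e.vi is None:
        raise ValidationError(f"effect {e.effect_id!r} has no sampling variance")
    return e.vi


def _require_yi(e: EffectRecord) -> float:
    if e.yi is None:
        raise ValidationError(f"effect {e.effect_id!r} has no effect size")
    return e.yi


def _cluster_label(e: EffectRecord, cluster_by: str) -> str:
    value = getattr(e, cluster_by, None)
    if value is None:
        value = e.moderators.get(cluster_by)
    if value is None:
        raise ValidationError(f"effect {e.effect_id!r} has no {cluster_by!r} label")
    return str(value)
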