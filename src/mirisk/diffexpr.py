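"""Probe-wise two-group linear models with empirical-Bayes moderated
t-statistics, Benjamini-Hochberg FDR control, and signed fold-change
reporting (positive = up in the first-named group; the linear-scale FC
carries a minus sign for down-regulation)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from mirisk.datamodel import ExpressionMatrix, Scale
from mirisk.errors import DegenerateVarianceError, DesignError, DomainError


@dataclass
class ModeratedFit:
    """Per-probe coefficients/variances plus the shared eb hyperparameters."""

    probe_ids: list[str]
    coef: np.ndarray            # logFC per probe
    stdev_unscaled: float       # sqrt(v): coefficient sd = sqrt(v * s^2)
    s2: np.ndarray              # residual variance per probe
    df_residual: float
    ave_expr: np.ndarray
    # populated by ebayes():
    df_prior: float | None = None
    s2_prior: float | None = None
    s2_post: np.ndarray | None = None
    t_mod: np.ndarray | None = None
    p_raw: np.ndarray | None = None
    zero_variance_probes: list[str] = field(default_factory=list)


def fit_probe_models(
    matrix: ExpressionMatrix,
    groups: dict[str, str] | "pd.Series",
    contrast: tuple[str, str],
) -> ModeratedFit:
    """Least-squares group-mean fit per probe for a two-group contrast.

    ``groups`` maps sample id -> group label; ``contrast = (a, b)`` estimates
    mean(a) - mean(b) per probe, so positive logFC means up in ``a``.
    ``ave_expr`` is the mean log2 expression over the contrasted samples.
    """
    if matrix.scale is not Scale.LOG2:
        raise DomainError("differential expression requires a log2-scale matrix")
    a, b = contrast
    groups = dict(groups)
    ia = [j for j, s in enumerate(matrix.sample_ids) if groups.get(s) == a]
    ib = [j for j, s in enumerate(matrix.sample_ids) if groups.get(s) == b]
    if len(ia) < 2 or len(ib) < 2:
        raise DesignError(
            f"each contrast group needs >=2 samples (got {a}: {len(ia)}, {b}: {len(ib)})"
        )
    xa = matrix.values[:, ia]
    xb = matrix.values[:, ib]
    na, nb = len(ia), len(ib)
    coef = xa.mean(axis=1) - xb.mean(axis=1)
    ss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xb - xb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = na + nb - 2
    s2 = ss / df
    ave = matrix.values[:, ia + ib].mean(axis=1)
    return ModeratedFit(
        probe_ids=list(matrix.probe_ids),
        coef=coef,
        stdev_unscaled=math.sqrt(1.0 / na + 1.0 / nb),
        s2=s2,
        df_residual=float(df),
        ave_expr=ave,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a log-convex scale)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_hyperparameters(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (df_prior, s2_prior) on log residual variances.

    Matches the mean/variance of log s^2 against a log scaled-F distribution;
    returns ``df_prior = inf`` when the observed spread is no larger than the
    sampling spread (fully pooled variance).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise DegenerateVarianceError("all residual variances are zero")
    z = np.log(s2[ok])
    e_z = z.mean()
    var_z = z.var(ddof=1) if z.size > 1 else 0.0
    excess = var_z - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        df_prior = math.inf
        s2_prior = math.exp(e_z - special.digamma(df / 2.0) + math.log(df / 2.0))
    else:
        half_d0 = _trigamma_inverse(excess)
        df_prior = 2.0 * half_d0
        s2_prior = math.exp(
            e_z
            - special.digamma(df / 2.0)
            + math.log(df / 2.0)
            + special.digamma(half_d0)
            - math.log(half_d0)
        )
    return float(df_prior), float(s2_prior)


def ebayes(fit: ModeratedFit, df_prior: float | None = None,
           s2_prior: float | None = None) -> ModeratedFit:
    """Shrink residual variances toward the ensemble prior and compute
    moderated t-statistics with two-sided p-values.

    Hyperparameters are estimated from the fit unless supplied explicitly;
    ``df_prior=0`` reproduces the ordinary t-statistic exactly.
    """
    if len(fit.probe_ids) < 10 and df_prior is None:
        raise DesignError("hyperparameter estimation needs >=10 probes")
    zero = fit.s2 <= 0
    fit.zero_variance_probes = [p for p, z in zip(fit.probe_ids, zero) if z]
    if df_prior is None or s2_prior is None:
        est_d0, est_s0 = estimate_hyperparameters(fit.s2, fit.df_residual)
        df_prior = est_d0 if df_prior is None else df_prior
        s2_prior = est_s0 if s2_prior is None else s2_prior
    d, d0 = fit.df_residual, df_prior
    if math.isinf(d0):
        s2_post = np.full_like(fit.s2, s2_prior)
        df_total = np.inf
    else:
        s2_post = (d0 * s2_prior + d * fit.s2) / (d0 + d)
        df_total = d + d0
    if np.all(s2_post <= 0):
        raise DegenerateVarianceError("posterior variances all zero")
    with np.errstate(divide="ignore"):
        t = fit.coef / np.sqrt(s2_post * fit.stdev_unscaled**2)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    fit.df_prior = float(df_prior)
    fit.s2_prior = float(s2_prior)
    fit.s2_post = s2_post
    fit.t_mod = t
    fit.p_raw = p
    return fit


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def signed_fold_change(logfc: float) -> float:
    """Linear-scale fold change with sign encoding direction:
    2**logFC for logFC >= 0, else -2**(-logFC); |FC| >= 1 always."""
    if not np.isfinite(logfc):
        raise DomainError("logFC must be finite")
    if logfc >= 0:
        return float(2.0**logfc)
    return float(-(2.0 ** (-logfc)))


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used in printed FC tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class DifferentialSummary:
    n_total: int
    n_down: int
    n_up: int
    alpha: float

    @property
    def n_signif(self) -> int:
        return self.n_down + self.n_up

    def percent(self, k: int) -> float:
        return round_half_away(100.0 * k / self.n_total, 1)

    def describe(self) -> str:
        return (
            f"{self.n_signif}/{self.n_total} ({self.percent(self.n_signif)}%) significant "
            f"at BH {self.alpha}: {self.n_down} down ({self.percent(self.n_down)}%), "
            f"{self.n_up} up ({self.percent(self.n_up)}%)"
        )


def differential_table(
    fit: ModeratedFit, alpha: float = 0.05
) -> tuple[pd.DataFrame, DifferentialSummary]:
    """Per-probe result table (probe, logFC, signed FC, average expression,
    raw/adjusted p) sorted by adjusted then raw p, plus up/down counts at
    the BH threshold."""
    if fit.p_raw is None:
        raise DesignError("run ebayes() before building the differential table")
    p_adj = bh_adjust(fit.p_raw)
    df = pd.DataFrame(
        {
            "probe_id": fit.probe_ids,
            "logFC": fit.coef,
            "FC": [signed_fold_change(c) for c in fit.coef],
            "ave_expr": fit.ave_expr,
            "t_mod": fit.t_mod,
            "p_raw": fit.p_raw,
            "p_adj": p_adj,
        }
    )
    df = df.sort_values(["p_adj", "p_raw", "probe_id"], kind="stable").reset_index(drop=True)
    sig = df[df["p_adj"] <= alpha]
    summary = DifferentialSummary(
        n_total=len(fit.probe_ids),
        n_down=int((sig["logFC"] < 0).sum()),
        n_up=int((sig["logFC"] > 0).sum()),
        alpha=alpha,
    )
    return df, summary
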