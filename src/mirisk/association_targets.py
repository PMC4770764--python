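"""Feature-covariate association tools: variance filtering, the
miRNA-mRNA Pearson correlation screen with FDR control and a
leave-one-out influence flag, the target-prediction consensus filter,
a permutation global association test, and two-group clinical tests."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mirisk.datamodel import ExpressionMatrix, PredictionTable, SurvivalOutcome
from mirisk.diffexpr import bh_adjust
from mirisk.errors import AssociationError, GroupingError

logger = logging.getLogger(__name__)


def variance_filter(matrix: ExpressionMatrix, keep_fraction: float) -> ExpressionMatrix:
    """Retain the ceil(keep_fraction * n) probes with highest sample variance.

    Deterministic: ties in variance break lexicographically on probe id.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise AssociationError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    n_keep = math.ceil(keep_fraction * matrix.n_probes)
    var = matrix.values.var(axis=1, ddof=1)
    ranked = sorted(zip(matrix.probe_ids, var), key=lambda pv: (-pv[1], pv[0]))
    keep_ids = sorted(p for p, _ in ranked[:n_keep])
    # preserve original probe order
    keep_set = set(keep_ids)
    ordered = [p for p in matrix.probe_ids if p in keep_set]
    return matrix.subset_probes(ordered)


@dataclass
class ConsensusTargetSet:
    mirna_id: str
    gene_ids: set[str]
    min_tools: int = 6
    n_tools: int = 7


def consensus_targets(
    table: PredictionTable, mirna_id: str, min_tools: int = 6
) -> ConsensusTargetSet:
    """Genes called by at least ``min_tools`` of the prediction tools."""
    if min_tools > table.n_tools:
        raise AssociationError(
            f"min_tools {min_tools} exceeds tool count {table.n_tools}"
        )
    hits = table.calls.sum(axis=1) >= min_tools
    genes = {g for g, h in zip(table.gene_ids, hits) if h}
    return ConsensusTargetSet(
        mirna_id=mirna_id, gene_ids=genes, min_tools=min_tools, n_tools=table.n_tools
    )


@dataclass
class CorrelationHit:
    mirna_id: str
    mrna_probeset: str
    r: float
    p_raw: float
    p_adj: float
    influence_flag: bool


def _pearson_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlations between two probe-by-sample blocks."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    r = (az @ bz.T) / np.outer(asd, bsd)
    return np.clip(r, -1.0, 1.0)


def correlation_screen(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    r_threshold: float = 0.6,
    alpha: float = 0.05,
) -> list[CorrelationHit]:
    """All-pairs Pearson screen between miRNA and mRNA probes.

    BH adjustment is over the full tested family. A hit is retained when
    |r| >= r_threshold and p_adj <= alpha; its influence flag is set when
    dropping any single sample pushes |r| below the threshold (automated
    surrogate for manual plausibility review of leverage-driven hits).
    """
    shared = [s for s in mirna.sample_ids if s in set(mrna.sample_ids)]
    if len(shared) < 5:
        raise AssociationError(f"need >=5 shared samples, got {len(shared)}")
    mi = mirna.subset_samples(shared)
    mr = mrna.subset_samples(shared)
    n = len(shared)

    def _drop_constant(m: ExpressionMatrix) -> ExpressionMatrix:
        var = m.values.var(axis=1)
        if (var == 0).any():
            bad = [p for p, v in zip(m.probe_ids, var) if v == 0]
            logger.warning("correlation_screen: dropping zero-variance probes %s", bad)
            m = m.subset_probes([p for p in m.probe_ids if p not in set(bad)])
        return m

    mi = _drop_constant(mi)
    mr = _drop_constant(mr)
    r = _pearson_matrix(mi.values, mr.values)
    # two-sided t-test p-values for Pearson r with n-2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    p_adj = bh_adjust(p.ravel()).reshape(p.shape)
    hits: list[CorrelationHit] = []
    for i, j in zip(*np.nonzero((np.abs(r) >= r_threshold) & (p_adj <= alpha))):
        x = mi.values[i]
        y = mr.values[j]
        influence = False
        for k in range(n):
            mask = np.arange(n) != k
            r_loo = stats.pearsonr(x[mask], y[mask]).statistic
            if abs(r_loo) < r_threshold:
                influence = True
                break
        hits.append(
            CorrelationHit(
                mirna_id=mi.probe_ids[i],
                mrna_probeset=mr.probe_ids[j],
                r=float(r[i, j]),
                p_raw=float(p[i, j]),
                p_adj=float(p_adj[i, j]),
                influence_flag=influence,
            )
        )
    hits.sort(key=lambda h: (h.p_adj, -abs(h.r), h.mirna_id, h.mrna_probeset))
    return hits


def hits_to_frame(hits: Sequence[CorrelationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [h.mirna_id for h in hits],
            "mrna_probeset": [h.mrna_probeset for h in hits],
            "r": [h.r for h in hits],
            "p_adj": [h.p_adj for h in hits],
            "influence_flag": [h.influence_flag for h in hits],
        }
    )


def _null_residuals(outcome, n: int) -> np.ndarray:
    """Residuals of the outcome under the no-covariate null model."""
    if len(outcome) and isinstance(outcome[0], SurvivalOutcome):
        time = np.array([o.time for o in outcome])
        event = np.array([o.event for o in outcome], dtype=float)
        # martingale residuals from the Nelson-Aalen cumulative hazard
        order = np.argsort(time, kind="stable")
        chaz = np.zeros(n)
        at_risk = n
        cum = 0.0
        k = 0
        sorted_t = time[order]
        while k < n:
            j = k
            d = 0.0
            while j < n and sorted_t[j] == sorted_t[k]:
                d += event[order[j]]
                j += 1
            cum += d / at_risk
            for m in range(k, j):
                chaz[order[m]] = cum
            at_risk -= j - k
            k = j
        return event - chaz
    y = np.asarray(outcome, dtype=float)
    if np.unique(y).size < 2:
        raise AssociationError("outcome is constant")
    return y - y.mean()


def global_association(
    expr_subset: ExpressionMatrix,
    outcome,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation global test of whether a feature set is associated with
    an outcome (continuous, binary, or a list of survival outcomes).

    Statistic: Q = r' (X X') r / p with X the centered sample-by-feature
    matrix and r the null-model residuals; p-value by permuting residuals.
    """
    if expr_subset.n_probes < 2:
        raise AssociationError("global test needs >=2 features")
    n = expr_subset.n_samples
    if n < 10:
        raise AssociationError("global test needs >=10 samples")
    if len(outcome) != n:
        raise AssociationError("outcome length must match sample count")
    r = _null_residuals(outcome, n)
    x = expr_subset.values.T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    proj = x.T  # features x samples

    def q(res: np.ndarray) -> float:
        v = proj @ res
        return float(v @ v) / expr_subset.n_probes

    obs = q(r)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if q(rng.permutation(r)) >= obs - 1e-12:
            hits += 1
    return obs, (hits + 1) / (n_perm + 1)


def wilcoxon_rank_sum(feature: Sequence[float], groups: Sequence[bool]) -> tuple[float, float]:
    """Two-group Wilcoxon rank-sum test on a continuous feature."""
    g = np.asarray(groups, dtype=bool)
    x = np.asarray(feature, dtype=float)
    if g.all() or not g.any():
        raise GroupingError("need two non-empty groups")
    res = stats.mannwhitneyu(x[g], x[~g], alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table: np.ndarray) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 contingency table; empty margins error."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise GroupingError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise GroupingError("contingency table has an empty margin")
    res = stats.fisher_exact(t)
    return float(res.statistic), float(res.pvalue)


def group_tests(
    feature: Sequence[float] | Sequence[bool],
    groups: Sequence[bool],
    kind: str = "continuous",
) -> tuple[float, float]:
    """Dispatch: Wilcoxon for a continuous feature vs a binary grouping,
    Fisher's exact for binary vs binary."""
    if kind == "continuous":
        return wilcoxon_rank_sum(feature, groups)
    if kind == "categorical":
        f = np.asarray(feature, dtype=bool)
        g = np.asarray(groups, dtype=bool)
        table = np.array(
            [
                [int((f & g).sum()), int((f & ~g).sum())],
                [int((~f & g).sum()), int((~f & ~g).sum())],
            ]
        )
        return fisher_exact_2x2(table)
    raise GroupingError(f"unknown test kind {kind!r}")
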