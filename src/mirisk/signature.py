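"""PCA-based survival risk signatures.

Construction: (1) center the selected features and project each sample onto
the first two principal axes, giving two weighted averages (w1, w2);
(2) fit a bivariate Cox model on (w1, w2) for each of EFS and OS;
(3) average the two coefficient pairs and score each sample as the inner
product of the averaged coefficients with (w1, w2); (4) pick the optimal
score cutoff by maximally selected rank statistics.

Transfer to an independent cohort is by documentation-by-value: the frozen
normalization reference, feature centers, loadings, averaged coefficients,
and cutoff are applied as-is, with no refitting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mirisk.datamodel import ExpressionMatrix, SurvivalOutcome
from mirisk.errors import CutpointError, SignatureError, TargetScoreError
from mirisk.preprocess import NormalizationModel, apply_normalization
from mirisk.survival_stats import MaxstatResult, cox_fit, maxstat_cutpoint

logger = logging.getLogger(__name__)

_AXIS_TOL = 1e-10  # relative singular-value floor for a usable second axis


@dataclass
class RiskSignature:
    """Frozen constants sufficient to re-score any cohort reproducibly."""

    feature_ids: list[str]
    center: np.ndarray
    loadings1: np.ndarray
    loadings2: np.ndarray
    beta_bar: np.ndarray                  # mean over {EFS, OS} Cox coefficient pairs
    cutoff: float
    high_score_is_high_risk: bool
    degenerate_second_axis: bool = False
    normalization: NormalizationModel | None = None
    source_mirna: str | None = None       # set for miRNA target scores
    maxstat: MaxstatResult | None = None

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "center": [float(v) for v in self.center],
            "loadings1": [float(v) for v in self.loadings1],
            "loadings2": [float(v) for v in self.loadings2],
            "beta_bar": [float(v) for v in self.beta_bar],
            "cutoff": float(self.cutoff),
            "high_score_is_high_risk": bool(self.high_score_is_high_risk),
            "degenerate_second_axis": bool(self.degenerate_second_axis),
            "source_mirna": self.source_mirna,
            "normalization": self.normalization.to_dict() if self.normalization else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskSignature":
        norm = d.get("normalization")
        return cls(
            feature_ids=list(d["feature_ids"]),
            center=np.asarray(d["center"], dtype=float),
            loadings1=np.asarray(d["loadings1"], dtype=float),
            loadings2=np.asarray(d["loadings2"], dtype=float),
            beta_bar=np.asarray(d["beta_bar"], dtype=float),
            cutoff=float(d["cutoff"]),
            high_score_is_high_risk=bool(d["high_score_is_high_risk"]),
            degenerate_second_axis=bool(d["degenerate_second_axis"]),
            source_mirna=d.get("source_mirna"),
            normalization=NormalizationModel.from_dict(norm) if norm else None,
        )

    def save(self, path) -> None:
        with open(str(path), "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RiskSignature":
        with open(str(path)) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ScoredCohort:
    sample_ids: list[str]
    w1: np.ndarray
    w2: np.ndarray
    score: np.ndarray
    risk_group: list[str] = field(default_factory=list)  # "low" | "high"


def _principal_axes(centered: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """First two principal axes (feature-space unit vectors) of a centered
    feature-by-sample matrix; signs fixed so each axis's largest-magnitude
    loading is positive. Returns (axis1, axis2, second_axis_degenerate)."""
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    axis1 = u[:, 0]
    degenerate = s.size < 2 or s[1] <= _AXIS_TOL * s[0]
    axis2 = np.zeros_like(axis1) if degenerate else u[:, 1]
    if np.abs(axis1).max() > 0 and axis1[np.argmax(np.abs(axis1))] < 0:
        axis1 = -axis1
    if not degenerate and axis2[np.argmax(np.abs(axis2))] < 0:
        axis2 = -axis2
    return axis1, axis2, degenerate


def build_signature(
    expr: ExpressionMatrix,
    efs: Sequence[SurvivalOutcome | None],
    os: Sequence[SurvivalOutcome | None],
    bounds: tuple[float, float] = (0.1, 0.9),
    normalization: NormalizationModel | None = None,
) -> tuple[RiskSignature, ScoredCohort]:
    """Build a risk signature from a feature-restricted expression matrix.

    ``efs`` and ``os`` run parallel to the matrix samples; samples missing an
    outcome are excluded from the corresponding Cox fit but still scored.
    Returns the frozen signature and the scored training cohort.
    """
    if expr.n_probes < 2:
        raise SignatureError("need at least 2 features to build a signature")
    efs = list(efs)
    os = list(os)
    if len(efs) != expr.n_samples or len(os) != expr.n_samples:
        raise SignatureError("outcome lists must run parallel to matrix samples")
    both = [i for i in range(expr.n_samples) if efs[i] is not None and os[i] is not None]
    if len(both) < 10:
        raise SignatureError(
            f"need >=10 samples with both outcomes, got {len(both)}"
        )
    center = expr.values.mean(axis=1)
    centered = expr.values - center[:, None]
    axis1, axis2, degenerate = _principal_axes(centered)
    if degenerate:
        logger.warning(
            "second principal axis degenerate; signature built on axis 1 only"
        )
    w1 = centered.T @ axis1
    w2 = centered.T @ axis2

    def _beta(outcomes: list[SurvivalOutcome | None]) -> np.ndarray:
        keep = [i for i in range(expr.n_samples) if outcomes[i] is not None]
        out = [outcomes[i] for i in keep]
        if degenerate:
            fit = cox_fit(w1[keep][:, None], out)
            return np.array([fit.coefficients[0], 0.0])
        fit = cox_fit(np.column_stack([w1[keep], w2[keep]]), out)
        return fit.coefficients

    beta_bar = (_beta(efs) + _beta(os)) / 2.0
    score = beta_bar[0] * w1 + beta_bar[1] * w2
    if np.unique(score).size < 2:
        raise CutpointError("scores are constant; no cutoff exists")
    efs_keep = [i for i in range(expr.n_samples) if efs[i] is not None]
    ms = maxstat_cutpoint(score[efs_keep], [efs[i] for i in efs_keep], bounds)
    # direction of risk is data-dependent: read it off the univariate Cox sign
    uni = cox_fit(score[efs_keep][:, None], [efs[i] for i in efs_keep])
    high_is_high_risk = bool(uni.coefficients[0] >= 0)
    sig = RiskSignature(
        feature_ids=list(expr.probe_ids),
        center=center,
        loadings1=axis1,
        loadings2=axis2,
        beta_bar=beta_bar,
        cutoff=float(ms.cutoff),
        high_score_is_high_risk=high_is_high_risk,
        degenerate_second_axis=degenerate,
        normalization=normalization,
        maxstat=ms,
    )
    scored = _score(sig, expr.values, list(expr.sample_ids))
    return sig, scored


def _score(sig: RiskSignature, values: np.ndarray, sample_ids: list[str]) -> ScoredCohort:
    centered = values - sig.center[:, None]
    w1 = centered.T @ sig.loadings1
    w2 = centered.T @ sig.loadings2
    score = sig.beta_bar[0] * w1 + sig.beta_bar[1] * w2
    if sig.high_score_is_high_risk:
        groups = ["high" if s > sig.cutoff else "low" for s in score]
    else:
        groups = ["low" if s > sig.cutoff else "high" for s in score]
    return ScoredCohort(sample_ids=sample_ids, w1=w1, w2=w2, score=score,
                        risk_group=groups)


def apply_signature(
    sig: RiskSignature,
    expr: ExpressionMatrix,
    use_documentation: bool = True,
) -> ScoredCohort:
    """Score a cohort with a frozen signature.

    With ``use_documentation`` the frozen normalization reference is applied
    to the cohort first (documentation-by-value); centering, loadings,
    averaged coefficients and cutoff are frozen either way — nothing is
    refit.
    """
    missing = [f for f in sig.feature_ids if f not in set(expr.probe_ids)]
    if missing:
        raise SignatureError(f"cohort is missing signature features: {missing}")
    if use_documentation and sig.normalization is not None:
        expr = apply_normalization(sig.normalization, expr)
    sub = expr.subset_probes(sig.feature_ids)
    return _score(sig, sub.values, list(sub.sample_ids))


def build_target_score(
    mirna_id: str,
    target_gene_ids: Sequence[str],
    mrna: ExpressionMatrix,
    efs: Sequence[SurvivalOutcome | None],
    os: Sequence[SurvivalOutcome | None],
    bounds: tuple[float, float] = (0.1, 0.9),
    normalization: NormalizationModel | None = None,
) -> tuple[RiskSignature, ScoredCohort]:
    """Risk score from a miRNA's predicted target genes: the signature
    algorithm applied to the target-gene rows of the mRNA matrix."""
    present = [g for g in target_gene_ids if g in set(mrna.probe_ids)]
    if len(present) < 2:
        raise TargetScoreError(
            f"{mirna_id}: only {len(present)} predicted targets on the mRNA "
            "matrix (need >=2)"
        )
    sig, scored = build_signature(
        mrna.subset_probes(present), efs, os, bounds=bounds,
        normalization=normalization,
    )
    sig.source_mirna = mirna_id
    return sig, scored
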