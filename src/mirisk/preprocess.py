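"""Raw-signal preprocessing: constant scaling before log2, then
rank-invariant normalization of each sample to a reference profile.

The normalization model is serializable so a frozen reference can be
shipped with a risk signature and applied to an independent cohort
(documentation-by-value transfer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from mirisk.datamodel import ExpressionMatrix, Scale
from mirisk.errors import AlignmentError, DomainError, NormalizationError

_MIN_SLOPE = 1e-9  # keeps the fitted mapping strictly increasing


def scaled_log2(matrix: ExpressionMatrix, offset: float | str = "auto") -> ExpressionMatrix:
    """log2-transform a raw matrix after adding a scaling constant.

    With ``offset="auto"`` the constant is chosen as ``1 - min(values)`` so the
    smallest shifted value is exactly 1 and the log2 minimum exactly 0.
    """
    if matrix.scale is not Scale.RAW:
        raise DomainError("scaled_log2 expects a raw-scale matrix")
    if offset == "auto":
        c = 1.0 - float(matrix.values.min())
    else:
        c = float(offset)
    shifted = matrix.values + c
    if np.any(shifted <= 0):
        raise DomainError(
            f"offset {c} leaves non-positive values (min shifted = {shifted.min()})"
        )
    return ExpressionMatrix(
        list(matrix.probe_ids), list(matrix.sample_ids), np.log2(shifted), Scale.LOG2
    )


@dataclass
class NormalizationModel:
    """Frozen per-probe reference plus the invariant-selection settings.

    The mapping for any sample (training or new) is re-derived against the
    frozen reference: select approximately rank-invariant probes, then fit a
    monotone piecewise-linear map through paired quantiles of the invariant
    values. ``mapping_knots`` caches the training-sample mappings.
    """

    probe_ids: list[str]
    reference_profile: np.ndarray
    rank_threshold: float = 0.05
    min_invariant: int = 20
    n_quantile_knots: int = 25
    max_iter: int = 10
    offset_constant: float | None = None
    invariant_probe_ids: dict[str, list[str]] = field(default_factory=dict)
    mapping_knots: dict[str, tuple[list[float], list[float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "probe_ids": list(self.probe_ids),
            "reference_profile": [float(v) for v in self.reference_profile],
            "rank_threshold": self.rank_threshold,
            "min_invariant": self.min_invariant,
            "n_quantile_knots": self.n_quantile_knots,
            "max_iter": self.max_iter,
            "offset_constant": self.offset_constant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationModel":
        return cls(
            probe_ids=list(d["probe_ids"]),
            reference_profile=np.asarray(d["reference_profile"], dtype=float),
            rank_threshold=float(d["rank_threshold"]),
            min_invariant=int(d["min_invariant"]),
            n_quantile_knots=int(d["n_quantile_knots"]),
            max_iter=int(d["max_iter"]),
            offset_constant=d.get("offset_constant"),
        )

    def save(self, path) -> None:
        with open(str(path), "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NormalizationModel":
        with open(str(path)) as fh:
            return cls.from_dict(json.load(fh))


def _select_invariant(sample: np.ndarray, reference: np.ndarray,
                      threshold: float, floor: int, max_iter: int) -> np.ndarray:
    """Iterated rank-invariant selection: keep probes whose within-set rank
    difference between sample and reference stays below threshold * set size."""
    n = sample.size
    keep = np.arange(n)
    for it in range(max_iter):
        rs = rankdata(sample[keep])
        rr = rankdata(reference[keep])
        ok = np.abs(rs - rr) / keep.size <= threshold
        if ok.sum() < floor:
            if it == 0:
                raise NormalizationError(
                    f"invariant set shrank to {int(ok.sum())} probes (< {floor}); "
                    "relax rank_threshold"
                )
            break  # keep the last admissible set
        if ok.all():
            break
        keep = keep[ok]
    return keep


def _fit_knots(sample_vals: np.ndarray, ref_vals: np.ndarray,
               n_knots: int) -> tuple[np.ndarray, np.ndarray]:
    """Monotone piecewise-linear knots through paired quantiles of the
    invariant values. Knot ordinates are forced non-decreasing, then a tiny
    slope floor keeps the interpolant strictly increasing."""
    qs = np.linspace(0.0, 1.0, min(n_knots, sample_vals.size))
    kx = np.quantile(np.sort(sample_vals), qs)
    ky = np.quantile(np.sort(ref_vals), qs)
    # collapse duplicate abscissae (ties in the sample values)
    kx, idx = np.unique(kx, return_index=True)
    ky = ky[idx]
    ky = np.maximum.accumulate(ky)
    if kx.size >= 2 and np.any(np.diff(ky) <= 0):
        ky = ky + _MIN_SLOPE * (kx - kx[0])
    return kx, ky


def _apply_knots(x: np.ndarray, kx: np.ndarray, ky: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation with end-slope linear extrapolation."""
    if kx.size == 1:
        return x - kx[0] + ky[0]
    y = np.interp(x, kx, ky)
    lo = x < kx[0]
    hi = x > kx[-1]
    if lo.any():
        s = max((ky[1] - ky[0]) / (kx[1] - kx[0]), _MIN_SLOPE)
        y[lo] = ky[0] + s * (x[lo] - kx[0])
    if hi.any():
        s = max((ky[-1] - ky[-2]) / (kx[-1] - kx[-2]), _MIN_SLOPE)
        y[hi] = ky[-1] + s * (x[hi] - kx[-1])
    return y


def _normalize_sample(sample: np.ndarray, model: NormalizationModel):
    keep = _select_invariant(
        sample, model.reference_profile, model.rank_threshold,
        model.min_invariant, model.max_iter,
    )
    kx, ky = _fit_knots(sample[keep], model.reference_profile[keep], model.n_quantile_knots)
    return _apply_knots(sample, kx, ky), keep, (kx, ky)


def fit_invariant_normalization(
    matrix: ExpressionMatrix,
    reference: str | np.ndarray = "median_sample",
    rank_threshold: float = 0.05,
    min_invariant: int = 20,
    n_quantile_knots: int = 25,
    offset_constant: float | None = None,
) -> NormalizationModel:
    """Fit a rank-invariant normalization model on a log2 matrix.

    ``reference`` is either ``"median_sample"`` (probe-wise median
    pseudo-sample, the default) or an explicit per-probe profile.
    """
    if matrix.scale is not Scale.LOG2:
        raise DomainError("normalization operates on log2-scale matrices")
    if matrix.n_samples < 2:
        raise NormalizationError("need at least 2 samples to fit normalization")
    if isinstance(reference, str):
        if reference != "median_sample":
            raise NormalizationError(f"unknown reference mode {reference!r}")
        ref = np.median(matrix.values, axis=1)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (matrix.n_probes,):
            raise AlignmentError("supplied reference length does not match probe count")
    model = NormalizationModel(
        probe_ids=list(matrix.probe_ids),
        reference_profile=ref,
        rank_threshold=rank_threshold,
        min_invariant=min_invariant,
        n_quantile_knots=n_quantile_knots,
        offset_constant=offset_constant,
    )
    for j, sid in enumerate(matrix.sample_ids):
        _, keep, (kx, ky) = _normalize_sample(matrix.values[:, j], model)
        model.invariant_probe_ids[sid] = [matrix.probe_ids[i] for i in keep]
        model.mapping_knots[sid] = (kx.tolist(), ky.tolist())
    return model


def apply_normalization(model: NormalizationModel, matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Map every sample of ``matrix`` onto the model's frozen reference.

    Probes must match the model's probe universe (order may differ). The
    per-sample mapping is monotone, so within-sample rank order is preserved.
    """
    if matrix.scale is not Scale.LOG2:
        raise DomainError("normalization operates on log2-scale matrices")
    if set(matrix.probe_ids) != set(model.probe_ids):
        unknown = sorted(set(matrix.probe_ids) - set(model.probe_ids))
        missing = sorted(set(model.probe_ids) - set(matrix.probe_ids))
        raise AlignmentError(
            f"probe universe mismatch (unknown: {unknown[:5]}, missing: {missing[:5]})"
        )
    aligned = matrix.subset_probes(model.probe_ids)
    out = np.empty_like(aligned.values)
    for j in range(aligned.n_samples):
        out[:, j], _, _ = _normalize_sample(aligned.values[:, j], model)
    return ExpressionMatrix(list(model.probe_ids), list(aligned.sample_ids), out, Scale.LOG2)
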