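"""Accuracy, precision and correlation statistics for fraction estimates.

Accuracy is the mean offset <dP> = mean(P_est - P_ref), precision the
(population) standard deviation of the offsets about their own mean, and
correlation the squared Pearson coefficient between estimate and reference.

Both offset conventions are always computed: the signed convention follows
the printed definition of <dP>; the absolute convention (offsets |P_est -
P_ref|) is the one whose degenerate-mixture limits under a flat fraction
prior are mean 1/4 and std 1/(4*sqrt(3)) ~ 0.144, matching the low-spacing
plateau of the spacing studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import FlimmixError, UndefinedStatisticError

__all__ = [
    "ComponentStats",
    "EvalReport",
    "mean_offset",
    "offset_std",
    "r_squared",
    "evaluate",
]

_CONVENTIONS = ("signed", "absolute")


def _offsets(pred, ref, convention: str) -> np.ndarray:
    p = np.asarray(pred, dtype=float).ravel()
    r = np.asarray(ref, dtype=float).ravel()
    if p.shape != r.shape or p.size < 1:
        raise FlimmixError("pred and ref must be equal-length non-empty columns")
    if convention not in _CONVENTIONS:
        raise FlimmixError(f"convention must be one of {_CONVENTIONS}")
    d = p - r
    return np.abs(d) if convention == "absolute" else d


def mean_offset(pred, ref, convention: str = "signed") -> float:
    """Mean offset between estimated and reference fractions."""
    return float(_offsets(pred, ref, convention).mean())


def offset_std(pred, ref, convention: str = "signed") -> float:
    """Population standard deviation of the offsets about their own mean."""
    d = _offsets(pred, ref, convention)
    if d.size < 2:
        raise UndefinedStatisticError("offset_std requires at least two samples")
    return float(d.std())


def r_squared(pred, ref, method: str = "pearson") -> float:
    """Squared correlation between estimate and reference.

    ``pearson`` (default) is the squared Pearson coefficient, defined as 0
    for a constant estimate.  ``identity`` scores agreement with the line
    P_est = P_ref (1 - SS_res/SS_tot, floored at 0).
    """
    p = np.asarray(pred, dtype=float).ravel()
    r = np.asarray(ref, dtype=float).ravel()
    if p.shape != r.shape or p.size < 2:
        raise FlimmixError("pred and ref must be equal-length columns with n >= 2")
    if np.ptp(r) == 0:
        raise UndefinedStatisticError("reference column is constant")
    if method == "pearson":
        if np.ptp(p) == 0:
            return 0.0
        return float(np.corrcoef(p, r)[0, 1] ** 2)
    if method == "identity":
        ss_res = np.sum((p - r) ** 2)
        ss_tot = np.sum((r - r.mean()) ** 2)
        return float(max(0.0, 1.0 - ss_res / ss_tot))
    raise FlimmixError("method must be 'pearson' or 'identity'")


@dataclass(frozen=True)
class ComponentStats:
    mean_offset_signed: float
    mean_offset_abs: float
    offset_std_signed: float
    offset_std_abs: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class EvalReport:
    """Per-fluorophore accuracy/precision/correlation statistics."""

    per_fluorophore: tuple[ComponentStats, ...]

    @property
    def n_components(self) -> int:
        return len(self.per_fluorophore)

    def stat(self, name: str) -> np.ndarray:
        return np.array([getattr(c, name) for c in self.per_fluorophore])

    def to_json(self) -> str:
        return json.dumps({"per_fluorophore": [asdict(c) for c in self.per_fluorophore]})

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per component x statistic."""
        rows = []
        for j, comp in enumerate(self.per_fluorophore):
            for key, value in asdict(comp).items():
                rows.append({"component": j, "statistic": key, "value": value})
        return pd.DataFrame(rows)


def evaluate(pred, ref) -> EvalReport:
    """All statistics per component column, under both offset conventions."""
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 2:
        raise FlimmixError("pred and ref must be matrices of identical shape")
    stats = []
    for j in range(p.shape[1]):
        stats.append(
            ComponentStats(
                mean_offset_signed=mean_offset(p[:, j], r[:, j], "signed"),
                mean_offset_abs=mean_offset(p[:, j], r[:, j], "absolute"),
                offset_std_signed=offset_std(p[:, j], r[:, j], "signed"),
                offset_std_abs=offset_std(p[:, j], r[:, j], "absolute"),
                r_squared=r_squared(p[:, j], r[:, j]),
                n=p.shape[0],
            )
        )
    return EvalReport(per_fluorophore=tuple(stats))
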