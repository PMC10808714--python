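"""Fixed-lifetime least-squares baseline for fraction determination.

With the lifetimes held fixed, the multi-exponential model is linear in the
amplitudes, so the fractional contributions follow from a non-negativity-
constrained linear least-squares fit of per-component expected bin shapes
plus a constant background term.  Unweighted by default; an optional
Poisson-variance weighting mode divides each bin by sqrt(max(counts, 1)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .decay import DecayCurve, InstrumentConfig, component_bin_masses
from .errors import DegenerateBasisError, FlimmixError

__all__ = ["LSFitResult", "ls_fixed_tau_fit"]


@dataclass(frozen=True)
class LSFitResult:
    amplitudes: tuple[float, ...]
    fractions: tuple[float, ...]
    residual_norm: float
    background: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "amplitudes": list(self.amplitudes),
                "fractions": list(self.fractions),
                "residual_norm": self.residual_norm,
                "background": self.background,
            }
        )


def ls_fixed_tau_fit(
    curve: DecayCurve,
    lifetimes: Sequence[float],
    instrument: InstrumentConfig,
    weighted: bool = False,
) -> LSFitResult:
    """Non-negative least-squares fit of a decay curve with known lifetimes.

    The design matrix columns are each component's per-bin arrival
    probabilities (decay convolved with the instrument kernel), so the fitted
    coefficient of column i is the expected number of photons emitted by
    component i; fractions are these coefficients normalized, identical to
    alpha_i tau_i / sum_j alpha_j tau_j.
    """
    taus = np.asarray(lifetimes, dtype=float)
    if taus.ndim != 1 or taus.size < 1 or np.any(taus <= 0):
        raise FlimmixError("lifetimes must be a non-empty sequence of positive reals")
    if taus.size > 1 and np.min(np.diff(np.sort(taus))) < 1e-9:
        raise DegenerateBasisError("duplicate lifetimes give a rank-deficient design")
    if len(curve.counts) != instrument.n_bins:
        raise FlimmixError(
            f"curve has {len(curve.counts)} bins, instrument expects {instrument.n_bins}"
        )

    masses = np.asarray(component_bin_masses(taus, instrument))
    design = np.column_stack([masses, np.ones(len(masses))])
    y = curve.counts.astype(float)
    if weighted:
        w = 1.0 / np.sqrt(np.maximum(y, 1.0))
        coeffs, resid = nnls(design * w[:, None], y * w)
    else:
        coeffs, resid = nnls(design, y)

    emitted = coeffs[: taus.size]  # photons emitted per component
    total = emitted.sum()
    if total <= 0:
        raise DegenerateBasisError("fit assigned zero signal to every component")
    fractions = emitted / total
    amplitudes = emitted / taus  # alpha_i up to a common scale
    return LSFitResult(
        amplitudes=tuple(float(a) for a in amplitudes),
        fractions=tuple(float(f) for f in fractions),
        residual_norm=float(resid),
        background=float(coeffs[-1]),
    )
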