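"""Lifetime-spacing studies and the minimal-spacing design law.

These experiments quantify how the spacing between fluorophore lifetimes
limits unmixing precision: a two-fluorophore spacing sweep, a three-
fluorophore middle-lifetime sweep, a bisection search for the minimal equal
spacing achieving a target precision, the log-linear design law
log10(dtau_min) = slope * N + intercept fitted over fluorophore counts, and
an SNR sensitivity sweep.

Every grid point trains a fresh estimator per replicate seed on freshly
simulated data and evaluates on a held-out set with a disjoint seed; the
reported statistic is the mean across replicates.  Precision statistics use
the absolute-offset convention throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace, asdict
from typing import Sequence

import numpy as np

from . import ann
from .decay import InstrumentConfig, generate_dataset
from .errors import BracketError, FlimmixError
from .metrics import ComponentStats, EvalReport, evaluate

__all__ = [
    "SweepResult",
    "SpacingLaw",
    "train_and_evaluate",
    "sweep_spacing_two",
    "sweep_middle_lifetime_three",
    "find_min_spacing",
    "fit_spacing_law",
    "snr_sweep",
    "max_distinguishable",
]

DEFAULT_BASE_LIFETIME_NS = 4.0


@dataclass(frozen=True)
class SweepResult:
    grid: tuple[float, ...]
    stats: tuple[EvalReport, ...]
    n_seeds: int
    config_digest: str

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.stats):
            raise FlimmixError("grid and stats must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise FlimmixError("grid must be strictly increasing")

    def stat(self, name: str) -> np.ndarray:
        """Statistic matrix, shape (len(grid), n_components)."""
        return np.stack([report.stat(name) for report in self.stats])

    def to_json(self) -> str:
        return json.dumps(
            {
                "grid": list(self.grid),
                "stats": [
                    {"per_fluorophore": [asdict(c) for c in r.per_fluorophore]}
                    for r in self.stats
                ],
                "n_seeds": self.n_seeds,
                "config_digest": self.config_digest,
            }
        )


@dataclass(frozen=True)
class SpacingLaw:
    """Fitted coefficients of log10(dtau_min) = slope * N + intercept."""

    n_values: tuple[int, ...]
    min_spacings_ns: tuple[float, ...]
    slope: float
    intercept: float
    fit_r_squared: float
    sigma_target: float = 0.05

    def __post_init__(self) -> None:
        if len(self.n_values) != len(self.min_spacings_ns):
            raise FlimmixError("n_values and min_spacings_ns must have equal length")
        if any(s <= 0 for s in self.min_spacings_ns):
            raise FlimmixError("min_spacings_ns must be positive")

    def predict_spacing(self, n_fluorophores: int) -> float:
        return float(10.0 ** (self.slope * n_fluorophores + self.intercept))

    def to_json(self) -> str:
        return json.dumps(asdict(self))


# ---------------------------------------------------------------------------
# seed plumbing

_SEED_MOD = 2**31


def _derive_seed(seed: int, *key: int) -> int:
    """Deterministic, collision-resistant sub-seed below 2**31."""
    state = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key))
    return int(state.generate_state(1)[0] % _SEED_MOD)


def _digest(**parts) -> str:
    blob = json.dumps({k: repr(v) for k, v in sorted(parts.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# single train/evaluate replicate and seed aggregation

def train_and_evaluate(
    lifetimes: Sequence[float],
    instrument: InstrumentConfig,
    est: ann.EstimatorConfig | None,
    n_train: int,
    n_test: int,
    seed: int,
) -> EvalReport:
    """Simulate disjoint train/test sets, train a fresh estimator, evaluate."""
    taus = [float(t) for t in lifetimes]
    if est is None:
        est = ann.build_estimator(len(taus))
    est = replace(est, n_components=len(taus), seed=_derive_seed(seed, 2))
    train_set = generate_dataset(
        n_train, taus, instrument, prior="flat", seed=_derive_seed(seed, 0)
    )
    test_set = generate_dataset(
        n_test, taus, instrument, prior="flat", seed=_derive_seed(seed, 1)
    )
    model = ann.train(est, train_set)
    pred = ann.predict(model, test_set)
    return evaluate(pred, test_set.labels)


def _mean_report(reports: Sequence[EvalReport]) -> EvalReport:
    """Average every statistic across replicate reports (n is summed)."""
    comps = []
    for j in range(reports[0].n_components):
        fields = {}
        for name in (
            "mean_offset_signed",
            "mean_offset_abs",
            "offset_std_signed",
            "offset_std_abs",
            "r_squared",
        ):
            fields[name] = float(
                np.mean([getattr(r.per_fluorophore[j], name) for r in reports])
            )
        fields["n"] = int(np.sum([r.per_fluorophore[j].n for r in reports]))
        comps.append(ComponentStats(**fields))
    return EvalReport(per_fluorophore=tuple(comps))


def _replicated(
    lifetimes: Sequence[float],
    instrument: InstrumentConfig,
    est: ann.EstimatorConfig | None,
    n_train: int,
    n_test: int,
    n_seeds: int,
    seed: int,
) -> EvalReport:
    reports = [
        train_and_evaluate(
            lifetimes, instrument, est, n_train, n_test, _derive_seed(seed, 3, rep)
        )
        for rep in range(n_seeds)
    ]
    return _mean_report(reports)


# ---------------------------------------------------------------------------
# sweeps

def sweep_spacing_two(
    tau_a_ns: float,
    delta_grid: Sequence[float],
    instrument: InstrumentConfig,
    est: ann.EstimatorConfig | None = None,
    n_train: int = 10_000,
    n_test: int = 2_000,
    n_seeds: int = 3,
    seed: int = 0,
) -> SweepResult:
    """Two-fluorophore sweep: lifetimes (tau_a, tau_a + dtau) per grid point."""
    grid = [float(d) for d in delta_grid]
    if any(d <= 0 for d in grid) or np.any(np.diff(grid) <= 0):
        raise FlimmixError("delta_grid must be positive and strictly increasing")
    stats = [
        _replicated(
            [tau_a_ns, tau_a_ns + d], instrument, est, n_train, n_test, n_seeds,
            _derive_seed(seed, 10, i),
        )
        for i, d in enumerate(grid)
    ]
    return SweepResult(
        grid=tuple(grid),
        stats=tuple(stats),
        n_seeds=n_seeds,
        config_digest=_digest(kind="two", tau_a=tau_a_ns, instrument=instrument,
                              est=est, n_train=n_train, n_test=n_test, seed=seed),
    )


def sweep_middle_lifetime_three(
    delta_grid: Sequence[float],
    tau_a_ns: float = 4.0,
    tau_c_ns: float = 10.0,
    instrument: InstrumentConfig | None = None,
    est: ann.EstimatorConfig | None = None,
    n_train: int = 10_000,
    n_test: int = 2_000,
    n_seeds: int = 3,
    seed: int = 0,
) -> SweepResult:
    """Three-fluorophore sweep: tau_A and tau_C fixed, tau_B = tau_A + dtau."""
    instrument = instrument or InstrumentConfig()
    grid = [float(d) for d in delta_grid]
    if np.any(np.diff(grid) <= 0):
        raise FlimmixError("delta_grid must be strictly increasing")
    if any(not tau_a_ns < tau_a_ns + d < tau_c_ns for d in grid):
        raise FlimmixError("grid must satisfy tau_A < tau_B < tau_C")
    stats = [
        _replicated(
            [tau_a_ns, tau_a_ns + d, tau_c_ns], instrument, est, n_train, n_test,
            n_seeds, _derive_seed(seed, 11, i),
        )
        for i, d in enumerate(grid)
    ]
    return SweepResult(
        grid=tuple(grid),
        stats=tuple(stats),
        n_seeds=n_seeds,
        config_digest=_digest(kind="three", tau_a=tau_a_ns, tau_c=tau_c_ns,
                              instrument=instrument, est=est, n_train=n_train,
                              n_test=n_test, seed=seed),
    )


def snr_sweep(
    snr_grid: Sequence[float],
    lifetimes: Sequence[float],
    instrument: InstrumentConfig | None = None,
    est: ann.EstimatorConfig | None = None,
    n_train: int = 10_000,
    n_test: int = 2_000,
    n_seeds: int = 3,
    seed: int = 0,
) -> SweepResult:
    """Precision and accuracy as a function of the peak-to-background SNR."""
    base = instrument or InstrumentConfig()
    grid = [float(s) for s in snr_grid]
    if any(s < 1 for s in grid) or np.any(np.diff(grid) <= 0):
        raise FlimmixError("snr_grid must be >= 1 and strictly increasing")
    stats = [
        _replicated(
            lifetimes, replace(base, snr=s), est, n_train, n_test, n_seeds,
            _derive_seed(seed, 12, i),
        )
        for i, s in enumerate(grid)
    ]
    return SweepResult(
        grid=tuple(grid),
        stats=tuple(stats),
        n_seeds=n_seeds,
        config_digest=_digest(kind="snr", lifetimes=list(lifetimes), instrument=base,
                              est=est, n_train=n_train, n_test=n_test, seed=seed),
    )


# ---------------------------------------------------------------------------
# minimal spacing search and design law

def _ladder(n_fluorophores: int, delta: float, base: float) -> list[float]:
    return [base + i * delta for i in range(n_fluorophores)]


def _aggregate_sigma(report: EvalReport, aggregate: str) -> float:
    sigmas = report.stat("offset_std_abs")
    if aggregate == "mean":
        return float(sigmas.mean())
    if aggregate == "worst":
        return float(sigmas.max())
    raise FlimmixError("aggregate must be 'mean' or 'worst'")


def find_min_spacing(
    n_fluorophores: int,
    sigma_target: float = 0.05,
    tol_ns: float = 0.2,
    instrument: InstrumentConfig | None = None,
    est: ann.EstimatorConfig | None = None,
    n_seeds: int = 3,
    n_train: int = 10_000,
    n_test: int = 2_000,
    seed: int = 0,
    bracket: tuple[float, float] = (0.1, 14.0),
    base_lifetime_ns: float = DEFAULT_BASE_LIFETIME_NS,
    aggregate: str = "mean",
    return_details: bool = False,
):
    """Smallest equal lifetime spacing achieving the precision target.

    Lifetimes form an equally spaced ladder from ``base_lifetime_ns``; the
    criterion is the seed-averaged absolute-offset standard deviation,
    aggregated across fluorophores (mean by default, worst-component
    optionally), compared against ``sigma_target``.  Bisection assumes a
    single crossing inside the bracket; both endpoints are verified first.
    """
    if n_fluorophores < 2:
        raise FlimmixError("n_fluorophores must be >= 2")
    if tol_ns <= 0 or sigma_target <= 0:
        raise FlimmixError("tol_ns and sigma_target must be positive")
    instrument = instrument or InstrumentConfig()
    lo, hi = float(bracket[0]), float(bracket[1])
    if not 0 < lo < hi:
        raise FlimmixError("bracket must satisfy 0 < lo < hi")

    evaluations: dict[float, float] = {}

    def sigma_at(delta: float) -> float:
        if delta not in evaluations:
            report = _replicated(
                _ladder(n_fluorophores, delta, base_lifetime_ns), instrument, est,
                n_train, n_test, n_seeds, _derive_seed(seed, 13, n_fluorophores),
            )
            evaluations[delta] = _aggregate_sigma(report, aggregate)
        return evaluations[delta]

    if sigma_at(hi) > sigma_target:
        raise BracketError(
            f"sigma({hi:g} ns) = {evaluations[hi]:.4f} > target {sigma_target:g}; "
            f"the precision target is unreachable inside the bracket "
            f"(n_fluorophores={n_fluorophores}, evaluations={evaluations})"
        )
    if sigma_at(lo) <= sigma_target:
        result = lo
    else:
        while hi - lo > tol_ns:
            mid = 0.5 * (lo + hi)
            if sigma_at(mid) <= sigma_target:
                hi = mid
            else:
                lo = mid
        result = hi
    if return_details:
        return result, dict(sorted(evaluations.items()))
    return result


def fit_spacing_law(
    n_values: Sequence[int],
    min_spacings_ns: Sequence[float],
    sigma_target: float = 0.05,
) -> SpacingLaw:
    """Ordinary least-squares line through (N, log10 dtau_min)."""
    n = np.asarray(n_values, dtype=float)
    d = np.asarray(min_spacings_ns, dtype=float)
    if n.size != d.size or n.size < 2:
        raise FlimmixError("need at least two (N, dtau_min) points")
    if np.any(d <= 0):
        raise FlimmixError("min_spacings_ns must be positive")
    y = np.log10(d)
    slope, intercept = np.polyfit(n, y, 1)
    fitted = slope * n + intercept
    ss_tot = np.sum((y - y.mean()) ** 2)
    ss_res = np.sum((y - fitted) ** 2)
    r2 = 1.0 if ss_tot == 0 else float(1.0 - ss_res / ss_tot)
    return SpacingLaw(
        n_values=tuple(int(v) for v in n_values),
        min_spacings_ns=tuple(float(v) for v in d),
        slope=float(slope),
        intercept=float(intercept),
        fit_r_squared=r2,
        sigma_target=sigma_target,
    )


def max_distinguishable(law: SpacingLaw, lifetime_budget_ns: float = 20.0) -> int:
    """Largest N with (N - 1) * dtau_min(N) within the lifetime budget.

    Most practical fluorophores have lifetimes below ~20 ns, so the ladder
    span (N - 1) * dtau_min(N) must fit into that budget.
    """
    n = 2
    while (n + 1 - 1) * law.predict_spacing(n + 1) <= lifetime_budget_ns:
        n += 1
        if n > 1000:
            break
    return n
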