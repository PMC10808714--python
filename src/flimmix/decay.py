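"""Physical decay model and Monte-Carlo TCSPC simulator.

A mixture of mono-exponential fluorophores produces the multi-exponential
decay

    I(t) = sum_i alpha_i * exp(-t / tau_i),

where ``alpha_i`` is the amplitude-representative factor and ``tau_i`` the
fluorescence lifetime of component ``i``.  The fractional contribution of a
component to the total emitted signal is

    P_i = alpha_i * tau_i / sum_j alpha_j * tau_j.

The simulator emulates a SPAD-array TCSPC acquisition: each detected photon
carries a fluorescence delay drawn from Exponential(tau_i), an excitation
offset from the laser pulse (Gaussian core plus exponential turn-off tail),
and Gaussian detector jitter.  Arrivals are binned into a fixed window; a
constant-rate Poisson background implied by the configured SNR is added per
bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.stats import exponnorm

from .errors import DegenerateMixtureError, FlimmixError, ReproducibilityError

__all__ = [
    "FluorophoreSpec",
    "MixtureSample",
    "InstrumentConfig",
    "DecayCurve",
    "LabeledDataset",
    "fractional_contributions",
    "reference_fractions",
    "amplitudes_from_fractions",
    "component_bin_masses",
    "expected_histogram",
    "simulate_decay",
    "generate_dataset",
    "snr_of",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class FluorophoreSpec:
    """One emitter: lifetime tau_i [ns], amplitude alpha_i, per-volume
    emission intensity factor I_0,i (used for reference fractions)."""

    lifetime_ns: float
    amplitude: float = 1.0
    intensity_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.lifetime_ns > 0:
            raise FlimmixError(f"lifetime_ns must be positive, got {self.lifetime_ns}")
        if self.amplitude < 0:
            raise FlimmixError(f"amplitude must be non-negative, got {self.amplitude}")
        if self.intensity_factor < 0:
            raise FlimmixError(
                f"intensity_factor must be non-negative, got {self.intensity_factor}"
            )


@dataclass(frozen=True)
class MixtureSample:
    """A fluorophore mixture with its fractional contributions P_i.

    ``fractions`` always sum to one.  ``volumes_ul`` is optional provenance
    for mixtures prepared volumetrically.
    """

    components: tuple[FluorophoreSpec, ...]
    fractions: tuple[float, ...]
    volumes_ul: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.components) != len(self.fractions):
            raise FlimmixError("components and fractions must have equal length")
        if self.volumes_ul is not None and len(self.volumes_ul) != len(self.components):
            raise FlimmixError("volumes_ul length must match components")
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < -1e-12):
            raise FlimmixError("fractions must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise FlimmixError(f"fractions must sum to 1, got {f.sum()!r}")

    @property
    def lifetimes_ns(self) -> np.ndarray:
        return np.array([c.lifetime_ns for c in self.components], dtype=float)

    @classmethod
    def from_fractions(
        cls, lifetimes_ns: Sequence[float], fractions: Sequence[float]
    ) -> "MixtureSample":
        comps = tuple(FluorophoreSpec(t) for t in lifetimes_ns)
        f = np.asarray(fractions, dtype=float)
        return cls(components=comps, fractions=tuple(f / f.sum()))

    @classmethod
    def from_amplitudes(
        cls, lifetimes_ns: Sequence[float], amplitudes: Sequence[float]
    ) -> "MixtureSample":
        frac = fractional_contributions(amplitudes, lifetimes_ns)
        comps = tuple(
            FluorophoreSpec(t, amplitude=a) for t, a in zip(lifetimes_ns, amplitudes)
        )
        return cls(components=comps, fractions=tuple(frac))

    @classmethod
    def from_volumes(
        cls,
        components: Sequence[FluorophoreSpec],
        volumes_ul: Sequence[float],
    ) -> "MixtureSample":
        frac = reference_fractions(
            volumes_ul, [c.intensity_factor for c in components]
        )
        return cls(
            components=tuple(components),
            fractions=tuple(frac),
            volumes_ul=tuple(float(v) for v in volumes_ul),
        )


@dataclass(frozen=True)
class InstrumentConfig:
    """TCSPC/laser/SPAD acquisition parameters.

    Defaults mirror a SPAD-array TCSPC setup: 312.5 ps bins over a 1.28 us
    window (4096 bins), a laser pulse with 1.25 ns FWHM Gaussian core and a
    600 ps exponential turn-off, 150 ps rms detector jitter, a peak-to-
    background SNR of 100, and 5e4 signal photons per curve.
    """

    bin_width_ns: float = 0.3125
    window_ns: float = 1280.0
    laser_fwhm_ns: float = 1.25
    laser_turnoff_ns: float = 0.6
    jitter_sigma_ns: float = 0.15
    snr: float | None = 100.0
    n_photons: int = 50_000

    def __post_init__(self) -> None:
        if self.bin_width_ns <= 0 or self.window_ns <= 0:
            raise FlimmixError("bin_width_ns and window_ns must be positive")
        ratio = self.window_ns / self.bin_width_ns
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise FlimmixError("window_ns / bin_width_ns must be a positive integer")
        if self.laser_fwhm_ns < 0 or self.laser_turnoff_ns < 0 or self.jitter_sigma_ns < 0:
            raise FlimmixError("laser and jitter parameters must be non-negative")
        if self.snr is not None and self.snr < 1:
            raise FlimmixError("snr must be >= 1 when set")
        if self.n_photons < 0:
            raise FlimmixError("n_photons must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(round(self.window_ns / self.bin_width_ns))

    @property
    def irf_sigma_ns(self) -> float:
        """Gaussian width of the combined laser-core + jitter blur."""
        return math.hypot(self.laser_fwhm_ns / _FWHM_TO_SIGMA, self.jitter_sigma_ns)

    @property
    def time_ns(self) -> np.ndarray:
        """Bin-start times (half-open bins [t, t + bin_width))."""
        return np.arange(self.n_bins) * self.bin_width_ns


@dataclass(frozen=True)
class DecayCurve:
    """A binned photon-count histogram with its time axis."""

    counts: np.ndarray
    time_ns: np.ndarray
    mixture: MixtureSample | None = None
    instrument: InstrumentConfig | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        time_ns = np.asarray(self.time_ns, dtype=float)
        if counts.ndim != 1 or counts.shape != time_ns.shape:
            raise FlimmixError("counts and time_ns must be 1-D arrays of equal length")
        if np.any(counts < 0):
            raise FlimmixError("counts must be non-negative")
        if len(time_ns) > 1:
            steps = np.diff(time_ns)
            if np.any(steps <= 0) or np.ptp(steps) > 1e-9:
                raise FlimmixError("time_ns must increase with a constant step")
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))
        object.__setattr__(self, "time_ns", time_ns)

    @property
    def bin_width_ns(self) -> float:
        return float(self.time_ns[1] - self.time_ns[0])


@dataclass(frozen=True)
class LabeledDataset:
    """Curves paired with reference fraction vectors P_Ref (one row each)."""

    curves: tuple[DecayCurve, ...]
    labels: np.ndarray
    seed: int
    prior_spec: str
    lifetimes_ns: tuple[float, ...]
    instrument: InstrumentConfig

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=float)
        if labels.ndim != 2 or labels.shape[0] != len(self.curves):
            raise FlimmixError("labels must have one row per curve")
        if np.any(np.abs(labels.sum(axis=1) - 1.0) > 1e-9):
            raise FlimmixError("label rows must sum to 1")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.curves)

    def count_matrix(self) -> np.ndarray:
        return np.stack([c.counts for c in self.curves])


# ---------------------------------------------------------------------------
# fraction algebra

def fractional_contributions(
    amplitudes: Sequence[float], lifetimes: Sequence[float]
) -> np.ndarray:
    """P_i = alpha_i tau_i / sum_j alpha_j tau_j."""
    a = np.asarray(amplitudes, dtype=float)
    t = np.asarray(lifetimes, dtype=float)
    if a.shape != t.shape or a.ndim != 1 or a.size < 1:
        raise FlimmixError("amplitudes and lifetimes must be equal-length 1-D sequences")
    if np.any(a < 0):
        raise FlimmixError("amplitudes must be non-negative")
    if np.any(t <= 0):
        raise FlimmixError("lifetimes must be positive")
    products = a * t
    total = products.sum()
    if total <= 0:
        raise DegenerateMixtureError("all alpha_i * tau_i products are zero")
    return products / total


def reference_fractions(
    volumes_ul: Sequence[float], intensity_factors: Sequence[float]
) -> np.ndarray:
    """P_Ref,i = I_0,i v_i / sum_j I_0,j v_j."""
    v = np.asarray(volumes_ul, dtype=float)
    i0 = np.asarray(intensity_factors, dtype=float)
    if v.shape != i0.shape or v.ndim != 1 or v.size < 1:
        raise FlimmixError("volumes and intensity factors must be equal-length 1-D sequences")
    if np.any(v < 0) or np.any(i0 < 0):
        raise FlimmixError("volumes and intensity factors must be non-negative")
    products = v * i0
    total = products.sum()
    if total <= 0:
        raise DegenerateMixtureError("sum of I_0,i * v_i is zero")
    return products / total


def amplitudes_from_fractions(
    fractions: Sequence[float], lifetimes: Sequence[float]
) -> np.ndarray:
    """Invert the fractional-contribution relation: alpha_i proportional to
    P_i / tau_i, normalized so that sum alpha_i tau_i = 1."""
    p = np.asarray(fractions, dtype=float)
    t = np.asarray(lifetimes, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 1:
        raise FlimmixError("fractions and lifetimes must be equal-length 1-D sequences")
    if np.any(t <= 0):
        raise FlimmixError("lifetimes must be positive")
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < -1e-12):
        raise FlimmixError("fractions must be non-negative and sum to 1")
    return p / t


# ---------------------------------------------------------------------------
# expected histogram

def _arrival_cdf(edges: np.ndarray, tau: float, sigma: float, tau_l: float) -> np.ndarray:
    """CDF of Exp(tau) + Exp(tau_l) + Normal(0, sigma) at ``edges``.

    Degenerate widths collapse to the matching closed form; a decay lifetime
    equal to the laser turn-off time is nudged to keep the two-exponential
    difference formula well conditioned.
    """
    if tau_l > 0 and abs(tau - tau_l) < 1e-9 * tau:
        tau_l = tau_l * (1.0 - 1e-6)
    if sigma <= 0:
        t = np.maximum(edges, 0.0)
        if tau_l <= 0:
            return -np.expm1(-t / tau)
        return 1.0 - (tau * np.exp(-t / tau) - tau_l * np.exp(-t / tau_l)) / (tau - tau_l)
    if tau_l <= 0:
        return exponnorm.cdf(edges, tau / sigma, scale=sigma)
    f_tau = exponnorm.cdf(edges, tau / sigma, scale=sigma)
    f_tl = exponnorm.cdf(edges, tau_l / sigma, scale=sigma)
    return (tau * f_tau - tau_l * f_tl) / (tau - tau_l)


@lru_cache(maxsize=64)
def _cached_masses(
    lifetimes: tuple[float, ...], instrument: InstrumentConfig
) -> np.ndarray:
    edges = np.arange(instrument.n_bins + 1) * instrument.bin_width_ns
    sigma = instrument.irf_sigma_ns
    tau_l = instrument.laser_turnoff_ns
    cols = [np.diff(_arrival_cdf(edges, tau, sigma, tau_l)) for tau in lifetimes]
    masses = np.stack(cols, axis=1)
    masses.setflags(write=False)
    return masses


def component_bin_masses(
    lifetimes: Sequence[float], instrument: InstrumentConfig
) -> np.ndarray:
    """Per-bin arrival probability for each component, shape (n_bins, n_comp).

    Column j integrates the normalized arrival-time density of component j
    (decay convolved with the laser/jitter kernel) over each half-open bin;
    column sums are the in-window detection probabilities.
    """
    return _cached_masses(tuple(float(t) for t in lifetimes), instrument)


def expected_histogram(
    mixture: MixtureSample, instrument: InstrumentConfig
) -> np.ndarray:
    """Noise-free expected bin contents: signal expectation plus the constant
    background level implied by the configured SNR."""
    masses = component_bin_masses(mixture.lifetimes_ns, instrument)
    signal = instrument.n_photons * (masses @ np.asarray(mixture.fractions))
    if instrument.snr is not None and signal.max() > 0:
        signal = signal + signal.max() / instrument.snr
    return signal


def _background_level(
    mixture: MixtureSample, instrument: InstrumentConfig
) -> float:
    if instrument.snr is None:
        return 0.0
    masses = component_bin_masses(mixture.lifetimes_ns, instrument)
    peak = instrument.n_photons * (masses @ np.asarray(mixture.fractions)).max()
    return float(peak / instrument.snr)


# ---------------------------------------------------------------------------
# Monte-Carlo simulation

_F32 = np.float32


def _simulate(
    mixture: MixtureSample,
    instrument: InstrumentConfig,
    seq: np.random.SeedSequence,
) -> DecayCurve:
    rng = np.random.default_rng(seq)
    n = instrument.n_photons
    n_bins = instrument.n_bins
    fractions = np.asarray(mixture.fractions, dtype=float)
    taus = mixture.lifetimes_ns

    # Photons are exchangeable within a histogram, so the per-photon
    # categorical component draw is realized as one multinomial split.
    per_comp = rng.multinomial(n, fractions)
    t = rng.standard_exponential(n, dtype=_F32)
    start = 0
    for count, tau in zip(per_comp, taus):
        t[start : start + count] *= _F32(tau)
        start += count
    if instrument.laser_turnoff_ns > 0:
        t += rng.standard_exponential(n, dtype=_F32) * _F32(instrument.laser_turnoff_ns)
    sigma = instrument.irf_sigma_ns
    if sigma > 0:
        t += rng.standard_normal(n, dtype=_F32) * _F32(sigma)

    # Shift bin index by one so that both early (t < 0) and late (t >= window)
    # photons land in overflow slots that are sliced away.
    k = (t * _F32(1.0 / instrument.bin_width_ns)).astype(np.int32) + 1
    np.clip(k, 0, n_bins + 1, out=k)
    k[t < 0] = 0
    counts = np.bincount(k, minlength=n_bins + 2)[1 : n_bins + 1]

    level = _background_level(mixture, instrument)
    if level > 0:
        counts = counts + rng.poisson(level, n_bins)

    return DecayCurve(
        counts=counts,
        time_ns=instrument.time_ns,
        mixture=mixture,
        instrument=instrument,
    )


def simulate_decay(
    mixture: MixtureSample, instrument: InstrumentConfig, seed: int
) -> DecayCurve:
    """Monte-Carlo sample one TCSPC decay curve.

    Each photon's component is chosen with probability P_i, its arrival time
    is Exponential(tau_i) plus the laser pulse offset (Gaussian core and
    exponential turn-off tail) plus Gaussian detector jitter; arrivals
    outside [0, window) are dropped.  Identical seeds give identical curves.
    """
    if seed is None:
        raise ReproducibilityError("simulate_decay requires an explicit seed")
    return _simulate(mixture, instrument, np.random.SeedSequence(int(seed)))


def _parse_prior(prior: str | Sequence[float] | None, n_components: int) -> np.ndarray:
    if prior is None or prior == "flat":
        return np.ones(n_components)
    alphas = np.asarray(prior, dtype=float)
    if alphas.shape != (n_components,) or np.any(alphas <= 0):
        raise FlimmixError(
            "prior must be 'flat' or a length-n vector of positive Dirichlet "
            f"concentrations, got {prior!r}"
        )
    return alphas


def generate_dataset(
    n_curves: int,
    lifetimes: Sequence[float],
    instrument: InstrumentConfig,
    prior: str | Sequence[float] | None = "flat",
    seed: int | None = None,
) -> LabeledDataset:
    """Simulate a labelled training/test set.

    Reference fractions are drawn per curve from a Dirichlet prior over the
    simplex (flat by default), converted to amplitudes, and each curve is
    simulated with a counter-based per-curve sub-seed, so the dataset is
    reproducible independent of generation order.
    """
    if seed is None:
        raise ReproducibilityError("generate_dataset requires an explicit seed")
    if n_curves < 1:
        raise FlimmixError("n_curves must be >= 1")
    taus = [float(t) for t in lifetimes]
    alphas = _parse_prior(prior, len(taus))

    label_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(0,))
    )
    labels = label_rng.dirichlet(alphas, size=n_curves)

    curves = []
    for i in range(n_curves):
        mixture = MixtureSample.from_fractions(taus, labels[i])
        seq = np.random.SeedSequence(entropy=int(seed), spawn_key=(1, i))
        curves.append(_simulate(mixture, instrument, seq))
    prior_spec = "flat" if prior is None or isinstance(prior, str) else (
        "dirichlet(" + ",".join(f"{a:g}" for a in alphas) + ")"
    )
    return LabeledDataset(
        curves=tuple(curves),
        labels=labels,
        seed=int(seed),
        prior_spec=prior_spec,
        lifetimes_ns=tuple(taus),
        instrument=instrument,
    )


def snr_of(curve: DecayCurve, tail_fraction: float = 0.1) -> float:
    """Peak counts divided by the mean of the final ``tail_fraction`` of the
    window (the noise-level estimate).  Returns +inf for a zero tail."""
    if not 0 < tail_fraction < 1:
        raise FlimmixError("tail_fraction must be in (0, 1)")
    counts = curve.counts
    if counts.size == 0:
        raise FlimmixError("curve is empty")
    n_tail = max(1, int(round(tail_fraction * counts.size)))
    noise = counts[-n_tail:].mean()
    if noise == 0:
        return math.inf
    return float(counts.max() / noise)
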