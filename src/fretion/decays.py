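"""Synthetic TCSPC decay histograms.

A fluorescence decay recorded by time-correlated single photon counting is
modelled as a sum of exponentials convolved with a Gaussian instrument
response function (IRF).  For component lifetime tau and a Gaussian IRF of
centre t0 and width sigma the convolution has the closed form

    m(t) = (A/2) * exp(sigma^2/(2 tau^2) - (t - t0)/tau)
               * erfc( (sigma/tau - (t - t0)/sigma) / sqrt(2) )

which this module evaluates on the TCSPC bin grid, scales to a requested
photon budget and (optionally) Poisson-samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = ["DecaySpec", "DecayHistogram", "decay_model", "simulate_decay"]


@dataclass(frozen=True)
class DecaySpec:
    """Parameters of a simulated TCSPC acquisition.

    lifetimes_ns / amplitudes define 1 or 2 decay components; ``irf_center_ns``
    and ``irf_width_ns`` the Gaussian IRF; the histogram has ``n_bins`` bins of
    ``bin_width_ns``.  ``total_counts`` is the expected photon budget; with
    ``noise='poisson'`` each bin is Poisson-sampled around the model.
    """

    lifetimes_ns: tuple[float, ...]
    amplitudes: tuple[float, ...]
    irf_center_ns: float = 2.0
    irf_width_ns: float = 0.2
    n_bins: int = 256
    bin_width_ns: float = 0.097
    total_counts: int = 100_000
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in self.lifetimes_ns)
        amps = tuple(float(a) for a in self.amplitudes)
        object.__setattr__(self, "lifetimes_ns", taus)
        object.__setattr__(self, "amplitudes", amps)
        if not 1 <= len(taus) <= 2 or len(amps) != len(taus):
            raise ValueError("1 or 2 components with matching amplitudes required")
        if any(t <= 0 for t in taus):
            raise ValueError("lifetimes must be > 0")
        if any(a < 0 for a in amps) or sum(amps) == 0:
            raise ValueError("amplitudes must be >= 0 with positive sum")
        if self.irf_width_ns <= 0:
            raise ValueError("IRF width must be > 0")
        if self.n_bins * self.bin_width_ns < 5 * max(taus):
            raise ValueError("time window must span >= 5 lifetimes")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def times_ns(self) -> np.ndarray:
        """Bin-centre time axis in ns."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns

    def intensity_weighted_lifetime(self) -> float:
        """Analytic tau_av_int = sum A_i tau_i^2 / sum A_i tau_i."""
        a = np.asarray(self.amplitudes)
        t = np.asarray(self.lifetimes_ns)
        return float(np.sum(a * t**2) / np.sum(a * t))


@dataclass
class DecayHistogram:
    """Time-binned photon counts."""

    times_ns: np.ndarray
    counts: np.ndarray
    bin_width_ns: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times_ns.shape != self.counts.shape or self.times_ns.size < 32:
            raise ValueError("need matching time/count arrays with >= 32 bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


def decay_model(
    times_ns: np.ndarray,
    lifetimes_ns,
    amplitudes,
    irf_center_ns: float,
    irf_width_ns: float,
) -> np.ndarray:
    """Multi-exponential decay reconvolved with a Gaussian IRF.

    Amplitudes are in relative units; the returned curve is not normalised.
    """
    t = np.asarray(times_ns, dtype=float)
    out = np.zeros_like(t)
    s = float(irf_width_ns)
    for tau, amp in zip(np.atleast_1d(lifetimes_ns), np.atleast_1d(amplitudes)):
        dt = t - irf_center_ns
        # exp * erfc written via erfcx for numerical stability at small tau
        arg = (s / tau - dt / s) / np.sqrt(2.0)
        log_pref = s**2 / (2.0 * tau**2) - dt / tau
        with np.errstate(over="ignore", invalid="ignore"):
            pos = special.erfcx(arg) * np.exp(log_pref - arg**2)
            neg = special.erfc(arg) * np.exp(log_pref)
            term = 0.5 * amp * np.where(arg > 0, np.nan_to_num(pos), np.nan_to_num(neg))
        out += term
    return out


def simulate_decay(spec: DecaySpec) -> DecayHistogram:
    """Simulate a TCSPC histogram for ``spec``.

    The noiseless reconvolved model is scaled so its sum equals
    ``spec.total_counts``; with ``noise='poisson'`` each bin is then an
    independent Poisson draw seeded by ``spec.seed``.
    """
    t = spec.times_ns
    model = decay_model(
        t, spec.lifetimes_ns, spec.amplitudes, spec.irf_center_ns, spec.irf_width_ns
    )
    model = model * (spec.total_counts / model.sum())
    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        counts = rng.poisson(model).astype(float)
    else:
        counts = model
    return DecayHistogram(
        times_ns=t,
        counts=counts,
        bin_width_ns=spec.bin_width_ns,
        meta={
            "lifetimes_ns": spec.lifetimes_ns,
            "amplitudes": spec.amplitudes,
            "irf_center_ns": spec.irf_center_ns,
            "irf_width_ns": spec.irf_width_ns,
            "noise": spec.noise,
            "seed": spec.seed,
        },
    )
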