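"""Biexponential NAD(P)H fluorescence decay model.

TCSPC instruments record, per pixel, a histogram of photon arrival times
relative to the excitation pulse.  NAD(P)H decays biexponentially: a short
component tau1 (~0.4 ns, free NAD(P)H) and a long component tau2 (~1.7-3 ns,
protein-bound NAD(P)H) with relative amplitude contributions a1 + a2 = 100 %.
The amplitude-weighted mean lifetime is

    tau_m = (a1 * tau1 + a2 * tau2) / (a1 + a2)

The expected histogram is the (optionally periodic) biexponential decay,
integrated over each time bin, circularly convolved with the instrument
response function (IRF), scaled and offset.  With an 80 MHz pulsed laser the
repetition period is 12.5 ns, so the slow component does not fully decay
between pulses; the periodic (steady-state) mode applies the geometric-series
correction 1 / (1 - exp(-T/tau)) for this incomplete-decay wrap-around.

Everything here is a pure function of its arguments; the simulator and the
fitter both build on these primitives so that fitting the simulator's output
is a genuine inverse problem with a shared forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeGrid",
    "PhotonHistogram",
    "InstrumentResponse",
    "DecayParams",
    "mean_lifetime",
    "decay_shape",
    "model_curve",
    "gaussian_irf",
    "delta_irf",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform TCSPC time binning within one repetition period.

    Parameters
    ----------
    n_bins : number of time bins.
    bin_width : bin width in ns.
    rep_period : laser repetition period in ns (12.5 ns at 80 MHz).
    """

    n_bins: int
    bin_width: float
    rep_period: float = 12.5

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        if self.n_bins * self.bin_width > self.rep_period * (1 + 1e-9):
            raise ValueError(
                "time window exceeds repetition period: "
                f"{self.n_bins} * {self.bin_width} > {self.rep_period}"
            )

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def compatible(self, other: "TimeGrid") -> bool:
        return (
            self.n_bins == other.n_bins
            and abs(self.bin_width - other.bin_width) < 1e-12
            and abs(self.rep_period - other.rep_period) < 1e-12
        )


@dataclass
class PhotonHistogram:
    """Binned photon arrival counts for one pixel or one pooled cell."""

    counts: np.ndarray
    grid: TimeGrid
    all_zero_warning: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) != self.grid.n_bins:
            raise ValueError(
                f"counts length {len(self.counts)} != n_bins {self.grid.n_bins}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())


@dataclass
class InstrumentResponse:
    """Discrete IRF kernel on the same circular time grid as the histograms.

    The kernel is a probability mass (sums to 1) over circular *shifts*:
    index j carries the IRF mass for temporal shifts near j * bin_width, so
    that discrete circular convolution with a bin-integrated decay stays
    aligned with the continuous convolution (an identity kernel at index 0
    leaves the curve untouched).  The centroid is the first moment on the
    shift axis.
    """

    kernel: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim != 1 or len(self.kernel) != self.grid.n_bins:
            raise ValueError("kernel length must equal n_bins")
        if np.any(self.kernel < 0):
            raise ValueError("kernel weights must be non-negative")
        s = self.kernel.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"kernel must sum to 1 (got {s!r})")

    @property
    def centroid(self) -> float:
        shifts = np.arange(self.grid.n_bins) * self.grid.bin_width
        return float(np.sum(self.kernel * shifts))


@dataclass
class DecayParams:
    """Biexponential decay parameters.

    a1, a2 are the relative contributions in percent (a1 + a2 = 100), tau1 <
    tau2 the short (free) and long (bound) lifetimes in ns.  ``amplitude`` is
    the expected number of decay photons per excitation cycle summed over a
    full period (the per-bin curve is amplitude times the per-bin decay
    probability); ``offset`` is a uniform background in counts per bin.
    """

    a1: float
    tau1: float
    tau2: float
    a2: float | None = None
    amplitude: float = 1.0
    offset: float = 0.0

    TAU1_BOUNDS = (0.1, 1.0)
    TAU2_BOUNDS = (1.0, 10.0)

    def __post_init__(self) -> None:
        if self.a2 is None:
            self.a2 = 100.0 - self.a1
        if not np.isclose(self.a1 + self.a2, 100.0, atol=1e-9):
            raise ValueError(f"a1 + a2 must equal 100, got {self.a1 + self.a2}")
        if not 0 <= self.a1 <= 100:
            raise ValueError(f"a1 must be in [0, 100], got {self.a1}")
        if not 0 < self.tau1 < self.tau2:
            raise ValueError(
                f"need 0 < tau1 < tau2, got tau1={self.tau1}, tau2={self.tau2}"
            )
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


def mean_lifetime(params: DecayParams) -> float:
    """Amplitude-weighted mean lifetime tau_m = (a1*tau1 + a2*tau2)/(a1+a2), ns."""
    denom = params.a1 + params.a2
    if denom == 0:
        raise ValueError("a1 + a2 = 0: mean lifetime undefined")
    return (params.a1 * params.tau1 + params.a2 * params.tau2) / denom


def _bin_integrated_exp(tau: float, grid: TimeGrid, periodic: bool) -> np.ndarray:
    """Per-bin decay probability of a single exponential on the grid.

    Bin k gets exp(-t_k/tau) - exp(-t_{k+1}/tau); in periodic mode this is
    divided by (1 - exp(-T/tau)) so that the mass over a full period is 1
    (incomplete-decay wrap-around from previous pulses).
    """
    edges = grid.edges
    mass = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
    if periodic:
        mass = mass / -np.expm1(-grid.rep_period / tau)
    return mass


def decay_shape(
    params: DecayParams, grid: TimeGrid, periodic: bool = True
) -> np.ndarray:
    """Mixture per-bin decay probability (no IRF, no amplitude, no offset)."""
    f1 = params.a1 / 100.0
    f2 = params.a2 / 100.0
    return f1 * _bin_integrated_exp(params.tau1, grid, periodic) + f2 * (
        _bin_integrated_exp(params.tau2, grid, periodic)
    )


def model_curve(
    params: DecayParams,
    irf: InstrumentResponse,
    grid: TimeGrid,
    periodic: bool = True,
) -> np.ndarray:
    """Expected counts per bin: amplitude * (decay (*) IRF) + offset.

    The convolution is circular on the bin grid, which is exact when the
    acquisition window spans the full repetition period.  Non-negative
    everywhere; linear in amplitude and offset.
    """
    if not grid.compatible(irf.grid):
        raise ValueError("IRF grid does not match the histogram grid")
    shape = decay_shape(params, grid, periodic=periodic)
    conv = _circular_convolve(shape, irf.kernel)
    return params.amplitude * conv + params.offset


def _circular_convolve(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = np.fft.irfft(np.fft.rfft(signal) * np.fft.rfft(kernel), n=len(signal))
    # fft round-off can leave tiny negative values
    return np.clip(out, 0.0, None)


def gaussian_irf(
    grid: TimeGrid, fwhm: float, center: float = 1.0
) -> InstrumentResponse:
    """Bin-integrated Gaussian IRF wrapped onto the circular grid.

    fwhm and center in ns.  A Gaussian is the usual effective-IRF model for a
    femtosecond-pulsed laser with detector-limited timing response.
    """
    from scipy.special import erf

    if fwhm <= 0:
        raise ValueError("irf fwhm must be positive")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    # shift-axis binning: bin j covers shifts [j*w - w/2, j*w + w/2)
    edges = grid.edges - 0.5 * grid.bin_width
    # wrap one period each way: more than enough for ns-scale sigma
    mass = np.zeros(grid.n_bins)
    for k in (-1, 0, 1):
        shifted = edges - center + k * grid.rep_period
        cdf = 0.5 * (1.0 + erf(shifted / (sigma * np.sqrt(2.0))))
        mass += np.diff(cdf)
    mass = np.clip(mass, 0.0, None)
    mass /= mass.sum()
    return InstrumentResponse(kernel=mass, grid=grid)


def delta_irf(grid: TimeGrid, bin_index: int = 0) -> InstrumentResponse:
    """Idealized delta-function IRF concentrated in a single bin."""
    kernel = np.zeros(grid.n_bins)
    kernel[bin_index] = 1.0
    return InstrumentResponse(kernel=kernel, grid=grid)
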