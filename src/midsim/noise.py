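"""Gaussian disturbance channels parameterized by power spectral density.

Disturbance strength is specified as a flat (white) power spectral density
level per channel.  A discrete-time white Gaussian process redrawn every
``T`` hours with per-draw variance ``sigma^2`` has a flat one-sided
spectrum of level ``sigma^2 * 2 * T`` over [0, 1/(2 T)]; a nominal PSD
level ``p`` therefore maps to per-draw variance

    sigma^2 = p / (2 * T_ref),

where ``T_ref`` (``DisturbanceSpec.ref_interval``) is the interval the PSD
level is referenced to.  By default ``T_ref`` is 24 h — the period of the
daily forcing and sampling design — so a nominal level states the
disturbance power in the frequency band a daily time series resolves, and
the channel amplitude does not depend on how finely the simulation redraws
it.  Set ``ref_interval`` equal to the redraw interval to recover the
literal white-noise convention, under which :func:`empirical_psd`
round-trips the nominal level exactly.

Any fixed convention preserves the ordering weak < strong disturbance,
which is what the community-level results depend on.

Draw order is fixed for bit-reproducibility: channels 1..5 in order, each
channel species-major (channel 3 row-major over ordered species pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_model import NoiseSample

__all__ = ["DisturbanceSpec", "NoiseGenerator", "sample_noise", "empirical_psd"]


@dataclass(frozen=True)
class DisturbanceSpec:
    """PSD level per disturbance channel plus the redraw interval.

    ``psd1..psd5`` are nonnegative flat-spectrum levels (nominal units
    W/Hz, treated as pure strength knobs) for the channels perturbing,
    respectively: specific growth rate, intraspecific competition,
    interspecific competition, substrate production, substrate
    consumption.  ``redraw_interval`` is the hold time in hours between
    fresh draws; the default of 24 h matches the period of the daily
    radiation/sampling cycle the disturbance emulates, so each day gets
    one realization of environmental conditions.  ``None`` redraws every
    integration step.
    """

    psd1: float = 0.0
    psd2: float = 0.0
    psd3: float = 0.0
    psd4: float = 0.0
    psd5: float = 0.0
    redraw_interval: float | None = 24.0
    #: interval (hours) the PSD levels are referenced to; per-draw
    #: variance is psd / (2 * ref_interval)
    ref_interval: float = 24.0
    #: clamp policy for disturbed parameters: "stability" (default; floor
    #: the competition/production/consumption channels, leave growth free
    #: to reverse sign), "all", "none", or five per-channel booleans; see
    #: midsim.core_model.CLAMP_POLICIES
    clamp: str | bool | tuple = "stability"

    def __post_init__(self) -> None:
        for name in ("psd1", "psd2", "psd3", "psd4", "psd5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.redraw_interval is not None and self.redraw_interval <= 0:
            raise ValueError("redraw_interval must be positive")
        if self.ref_interval <= 0:
            raise ValueError("ref_interval must be positive")

    @property
    def levels(self) -> tuple[float, float, float, float, float]:
        return (self.psd1, self.psd2, self.psd3, self.psd4, self.psd5)

    def is_silent(self) -> bool:
        return all(p == 0.0 for p in self.levels)


def _sigmas(spec: DisturbanceSpec) -> np.ndarray:
    """Per-draw standard deviation of each channel."""
    return np.sqrt(np.asarray(spec.levels) / (2.0 * spec.ref_interval))


def sample_noise(spec: DisturbanceSpec, dims: tuple[int, int],
                 rng: np.random.Generator) -> NoiseSample:
    """Draw one independent realization of the five channels.

    Parameters
    ----------
    spec : DisturbanceSpec
        PSD level per channel (variance psd / (2 * spec.ref_interval)).
    dims : (M, m)
        Community dimensions; channels 1, 2, 4, 5 get one draw per
        species, channel 3 one draw per ordered species pair (diagonal
        zeroed, since self-competition lives in channel 2).
    rng : numpy Generator
        Source of randomness; the caller owns seeding.
    """
    M, m = dims
    if M < 1 or m < 1:
        raise ValueError("dims must be positive")
    s = _sigmas(spec)

    def draw(sigma: float, shape) -> np.ndarray:
        if sigma == 0.0:
            return np.zeros(shape)
        return rng.normal(0.0, sigma, size=shape)

    eps1 = draw(s[0], M)
    eps2 = draw(s[1], M)
    eps3 = draw(s[2], (M, M))
    np.fill_diagonal(eps3, 0.0)
    eps4 = draw(s[3], M)
    eps5 = draw(s[4], M)
    return NoiseSample(eps1=eps1, eps2=eps2, eps3=eps3, eps4=eps4, eps5=eps5)


class NoiseGenerator:
    """Stateful per-run noise stream with an optional hold time.

    Redraws all channels whenever simulated time crosses a multiple of
    ``spec.redraw_interval`` (default: every call, i.e. every integration
    step).  One underlying RNG stream, fixed draw order.
    """

    def __init__(self, spec: DisturbanceSpec, dims: tuple[int, int],
                 rng: np.random.Generator, dt: float):
        self.spec = spec
        self.dims = dims
        self.rng = rng
        self.dt = dt
        self.hold = spec.redraw_interval if spec.redraw_interval else dt
        if self.hold < dt:
            raise ValueError("redraw_interval must be >= integration step")
        self._current: NoiseSample | None = None
        self._next_redraw = 0.0

    def at(self, t: float) -> NoiseSample:
        """Noise realization in effect at simulated time t (nondecreasing)."""
        if self._current is None or t >= self._next_redraw - 1e-12:
            self._current = sample_noise(self.spec, self.dims, self.rng)
            self._next_redraw = (np.floor(t / self.hold) + 1) * self.hold
        return self._current


def empirical_psd(series, dt: float, n_segments: int = 8):
    """Averaged-periodogram (Bartlett) estimate of the one-sided PSD.

    For a white channel generated at nominal level ``p`` and redraw
    interval ``dt``, the mean of the estimate over nonzero frequencies is
    an unbiased estimate of ``p``.

    Returns
    -------
    freqs : ndarray
        One-sided frequency grid in 1/h (DC bin dropped).
    psd : ndarray
        Spectral density estimate at each frequency.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 8:
        raise ValueError("series must be 1-D with at least 8 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    nperseg = max(series.size // n_segments, 4)
    freqs, psd = signal.welch(
        series, fs=1.0 / dt, window="boxcar", nperseg=nperseg,
        noverlap=0, detrend="constant", scaling="density",
    )
    return freqs[1:], psd[1:]
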