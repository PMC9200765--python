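"""Spike-train quantification for looming-sensitive neurons.

The pipeline mirrors standard practice for intracellular recordings of
lobula giant neurons: each spike train is smoothed with a Gaussian kernel
(FWHM 200 ms) into an instantaneous firing-rate profile whose integral is
normalized to conserve the recorded spike count; the mean and SD of the
rate during an unstimulated (spontaneous) segment define a response
threshold of mean + 2 SD; the response onset is the earliest sustained
threshold crossing, and peak / average rate are measured from onset to
the end of stimulation.

Times are seconds relative to the predicted collision (negative before
collision); "time to collision" of an event at time t is -t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circstats import InvalidInputError

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SpikeTrain:
    """Spike times for one neuron/trial, with the recording windows.

    ``trial_span`` is the stimulated interval and ``spont_span`` the
    unstimulated interval used for the baseline, both (start, end) in
    seconds relative to predicted collision.  Spike times are sorted and
    must fall inside one of the two spans.
    """

    spike_times: np.ndarray
    trial_span: tuple[float, float] = (-11.11, 0.0)
    spont_span: tuple[float, float] | None = None
    neuron_id: str = "n0"
    crab_id: str = "c0"
    trial_id: str = "t0"
    treatment: str = "Single"

    def __post_init__(self) -> None:
        self.spike_times = np.sort(np.asarray(self.spike_times, dtype=float))
        lo, hi = self.full_span
        if self.spike_times.size and (
            self.spike_times[0] < lo - 1e-9 or self.spike_times[-1] > hi + 1e-9
        ):
            raise InvalidInputError(
                f"trial {self.trial_id}: spike outside declared spans"
            )

    @property
    def full_span(self) -> tuple[float, float]:
        spans = [self.trial_span] + (
            [self.spont_span] if self.spont_span else []
        )
        return (min(s[0] for s in spans), max(s[1] for s in spans))

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class RateProfile:
    """Instantaneous firing rate on a uniform time grid (Hz)."""

    time_grid: np.ndarray
    rate: np.ndarray
    kernel_fwhm: float
    n_spikes: int = 0
    train: SpikeTrain | None = field(default=None, repr=False)

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])

    def integral(self, window: tuple[float, float] | None = None) -> float:
        """Trapezoidal integral of the rate, optionally over ``window``."""
        if window is None:
            return float(np.trapezoid(self.rate, self.time_grid))
        mask = (self.time_grid >= window[0]) & (self.time_grid <= window[1])
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.rate[mask], self.time_grid[mask]))

    def restrict(self, window: tuple[float, float]) -> "RateProfile":
        mask = (self.time_grid >= window[0]) & (self.time_grid <= window[1])
        return RateProfile(
            time_grid=self.time_grid[mask],
            rate=self.rate[mask],
            kernel_fwhm=self.kernel_fwhm,
            n_spikes=self.n_spikes,
        )


@dataclass(frozen=True)
class ResponseMetrics:
    """Summary of one looming response.

    ``onset_time_to_collision`` is positive when the response starts
    before the predicted collision.
    """

    responded: bool
    onset_time_to_collision: float | None = None
    peak_rate: float | None = None
    mean_rate_during_response: float | None = None


def estimate_rate(
    train: SpikeTrain, fwhm: float = 0.2, dt: float = 0.001
) -> RateProfile:
    """Gaussian-kernel instantaneous firing rate with count conservation.

    Each spike contributes a Gaussian of sigma = fwhm / (2*sqrt(2 ln 2));
    kernels are truncated at the edges of the recording span, and the
    summed profile is rescaled globally so its trapezoidal integral over
    the whole span equals the number of spikes.  An empty train yields an
    all-zero profile.

    ``dt`` must be <= fwhm / 10 so the grid resolves the kernel.
    """
    if fwhm <= 0:
        raise InvalidInputError("kernel FWHM must be > 0")
    if dt <= 0 or dt > fwhm / 10.0 + 1e-12:
        raise InvalidInputError("dt must satisfy 0 < dt <= fwhm / 10")
    sigma = fwhm * FWHM_TO_SIGMA
    lo, hi = train.full_span
    grid = np.arange(lo, hi + dt / 2.0, dt)
    rate = np.zeros_like(grid)
    if train.n_spikes:
        half = int(np.ceil(6.0 * sigma / dt))  # +-6 sigma kernel support
        offsets = np.arange(-half, half + 1)
        centre_idx = np.clip(
            np.rint((train.spike_times - lo) / dt).astype(int),
            0,
            grid.size - 1,
        )
        idx = centre_idx[:, None] + offsets[None, :]
        valid = (idx >= 0) & (idx < grid.size)
        idx_c = np.clip(idx, 0, grid.size - 1)
        z = (grid[idx_c] - train.spike_times[:, None]) / sigma
        vals = np.exp(-0.5 * z**2) / (sigma * np.sqrt(2.0 * np.pi))
        np.add.at(rate, idx_c[valid], vals[valid])
        integral = np.trapezoid(rate, grid)
        if integral > 0:
            rate *= train.n_spikes / integral
    return RateProfile(
        time_grid=grid,
        rate=rate,
        kernel_fwhm=fwhm,
        n_spikes=train.n_spikes,
        train=train,
    )


def spontaneous_stats(
    profile: RateProfile, spont_span: tuple[float, float]
) -> tuple[float, float]:
    """Mean and SD of the rate profile over the spontaneous segment.

    The segment edges are trimmed by 3 kernel sigmas to avoid truncation
    and stimulus bleed-through.  Requires a segment of at least 10 kernel
    FWHMs.  An empty (zero-rate) segment yields (0, 0).
    """
    lo, hi = spont_span
    if hi - lo < 10.0 * profile.kernel_fwhm:
        raise InvalidInputError(
            "spontaneous span must be at least 10 kernel FWHMs long"
        )
    trim = 3.0 * profile.kernel_fwhm * FWHM_TO_SIGMA
    sub = profile.restrict((lo + trim, hi - trim))
    if sub.rate.size == 0:
        return 0.0, 0.0
    return float(sub.rate.mean()), float(sub.rate.std())


def detect_onset(
    profile: RateProfile,
    spont_mean: float,
    spont_sd: float,
    min_duration: float | None = None,
    window: tuple[float, float] | None = None,
) -> float | None:
    """Earliest sustained crossing of the response threshold.

    The threshold is ``spont_mean + 2 * spont_sd``; the rate must stay
    above it for at least ``min_duration`` (default one kernel FWHM) for
    the crossing to count, which suppresses single-sample flickers.
    Returns the onset time (s, same axis as the profile) or None.
    """
    if min_duration is None:
        min_duration = profile.kernel_fwhm
    sub = profile.restrict(window) if window is not None else profile
    if sub.rate.size == 0:
        return None
    threshold = spont_mean + 2.0 * spont_sd
    above = sub.rate > threshold
    need = max(int(np.round(min_duration / profile.dt)), 1)
    if not above.any():
        return None
    if need == 1:
        return float(sub.time_grid[int(np.argmax(above))])
    # first index where `need` consecutive samples are all above threshold
    runs = np.convolve(above.astype(float), np.ones(need), mode="valid")
    hits = np.nonzero(runs >= need - 0.5)[0]
    return float(sub.time_grid[int(hits[0])]) if hits.size else None


def response_metrics(
    profile: RateProfile,
    onset: float | None,
    end_of_stimulation: float = 0.0,
) -> ResponseMetrics:
    """Peak and average rate from onset to the end of stimulation."""
    if onset is None:
        return ResponseMetrics(responded=False)
    window = (onset, end_of_stimulation)
    sub = profile.restrict(window)
    if sub.rate.size == 0:
        return ResponseMetrics(responded=False)
    peak = float(sub.rate.max())
    if sub.rate.size > 1:
        mean = float(
            np.trapezoid(sub.rate, sub.time_grid)
            / (sub.time_grid[-1] - sub.time_grid[0])
        )
    else:
        mean = peak
    return ResponseMetrics(
        responded=True,
        onset_time_to_collision=-float(onset),
        peak_rate=peak,
        mean_rate_during_response=mean,
    )


def analyze_train(
    train: SpikeTrain,
    fwhm: float = 0.2,
    dt: float = 0.001,
    min_duration: float | None = None,
    end_of_stimulation: float = 0.0,
) -> ResponseMetrics:
    """Full per-train pipeline: rate, baseline, onset, response metrics."""
    profile = estimate_rate(train, fwhm=fwhm, dt=dt)
    if train.spont_span is not None:
        mean, sd = spontaneous_stats(profile, train.spont_span)
    else:
        mean, sd = 0.0, 0.0
    onset = detect_onset(
        profile,
        mean,
        sd,
        min_duration=min_duration,
        window=(train.trial_span[0], end_of_stimulation),
    )
    return response_metrics(profile, onset, end_of_stimulation)
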