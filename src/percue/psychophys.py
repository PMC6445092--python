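"""Stimulus synthesis and adaptive threshold estimation.

Stimuli are annular sinusoidal gratings (+/-45 deg, 0.87 cycles/degree,
inner/outer diameters 9.94/20.93 deg of visual angle) embedded in smoothed
annular noise:

    I = 0.5 * (1 + w_s * G + w_n * N)

with G and N each rescaled to [-0.5, 0.5] inside the annulus and the
background at mid-grey 0.5.  The noise weight w_n is fixed at 0.25; the
signal weight follows from the signal percentage s via

    w_s = w_n * s / (100 - s).

The signal level producing ~80% correct is found with a two-phase
2-down-1-up staircase whose down/up step ratio is 0.5548: the signal drops
after two consecutive correct responses and rises after every error, which
converges near the 80%-correct point of the psychometric function
(equilibrium where p^2 * step_down = (1 - p^2) * step_up).  Phase 1 uses
coarse steps (up 1%, down 0.5548%) to bracket the threshold; phase 2
restarts at the phase-1 estimate with halved steps (up 0.5%, down 0.2774%).
The threshold is the mean signal at the last four reversals of phase 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "StimulusSpec",
    "StaircaseState",
    "Staircase",
    "signal_weight",
    "compose_stimulus",
    "staircase_step",
    "run_staircase",
    "STEP_RATIO",
]

#: Down/up step-size ratio of the weighted 2-down-1-up rule.
STEP_RATIO = 0.5548


def signal_weight(s: float, w_n: float = 0.25) -> float:
    """Signal weight w_s = w_n * s / (100 - s) for signal percentage s."""
    if not (0.0 <= s < 100.0):
        raise ValueError(f"signal percentage must be in [0, 100), got {s}")
    if w_n < 0:
        raise ValueError("noise weight must be >= 0")
    return w_n * s / (100.0 - s)


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and weights of one grating-in-noise stimulus."""

    signal_percent: float
    orientation_deg: float = 45.0
    spatial_frequency_cpd: float = 0.87
    inner_diameter_deg: float = 9.94
    outer_diameter_deg: float = 20.93
    noise_weight: float = 0.25
    image_size_px: int = 256
    # None: resolved so the outer annulus fills ~95% of the image.
    pixels_per_degree: float | None = None
    grating_phase_rad: float = 0.0
    noise_smoothing_deg: float = 0.25  # Gaussian sigma of the noise filter

    def __post_init__(self) -> None:
        if not (0 < self.inner_diameter_deg < self.outer_diameter_deg):
            raise ValueError("need 0 < inner diameter < outer diameter")
        if self.image_size_px < 8:
            raise ValueError("image_size_px too small")
        if self.pixels_per_degree is not None and self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be > 0")

    @property
    def signal_weight(self) -> float:
        return signal_weight(self.signal_percent, self.noise_weight)

    @property
    def resolved_pixels_per_degree(self) -> float:
        if self.pixels_per_degree is not None:
            return self.pixels_per_degree
        return 0.95 * self.image_size_px / self.outer_diameter_deg


def _rescale_centered(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Affinely rescale the masked region to [-0.5, 0.5]; zero elsewhere."""
    out = np.zeros_like(img)
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        out[mask] = (vals - lo) / (hi - lo) - 0.5
    return out


def compose_stimulus(
    spec: StimulusSpec, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Render one stimulus image with pixel values in [0, 1].

    The grating and (seeded) smoothed-noise layers are each rescaled to
    [-0.5, 0.5] within the annulus and combined as
    ``0.5 * (1 + w_s*G + w_n*N)``; pixels outside the annulus sit at the
    0.5 background.  Deterministic given the RNG seed.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = spec.image_size_px
    ppd = spec.resolved_pixels_per_degree
    # Symmetric coordinate grid in degrees, centred on the image.
    coords = (np.arange(n) - (n - 1) / 2.0) / ppd
    x, y = np.meshgrid(coords, coords)
    r = np.hypot(x, y)
    mask = (r >= spec.inner_diameter_deg / 2.0) & (r <= spec.outer_diameter_deg / 2.0)
    if not mask.any():
        raise ValueError("annulus does not intersect the image; check geometry")

    theta = np.deg2rad(spec.orientation_deg)
    carrier = np.sin(
        2.0 * np.pi * spec.spatial_frequency_cpd * (x * np.cos(theta) + y * np.sin(theta))
        + spec.grating_phase_rad
    )
    grating = _rescale_centered(carrier, mask)

    w_s = spec.signal_weight
    w_n = spec.noise_weight
    noise = np.zeros_like(grating)
    if w_n > 0:
        raw = rng.standard_normal((n, n))
        smoothed = gaussian_filter(raw, sigma=spec.noise_smoothing_deg * ppd)
        noise = _rescale_centered(smoothed, mask)

    image = 0.5 * (1.0 + w_s * grating + w_n * noise)
    image[~mask] = 0.5
    return image


@dataclass(frozen=True)
class StaircaseState:
    """State of one phase of the weighted 2-down-1-up staircase."""

    phase: int  # 1 or 2
    current_signal: float  # percent
    step_up: float
    step_down: float
    consecutive_correct: int = 0
    reversal_signals: tuple[float, ...] = ()
    trial_count: int = 0
    last_direction: int = 0  # +1 up, -1 down, 0 none yet
    signal_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.phase not in (1, 2):
            raise ValueError("phase must be 1 or 2")
        if self.step_up <= 0 or self.step_down <= 0:
            raise ValueError("step sizes must be > 0")
        if self.current_signal <= 0:
            raise ValueError("signal must stay > 0")


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one trial.

    After two consecutive correct responses the signal decreases by
    ``step_down`` (counter resets); after any error it increases by
    ``step_up``.  A reversal is recorded — at the pre-step signal level —
    whenever the direction of change flips.  The signal is clipped at
    ``signal_floor`` to stay positive.
    """
    signal = state.current_signal
    consecutive = state.consecutive_correct
    direction = 0
    if correct:
        consecutive += 1
        if consecutive >= 2:
            direction = -1
            consecutive = 0
    else:
        direction = +1
        consecutive = 0

    reversals = state.reversal_signals
    last_direction = state.last_direction
    if direction != 0:
        if last_direction != 0 and direction != last_direction:
            reversals = reversals + (signal,)
        last_direction = direction
        signal = signal + (state.step_up if direction > 0 else -state.step_down)
        signal = max(signal, state.signal_floor)
    return replace(
        state,
        current_signal=signal,
        consecutive_correct=consecutive,
        reversal_signals=reversals,
        trial_count=state.trial_count + 1,
        last_direction=last_direction,
    )


def _phase_threshold(reversals: tuple[float, ...], last: int = 4) -> float:
    if len(reversals) == 0:
        raise ValueError("no reversals recorded; cannot estimate a threshold")
    tail = reversals[-last:]
    return float(np.mean(tail))


@dataclass
class Staircase:
    """Two-phase weighted 2-down-1-up staircase controller.

    Phase 1 runs until ``phase1_reversals`` reversals (default 8) or
    ``max_trials_per_phase`` trials; phase 2 restarts at the phase-1
    threshold with half-size steps and runs until ``phase2_reversals``
    (default 6, the refined protocol; 10 in the original run) or the trial
    cap.  ``threshold`` is the mean signal at the last four reversals of
    phase 2.
    """

    start_signal: float = 10.0
    phase1_reversals: int = 8
    phase2_reversals: int = 6
    max_trials_per_phase: int = 80
    signal_floor: float = 0.1
    state: StaircaseState = field(init=False)

    def __post_init__(self) -> None:
        self.state = StaircaseState(
            phase=1,
            current_signal=self.start_signal,
            step_up=1.0,
            step_down=STEP_RATIO,
            signal_floor=self.signal_floor,
        )
        self._phase2_reversal_log: tuple[float, ...] = ()
        self._done = False

    @property
    def done(self) -> bool:
        return self._done

    @property
    def current_signal(self) -> float:
        return self.state.current_signal

    def step(self, correct: bool) -> None:
        if self._done:
            raise RuntimeError("staircase already finished")
        self.state = staircase_step(self.state, correct)
        if self.state.phase == 1:
            if (
                len(self.state.reversal_signals) >= self.phase1_reversals
                or self.state.trial_count >= self.max_trials_per_phase
            ):
                phase1_threshold = _phase_threshold(self.state.reversal_signals)
                self.state = StaircaseState(
                    phase=2,
                    current_signal=max(phase1_threshold, self.signal_floor),
                    step_up=0.5,
                    step_down=0.5 * STEP_RATIO,
                    signal_floor=self.signal_floor,
                )
        else:
            if (
                len(self.state.reversal_signals) >= self.phase2_reversals
                or self.state.trial_count >= self.max_trials_per_phase
            ):
                self._phase2_reversal_log = self.state.reversal_signals
                self._done = True

    @property
    def threshold(self) -> float:
        """Mean signal at the last four reversals of phase 2."""
        if not self._done:
            raise RuntimeError("staircase has not finished")
        return _phase_threshold(self._phase2_reversal_log)


def run_staircase(
    psychometric: Callable[[float], float],
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> tuple[float, list[dict]]:
    """Run a staircase against a simulated observer.

    ``psychometric(signal)`` returns the probability of a correct response
    at that signal level.  Returns the converged threshold and a per-trial
    trace (trial, phase, signal, correct, reversal count).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    stair = Staircase(**kwargs)
    trace: list[dict] = []
    trial = 0
    while not stair.done:
        trial += 1
        signal = stair.current_signal
        correct = bool(rng.random() < psychometric(signal))
        phase = stair.state.phase
        stair.step(correct)
        trace.append(
            {
                "trial": trial,
                "phase": phase,
                "signal": signal,
                "correct": int(correct),
                "n_reversals": len(stair.state.reversal_signals)
                if not stair.done
                else len(stair._phase2_reversal_log),
            }
        )
    return stair.threshold, trace
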