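"""Oscillation phenotyping: period, amplitude and rhythmicity of a trajectory.

Period is the time difference between the last two peaks of the marker
species — nuclear *BMAL1* mRNA by default, switching to nuclear *PER2* mRNA
under *BMAL1* knockout, where *BMAL1* transcription is silenced.  Amplitude is
the difference between the last peak and the last trough.  Peaks are discrete
local maxima refined by three-point quadratic interpolation, which keeps
period comparisons meaningful well below the grid resolution.  A trajectory
counts as arrhythmic when fewer than two peaks survive the transient or the
final peak-to-trough excursion falls below 1% of the marker's overall range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrators import Trajectory

__all__ = [
    "DEFAULT_MARKER",
    "BMAL1_KO_MARKER",
    "OscillationFeatures",
    "extract_features",
    "normalized_period",
    "marker_consistency",
]

DEFAULT_MARKER = "MnB"       # nuclear BMAL1 mRNA
BMAL1_KO_MARKER = "MnPt"     # nuclear PER2 mRNA, used when BMAL1 is knocked out

#: relative rhythmicity threshold: last-cycle amplitude vs overall range
RHYTHM_THRESHOLD = 0.01


@dataclass(frozen=True)
class OscillationFeatures:
    rhythmic: bool
    period: float | None          # hours
    amplitude: float              # a.u., last peak minus last trough
    marker_species: str
    peak_times: tuple[float, ...]
    mean_level: float = 0.0

    def __post_init__(self) -> None:
        if self.rhythmic and (self.period is None or self.period <= 0):
            raise ValueError("rhythmic features require a positive period")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if any(b <= a for a, b in zip(self.peak_times, self.peak_times[1:])):
            raise ValueError("peak times must be strictly increasing")


def _refine(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Quadratic (three-point) interpolation of an extremum at grid index i."""
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dt = t[i + 1] - t[i]
    t_ref = float(t[i] + delta * dt)
    y_ref = float(y1 - 0.25 * (y0 - y2) * delta)
    return t_ref, y_ref


def _local_extrema(y: np.ndarray, maxima: bool) -> np.ndarray:
    s = y if maxima else -y
    return np.where((s[1:-1] > s[:-2]) & (s[1:-1] > s[2:]))[0] + 1


def extract_features(traj: Trajectory, marker: str = DEFAULT_MARKER
                     ) -> OscillationFeatures:
    """Extract period/amplitude/rhythmicity for *marker* after the transient."""
    if marker not in traj.species_order:
        raise KeyError(f"marker species {marker!r} absent from trajectory")
    post = traj.after_transient()
    t, y = post.times, post.series(marker)
    if len(t) < 5:
        raise ValueError("trajectory too short after transient discard")

    peaks = _local_extrema(y, maxima=True)
    troughs = _local_extrema(y, maxima=False)
    overall_range = float(y.max() - y.min())
    mean_level = float(y.mean())

    if len(peaks) < 2 or len(troughs) < 1:
        return OscillationFeatures(False, None, 0.0, marker, (), mean_level)

    refined_peaks = [_refine(t, y, i) for i in peaks]
    peak_times = tuple(p[0] for p in refined_peaks)
    p_last_t, p_last_v = refined_peaks[-1]
    p_prev_t, _ = refined_peaks[-2]
    tr_last_t, tr_last_v = _refine(t, y, troughs[-1])

    amplitude = max(p_last_v - tr_last_v, 0.0)
    period = p_last_t - p_prev_t
    scale = max(overall_range, 1e-300)
    if amplitude < RHYTHM_THRESHOLD * scale or amplitude <= 0:
        return OscillationFeatures(False, None, amplitude, marker, peak_times,
                                   mean_level)
    return OscillationFeatures(True, float(period), float(amplitude), marker,
                               peak_times, mean_level)


def normalized_period(features_mutant: OscillationFeatures,
                      features_wt: OscillationFeatures) -> float:
    """Mutant period divided by wild-type period (same parameter set)."""
    for which, f in (("mutant", features_mutant), ("wild-type", features_wt)):
        if not f.rhythmic:
            raise ValueError(
                f"{which} trajectory is arrhythmic; compare the rhythmic flag "
                f"rather than a period ratio")
    return features_mutant.period / features_wt.period


def marker_consistency(traj: Trajectory,
                       markers: tuple[str, ...] = ("MnB", "MnPo", "MnPt", "MnCo")
                       ) -> dict:
    """Percent period differences among clock-gene mRNA markers.

    Differences are reported relative to the *BMAL1*-derived period (the first
    marker).  All markers must be rhythmic.
    """
    feats = {m: extract_features(traj, m) for m in markers}
    for m, f in feats.items():
        if not f.rhythmic:
            raise ValueError(f"marker {m} is arrhythmic; no period to compare")
    ref = feats[markers[0]].period
    diffs = {m: abs(feats[m].period - ref) / ref * 100.0 for m in markers[1:]}
    return {
        "reference": markers[0],
        "reference_period": ref,
        "percent_diff": diffs,
        "max_percent_diff": max(diffs.values()),
        "periods": {m: feats[m].period for m in markers},
    }
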