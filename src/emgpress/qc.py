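"""Electrode-placement quality control from the power spectrum.

A cleanly placed electrode yields a unimodal, "belly-shaped" EMG power
spectrum with its bulk in the tens-of-Hz range. Line interference, motion
artifact, and placement over the innervation zone each deform the spectrum
in a characteristic way. This module quantifies the visual check: the
spectrum of short segments at the start, middle and end of each trial is
screened with four numeric criteria (median frequency band, low-frequency
power fraction, mains line ratio, pronounced edge mode), every threshold
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .datatypes import EventTable, Recording

__all__ = [
    "QCThresholds",
    "SpectrumQCReport",
    "power_spectrum",
    "belly_shape_check",
    "qc_trial",
]


@dataclass(frozen=True)
class QCThresholds:
    """Numeric surrogates for the visual belly-shape check.

    median_band
        Acceptable range for the spectral median frequency (Hz).
    low_freq_cutoff_hz / low_freq_max
        Fraction of total power below the cutoff must stay under the max.
    line_freq_hz / line_halfwidth_hz / line_ratio_max
        Mains interference: power density in line_freq +- halfwidth divided
        by the mean density in flanking bands of the same width must stay
        under the max. 50 Hz default; set 60 for 60-Hz grids.
    expected_band / edge_margin_hz / edge_peak_factor
        A spectral mode within edge_margin of either edge of the expected
        physiological band, standing edge_peak_factor above the in-band
        median density, flags placement over the innervation zone. The
        peak-factor guard keeps the flat top of a healthy spectrum, whose
        noisy argmax can land anywhere, from tripping the flag.
    """

    median_band: tuple[float, float] = (40.0, 150.0)
    low_freq_cutoff_hz: float = 20.0
    low_freq_max: float = 0.10
    line_freq_hz: float = 50.0
    line_halfwidth_hz: float = 2.0
    line_ratio_max: float = 5.0
    expected_band: tuple[float, float] = (20.0, 150.0)
    edge_margin_hz: float = 5.0
    edge_peak_factor: float = 3.0
    segment_s: float = 1.0
    block_s: float = 0.25


@dataclass(frozen=True)
class SpectrumQCReport:
    """Outcome of the belly-shape check on one trial segment."""

    trial: str
    segment: str  # "start" | "middle" | "end"
    median_frequency: float
    low_freq_power_fraction: float
    line_ratio: float
    edge_mode_flag: bool
    passed: bool
    reasons: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "trial": self.trial,
            "segment": self.segment,
            "median_frequency": round(self.median_frequency, 3),
            "low_freq_power_fraction": round(self.low_freq_power_fraction, 6),
            "line_ratio": round(self.line_ratio, 3) if np.isfinite(self.line_ratio) else None,
            "edge_mode_flag": self.edge_mode_flag,
            "pass": self.passed,
            "reasons": list(self.reasons),
        }


def power_spectrum(
    rec: Recording, block_s: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided averaged-periodogram PSD (Welch, Hann-tapered
    half-overlapping blocks of ``block_s`` seconds).

    Returns ``(freqs, psd)`` in Hz and µV²/Hz. The integral of the PSD
    estimates the segment variance (power conservation, asymptotically).
    """
    if rec.duration < 0.5 - 1e-9:
        raise ValueError(f"segment of {rec.duration:.3f} s is under the 0.5-s minimum")
    nperseg = int(round(block_s * rec.fs))
    nperseg = min(nperseg, rec.samples.size)
    freqs, psd = sps.welch(
        rec.samples,
        fs=rec.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        scaling="density",
    )
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask])) if mask.sum() > 1 else float(psd[mask][0])


def median_frequency(freqs: np.ndarray, psd: np.ndarray) -> float:
    """Frequency splitting the spectral power in half."""
    cum = np.cumsum(psd)
    total = cum[-1]
    if total <= 0:
        return float("nan")
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(freqs[min(idx, freqs.size - 1)])


def belly_shape_check(
    freqs: np.ndarray,
    psd: np.ndarray,
    thresholds: QCThresholds = QCThresholds(),
    trial: str = "",
    segment: str = "",
) -> SpectrumQCReport:
    """Classify one segment's spectrum as belly-shaped or artifact-bearing."""
    th = thresholds
    total = float(np.trapezoid(psd, freqs))
    if total <= 0:
        return SpectrumQCReport(
            trial=trial, segment=segment, median_frequency=float("nan"),
            low_freq_power_fraction=0.0, line_ratio=float("nan"),
            edge_mode_flag=False, passed=False, reasons=("no signal",),
        )

    med = median_frequency(freqs, psd)
    low_frac = _band_power(freqs, psd, 0.0, th.low_freq_cutoff_hz) / total

    line_lo = th.line_freq_hz - th.line_halfwidth_hz
    line_hi = th.line_freq_hz + th.line_halfwidth_hz
    in_line = (freqs >= line_lo) & (freqs <= line_hi)
    flank = (
        ((freqs >= line_lo - 4 * th.line_halfwidth_hz) & (freqs < line_lo))
        | ((freqs > line_hi) & (freqs <= line_hi + 4 * th.line_halfwidth_hz))
    )
    if in_line.any() and flank.any() and psd[flank].mean() > 0:
        line_ratio = float(psd[in_line].mean() / psd[flank].mean())
    else:
        line_ratio = 1.0

    lo_edge, hi_edge = th.expected_band
    in_band = (freqs >= lo_edge) & (freqs <= hi_edge)
    mode_freq = float(freqs[np.argmax(psd)])
    band_median = float(np.median(psd[in_band])) if in_band.any() else 0.0
    near_edge = (
        abs(mode_freq - lo_edge) <= th.edge_margin_hz
        or abs(mode_freq - hi_edge) <= th.edge_margin_hz
    )
    pronounced = band_median > 0 and float(psd.max()) > th.edge_peak_factor * band_median
    edge_mode = bool(near_edge and pronounced)

    reasons = []
    if not (th.median_band[0] <= med <= th.median_band[1]):
        reasons.append("median_frequency")
    if low_frac >= th.low_freq_max:
        reasons.append("low_freq_power_fraction")
    if line_ratio >= th.line_ratio_max:
        reasons.append("line_ratio")
    if edge_mode:
        reasons.append("edge_mode")

    return SpectrumQCReport(
        trial=trial,
        segment=segment,
        median_frequency=med,
        low_freq_power_fraction=low_frac,
        line_ratio=line_ratio,
        edge_mode_flag=edge_mode,
        passed=not reasons,
        reasons=tuple(reasons),
    )


def qc_trial(
    rec: Recording,
    events: Optional[EventTable] = None,
    thresholds: QCThresholds = QCThresholds(),
) -> list[SpectrumQCReport]:
    """Belly-shape check at the start, middle and end of a trial.

    The trial passes only if all three segments pass; a failure anywhere
    means the electrode would have been repositioned.
    """
    th = thresholds
    seg_n = int(round(th.segment_s * rec.fs))
    n = rec.samples.size
    if n < 3 * seg_n:
        raise ValueError(
            f"trial of {n} samples is shorter than three {th.segment_s}-s QC segments"
        )
    starts = {
        "start": 0,
        "middle": (n - seg_n) // 2,
        "end": n - seg_n,
    }
    reports = []
    for name, s0 in starts.items():
        seg = rec.with_samples(rec.samples[s0 : s0 + seg_n])
        freqs, psd = power_spectrum(seg, block_s=th.block_s)
        reports.append(
            belly_shape_check(freqs, psd, th, trial=rec.label(), segment=name)
        )
    return reports
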