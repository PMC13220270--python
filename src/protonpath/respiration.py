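"""Oxygen-consumption rates, FeCN normalisation and sfGFP quantification.

Respiration of membranes expressing a transporter construct is measured
as the O₂ decline after NADH addition (Clark electrode).  Raw slopes are
normalised by the total protein concentration and by the NADH
dehydrogenase activity (rate of FeCN absorbance decay at 410 nm), then
expressed as a percentage of a designated reference construct.  O₂
consumption rates are reported positive for consumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AssayTrace

__all__ = [
    "NormalizedRate",
    "linear_rate",
    "fecn_activity",
    "normalize",
    "gfp_level",
]


@dataclass
class NormalizedRate:
    """A construct's respiration rate normalised to a reference (= 100%)."""

    raw_rate: float  # signal units s⁻¹
    protein_conc: float  # mg mL⁻¹
    fecn_rate: float  # A410 units s⁻¹
    normalized: float = 100.0  # % of reference
    sd: float = 0.0

    @property
    def specific_rate(self) -> float:
        return self.raw_rate / self.protein_conc / self.fecn_rate


def _window_slope(t, y):
    return np.polyfit(t, y, 1)[0]


def linear_rate(
    trace: AssayTrace,
    channel: str | None = None,
    window: tuple[float, float] | None = None,
    local_window: int = 10,
    tolerance: float = 0.10,
) -> float:
    """Slope of the linear phase of a trace (signal units per second).

    With an explicit ``window`` (t_start, t_end) the slope is a plain LS
    fit over it.  In auto mode a running local slope (over
    ``local_window`` consecutive points) is computed; the fit uses the
    longest run of points whose local slope stays within ``tolerance``
    (relative) of the median local slope, which isolates the linear phase
    from baseline and plateau.
    """
    if channel is None:
        if len(trace.channels) != 1:
            raise ValueError("specify the channel for a multi-channel trace")
        channel = next(iter(trace.channels))
    t = trace.time
    y = trace[channel]
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < 5:
            raise ValueError("fewer than 5 points in the requested window")
        return float(_window_slope(t[mask], y[mask]))

    n = len(t)
    if n < max(local_window, 5):
        raise ValueError("trace too short for automatic range selection")
    local = np.array(
        [
            _window_slope(t[i : i + local_window], y[i : i + local_window])
            for i in range(n - local_window + 1)
        ]
    )
    med = np.median(local)
    scale = max(abs(med), 1e-30)
    ok = np.abs(local - med) <= tolerance * scale
    # longest contiguous run of acceptable local slopes
    best_len, best_start, run_start = 0, 0, None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len == 0:
        raise ValueError(
            "no linear range found; pass an explicit window=(t0, t1)"
        )
    lo = best_start
    hi = best_start + best_len - 1 + local_window  # last covered point
    if hi - lo < 5:
        raise ValueError(
            "linear range shorter than 5 points; pass an explicit window"
        )
    return float(_window_slope(t[lo:hi], y[lo:hi]))


def fecn_activity(trace: AssayTrace, **kwargs) -> float:
    """Rate of FeCN absorbance decay at 410 nm (same contract as linear_rate)."""
    channel = kwargs.pop("channel", "A410")
    return linear_rate(trace, channel=channel, **kwargs)


def normalize(
    raw: float,
    protein: float,
    fecn: float,
    reference: NormalizedRate,
    raw_sd: float = 0.0,
    protein_sd: float = 0.0,
    fecn_sd: float = 0.0,
    reference_sd_percent: float = 0.0,
) -> NormalizedRate:
    """Percentage of the reference construct's specific respiration rate.

    normalized = 100·(raw/protein/fecn) / (raw_ref/protein_ref/fecn_ref).
    The SD is propagated to first order: relative variances of the
    factors (and of the reference percentage) add.
    """
    if protein <= 0:
        raise ValueError("protein concentration must be positive")
    if fecn == 0 or reference.fecn_rate == 0 or reference.protein_conc == 0:
        raise ValueError("zero divisor in normalisation")
    ref_specific = reference.specific_rate
    if ref_specific == 0:
        raise ValueError("reference specific rate is zero")
    value = 100.0 * (raw / protein / fecn) / ref_specific
    rel2 = 0.0
    for v, s in ((raw, raw_sd), (protein, protein_sd), (fecn, fecn_sd)):
        if s:
            rel2 += (s / v) ** 2
    if reference_sd_percent:
        rel2 += (reference_sd_percent / 100.0) ** 2
    sd = abs(value) * np.sqrt(rel2)
    return NormalizedRate(
        raw_rate=raw, protein_conc=protein, fecn_rate=fecn,
        normalized=float(value), sd=float(sd),
    )


def gfp_level(
    spectrum: AssayTrace,
    protein: float,
    peak_nm: float = 510.0,
    mode: str = "nearest",
    search_halfwidth: float = 5.0,
) -> float:
    """sfGFP expression: emission at the 510 nm peak per mg protein.

    ``spectrum`` uses the time axis to carry wavelength (nm) and a single
    emission channel.  ``mode='nearest'`` reads the sample closest to
    ``peak_nm``; ``mode='quadratic'`` locates the local maximum within
    ``search_halfwidth`` nm of it and refines the peak height with a
    three-point quadratic interpolation.
    """
    if protein <= 0:
        raise ValueError("protein concentration must be positive")
    wl = spectrum.time
    if len(spectrum.channels) != 1:
        raise ValueError("spectrum must have exactly one emission channel")
    em = next(iter(spectrum.channels.values()))
    if peak_nm < wl[0] or peak_nm > wl[-1]:
        raise ValueError(f"{peak_nm} nm outside the recorded spectrum")
    if mode == "nearest":
        value = em[np.argmin(np.abs(wl - peak_nm))]
    elif mode == "quadratic":
        near = np.flatnonzero(np.abs(wl - peak_nm) <= search_halfwidth)
        i = near[np.argmax(em[near])]
        if 0 < i < len(wl) - 1:
            x = wl[i - 1 : i + 2]
            y = em[i - 1 : i + 2]
            coef = np.polyfit(x, y, 2)
            if coef[0] < 0:
                x_peak = -coef[1] / (2 * coef[0])
                value = np.polyval(coef, x_peak)
            else:
                value = y[1]
        else:
            value = em[i]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(value) / protein
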