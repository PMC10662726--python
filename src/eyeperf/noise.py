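"""Pressure-noise records for ex vivo and in vivo perfusion regimes.

Three regimes are modelled.  Ex vivo noise follows the published recipe for
enucleated eyes: Gaussian white noise sampled at 10 Hz passed through a
first-order lowpass at 0.4 Hz, rescaled so the record SD is 0.04 mmHg.  The
in vivo regimes are surrogate generators calibrated only to the printed
summary statistics — anesthetized records are more variable (SD 0.23 mmHg)
with sporadic transient fluctuations; conscious records add large erratic
positive IOP bumps that skew the distribution — plus the qualitative event
structure visible in recorded rat IOP.  Real recorded IOP time series can be
loaded from CSV instead and used anywhere a synthetic record is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal
from scipy import stats

__all__ = [
    "NoiseRecord", "NoiseSummary", "synth_exvivo", "synth_surrogate",
    "load_records", "save_record", "resample", "characterize",
    "ANESTHETIZED_DEFAULTS", "CONSCIOUS_DEFAULTS",
]


@dataclass
class NoiseRecord:
    """A zero-mean pressure-fluctuation time series.

    ``label`` identifies the regime (exvivo / anesthetized / conscious /
    custom), ``sample_rate`` is in Hz and ``samples`` in mmHg.
    """

    label: str
    sample_rate: float
    samples: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def duration_min(self) -> float:
        return len(self.samples) / self.sample_rate / 60.0

    @property
    def sd(self) -> float:
        return float(np.std(self.samples))


@dataclass
class NoiseSummary:
    """Distribution and spectrum statistics of a record."""

    sd: float                    # mmHg
    skewness: float
    hist_edges: np.ndarray       # mmHg
    hist_counts: np.ndarray
    psd_freq: np.ndarray         # Hz
    psd: np.ndarray              # mmHg^2/Hz


def _lowpass_onepole(x: np.ndarray, cutoff_hz: float, rate_hz: float) -> np.ndarray:
    """Single-pole IIR lowpass, coefficients by bilinear transform."""
    wc = np.tan(np.pi * cutoff_hz / rate_hz)
    b = np.array([wc, wc]) / (1.0 + wc)
    a = np.array([1.0, (wc - 1.0) / (1.0 + wc)])
    return signal.lfilter(b, a, x)


def synth_exvivo(duration_min: float = 60.0, seed: Optional[int] = None,
                 sample_rate: float = 10.0, sd: float = 0.04,
                 cutoff_hz: float = 0.4, rescale: bool = True) -> NoiseRecord:
    """Synthesize an enucleated-eye pressure-noise record.

    White Gaussian noise (SD ``sd``) at ``sample_rate`` through a first-order
    lowpass at ``cutoff_hz``.  Filtering reduces the SD, so by default the
    output is rescaled back to ``sd`` — the statistic published records are
    validated against; pass ``rescale=False`` to keep the raw filter output.
    """
    if duration_min <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_min * 60.0 * sample_rate))
    warmup = int(10 * sample_rate / cutoff_hz)
    white = rng.standard_normal(n + warmup) * sd
    y = _lowpass_onepole(white, cutoff_hz, sample_rate)[warmup:]
    y = y - y.mean()
    if rescale and y.std() > 0:
        y *= sd / y.std()
    return NoiseRecord("exvivo", sample_rate, y, seed=seed)


#: Surrogate event statistics.  Only the overall SD (anesthetized) and the
#: positive skew (conscious) are published; rates/amplitudes/decays below were
#: chosen once to mimic the qualitative appearance of recorded rat IOP and are
#: not claims about rat physiology.
ANESTHETIZED_DEFAULTS = dict(
    base_sd=0.21,          # mmHg, lowpass-filtered Gaussian floor
    base_cutoff_hz=0.4,
    event_rate=0.08,       # sporadic transients per minute (Poisson)
    event_amp=1.2,         # mmHg, mean |amplitude| (lognormal)
    event_amp_sigma=0.5,
    event_decay_s=25.0,    # exponential decay of each transient
    target_sd=0.23,        # mmHg, overall record SD
)
CONSCIOUS_DEFAULTS = dict(
    base_sd=0.25,
    base_cutoff_hz=0.1,
    event_rate=0.25,       # erratic bumps per minute (Poisson)
    event_amp=1.3,         # mmHg, mean bump height (all positive)
    event_amp_sigma=0.7,
    event_decay_s=15.0,
    target_sd=None,        # not printed; left unscaled
)


def synth_surrogate(regime: str, duration_min: float = 60.0,
                    seed: Optional[int] = None, params: Optional[dict] = None,
                    sample_rate: float = 10.0) -> NoiseRecord:
    """Surrogate in vivo pressure noise (anesthetized or conscious regime).

    Both regimes are a lowpass-filtered Gaussian base plus Poisson-arrival
    transient events.  Anesthetized events are sporadic, signed, and the
    whole record is rescaled to the published SD of 0.23 mmHg.  Conscious
    events are larger, more frequent and strictly positive (erratic IOP
    bumps), yielding a positively skewed distribution; the record is
    mean-subtracted but not rescaled.  Set ``event_rate`` to 0 in ``params``
    to recover the pure Gaussian base.
    """
    if regime == "anesthetized":
        p = dict(ANESTHETIZED_DEFAULTS)
        signed = True
    elif regime == "conscious":
        p = dict(CONSCIOUS_DEFAULTS)
        signed = False
    else:
        raise ValueError(f"unknown regime {regime!r}")
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    n = int(round(duration_min * 60.0 * sample_rate))
    warmup = int(10 * sample_rate / p["base_cutoff_hz"])
    base = _lowpass_onepole(rng.standard_normal(n + warmup),
                            p["base_cutoff_hz"], sample_rate)[warmup:]
    if base.std() > 0:
        base *= p["base_sd"] / base.std()

    n_events = rng.poisson(p["event_rate"] * duration_min)
    events = np.zeros(n)
    if n_events > 0 and p["event_amp"] > 0:
        onsets = rng.integers(0, n, n_events)
        # lognormal magnitudes with the requested mean
        sigma = p.get("event_amp_sigma", 0.7)
        mu = np.log(p["event_amp"]) - 0.5 * sigma**2
        amps = rng.lognormal(mu, sigma, n_events)
        if signed:
            amps *= rng.choice([-1.0, 1.0], n_events)
        decay = p["event_decay_s"]
        rise_s = 2.0
        klen = min(n, int((rise_s + 6 * decay) * sample_rate))
        t = np.arange(klen) / sample_rate
        kernel = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay)
        kernel /= kernel.max()
        for onset, amp in zip(onsets, amps):
            stop = min(n, onset + klen)
            events[onset:stop] += amp * kernel[:stop - onset]
    y = base + events
    y = y - y.mean()
    if p.get("target_sd") and y.std() > 0:
        y *= p["target_sd"] / y.std()
    return NoiseRecord(regime, sample_rate, y, seed=seed)


def make_records(regime: str, n: int = 12, duration_min: float = 60.0,
                 seed: Optional[int] = None) -> list[NoiseRecord]:
    """A reproducible cohort of synthetic records with derived child seeds."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, n)
    out = []
    for s in child_seeds:
        if regime == "exvivo":
            out.append(synth_exvivo(duration_min, seed=int(s)))
        else:
            out.append(synth_surrogate(regime, duration_min, seed=int(s)))
    return out


def save_record(record: NoiseRecord, path) -> None:
    """Write a record as CSV with columns ``time_s, pressure_mmHg``."""
    t = np.arange(len(record.samples)) / record.sample_rate
    pd.DataFrame({"time_s": t, "pressure_mmHg": record.samples}).to_csv(
        path, index=False)


def load_records(paths, sample_rate: Optional[float] = None,
                 label: str = "custom") -> list[NoiseRecord]:
    """Load pressure records from CSV files.

    Accepts either a single ``pressure_mmHg`` column (``sample_rate``
    required) or ``time_s, pressure_mmHg`` pairs with uniform spacing.  The
    mean pressure is subtracted from each record, as fluctuation records are
    defined about the prevailing IOP.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    records = []
    for path in paths:
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise ValueError(f"{path}: could not parse as CSV ({exc})") from exc
        cols = list(df.columns)
        if "pressure_mmHg" in cols:
            pressure = df["pressure_mmHg"]
        elif len(cols) == 1:
            pressure = df[cols[0]]
        elif len(cols) >= 2:
            pressure = df[cols[1]]
        else:
            raise ValueError(f"{path}: no pressure column found")
        pressure = pd.to_numeric(pressure, errors="coerce").to_numpy()
        if np.isnan(pressure).any():
            raise ValueError(f"{path}: non-numeric pressure values")
        if "time_s" in cols or len(cols) >= 2:
            tcol = "time_s" if "time_s" in cols else cols[0]
            t = pd.to_numeric(df[tcol], errors="coerce").to_numpy()
            if np.isnan(t).any():
                raise ValueError(f"{path}: non-numeric time values")
            dt = np.diff(t)
            if len(dt) == 0:
                raise ValueError(f"{path}: record too short")
            if np.max(np.abs(dt - dt.mean())) > 1e-6 * max(dt.mean(), 1e-12) + 1e-9:
                raise ValueError(
                    f"{path}: irregular timestamps; resample to a uniform "
                    "grid before loading")
            rate = 1.0 / dt.mean()
        else:
            if sample_rate is None:
                raise ValueError(
                    f"{path}: single-column file needs an explicit sample_rate")
            rate = sample_rate
        records.append(NoiseRecord(label, rate, pressure - pressure.mean()))
    return records


def resample(record: NoiseRecord, target_rate: float = 10.0,
             method: str = "stepwise") -> NoiseRecord:
    """Bring a record to the model update rate.

    Downsampling by an integer factor averages consecutive blocks (a 20 Hz
    record becomes pair means at 10 Hz); upsampling by an integer factor
    repeats samples (zero-order hold, the natural reading of a 1 Hz record).
    ``method="linear"`` interpolates instead.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    if len(record.samples) == 0:
        raise ValueError("cannot resample an empty record")
    ratio = record.sample_rate / target_rate
    x = record.samples
    if abs(ratio - 1.0) < 1e-9:
        y = x.copy()
    elif method == "linear":
        n_out = int(round(len(x) / ratio))
        t_in = np.arange(len(x)) / record.sample_rate
        t_out = np.arange(n_out) / target_rate
        y = np.interp(t_out, t_in, x)
    elif ratio >= 1.0 and abs(ratio - round(ratio)) < 1e-9:
        f = int(round(ratio))
        m = (len(x) // f) * f
        y = x[:m].reshape(-1, f).mean(axis=1)
    elif ratio < 1.0 and abs(1.0 / ratio - round(1.0 / ratio)) < 1e-9:
        f = int(round(1.0 / ratio))
        y = np.repeat(x, f)
    else:
        n_out = int(round(len(x) / ratio))
        t_in = np.arange(len(x)) / record.sample_rate
        t_out = np.arange(n_out) / target_rate
        y = np.interp(t_out, t_in, x)
    return NoiseRecord(record.label, target_rate, y, seed=record.seed)


def characterize(record: NoiseRecord, nperseg: int = 2**12,
                 bins: int = 50) -> NoiseSummary:
    """SD, skewness, histogram and Welch power spectrum of a record.

    The spectrum averages Hann-windowed periodograms of ``nperseg`` samples
    with 50% overlap; the record must cover at least two segments.
    """
    x = record.samples
    if len(x) < 2 * nperseg:
        raise ValueError(
            f"record too short for spectral averaging: need >= {2 * nperseg} "
            f"samples, got {len(x)}")
    freq, psd = signal.welch(x, fs=record.sample_rate, window="hann",
                             nperseg=nperseg, noverlap=nperseg // 2)
    counts, edges = np.histogram(x, bins=bins)
    return NoiseSummary(sd=float(np.std(x)),
                        skewness=float(stats.skew(x)),
                        hist_edges=edges, hist_counts=counts,
                        psd_freq=freq, psd=psd)
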