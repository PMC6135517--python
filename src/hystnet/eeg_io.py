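"""Multichannel EEG I/O, referencing, zero-phase band filtering and windowing.

All signal-level conventions live here: the in-memory recording container,
the delimited on-disk dialect (TSV matrix + JSON sidecar), average
referencing, the windowed-sinc FIR band-pass, and the epoch/window plan used
by the connectivity pipeline (2-minute state epochs cut into 10-second
moving windows).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "BandSpec",
    "WindowPlan",
    "read_eeg",
    "write_eeg",
    "rereference_average",
    "bandpass_fir",
    "fir_kernel_length",
    "segment",
]

#: canonical state order for the four-state anesthetic transition
STATE_ORDER = ("baseline", "induction", "unconscious", "emergence")


@dataclass
class EEGRecording:
    """A referenced multichannel EEG signal with state-epoch annotations.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in samples per second.
    labels : list of str
        Unique channel names, one per row of ``data``.
    epochs : dict
        Maps a state name (e.g. ``"baseline"``) to a half-open sample range
        ``(start, stop)`` within ``data``.
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    epochs: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        for state, (a, b) in self.epochs.items():
            if not (0 <= a < b <= self.data.shape[1]):
                raise ValueError(f"epoch {state!r} bounds outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def epoch_data(self, state: str) -> np.ndarray:
        """Return the (channels x samples) slice of one annotated state."""
        a, b = self.epochs[state]
        return self.data[:, a:b]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band ``[lo, hi]`` in Hz with an optional display label."""

    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError("band edges must satisfy 0 <= lo < hi")

    def validate_rate(self, rate: float) -> None:
        if self.hi >= rate / 2:
            raise ValueError(
                f"band {self.lo}-{self.hi} Hz exceeds the Nyquist frequency {rate / 2} Hz"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label or f"{self.lo:g}-{self.hi:g} Hz"


@dataclass(frozen=True)
class WindowPlan:
    """Epoch length and moving-window layout, all in seconds.

    Defaults follow the study design: a 120 s epoch per state split into
    10 s non-overlapping windows (12 windows per state).
    """

    epoch_len: float = 120.0
    win_len: float = 10.0
    overlap: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.win_len <= self.epoch_len):
            raise ValueError("need 0 < win_len <= epoch_len")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be a fraction in [0, 1)")

    @property
    def step(self) -> float:
        return self.win_len * (1.0 - self.overlap)

    def n_windows(self) -> int:
        return int(np.floor((self.epoch_len - self.win_len) / self.step)) + 1


# ---------------------------------------------------------------------------
# delimited dialect: UTF-8 TSV (header = labels, one row per sample) + JSON
# sidecar carrying the rate and the epoch table.


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_eeg(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording in the delimited dialect (TSV + JSON sidecar)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(rec.labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.10g", delimiter="\t")
    meta = {
        "rate": rec.rate,
        "epochs": {k: [int(a), int(b)] for k, (a, b) in rec.epochs.items()},
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def _read_delimited(path: Path) -> EEGRecording:
    with open(path, encoding="utf-8") as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        rows = []
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            vals = line.rstrip("\n").split("\t")
            if len(vals) != len(labels):
                raise ValueError(
                    f"inconsistent channel lengths at line {ln}: "
                    f"expected {len(labels)} columns, found {len(vals)}"
                )
            rows.append([float(v) for v in vals])
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing rate: no sidecar metadata at {sidecar}")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    if "rate" not in meta:
        raise ValueError("missing rate in sidecar metadata")
    epochs = {k: (int(a), int(b)) for k, (a, b) in meta.get("epochs", {}).items()}
    return EEGRecording(np.asarray(rows).T, float(meta["rate"]), labels, epochs)


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def read_eeg(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read an EEG recording from EDF or the delimited TSV dialect.

    ``format`` is ``"edf"`` or ``"delimited"``; when omitted it is inferred
    from the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# referencing and filtering


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the instantaneous channel average.

    After the operation every sample's mean across channels is zero.
    Idempotent.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def fir_kernel_length(rate: float, lo: float) -> int:
    """Length (odd) of the windowed-sinc kernel used for a band with low edge ``lo``.

    At least three cycles of the lowest passband frequency, never below 101
    taps, rounded up to odd so the kernel has exact linear phase.
    """
    n = max(int(round(3.0 * rate / lo)), 101)
    return n if n % 2 == 1 else n + 1


def bandpass_fir(
    rec: EEGRecording,
    band: BandSpec,
    *,
    two_pass: bool = False,
    min_lo: float = 0.1,
) -> EEGRecording:
    """Zero-phase band-pass with a Hamming-windowed sinc FIR kernel.

    The default realization convolves once with the symmetric (linear-phase)
    kernel and removes the group delay, which preserves signal phases — the
    property the PLI pipeline depends on.  ``two_pass=True`` selects
    forward-backward filtering instead (squared magnitude response).

    A low edge below ``min_lo`` (or below what the epoch length can resolve)
    is clamped with a warning to keep the kernel length finite.
    """
    band.validate_rate(rec.rate)
    lo = band.lo
    floor = max(min_lo, 2.0 / rec.duration)
    if lo < floor:
        warnings.warn(
            f"band low edge {lo:g} Hz clamped to {floor:g} Hz "
            "(unresolvable at this epoch length)",
            stacklevel=2,
        )
        lo = floor
        if lo >= band.hi:
            raise ValueError("band collapsed: clamped low edge reaches the high edge")
    numtaps = fir_kernel_length(rec.rate, lo)
    if rec.n_samples <= numtaps:
        raise ValueError(
            f"signal ({rec.n_samples} samples) shorter than the "
            f"{numtaps}-tap filter kernel"
        )
    kernel = sps.firwin(numtaps, [lo, band.hi], pass_zero=False, window="hamming", fs=rec.rate)
    if two_pass:
        out = sps.filtfilt(kernel, [1.0], rec.data, axis=1)
    else:
        # 'same' convolution with an odd symmetric kernel centers the output,
        # i.e. applies the filter and compensates the (numtaps-1)/2 group delay.
        out = sps.fftconvolve(rec.data, kernel[np.newaxis, :], mode="same", axes=1)
    return replace(rec, data=out)


def segment(rec: EEGRecording, state: str, plan: WindowPlan = WindowPlan()) -> list[np.ndarray]:
    """Cut one state's epoch into moving windows.

    Returns ``floor((epoch_len - win_len)/step) + 1`` channel x sample views
    in temporal order.  The epoch must be at least ``plan.epoch_len`` long;
    only its first ``epoch_len`` seconds are used.
    """
    if state not in rec.epochs:
        raise KeyError(f"state {state!r} not annotated in this recording")
    a, b = rec.epochs[state]
    need = int(round(plan.epoch_len * rec.rate))
    if b - a < need:
        raise ValueError(
            f"epoch {state!r} is {(b - a) / rec.rate:g} s, shorter than the "
            f"planned {plan.epoch_len:g} s"
        )
    win = int(round(plan.win_len * rec.rate))
    step = int(round(plan.step * rec.rate))
    n_win = (need - win) // step + 1
    return [rec.data[:, a + i * step : a + i * step + win] for i in range(n_win)]
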