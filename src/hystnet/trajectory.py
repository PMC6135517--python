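"""State-space trajectories of functional brain networks and their hysteresis.

A brain state is summarised by two network coordinates computed per
10-second window and reduced to a per-state median:

* **topographic similarity** — Pearson correlation between a window's
  node-degree vector and the baseline mean degree vector (how far the
  network's structure has moved from baseline), and
* **average node degree** — the mean binary link count (connection
  strength).

The four state medians (baseline -> induction -> unconscious -> emergence)
trace a closed quadrilateral in this plane; its shoelace area is the
hysteresis size.  A parallel pipeline uses per-channel band power instead
of node degree, which serves as the control analysis: path dependence
appears in connectivity, not power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .connectivity import (
    DEFAULT_N_SURROGATES,
    DEFAULT_THRESHOLD,
    FunctionalNetwork,
    window_networks,
)
from .eeg_io import (
    STATE_ORDER,
    BandSpec,
    EEGRecording,
    WindowPlan,
    bandpass_fir,
    fir_kernel_length,
    segment,
)

__all__ = [
    "StatePoint",
    "Trajectory",
    "PowerTopography",
    "topographic_similarity",
    "average_node_degree",
    "state_point",
    "hysteresis_area",
    "polygon_self_intersects",
    "state_trajectory",
    "band_sweep",
    "default_band_bins",
    "band_area_stats",
    "power_topography",
    "power_trajectory",
    "peak_frequency_spread",
    "rank_correlation",
    "permutation_null_areas",
]


@dataclass(frozen=True)
class StatePoint:
    """One state's coordinates in (topographic similarity, strength) space."""

    state: str
    topo_sim: float
    avg_degree: float


@dataclass
class Trajectory:
    """Four state points in canonical order, with their enclosed area."""

    points: list[StatePoint]
    area: float
    window_values: dict[str, pd.DataFrame] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": [p.state for p in self.points],
                "topo_sim": [p.topo_sim for p in self.points],
                "avg_degree": [p.avg_degree for p in self.points],
            }
        )


@dataclass(frozen=True)
class PowerTopography:
    """Per-channel median band power density (microvolt^2/Hz)."""

    band_power: np.ndarray
    band: BandSpec


# ---------------------------------------------------------------------------
# elementary statistics


def topographic_similarity(baseline_mean_degrees: np.ndarray, epoch_degrees: np.ndarray) -> float:
    """Pearson correlation between a baseline-mean and an epoch degree vector."""
    b = np.asarray(baseline_mean_degrees, dtype=np.float64)
    a = np.asarray(epoch_degrees, dtype=np.float64)
    if b.shape != a.shape or b.size < 3:
        raise ValueError("degree vectors must have equal length >= 3")
    if b.std() == 0 or a.std() == 0:
        raise ValueError("degenerate degree topography: zero-variance vector")
    return float(np.corrcoef(b, a)[0, 1])


def average_node_degree(adjacency: np.ndarray) -> float:
    """Mean binary link count over nodes."""
    adj = np.asarray(adjacency)
    return float(adj.sum(axis=1).mean())


def state_point(
    networks: list[FunctionalNetwork],
    baseline_mean_degrees: np.ndarray,
    state: str,
) -> StatePoint:
    """Median-over-windows state coordinates for one state's networks.

    Windows whose degree vector has zero variance (empty or complete
    graphs) have no defined topography correlation; they are dropped from
    the similarity median but still count toward the degree median.  If
    every window is degenerate — typical for an analysis band containing
    no oscillatory structure at all — the state carries no topographic
    information and the similarity falls back to 0 with a warning.
    """
    if not networks:
        raise ValueError("state_point needs at least one window network")
    sims = []
    for n in networks:
        if np.std(n.degrees) == 0 or np.std(baseline_mean_degrees) == 0:
            continue
        sims.append(topographic_similarity(baseline_mean_degrees, n.degrees))
    if not sims:
        warnings.warn(
            f"degenerate degree topography in every window of state {state!r}; "
            "topographic similarity set to 0",
            stacklevel=2,
        )
        sims = [0.0]
    degs = [n.average_degree for n in networks]
    return StatePoint(state, float(np.median(sims)), float(np.median(degs)))


def hysteresis_area(points) -> float:
    """Absolute shoelace area of the closed four-state quadrilateral.

    ``points`` is either four :class:`StatePoint` in canonical order or an
    (n, 2) coordinate array; the polygon is closed from the last point back
    to the first.
    """
    xy = _as_coords(points)
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates")
    x, y = xy[:, 0], xy[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _as_coords(points) -> np.ndarray:
    if len(points) and isinstance(points[0], StatePoint):
        return np.array([[p.topo_sim, p.avg_degree] for p in points], dtype=np.float64)
    return np.asarray(points, dtype=np.float64)


def polygon_self_intersects(points) -> bool:
    """True if the closed quadrilateral crosses itself (bow-tie shape).

    A self-intersecting path makes the shoelace sum under-report the visual
    area; callers can surface this diagnostic alongside the area.
    """
    xy = _as_coords(points)
    n = len(xy)

    def _seg_cross(p, q, r, s):
        d1, d2 = q - p, s - r
        denom = d1[0] * d2[1] - d1[1] * d2[0]
        if denom == 0:
            return False
        t = ((r - p)[0] * d2[1] - (r - p)[1] * d2[0]) / denom
        u = ((r - p)[0] * d1[1] - (r - p)[1] * d1[0]) / denom
        return 0 < t < 1 and 0 < u < 1

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent via the closing edge
            if _seg_cross(xy[i], xy[(i + 1) % n], xy[j], xy[(j + 1) % n]):
                return True
    return False


# ---------------------------------------------------------------------------
# the full connectivity pipeline


def _degree_table(nets: list[FunctionalNetwork]) -> np.ndarray:
    return np.array([n.degrees for n in nets], dtype=np.float64)


def state_trajectory(
    rec: EEGRecording,
    band: BandSpec,
    plan: WindowPlan = WindowPlan(),
    *,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    prefiltered: bool = False,
) -> Trajectory:
    """Connectivity-space trajectory of the four anesthetic states.

    Pipeline per state: band-pass filter, 10-s moving windows, Hilbert
    phases (filter-transient samples discarded at window edges), PLI,
    surrogate-median correction, binary thresholding, then the median
    topographic similarity and average degree across windows.  The baseline
    reference is the mean degree vector over all baseline windows.
    """
    for st in STATE_ORDER:
        if st not in rec.epochs:
            raise KeyError(f"missing state epoch {st!r}")
    filtered = rec if prefiltered else bandpass_fir(rec, band)
    win_samples = int(round(plan.win_len * rec.rate))
    edge = min(fir_kernel_length(rec.rate, max(band.lo, 0.1)) // 2, win_samples // 8)

    nets: dict[str, list[FunctionalNetwork]] = {}
    for s_idx, st in enumerate(STATE_ORDER):
        nets[st] = window_networks(
            filtered,
            st,
            plan,
            n_surrogates=n_surrogates,
            threshold=threshold,
            edge_discard=edge,
            seed=seed + 104729 * s_idx,
        )
    baseline_mean = _degree_table(nets["baseline"]).mean(axis=0)
    points = [state_point(nets[st], baseline_mean, st) for st in STATE_ORDER]
    traj = Trajectory(points, hysteresis_area(points))
    traj.window_values = {
        st: pd.DataFrame(_degree_table(nets[st])) for st in STATE_ORDER
    }
    return traj


def default_band_bins(lo: float = 0.1, hi: float = 31.0) -> list[BandSpec]:
    """2-Hz analysis bins with odd-integer edges: 0.1-1, 1-3, ..., 29-31 Hz.

    The first bin is ragged (0.9 Hz wide) so that 9-11 Hz falls on a single
    bin; it is labelled accordingly.
    """
    bins = [BandSpec(lo, 1.0, label=f"{lo:g}-1 Hz (ragged)")]
    e = 1.0
    while e < hi - 1e-9:
        bins.append(BandSpec(e, min(e + 2.0, hi)))
        e += 2.0
    return bins


def band_sweep(
    rec: EEGRecording,
    bins: list[BandSpec] | None = None,
    plan: WindowPlan = WindowPlan(),
    *,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> pd.DataFrame:
    """Hysteresis area per frequency bin.

    Returns a frame with columns ``(lo, hi, label, area)`` and the
    per-bin :class:`Trajectory` objects under the ``trajectory`` column.
    """
    if bins is None:
        bins = default_band_bins()
    rows = []
    for b_idx, band in enumerate(bins):
        traj = state_trajectory(
            rec, band, plan,
            n_surrogates=n_surrogates, threshold=threshold, seed=seed + 31 * b_idx,
        )
        rows.append({"lo": band.lo, "hi": band.hi, "label": str(band),
                     "area": traj.area, "trajectory": traj})
    return pd.DataFrame(rows)


def permutation_null_areas(
    window_degrees: dict[str, np.ndarray],
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the hysteresis area under window-label exchange.

    Pools every state's per-window degree vectors, reassigns windows to
    states at random (original group sizes kept), and recomputes the full
    statistic — including the baseline mean reference — per permutation.
    """
    states = list(STATE_ORDER)
    tables = [np.asarray(window_degrees[s], dtype=np.float64) for s in states]
    sizes = [t.shape[0] for t in tables]
    pool = np.vstack(tables)
    rng = np.random.default_rng(seed)
    areas = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(pool.shape[0])
        offs = np.cumsum([0] + sizes)
        groups = [pool[perm[offs[i]:offs[i + 1]]] for i in range(len(states))]
        bmean = groups[0].mean(axis=0)
        pts = []
        for st, g in zip(states, groups):
            sims = [
                topographic_similarity(bmean, row)
                for row in g
                if np.std(row) > 0 and np.std(bmean) > 0
            ]
            if not sims:
                sims = [0.0]
            pts.append(StatePoint(st, float(np.median(sims)), float(np.median(g.mean(axis=1)))))
        areas[p] = hysteresis_area(pts)
    return areas


def band_area_stats(per_subject_areas: pd.DataFrame, alpha: float = 0.05):
    """One-way ANOVA across frequency bins with Tukey-Kramer pairwise tests.

    ``per_subject_areas`` is subjects x bins.  Returns ``(F, p, pairwise)``
    where ``pairwise`` is a frame of adjusted p-values at family level
    ``alpha``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    cols = list(per_subject_areas.columns)
    if len(cols) < 2 or per_subject_areas.shape[0] < 2:
        raise ValueError("need at least 2 bins and 2 subjects")
    groups = [per_subject_areas[c].to_numpy(dtype=np.float64) for c in cols]
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("degenerate table: all values constant")
    F, p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.repeat([str(c) for c in cols], [len(g) for g in groups])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return float(F), float(p), pairwise


# ---------------------------------------------------------------------------
# spectral power control analysis


def power_topography(
    window: np.ndarray,
    rate: float,
    band: BandSpec,
    *,
    seg_len: float = 3.0,
    overlap: float = 0.5,
) -> PowerTopography:
    """Per-channel median band power density of one window.

    Short-time Fourier power with ``seg_len``-second Hamming segments at
    ``overlap`` fractional overlap; per channel the band-mean power density
    is taken per segment and the median over segments reported.
    """
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    nper = int(round(seg_len * rate))
    if window.shape[1] < 2 * nper:
        raise ValueError(f"window shorter than {2 * seg_len:g} s")
    freqs, _, sxx = sps.spectrogram(
        window, fs=rate, window="hamming", nperseg=nper,
        noverlap=int(round(nper * overlap)), axis=1,
    )
    sel = (freqs >= band.lo) & (freqs <= band.hi)
    if not sel.any():
        raise ValueError("band contains no spectrogram frequency bins")
    band_density = sxx[:, sel, :].mean(axis=1)  # channels x segments
    return PowerTopography(np.median(band_density, axis=1), band)


def power_trajectory(
    rec: EEGRecording,
    band: BandSpec,
    plan: WindowPlan = WindowPlan(),
) -> Trajectory:
    """Trajectory in (power topographic similarity, average power) space.

    Same reduction as the connectivity trajectory, with per-channel band
    power replacing node degree — the control analysis in which path
    dependence is expected to vanish.
    """
    for st in STATE_ORDER:
        if st not in rec.epochs:
            raise KeyError(f"missing state epoch {st!r}")
    tables: dict[str, np.ndarray] = {}
    for st in STATE_ORDER:
        tables[st] = np.array(
            [power_topography(w, rec.rate, band).band_power for w in segment(rec, st, plan)]
        )
    bmean = tables["baseline"].mean(axis=0)
    points = []
    for st in STATE_ORDER:
        sims = [topographic_similarity(bmean, row) for row in tables[st]]
        powers = tables[st].mean(axis=1)
        points.append(StatePoint(st, float(np.median(sims)), float(np.median(powers))))
    traj = Trajectory(points, hysteresis_area(points))
    traj.window_values = {st: pd.DataFrame(tables[st]) for st in STATE_ORDER}
    return traj


def peak_frequency_spread(
    rec: EEGRecording,
    state: str,
    band: BandSpec,
    *,
    seg_len: float = 3.0,
    overlap: float = 0.5,
) -> tuple[float, float]:
    """Variance (Hz^2) and SD (Hz) of per-channel spectral peak frequencies.

    Per channel, the median power density across short-time segments of the
    state epoch is computed and its maximising frequency within ``band``
    taken as the channel peak.  Flat spectra break ties toward the lowest
    frequency with a warning.
    """
    data = rec.epoch_data(state)
    nper = int(round(seg_len * rec.rate))
    freqs, _, sxx = sps.spectrogram(
        data, fs=rec.rate, window="hamming", nperseg=nper,
        noverlap=int(round(nper * overlap)), axis=1,
    )
    sel = (freqs >= band.lo) & (freqs <= band.hi)
    med = np.median(sxx[:, sel, :], axis=2)  # channels x band freqs
    fband = freqs[sel]
    flat = np.ptp(med, axis=1) == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} channel(s) have flat spectra; "
            "peak tie broken to the lowest frequency",
            stacklevel=2,
        )
    peaks = fband[np.argmax(med, axis=1)]
    return float(np.var(peaks)), float(np.std(peaks))


def rank_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation and its p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need paired samples of equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
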