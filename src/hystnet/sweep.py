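"""Quasi-static coupling sweeps: explosive synchronization and its hysteresis.

The coupling strength S is stepped up from 0 to 50 and back down, carrying
the oscillator state from one step to the next within a leg (quasi-static
continuation) so that each measurement reflects the attractor reached from
the previous step.  With adaptive feedback (Z > 0) the two legs separate:
synchronization is gained at a critical coupling ``s_inc`` on the way up
and lost at a smaller ``s_dec`` on the way down, enclosing a bistable band.
Hysteresis size is reported both as ``s_inc - s_dec`` and as the area
between the two R(S) curves (the headline number).

``scan_feedback`` and ``scan_domega`` repeat sweeps over fresh frequency
configurations to map hysteresis size against the feedback power Z and the
frequency spread (delta-omega); ``model_trajectory`` projects one sweep's
node signals through the PLI pipeline into the same
(topographic similarity, strength) plane used for the EEG analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .brain_model import (
    Connectome,
    ModelParams,
    draw_natural_frequencies,
    initial_state,
    simulate,
)
from .connectivity import build_network, instantaneous_phase, pli_matrix, surrogate_pli_stack
from .trajectory import topographic_similarity

__all__ = [
    "SweepResult",
    "ModelTrajectory",
    "default_s_grid",
    "run_sweep",
    "critical_coupling",
    "curve_area",
    "scan_feedback",
    "scan_domega",
    "model_trajectory",
]


def default_s_grid(n: int = 60, s_max: float = 50.0, s_min_pos: float = 0.25) -> np.ndarray:
    """Coupling grid over [0, s_max], logarithmically dense at the low end.

    The transition sits at small S relative to the full range, so a uniform
    grid would waste most steps deep in the synchronized regime.
    """
    if n < 2:
        raise ValueError("need at least 2 grid points")
    return np.concatenate([[0.0], s_max * np.geomspace(s_min_pos / s_max, 1.0, n - 1)])


@dataclass
class SweepResult:
    """Up/down R(S) curves of one quasi-static sweep with derived measures."""

    s_grid: np.ndarray
    r_up: np.ndarray
    r_down: np.ndarray
    threshold: float = 0.5
    signals_up: list[np.ndarray] | None = None
    signals_down: list[np.ndarray] | None = None
    signal_rate: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.s_grid) <= 0):
            raise ValueError("s_grid must be strictly increasing")

    @property
    def s_inc(self) -> float | None:
        """Critical coupling on the increasing leg (first upward R crossing)."""
        return critical_coupling(self.s_grid, self.r_up, self.threshold, direction="up")

    @property
    def s_dec(self) -> float | None:
        """Critical coupling on the decreasing leg (first downward R crossing)."""
        return critical_coupling(self.s_grid, self.r_down, self.threshold, direction="down")

    @property
    def hysteresis_ds(self) -> float | None:
        if self.s_inc is None or self.s_dec is None:
            return None
        return self.s_inc - self.s_dec

    @property
    def hysteresis_area(self) -> float:
        return curve_area(self.s_grid, self.r_up, self.r_down)

    @property
    def max_leg_gap(self) -> float:
        """Largest |r_up - r_down| over the grid (bistable-band depth)."""
        return float(np.max(np.abs(self.r_up - self.r_down)))


def curve_area(s_grid: np.ndarray, r_up: np.ndarray, r_down: np.ndarray) -> float:
    """Area between the two legs, integral of |r_up - r_down| over S."""
    return float(np.trapezoid(np.abs(np.asarray(r_up) - np.asarray(r_down)), s_grid))


def critical_coupling(
    s_grid: np.ndarray,
    r_curve: np.ndarray,
    threshold: float = 0.5,
    direction: str = "up",
) -> float | None:
    """Linearly interpolated first threshold crossing along a leg.

    ``direction='up'`` walks the grid from low to high S and returns the S
    of the first upward crossing of ``threshold``; ``'down'`` walks from
    high to low S and returns the first downward crossing.  ``None`` when
    the leg never crosses ("no transition").
    """
    s = np.asarray(s_grid, dtype=np.float64)
    r = np.asarray(r_curve, dtype=np.float64)
    if s.shape != r.shape:
        raise ValueError("r_curve must be defined on s_grid")
    idx = range(1, len(s)) if direction == "up" else range(len(s) - 2, -1, -1)
    for i in idx:
        if direction == "up":
            a, b = r[i - 1], r[i]
            sa, sb = s[i - 1], s[i]
            crossed = a < threshold <= b
        else:
            a, b = r[i + 1], r[i]
            sa, sb = s[i + 1], s[i]
            crossed = a >= threshold > b
        if crossed:
            return float(sa + (threshold - a) / (b - a) * (sb - sa))
    return None


def run_sweep(
    conn: Connectome,
    params: ModelParams,
    s_grid: np.ndarray | None = None,
    t_transient: float = 2.0,
    t_measure: float = 2.0,
    seed: int = 0,
    *,
    continuation: bool = True,
    record_signals: bool = False,
    signal_rate: float = 200.0,
    threshold: float = 0.5,
) -> SweepResult:
    """One up-then-down quasi-static sweep of the coupling strength.

    At every S the system integrates ``t_transient`` seconds (discarded)
    then ``t_measure`` seconds over which R is time-averaged.  The state is
    carried across S steps within each leg; each leg starts from a fresh
    random initial condition.  ``continuation=False`` re-randomizes the
    state at every step instead — a control that destroys the bistable
    band.  ``record_signals`` keeps decimated node signals per measurement
    window for :func:`model_trajectory`.
    """
    if s_grid is None:
        s_grid = default_s_grid()
    s_grid = np.asarray(s_grid, dtype=np.float64)
    if np.any(np.diff(s_grid) <= 0):
        raise ValueError("s_grid must be strictly increasing")
    omega = params.realized_omega(conn.n_nodes)
    params = replace(params, omega=omega)
    rec_every = max(int(round(1.0 / (signal_rate * params.dt))), 1) if record_signals else 0

    def _leg(order: np.ndarray, leg_seed: int):
        r_mean = np.empty(len(order))
        sigs: list[np.ndarray] = []
        state = initial_state(conn, params, seed=leg_seed)
        for i, s_val in enumerate(order):
            if not continuation and i > 0:
                state = initial_state(conn, params, seed=leg_seed + 1000 + i)
            p = replace(params, S=float(s_val))
            if t_transient > 0:
                res = simulate(conn, p, t_transient, state=state,
                               record_every=0, seed=leg_seed + 2 * i)
                state = res.final_state
            res = simulate(conn, p, t_measure, state=state,
                           record_every=rec_every if record_signals else 0,
                           seed=leg_seed + 2 * i + 1)
            state = res.final_state
            r_mean[i] = res.R.mean()
            if record_signals:
                sigs.append(res.node_signals().astype(np.float32))
        return r_mean, sigs

    r_up, sig_up = _leg(s_grid, seed)
    r_dn_rev, sig_dn_rev = _leg(s_grid[::-1], seed + 1)
    result = SweepResult(
        s_grid, r_up, r_dn_rev[::-1].copy(), threshold=threshold,
        signals_up=sig_up if record_signals else None,
        signals_down=sig_dn_rev[::-1] if record_signals else None,
        signal_rate=1.0 / (rec_every * params.dt) if record_signals else None,
    )
    return result


def _config_sweeps(conn, base_params, n_configs, seed, sweep_kwargs):
    """Sweeps over fresh frequency/phase configurations."""
    out = []
    for c in range(n_configs):
        cfg_seed = seed + 9973 * c
        omega = draw_natural_frequencies(
            conn.n_nodes, base_params.delta_omega, cfg_seed, base_params.center_freq
        )
        p = replace(base_params, omega=omega, seed=cfg_seed)
        out.append(run_sweep(conn, p, seed=cfg_seed, **sweep_kwargs))
    return out


def scan_feedback(
    conn: Connectome,
    base_params: ModelParams,
    z_values: tuple = (2, 3, 4, 5, 6, 7, 8),
    n_configs: int = 200,
    seed: int = 0,
    **sweep_kwargs,
) -> pd.DataFrame:
    """Hysteresis size versus feedback power Z.

    Per Z, ``n_configs`` sweeps with fresh natural-frequency draws and
    initial phases; reports the mean and dispersion of both hysteresis
    measures.  Stronger adaptive feedback produces larger hysteresis.
    """
    rows = []
    for z in z_values:
        sweeps = _config_sweeps(conn, replace(base_params, Z=float(z)),
                                n_configs, seed + int(round(z * 1009)), sweep_kwargs)
        areas = np.array([s.hysteresis_area for s in sweeps])
        ds = np.array([s.hysteresis_ds for s in sweeps if s.hysteresis_ds is not None])
        rows.append({
            "Z": float(z),
            "mean_area": areas.mean(), "sd_area": areas.std(ddof=min(1, len(areas) - 1)),
            "mean_ds": ds.mean() if ds.size else np.nan,
            "sd_ds": ds.std(ddof=1) if ds.size > 1 else np.nan,
            "n_configs": n_configs,
        })
    return pd.DataFrame(rows)


def scan_domega(
    conn: Connectome,
    base_params: ModelParams,
    domega_values: tuple = (0.1, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0),
    n_configs: int = 200,
    seed: int = 0,
    **sweep_kwargs,
) -> pd.DataFrame:
    """Critical couplings and hysteresis size versus frequency spread.

    Per delta-omega (Hz), reports mean ``s_inc``/``s_dec`` over
    configurations alongside the hysteresis measures; both critical
    couplings grow roughly linearly with the spread.
    """
    rows = []
    for i, dw in enumerate(domega_values):
        sweeps = _config_sweeps(conn, replace(base_params, delta_omega=float(dw)),
                                n_configs, seed + 7879 * i, sweep_kwargs)
        s_inc = np.array([s.s_inc for s in sweeps if s.s_inc is not None])
        s_dec = np.array([s.s_dec for s in sweeps if s.s_dec is not None])
        areas = np.array([s.hysteresis_area for s in sweeps])
        rows.append({
            "delta_omega": float(dw),
            "mean_s_inc": s_inc.mean() if s_inc.size else np.nan,
            "mean_s_dec": s_dec.mean() if s_dec.size else np.nan,
            "mean_area": areas.mean(),
            "sd_area": areas.std(ddof=1) if len(areas) > 1 else np.nan,
            "n_transitions": int(min(s_inc.size, s_dec.size)),
            "n_configs": n_configs,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# projection into the EEG trajectory plane


@dataclass
class ModelTrajectory:
    """Per-leg (topographic similarity, strength) curves from model signals.

    ``area`` is the shoelace area of the closed up-then-down path with the
    strength axis normalized by its maximum over the run, making
    connectivity-space and power-space areas directly comparable.
    """

    up: pd.DataFrame
    down: pd.DataFrame
    area: float
    space: str = "connectivity"


def _closed_path_area(up_xy: np.ndarray, down_xy: np.ndarray) -> float:
    path = np.vstack([up_xy, down_xy[::-1]])
    x, y = path[:, 0], path[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def model_trajectory(
    sweep: SweepResult,
    *,
    n_surrogates: int = 20,
    pli_threshold: float = 0.1,
    seed: int = 0,
) -> tuple[ModelTrajectory, ModelTrajectory]:
    """Connectivity- and power-space trajectories of one recorded sweep.

    Each S step's measurement window of node signals x_j = r_j cos(theta_j)
    is treated like an EEG window: Hilbert phases, PLI, surrogate-median
    correction, binary network and degree vector for the connectivity
    space; per-node mean squared amplitude for the power space.  The
    topographic reference is the mean vector over the maximally coupled
    windows (top grid point of both legs).  Returns the pair
    (connectivity, power).
    """
    if sweep.signals_up is None or sweep.signals_down is None:
        raise ValueError("sweep was run without record_signals=True")

    def _window_features(sig: np.ndarray, w_seed: int):
        phases = instantaneous_phase(sig, sweep.signal_rate,
                                     edge_discard=max(sig.shape[1] // 20, 1))
        pli = pli_matrix(phases)
        stack = surrogate_pli_stack(phases, n=n_surrogates, seed=w_seed)
        net = build_network(pli, stack, pli_threshold)
        power = (sig.astype(np.float64) ** 2).mean(axis=1)
        return net.degrees.astype(np.float64), power

    feats = {"up": [], "down": []}
    for leg, sigs in (("up", sweep.signals_up), ("down", sweep.signals_down)):
        for i, sig in enumerate(sigs):
            feats[leg].append(_window_features(sig, seed + (0 if leg == "up" else 5000) + 13 * i))

    deg_ref = np.mean([feats["up"][-1][0], feats["down"][-1][0]], axis=0)
    pow_ref = np.mean([feats["up"][-1][1], feats["down"][-1][1]], axis=0)

    def _leg_frame(leg: str, kind: int, ref: np.ndarray) -> pd.DataFrame:
        sims, strengths = [], []
        for vec, pvec in feats[leg]:
            v = vec if kind == 0 else pvec
            if np.std(v) == 0 or np.std(ref) == 0:
                sims.append(np.nan)
            else:
                sims.append(topographic_similarity(ref, v))
            strengths.append(float(np.mean(v)))
        return pd.DataFrame({"S": sweep.s_grid, "topo_sim": sims, "strength": strengths})

    out = []
    for kind, (space, ref) in enumerate((("connectivity", deg_ref), ("power", pow_ref))):
        up = _leg_frame("up", kind, ref)
        down = _leg_frame("down", kind, ref)
        smax = max(np.nanmax(up["strength"]), np.nanmax(down["strength"]), 1e-12)
        up_xy = np.column_stack([np.nan_to_num(up["topo_sim"]), up["strength"] / smax])
        down_xy = np.column_stack([np.nan_to_num(down["topo_sim"]), down["strength"] / smax])
        out.append(ModelTrajectory(up, down, _closed_path_area(up_xy, down_xy), space))
    return out[0], out[1]
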