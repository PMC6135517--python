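"""Delayed Stuart-Landau network with adaptive feedback (explosive synchronization).

Each of N cortical nodes is an oscillator with amplitude ``r_j`` and phase
``theta_j`` coupled over a structural connectome ``A_jk`` with
distance-proportional conduction delays ``tau_jk``:

    dr_j/dt     = (lambda_j - r_j^2) r_j
                  + S * sum_k A_jk r_k cos(theta_k(t - tau_jk) - theta_j(t))
    dtheta_j/dt = omega_j + xi_j(t)
                  + R_j^Z * S * sum_k A_jk (r_k/r_j) sin(theta_k(t - tau_jk) - theta_j(t))

where ``S`` is the global coupling strength, ``omega_j`` the natural
frequency (Gaussian around 10 Hz), ``xi_j`` Gaussian frequency noise, and

    R_j = | (e^{i theta_j} + (1/N) sum_k e^{i theta_k}) / 2 |

the node synchrony.  The multiplicative feedback ``R_j^Z`` on the phase
coupling suppresses gradual cluster growth and produces a discontinuous
(explosive) synchronization transition with a bistable coupling range —
the mechanism for hysteresis between the loss and recovery of a
synchronized (conscious-like) network state.  The feedback power ``Z``
plays the role of the anesthetic dose-response (Hill) slope via the
effective coupling ``S_eff = S R^Z``.

Integration is fixed-step Euler-Maruyama with a ring-buffer delay history,
JIT-compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "Connectome",
    "ModelParams",
    "OscillatorState",
    "SimulationResult",
    "build_delays",
    "node_synchrony",
    "global_order",
    "draw_natural_frequencies",
    "initial_state",
    "simulate",
    "meanfield_thresholds",
    "effective_coupling",
]

DEFAULT_SPEED = 8.6   # axonal propagation, m/s
CENTER_FREQ = 10.0    # alpha carrier, Hz
R_FLOOR = 1e-6        # guards the r_k/r_j quotient and amplitude underflow


def build_delays(distances_mm: np.ndarray, speed: float = DEFAULT_SPEED) -> np.ndarray:
    """Conduction delays (seconds) from inter-node distances (millimetres).

    ``tau = d / v`` with v in m/s; 8.6 mm at 8.6 m/s gives exactly 1 ms.
    """
    d = np.asarray(distances_mm, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if speed <= 0:
        raise ValueError("propagation speed must be positive")
    return d * 1e-3 / speed


@dataclass
class Connectome:
    """Structural scaffold: binary adjacency, distances (mm) and delays (s)."""

    adjacency: np.ndarray
    distances: np.ndarray
    coords: np.ndarray | None = None
    speed: float = DEFAULT_SPEED
    delays: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.int8)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if self.distances.shape != a.shape:
            raise ValueError("distances must match adjacency shape")
        self.delays = build_delays(self.distances, self.speed)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def min_positive_delay(self) -> float | None:
        mask = (self.adjacency > 0) & (self.delays > 0)
        return float(self.delays[mask].min()) if mask.any() else None

    # -- TSV round trip ----------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "adjacency.tsv", self.adjacency, fmt="%d", delimiter="\t")
        np.savetxt(path / "distances.tsv", self.distances, fmt="%.6f", delimiter="\t")
        if self.coords is not None:
            np.savetxt(path / "coords.tsv", self.coords, fmt="%.6f", delimiter="\t")

    @classmethod
    def from_dir(cls, path: str | Path, speed: float = DEFAULT_SPEED) -> "Connectome":
        path = Path(path)
        adj = np.loadtxt(path / "adjacency.tsv", delimiter="\t")
        coords = None
        if (path / "distances.tsv").exists():
            dist = np.loadtxt(path / "distances.tsv", delimiter="\t")
        elif (path / "coords.tsv").exists():
            coords = np.loadtxt(path / "coords.tsv", delimiter="\t")
            diff = coords[:, None, :] - coords[None, :, :]
            dist = np.sqrt((diff**2).sum(-1))
        else:
            raise FileNotFoundError("need distances.tsv or coords.tsv")
        if coords is None and (path / "coords.tsv").exists():
            coords = np.loadtxt(path / "coords.tsv", delimiter="\t")
        return cls(adj, dist, coords=coords, speed=speed)


def draw_natural_frequencies(
    n: int,
    delta_omega: float = 1.0,
    seed: int = 0,
    center: float = CENTER_FREQ,
) -> np.ndarray:
    """Natural frequencies (rad/s) ~ Gaussian(2*pi*center, 2*pi*delta_omega).

    ``delta_omega`` is the frequency-spread control parameter in Hz (SD).
    """
    rng = np.random.default_rng(seed)
    return 2.0 * np.pi * rng.normal(center, delta_omega, size=n)


@dataclass
class ModelParams:
    """Parameters of one simulation run.

    ``omega`` (rad/s per node) may be given explicitly; otherwise it is
    drawn from Gaussian(2*pi*center_freq, 2*pi*delta_omega) using ``seed``.

    ``feedback_tau`` (seconds) optionally low-pass filters the node
    synchrony driving the adaptive feedback: R_j in the phase equation
    becomes an exponential moving average with this time constant instead
    of the instantaneous value (the default, 0).  A memory of a few
    carrier cycles (e.g. 0.5 s) suppresses fluctuation-seeded cluster
    nucleation on the synchronizing path and widens the bistable band
    dramatically, at the cost of altering the trajectory-space geometry;
    see docs/methods.md for the trade-off.

    Noise is a Gaussian frequency perturbation in Hz: the mean enters as a
    uniform frequency offset (it cannot affect phase differences).  Two
    scalings of the fluctuating part are supported.  The default,
    ``noise_scaling="per_step"``, redraws an independent frequency jitter of
    SD ``noise_sd`` Hz at every integration step (phase increment
    2*pi*noise_sd*dt*N(0,1)), whose effective phase diffusion
    (2*pi*noise_sd)^2*dt/2 vanishes with the step — a dynamically gentle
    perturbation compatible with explosive synchronization at couplings of
    order 1.  ``"sqrt_dt"`` treats ``noise_sd`` as the intensity of
    continuous-time white noise (increment 2*pi*noise_sd*sqrt(dt)*N(0,1));
    at 2 Hz this yields a phase diffusion of ~79 rad^2/s that overwhelms a
    1 Hz natural-frequency spread and suppresses the discontinuous
    transition entirely, so it is not the default.
    """

    S: float
    Z: float = 4.0
    lam: float = 1.0
    omega: np.ndarray | None = None
    delta_omega: float = 1.0
    center_freq: float = CENTER_FREQ
    noise_mean: float = 2.0
    noise_sd: float = 2.0
    noise_scaling: str = "per_step"
    feedback_tau: float = 0.0
    dt: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 0 or self.Z < 0 or self.delta_omega < 0 or self.dt <= 0:
            raise ValueError("require S >= 0, Z >= 0, delta_omega >= 0, dt > 0")
        if self.noise_scaling not in ("per_step", "sqrt_dt"):
            raise ValueError("noise_scaling must be 'per_step' or 'sqrt_dt'")
        if self.omega is not None:
            self.omega = np.asarray(self.omega, dtype=np.float64)

    def realized_omega(self, n: int) -> np.ndarray:
        if self.omega is not None:
            if self.omega.shape != (n,):
                raise ValueError("omega length must equal the node count")
            return self.omega
        return draw_natural_frequencies(n, self.delta_omega, self.seed, self.center_freq)


@dataclass
class OscillatorState:
    """Amplitudes, phases and the delay history ring buffer.

    History arrays have shape (H, N) with ``ptr`` indexing the most recent
    row; H covers the maximum delay in steps plus one.  Cosines and sines
    of the phase history are cached so delayed coupling terms need no trig
    in the integration loop.
    """

    r: np.ndarray
    theta: np.ndarray
    hist_r: np.ndarray
    hist_theta: np.ndarray
    hist_cos: np.ndarray
    hist_sin: np.ndarray
    ptr: int
    feedback: np.ndarray | None = None  # low-pass filtered R_j, if enabled


@dataclass
class SimulationResult:
    """Recorded trajectories of one integration run.

    ``R`` is the global order parameter at every integration step;
    ``r``/``theta`` are decimated by ``record_every``.
    """

    times: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    R: np.ndarray
    R_times: np.ndarray
    dt: float
    final_state: OscillatorState

    def node_signals(self) -> np.ndarray:
        """Surface-like signals x_j(t) = r_j(t) cos(theta_j(t)), nodes x time."""
        return (self.r * np.cos(self.theta)).T

    def mean_order(self) -> float:
        return float(self.R.mean())


def node_synchrony(theta: np.ndarray, j: int) -> float:
    """Synchrony of node j with the network: |(e^{i th_j} + mean phasor)/2|."""
    theta = np.asarray(theta, dtype=np.float64)
    m = np.exp(1j * theta).mean()
    return float(abs(0.5 * (np.exp(1j * theta[j]) + m)))


def global_order(theta: np.ndarray) -> float:
    """Global order parameter R = |mean e^{i theta}| in [0, 1]."""
    theta = np.asarray(theta, dtype=np.float64)
    return float(abs(np.exp(1j * theta).mean()))


# ---------------------------------------------------------------------------
# jitted core


@njit(cache=True, fastmath=True)
def _integrate(indptr, indices, dsteps, hist_r, hist_th, hist_c, hist_s, ptr,
               omega, S, Z, lam, freq_off, diff_coef, fb_alpha, fb_state,
               dt, n_steps, record_every,
               out_r, out_th, out_R, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n = omega.shape[0]
    H = hist_r.shape[0]
    rec = 0
    for step in range(n_steps):
        r = hist_r[ptr]
        th = hist_th[ptr]
        cth = hist_c[ptr]
        sth = hist_s[ptr]
        # global mean phasor from the cached cos/sin
        C = 0.0
        Sm = 0.0
        for k in range(n):
            C += cth[k]
            Sm += sth[k]
        C /= n
        Sm /= n
        out_R[step] = np.sqrt(C * C + Sm * Sm)
        new_ptr = (ptr + 1) % H
        for j in range(n):
            cj = cth[j]
            sj = sth[j]
            Rj = 0.5 * np.sqrt((cj + C) ** 2 + (sj + Sm) ** 2)
            if fb_alpha > 0.0:
                fb_state[j] += fb_alpha * (Rj - fb_state[j])
                Rj = fb_state[j]
            acc_amp = 0.0
            acc_ph = 0.0
            rj = r[j]
            if rj < R_FLOOR:
                rj = R_FLOOR
            for e in range(indptr[j], indptr[j + 1]):
                k = indices[e]
                hidx = (ptr - dsteps[e]) % H
                rk = hist_r[hidx, k]
                ck = hist_c[hidx, k]
                sk = hist_s[hidx, k]
                # cos/sin of (theta_k(t - tau) - theta_j(t)) via identities
                acc_amp += rk * (ck * cj + sk * sj)
                acc_ph += rk * (sk * cj - ck * sj)
            dr = (lam - r[j] * r[j]) * r[j] + S * acc_amp
            fb = Rj ** Z if Z != 0.0 else 1.0
            dth = omega[j] + freq_off + fb * S * (acc_ph / rj)
            rn = r[j] + dt * dr
            if rn < R_FLOOR:
                rn = R_FLOOR
            tn = th[j] + dt * dth
            if diff_coef != 0.0:
                tn += diff_coef * np.random.normal()
            hist_r[new_ptr, j] = rn
            hist_th[new_ptr, j] = tn
            hist_c[new_ptr, j] = np.cos(tn)
            hist_s[new_ptr, j] = np.sin(tn)
        ptr = new_ptr
        if record_every > 0 and (step + 1) % record_every == 0:
            for j in range(n):
                out_r[rec, j] = hist_r[ptr, j]
                out_th[rec, j] = hist_th[ptr, j]
            rec += 1
    return ptr


def _csr_neighbors(conn: Connectome, dt: float):
    """Adjacency in CSR form with per-edge delay step counts."""
    n = conn.n_nodes
    indptr = np.zeros(n + 1, dtype=np.int64)
    idx_list = []
    dst_list = []
    for j in range(n):
        nbrs = np.nonzero(conn.adjacency[j])[0]
        indptr[j + 1] = indptr[j] + len(nbrs)
        idx_list.append(nbrs)
        dst_list.append(np.rint(conn.delays[j, nbrs] / dt).astype(np.int64))
    indices = np.concatenate(idx_list) if idx_list else np.empty(0, dtype=np.int64)
    dsteps = np.concatenate(dst_list) if dst_list else np.empty(0, dtype=np.int64)
    return indptr, indices.astype(np.int64), dsteps


def initial_state(
    conn: Connectome,
    params: ModelParams,
    seed: int | None = None,
    r0: float = 1.0,
) -> OscillatorState:
    """Fresh state: r = r0, uniform random phases, history back-extrapolated.

    The ring buffer is pre-filled along each node's natural frequency,
    theta(-s) = theta(0) - omega*s and r(-s) = r0, which avoids a startup
    discontinuity in the delayed coupling terms.
    """
    n = conn.n_nodes
    rng = np.random.default_rng(params.seed if seed is None else seed)
    theta0 = rng.uniform(-np.pi, np.pi, size=n)
    omega = params.realized_omega(n)
    max_dsteps = int(np.rint(conn.delays.max() / params.dt)) if conn.n_nodes else 0
    # depth >= 2 keeps the update synchronous (never write into the row
    # still being read within the current step)
    H = max(max_dsteps + 1, 2)
    hist_r = np.full((H, n), r0, dtype=np.float64)
    hist_th = np.empty((H, n), dtype=np.float64)
    ptr = H - 1
    for h in range(H):
        lag = (ptr - h) * params.dt
        hist_th[h] = theta0 - omega * lag
    fb = np.array([node_synchrony(theta0, j) for j in range(n)])
    return OscillatorState(hist_r[ptr].copy(), hist_th[ptr].copy(),
                           hist_r, hist_th, np.cos(hist_th), np.sin(hist_th), ptr,
                           feedback=fb)


def simulate(
    conn: Connectome,
    params: ModelParams,
    duration: float,
    state: OscillatorState | None = None,
    record_every: int = 1,
    seed: int | None = None,
) -> SimulationResult:
    """Integrate the network for ``duration`` seconds.

    Starting from ``state`` (or a fresh random initial condition), performs
    Euler-Maruyama steps of size ``params.dt``; ``record_every`` decimates
    the stored (r, theta) trajectories while the order parameter R is kept
    at every step.  Deterministic under a fixed seed.  The returned
    ``final_state`` allows quasi-static continuation across parameter steps.
    """
    mind = conn.min_positive_delay()
    if mind is not None and params.dt > mind:
        raise ValueError(
            f"dt = {params.dt:g} s exceeds the smallest positive delay {mind:g} s"
        )
    seed = params.seed if seed is None else seed
    if state is None:
        state = initial_state(conn, params, seed=seed)
    omega = params.realized_omega(conn.n_nodes)
    indptr, indices, dsteps = _csr_neighbors(conn, params.dt)
    n_steps = int(round(duration / params.dt))
    n_rec = n_steps // record_every if record_every > 0 else 0
    out_r = np.empty((n_rec, conn.n_nodes), dtype=np.float64)
    out_th = np.empty((n_rec, conn.n_nodes), dtype=np.float64)
    out_R = np.empty(n_steps, dtype=np.float64)
    fb_alpha = params.dt / params.feedback_tau if params.feedback_tau > 0 else 0.0
    fb_state = state.feedback
    if fb_state is None:
        fb_state = np.array([node_synchrony(state.theta, j) for j in range(conn.n_nodes)])
    ptr = _integrate(
        indptr, indices, dsteps, state.hist_r, state.hist_theta,
        state.hist_cos, state.hist_sin, state.ptr,
        omega, float(params.S), float(params.Z), float(params.lam),
        2.0 * np.pi * params.noise_mean,
        2.0 * np.pi * params.noise_sd
        * (params.dt if params.noise_scaling == "per_step" else np.sqrt(params.dt)),
        fb_alpha, fb_state,
        params.dt, n_steps, record_every, out_r, out_th, out_R,
        seed % (2**32),
    )
    final = OscillatorState(
        state.hist_r[ptr].copy(), state.hist_theta[ptr].copy(),
        state.hist_r, state.hist_theta, state.hist_cos, state.hist_sin, ptr,
        feedback=fb_state,
    )
    times = params.dt * record_every * np.arange(1, n_rec + 1)
    r_times = params.dt * np.arange(n_steps)
    return SimulationResult(times, out_r, out_th, out_R, r_times, params.dt, final)


# ---------------------------------------------------------------------------
# analytic helpers


def meanfield_thresholds(S: float, R_tilde: float, k_j: float) -> tuple[float, float]:
    """Mean-field frequency thresholds for joining a synchronized cluster.

    On the decreasing-synchrony path an oscillator stays entrained while
    ``omega_j < Omega_dec ~ S * R~^2 * k_j``; on the increasing path it can
    join while ``omega_j < Omega_inc ~ S * R~ * k_j``.  Since R~ <= 1,
    ``Omega_dec <= Omega_inc``, and the gap widens as R~ -> 0 — the
    asymmetry behind the hysteresis.
    """
    if not (0 <= R_tilde <= 1):
        raise ValueError("R_tilde must lie in [0, 1]")
    if S < 0 or k_j < 0:
        raise ValueError("S and k_j must be nonnegative")
    return S * R_tilde**2 * k_j, S * R_tilde * k_j


def effective_coupling(S: float, R: float, Z: float) -> float:
    """Effective coupling under the adaptive feedback, S_eff = S * R^Z.

    Documentation/analysis helper: the feedback power Z corresponds to the
    Hill slope of an anesthetic dose-response curve, with S_eff the coupling
    an anesthetized network effectively retains at synchrony R.
    """
    if not (0 <= R <= 1):
        raise ValueError("R must lie in [0, 1]")
    return S * R**Z
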