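"""Synthetic connectomes and four-state EEG with known, injected hysteresis.

Nothing in the analysis pipeline requires downloaded data: this module
generates (a) a spatially embedded 78-node connectome standing in for a
DTI-derived cortical parcellation, and (b) four-state multichannel EEG
whose carriers are runs of the delayed Stuart-Landau network itself at
state-specific coupling strengths, so the analysis pipeline and the model
are exercised jointly.  The ground truth (couplings, frequency draws,
seeds) is serialized next to every dataset, making any synthetic recording
bit-reproducible from its JSON record.

Hysteresis is "injected" through the coupling schedule: the induction-leg
and emergence-leg couplings differ by a controllable gap while baseline is
strongly and the unconscious state weakly coupled.  Per-channel amplitudes
follow a separate schedule (default: constant), so connectivity hysteresis
and power changes are independently controllable — the dissociation the
power control analysis is meant to detect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .brain_model import Connectome, ModelParams, initial_state, simulate
from .eeg_io import EEGRecording, write_eeg

__all__ = [
    "SynthConnectomeSpec",
    "SynthEEGSpec",
    "synth_connectome",
    "synth_eeg",
    "make_fixtures",
]

#: default per-state coupling schedule.  Baseline couples well above the
#: synchronization transition; unconscious sits deep in the incoherent
#: regime; the induction-leg coupling stays on the synchronized side of the
#: transition while the emergence-leg coupling stays on the incoherent
#: side — the 3.5 gap between them is the injected hysteresis.
DEFAULT_S_STATE = {
    "baseline": 7.0,
    "induction": 4.5,
    "unconscious": 0.5,
    "emergence": 1.0,
}


@dataclass(frozen=True)
class SynthConnectomeSpec:
    """Distance-decay random geometric connectome in an ellipsoidal volume.

    Nodes are placed uniformly (with a minimum separation, mm) inside an
    ellipsoid whose largest axis is ``extent`` mm; edge probability decays
    as exp(-d/decay) with the prefactor calibrated to the target mean
    degree.  Regenerates until connected.
    """

    n_nodes: int = 78
    extent: float = 140.0
    decay: float = 30.0
    target_mean_degree: float = 10.0
    min_separation: float = 6.0
    seed: int = 0
    max_retries: int = 30


@dataclass(frozen=True)
class SynthEEGSpec:
    """Four-state EEG generation conditions.

    Each state lasts ``state_len`` (>= 120) seconds at ``rate`` samples/s;
    carriers are network oscillators whose *observable* coupled rhythm sits
    near ``center_freq`` Hz with natural-frequency SD ``delta_omega``.
    Conduction delays depress the synchronized rhythm below the
    natural-frequency center (by ~1-2 Hz at the default coupling
    schedule), so natural frequencies are drawn at
    ``center_freq + carrier_offset``; the default offset of 0.75 Hz
    pre-compensates that depression for the strongly coupled (conscious)
    states.  ``s_state`` is the coupling
    schedule, ``amp_state`` the per-state amplitude schedule (microvolts
    RMS), ``noise_floor`` the pink-noise RMS relative to the signal, and
    ``mixing`` an optional neighbor-blur weight emulating
    volume-conduction-like zero-lag spread.
    """

    n_channels: int = 64
    rate: float = 500.0
    state_len: float = 120.0
    s_state: dict = field(default_factory=lambda: dict(DEFAULT_S_STATE))
    amp_state: dict = field(
        default_factory=lambda: {k: 1.0 for k in DEFAULT_S_STATE}
    )
    center_freq: float = 10.0
    carrier_offset: float = 0.75
    delta_omega: float = 1.0
    Z: float = 4.0
    noise_mean: float = 2.0
    noise_sd: float = 2.0
    amplitude: float = 40.0
    noise_floor: float = 0.4
    mixing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(DEFAULT_S_STATE) - set(self.s_state)
        if missing:
            raise ValueError(f"coupling schedule missing states: {sorted(missing)}")
        if self.state_len < 120.0:
            raise ValueError("each state must last at least 120 s")


def _place_nodes(spec: SynthConnectomeSpec, rng: np.random.Generator) -> np.ndarray:
    semi = np.array([spec.extent / 2, spec.extent / 2 * 0.78, spec.extent / 2 * 0.64])
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < spec.n_nodes:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("node placement failed; lower min_separation")
        p = rng.uniform(-1, 1, 3)
        if (p**2).sum() > 1:
            continue
        p = p * semi
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < spec.min_separation:
            continue
        pts.append(p)
    return np.array(pts)


def synth_connectome(spec: SynthConnectomeSpec = SynthConnectomeSpec()) -> Connectome:
    """Generate a connected spatial connectome matching the spec.

    The exp(-d/decay) edge-probability prefactor is solved so the expected
    mean degree hits the target; realized mean degree must land within
    +/-10% and the graph must be connected, else a fresh attempt is made.
    """
    if spec.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    for retry in range(spec.max_retries):
        rng = np.random.default_rng(spec.seed + 104729 * retry)
        coords = _place_nodes(spec, rng)
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        w = np.exp(-dist / spec.decay)
        np.fill_diagonal(w, 0.0)
        # calibrate the prefactor by bisection on expected mean degree
        target_sum = spec.target_mean_degree * spec.n_nodes
        lo_c, hi_c = 0.0, 1e6
        for _ in range(200):
            c = 0.5 * (lo_c + hi_c)
            if np.minimum(c * w, 1.0).sum() < target_sum:
                lo_c = c
            else:
                hi_c = c
        p = np.minimum(0.5 * (lo_c + hi_c) * w, 1.0)
        u = rng.uniform(size=p.shape)
        u = np.triu(u, 1)
        adj = ((u < np.triu(p, 1)) & (np.triu(np.ones_like(p), 1) > 0)).astype(np.int8)
        adj = adj + adj.T
        mean_deg = adj.sum() / spec.n_nodes
        if abs(mean_deg - spec.target_mean_degree) > 0.1 * spec.target_mean_degree:
            continue
        if not nx.is_connected(nx.from_numpy_array(adj)):
            continue
        return Connectome(adj, dist, coords=coords)
    raise RuntimeError(
        f"no connected graph at the target density after {spec.max_retries} attempts"
    )


def _pink_noise(shape: tuple[int, int], rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise per channel."""
    n_ch, n_s = shape
    freqs = np.fft.rfftfreq(n_s, d=1.0 / rate)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_ch, freqs.size)) + 1j * rng.standard_normal((n_ch, freqs.size))) * scale
    x = np.fft.irfft(spec, n=n_s, axis=1)
    return x / x.std(axis=1, keepdims=True)


def synth_eeg(
    spec: SynthEEGSpec = SynthEEGSpec(),
    conn: Connectome | None = None,
    conn_spec: SynthConnectomeSpec | None = None,
) -> tuple[EEGRecording, dict]:
    """Four-state EEG from state-specific runs of the oscillator network.

    The network is integrated through baseline -> induction -> unconscious
    -> emergence with quasi-static continuation (the state at the end of
    one condition seeds the next), at the coupling schedule ``s_state``.
    Node signals x_j = r_j cos(theta_j) are RMS-normalized per state and
    channel — the amplitude schedule is then the sole control of band
    power — scaled to microvolts, optionally neighbor-blurred, and summed
    with a pink-noise floor.  Returns the recording and its ground-truth
    record.
    """
    if conn is None:
        conn = synth_connectome(conn_spec or SynthConnectomeSpec(seed=spec.seed))
    if spec.n_channels > conn.n_nodes:
        raise ValueError("more channels than nodes to map them to")
    states = ["baseline", "induction", "unconscious", "emergence"]
    params = ModelParams(
        S=spec.s_state["baseline"], Z=spec.Z, delta_omega=spec.delta_omega,
        center_freq=spec.center_freq + spec.carrier_offset,
        noise_mean=spec.noise_mean, noise_sd=spec.noise_sd, seed=spec.seed,
    )
    rec_every = max(int(round(1.0 / (spec.rate * params.dt))), 1)
    eff_rate = 1.0 / (rec_every * params.dt)

    rng = np.random.default_rng(spec.seed + 1)
    osc = initial_state(conn, params, seed=spec.seed)
    pieces = []
    epochs: dict[str, tuple[int, int]] = {}
    cursor = 0
    for s_idx, st in enumerate(states):
        from dataclasses import replace

        p = replace(params, S=float(spec.s_state[st]))
        res = simulate(conn, p, spec.state_len, state=osc,
                       record_every=rec_every, seed=spec.seed + 31 * s_idx)
        osc = res.final_state
        x = res.node_signals()[: spec.n_channels]  # channels x samples
        if spec.mixing > 0:
            x = _neighbor_blur(x, conn, spec.mixing)
        rms = x.std(axis=1, keepdims=True)
        rms[rms == 0] = 1.0
        x = x / rms * spec.amplitude * spec.amp_state[st]
        noise = _pink_noise(x.shape, eff_rate, rng) * spec.amplitude * spec.noise_floor
        pieces.append(x + noise)
        epochs[st] = (cursor, cursor + x.shape[1])
        cursor += x.shape[1]

    data = np.concatenate(pieces, axis=1)
    labels = [f"CH{i:03d}" for i in range(spec.n_channels)]
    rec = EEGRecording(data, eff_rate, labels, epochs)
    truth = {
        "spec": asdict(spec),
        "connectome_seed": None if conn_spec is None else conn_spec.seed,
        "effective_rate": eff_rate,
        "states": states,
        "s_state": spec.s_state,
        "hysteresis_gap": abs(spec.s_state["induction"] - spec.s_state["emergence"]),
    }
    return rec, truth


def _neighbor_blur(x: np.ndarray, conn: Connectome, m: float) -> np.ndarray:
    """Each channel mixed with the mean of its node's graph neighbors."""
    n_ch = x.shape[0]
    adj = conn.adjacency[:n_ch, :n_ch].astype(np.float64)
    deg = adj.sum(axis=1, keepdims=True)
    deg[deg == 0] = 1.0
    return (1.0 - m) * x + m * (adj @ x) / deg


def make_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the small deterministic fixture set used by the test suite.

    A toy delimited EEG (4 channels, sinusoids with known phase offsets), a
    small connected connectome in the TSV dialect, and the ground-truth
    JSON.  Byte-identical across runs at the same seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rng = np.random.default_rng(seed)
    rate = 250.0
    t = np.arange(int(4 * rate)) / rate
    data = np.vstack([
        np.cos(2 * np.pi * 10 * t),
        np.cos(2 * np.pi * 10 * t - np.pi / 2),
        np.cos(2 * np.pi * 6 * t),
        rng.standard_normal(t.size),
    ])
    rec = EEGRecording(data, rate, ["A", "B", "C", "D"],
                       {"baseline": (0, t.size // 2), "unconscious": (t.size // 2, t.size)})
    eeg_path = out / "toy_eeg.tsv"
    write_eeg(rec, eeg_path)
    written += [eeg_path, eeg_path.with_suffix(".tsv.json")]

    conn = synth_connectome(SynthConnectomeSpec(n_nodes=12, target_mean_degree=4.0,
                                                extent=80.0, seed=seed))
    conn_dir = out / "toy_connectome"
    conn.to_dir(conn_dir)
    written += sorted(conn_dir.glob("*.tsv"))

    meta = {"seed": seed, "rate": rate, "channels": rec.labels,
            "connectome_nodes": conn.n_nodes}
    meta_path = out / "fixtures.json"
    meta_path.write_text(json.dumps(meta, indent=1), encoding="utf-8")
    written.append(meta_path)
    return written
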