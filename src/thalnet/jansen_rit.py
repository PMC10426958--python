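"""Jansen-Rit neural-mass network with conduction delays and noisy drive.

Each brain region is a Jansen-Rit cortical column: three coupled
subpopulations (pyramidal cells, excitatory and inhibitory interneurons)
whose mean postsynaptic potentials evolve as a six-dimensional second-order
ODE system. The pyramidal membrane potential ``v = y1 - y2`` is the model
output, converted to a firing rate by a sigmoid. Regions are coupled through
the structural connectome: the input to region ``i`` is

    input_i(t) = p_i + eta_i(t) + g * sum_j w_ji * S[v_j(t - d_ji)]

with per-region mean drive ``p_i`` (ms^-1), Gaussian noise of standard
deviation ``eta_i`` drawn once per integration step, global coupling ``g``
and delays ``d_ji`` = tract length / conduction speed.

Depending on its total input a node is either a damped oscillator relaxing
to a fixed point (prebifurcation) or a self-sustained limit cycle
(postbifurcation); increasing constant drive the model passes first through
a slow high-amplitude limit cycle before settling into ~10 Hz alpha.

Time is in ms throughout; voltages in mV; rates in ms^-1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sps
from scipy.optimize import brentq

from .connectome import StructuralConnectome

__all__ = [
    "JRParameters",
    "DriveConfig",
    "CouplingConfig",
    "NodeState",
    "SimulationConfig",
    "SimulationResult",
    "SimulationDiverged",
    "sigmoid",
    "jr_derivatives",
    "network_input",
    "simulate_network",
    "fixed_point",
    "fixed_points",
    "bifurcation_scan",
]


@dataclass(frozen=True)
class JRParameters:
    """Jansen-Rit column parameters (defaults: standard alpha-regime set).

    A, B : mV — excitatory / inhibitory synaptic gains
    a, b : ms^-1 — inverse synaptic time constants
    C1..C4 : dimensionless connectivity constants within the column
    vmax : ms^-1 — half the maximum firing rate
    r : mV^-1 — sigmoid slope;  v0 : mV — sigmoid midpoint
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 0.1
    b: float = 0.05
    C1: float = 135.0
    C2: float = 108.0
    C3: float = 33.75
    C4: float = 33.75
    vmax: float = 0.0025
    r: float = 0.56
    v0: float = 6.0

    def __post_init__(self):
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"JR parameter {name} must be strictly positive")


@dataclass
class DriveConfig:
    """Per-node intrinsic drive: mean ``p`` and noise std ``eta`` (ms^-1)."""

    p: np.ndarray
    eta: np.ndarray

    def __post_init__(self):
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        if self.p.shape != self.eta.shape:
            raise ValueError("p and eta must have the same length")
        if (self.p < 0).any() or (self.eta < 0).any():
            raise ValueError("p and eta must be nonnegative")

    @classmethod
    def uniform(cls, n: int, p: float = 0.09, eta: float = 2.2e-8) -> "DriveConfig":
        return cls(np.full(n, p), np.full(n, eta))

    @classmethod
    def with_driver(
        cls,
        sc: StructuralConnectome,
        driver_role: str,
        p_driver: float = 0.09,
        eta_driver: float = 0.022,
        p_cortical: float = 0.09,
        eta_cortical: float = 2.2e-8,
    ) -> "DriveConfig":
        """Cortical defaults everywhere, overridden on the driver-role regions."""
        cfg = cls.uniform(sc.n_regions, p_cortical, eta_cortical)
        idx = sc.role_indices(driver_role)
        cfg.p[idx] = p_driver
        cfg.eta[idx] = eta_driver
        return cfg


@dataclass
class CouplingConfig:
    """Global coupling factor ``g`` and conduction speed (mm/ms)."""

    g: float = 0.0
    speed: float = 15.0

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if not self.speed > 0:
            raise ValueError("speed must be > 0")


@dataclass
class NodeState:
    """The six JR state variables (y0,y1,y2 in mV; y3,y4,y5 in mV/ms)."""

    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).reshape(6)

    @property
    def output(self) -> float:
        """Pyramidal membrane potential y1 - y2 (mV)."""
        return float(self.y[1] - self.y[2])


@dataclass
class SimulationConfig:
    """Integration settings. ``dt`` in ms; ``duration``/``transient`` in ms."""

    duration: float = 10_000.0
    transient: float = 2_000.0
    dt: float = 0.1
    seed: int = 0
    output_fs: float = 1000.0

    def __post_init__(self):
        if not 0 < self.dt <= 1:
            raise ValueError("dt must be in (0, 1] ms")
        if not self.transient < self.duration:
            raise ValueError("transient must be shorter than duration")
        if self.output_fs > 1000.0 / self.dt:
            raise ValueError("output_fs exceeds the integration rate")


class SimulationDiverged(RuntimeError):
    pass


@dataclass
class SimulationResult:
    """Decimated pyramidal output per region plus provenance."""

    signals: np.ndarray        # (n_regions, n_samples), mV
    fs: float                  # Hz
    transient_samples: int
    labels: list
    roles: list
    final_state: np.ndarray    # (6, n_regions)
    config: dict

    @property
    def n_regions(self) -> int:
        return self.signals.shape[0]

    def post_transient(self) -> np.ndarray:
        return self.signals[:, self.transient_samples:]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=self.signals)
            f.create_dataset("final_state", data=self.final_state)
            f.attrs["fs"] = self.fs
            f.attrs["transient_samples"] = self.transient_samples
            f.attrs["labels"] = json.dumps(self.labels)
            f.attrs["roles"] = json.dumps(self.roles)
            f.attrs["config"] = json.dumps(self.config)

    @classmethod
    def load(cls, path) -> "SimulationResult":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                signals=f["signals"][:],
                fs=float(f.attrs["fs"]),
                transient_samples=int(f.attrs["transient_samples"]),
                labels=json.loads(f.attrs["labels"]),
                roles=json.loads(f.attrs["roles"]),
                final_state=f["final_state"][:],
                config=json.loads(f.attrs["config"]),
            )


# -- elementary pieces ------------------------------------------------------

def sigmoid(v, params: JRParameters = JRParameters()):
    """Voltage-to-firing-rate conversion: S[v] = 2*vmax / (1 + exp(r*(v0-v)))."""
    v = np.asarray(v, dtype=float)
    out = 2.0 * params.vmax / (1.0 + np.exp(params.r * (params.v0 - v)))
    return float(out) if out.ndim == 0 else out


def jr_derivatives(state, input_value, params: JRParameters = JRParameters()):
    """Right-hand side of the six JR equations for one node.

    ``input_value`` is the total extrinsic input (intrinsic drive + noise +
    network coupling, ms^-1); it enters only the excitatory-interneuron
    acceleration equation.
    """
    y0, y1, y2, y3, y4, y5 = np.asarray(state, dtype=float).reshape(6)
    A, B, a, b = params.A, params.B, params.a, params.b
    S = lambda v: sigmoid(v, params)
    return np.array(
        [
            y3,
            y4,
            y5,
            A * a * S(y1 - y2) - 2 * a * y3 - a * a * y0,
            A * a * (input_value + params.C2 * S(params.C1 * y0)) - 2 * a * y4 - a * a * y1,
            B * b * (params.C4 * S(params.C3 * y0)) - 2 * b * y5 - b * b * y2,
        ]
    )


def network_input(
    node_i: int,
    delayed_outputs: np.ndarray,
    drive: DriveConfig,
    coupling: CouplingConfig,
    sc: StructuralConnectome,
    noise_sample: float,
    params: JRParameters = JRParameters(),
) -> float:
    """Total input to node ``i``: p_i + noise + g * sum_j w_ji * S[v_j(t - d_ji)].

    ``delayed_outputs[j]`` must hold the delayed pyramidal output of region
    ``j`` as seen from node ``i``. Weights are normalized by their maximum
    over the connectome, matching the simulator's convention.
    """
    delayed_outputs = np.asarray(delayed_outputs, dtype=float)
    if delayed_outputs.shape != (sc.n_regions,):
        raise ValueError("delayed_outputs must provide one value per region")
    wmax = sc.weights.max()
    w_col = sc.weights[:, node_i] / wmax if wmax > 0 else sc.weights[:, node_i]
    return float(
        drive.p[node_i]
        + noise_sample
        + coupling.g * np.dot(w_col, sigmoid(delayed_outputs, params))
    )


# -- integrator -------------------------------------------------------------

@njit(cache=True)
def _heun_loop(w, dsteps, p, eta, g, A, B, a, b, C1, C2, C3, C4, vmax, r, v0,
               dt, n_steps, horizon, seed, out):  # pragma: no cover - numba
    n = w.shape[0]
    np.random.seed(seed)
    y = np.zeros((6, n))
    bufS = np.empty((horizon, n))
    s_init = 2.0 * vmax / (1.0 + np.exp(r * v0))
    for t in range(horizon):
        for j in range(n):
            bufS[t, j] = s_init
    k1 = np.empty((6, n))
    yp = np.empty((6, n))
    inp = np.empty(n)
    for t in range(n_steps):
        # frozen per-step input: drive + noise + delayed coupling
        for i in range(n):
            acc = 0.0
            for j in range(n):
                wji = w[j, i]
                if wji != 0.0:
                    acc += wji * bufS[(t - dsteps[j, i]) % horizon, j]
            inp[i] = p[i] + eta[i] * np.random.normal() + g * acc
        # Heun predictor-corrector with the input held fixed
        for i in range(n):
            y0_, y1_, y2_, y3_, y4_, y5_ = y[0, i], y[1, i], y[2, i], y[3, i], y[4, i], y[5, i]
            s_v = 2.0 * vmax / (1.0 + np.exp(r * (v0 - (y1_ - y2_))))
            s_c1 = 2.0 * vmax / (1.0 + np.exp(r * (v0 - C1 * y0_)))
            s_c3 = 2.0 * vmax / (1.0 + np.exp(r * (v0 - C3 * y0_)))
            k1[0, i] = y3_
            k1[1, i] = y4_
            k1[2, i] = y5_
            k1[3, i] = A * a * s_v - 2 * a * y3_ - a * a * y0_
            k1[4, i] = A * a * (inp[i] + C2 * s_c1) - 2 * a * y4_ - a * a * y1_
            k1[5, i] = B * b * C4 * s_c3 - 2 * b * y5_ - b * b * y2_
            for k in range(6):
                yp[k, i] = y[k, i] + dt * k1[k, i]
        for i in range(n):
            y0_, y1_, y2_, y3_, y4_, y5_ = yp[0, i], yp[1, i], yp[2, i], yp[3, i], yp[4, i], yp[5, i]
            s_v = 2.0 * vmax / (1.0 + np.exp(r * (v0 - (y1_ - y2_))))
            s_c1 = 2.0 * vmax / (1.0 + np.exp(r * (v0 - C1 * y0_)))
            s_c3 = 2.0 * vmax / (1.0 + np.exp(r * (v0 - C3 * y0_)))
            k2_0 = y3_
            k2_1 = y4_
            k2_2 = y5_
            k2_3 = A * a * s_v - 2 * a * y3_ - a * a * y0_
            k2_4 = A * a * (inp[i] + C2 * s_c1) - 2 * a * y4_ - a * a * y1_
            k2_5 = B * b * C4 * s_c3 - 2 * b * y5_ - b * b * y2_
            y[0, i] += 0.5 * dt * (k1[0, i] + k2_0)
            y[1, i] += 0.5 * dt * (k1[1, i] + k2_1)
            y[2, i] += 0.5 * dt * (k1[2, i] + k2_2)
            y[3, i] += 0.5 * dt * (k1[3, i] + k2_3)
            y[4, i] += 0.5 * dt * (k1[4, i] + k2_4)
            y[5, i] += 0.5 * dt * (k1[5, i] + k2_5)
        slot = (t + 1) % horizon
        for j in range(n):
            v_new = y[1, j] - y[2, j]
            bufS[slot, j] = 2.0 * vmax / (1.0 + np.exp(r * (v0 - v_new)))
            out[t, j] = v_new
        if (t + 1) % 10000 == 0:
            ok = True
            for j in range(n):
                if not np.isfinite(y[1, j] - y[2, j]):
                    ok = False
            if not ok:
                return y, t + 1
    return y, n_steps


def simulate_network(
    sc: StructuralConnectome,
    params: JRParameters,
    drive: DriveConfig,
    coupling: CouplingConfig,
    config: SimulationConfig,
) -> SimulationResult:
    """Integrate the delayed stochastic JR network and return decimated output.

    Stochastic Heun integration at ``config.dt`` with per-step Gaussian
    noise of std ``eta_i`` held constant within the step. Connectome weights
    are normalized by their maximum before ``g`` is applied. Delays are
    tract length / speed rounded to integration steps; the history buffer is
    pre-filled with the sigmoid of the zero initial output. Output is the
    pyramidal potential ``y1 - y2`` per region, anti-alias filtered and
    decimated to ``config.output_fs``. Identical configuration and seed give
    bit-identical results.
    """
    n = sc.n_regions
    if drive.p.shape[0] != n:
        raise ValueError("drive vectors must match the connectome size")
    wmax = sc.weights.max()
    w = sc.weights / wmax if wmax > 0 else sc.weights.copy()
    dsteps = np.rint(sc.lengths / coupling.speed / config.dt).astype(np.int64)
    horizon = int(dsteps.max()) + 1
    n_steps = int(round(config.duration / config.dt))
    out = np.empty((n_steps, n))
    final_state, steps_done = _heun_loop(
        np.ascontiguousarray(w), dsteps, drive.p, drive.eta, float(coupling.g),
        params.A, params.B, params.a, params.b, params.C1, params.C2,
        params.C3, params.C4, params.vmax, params.r, params.v0,
        config.dt, n_steps, horizon, int(config.seed) & 0x7FFFFFFF, out,
    )
    if steps_done < n_steps:
        raise SimulationDiverged(
            f"non-finite state at t = {steps_done * config.dt:.1f} ms "
            f"(g={coupling.g}, max eta={drive.eta.max()})"
        )
    fs_sim = 1000.0 / config.dt
    q = int(round(fs_sim / config.output_fs))
    if q > 1:
        # polyphase FIR decimation; linear-trend padding avoids boundary
        # ripple on signals sitting at a nonzero fixed point
        signals = sps.resample_poly(out.T, 1, q, axis=-1, padtype="line")
        fs = fs_sim / q
    else:
        signals = out.T.copy()
        fs = fs_sim
    transient_samples = int(round(config.transient / 1000.0 * fs))
    return SimulationResult(
        signals=signals,
        fs=fs,
        transient_samples=transient_samples,
        labels=list(sc.labels),
        roles=list(sc.roles),
        final_state=np.asarray(final_state),
        config={
            "params": asdict(params),
            "p": drive.p.tolist(),
            "eta": drive.eta.tolist(),
            "g": coupling.g,
            "speed": coupling.speed,
            "dt": config.dt,
            "duration": config.duration,
            "transient": config.transient,
            "seed": int(config.seed),
            "output_fs": config.output_fs,
            "subject_id": sc.subject_id,
        },
    )


# -- fixed points -----------------------------------------------------------

def _equilibrium_mismatch(v: float, p: float, params: JRParameters) -> float:
    """f(v) = v_implied(v) - v where v_implied follows from the equilibrium
    relations y0 = (A/a) S[v], y1 = (A/a)(p + C2 S[C1 y0]),
    y2 = (B/b) C4 S[C3 y0]."""
    y0 = params.A / params.a * sigmoid(v, params)
    y1 = params.A / params.a * (p + params.C2 * sigmoid(params.C1 * y0, params))
    y2 = params.B / params.b * params.C4 * sigmoid(params.C3 * y0, params)
    return (y1 - y2) - v


def _sigmoid_slope(v: float, params: JRParameters) -> float:
    e = np.exp(params.r * (params.v0 - v))
    return 2.0 * params.vmax * params.r * e / (1.0 + e) ** 2


def _jacobian(state: np.ndarray, params: JRParameters) -> np.ndarray:
    y0, y1, y2 = state[0], state[1], state[2]
    A, B, a, b = params.A, params.B, params.a, params.b
    sp_v = _sigmoid_slope(y1 - y2, params)
    sp_c1 = _sigmoid_slope(params.C1 * y0, params)
    sp_c3 = _sigmoid_slope(params.C3 * y0, params)
    J = np.zeros((6, 6))
    J[0, 3] = J[1, 4] = J[2, 5] = 1.0
    J[3, 0] = -a * a
    J[3, 1] = A * a * sp_v
    J[3, 2] = -A * a * sp_v
    J[3, 3] = -2 * a
    J[4, 0] = A * a * params.C2 * params.C1 * sp_c1
    J[4, 1] = -a * a
    J[4, 4] = -2 * a
    J[5, 0] = B * b * params.C4 * params.C3 * sp_c3
    J[5, 2] = -b * b
    J[5, 5] = -2 * b
    return J


def fixed_points(
    params: JRParameters, p: float, tolerance: float = 1e-12,
    v_range: tuple = (-80.0, 120.0), n_grid: int = 4000,
):
    """All equilibria of an uncoupled node at constant input ``p``.

    The six-dimensional equilibrium conditions reduce to a scalar equation
    in the output ``v = y1 - y2``; sign changes on a dense grid are polished
    with Brent's method. Returns a list of ``(NodeState, stable)`` sorted by
    ``v``; stability from the eigenvalues of the 6-D Jacobian.
    """
    grid = np.linspace(v_range[0], v_range[1], n_grid)
    f = np.array([_equilibrium_mismatch(v, p, params) for v in grid])
    roots = []
    for i in np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]:
        v = brentq(_equilibrium_mismatch, grid[i], grid[i + 1],
                   args=(p, params), xtol=tolerance)
        y0 = params.A / params.a * sigmoid(v, params)
        y1 = params.A / params.a * (p + params.C2 * sigmoid(params.C1 * y0, params))
        y2 = params.B / params.b * params.C4 * sigmoid(params.C3 * y0, params)
        state = NodeState(np.array([y0, y1, y2, 0.0, 0.0, 0.0]))
        stable = bool(np.max(np.linalg.eigvals(_jacobian(state.y, params)).real) < 0)
        roots.append((state, stable))
    return roots


def fixed_point(params: JRParameters, p: float, tolerance: float = 1e-12) -> NodeState:
    """The resting stable equilibrium of an uncoupled node at input ``p``.

    The node can be bistable (a high-voltage branch coexists with the
    damped resting branch); this returns the stable root with the lowest
    output, which is the attractor reached from the zero initial state in
    the damped regime. Raises if no stable equilibrium exists (the node is
    then in a pure limit-cycle regime; use :func:`fixed_points` for the
    unstable roots).
    """
    stable = [s for s, ok in fixed_points(params, p, tolerance) if ok]
    if not stable:
        raise ValueError(f"no stable equilibrium at p={p}; use fixed_points()")
    return min(stable, key=lambda s: s.output)


# -- bifurcation scan -------------------------------------------------------

def bifurcation_scan(
    sc: StructuralConnectome,
    params: JRParameters,
    drive_template: DriveConfig,
    coupling_template: CouplingConfig,
    scan_parameter: str,
    grid,
    sim_config: SimulationConfig,
    driver_role: str = "thalamic",
) -> pd.DataFrame:
    """Post-transient signal extrema along a parameter grid.

    ``scan_parameter`` is one of ``g``, ``p_driver``, ``eta_driver``. For
    each grid value the network is simulated and the per-node post-transient
    maximum and minimum of the output are averaged within the cortical
    group, the driver-role group, and over all nodes. Seeds increment along
    the grid so repeated values are independent draws.
    """
    if scan_parameter not in ("g", "p_driver", "eta_driver"):
        raise ValueError(f"unknown scan parameter {scan_parameter!r}")
    drv = sc.role_indices(driver_role)
    ctx = sc.role_indices("cortical")
    rows = []
    for k, value in enumerate(np.asarray(grid, dtype=float)):
        drive = DriveConfig(drive_template.p.copy(), drive_template.eta.copy())
        coupling = CouplingConfig(coupling_template.g, coupling_template.speed)
        if scan_parameter == "g":
            coupling.g = float(value)
        elif scan_parameter == "p_driver":
            drive.p[drv] = value
        else:
            drive.eta[drv] = value
        cfg = SimulationConfig(
            duration=sim_config.duration, transient=sim_config.transient,
            dt=sim_config.dt, seed=sim_config.seed + k, output_fs=sim_config.output_fs,
        )
        res = simulate_network(sc, params, drive, coupling, cfg)
        x = res.post_transient()
        vmax_node = x.max(axis=1)
        vmin_node = x.min(axis=1)
        for group, idx in (("cortical", ctx), ("driver", drv),
                           ("all", np.arange(sc.n_regions))):
            if idx.size == 0:
                continue
            rows.append({
                scan_parameter: float(value), "group": group,
                "vmax": float(vmax_node[idx].mean()),
                "vmin": float(vmin_node[idx].mean()),
            })
    return pd.DataFrame(rows)
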