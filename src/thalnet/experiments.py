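"""In-silico experiment drivers: g sweeps, 2-D explorations, regime splitting.

The central experiment couples a cohort of structural connectomes to the
Jansen-Rit network under factorial conditions — connectome variant of the
driver region (parceled / single / removed) crossed with driver noise level
(high 0.022 vs low 2.2e-8 ms^-1) — sweeps the global coupling ``g``, and
scores every simulation against a reference FC/dFC target with the
Pearson-r FC fit (r_PLV) and the KS distance between dFC distributions.
Sweep records split into a prebifurcation regime (damped cortical nodes)
and a postbifurcation regime (self-oscillating cortex); the *working point*
is the best-fitting coupling within a regime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .connectome import StructuralConnectome, build_variant
from .jansen_rit import (
    CouplingConfig,
    DriveConfig,
    JRParameters,
    SimulationConfig,
    SimulationDiverged,
    simulate_network,
)
from .metrics import (
    ALPHA_BAND,
    bandpass_filter,
    dfc_matrix,
    fc_similarity,
    instantaneous_phase,
    ks_distance,
    plv_matrix,
    relative_power,
    snr,
    spectral_summary,
)
from .synthetic import PseudoEmpiricalTarget

__all__ = [
    "Condition",
    "default_conditions",
    "derive_seed",
    "run_trial",
    "g_sweep",
    "grid_exploration",
    "split_regimes",
    "working_point",
]

HIGH_NOISE = 0.022
LOW_NOISE = 2.2e-8


@dataclass(frozen=True)
class Condition:
    """One experimental cell: connectome variant x drive parametrization."""

    sc_variant: str = "parceled"        # parceled | single | removed
    driver_role: str = "thalamic"
    driver_p: float = 0.09              # ms^-1
    driver_eta: float = HIGH_NOISE      # ms^-1
    cortical_p: float = 0.09
    cortical_eta: float = LOW_NOISE

    @property
    def name(self) -> str:
        noise = "high" if self.driver_eta >= 1e-3 else "low"
        tag = "-cxnoise" if self.cortical_eta >= 1e-3 else ""
        return f"{self.sc_variant}-{noise}{tag}"


def default_conditions(driver_role: str = "thalamic") -> list:
    """The 3 variants x 2 driver-noise levels factorial (6 conditions)."""
    return [
        Condition(sc_variant=v, driver_role=driver_role, driver_eta=eta)
        for eta in (HIGH_NOISE, LOW_NOISE)
        for v in ("parceled", "single", "removed")
    ]


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic per-record seed: SeedSequence(master, spawn_key=keys)."""
    return int(np.random.SeedSequence(master, spawn_key=tuple(keys)).generate_state(1)[0] % (2**31))


def run_trial(
    sc: StructuralConnectome,
    condition: Condition,
    g: float,
    sim_config: SimulationConfig,
    reference_target: PseudoEmpiricalTarget | None,
    params: JRParameters = JRParameters(),
    speed: float = 15.0,
) -> dict:
    """Simulate one cell and compute the full metrics record.

    Builds the condition's connectome variant, simulates at coupling ``g``,
    and derives: r_PLV against the reference FC (cortical regions only),
    KSD against the reference dFC sample, per-group signal extrema,
    node-averaged spectral peak, driver SNR and cortex/driver relative
    power. A degenerate FC comparison (constant vector, the functional
    disconnection seen at low coupling and low noise) is flagged with
    ``r_plv = NaN`` rather than an error; divergent simulations are flagged
    ``failed``.
    """
    variant = build_variant(sc, condition.driver_role, condition.sc_variant)
    drive = DriveConfig.with_driver(
        variant, condition.driver_role,
        p_driver=condition.driver_p, eta_driver=condition.driver_eta,
        p_cortical=condition.cortical_p, eta_cortical=condition.cortical_eta,
    )
    record = {
        "subject": sc.subject_id,
        "condition": condition.name,
        "sc_variant": condition.sc_variant,
        "driver_eta": condition.driver_eta,
        "driver_p": condition.driver_p,
        "g": float(g),
        "seed": int(sim_config.seed),
        "failed": False,
        "disconnected_fc": False,
    }
    try:
        res = simulate_network(variant, params, drive, CouplingConfig(g=g, speed=speed), sim_config)
    except SimulationDiverged as err:
        record.update({"failed": True, "r_plv": np.nan, "ksd": np.nan,
                       "peak_hz": np.nan, "snr_driver": np.nan, "rel_power": np.nan,
                       "plv_mean": np.nan, "plv_std": np.nan,
                       "vmax_cortical": np.nan, "vmin_cortical": np.nan,
                       "vmax_driver": np.nan, "vmin_driver": np.nan,
                       "note": str(err)})
        return record

    cortical = variant.role_indices("cortical")
    drv = variant.role_indices(condition.driver_role)
    x = res.post_transient()

    filtered = bandpass_filter(x, *ALPHA_BAND, res.fs)
    phases, edge = instantaneous_phase(filtered, res.fs)
    fc = plv_matrix(phases, exclude_edges=edge)
    fc_ctx = fc.values[np.ix_(cortical, cortical)]
    iu = np.triu_indices(len(cortical), k=1)
    record["plv_mean"] = float(fc_ctx[iu].mean())
    record["plv_std"] = float(fc_ctx[iu].std())

    if reference_target is not None:
        try:
            record["r_plv"] = fc_similarity(fc_ctx, reference_target.fc.values)
        except ValueError:
            record["r_plv"] = np.nan
            record["disconnected_fc"] = True
        try:
            dfc = dfc_matrix(x[cortical], res.fs)
            record["ksd"] = ks_distance(dfc.upper_values(), reference_target.dfc_values)
        except ValueError:
            record["ksd"] = np.nan
    else:
        record["r_plv"] = np.nan
        record["ksd"] = np.nan

    spec = spectral_summary(x, res.fs)
    record["peak_hz"] = spec["peak_hz"]
    vmax_node, vmin_node = x.max(axis=1), x.min(axis=1)
    record["vmax_cortical"] = float(vmax_node[cortical].mean())
    record["vmin_cortical"] = float(vmin_node[cortical].mean())
    if drv.size:
        record["vmax_driver"] = float(vmax_node[drv].mean())
        record["vmin_driver"] = float(vmin_node[drv].mean())
        record["snr_driver"] = (
            snr(x, condition.driver_eta, node_set=drv) if condition.driver_eta > 0 else np.nan
        )
        record["rel_power"] = relative_power(spec, cortical, drv)
    else:
        record["vmax_driver"] = record["vmin_driver"] = np.nan
        record["snr_driver"] = record["rel_power"] = np.nan
    return record


def g_sweep(
    cohort,
    conditions,
    g_grid,
    reps: int,
    sim_config: SimulationConfig,
    targets,
    params: JRParameters = JRParameters(),
) -> pd.DataFrame:
    """Full factorial sweep: subject x condition x g x repetition.

    ``targets`` is one reference target per cohort subject (or a single
    shared target). Repetition seeds derive deterministically from
    ``sim_config.seed`` via (subject, condition, grid index, rep), so any
    record is reproducible in isolation.
    """
    if len(np.atleast_1d(g_grid)) == 0 or not conditions:
        raise ValueError("empty grid or condition list")
    if isinstance(targets, PseudoEmpiricalTarget) or targets is None:
        targets = [targets] * len(cohort)
    rows = []
    for si, (sc, target) in enumerate(zip(cohort, targets)):
        for ci, cond in enumerate(conditions):
            for gi, g in enumerate(np.asarray(g_grid, dtype=float)):
                for rep in range(reps):
                    cfg = replace(sim_config, seed=derive_seed(sim_config.seed, si, ci, gi, rep))
                    rec = run_trial(sc, cond, g, cfg, target, params=params)
                    rec["rep"] = rep
                    rows.append(rec)
    return pd.DataFrame(rows)


def grid_exploration(
    sc: StructuralConnectome,
    vary: str,
    vary_grid,
    g_grid,
    sim_config: SimulationConfig,
    target: PseudoEmpiricalTarget | None,
    base_condition: Condition | None = None,
    params: JRParameters = JRParameters(),
) -> pd.DataFrame:
    """2-D exploration of (driver_p | driver_eta) x g on one subject.

    Returns one row per grid cell with the heatmap panel set: r_PLV, mean
    and std of cortical PLV entries, spectral peak, driver SNR and the
    cortical bifurcation extrema.
    """
    if vary not in ("driver_p", "driver_eta"):
        raise ValueError("vary must be 'driver_p' or 'driver_eta'")
    cond0 = base_condition or Condition()
    rows = []
    for vi, value in enumerate(np.asarray(vary_grid, dtype=float)):
        cond = replace(cond0, **{vary: float(value)})
        for gi, g in enumerate(np.asarray(g_grid, dtype=float)):
            cfg = replace(sim_config, seed=derive_seed(sim_config.seed, vi, gi))
            rec = run_trial(sc, cond, g, cfg, target, params=params)
            rec[vary] = float(value)
            rows.append(rec)
    return pd.DataFrame(rows)


def split_regimes(
    sweep_table: pd.DataFrame,
    method: str = "fixed_threshold",
    threshold: float = 7.0,
    oscillation_tol: float = 2.0,
) -> pd.DataFrame:
    """Label every record prebifurcation ('pre') or postbifurcation ('post').

    ``fixed_threshold`` labels ``g < threshold`` as prebifurcation.
    ``auto`` finds, per (subject, condition) trace, the first coupling at
    which the repetition-averaged cortical peak-to-peak amplitude exceeds
    ``oscillation_tol`` (mV); everything from that coupling on is
    postbifurcation, everything below it prebifurcation.
    """
    out = sweep_table.copy()
    if method == "fixed_threshold":
        out["regime"] = np.where(out["g"] < threshold, "pre", "post")
        return out
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    out["regime"] = "pre"
    for (_, _), idx in out.groupby(["subject", "condition"]).groups.items():
        sub = out.loc[idx]
        mean_amp = (sub["vmax_cortical"] - sub["vmin_cortical"]).groupby(sub["g"]).mean()
        above = mean_amp[mean_amp > oscillation_tol]
        if len(above):
            g_onset = above.index.min()
            out.loc[idx[sub["g"] >= g_onset], "regime"] = "post"
    return out


def working_point(
    sweep_table: pd.DataFrame,
    metric: str = "r_plv",
    regime: str = "pre",
) -> pd.DataFrame:
    """Best repetition-averaged record per subject x condition in a regime.

    ``metric='r_plv'`` takes the argmax, ``metric='ksd'`` the argmin; ties
    break toward the lower coupling. Requires a regime-labeled table.
    """
    if "regime" not in sweep_table.columns:
        raise ValueError("sweep table lacks regime labels; run split_regimes first")
    sub = sweep_table[sweep_table["regime"] == regime]
    if sub.empty:
        raise ValueError(f"no records in regime {regime!r}")
    value_cols = [c for c in sub.columns if sub[c].dtype.kind in "fc"]
    avg = (
        sub.groupby(["subject", "condition", "g"], as_index=False)[value_cols]
        .mean()
        .sort_values("g", kind="stable")
    )
    rows = []
    for (subject, cond), grp in avg.groupby(["subject", "condition"]):
        vals = grp[metric]
        if vals.isna().all():
            continue
        idx = vals.idxmax() if metric != "ksd" else vals.idxmin()
        rows.append(grp.loc[idx])
    return pd.DataFrame(rows).reset_index(drop=True)
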