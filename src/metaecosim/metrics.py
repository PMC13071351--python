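"""Emergent flow, regulation and function metrics.

Net spatial flows identify *source* patches (net exporters of a
compartment: negative time-averaged flow term) and *sink* patches (net
importers: positive).  The net trophic effect E_i of spatial coupling on
producer regulation compares secondary- and primary-production shifts
against an uncoupled reference run of the same parameters:

    E_i = [<C_i f_C(P_i)>_coupled - <C_i f_C(P_i)>_ref]
        - [<P_i f_P(N_i)>_coupled - <P_i f_P(N_i)>_ref]

E_i > 0 means spatial flows strengthen grazing relative to uptake (net
top-down impact on producers); E_i < 0 the reverse (net bottom-up).

Local ecosystem function is measured as time-averaged primary production
<P f_P(N)>, secondary production <C f_C(P)> and nutrient retention
(turnover time): total local stocks divided by the instantaneous rate at
which nutrients leave the meta-ecosystem through that patch
(L_i = e_N N_i + (1-r_P) m_P P_i + (1-r_C) m_C C_i).  Spatial transfers
are not counted as losses: they stay inside the system.  Local retention
averages the ratio over time; meta-level retention uses the pooled ratio
<sum stocks / sum losses>.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelParams, uptake_consumer, uptake_producer
from .simulate import Trajectory
from .topology import MetaTopology

__all__ = [
    "FluxAndFunctionSummary",
    "net_flows",
    "source_sink_labels",
    "trophic_effect",
    "local_functions",
    "meta_functions",
    "compute_summary",
]

#: Net flows smaller than this are reported as neutral (no net exchange).
FLOW_TOL = 1e-10


def _trap_mean(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.trapezoid(y, t, axis=0) / (t[-1] - t[0])


def net_flows(
    traj: Trajectory, params: ModelParams, topo: MetaTopology
) -> dict[str, np.ndarray]:
    """Per-patch time-averaged net spatial flow for N and C.

    The instantaneous flow term for patch *i* and compartment *x* is
    ``d_x * sum_j s_x[i, j] * x_j``; because it is linear in the stocks,
    its time average equals the term evaluated at the time-averaged
    stocks.  Negative = net exporter (source); positive = net importer
    (sink).
    """
    t = traj.t_window
    X = traj.X_window
    n = topo.n
    mean_N = _trap_mean(t, X[:, :n])
    mean_C = _trap_mean(t, X[:, 2 * n :])
    return {
        "N": params.d_N * (topo.S_N @ mean_N),
        "C": np.asarray(params.d_C) * (topo.S_C @ mean_C),
    }


def source_sink_labels(flows: dict[str, np.ndarray]) -> dict[str, list[str]]:
    """Map net flows to 'source' / 'sink' / 'neutral' per compartment."""
    out = {}
    for comp, f in flows.items():
        out[comp] = [
            "source" if v < -FLOW_TOL else "sink" if v > FLOW_TOL else "neutral"
            for v in f
        ]
    return out


def _production_means(
    traj: Trajectory, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged primary and secondary production per patch."""
    t = traj.t_window
    N = traj.compartment("N")
    P = traj.compartment("P")
    C = traj.compartment("C")
    primary = _trap_mean(t, P * uptake_producer(N, params))
    secondary = _trap_mean(t, C * uptake_consumer(P, params))
    return primary, secondary


def trophic_effect(
    traj_coupled: Trajectory,
    traj_reference: Trajectory,
    params: ModelParams,
) -> np.ndarray:
    """Net effect E_i of spatial flows on producer regulation, per patch.

    ``traj_reference`` must be a run of the identical non-spatial
    parameterization with all spatial rates zero.
    """
    ref = traj_reference.params
    for name in ("I_N", "e_N", "m_P", "m_C", "a_P", "b_P", "a_C", "b_C",
                 "r_P", "r_C"):
        if getattr(ref, name) != getattr(params, name):
            raise ValueError(
                f"reference run disagrees on parameter {name}: "
                f"{getattr(ref, name)} != {getattr(params, name)}"
            )
    if ref.d_N != 0.0 or np.any(ref.d_C != 0.0) or ref.d_P != 0.0:
        raise ValueError("reference run must have all spatial rates zero")
    prim_c, sec_c = _production_means(traj_coupled, params)
    prim_r, sec_r = _production_means(traj_reference, params)
    return (sec_c - sec_r) - (prim_c - prim_r)


def local_functions(
    traj: Trajectory, params: ModelParams
) -> dict[str, np.ndarray]:
    """Per-patch production and nutrient retention (turnover time)."""
    t = traj.t_window
    N = traj.compartment("N")
    P = traj.compartment("P")
    C = traj.compartment("C")
    primary, secondary = _production_means(traj, params)
    losses = (
        params.e_N * N
        + (1.0 - params.r_P) * params.m_P * P
        + (1.0 - params.r_C) * params.m_C * C
    )
    stocks = N + P + C
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(losses > 0, stocks / np.where(losses > 0, losses, 1.0), 0.0)
    return {
        "primary_production": primary,
        "secondary_production": secondary,
        "nutrient_retention": _trap_mean(t, ratio),
        "mean_N": _trap_mean(t, N),
        "mean_P": _trap_mean(t, P),
        "mean_C": _trap_mean(t, C),
    }


def meta_functions(
    traj: Trajectory, params: ModelParams, locals_: dict[str, np.ndarray] | None = None
) -> dict[str, float]:
    """Meta-ecosystem totals: summed production, pooled retention, stocks."""
    if locals_ is None:
        locals_ = local_functions(traj, params)
    t = traj.t_window
    N = traj.compartment("N")
    P = traj.compartment("P")
    C = traj.compartment("C")
    tot_stocks = (N + P + C).sum(axis=1)
    tot_losses = (
        params.e_N * N
        + (1.0 - params.r_P) * params.m_P * P
        + (1.0 - params.r_C) * params.m_C * C
    ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.where(tot_losses > 0, tot_stocks / np.where(tot_losses > 0, tot_losses, 1.0), 0.0)
    c_total = C.sum(axis=1)
    return {
        "primary_production": float(locals_["primary_production"].sum()),
        "secondary_production": float(locals_["secondary_production"].sum()),
        "nutrient_retention": float(_trap_mean(t, pooled)),
        "total_N": float(locals_["mean_N"].sum()),
        "total_P": float(locals_["mean_P"].sum()),
        "total_C": float(locals_["mean_C"].sum()),
        "consumer_min": float(c_total.min()),
        "consumer_max": float(c_total.max()),
    }


@dataclass
class FluxAndFunctionSummary:
    """Per-patch flows, source/sink labels, E_i and functions, plus totals."""

    patch_names: list[str]
    net_resource_flow: np.ndarray
    net_dispersal: np.ndarray
    source_sink: dict[str, list[str]]
    E: np.ndarray | None
    local: dict[str, np.ndarray]
    meta: dict[str, float]
    context: dict = field(default_factory=dict)

    def to_frame(self):
        """Tidy per-patch table (one row per patch)."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "patch": self.patch_names,
                "net_resource_flow": self.net_resource_flow,
                "net_dispersal": self.net_dispersal,
                "nutrient_role": self.source_sink["N"],
                "consumer_role": self.source_sink["C"],
                "primary_production": self.local["primary_production"],
                "secondary_production": self.local["secondary_production"],
                "nutrient_retention": self.local["nutrient_retention"],
                "mean_N": self.local["mean_N"],
                "mean_P": self.local["mean_P"],
                "mean_C": self.local["mean_C"],
            }
        )
        if self.E is not None:
            df["E"] = self.E
        for k, v in self.context.items():
            df[k] = v
        return df

    def to_json_dict(self) -> dict:
        return {
            "meta": self.meta,
            "context": self.context,
        }


def compute_summary(
    traj: Trajectory,
    params: ModelParams,
    topo: MetaTopology,
    traj_reference: Trajectory | None = None,
    context: dict | None = None,
) -> FluxAndFunctionSummary:
    """Bundle all emergent metrics for one classified run."""
    flows = net_flows(traj, params, topo)
    loc = local_functions(traj, params)
    return FluxAndFunctionSummary(
        patch_names=topo.patch_names,
        net_resource_flow=flows["N"],
        net_dispersal=flows["C"],
        source_sink=source_sink_labels(flows),
        E=(
            trophic_effect(traj, traj_reference, params)
            if traj_reference is not None
            else None
        ),
        local=loc,
        meta=meta_functions(traj, params, loc),
        context=dict(context or {}),
    )
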