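"""Numerical integration and initial-condition ensembles.

Integration uses LSODA (``scipy.integrate.odeint``), which runs a
non-stiff Adams method and switches automatically to stiff BDF when the
step size collapses, with a compiled right-hand side.  Default tolerances
are tight (rtol 1e-8, atol 1e-10) because downstream classification
compares patches at much coarser tolerances and must not be confounded by
solver error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

from ._kernels import pack_params, rhs_odeint
from .model import MetaState, ModelParams, closed_ecosystem_equilibrium
from .topology import MetaTopology

__all__ = [
    "Trajectory",
    "InitialConditionEnsemble",
    "IntegrationError",
    "integrate",
    "continue_integration",
    "sample_initial_conditions",
    "default_ic_ranges",
]

#: Solver excursions below this are treated as failure, not clipped.
NEGATIVITY_SLACK = -1e-9


class IntegrationError(RuntimeError):
    """Integration failed; carries the offending parameter set."""

    def __init__(self, message: str, params: ModelParams | None = None):
        super().__init__(message)
        self.params = params


@dataclass
class Trajectory:
    """Time-stamped states of the full meta-ecosystem.

    ``X`` has shape (n_times, 3n) in the flat [N..., P..., C...] layout.
    ``transient_end`` is the index of the first sample of the evaluation
    window (everything before it is burn-in).
    """

    t: np.ndarray
    X: np.ndarray
    params: ModelParams
    topo: MetaTopology
    transient_end: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.X.min() < NEGATIVITY_SLACK:
            raise IntegrationError(
                f"state went negative ({self.X.min():.3g}); "
                "integration considered failed",
                self.params,
            )

    @property
    def n_patches(self) -> int:
        return self.topo.n

    # evaluation-window views (clipped for reporting)
    @property
    def t_window(self) -> np.ndarray:
        return self.t[self.transient_end :]

    @property
    def X_window(self) -> np.ndarray:
        return np.clip(self.X[self.transient_end :], 0.0, None)

    def state_at(self, idx: int) -> MetaState:
        return MetaState.from_vector(np.clip(self.X[idx], 0.0, None), self.n_patches)

    def compartment(self, name: str) -> np.ndarray:
        """Window samples of one compartment, shape (n_times, n_patches)."""
        k = {"N": 0, "P": 1, "C": 2}[name]
        n = self.n_patches
        return self.X_window[:, k * n : (k + 1) * n]

    def to_frame(self):
        """Tidy table: columns t, patch, type, location, N, P, C."""
        import pandas as pd

        n = self.n_patches
        rows = []
        Xc = np.clip(self.X, 0.0, None)
        for i in range(n):
            rows.append(
                pd.DataFrame(
                    {
                        "t": self.t,
                        "patch": self.topo.patch_names[i],
                        "type": self.topo.type_label[i],
                        "location": self.topo.location_label[i],
                        "N": Xc[:, i],
                        "P": Xc[:, n + i],
                        "C": Xc[:, 2 * n + i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _integrate_raw(
    y0: np.ndarray,
    t_pts: np.ndarray,
    params: ModelParams,
    topo: MetaTopology,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """odeint wrapper returning states at ``t_pts`` (t_pts[0] = start)."""
    out, info = odeint(
        rhs_odeint,
        y0,
        t_pts,
        args=(
            pack_params(params),
            topo.S_N,
            topo.S_C,
            topo.S_P,
            np.asarray(params.d_C, dtype=float),
        ),
        rtol=rtol,
        atol=atol,
        mxstep=10**8,
        full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"LSODA failed: {info['message']} (params={params.to_dict()})",
            params,
        )
    return out


def integrate(
    params: ModelParams,
    topo: MetaTopology,
    x0: MetaState,
    t_end: float,
    t_transient: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    window_dt: float = 1.25,
    transient_samples: int = 64,
) -> Trajectory:
    """Integrate from ``x0``, separating burn-in from evaluation window.

    The window is sampled every ``window_dt`` time units (dense enough to
    resolve extrema of the limit cycles seen here, whose periods are of
    order 10^2); the burn-in is sampled coarsely.
    """
    x0.require_nonnegative()
    if not 0 <= t_transient < t_end:
        raise ValueError("need 0 <= t_transient < t_end")
    y0 = x0.to_vector()
    n_win = max(int(np.ceil((t_end - t_transient) / window_dt)), 20) + 1
    t_trans = np.linspace(0.0, t_transient, max(transient_samples, 2))
    t_win = np.linspace(t_transient, t_end, n_win)
    if t_transient > 0:
        X_trans = _integrate_raw(y0, t_trans, params, topo, rtol, atol)
        X_win = _integrate_raw(X_trans[-1], t_win, params, topo, rtol, atol)
        t = np.concatenate([t_trans[:-1], t_win])
        X = np.vstack([X_trans[:-1], X_win])
        transient_end = len(t_trans) - 1
    else:
        X = _integrate_raw(y0, t_win, params, topo, rtol, atol)
        t, transient_end = t_win, 0
    return Trajectory(t, X, params, topo, transient_end=transient_end)


def continue_integration(
    traj: Trajectory,
    t_extra: float,
    window: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    window_dt: float = 1.25,
) -> Trajectory:
    """Continue a trajectory by ``t_extra`` and re-window the final stretch.

    Used by the attractor-settling loop: the returned trajectory's
    evaluation window is the last ``window`` time units.
    """
    t0 = traj.t[-1]
    y0 = traj.X[-1]
    t_gap = t_extra - window
    if t_gap > 0:
        y0 = _integrate_raw(
            y0, np.array([t0, t0 + t_gap]), traj.params, traj.topo, rtol, atol
        )[-1]
        t0 = t0 + t_gap
    n_win = int(np.ceil(window / window_dt)) + 1
    t_win = np.linspace(t0, t0 + window, n_win)
    X_win = _integrate_raw(y0, t_win, traj.params, traj.topo, rtol, atol)
    return Trajectory(
        np.concatenate([[traj.t[0]], t_win]),
        np.vstack([traj.X[0], X_win]),
        traj.params,
        traj.topo,
        transient_end=1,
    )


@dataclass
class InitialConditionEnsemble:
    """Seeded random initial states for the stable-state protocol."""

    seed: int
    draws: list[MetaState] = field(default_factory=list)
    ranges: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.draws)


def default_ic_ranges(params: ModelParams) -> dict[str, tuple[float, float]]:
    """Per-compartment sampling ranges (0, 2 x closed-patch equilibrium].

    Wide enough to bracket all attractors seen at baseline and to discover
    both branches of the bistable heterogeneous equilibrium.
    """
    N_star, P_star, C_star = closed_ecosystem_equilibrium(params)
    return {
        "N": (0.0, 2.0 * N_star),
        "P": (0.0, 2.0 * P_star),
        "C": (0.0, 2.0 * C_star),
    }


def sample_initial_conditions(
    seed: int,
    n_draws: int,
    ranges: dict[str, tuple[float, float]],
    n_patches: int = 4,
) -> InitialConditionEnsemble:
    """Draw ``n_draws`` independent uniform initial states.

    Each patch-compartment value is uniform on the half-open interval
    (lo, hi]; draws are strictly positive and reproducible given ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    for comp in ("N", "P", "C"):
        lo, hi = ranges[comp]
        if lo < 0 or hi <= 0 or hi <= lo:
            raise ValueError(
                f"range for {comp} must satisfy 0 <= lo < hi with hi > 0"
            )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = []
    for _ in range(n_draws):
        vals = {}
        for comp in ("N", "P", "C"):
            lo, hi = ranges[comp]
            u = rng.uniform(size=n_patches)  # in [0, 1)
            vals[comp] = hi - u * (hi - lo)  # in (lo, hi]
        draws.append(MetaState(vals["N"], vals["P"], vals["C"]))
    return InitialConditionEnsemble(seed=seed, draws=draws, ranges=dict(ranges))
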