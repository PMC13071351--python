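"""Sweep pipelines: state diagrams, bifurcation transects, dispersal plane.

Every grid cell runs the full stable-state protocol: a seeded ensemble of
random initial conditions, adaptive settling of each trajectory, and an
ensemble verdict (consensus state, attractor count, bistability).  Cells
are independent and processed row-major; results can be written
incrementally so long sweeps are crash-safe.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    EnsembleVerdict,
    SettleSettings,
    classify_ensemble,
    settle_and_classify,
)
from .metrics import compute_summary
from .model import ModelParams
from .simulate import default_ic_ranges, sample_initial_conditions
from .topology import (
    MetaTopology,
    fully_connected_resource_topology,
    nested_topology,
    validate,
)

__all__ = [
    "SweepSpec",
    "state_diagram",
    "bifurcation_transect",
    "dispersal_plane",
    "run_functions_transect",
    "smallest_dN_with_state",
    "critical_dispersal",
    "PRESETS",
    "write_manifest",
]

logger = logging.getLogger("metaecosim")
if not logger.handlers:  # default: log to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

_HET_CODES = ("HET_OSC", "HET_EQ")


@dataclass
class SweepSpec:
    """What to sweep and under which protocol.

    ``d_N_values`` and ``d_C_values`` are the grid axes (``d_C_values``
    holds equal-for-both-types dispersal rates; the dispersal plane uses
    ``d_CA_values`` x ``d_CB_values`` instead).  ``n_ic`` initial
    conditions are drawn per cell from a cell-specific stream derived
    from ``seed``.
    """

    topology: str = "nested"
    n_locations: int = 2
    flow_normalization: str = "donor_split"
    d_N_values: Sequence[float] = field(default_factory=lambda: [0.0])
    d_C_values: Sequence[float] = field(default_factory=lambda: [0.4])
    d_CA_values: Sequence[float] | None = None
    d_CB_values: Sequence[float] | None = None
    n_ic: int = 50
    seed: int = 1
    settle: SettleSettings = field(default_factory=SettleSettings)
    base_params: ModelParams | None = None

    def build_topology(self) -> MetaTopology:
        builder = {
            "nested": nested_topology,
            "fully_connected": fully_connected_resource_topology,
        }[self.topology]
        return builder(self.n_locations, self.flow_normalization)

    def cell_params(self, d_N: float, d_CA: float, d_CB: float) -> ModelParams:
        base = self.base_params or ModelParams()
        d_C = np.tile([d_CA, d_CB], self.n_locations)
        return base.replace(d_N=float(d_N), d_C=d_C)

    def cell_seed(self, index: int) -> int:
        # distinct deterministic stream per cell, kept below 2**31
        return int((self.seed * 1_000_003 + 7919 * index) % (2**31 - 1))


def _cell_verdict(
    spec: SweepSpec,
    topo: MetaTopology,
    d_N: float,
    d_CA: float,
    d_CB: float,
    index: int,
) -> tuple[EnsembleVerdict, list]:
    params = spec.cell_params(d_N, d_CA, d_CB)
    problems = validate(topo, params)
    if problems:
        raise ValueError("; ".join(problems))
    ranges = default_ic_ranges(params)
    ens = sample_initial_conditions(
        spec.cell_seed(index), spec.n_ic, ranges, n_patches=topo.n
    )
    reports = [
        settle_and_classify(params, topo, x0, spec.settle) for x0 in ens.draws
    ]
    return classify_ensemble(reports, topo), reports


def _append_row(out_path: Path | None, row: dict, first: bool) -> None:
    if out_path is None:
        return
    pd.DataFrame([row]).to_csv(
        out_path, mode="w" if first else "a", header=first, index=False
    )


def state_diagram(
    spec: SweepSpec,
    out_path: str | Path | None = None,
    stop_condition: Callable[[list[dict]], bool] | None = None,
) -> pd.DataFrame:
    """Grid of ensemble state codes over (d_N, d_C).

    Individual cell failures are logged and coded FAILED; they never
    abort the grid.  ``stop_condition`` (called on the accumulated rows)
    allows ascending scans to stop early once the states of interest have
    been found.
    """
    topo = spec.build_topology()
    out_path = Path(out_path) if out_path else None
    rows: list[dict] = []
    index = 0
    for d_C in spec.d_C_values:
        for d_N in spec.d_N_values:
            row = {"d_N": float(d_N), "d_C": float(d_C)}
            try:
                verdict, _ = _cell_verdict(spec, topo, d_N, d_C, d_C, index)
                row.update(verdict.to_json_dict())
            except Exception as exc:  # noqa: BLE001 - cell isolation
                logger.warning("cell d_N=%s d_C=%s failed: %s", d_N, d_C, exc)
                row.update(
                    state_code="FAILED",
                    n_attractors=0,
                    bistable=False,
                    n_inconclusive=spec.n_ic,
                )
            _append_row(out_path, row, first=index == 0)
            rows.append(row)
            logger.info(
                "cell d_N=%.3g d_C=%.3g -> %s", d_N, d_C, row["state_code"]
            )
            index += 1
            if stop_condition is not None and stop_condition(rows):
                return pd.DataFrame(rows)
    return pd.DataFrame(rows)


def bifurcation_transect(
    spec: SweepSpec,
    d_C: float,
    out_path: str | Path | None = None,
    stop_condition: Callable[[list[dict]], bool] | None = None,
) -> pd.DataFrame:
    """Per-d_N consensus state plus meta-level consumer min/max.

    On a point equilibrium the consumer minimum equals the maximum; on a
    cycle they trace the envelope used in bifurcation diagrams.
    """
    topo = spec.build_topology()
    out_path = Path(out_path) if out_path else None
    rows: list[dict] = []
    for index, d_N in enumerate(spec.d_N_values):
        row = {"d_N": float(d_N), "d_C": float(d_C)}
        try:
            verdict, reports = _cell_verdict(spec, topo, d_N, d_C, d_C, index)
            ok = [r for r in reports if not r.inconclusive]
            row.update(verdict.to_json_dict())
            row["C_meta_min"] = min(r.meta_c_min for r in ok) if ok else np.nan
            row["C_meta_max"] = max(r.meta_c_max for r in ok) if ok else np.nan
        except Exception as exc:  # noqa: BLE001
            logger.warning("transect d_N=%s failed: %s", d_N, exc)
            row.update(
                state_code="FAILED",
                n_attractors=0,
                bistable=False,
                n_inconclusive=spec.n_ic,
                C_meta_min=np.nan,
                C_meta_max=np.nan,
            )
        _append_row(out_path, row, first=index == 0)
        rows.append(row)
        logger.info("transect d_N=%.3g -> %s", d_N, row["state_code"])
        if stop_condition is not None and stop_condition(rows):
            break
    return pd.DataFrame(rows)


def dispersal_plane(
    spec: SweepSpec, d_N: float, out_path: str | Path | None = None
) -> pd.DataFrame:
    """Grid of state codes over ecosystem-specific dispersal (d_CA, d_CB)."""
    if spec.d_CA_values is None or spec.d_CB_values is None:
        raise ValueError("dispersal_plane needs d_CA_values and d_CB_values")
    topo = spec.build_topology()
    out_path = Path(out_path) if out_path else None
    rows: list[dict] = []
    index = 0
    for d_CB in spec.d_CB_values:
        for d_CA in spec.d_CA_values:
            row = {"d_N": float(d_N), "d_CA": float(d_CA), "d_CB": float(d_CB)}
            try:
                verdict, _ = _cell_verdict(spec, topo, d_N, d_CA, d_CB, index)
                row.update(verdict.to_json_dict())
            except Exception as exc:  # noqa: BLE001
                logger.warning(
                    "cell d_CA=%s d_CB=%s failed: %s", d_CA, d_CB, exc
                )
                row.update(
                    state_code="FAILED",
                    n_attractors=0,
                    bistable=False,
                    n_inconclusive=spec.n_ic,
                )
            _append_row(out_path, row, first=index == 0)
            rows.append(row)
            logger.info(
                "cell d_CA=%.3g d_CB=%.3g -> %s", d_CA, d_CB, row["state_code"]
            )
            index += 1
    return pd.DataFrame(rows)


def run_functions_transect(
    spec: SweepSpec, d_C: float, out_path: str | Path | None = None
) -> pd.DataFrame:
    """Per-patch flows, E_i and functions along a d_N transect.

    The trophic-effect reference (the identical parameterization with all
    spatial rates zero) is integrated once and shared across the
    transect.  For each d_N one member of the seeded ensemble is settled
    to the attractor; per-patch values are reported in the raw patch
    order (orientation of the bistable pair is whatever that initial
    condition selected).
    """
    topo = spec.build_topology()
    ref_params = spec.cell_params(0.0, 0.0, 0.0)
    ranges = default_ic_ranges(ref_params)
    ens0 = sample_initial_conditions(
        spec.cell_seed(0), 1, ranges, n_patches=topo.n
    )
    _, ref_traj = settle_and_classify(
        ref_params, topo, ens0.draws[0], spec.settle, return_trajectory=True
    )
    frames = []
    for index, d_N in enumerate(spec.d_N_values):
        params = spec.cell_params(d_N, d_C, d_C)
        ens = sample_initial_conditions(
            spec.cell_seed(index), 1, default_ic_ranges(params), n_patches=topo.n
        )
        report, traj = settle_and_classify(
            params, topo, ens.draws[0], spec.settle, return_trajectory=True
        )
        summary = compute_summary(
            traj,
            params,
            topo,
            traj_reference=ref_traj,
            context={
                "d_N": float(d_N),
                "d_CA": d_C,
                "d_CB": d_C,
                "topology": topo.name,
                "state_code": report.state_code,
            },
        )
        frames.append(summary.to_frame())
        logger.info("functions d_N=%.3g -> %s", d_N, report.state_code)
    df = pd.concat(frames, ignore_index=True)
    if out_path:
        df.to_csv(out_path, index=False)
    return df


# ------------------------- threshold extraction -------------------------


def smallest_dN_with_state(
    df: pd.DataFrame, codes: Sequence[str] = _HET_CODES
) -> float | None:
    """Smallest grid d_N whose cell carries one of the given state codes."""
    hit = df[df["state_code"].isin(list(codes))]
    return float(hit["d_N"].min()) if len(hit) else None


def critical_dispersal(
    df: pd.DataFrame, axis: str, other_axis: str, other_value: float,
    code: str = "HET_EQ",
) -> float | None:
    """Smallest dispersal rate on ``axis`` with state ``code``, at a fixed
    value of the other axis (the critical rate below which the state is
    lost)."""
    sel = df[np.isclose(df[other_axis], other_value)]
    hit = sel[sel["state_code"] == code]
    return float(hit[axis].min()) if len(hit) else None


# ------------------------------ presets ---------------------------------


def _grid(start: float, stop: float, step: float) -> list[float]:
    n = int(round((stop - start) / step))
    return [round(start + k * step, 10) for k in range(n + 1)]


#: Named sweep presets.  The replication presets pin the published grids
#: (ensemble of 50; multi-hour runs); "ci" is a coarse smoke-test grid.
PRESETS: dict[str, dict] = {
    "state-grid": dict(
        d_N_values=_grid(0.0, 5.0, 0.05),
        d_C_values=_grid(0.02, 0.5, 0.02),
        n_ic=50,
    ),
    "transects": dict(
        d_N_values=_grid(0.0, 5.0, 0.05),
        d_C_values=[0.1, 0.4],
        n_ic=50,
    ),
    "functions": dict(
        d_N_values=_grid(0.0, 5.0, 0.05),
        d_C_values=[0.4],
        n_ic=50,
    ),
    "dispersal-plane": dict(
        d_N_values=[5.0],
        d_CA_values=_grid(0.02, 0.5, 0.02),
        d_CB_values=_grid(0.02, 0.5, 0.02),
        n_ic=50,
    ),
    "ci": dict(
        d_N_values=[0.0, 1.0, 3.0, 5.0],
        d_C_values=[0.1, 0.4],
        n_ic=8,
    ),
}


def spec_from_preset(name: str, seed: int = 1, **overrides) -> SweepSpec:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    spec = SweepSpec(seed=seed, **kwargs)
    if name == "ci":
        spec = replace(spec, settle=spec.settle.fast())
    return spec


def write_manifest(path: str | Path, spec: SweepSpec, extra: dict | None = None) -> None:
    """Machine-readable record of everything that determined a sweep."""
    from dataclasses import asdict

    settle = asdict(spec.settle)
    manifest = {
        "package": "metaecosim",
        "version": __version__,
        "topology": spec.topology,
        "n_locations": spec.n_locations,
        "flow_normalization": spec.flow_normalization,
        "d_N_values": [float(v) for v in spec.d_N_values],
        "d_C_values": [float(v) for v in spec.d_C_values],
        "d_CA_values": (
            [float(v) for v in spec.d_CA_values] if spec.d_CA_values is not None else None
        ),
        "d_CB_values": (
            [float(v) for v in spec.d_CB_values] if spec.d_CB_values is not None else None
        ),
        "n_ic": spec.n_ic,
        "seed": spec.seed,
        "settle": settle,
        "params": (spec.base_params or ModelParams()).to_dict(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
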