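"""Connectivity matrices for the meta-ecosystem.

A :class:`MetaTopology` holds one n-by-n connectivity matrix per
compartment: entry ``s_ij >= 0`` (i != j) is the flow entering patch *i*
from patch *j*, and the diagonal ``s_ii <= 0`` is the flow leaving patch
*i*.  Every column sums to zero so that transported mass is conserved in
transit.

Two builders cover the study designs:

* :func:`nested_topology` -- resource flows couple the type-A and type-B
  patch *within* each location, while consumer dispersal couples same-type
  patches *across* locations ("spatially nested": small-scale resource
  links embedded in a larger-scale dispersal network).
* :func:`fully_connected_resource_topology` -- identical dispersal, but
  resource flows connect *every* pair of patches regardless of location
  (the control design that removes the scale contrast).

The patch ordering convention in all I/O is (A-loc1, B-loc1, A-loc2,
B-loc2, ...): type A on even indices, type B on odd indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import ModelParams

__all__ = [
    "MetaTopology",
    "nested_topology",
    "fully_connected_resource_topology",
    "custom_topology",
    "validate",
]

_COLSUM_TOL = 1e-12


@dataclass
class MetaTopology:
    """Patch labels plus per-compartment connectivity matrices."""

    n: int
    type_label: list[str]
    location_label: list[int]
    S_N: np.ndarray
    S_C: np.ndarray
    S_P: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.S_P is None:
            self.S_P = np.zeros((self.n, self.n))
        for attr in ("S_N", "S_C", "S_P"):
            M = np.asarray(getattr(self, attr), dtype=float)
            if M.shape != (self.n, self.n):
                raise ValueError(f"{attr} must be {self.n}x{self.n}")
            setattr(self, attr, M)
        if len(self.type_label) != self.n or len(self.location_label) != self.n:
            raise ValueError("label lengths must equal patch count")

    # --------------------------- conveniences ---------------------------
    @property
    def patch_names(self) -> list[str]:
        return [
            f"{t}{loc}" for t, loc in zip(self.type_label, self.location_label)
        ]

    @property
    def n_locations(self) -> int:
        return len(set(self.location_label))

    def same_type_groups(self) -> dict[str, np.ndarray]:
        """Patch indices grouped by ecosystem type ("homologous" patches)."""
        groups: dict[str, list[int]] = {}
        for i, t in enumerate(self.type_label):
            groups.setdefault(t, []).append(i)
        return {t: np.array(ix) for t, ix in groups.items()}

    def location_swap_permutation(self) -> np.ndarray:
        """Permutation exchanging locations 1 and 2 (two-location case).

        This is the spatial symmetry behind the mirror-image bistable
        equilibria: applying it to any trajectory yields another valid
        trajectory.
        """
        locs = sorted(set(self.location_label))
        if len(locs) != 2:
            raise ValueError(
                "location swap is defined for two-location topologies"
            )
        perm = np.empty(self.n, dtype=int)
        for i in range(self.n):
            target_loc = locs[1] if self.location_label[i] == locs[0] else locs[0]
            matches = [
                j
                for j in range(self.n)
                if self.type_label[j] == self.type_label[i]
                and self.location_label[j] == target_loc
            ]
            if len(matches) != 1:
                raise ValueError("topology is not location-symmetric")
            perm[i] = matches[0]
        return perm

    # ---------------------------- serialization --------------------------
    def to_config_block(self) -> dict:
        """Plain-text representation (rows = receiving patch)."""
        return {
            "name": self.name,
            "type_label": list(self.type_label),
            "location_label": [int(v) for v in self.location_label],
            "S_N": self.S_N.tolist(),
            "S_C": self.S_C.tolist(),
            "S_P": self.S_P.tolist(),
        }

    @classmethod
    def from_config_block(cls, block: dict) -> "MetaTopology":
        known = {"name", "type_label", "location_label", "S_N", "S_C", "S_P"}
        unknown = set(block) - known
        if unknown:
            raise KeyError(f"unknown topology key(s): {sorted(unknown)}")
        n = len(block["type_label"])
        return cls(
            n=n,
            type_label=list(block["type_label"]),
            location_label=list(block["location_label"]),
            S_N=np.asarray(block["S_N"], dtype=float),
            S_C=np.asarray(block["S_C"], dtype=float),
            S_P=np.asarray(block.get("S_P", np.zeros((n, n))), dtype=float),
            name=block.get("name", "custom"),
        )

    def to_csv(self, path_prefix: str) -> list[str]:
        """Write each connectivity matrix to ``<prefix>_S_<x>.csv``."""
        import pandas as pd

        paths = []
        for attr in ("S_N", "S_C", "S_P"):
            p = f"{path_prefix}_{attr}.csv"
            pd.DataFrame(
                getattr(self, attr),
                index=self.patch_names,
                columns=self.patch_names,
            ).to_csv(p)
            paths.append(p)
        return paths


def _donor_matrix(
    n: int, edges: Iterable[tuple[int, int]], normalization: str
) -> np.ndarray:
    """Symmetric connectivity from an undirected edge list.

    ``donor_split``: each connected patch exports at total (unit) rate and
    splits it equally among its receivers, so the realized per-patch
    emigration rate equals the compartment's rate constant regardless of
    degree.  ``per_link``: each link carries unit rate, so the diagonal is
    minus the degree.  Both conventions have zero column sums; they
    coincide for degree-1 graphs such as the 4-patch nested design.
    """
    M = np.zeros((n, n))
    for i, j in edges:
        if i == j:
            raise ValueError("self-links are not allowed")
        M[i, j] = 1.0
        M[j, i] = 1.0
    degree = M.sum(axis=0)
    if normalization == "donor_split":
        with np.errstate(divide="ignore", invalid="ignore"):
            M = np.where(degree > 0, M / degree, 0.0)
        np.fill_diagonal(M, np.where(degree > 0, -1.0, 0.0))
    elif normalization == "per_link":
        np.fill_diagonal(M, -degree)
    else:
        raise ValueError(
            "flow_normalization must be 'donor_split' or 'per_link'"
        )
    return M


def _labels(n_locations: int) -> tuple[list[str], list[int]]:
    types = ["A", "B"] * n_locations
    locs = [loc for loc in range(1, n_locations + 1) for _ in ("A", "B")]
    return types, locs


def _dispersal_edges(n_locations: int) -> list[tuple[int, int]]:
    """Same-type, cross-location dispersal links (complete within a type)."""
    edges = []
    for offset in (0, 1):  # type A then type B
        patches = [2 * k + offset for k in range(n_locations)]
        edges.extend(
            (patches[a], patches[b])
            for a in range(len(patches))
            for b in range(a + 1, len(patches))
        )
    return edges


def nested_topology(
    n_locations: int = 2, flow_normalization: str = "donor_split"
) -> MetaTopology:
    """Spatially nested topology (the main study design).

    Resource flows (``S_N``) connect the A-B pair within each location;
    consumer dispersal (``S_C``) connects same-type patches across
    locations.  With the default two locations every patch has degree one
    in both matrices, so the matrices are identical under either
    normalization convention.
    """
    if n_locations < 2:
        raise ValueError(
            "need at least two locations for cross-location dispersal"
        )
    n = 2 * n_locations
    types, locs = _labels(n_locations)
    resource_edges = [(2 * k, 2 * k + 1) for k in range(n_locations)]
    S_N = _donor_matrix(n, resource_edges, flow_normalization)
    S_C = _donor_matrix(n, _dispersal_edges(n_locations), flow_normalization)
    return MetaTopology(n, types, locs, S_N, S_C, name="nested")


def fully_connected_resource_topology(
    n_locations: int = 2, flow_normalization: str = "donor_split"
) -> MetaTopology:
    """Control design: resource flows between every pair of patches.

    Dispersal links are identical to :func:`nested_topology`; only the
    resource-flow matrix changes, so the two designs are directly
    comparable at equal rate constants.
    """
    if n_locations < 2:
        raise ValueError(
            "need at least two locations for cross-location dispersal"
        )
    n = 2 * n_locations
    types, locs = _labels(n_locations)
    resource_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    S_N = _donor_matrix(n, resource_edges, flow_normalization)
    S_C = _donor_matrix(n, _dispersal_edges(n_locations), flow_normalization)
    return MetaTopology(n, types, locs, S_N, S_C, name="fully_connected")


def custom_topology(
    type_label: Sequence[str],
    location_label: Sequence[int],
    resource_edges: Iterable[tuple[int, int]],
    dispersal_edges: Iterable[tuple[int, int]],
    producer_edges: Iterable[tuple[int, int]] = (),
    flow_normalization: str = "donor_split",
    name: str = "custom",
) -> MetaTopology:
    """Generalized builder for user-defined connection graphs."""
    n = len(type_label)
    return MetaTopology(
        n,
        list(type_label),
        list(location_label),
        _donor_matrix(n, resource_edges, flow_normalization),
        _donor_matrix(n, dispersal_edges, flow_normalization),
        _donor_matrix(n, producer_edges, flow_normalization),
        name=name,
    )


def validate(topo: MetaTopology, params: ModelParams | None = None) -> list[str]:
    """Check all structural invariants; returns a list of violations.

    Never raises: an empty list means the topology is valid (for the given
    parameters, if supplied).
    """
    out: list[str] = []
    for attr in ("S_N", "S_C", "S_P"):
        M = getattr(topo, attr)
        colsums = M.sum(axis=0)
        if np.any(np.abs(colsums) > _COLSUM_TOL):
            worst = int(np.argmax(np.abs(colsums)))
            out.append(
                f"{attr}: column {worst} sums to {colsums[worst]:.3g} "
                "(mass not conserved in transit)"
            )
        off = M - np.diag(np.diag(M))
        if np.any(off < 0):
            out.append(f"{attr}: negative off-diagonal entry")
        if np.any(np.diag(M) > 0):
            out.append(f"{attr}: positive diagonal entry")
    # dispersal must stay within an ecosystem type
    for i in range(topo.n):
        for j in range(topo.n):
            if i != j and topo.S_C[i, j] > 0:
                if topo.type_label[i] != topo.type_label[j]:
                    out.append(
                        f"S_C links patches {j}->{i} of different types "
                        f"({topo.type_label[j]} vs {topo.type_label[i]})"
                    )
    if params is not None:
        if params.n_patches != topo.n:
            out.append(
                f"params.d_C has {params.n_patches} entries for {topo.n} patches"
            )
        else:
            # patches joined by a dispersal link must share one rate,
            # otherwise the dispersal flux does not conserve consumers
            for i in range(topo.n):
                for j in range(i + 1, topo.n):
                    if (topo.S_C[i, j] > 0 or topo.S_C[j, i] > 0) and (
                        params.d_C[i] != params.d_C[j]
                    ):
                        out.append(
                            f"patches {i} and {j} are dispersal-linked but "
                            f"have different d_C ({params.d_C[i]} vs "
                            f"{params.d_C[j]})"
                        )
    return out
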