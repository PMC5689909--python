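"""Absorber models and water-equivalent path length (WEPL) bookkeeping.

Two absorber representations are supported: homogeneous slab stacks with
known relative stopping power (RSP), emulating water-equivalent plastic,
and 1-D voxel lines of CT numbers converted to RSP through a piecewise
linear Hounsfield-unit calibration.  WEPL at a geometric depth is the
line integral of RSP from the entrance surface, with partial slabs or
voxels pro-rated linearly.  Depth is measured from the entrance surface
along the beam axis; intervals are half-open ``[start, end)``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SlabPhantom",
    "VoxelLinePhantom",
    "HUCalibration",
    "DEFAULT_HU_CALIBRATION",
    "hu_to_rsp",
    "wepl_at",
    "depth_for_wepl",
    "water_phantom",
    "soft_tissue_ct_line",
]


@dataclass
class HUCalibration:
    """Piecewise-linear CT-number to relative-stopping-power conversion.

    Nodes are ordered (hu, rsp) pairs; conversion clamps at the end
    nodes.  The node (0, 1.0) — water — must be present.
    """

    nodes: list[tuple[float, float]]

    def __post_init__(self) -> None:
        hu = np.array([n[0] for n in self.nodes], dtype=float)
        rsp = np.array([n[1] for n in self.nodes], dtype=float)
        if hu.size < 2:
            raise ValueError("calibration needs at least two nodes")
        if not (np.diff(hu) > 0).all():
            raise ValueError("hu nodes must be strictly increasing")
        if (np.diff(rsp) < 0).any():
            raise ValueError("rsp must be non-decreasing")
        if not any(h == 0.0 and r == 1.0 for h, r in self.nodes):
            raise ValueError("calibration must pass through (0, 1.0)")
        self._hu, self._rsp = hu, rsp

    def __call__(self, hu) -> np.ndarray | float:
        return np.interp(hu, self._hu, self._rsp)


#: Two-segment soft-tissue calibration: slope 0.001 RSP/HU around water,
#: so a 20 HU shift maps to a 0.02 RSP shift.
DEFAULT_HU_CALIBRATION = HUCalibration(
    nodes=[(-1000.0, 0.001), (0.0, 1.0), (100.0, 1.10)]
)


def hu_to_rsp(hu, calibration: HUCalibration = DEFAULT_HU_CALIBRATION):
    """Convert CT number(s) to relative stopping power."""
    return calibration(hu)


@dataclass
class SlabPhantom:
    """Ordered stack of homogeneous slabs: (thickness_cm, rsp)."""

    slabs: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for t, r in self.slabs:
            if t <= 0:
                raise ValueError("slab thickness must be positive")
            if r <= 0:
                raise ValueError("slab rsp must be positive")

    @property
    def total_depth_cm(self) -> float:
        return float(sum(t for t, _ in self.slabs))

    @property
    def total_wepl_cm(self) -> float:
        return float(sum(t * r for t, r in self.slabs))

    def _boundaries(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.array([s[0] for s in self.slabs])
        r = np.array([s[1] for s in self.slabs])
        edges = np.concatenate([[0.0], np.cumsum(t)])
        wepl_edges = np.concatenate([[0.0], np.cumsum(t * r)])
        return edges, wepl_edges

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"slabs": [list(s) for s in self.slabs]}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SlabPhantom":
        with open(path) as fh:
            d = json.load(fh)
        return cls(slabs=[tuple(s) for s in d["slabs"]])


@dataclass
class VoxelLinePhantom:
    """1-D line of CT numbers along the beam axis."""

    voxel_size_cm: float
    hu_values: np.ndarray
    calibration: HUCalibration = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.voxel_size_cm <= 0:
            raise ValueError("voxel_size_cm must be positive")
        self.hu_values = np.asarray(self.hu_values, dtype=float)
        if self.hu_values.ndim != 1 or self.hu_values.size == 0:
            raise ValueError("hu_values must be a non-empty 1-D array")
        if not np.isfinite(self.hu_values).all():
            raise ValueError("hu_values must be finite")
        if self.calibration is None:
            self.calibration = DEFAULT_HU_CALIBRATION

    @property
    def total_depth_cm(self) -> float:
        return float(self.voxel_size_cm * self.hu_values.size)

    @property
    def rsp_values(self) -> np.ndarray:
        return np.asarray(self.calibration(self.hu_values), dtype=float)

    @property
    def total_wepl_cm(self) -> float:
        return float(self.rsp_values.sum() * self.voxel_size_cm)

    def _boundaries(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.hu_values.size
        edges = np.arange(n + 1) * self.voxel_size_cm
        wepl_edges = np.concatenate(
            [[0.0], np.cumsum(self.rsp_values) * self.voxel_size_cm]
        )
        return edges, wepl_edges

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# voxel_size_cm={self.voxel_size_cm}\n")
            for hu in self.hu_values:
                fh.write(f"{hu}\n")

    @classmethod
    def from_csv(cls, path, calibration: HUCalibration | None = None) -> "VoxelLinePhantom":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# voxel_size_cm="):
                raise ValueError("missing '# voxel_size_cm=' header line")
            voxel = float(header.split("=", 1)[1])
            hu = np.array([float(line) for line in fh if line.strip()])
        return cls(voxel_size_cm=voxel, hu_values=hu, calibration=calibration)


Phantom = SlabPhantom | VoxelLinePhantom


def wepl_at(phantom: Phantom, geometric_depth_cm) -> np.ndarray | float:
    """WEPL (cm) at geometric depth(s): line integral of RSP from surface."""
    scalar = np.isscalar(geometric_depth_cm)
    z = np.atleast_1d(np.asarray(geometric_depth_cm, dtype=float))
    edges, wepl_edges = phantom._boundaries()
    if (z < 0).any() or (z > edges[-1] + 1e-12).any():
        raise ValueError(
            f"depth outside phantom extent [0, {edges[-1]:g}] cm"
        )
    w = np.interp(z, edges, wepl_edges)
    return float(w[0]) if scalar else w


def depth_for_wepl(phantom: Phantom, wepl_cm) -> np.ndarray | float:
    """Geometric depth at which the given WEPL is accumulated (inverse map)."""
    scalar = np.isscalar(wepl_cm)
    w = np.atleast_1d(np.asarray(wepl_cm, dtype=float))
    edges, wepl_edges = phantom._boundaries()
    if (w < 0).any() or (w > wepl_edges[-1] + 1e-12).any():
        raise ValueError(
            f"wepl outside phantom total [0, {wepl_edges[-1]:g}] cm"
        )
    z = np.interp(w, wepl_edges, edges)
    return float(z[0]) if scalar else z


def water_phantom(thickness_cm: float = 40.0) -> SlabPhantom:
    """Homogeneous water-equivalent slab (RSP = 1)."""
    return SlabPhantom(slabs=[(thickness_cm, 1.0)])


def soft_tissue_ct_line(
    length_cm: float = 40.0,
    voxel_size_cm: float = 0.1,
    mean_hu: float = 40.0,
    sigma_hu: float = 20.0,
    seed: int = 0,
    calibration: HUCalibration | None = None,
) -> VoxelLinePhantom:
    """Synthetic abdominal soft-tissue CT line: Gaussian HU about a soft-
    tissue mean, no air cavities.  Stands in for a patient CT column."""
    rng = np.random.default_rng(seed)
    n = int(round(length_cm / voxel_size_cm))
    hu = rng.normal(mean_hu, sigma_hu, n)
    return VoxelLinePhantom(
        voxel_size_cm=voxel_size_cm, hu_values=hu, calibration=calibration
    )
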