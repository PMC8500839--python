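"""Rigid-body lattice geometry of tubulin dimers.

A microtubule (doublet) lattice is modelled as rigid copies of one reference
tubulin-dimer point set, indexed by protofilament (PF) and axial repeat.  The
inter-PF angle is the lateral rotation relating the rigid-body fits of two
adjacent-PF dimers; it is summarised over a few axial regions (two near the
lattice edges, one in the middle) as mean ± s.d. per adjacent pair.  The same
machinery measures domain rotations between structural states after
superposing on a common frame (e.g. the 18-degree stalk reorientation between
the two microtubule-binding states) and signed axial offsets between binding
sites (e.g. the 8-nm lead of one MTBD over another, one dimer repeat).

Rigid fits are least-squares proper rotations (Kabsch, via
``scipy.spatial.transform.Rotation.align_vectors``); reflections are never
returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "PointSet",
    "LatticeModel",
    "InterPFAngleTable",
    "fit_rigid",
    "rotation_angle_between",
    "inter_pf_angle_table",
    "domain_rotation_between_states",
    "axial_offset",
    "principal_axis",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (coordinates in Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class PointSet:
    """Labelled ordered point cloud; correspondence is by index."""

    label: str
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)

    def centroid(self) -> np.ndarray:
        return self.coordinates.mean(axis=0)


@dataclass
class LatticeModel:
    """Rigid dimer copies indexed by (pf_index, repeat_index), one frame."""

    dimers: dict[tuple[int, int], PointSet]
    reference_dimer: PointSet
    closed: bool = False

    def pf_indices(self) -> list[int]:
        return sorted({pf for pf, _ in self.dimers})

    def repeat_indices(self) -> list[int]:
        return sorted({r for _, r in self.dimers})


@dataclass
class InterPFAngleTable:
    """Per-pair, per-region inter-PF angles with mean and s.d. across regions."""

    table: pd.DataFrame  # columns: pf_a, pf_b, region, angle_deg
    n_regions: int

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby(["pf_a", "pf_b"])["angle_deg"]
        out = g.agg(mean="mean", sd=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0)
        return out.reset_index()


def _check_fittable(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    if coords.shape[0] < 3 or np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate point set: need >= 3 non-collinear points")


def fit_rigid(moving: PointSet, fixed: PointSet) -> RigidTransform:
    """Least-squares proper rigid motion taking ``moving`` onto ``fixed``."""
    a = moving.coordinates
    b = fixed.coordinates
    if a.shape != b.shape:
        raise ValueError("point sets must have equal cardinality and ordering")
    _check_fittable(a)
    _check_fittable(b)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b - cb, a - ca)
    R = rot.as_matrix()
    return RigidTransform(rotation=R, translation=cb - R @ ca)


def rotation_angle_between(a: RigidTransform, b: RigidTransform) -> float:
    """Rotation angle (degrees, [0, 180]) of the relative rotation b·a⁻¹."""
    rel = b.rotation @ a.rotation.T
    cos = (np.trace(rel) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def rotation_angle_about_axis(a: RigidTransform, b: RigidTransform, axis: np.ndarray) -> float:
    """Component of the relative rotation about ``axis`` (degrees, signed).

    A projected "lateral" variant of :func:`rotation_angle_between` for
    strict lateral-rotation readings about the lattice axis.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("axis must be non-zero")
    rotvec = Rotation.from_matrix(b.rotation @ a.rotation.T).as_rotvec()
    return float(np.degrees(rotvec @ (axis / n)))


def _adjacent_pairs(lattice: LatticeModel) -> list[tuple[int, int]]:
    pfs = lattice.pf_indices()
    pairs = [(pfs[i], pfs[i + 1]) for i in range(len(pfs) - 1)]
    if lattice.closed and len(pfs) > 2:
        pairs.append((pfs[-1], pfs[0]))
    return pairs


def default_regions(lattice: LatticeModel, n_regions: int = 3) -> list[list[int]]:
    """Axial windows: first repeat, middle repeat(s), last repeat."""
    reps = lattice.repeat_indices()
    if len(reps) < n_regions:
        raise ValueError("fewer repeats than requested regions")
    picks = np.unique(np.linspace(0, len(reps) - 1, n_regions).round().astype(int))
    return [[reps[i]] for i in picks]


def inter_pf_angle_table(
    lattice: LatticeModel,
    regions: Optional[Sequence[Sequence[int]]] = None,
    projected_axis: Optional[np.ndarray] = None,
) -> InterPFAngleTable:
    """Inter-PF lateral rotation angles per adjacent pair and axial region.

    Every dimer is rigid-fitted to the reference dimer; the angle for a pair
    in a region is the mean over that region's repeats of the relative
    rotation angle between the two fits.  With ``projected_axis`` set, the
    signed rotation component about that axis is reported instead of the full
    rotation-angle magnitude.
    """
    if len(lattice.pf_indices()) < 2:
        raise ValueError("need at least two protofilaments")
    if regions is None:
        regions = default_regions(lattice)
    fits: dict[tuple[int, int], RigidTransform] = {}

    def fit_of(key: tuple[int, int]) -> RigidTransform:
        if key not in fits:
            if key not in lattice.dimers:
                raise ValueError(f"missing dimer at (pf, repeat) = {key}")
            fits[key] = fit_rigid(lattice.reference_dimer, lattice.dimers[key])
        return fits[key]

    rows = []
    for pf_a, pf_b in _adjacent_pairs(lattice):
        for ridx, region in enumerate(regions):
            vals = []
            for rep in region:
                ta, tb = fit_of((pf_a, rep)), fit_of((pf_b, rep))
                if projected_axis is not None:
                    vals.append(rotation_angle_about_axis(ta, tb, projected_axis))
                else:
                    vals.append(rotation_angle_between(ta, tb))
            rows.append(
                {"pf_a": pf_a, "pf_b": pf_b, "region": ridx, "angle_deg": float(np.mean(vals))}
            )
    return InterPFAngleTable(table=pd.DataFrame(rows), n_regions=len(regions))


def domain_rotation_between_states(
    state1: Mapping[str, PointSet],
    state2: Mapping[str, PointSet],
    align_selection: Sequence[str],
    measure_selection: Sequence[str],
) -> float:
    """Domain rotation (degrees) between two states after superposition.

    State 2 is superposed onto state 1 using the align selection (e.g. the
    microtubule protofilaments); the reported angle is the relative rotation
    between the rigid fits of the measure selection (e.g. a dynein stalk) in
    the two aligned states.
    """
    if not align_selection or not measure_selection:
        raise ValueError("selections must be non-empty")

    def gather(state: Mapping[str, PointSet], labels: Sequence[str]) -> PointSet:
        missing = [l for l in labels if l not in state]
        if missing:
            raise ValueError(f"selection labels missing from state: {missing}")
        coords = np.vstack([state[l].coordinates for l in labels])
        return PointSet(label="+".join(labels), coordinates=coords)

    align1, align2 = gather(state1, align_selection), gather(state2, align_selection)
    superpose = fit_rigid(align2, align1)
    meas1 = gather(state1, measure_selection)
    meas2 = gather(state2, measure_selection)
    meas2_aligned = PointSet(meas2.label, superpose.apply(meas2.coordinates))
    t1 = fit_rigid(meas1, meas1)  # identity reference frame
    t2 = fit_rigid(meas1, meas2_aligned)
    return rotation_angle_between(t1, t2)


def axial_offset(site_a: PointSet, site_b: PointSet, axis: np.ndarray) -> float:
    """Signed offset (nm) of site_b relative to site_a along ``axis``.

    Projection of the centroid difference onto the unit axis; positive values
    point along the axis direction (toward the microtubule plus end when the
    axis is oriented that way).  Input coordinates are in Å.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("axis must be non-zero")
    if site_a.coordinates.size == 0 or site_b.coordinates.size == 0:
        raise ValueError("selections must be non-empty")
    delta = site_b.centroid() - site_a.centroid()
    return float(delta @ (axis / n)) / 10.0


def principal_axis(lattice: LatticeModel) -> np.ndarray:
    """Helical-axis estimate: first principal component of dimer centroids."""
    cents = np.array([ps.centroid() for ps in lattice.dimers.values()])
    if len(cents) < 2:
        raise ValueError("need at least two dimers to estimate an axis")
    centered = cents - cents.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # orient toward increasing repeat index
    reps = np.array([r for _, r in lattice.dimers])
    if np.corrcoef(cents @ axis, reps)[0, 1] < 0:
        axis = -axis
    return axis
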