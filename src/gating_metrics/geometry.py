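"""Superposition and geometric gating metrics.

The observables here are the ones used to compare Kir channel conformations:

* per-residue displacement between two structures after aligning the
  transmembrane-helix backbones (Kabsch superposition restricted to proper
  rotations);
* distances between named-atom geometric centers — e.g. the R78–R186
  distance (NH1/NH2 centers of two arginines of the same subunit) and the
  TMD–CTD distance (D76-Cα of one subunit to K220-Cα of an adjacent
  subunit);
* the orientation angle of a side-chain vector (Ile CG1→CG2 or Leu
  CD1→CD2) against the membrane normal, reported unfolded in [0°, 180°].

Subunit adjacency is explicit: a ring order of chain ids plus a signed
chain offset decide which neighbour "the next subunit" is, because the
clockwise/anticlockwise convention is an input, not something this module
guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .structure import (
    EmptySelectionError,
    Selection,
    Structure,
    Trajectory,
    resolve_selection,
)

__all__ = [
    "SuperpositionResult",
    "DisplacementProfile",
    "SiteSpec",
    "DistanceMetric",
    "AngleMetric",
    "MetricTimeSeries",
    "SuperpositionError",
    "kabsch_superpose",
    "align_structures",
    "residue_displacement",
    "site_center_distance",
    "sidechain_axis_angle",
    "metric_over_trajectory",
]


class SuperpositionError(ValueError):
    """Raised for degenerate point sets (<3 points or collinear geometry)."""


@dataclass(frozen=True)
class SuperpositionResult:
    """A proper rigid-body fit: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms_fit: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Minimises RMSD over all proper rotations + translations (SVD route with
    determinant correction, so reflections are excluded).  Requires >=3
    non-collinear points in each set.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError(f"point sets must share shape (n, 3); got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError(f"need >=3 points, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear (or coincident) point sets leave the rotation underdetermined
    spread = np.linalg.svd(P0, compute_uv=False)
    if spread[1] < 1e-8 * max(spread[0], 1.0):
        raise SuperpositionError("degenerate geometry: points are collinear or coincident")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms_fit=n)


def _correspondence(
    mobile: Structure, reference: Structure, fit_sel: Selection
) -> tuple[list[int], list[int]]:
    idx_m = resolve_selection(mobile, fit_sel)
    idx_r = resolve_selection(reference, fit_sel)
    keys_m = [
        (mobile.atoms[i].chain_id, mobile.atoms[i].res_seq, mobile.atoms[i].name)
        for i in idx_m
    ]
    keys_r = [
        (reference.atoms[i].chain_id, reference.atoms[i].res_seq, reference.atoms[i].name)
        for i in idx_r
    ]
    if keys_m != keys_r:
        for km, kr in zip(keys_m, keys_r):
            if km != kr:
                raise ValueError(f"fit-selection mismatch: mobile has {km}, reference has {kr}")
        raise ValueError(
            f"fit-selection mismatch: {len(keys_m)} atoms in mobile vs {len(keys_r)} in reference;"
            f" first unpaired: "
            f"{keys_m[len(keys_r):][:1] or keys_r[len(keys_m):][:1]}"
        )
    return idx_m, idx_r


def align_structures(
    mobile: Structure, reference: Structure, fit_sel: Selection
) -> tuple[Structure, SuperpositionResult]:
    """Fit on ``fit_sel`` only, then transform ALL atoms of ``mobile``."""
    idx_m, idx_r = _correspondence(mobile, reference, fit_sel)
    fit = kabsch_superpose(mobile.coords[idx_m], reference.coords[idx_r])
    return mobile.with_coords(fit.apply(mobile.coords)), fit


@dataclass
class DisplacementProfile:
    """Per-residue displacement (Å) between two aligned conformations."""

    entries: list[tuple[str, int, str, float]]
    skipped: list[tuple[str, int]] = field(default_factory=list)
    fit: SuperpositionResult | None = None

    def as_dict(self) -> dict[tuple[str, int], float]:
        return {(c, r): d for c, r, _, d in self.entries}


def _heavy_centers(structure: Structure) -> dict[tuple[str, int], np.ndarray]:
    """Unweighted geometric center of each residue's heavy atoms."""
    sums: dict[tuple[str, int], np.ndarray] = {}
    counts: dict[tuple[str, int], int] = {}
    for i, a in enumerate(structure.atoms):
        if a.is_hydrogen:
            continue
        key = a.residue
        if key in sums:
            sums[key] += structure.coords[i]
            counts[key] += 1
        else:
            sums[key] = structure.coords[i].copy()
            counts[key] = 1
    return {k: sums[k] / counts[k] for k in sums}


def residue_displacement(
    a: Structure, b: Structure, fit_sel: Selection
) -> DisplacementProfile:
    """Displacement of each residue's heavy-atom center, b aligned onto a.

    Residues present in only one structure are skipped and listed in
    ``skipped``; zero common residues is an error.
    """
    b_aligned, fit = align_structures(b, a, fit_sel)
    centers_a = _heavy_centers(a)
    centers_b = _heavy_centers(b_aligned)
    names = {(c, r): n for c, r, n in a.residues()}
    entries: list[tuple[str, int, str, float]] = []
    skipped = sorted(set(centers_a) ^ set(centers_b))
    for c, r, n in a.residues():
        if (c, r) in centers_b and (c, r) in centers_a:
            d = float(np.linalg.norm(centers_a[(c, r)] - centers_b[(c, r)]))
            entries.append((c, r, n, d))
    if not entries:
        raise ValueError("no residues are common to both structures")
    return DisplacementProfile(entries=entries, skipped=skipped, fit=fit)


@dataclass(frozen=True)
class SiteSpec:
    """A named-atom geometric center on one subunit.

    ``chain_offset`` counts steps along the subunit ring order: 0 means the
    same subunit the metric is instantiated on, ±1 an adjacent subunit.  A
    concrete ``chain_id`` may be given instead for one-off measurements.
    """

    res_seq: int
    atom_names: frozenset[str]
    chain_id: str | None = None
    chain_offset: int = 0

    def __post_init__(self) -> None:
        if not self.atom_names:
            raise ValueError("atom_names must be non-empty")

    @staticmethod
    def make(
        res_seq: int,
        atom_names: Sequence[str],
        chain_id: str | None = None,
        chain_offset: int = 0,
    ) -> "SiteSpec":
        return SiteSpec(
            res_seq=int(res_seq),
            atom_names=frozenset(atom_names),
            chain_id=chain_id,
            chain_offset=int(chain_offset),
        )


def _resolve_site_chain(
    site: SiteSpec, subunit: str | None, ring_order: Sequence[str] | None
) -> str:
    if site.chain_id is not None:
        return site.chain_id
    if subunit is None:
        raise ValueError("site has no chain_id; a subunit to instantiate on is required")
    if site.chain_offset == 0:
        return subunit
    if ring_order is None:
        raise ValueError("chain_offset != 0 requires a ring order")
    k = list(ring_order).index(subunit)
    return list(ring_order)[(k + site.chain_offset) % len(ring_order)]


def _site_center(
    structure: Structure, site: SiteSpec, chain: str
) -> np.ndarray:
    sel = Selection.make(
        chain_ids=[chain],
        res_seq_ranges=[(site.res_seq, site.res_seq)],
        atom_names=site.atom_names,
    )
    try:
        idx = resolve_selection(structure, sel)
    except EmptySelectionError as exc:
        raise EmptySelectionError(
            f"site {chain}:{site.res_seq}:{sorted(site.atom_names)} resolved no atoms"
        ) from exc
    return structure.coords[idx].mean(axis=0)


def site_center_distance(
    structure: Structure,
    site_a: SiteSpec,
    site_b: SiteSpec,
    ring_order: Sequence[str] | None = None,
    subunit: str | None = None,
) -> float:
    """Euclidean distance (Å) between two unweighted named-atom centers."""
    ca = _site_center(structure, site_a, _resolve_site_chain(site_a, subunit, ring_order))
    cb = _site_center(structure, site_b, _resolve_site_chain(site_b, subunit, ring_order))
    return float(np.linalg.norm(ca - cb))


def sidechain_axis_angle(
    structure: Structure,
    chain_id: str,
    res_seq: int,
    atom_from: str,
    atom_to: str,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
) -> float:
    """Angle (degrees, unfolded in [0, 180]) between a side-chain vector and an axis.

    The vector points from ``atom_from`` to ``atom_to`` (e.g. Ile CG1→CG2);
    the default axis is +Z, the membrane normal of the input frame.
    """
    axis = np.asarray(axis, dtype=float)
    norm_ax = np.linalg.norm(axis)
    if norm_ax == 0:
        raise ValueError("axis must be non-zero")
    try:
        i = structure.atom_index(chain_id, res_seq, atom_from)
        j = structure.atom_index(chain_id, res_seq, atom_to)
    except KeyError as exc:
        raise KeyError(f"missing atom for angle metric: {exc}") from exc
    v = structure.coords[j] - structure.coords[i]
    norm_v = np.linalg.norm(v)
    if norm_v == 0:
        raise ValueError(f"zero-length side-chain vector {atom_from}->{atom_to}")
    cosang = float(np.clip(np.dot(v, axis) / (norm_v * norm_ax), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


@dataclass(frozen=True)
class DistanceMetric:
    """A site-center distance instantiated per subunit along the ring order."""

    name: str
    site_a: SiteSpec
    site_b: SiteSpec

    def evaluate(
        self, frame: Structure, subunit: str, ring_order: Sequence[str]
    ) -> float:
        return site_center_distance(
            frame, self.site_a, self.site_b, ring_order=ring_order, subunit=subunit
        )


@dataclass(frozen=True)
class AngleMetric:
    """A side-chain orientation angle instantiated per subunit."""

    name: str
    res_seq: int
    atom_from: str
    atom_to: str
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def evaluate(
        self, frame: Structure, subunit: str, ring_order: Sequence[str]
    ) -> float:
        return sidechain_axis_angle(
            frame, subunit, self.res_seq, self.atom_from, self.atom_to, self.axis
        )


@dataclass
class MetricTimeSeries:
    """One value per frame per subunit for a single metric."""

    metric_name: str
    per_subunit: dict[str, np.ndarray]
    times: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ns": self.times, **self.per_subunit})


def metric_over_trajectory(
    traj: Trajectory,
    metric: DistanceMetric | AngleMetric,
    subunits: Sequence[str] | None = None,
    ring_order: Sequence[str] | None = None,
) -> MetricTimeSeries:
    """Evaluate a metric on every frame for every requested subunit.

    ``ring_order`` defaults to the topology's chain order of appearance; any
    cross-subunit site offsets are interpreted cyclically along it.
    """
    if ring_order is None:
        ring_order = traj.topology.chains
    if subunits is None:
        subunits = list(ring_order)
    per: dict[str, np.ndarray] = {}
    for chain in subunits:
        vals = np.empty(traj.n_frames)
        for i in range(traj.n_frames):
            vals[i] = metric.evaluate(traj.frame(i), chain, ring_order)
        per[chain] = vals
    return MetricTimeSeries(metric_name=metric.name, per_subunit=per, times=traj.times)
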