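"""Synthetic tetramers, trajectories and recordings with known ground truth.

Every analysis in this package is exercised against data whose true signal
is planted by construction: a reduced 4-fold-symmetric tetramer with the
named atoms the metrics address (Arg NH1/NH2, Ile CG1/CG2, Leu CD1/CD2,
Asp/Lys Cα, donor hydrogens, …), trajectories built as reference + iid
Gaussian jitter + optional planted drifts and H-bond on/off schedules, toy
nonbonded parameter tables, and noiseless or noisy Hill dose-response
curves and exponential current traces.

The residues are reduced templates (backbone plus the specific side-chain
atoms the metrics touch), the jitter has no temporal correlation, and the
fold is not the real Kir2.2 fold; what these generators guarantee is exact,
recoverable ground truth, not physical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import SiteSpec
from .hbonds import PairSpec
from .kinetics import DoseResponse, hill_response
from .structure import Atom, Structure, Trajectory

__all__ = [
    "TetramerConfig",
    "DriftPlan",
    "HBondSchedule",
    "build_tetramer",
    "with_ligands",
    "simulate_trajectory",
    "gen_params",
    "gen_dose_response",
    "gen_trace",
    "demo_config",
    "RESIDUE_TEMPLATES",
]

# ---------------------------------------------------------------------------
# Residue templates: (atom_name, element, (du, dv, dw)) offsets in a local
# frame with u = radial outward, v = tangent, w = +Z.  Backbone is shared;
# side chains extend outward so C4-related chains never collide.

_BACKBONE = [
    ("N", "N", (0.0, -1.2, 0.4)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (0.0, 1.2, 0.4)),
    ("O", "O", (0.0, 1.9, 1.3)),
]

RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", (1.4, 0.0, 0.4))],
    "ARG": [
        ("CB", "C", (1.4, 0.0, 0.3)),
        ("NE", "N", (3.0, 0.0, 0.4)),
        ("CZ", "C", (4.2, 0.0, 0.5)),
        ("NH1", "N", (5.0, 0.9, 0.5)),
        ("NH2", "N", (5.0, -0.9, 0.5)),
        ("HH11", "H", (5.6, 1.6, 0.5)),
        ("HH12", "H", (4.6, 1.8, 0.7)),
        ("HH21", "H", (5.6, -1.6, 0.5)),
        ("HH22", "H", (4.6, -1.8, 0.7)),
    ],
    "LYS": [
        ("CB", "C", (1.4, 0.0, 0.3)),
        ("NZ", "N", (3.2, 0.0, 0.5)),
        ("HZ1", "H", (3.8, 0.6, 0.5)),
        ("HZ2", "H", (3.8, -0.6, 0.5)),
        ("HZ3", "H", (3.2, 0.0, 1.4)),
    ],
    "ASP": [
        ("CB", "C", (1.4, 0.0, 0.3)),
        ("CG", "C", (2.4, 0.0, 0.4)),
        ("OD1", "O", (3.2, 0.7, 0.4)),
        ("OD2", "O", (3.2, -0.7, 0.4)),
    ],
    "GLU": [
        ("CB", "C", (1.4, 0.0, 0.3)),
        ("CD", "C", (2.6, 0.0, 0.4)),
        ("OE1", "O", (3.4, 0.7, 0.4)),
        ("OE2", "O", (3.4, -0.7, 0.4)),
    ],
    "THR": [
        ("CB", "C", (1.4, 0.0, 0.3)),
        ("OG1", "O", (2.3, 0.0, 0.9)),
        ("HG1", "H", (2.9, 0.0, 1.5)),
        ("CG2", "C", (2.3, 0.0, -0.7)),
    ],
    "SER": [
        ("CB", "C", (1.4, 0.0, 0.3)),
        ("OG", "O", (2.3, 0.0, 0.6)),
        ("HG", "H", (2.9, 0.0, 1.2)),
    ],
    "HIS": [
        ("CB", "C", (1.4, 0.0, 0.3)),
        ("ND1", "N", (2.5, 0.7, 0.3)),
        ("HD1", "H", (2.9, 1.5, 0.3)),
        ("NE2", "N", (3.3, -0.5, 0.3)),
        ("HE2", "H", (4.0, -1.1, 0.3)),
    ],
    "MET": [
        ("CB", "C", (1.4, 0.0, 0.3)),
        ("SD", "S", (2.8, 0.0, 0.5)),
    ],
    "VAL": [
        ("CB", "C", (1.4, 0.0, 0.3)),
        ("CG1", "C", (2.3, 0.7, 0.3)),
        ("CG2", "C", (2.3, -0.7, 0.3)),
    ],
    "TRP": [
        ("CB", "C", (1.4, 0.0, 0.3)),
        ("NE1", "N", (2.8, 0.5, 0.4)),
        ("HE1", "H", (3.4, 1.1, 0.4)),
    ],
}

# Ile/Leu get their terminal-branch pair placed by an orientation angle so
# the CG1->CG2 (CD1->CD2) vector makes a chosen angle with +Z.
_ORIENTED = {
    "ILE": ("CG1", "CG2", (4.5, 0.0, 0.65), 0.78, [("CB", "C", (1.4, 0.0, 0.3))]),
    "LEU": (
        "CD1",
        "CD2",
        (4.7, 0.0, 0.65),
        0.78,
        [("CB", "C", (1.4, 0.0, 0.3)), ("CG", "C", (2.3, 0.0, 0.1))],
    ),
}

_DEFAULT_ORIENTATION = {"ILE": 75.0, "LEU": 20.0}

MIN_ATOM_SEPARATION = 0.8  # Å


@dataclass(frozen=True)
class TetramerConfig:
    """Geometry plan for a reduced C4-symmetric tetramer.

    Chain 0 runs down a helical path (theta advancing ``theta_step_deg`` and
    z dropping ``z_step`` per residue from ``z_top``); chains 1–3 are chain 0
    rotated by 90°, 180°, 270° about Z.  ``special_residues`` maps res_seq to
    a template name, or to ``(name, angle_deg)`` for Ile/Leu whose branch
    vector orientation against +Z is part of the plan.  ``tm_ranges`` are the
    residue ranges this topology declares as its transmembrane helices, used
    as the alignment selection by displacement analyses.
    """

    n_residues_per_chain: int = 40
    ring_radius: float = 12.0
    chain_ids: tuple[str, str, str, str] = ("A", "B", "C", "D")
    special_residues: Mapping[int, object] = field(default_factory=dict)
    tm_ranges: tuple[tuple[int, int], ...] = ()
    seed: int = 0
    res_seqs: tuple[int, ...] | None = None  # explicit numbering (gaps allowed)
    theta_step_deg: float = 4.0
    z_step: float = 1.3
    z_top: float = 40.0

    def residue_numbers(self) -> list[int]:
        if self.res_seqs is not None:
            return list(self.res_seqs)
        return list(range(1, self.n_residues_per_chain + 1))


def _template_for(spec) -> tuple[str, list[tuple[str, str, tuple[float, float, float]]]]:
    """Resolve a special-residue spec to (res_name, side-chain atom list)."""
    if isinstance(spec, tuple):
        name, angle = spec
    else:
        name, angle = spec, None
    if name in _ORIENTED:
        a_from, a_to, pivot, half_len, stem = _ORIENTED[name]
        theta = np.radians(_DEFAULT_ORIENTATION[name] if angle is None else float(angle))
        direction = np.array([np.sin(theta), 0.0, np.cos(theta)])
        p = np.array(pivot)
        lo = tuple(p - half_len * direction)
        hi = tuple(p + half_len * direction)
        return name, stem + [(a_from, "C", lo), (a_to, "C", hi)]
    if name not in RESIDUE_TEMPLATES:
        raise ValueError(f"unknown residue template {name!r}")
    return name, RESIDUE_TEMPLATES[name]


def _rotation_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_tetramer(config: TetramerConfig) -> Structure:
    """Deterministically build the C4-symmetric reduced tetramer.

    Raises a generation error if any two atoms end up closer than 0.8 Å.
    """
    res_numbers = config.residue_numbers()
    atoms: list[Atom] = []
    serial = 1
    chain0: list[tuple[Atom, np.ndarray]] = []
    for k, res_seq in enumerate(res_numbers):
        theta = np.radians(config.theta_step_deg * k)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        v = np.array([-np.sin(theta), np.cos(theta), 0.0])
        w = np.array([0.0, 0.0, 1.0])
        origin = config.ring_radius * u + np.array([0.0, 0.0, config.z_top - config.z_step * k])
        if res_seq in config.special_residues:
            res_name, sidechain = _template_for(config.special_residues[res_seq])
        else:
            res_name, sidechain = "ALA", RESIDUE_TEMPLATES["ALA"]
        for name, element, (du, dv, dw) in _BACKBONE + list(sidechain):
            pos = origin + du * u + dv * v + dw * w
            chain0.append(
                (
                    Atom(
                        serial=0,
                        name=name,
                        element=element,
                        res_name=res_name,
                        res_seq=res_seq,
                        chain_id=config.chain_ids[0],
                        coords=(0.0, 0.0, 0.0),
                        is_hydrogen=(element == "H"),
                    ),
                    pos,
                )
            )
    for ci, chain_id in enumerate(config.chain_ids):
        R = _rotation_z(np.radians(90.0 * ci))
        for atom, pos in chain0:
            p = R @ pos
            atoms.append(
                Atom(
                    serial=serial,
                    name=atom.name,
                    element=atom.element,
                    res_name=atom.res_name,
                    res_seq=atom.res_seq,
                    chain_id=chain_id,
                    coords=(float(p[0]), float(p[1]), float(p[2])),
                    is_hydrogen=atom.is_hydrogen,
                )
            )
            serial += 1
    structure = Structure(atoms, label=f"synthetic-tetramer-seed{config.seed}")
    tree = cKDTree(structure.coords)
    close = tree.query_pairs(MIN_ATOM_SEPARATION)
    if close:
        i, j = sorted(close)[0]
        raise ValueError(
            f"generation error: atoms {structure.atoms[i]} and {structure.atoms[j]} "
            f"are closer than {MIN_ATOM_SEPARATION} Å"
        )
    return structure


def with_ligands(
    structure: Structure,
    anchor_res_seq: int = 78,
    anchor_atoms: Sequence[str] = ("NH1", "NH2"),
    chain_ids: Sequence[str] = ("W", "X", "Y", "Z"),
    offset: float = 3.0,
    ring_order: Sequence[str] | None = None,
) -> Structure:
    """Append one 3-atom phosphate-like ligand (res PLH) per subunit.

    Each ligand's central P1 sits ``offset`` Å radially outward of the
    subunit's anchor-atom center, so a C4-symmetric protein gets
    C4-symmetric ligands.
    """
    if ring_order is None:
        ring_order = structure.chains
    atoms = list(structure.atoms)
    serial = max(a.serial for a in atoms) + 1
    for lig_chain, prot_chain in zip(chain_ids, ring_order):
        idx = [
            i
            for i, a in enumerate(structure.atoms)
            if a.chain_id == prot_chain and a.res_seq == anchor_res_seq and a.name in anchor_atoms
        ]
        if not idx:
            raise ValueError(
                f"anchor {prot_chain}:{anchor_res_seq}:{list(anchor_atoms)} not found"
            )
        center = structure.coords[idx].mean(axis=0)
        outward = center.copy()
        outward[2] = 0.0
        n = np.linalg.norm(outward)
        outward = outward / n if n > 0 else np.array([1.0, 0.0, 0.0])
        p1 = center + offset * outward
        for name, element, delta in [
            ("P1", "P", np.zeros(3)),
            ("O1", "O", np.array([0.0, 0.0, 1.2])),
            ("O2", "O", np.array([0.0, 0.0, -1.2])),
        ]:
            pos = p1 + delta
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    res_name="PLH",
                    res_seq=1,
                    chain_id=lig_chain,
                    coords=(float(pos[0]), float(pos[1]), float(pos[2])),
                    is_hydrogen=False,
                )
            )
            serial += 1
    return Structure(atoms, label=structure.label + "+ligands")


@dataclass(frozen=True)
class DriftPlan:
    """A planted monotone change of a site-center distance metric.

    The residue holding ``site_b`` is translated along the line toward
    ``site_a``'s center so that the metric changes by exactly
    ``total_change`` Å (negative = shrink) between first and last frame when
    the fluctuation is zero.  ``profile`` is "linear" or "sigmoid";
    ``affected_subunits`` lists the chains whose metric instance drifts.
    """

    site_a: SiteSpec
    site_b: SiteSpec
    total_change: float
    profile: str = "linear"
    affected_subunits: tuple[str, ...] = ()
    name: str = "drift"

    def fraction(self, frame_index: int, n_frames: int) -> float:
        if n_frames < 2:
            return 1.0
        x = frame_index / (n_frames - 1)
        if self.profile == "linear":
            return x
        if self.profile == "sigmoid":
            raw = 1.0 / (1.0 + np.exp(-10.0 * (x - 0.5)))
            lo = 1.0 / (1.0 + np.exp(5.0))
            hi = 1.0 / (1.0 + np.exp(-5.0))
            return float((raw - lo) / (hi - lo))
        raise ValueError(f"unknown drift profile {self.profile!r}")


@dataclass(frozen=True)
class HBondSchedule:
    """A planted on/off H-bond between one residue pair, per subunit.

    On frames where ``bonded`` holds, the acceptor heavy atom of
    ``pair.res_b`` is placed 3.0 Å from the donor heavy atom of
    ``pair.res_a`` along the donor's N/O–H direction (zero deviation from
    linearity); otherwise it is placed 4.5 Å out, which violates the 3.5-Å
    distance criterion.
    """

    pair: PairSpec
    bonded: Callable[[int], bool] | frozenset[int] | tuple[int, ...]
    affected_subunits: tuple[str, ...] = ()
    bonded_distance: float = 3.0
    broken_distance: float = 4.5

    def is_bonded(self, frame_index: int) -> bool:
        if callable(self.bonded):
            return bool(self.bonded(frame_index))
        return frame_index in self.bonded


def _site_indices(structure: Structure, chain: str, res_seq: int, names) -> list[int]:
    return [
        i
        for i, a in enumerate(structure.atoms)
        if a.chain_id == chain and a.res_seq == res_seq and (names is None or a.name in names)
    ]


def _find_donor(structure: Structure, chain: str, res_seq: int) -> tuple[int, int]:
    from .hbonds import COVALENT_H_CUTOFF, DONOR_ACCEPTOR_ELEMENTS

    res_idx = _site_indices(structure, chain, res_seq, None)
    heavies = [i for i in res_idx if structure.atoms[i].element in DONOR_ACCEPTOR_ELEMENTS]
    hydros = [i for i in res_idx if structure.atoms[i].is_hydrogen]
    for d in heavies:
        for h in hydros:
            if np.linalg.norm(structure.coords[h] - structure.coords[d]) <= COVALENT_H_CUTOFF:
                return d, h
    raise ValueError(f"residue {chain}:{res_seq} has no donor (N/O/S with attached H)")


def _find_acceptor(structure: Structure, chain: str, res_seq: int, exclude: int) -> int:
    from .hbonds import DONOR_ACCEPTOR_ELEMENTS

    for i in _site_indices(structure, chain, res_seq, None):
        a = structure.atoms[i]
        if i != exclude and not a.is_hydrogen and a.element in DONOR_ACCEPTOR_ELEMENTS:
            return i
    raise ValueError(f"residue {chain}:{res_seq} has no acceptor (N/O/S heavy atom)")


def simulate_trajectory(
    structure: Structure,
    n_frames: int,
    dt_ns: float = 1.0,
    fluctuation_sd: float = 0.0,
    drifts: Sequence[DriftPlan] = (),
    schedules: Sequence[HBondSchedule] = (),
    seed: int = 0,
    ring_order: Sequence[str] | None = None,
) -> Trajectory:
    """Reference + iid Gaussian jitter + planted drifts and H-bond schedules.

    Deterministic per seed.  Drift plans may not share moving residues with
    each other or with schedule acceptor atoms (conflicting plans are an
    error, not a silent overwrite).
    """
    if ring_order is None:
        ring_order = structure.chains
    ring = list(ring_order)
    rng = np.random.default_rng(seed)

    # resolve drift instances: (moving atom indices, unit vector, site-b residue key)
    drift_instances = []
    moved_residues: dict[tuple[str, int], str] = {}
    for plan in drifts:
        subunits = plan.affected_subunits or tuple(ring)
        for su in subunits:
            chain_a = su if plan.site_a.chain_id is None else plan.site_a.chain_id
            if plan.site_a.chain_offset and plan.site_a.chain_id is None:
                chain_a = ring[(ring.index(su) + plan.site_a.chain_offset) % len(ring)]
            chain_b = su if plan.site_b.chain_id is None else plan.site_b.chain_id
            if plan.site_b.chain_offset and plan.site_b.chain_id is None:
                chain_b = ring[(ring.index(su) + plan.site_b.chain_offset) % len(ring)]
            ia = _site_indices(structure, chain_a, plan.site_a.res_seq, plan.site_a.atom_names)
            ib = _site_indices(structure, chain_b, plan.site_b.res_seq, plan.site_b.atom_names)
            if not ia or not ib:
                raise ValueError(f"drift {plan.name}: site unresolved on subunit {su}")
            key = (chain_b, plan.site_b.res_seq)
            if key in moved_residues:
                raise ValueError(
                    f"conflicting plans: residue {key} moved by both "
                    f"{moved_residues[key]!r} and {plan.name!r}"
                )
            moved_residues[key] = plan.name
            ca = structure.coords[ia].mean(axis=0)
            cb = structure.coords[ib].mean(axis=0)
            u = ca - cb
            dist = np.linalg.norm(u)
            if dist == 0:
                raise ValueError(f"drift {plan.name}: coincident site centers")
            u /= dist
            if abs(plan.total_change) >= dist:
                raise ValueError(
                    f"drift {plan.name}: |total_change| {abs(plan.total_change)} >= "
                    f"initial distance {dist:.2f}"
                )
            moving = _site_indices(structure, chain_b, plan.site_b.res_seq, None)
            drift_instances.append((plan, moving, u))

    # resolve schedule instances: (schedule, donor, hydrogen, acceptor)
    schedule_instances = []
    for sched in schedules:
        subunits = sched.affected_subunits or tuple(ring)
        for su in subunits:
            chain_b = ring[(ring.index(su) + sched.pair.chain_offset) % len(ring)]
            try:
                d, h = _find_donor(structure, su, sched.pair.res_a)
                a = _find_acceptor(structure, chain_b, sched.pair.res_b, exclude=d)
            except ValueError:
                d, h = _find_donor(structure, chain_b, sched.pair.res_b)
                a = _find_acceptor(structure, su, sched.pair.res_a, exclude=d)
            akey = (structure.atoms[a].chain_id, structure.atoms[a].res_seq)
            if akey in moved_residues:
                raise ValueError(
                    f"conflicting plans: residue {akey} touched by both "
                    f"{moved_residues[akey]!r} and the {sched.pair.name()} schedule"
                )
            schedule_instances.append((sched, d, h, a))

    frames = []
    ref = structure.coords
    for fi in range(n_frames):
        coords = ref.copy()
        for plan, moving, u in drift_instances:
            # translating site_b toward site_a by c changes the distance by -c
            shift = -plan.total_change * plan.fraction(fi, n_frames)
            coords[moving] += shift * u
        if fluctuation_sd > 0:
            coords += rng.normal(0.0, fluctuation_sd, size=coords.shape)
        for sched, d, h, a in schedule_instances:
            direction = coords[h] - coords[d]
            direction /= np.linalg.norm(direction)
            length = sched.bonded_distance if sched.is_bonded(fi) else sched.broken_distance
            coords[a] = coords[d] + length * direction
        frames.append(coords)
    times = dt_ns * np.arange(n_frames, dtype=float)
    return Trajectory(topology=structure, frames=frames, times=times)


def gen_params(
    structure: Structure,
    charge_plan: Mapping[tuple[str, str], float] | None = None,
    epsilon: float = 0.1,
    rmin_half: float = 1.8,
):
    """Toy nonbonded parameter table covering every atom of ``structure``.

    Charges default to zero (a neutral plan) and are overridden per
    (res_name, atom_name) by ``charge_plan``; ε and rmin/2 are uniform toy
    values.
    """
    import pandas as pd

    from .energy import NonbondedParams

    charge_plan = dict(charge_plan or {})
    rows = []
    seen = set()
    for a in structure.atoms:
        key = (a.res_name, a.name)
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {
                "res_name": a.res_name,
                "atom_name": a.name,
                "charge_e": charge_plan.get(key, 0.0),
                "epsilon_kcal": epsilon,
                "rmin_half_A": rmin_half,
            }
        )
    return NonbondedParams(pd.DataFrame(rows))


def gen_dose_response(
    ec50: float,
    hill_n: float = 1.0,
    i_max: float = 1.0,
    concentrations: Iterable[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponse:
    """Hill-curve responses at the given concentrations, plus Gaussian noise.

    Default concentrations: 8 log-spaced points from 0.03 to 100 μM.
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if concentrations is None:
        concentrations = np.logspace(np.log10(0.03), np.log10(100.0), 8)
    c = np.asarray(list(concentrations), dtype=float)
    resp = hill_response(c, ec50, hill_n, i_max)
    if noise_sd > 0:
        resp = resp + np.random.default_rng(seed).normal(0.0, noise_sd, size=resp.shape)
    return DoseResponse(concentrations=c, responses=resp)


def gen_trace(
    tau_half: float,
    mode: str,
    amplitude: float = 1.0,
    duration: float = 120.0,
    dt: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential inhibition ("off") or saturating-rise activation ("on") trace.

    off: I(t) = I₀·2^(−t/τ½) — crosses I₀/2 at exactly t = τ½.
    on:  I(t) = I_max·(1 − 2^(−t/τ½)) — crosses I_max/2 at exactly t = τ½.
    """
    if tau_half <= 0:
        raise ValueError("tau_half must be positive")
    if duration <= tau_half:
        raise ValueError("duration must exceed tau_half")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    k = np.log(2.0) / tau_half
    if mode == "off":
        y = amplitude * np.exp(-k * t)
    elif mode == "on":
        y = amplitude * (1.0 - np.exp(-k * t))
    else:
        raise ValueError(f"mode must be 'on' or 'off', got {mode!r}")
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=y.shape)
    return t, y


def demo_config(mutant: bool = False, seed: int = 0) -> TetramerConfig:
    """The shipped demo tetramer: canonical Kir2.2-style residue numbering.

    Carries the named sites all metrics address (R78/R186 NH centers,
    D76/K220 Cα, position 223 as Ile in the wild-type layout or Leu in the
    mutant layout, the H-bond pair residues of the interaction-network
    analysis, and the PIP₂-binding basic residues) spread over N-terminus,
    two declared TM helices, C linker, CD loop and G loop blocks.
    """
    res_seqs = (
        list(range(52, 59))  # N-terminus (E55)
        + list(range(70, 100))  # N linker (D76, R78, W79, R80) + TM helix M1
        + list(range(150, 200))  # TM helix M2 + C linker (K183, R186, K188, K189, T193)
        + list(range(215, 235))  # CD loop (L219, K220, H222, I/L223, V224, E225, H227)
        + list(range(300, 312))  # G loop (M302, V303, E304, M308)
    )
    special = {
        55: "GLU",
        76: "ASP",
        78: "ARG",
        79: "TRP",
        80: "ARG",
        183: "LYS",
        186: "ARG",
        188: "LYS",
        189: "LYS",
        193: "THR",
        219: "LEU",
        220: "LYS",
        222: "HIS",
        223: ("LEU", 20.0) if mutant else ("ILE", 75.0),
        224: "VAL",
        225: "GLU",
        227: "HIS",
        302: "MET",
        303: "VAL",
        304: "GLU",
        308: "MET",
    }
    return TetramerConfig(
        n_residues_per_chain=len(res_seqs),
        res_seqs=tuple(res_seqs),
        ring_radius=12.0,
        special_residues=special,
        tm_ranges=((80, 99), (150, 179)),
        seed=seed,
    )
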