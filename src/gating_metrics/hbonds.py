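"""Hydrogen-bond detection and residue-pair network statistics.

A hydrogen bond is a donor–hydrogen–acceptor triple with donor–acceptor
distance < 3.5 Å and near-linear geometry: the deviation from linearity,
180° − ∠(D,H,A), must be < 45°.  (A literal "D–H–A angle < 45°" criterion
would be geometrically impossible for a real H bond, so the threshold is
applied to the deviation; the raw ∠DHA is kept on each detection.)

Donors are N/O/S heavy atoms with a covalently attached hydrogen (H within
1.25 Å, same residue); acceptors are all N/O/S heavy atoms.  Intra-residue
bonds are excluded.  Counts are per (donor, H, acceptor) triple, so a
residue pair can contribute more than one bond per frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure import Structure, Trajectory

__all__ = [
    "HBondCriteria",
    "HBond",
    "PairSpec",
    "PairHBondSeries",
    "PairHBondStats",
    "infer_donors_acceptors",
    "detect_hbonds",
    "pair_hbond_timeseries",
    "summarize_pairs",
]

DONOR_ACCEPTOR_ELEMENTS = frozenset({"N", "O", "S"})
COVALENT_H_CUTOFF = 1.25  # Å; covers N-H, O-H, S-H without nonbonded contacts


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 3.5  # Å, donor-acceptor
    max_angle_deviation: float = 45.0  # degrees from linearity

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0 or self.max_angle_deviation <= 0:
            raise ValueError("criteria must be strictly positive")


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    da_distance: float
    angle_deviation: float
    dha_angle: float
    donor_residue: tuple[str, int]
    acceptor_residue: tuple[str, int]


def infer_donors_acceptors(
    structure: Structure,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Identify (donor heavy atom, hydrogen) pairs and acceptor heavy atoms.

    A structure with no hydrogens cannot donate; that case returns an empty
    donor list with a warning, while acceptors are still reported.
    """
    coords = structure.coords
    heavy_idx = [
        i
        for i, a in enumerate(structure.atoms)
        if not a.is_hydrogen and a.element in DONOR_ACCEPTOR_ELEMENTS
    ]
    h_by_res: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.is_hydrogen:
            h_by_res.setdefault(a.residue, []).append(i)
    donors: list[tuple[int, int]] = []
    for i in heavy_idx:
        res = structure.atoms[i].residue
        for h in h_by_res.get(res, ()):
            if np.linalg.norm(coords[h] - coords[i]) <= COVALENT_H_CUTOFF:
                donors.append((i, h))
    if not h_by_res:
        warnings.warn(
            "structure contains no hydrogens: no donors can be inferred",
            stacklevel=2,
        )
    return donors, heavy_idx


def detect_hbonds(
    frame: Structure,
    criteria: HBondCriteria = HBondCriteria(),
    donors: list[tuple[int, int]] | None = None,
    acceptors: list[int] | None = None,
) -> list[HBond]:
    """All hydrogen bonds in one frame, ordered by (donor, acceptor, hydrogen).

    ``donors``/``acceptors`` may be passed in when detecting over many frames
    of one topology; otherwise they are inferred from the frame.
    """
    if donors is None or acceptors is None:
        donors, acceptors = infer_donors_acceptors(frame)
    if not donors or not acceptors:
        return []
    coords = frame.coords
    d_heavy = np.array([d for d, _ in donors])
    d_hydro = np.array([h for _, h in donors])
    acc = np.array(acceptors)
    dist = cdist(coords[d_heavy], coords[acc])
    close = dist < criteria.max_da_distance
    # exclude self-pairs and intra-residue pairs
    res_of = [a.residue for a in frame.atoms]
    out: list[HBond] = []
    for di, ai in zip(*np.nonzero(close)):
        d, h, a = int(d_heavy[di]), int(d_hydro[di]), int(acc[ai])
        if d == a or res_of[d] == res_of[a]:
            continue
        v1 = coords[d] - coords[h]
        v2 = coords[a] - coords[h]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            continue
        cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
        dha = float(np.degrees(np.arccos(cosang)))
        deviation = 180.0 - dha
        if deviation < criteria.max_angle_deviation:
            out.append(
                HBond(
                    donor=d,
                    hydrogen=h,
                    acceptor=a,
                    da_distance=float(dist[di, ai]),
                    angle_deviation=deviation,
                    dha_angle=dha,
                    donor_residue=res_of[d],
                    acceptor_residue=res_of[a],
                )
            )
    out.sort(key=lambda b: (b.donor, b.acceptor, b.hydrogen))
    return out


@dataclass(frozen=True)
class PairSpec:
    """A residue pair instantiated once per subunit via the ring order.

    Residue A lives on the subunit itself; residue B on the subunit
    ``chain_offset`` steps along the ring (0 = intrasubunit).
    """

    res_a: int
    res_b: int
    chain_offset: int = 0
    label: str = ""

    @property
    def kind(self) -> str:
        return "intra" if self.chain_offset == 0 else "inter"

    def name(self) -> str:
        return self.label or f"{self.res_a}-{self.res_b}({self.kind})"


@dataclass
class PairHBondSeries:
    pair: PairSpec
    per_subunit: dict[str, np.ndarray]  # chain -> count per frame
    times: np.ndarray
    res_names: tuple[str, str] = ("", "")


@dataclass
class PairHBondStats:
    pair: PairSpec
    kind: str
    per_subunit_mean: list[float]
    mean: float
    sd: float
    res_names: tuple[str, str] = ("", "")


def _residue_names(topology: Structure, res_seq: int) -> str:
    for c, r, n in topology.residues():
        if r == res_seq:
            return n
    return ""


def pair_hbond_timeseries(
    traj: Trajectory,
    pairs: list[PairSpec],
    criteria: HBondCriteria = HBondCriteria(),
    ring_order: list[str] | None = None,
) -> list[PairHBondSeries]:
    """Per-frame H-bond counts for each residue pair, one series per subunit.

    Bonds are counted regardless of which residue donates; detection runs
    once per frame and the counts are split per pair instance afterwards.
    """
    top = traj.topology
    if ring_order is None:
        ring_order = top.chains
    donors, acceptors = infer_donors_acceptors(top)
    residues = {(c, r) for c, r, _ in top.residues()}
    # pair instances: (pair index, subunit chain) -> frozenset of the two residues
    instances: dict[tuple[int, str], frozenset] = {}
    for pi, p in enumerate(pairs):
        found = False
        for k, chain in enumerate(ring_order):
            other = ring_order[(k + p.chain_offset) % len(ring_order)]
            ra, rb = (chain, p.res_a), (other, p.res_b)
            if ra in residues and rb in residues:
                instances[(pi, chain)] = frozenset((ra, rb))
                found = True
        if not found:
            raise ValueError(f"pair {p.name()} resolves on no subunit of the topology")
    counts = {key: np.zeros(traj.n_frames) for key in instances}
    for fi in range(traj.n_frames):
        frame = traj.frame(fi)
        bonds = detect_hbonds(frame, criteria, donors=donors, acceptors=acceptors)
        for b in bonds:
            bond_pair = frozenset((b.donor_residue, b.acceptor_residue))
            for key, inst in instances.items():
                if inst == bond_pair:
                    counts[key][fi] += 1
    out = []
    for pi, p in enumerate(pairs):
        per = {
            chain: counts[(pi, chain)]
            for chain in ring_order
            if (pi, chain) in counts
        }
        out.append(
            PairHBondSeries(
                pair=p,
                per_subunit=per,
                times=traj.times,
                res_names=(_residue_names(top, p.res_a), _residue_names(top, p.res_b)),
            )
        )
    return out


def summarize_pairs(
    series: list[PairHBondSeries], window: tuple[float, float]
) -> list[PairHBondStats]:
    """Tetramer statistics of pair H-bond counts over a time window.

    Each subunit's count series is time-averaged over the (inclusive)
    window; the mean and sample SD (n−1) are then taken across the subunit
    averages — the "mean ± SD of the tetramer after the window average of
    each subunit" protocol.
    """
    from .stats import tetramer_stats, window_mask

    out = []
    for s in series:
        mask = window_mask(s.times, window)
        per_mean = [float(v[mask].mean()) for v in s.per_subunit.values()]
        ws = tetramer_stats(per_mean)
        out.append(
            PairHBondStats(
                pair=s.pair,
                kind=s.pair.kind,
                per_subunit_mean=per_mean,
                mean=ws.mean,
                sd=ws.sd,
                res_names=s.res_names,
            )
        )
    return out
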