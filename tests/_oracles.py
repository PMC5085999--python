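"""Independent reference implementations used only to check the package.

These deliberately take different algorithmic routes from the library code:
the superposition oracle uses Horn's quaternion eigenvalue method instead
of SVD, the H-bond oracle enumerates every donor×acceptor triple with plain
Python loops, and the Welch oracle evaluates the textbook formulas with
scipy's t distribution directly.
"""

import math

import numpy as np
from scipy import stats as sps


def horn_quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's closed-form quaternion method."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    n = P.shape[0]
    msd = max(((P0**2).sum() + (Q0**2).sum() - 2.0 * lam) / n, 0.0)
    return math.sqrt(msd)


def brute_force_hbonds(structure, criteria):
    """Every (donor, hydrogen, acceptor) triple, checked one by one."""
    coords = structure.coords
    triples = set()
    donor_elements = {"N", "O", "S"}
    for d, ad in enumerate(structure.atoms):
        if ad.is_hydrogen or ad.element not in donor_elements:
            continue
        for h, ah in enumerate(structure.atoms):
            if not ah.is_hydrogen or ah.residue != ad.residue:
                continue
            if np.linalg.norm(coords[h] - coords[d]) > 1.25:
                continue
            for a, aa in enumerate(structure.atoms):
                if aa.is_hydrogen or aa.element not in donor_elements:
                    continue
                if a == d or aa.residue == ad.residue:
                    continue
                if np.linalg.norm(coords[d] - coords[a]) >= criteria.max_da_distance:
                    continue
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                dha = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if 180.0 - dha < criteria.max_angle_deviation:
                    triples.add((d, h, a))
    return triples


def welch_formula(a, b):
    """Textbook Welch t, Welch–Satterthwaite dof and two-sided p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
    dof = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), dof)
    return t, dof, p


def charmm_switch_reference(r, r_on, r_off):
    """Direct evaluation of the switching polynomial."""
    if r <= r_on:
        return 1.0
    if r >= r_off:
        return 0.0
    return ((r_off**2 - r**2) ** 2 * (r_off**2 + 2 * r**2 - 3 * r_on**2)) / (
        (r_off**2 - r_on**2) ** 3
    )
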