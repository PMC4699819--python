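"""Batched internal-coordinate construction of poly-alanine backbones.

Chains are grown atom by atom with the natural-extension-reference-frame
(NeRF) rule from standard bond lengths and angles (Engh/Huber values); the
only degrees of freedom are the backbone dihedrals phi, psi and omega.
Heavy atoms only: N, CA, C, O and the side-chain CB, with CB placed for the
L configuration.  All routines operate on a leading batch axis so that
thousands of conformers are built in lockstep with numpy.

Atom layout: ``coords[b, i, a, :]`` with ``a`` indexing (N, CA, C, O, CB).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ATOM_NAMES",
    "BOND_LENGTHS",
    "BOND_ANGLES",
    "nerf",
    "build_backbone",
    "measure_dihedral",
    "max_ca_distance",
]

ATOM_NAMES = ("N", "CA", "C", "O", "CB")
N_, CA_, C_, O_, CB_ = range(5)

#: Standard backbone bond lengths (Å).
BOND_LENGTHS = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "CA-CB": 1.521,
}

#: Standard backbone bond angles (degrees).
BOND_ANGLES = {
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
    "C-CA-CB": 110.5,
}

#: Improper torsion N-C-CA-CB fixing the L configuration at CA (degrees).
CB_TORSION = -122.6


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def nerf(a, b, c, bond: float, angle_deg: float, torsion_deg) -> np.ndarray:
    """Place atom d given frame atoms a, b, c.

    Returns d such that |c-d| = bond, angle(b, c, d) = angle_deg and
    dihedral(a, b, c, d) = torsion_deg.  ``a, b, c`` are (..., 3) arrays;
    ``torsion_deg`` may be scalar or batched.
    """
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(np.asarray(torsion_deg, dtype=float))
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * np.cos(ang) * np.ones_like(tor),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ],
        axis=-1,
    )
    return c + (
        d_local[..., 0:1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n
    )


def build_backbone(phi, psi, omega) -> np.ndarray:
    """Build poly-ALA heavy-atom coordinates from dihedral arrays.

    ``phi, psi, omega`` have shape (B, N) (or (N,), promoted to one chain) in
    degrees.  phi[.., 0] and omega[.., N-1] have no geometric effect and are
    accepted for uniform bookkeeping.  Returns coordinates of shape
    (B, N, 5, 3) in Å.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    if phi.shape != psi.shape or phi.shape != omega.shape:
        raise ValueError("phi, psi, omega must share a shape")
    b, n = phi.shape
    if n < 1:
        raise ValueError("need at least one residue")

    coords = np.empty((b, n, 5, 3), dtype=float)
    # first residue: N at origin, CA on +x, C in the xy-plane
    coords[:, 0, N_] = 0.0
    coords[:, 0, CA_] = np.array([BOND_LENGTHS["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(BOND_ANGLES["N-CA-C"])
    coords[:, 0, C_] = coords[:, 0, CA_] + BOND_LENGTHS["CA-C"] * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(n):
        ni, cai, ci = coords[:, i, N_], coords[:, i, CA_], coords[:, i, C_]
        # carbonyl O: anti to the next amide N across the C=O plane
        coords[:, i, O_] = nerf(
            ni, cai, ci,
            BOND_LENGTHS["C-O"], BOND_ANGLES["CA-C-O"], psi[:, i] + 180.0,
        )
        coords[:, i, CB_] = nerf(
            ni, ci, cai,
            BOND_LENGTHS["CA-CB"], BOND_ANGLES["C-CA-CB"], CB_TORSION,
        )
        if i + 1 < n:
            n_next = nerf(
                ni, cai, ci,
                BOND_LENGTHS["C-N"], BOND_ANGLES["CA-C-N"], psi[:, i],
            )
            ca_next = nerf(
                cai, ci, n_next,
                BOND_LENGTHS["N-CA"], BOND_ANGLES["C-N-CA"], omega[:, i],
            )
            c_next = nerf(
                ci, n_next, ca_next,
                BOND_LENGTHS["CA-C"], BOND_ANGLES["N-CA-C"], phi[:, i + 1],
            )
            coords[:, i + 1, N_] = n_next
            coords[:, i + 1, CA_] = ca_next
            coords[:, i + 1, C_] = c_next
    return coords


def measure_dihedral(a, b, c, d) -> np.ndarray:
    """Signed dihedral angle a-b-c-d in degrees (IUPAC sign convention)."""
    b1 = np.asarray(b) - np.asarray(a)
    b2 = np.asarray(c) - np.asarray(b)
    b3 = np.asarray(d) - np.asarray(c)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def max_ca_distance(coords: np.ndarray) -> np.ndarray:
    """Maximum CA-CA distance L (Å) per conformer; coords (B, N, 5, 3)."""
    ca = coords[..., CA_, :]
    diff = ca[:, :, None, :] - ca[:, None, :, :]
    d2 = np.einsum("bijk,bijk->bij", diff, diff)
    return np.sqrt(d2.max(axis=(1, 2)))
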