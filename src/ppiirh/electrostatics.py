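"""Debye-screened Coulomb energies and charge patterning for model chains.

Charges are unit point charges placed at anchor atoms of a poly-alanine
conformer: the CB atom of a "charged residue" (standing in for a flexible
charged side chain), or the backbone N / O of the first / last residue for
terminal charges.  The interaction energy of a conformer is the pairwise
screened Coulomb sum

    dG = (332 / D) * sum_{i<j} Z_i Z_j exp(-kappa * R_ij) / R_ij   [kcal/mol]

with R_ij in Å, D the solvent dielectric and kappa the inverse Debye length,
kappa = 2.913 * sqrt(I / D) per Å for ionic strength I in molar.  At
I = 0.1 M and D = 78.3 the Debye length 1/kappa is 9.6 Å.  Ensembles are
population-weighted by Boltzmann factors of this energy at 25 °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "RT_25C",
    "ScreeningContext",
    "debye",
    "ChargeSite",
    "ChargeAssignment",
    "every_kth",
    "charge_clusters",
    "alternating",
    "alternating_clusters",
    "termini_only",
    "parse_pattern",
    "load_charges_tsv",
    "coulomb_energy",
    "nearest_charged_distance",
    "boltzmann_weights",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.987204259e-3
#: RT at 25 degC (kcal/mol).
RT_25C = R_KCAL * 298.15

_COULOMB_KCAL = 332.0  # q^2/(4 pi eps0), kcal*Å/mol for unit charges
_KAPPA_COEFF = 2.913  # 1/Å per sqrt(M), folds in sqrt(8 pi e^2 N_A / (1000 kB T))

Anchor = Literal["CB", "N", "O"]
_ANCHOR_ATOM = {"N": 0, "O": 3, "CB": 4}  # indices into the (N, CA, C, O, CB) layout


@dataclass(frozen=True)
class ScreeningContext:
    """Solution conditions entering the screened Coulomb energy."""

    ionic_strength: float
    dielectric: float = 78.3
    temperature: float = 298.15

    @property
    def kappa(self) -> float:
        """Inverse Debye length (1/Å)."""
        return _KAPPA_COEFF * np.sqrt(self.ionic_strength / self.dielectric)

    @property
    def debye_length(self) -> float:
        """1/kappa (Å); infinite in the unscreened I = 0 limit."""
        k = self.kappa
        return float("inf") if k == 0 else 1.0 / k


def debye(ionic_strength: float, dielectric: float = 78.3) -> ScreeningContext:
    """Screening context for an ionic strength (M) and solvent dielectric."""
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if dielectric <= 0:
        raise ValueError("dielectric must be > 0")
    return ScreeningContext(ionic_strength=ionic_strength, dielectric=dielectric)


@dataclass(frozen=True)
class ChargeSite:
    """A unit charge anchored at an atom of one residue."""

    residue: int
    anchor: Anchor
    z: int

    def __post_init__(self):
        if self.z not in (-1, 1):
            raise ValueError("site charge must be -1 or +1")
        if self.anchor not in _ANCHOR_ATOM:
            raise ValueError(f"unknown anchor {self.anchor!r}")


@dataclass(frozen=True)
class ChargeAssignment:
    """Immutable set of charge sites on an N-residue chain."""

    n_residues: int
    sites: tuple = field(default_factory=tuple)

    def __post_init__(self):
        seen = set()
        for s in self.sites:
            if not 0 <= s.residue < self.n_residues:
                raise ValueError(
                    f"charge at residue {s.residue} outside chain of length {self.n_residues}"
                )
            key = (s.residue, s.anchor)
            if key in seen:
                raise ValueError(f"duplicate charge anchor {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def charges(self) -> np.ndarray:
        return np.array([s.z for s in self.sites], dtype=float)

    def atom_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(residue index, atom index) arrays addressing a (B, N, 5, 3) array."""
        res = np.array([s.residue for s in self.sites], dtype=int)
        atom = np.array([_ANCHOR_ATOM[s.anchor] for s in self.sites], dtype=int)
        return res, atom

    def cb_residues(self) -> np.ndarray:
        """Sorted residue indices of side-chain (CB) charges."""
        return np.array(sorted(s.residue for s in self.sites if s.anchor == "CB"), dtype=int)

    def site_coords(self, coords: np.ndarray) -> np.ndarray:
        """Anchor coordinates (B, n_sites, 3) from conformer coords (B, N, 5, 3)."""
        res, atom = self.atom_indices()
        return coords[:, res, atom, :]


def _cb_sites(residues: Iterable[int], signs: Iterable[int], n: int) -> ChargeAssignment:
    sites = tuple(ChargeSite(int(r), "CB", int(z)) for r, z in zip(residues, signs))
    return ChargeAssignment(n_residues=n, sites=sites)


def every_kth(n: int, sign: int, k: int = 1) -> ChargeAssignment:
    """Identical charge at residues 0, k, 2k, ... (k = 1 charges every residue)."""
    if n < 2:
        raise ValueError("need at least 2 residues")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"stride {k} exceeds chain length {n}")
    res = range(0, n, k)
    return _cb_sites(res, [sign] * len(range(0, n, k)), n)


def charge_clusters(n: int, sign: int, size: int = 3, gap: int = 2) -> ChargeAssignment:
    """Like-charged clusters of ``size`` consecutive residues, ``gap`` apart."""
    if size < 1 or gap < 0:
        raise ValueError("size must be >= 1 and gap >= 0")
    if size > n:
        raise ValueError(f"cluster size {size} exceeds chain length {n}")
    res = [i for start in range(0, n, size + gap) for i in range(start, min(start + size, n))]
    return _cb_sites(res, [sign] * len(res), n)


def alternating(n: int, k: int = 1) -> ChargeAssignment:
    """Opposite charges at every k-th residue, starting negative."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"stride {k} exceeds chain length {n}")
    res = list(range(0, n, k))
    signs = [(-1) ** (j + 1) for j in range(len(res))]  # -1, +1, -1, ...
    return _cb_sites(res, signs, n)


def alternating_clusters(n: int, size: int = 3, gap: int = 0) -> ChargeAssignment:
    """Charged clusters with alternating cluster sign, starting negative."""
    if size < 1 or gap < 0:
        raise ValueError("size must be >= 1 and gap >= 0")
    if size > n:
        raise ValueError(f"cluster size {size} exceeds chain length {n}")
    res, signs = [], []
    sign = -1
    for start in range(0, n, size + gap):
        for i in range(start, min(start + size, n)):
            res.append(i)
            signs.append(sign)
        sign = -sign
    return _cb_sites(res, signs, n)


def termini_only(n: int) -> ChargeAssignment:
    """+1 at the N-terminal backbone N, -1 at the C-terminal backbone O."""
    if n < 2:
        raise ValueError("need at least 2 residues")
    return ChargeAssignment(
        n_residues=n,
        sites=(ChargeSite(0, "N", +1), ChargeSite(n - 1, "O", -1)),
    )


def parse_pattern(spec: str, n: int) -> ChargeAssignment | None:
    """Parse a compact charge-pattern string into an assignment.

    Grammar (colon-separated)::

        none                      no charges
        termini                   charged N- and C-termini
        neg:every:K | pos:every:K identical charge every K-th residue
        neg:cluster:SIZE:gapG     like-charged clusters, G residues apart
        alt:every:K               alternating single-residue charges
        alt:cluster:SIZE:gapG     alternating charge clusters
    """
    parts = spec.strip().lower().split(":")
    if parts[0] == "none":
        return None
    if parts[0] == "termini":
        return termini_only(n)
    sign = {"neg": -1, "pos": +1, "alt": 0}.get(parts[0])
    if sign is None or len(parts) < 2:
        raise ValueError(f"cannot parse charge pattern {spec!r}")
    kind = parts[1]
    if kind == "every":
        k = int(parts[2]) if len(parts) > 2 else 1
        return alternating(n, k) if sign == 0 else every_kth(n, sign, k)
    if kind == "cluster":
        size = int(parts[2]) if len(parts) > 2 else 3
        gap = 0
        if len(parts) > 3:
            if not parts[3].startswith("gap"):
                raise ValueError(f"cannot parse charge pattern {spec!r}")
            gap = int(parts[3][3:])
        if sign == 0:
            return alternating_clusters(n, size, gap)
        return charge_clusters(n, sign, size, gap)
    raise ValueError(f"cannot parse charge pattern {spec!r}")


def load_charges_tsv(path, n: int) -> ChargeAssignment:
    """Read an explicit charge table: TSV columns residue_index, anchor, sign.

    ``residue_index`` is zero-based; ``anchor`` is CB, N or O; ``sign`` is
    +1/-1 (or +/-).  '#' lines are comments.
    """
    sites = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        res, anchor, sign = line.split("\t")
        z = {"+": 1, "-": -1}.get(sign.strip(), None)
        if z is None:
            z = int(sign)
        sites.append(ChargeSite(int(res), anchor.strip(), z))
    return ChargeAssignment(n_residues=n, sites=tuple(sites))


def coulomb_energy(site_coords: np.ndarray, charges: np.ndarray,
                   ctx: ScreeningContext) -> np.ndarray:
    """Screened Coulomb energy (kcal/mol) per conformer.

    ``site_coords`` is (B, S, 3) anchor coordinates (a single conformer may
    be passed as (S, 3)); ``charges`` is length S.  Zero when S < 2.
    """
    single = site_coords.ndim == 2
    xyz = site_coords[None] if single else site_coords
    z = np.asarray(charges, dtype=float)
    s = xyz.shape[1]
    if z.shape != (s,):
        raise ValueError("charges length must match number of sites")
    if s < 2:
        out = np.zeros(xyz.shape[0])
        return float(out[0]) if single else out
    iu, ju = np.triu_indices(s, k=1)
    diff = xyz[:, iu] - xyz[:, ju]
    r = np.sqrt(np.einsum("bpk,bpk->bp", diff, diff))
    if np.any(r < 1e-6):
        raise ValueError("two charges at (near-)identical coordinates")
    zz = z[iu] * z[ju]
    e = (_COULOMB_KCAL / ctx.dielectric) * np.sum(
        zz * np.exp(-ctx.kappa * r) / r, axis=1
    )
    return float(e[0]) if single else e


def nearest_charged_distance(coords: np.ndarray, assignment: ChargeAssignment,
                             weights: np.ndarray | None = None) -> float:
    """Ensemble-averaged CB-CB distance between sequence-adjacent charged residues.

    ``coords`` is a conformer stack (B, N, 5, 3); only side-chain (CB)
    charges qualify, and "adjacent" means consecutive in the sequence order
    of the charged residues.  Terminal backbone charges have no CB anchor,
    so an assignment with fewer than two side-chain charges is an error.
    """
    cb = assignment.cb_residues()
    if len(cb) < 2:
        raise ValueError("need at least two side-chain (CB) charges")
    xyz = coords[:, cb, 4, :]
    d = np.linalg.norm(np.diff(xyz, axis=1), axis=2).mean(axis=1)
    if weights is None:
        return float(d.mean())
    w = np.asarray(weights, dtype=float)
    return float(np.sum(d * w) / w.sum())


def boltzmann_weights(energies, temperature: float = 298.15) -> np.ndarray:
    """Normalized Boltzmann probabilities exp(-E/RT) of a list of energies."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy list")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    rt = R_KCAL * temperature
    w = np.exp(-(e - e.min()) / rt)
    return w / w.sum()
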