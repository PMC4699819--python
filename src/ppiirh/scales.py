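"""Amino-acid polyproline-II (PPII) propensity scales.

A propensity scale maps each of the 20 standard amino acids to the intrinsic
fraction of time its backbone samples the PPII conformation when placed as a
guest residue in a short disordered host peptide.  Three experimental scales
are packaged (named after the groups that measured them: Kallenbach, Creamer,
Hilser), together with two reference scales used as controls:

``null``
    every residue at the random-coil background propensity 0.012, i.e. the
    PPII fraction an excluded-volume chain shows with no applied bias;
``static``
    every residue at 0.364, the average apparent chain propensity obtained by
    inverting the hydrodynamic scaling law on a reference set of disordered
    proteins.

Scales measured in different host peptides disagree substantially (e.g. the
reported alanine propensities span 0.37-0.818), so a context-dependent
*composite* lookup is also provided: Hilser values by default, Kallenbach
values for residues flanked by glycines (G-X-G) and Creamer values for
residues flanked by prolines (P-X-P), mirroring each scale's host context.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "STANDARD_AA",
    "NULL_PROPENSITY",
    "STATIC_FPPII",
    "PropensityScale",
    "BUILTIN_SCALE_NAMES",
    "load_builtin_scale",
    "load_scale_tsv",
    "scale_average",
    "position_propensity",
    "random_scale",
    "random_scales",
]

#: The 20 standard amino acids, one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Background PPII fraction of an unbiased excluded-volume chain.
NULL_PROPENSITY = 0.012

#: Dataset-averaged apparent chain PPII fraction (scaling-law inversion).
STATIC_FPPII = 0.364

BUILTIN_SCALE_NAMES = ("kallenbach", "creamer", "hilser", "null", "static")

_HOSTS = {
    "kallenbach": "Ac-G2XG2-NH2",
    "creamer": "Ac-P3XP3GY-NH2",
    "hilser": "Ac-VP2XVP2R3Y-NH2",
    "null": "random-coil background (no host)",
    "static": "dataset-average apparent propensity (no host)",
}


@dataclass(frozen=True)
class PropensityScale:
    """Mapping from one-letter amino-acid codes to PPII propensities.

    Parameters
    ----------
    name : str
        Identifier of the scale.
    host_peptide : str
        Free-text description of the host peptide the propensities were
        measured in (or of the rule that defined them).
    values : mapping
        Code -> propensity, each in [0, 1].  Built-in scales are complete
        over the 20 standard residues; user scales may be partial, but
        looking up a missing residue raises ``KeyError``.
    imputed : frozenset of str
        Residues whose value was assigned rather than measured.
    """

    name: str
    host_peptide: str
    values: Mapping[str, float]
    imputed: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        for code, val in self.values.items():
            if code not in STANDARD_AA:
                raise ValueError(f"non-standard residue code {code!r} in scale {self.name!r}")
            if not 0.0 <= float(val) <= 1.0:
                raise ValueError(
                    f"propensity for {code} in scale {self.name!r} is {val}, outside [0, 1]"
                )

    def __getitem__(self, code: str) -> float:
        try:
            return float(self.values[code])
        except KeyError:
            raise KeyError(
                f"residue {code!r} has no propensity in scale {self.name!r}"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code in self.values

    def is_complete(self) -> bool:
        return all(code in self.values for code in STANDARD_AA)

    def as_array(self) -> np.ndarray:
        """Propensities ordered as :data:`STANDARD_AA` (complete scales only)."""
        if not self.is_complete():
            raise ValueError(f"scale {self.name!r} is missing residues")
        return np.array([self.values[c] for c in STANDARD_AA], dtype=float)

    def mean(self, residues: Iterable[str] | None = None) -> float:
        return scale_average(self, residues)


def _constant_scale(name: str, value: float) -> PropensityScale:
    return PropensityScale(
        name=name,
        host_peptide=_HOSTS[name],
        values={c: value for c in STANDARD_AA},
        imputed=frozenset(),
    )


def load_scale_tsv(path, name: str | None = None, host_peptide: str = "") -> PropensityScale:
    """Read a scale from a two/three-column TSV (code, propensity[, provenance]).

    Lines starting with ``#`` are comments.  A third column equal to
    ``imputed`` flags assigned values.
    """
    path = Path(path)
    values: dict[str, float] = {}
    imputed: set[str] = set()
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed scale line in {path}: {raw!r}")
        code = parts[0].strip().upper()
        values[code] = float(parts[1])
        if len(parts) >= 3 and parts[2].strip().lower() == "imputed":
            imputed.add(code)
    return PropensityScale(
        name=name or path.stem,
        host_peptide=host_peptide,
        values=values,
        imputed=frozenset(imputed),
    )


def load_builtin_scale(name: str) -> PropensityScale:
    """Return one of the packaged scales.

    ``kallenbach``, ``creamer`` and ``hilser`` are the experimental sets
    (with the documented imputations applied so all 20 residues resolve);
    ``null`` assigns 0.012 to every residue and ``static`` assigns 0.364.
    """
    key = name.lower()
    if key not in BUILTIN_SCALE_NAMES:
        raise ValueError(
            f"unknown scale {name!r}; built-ins are {', '.join(BUILTIN_SCALE_NAMES)}"
        )
    if key == "null":
        return _constant_scale("null", NULL_PROPENSITY)
    if key == "static":
        return _constant_scale("static", STATIC_FPPII)
    ref = importlib.resources.files("ppiirh.data") / f"{key}.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_scale_tsv(path, name=key, host_peptide=_HOSTS[key])


def scale_average(scale: PropensityScale, residues: Iterable[str] | None = None) -> float:
    """Arithmetic mean of the scale over ``residues`` (default: all present).

    The experimental tables report their averages over the *measured*
    residues only; pass e.g. ``set(STANDARD_AA) - scale.imputed`` to
    reproduce those.
    """
    if residues is None:
        residues = list(scale.values)
    residues = list(residues)
    if not residues:
        raise ValueError("empty residue subset")
    return float(np.mean([scale[c] for c in residues]))


def position_propensity(sequence, i: int, scale="composite") -> float:
    """Propensity of residue ``i`` of ``sequence`` under a scale or the composite rule.

    With a :class:`PropensityScale`, this is a plain lookup.  With the string
    ``"composite"``, the flanking residues select the scale: Kallenbach for a
    G-X-G context, Creamer for P-X-P, Hilser otherwise (including at the
    chain termini, where no flanking pair exists).
    """
    residues = getattr(sequence, "residues", sequence)
    n = len(residues)
    if not 0 <= i < n:
        raise IndexError(f"position {i} outside sequence of length {n}")
    for pos, code in enumerate(residues):
        if code not in STANDARD_AA:
            raise ValueError(f"non-standard residue {code!r} at position {pos}")
    if isinstance(scale, PropensityScale):
        return scale[residues[i]]
    if scale != "composite":
        raise ValueError(f"scale must be a PropensityScale or 'composite', got {scale!r}")
    scales = _composite_scales()
    if 0 < i < n - 1:
        left, right = residues[i - 1], residues[i + 1]
        if left == "G" and right == "G":
            return scales["kallenbach"][residues[i]]
        if left == "P" and right == "P":
            return scales["creamer"][residues[i]]
    return scales["hilser"][residues[i]]


_COMPOSITE_CACHE: dict[str, PropensityScale] = {}


def _composite_scales() -> dict[str, PropensityScale]:
    if not _COMPOSITE_CACHE:
        for key in ("kallenbach", "creamer", "hilser"):
            _COMPOSITE_CACHE[key] = load_builtin_scale(key)
    return _COMPOSITE_CACHE


# ---------------------------------------------------------------------------
# Random scales
# ---------------------------------------------------------------------------

def _slab_hit_and_run(targets: np.ndarray, tol: float, rng: np.random.Generator,
                      n_sweeps: int = 500) -> np.ndarray:
    """Uniform samples from {x in [0,1]^20 : |mean(x) - t| <= tol}, one row per target.

    Hit-and-run over the convex slab; each chain starts at the constant
    vector x = t (which always lies inside) and mixes for ``n_sweeps``
    random directions.  Runs all chains in lockstep.
    """
    d = 20
    m = targets.shape[0]
    x = np.clip(np.repeat(targets[:, None], d, axis=1), 0.0, 1.0)
    lo_sum = np.maximum((targets - tol) * d, 0.0)
    hi_sum = np.minimum((targets + tol) * d, float(d))
    for _ in range(n_sweeps):
        u = rng.standard_normal((m, d))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            t0 = (0.0 - x) / u
            t1 = (1.0 - x) / u
        lo = np.where(u > 0, t0, t1)
        hi = np.where(u > 0, t1, t0)
        # atoms with u == 0 impose no constraint
        lo[u == 0] = -np.inf
        hi[u == 0] = np.inf
        lam_lo = lo.max(axis=1)
        lam_hi = hi.min(axis=1)
        s = x.sum(axis=1)
        us = u.sum(axis=1)
        nz = np.abs(us) > 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (lo_sum - s) / us
            b = (hi_sum - s) / us
        slo = np.where(us > 0, a, b)
        shi = np.where(us > 0, b, a)
        lam_lo = np.where(nz, np.maximum(lam_lo, slo), lam_lo)
        lam_hi = np.where(nz, np.minimum(lam_hi, shi), lam_hi)
        lam = lam_lo + (lam_hi - lam_lo) * rng.random(m)
        x = np.clip(x + lam[:, None] * u, 0.0, 1.0)
    return x


def random_scales(n_scales: int, rng_seed: int | np.random.Generator,
                  target_tolerance: float = 0.05) -> list[PropensityScale]:
    """Generate random propensity scales by the two-step targeting protocol.

    Step one draws a target average uniformly on [0, 1] for each scale; step
    two draws the 20 residue values i.i.d. uniform on [0, 1] conditioned on
    their mean lying within ``target_tolerance`` of the target.  The
    conditional draw is realised by hit-and-run sampling over the mean-
    constrained cube, so every target — including extreme ones a naive
    accept/reject loop could never hit — is served, and scale means end up
    approximately uniform on [0, 1].
    """
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    if target_tolerance <= 0:
        raise ValueError("target_tolerance must be > 0")
    rng = np.random.default_rng(rng_seed)
    targets = rng.random(n_scales)
    xs = _slab_hit_and_run(targets, target_tolerance, rng)
    out = []
    for k in range(n_scales):
        values = dict(zip(STANDARD_AA, xs[k]))
        out.append(
            PropensityScale(
                name=f"random-{k}",
                host_peptide=f"random target={targets[k]:.4f} tol={target_tolerance}",
                values=values,
            )
        )
    return out


def random_scale(rng_seed: int | np.random.Generator,
                 target_tolerance: float = 0.05) -> PropensityScale:
    """Single random scale; see :func:`random_scales`."""
    return random_scales(1, rng_seed, target_tolerance)[0]
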