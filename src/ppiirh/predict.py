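"""Hydrodynamic radius prediction from sequence PPII propensity.

The central relation is a power law in chain length whose exponent grows
logarithmically with the chain's PPII fraction::

    Rh(N, f) = 2.16 * N ** (0.503 - 0.11 * ln(1 - f))

with ``N`` the residue count and ``f`` the chain-averaged PPII propensity
(``f_PPII,chain``), obtained from a propensity scale by averaging the
per-residue values over the sequence.  The constants were fit to
hard-sphere-collision ensemble simulations (see :mod:`ppiirh.fitting`).

Reference baselines:

* random coil: the same relation at the background propensity f = 0.012;
* Marsh/Forman-Kay: Rh = R0 * N**0.509 with R0 depending on proline
  fraction and absolute net charge;
* chemically denatured chains: Rh = 2.2 * N**0.57.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import scales as _scales
from . import sequences as _sequences
from .scales import PropensityScale, position_propensity

__all__ = [
    "RH_PREFACTOR",
    "V0",
    "BETA",
    "predict_rh",
    "scaling_exponent",
    "apparent_fppii",
    "random_coil_rh",
    "marsh_forman_kay_r0",
    "marsh_forman_kay_rh",
    "denatured_rh",
    "chain_fppii",
    "PredictionResult",
    "predict_sequence",
    "DatasetEvaluation",
    "evaluate_dataset",
]

#: Power-law prefactor R0 (Å) of the scaling relation.
RH_PREFACTOR = 2.16
#: Scaling exponent at zero PPII content.
V0 = 0.503
#: Logarithmic growth coefficient of the exponent with PPII content.
BETA = -0.11

_MFK_EXPONENT = 0.509
_DENATURED_R0 = 2.2
_DENATURED_EXPONENT = 0.57


def scaling_exponent(f_ppii_chain):
    """Exponent v(f) = 0.503 - 0.11 * ln(1 - f)."""
    f = np.asarray(f_ppii_chain, dtype=float)
    if np.any(f < 0) or np.any(f >= 1):
        raise ValueError("f_ppii_chain must lie in [0, 1)")
    out = V0 + BETA * np.log1p(-f)
    return float(out) if out.ndim == 0 else out


def predict_rh(n, f_ppii_chain):
    """Hydrodynamic radius (Å) of an N-residue chain with PPII fraction f."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("N must be >= 1")
    v = scaling_exponent(f_ppii_chain)
    out = RH_PREFACTOR * n_arr**v
    return float(out) if np.ndim(out) == 0 else out


def apparent_fppii(rh, n):
    """Invert the scaling relation: the chain PPII fraction implied by an Rh.

    Exact round trip of :func:`predict_rh`; this inversion over an observed
    dataset is how the ``static`` scale's 0.364 value is defined.
    """
    rh_arr = np.asarray(rh, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(rh_arr <= 0) or np.any(n_arr < 2):
        raise ValueError("need rh > 0 and N >= 2")
    v = np.log(rh_arr / RH_PREFACTOR) / np.log(n_arr)
    out = -np.expm1((v - V0) / BETA)
    return float(out) if np.ndim(out) == 0 else out


def random_coil_rh(n):
    """Rh (Å) of the random-coil (null) model: f = 0.012."""
    return predict_rh(n, _scales.NULL_PROPENSITY)


def marsh_forman_kay_r0(f_pro: float, abs_q: int) -> float:
    """Power-law prefactor R0 (Å) from proline fraction and |net charge|."""
    if not 0.0 <= f_pro <= 1.0:
        raise ValueError("f_pro must be in [0, 1]")
    if abs_q < 0:
        raise ValueError("abs_q must be >= 0")
    return (1.24 * f_pro + 0.904) * (0.00759 * abs_q + 0.963) * 2.49


def marsh_forman_kay_rh(n: int, f_pro: float, abs_q: int) -> float:
    """Rh (Å) from the empirical IDP baseline R0 * N**0.509."""
    if n < 1:
        raise ValueError("N must be >= 1")
    return marsh_forman_kay_r0(f_pro, abs_q) * n**_MFK_EXPONENT


def denatured_rh(n: int) -> float:
    """Rh (Å) of a chemically denatured chain: 2.2 * N**0.57."""
    if n < 1:
        raise ValueError("N must be >= 1")
    return _DENATURED_R0 * n**_DENATURED_EXPONENT


def chain_fppii(sequence, scale="composite") -> float:
    """Chain PPII fraction: mean per-residue propensity over the sequence.

    ``scale`` is a :class:`~ppiirh.scales.PropensityScale` or the string
    ``"composite"`` for the context-dependent lookup.
    """
    residues = getattr(sequence, "residues", sequence)
    n = len(residues)
    if n < 1:
        raise ValueError("empty sequence")
    if isinstance(scale, PropensityScale):
        return float(np.mean([scale[c] for c in residues]))
    return float(
        np.mean([position_propensity(residues, i, scale) for i in range(n)])
    )


@dataclass(frozen=True)
class PredictionResult:
    """Predicted Rh of one sequence under one scale."""

    id: str
    n: int
    rh_pred: float
    f_ppii_chain: float
    v: float
    scale_name: str


def predict_sequence(sequence, scale="composite") -> PredictionResult:
    """Predict Rh for a single sequence record."""
    residues = getattr(sequence, "residues", sequence)
    f = chain_fppii(residues, scale)
    n = len(residues)
    name = scale.name if isinstance(scale, PropensityScale) else str(scale)
    return PredictionResult(
        id=getattr(sequence, "id", "seq"),
        n=n,
        rh_pred=predict_rh(n, f),
        f_ppii_chain=f,
        v=scaling_exponent(f),
        scale_name=name,
    )


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of the OLS line of y on x."""
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.linregress(x, y).rvalue ** 2)


@dataclass(frozen=True)
class DatasetEvaluation:
    """Per-protein table plus dataset summaries of prediction quality."""

    table: pd.DataFrame
    mean_abs_error: float
    sd_abs_error: float
    r2_pred_obs: float
    mean_norm_error: float
    sd_norm_error: float
    r2_nerr_ncd: float
    r2_nerr_ncd_high_bias: float
    r2_nerr_ncd_low_bias: float
    dataset_charge_bias: float
    scale_name: str


def evaluate_dataset(records, observed_rh, scale="composite") -> DatasetEvaluation:
    """Evaluate Rh predictions against observed values for a dataset.

    Parameters
    ----------
    records : sequence of SequenceRecord
    observed_rh : mapping id -> observed Rh (Å), or a pandas Series
    scale : PropensityScale or "composite"

    Per protein the table carries the prediction, the absolute error, the
    normalized error (predicted - observed)/(random-coil Rh), and the charge
    statistics; the summaries include the error moments, R² of predicted vs
    observed Rh, and R² of normalized error vs net charge density — overall
    and split into high/low charge-bias subsets at the charge bias of the
    concatenated dataset sequence.
    """
    records = list(records)
    if not records:
        raise ValueError("empty dataset")
    obs = pd.Series(dict(observed_rh)) if not isinstance(observed_rh, pd.Series) else observed_rh

    rows = []
    for rec in records:
        if rec.id not in obs.index:
            raise KeyError(f"no observed Rh for {rec.id!r}")
        rh_obs = float(obs[rec.id])
        if rh_obs <= 0:
            raise ValueError(f"observed Rh for {rec.id!r} must be > 0")
        pred = predict_sequence(rec, scale)
        rc = random_coil_rh(rec.n)
        cs = _sequences.charge_stats(rec, rc)
        rows.append(
            {
                "id": rec.id,
                "n": rec.n,
                "f_ppii_chain": pred.f_ppii_chain,
                "rh_pred": pred.rh_pred,
                "rh_obs": rh_obs,
                "abs_error": abs(pred.rh_pred - rh_obs),
                "norm_error": (pred.rh_pred - rh_obs) / rc,
                "random_coil_rh": rc,
                "net_charge": cs.net_charge,
                "ncd": cs.ncd,
                "net_adjacent_charge": cs.net_adjacent_charge,
                "nacd": cs.nacd,
                "charge_bias": cs.charge_bias,
            }
        )
    table = pd.DataFrame(rows)

    concatenated = "".join(rec.residues for rec in records)
    split_bias = _sequences.charge_bias(concatenated)
    if split_bias is None:
        split_bias = math.inf

    bias = table["charge_bias"].astype(float)
    high = bias > split_bias
    low = ~high

    def subset_r2(mask) -> float:
        sub = table[mask]
        return _r2(sub["ncd"].to_numpy(), sub["norm_error"].to_numpy())

    name = scale.name if isinstance(scale, PropensityScale) else str(scale)
    return DatasetEvaluation(
        table=table,
        mean_abs_error=float(table["abs_error"].mean()),
        sd_abs_error=float(table["abs_error"].std(ddof=1)) if len(table) > 1 else 0.0,
        r2_pred_obs=_r2(table["rh_pred"].to_numpy(), table["rh_obs"].to_numpy()),
        mean_norm_error=float(table["norm_error"].mean()),
        sd_norm_error=float(table["norm_error"].std(ddof=1)) if len(table) > 1 else 0.0,
        r2_nerr_ncd=_r2(table["ncd"].to_numpy(), table["norm_error"].to_numpy()),
        r2_nerr_ncd_high_bias=subset_r2(high),
        r2_nerr_ncd_low_bias=subset_r2(low),
        dataset_charge_bias=float(split_bias),
        scale_name=name,
    )
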