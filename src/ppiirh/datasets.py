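"""Loading observed-Rh benchmark datasets.

The published 22-protein benchmark (names, lengths, observed hydrodynamic
radii and sequences) lives in journal supplementary tables that are not
redistributed with this package.  If you have them, save a tab-separated
file with columns ``id``, ``sequence``, ``rh_obs`` (Å) — extra columns are
ignored — and point :func:`load_idp_dataset` at it, or drop it into the
package data directory as ``idp_dataset.tsv``.  When the file is absent the
synthetic stand-in (:mod:`ppiirh.synthetic`) is the way to exercise the
dataset-level machinery.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

from .sequences import SequenceRecord

__all__ = ["load_idp_dataset", "idp_dataset_available", "load_observed_rh_tsv"]

_FIXTURE_NAME = "idp_dataset.tsv"


def _fixture_path() -> Path | None:
    ref = importlib.resources.files("ppiirh.data") / _FIXTURE_NAME
    try:
        with importlib.resources.as_file(ref) as p:
            return p if p.exists() else None
    except FileNotFoundError:
        return None


def idp_dataset_available(path=None) -> bool:
    """Whether a benchmark table is present (packaged or at ``path``)."""
    if path is not None:
        return Path(path).exists()
    return _fixture_path() is not None


def load_idp_dataset(path=None) -> tuple[list[SequenceRecord], pd.Series]:
    """Load a benchmark table into (records, observed-Rh Series).

    Looks at ``path`` if given, otherwise for the packaged
    ``idp_dataset.tsv``.  Raises ``FileNotFoundError`` when neither exists.
    """
    p = Path(path) if path is not None else _fixture_path()
    if p is None or not p.exists():
        raise FileNotFoundError(
            "no benchmark dataset found; supply a TSV with columns "
            "id, sequence, rh_obs (see ppiirh.datasets docstring)"
        )
    df = pd.read_csv(p, sep="\t", comment="#")
    required = {"id", "sequence", "rh_obs"}
    if not required.issubset(df.columns):
        raise ValueError(f"dataset {p} must have columns {sorted(required)}")
    records = [
        SequenceRecord(id=str(r.id), residues=str(r.sequence).upper())
        for r in df.itertuples()
    ]
    observed = pd.Series(df["rh_obs"].to_numpy(), index=df["id"].astype(str), name="rh_obs")
    return records, observed


def load_observed_rh_tsv(path) -> pd.Series:
    """Observed-Rh table: TSV with columns ``id`` and ``rh_obs`` (Å)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"id", "rh_obs"}.issubset(df.columns):
        raise ValueError(f"{path} must have columns id, rh_obs")
    return pd.Series(df["rh_obs"].to_numpy(), index=df["id"].astype(str), name="rh_obs")
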