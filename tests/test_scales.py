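"""Propensity-scale tables, imputation, composite lookup and random scales."""

import numpy as np
import pytest
from scipy import stats

import ppiirh
from ppiirh.scales import (
    STANDARD_AA,
    PropensityScale,
    load_builtin_scale,
    position_propensity,
    random_scales,
    scale_average,
)


@pytest.mark.parametrize(
    "name,code,value",
    [
        ("kallenbach", "A", 0.818),
        ("kallenbach", "P", 1.00),  # imputed: strongest accepted PPII former
        ("kallenbach", "G", 0.50),  # imputed compromise value
        ("creamer", "W", 0.58),  # imputed with the 18-residue average
        ("creamer", "Y", 0.58),
        ("hilser", "P", 1.00),
        ("hilser", "A", 0.37),
        ("null", "G", 0.012),
        ("static", "Q", 0.364),
    ],
)
def test_builtin_values(name, code, value):
    assert load_builtin_scale(name)[code] == pytest.approx(value)


def test_builtins_complete_and_flagged(builtin_scales):
    for name, scale in builtin_scales.items():
        assert scale.is_complete()
        for code in STANDARD_AA:
            assert 0.0 <= scale[code] <= 1.0
    assert builtin_scales["kallenbach"].imputed == {"P", "G"}
    assert builtin_scales["creamer"].imputed == {"W", "Y"}
    assert builtin_scales["hilser"].imputed == frozenset()


def test_unknown_builtin_names_available():
    with pytest.raises(ValueError, match="hilser"):
        load_builtin_scale("zondlo")


@pytest.mark.parametrize(
    "name,subset,decimals,value",
    [
        ("hilser", None, 2, 0.35),
        ("kallenbach", "measured", 3, 0.626),
        ("creamer", "measured", 2, 0.58),
    ],
)
def test_table_averages(builtin_scales, name, subset, decimals, value):
    """The printed per-scale averages (over the measured residues only)."""
    scale = builtin_scales[name]
    residues = None if subset is None else sorted(set(STANDARD_AA) - scale.imputed)
    assert round(scale_average(scale, residues), decimals) == pytest.approx(value)


def test_average_constant_scale_and_errors():
    flat = PropensityScale("flat", "", {c: 0.5 for c in STANDARD_AA})
    assert scale_average(flat, ["A", "W", "P"]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        scale_average(flat, [])


def test_partial_scale_lookup_is_error():
    partial = PropensityScale("partial", "", {"A": 0.3})
    assert partial["A"] == 0.3
    with pytest.raises(KeyError, match="G"):
        partial["G"]


@pytest.mark.parametrize(
    "seq,i,expected",
    [
        ("GAG", 1, 0.818),  # G-X-G context -> Kallenbach ALA
        ("PAP", 1, 0.61),  # P-X-P context -> Creamer ALA
        ("VAV", 1, 0.37),  # default -> Hilser ALA
        ("GGG", 1, 0.50),  # literal triplet test applies to G itself
        ("AAA", 0, 0.37),  # terminal residue falls back to Hilser
        ("GAGA", 3, 0.37),
    ],
)
def test_composite_rule(seq, i, expected):
    assert position_propensity(seq, i, "composite") == pytest.approx(expected)


def test_position_propensity_errors():
    with pytest.raises(ValueError, match="position 1"):
        position_propensity("AXA", 0)
    with pytest.raises(IndexError):
        position_propensity("AAA", 3)


def test_random_scales_reproducible_and_targeted():
    a = random_scales(5, rng_seed=42)
    b = random_scales(5, rng_seed=42)
    for sa, sb in zip(a, b):
        assert all(sa[c] == sb[c] for c in STANDARD_AA)
    for s in a:
        vals = s.as_array()
        assert np.all(vals >= 0) and np.all(vals <= 1)
        target = float(s.host_peptide.split("target=")[1].split()[0])
        assert abs(vals.mean() - target) <= 0.05 + 1e-12


def test_random_scale_means_cover_unit_interval():
    """The two-step targeting yields scale means ~uniform on [0, 1]."""
    scales = random_scales(10_000, rng_seed=7)
    means = np.array([s.as_array().mean() for s in scales])
    d = stats.kstest(means, "uniform").statistic
    assert d < 0.05
    # extreme targets are actually reachable
    assert means.min() < 0.1 and means.max() > 0.9
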