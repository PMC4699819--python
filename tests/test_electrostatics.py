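"""Screened Coulomb energies, charge patterns and Boltzmann weighting."""

import numpy as np
import pytest

from ppiirh import electrostatics as el
from ppiirh import simulator as sim


def test_debye_length_reference_conditions():
    assert el.debye(0.1, 78.3).debye_length == pytest.approx(9.6, abs=0.05)
    assert el.debye(0.0, 78.3).kappa == 0.0
    assert el.debye(0.0, 78.3).debye_length == np.inf
    # quadrupling the ionic strength halves the Debye length
    assert el.debye(0.4, 78.3).debye_length == pytest.approx(4.8, abs=0.05)
    with pytest.raises(ValueError):
        el.debye(-0.1)
    with pytest.raises(ValueError):
        el.debye(0.1, 0.0)


def test_coulomb_pair_at_debye_length():
    """(332/78.3) * e^-1 / 9.6 for a like pair separated by one Debye length."""
    ctx = el.debye(0.1, 78.3)
    r = ctx.debye_length
    xyz = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    e = el.coulomb_energy(xyz, [1, 1], ctx)
    assert e == pytest.approx(0.163, abs=2e-3)


def test_coulomb_edge_cases():
    ctx = el.debye(0.1)
    assert el.coulomb_energy(np.zeros((4, 0, 3)), [], ctx).tolist() == [0.0] * 4
    xyz = np.array([[0.0, 0, 0], [5.0, 0, 0], [9.0, 3, 0]])
    flipped = el.coulomb_energy(xyz, [-1, 1, -1], ctx)
    assert el.coulomb_energy(xyz, [1, -1, 1], ctx) == pytest.approx(flipped)
    with pytest.raises(ValueError):
        el.coulomb_energy(np.zeros((2, 3)), [1, -1], ctx)


def test_coulomb_screening_limits():
    xyz = np.array([[0.0, 0, 0], [7.0, 0, 0]])
    bare = el.coulomb_energy(xyz, [1, 1], el.debye(0.0))
    assert bare == pytest.approx(332.0 / 78.3 / 7.0)
    assert el.coulomb_energy(xyz, [1, 1], el.debye(50.0)) < 1e-3 * bare


def test_boltzmann_weights():
    assert np.allclose(el.boltzmann_weights([3.0, 3.0, 3.0]), 1 / 3)
    w = el.boltzmann_weights([0.0, el.RT_25C * np.log(2.0)])
    assert np.allclose(w, [2 / 3, 1 / 3])
    assert el.boltzmann_weights(np.random.default_rng(0).normal(size=50)).sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        el.boltzmann_weights([])
    with pytest.raises(ValueError):
        el.boltzmann_weights([1.0], temperature=0.0)


def test_every_kth_patterns():
    a = el.every_kth(25, -1, 1)
    assert len(a) == 25
    assert all(s.anchor == "CB" and s.z == -1 for s in a.sites)
    b = el.every_kth(25, +1, 2)
    assert [s.residue for s in b.sites] == list(range(0, 25, 2))
    with pytest.raises(ValueError):
        el.every_kth(25, -1, 25)


def test_cluster_pattern_enumeration():
    """Three-residue clusters with two intervening residues, 25-mer."""
    a = el.charge_clusters(25, -1, size=3, gap=2)
    expected = [0, 1, 2, 5, 6, 7, 10, 11, 12, 15, 16, 17, 20, 21, 22]
    assert [s.residue for s in a.sites] == expected


def test_alternating_patterns():
    a = el.alternating(6, 1)
    assert [(s.residue, s.z) for s in a.sites] == [
        (0, -1), (1, 1), (2, -1), (3, 1), (4, -1), (5, 1)
    ]
    b = el.alternating_clusters(9, size=3, gap=0)
    assert [s.z for s in b.sites] == [-1] * 3 + [1] * 3 + [-1] * 3


def test_termini_pattern_and_validation():
    t = el.termini_only(10)
    assert [(s.residue, s.anchor, s.z) for s in t.sites] == [
        (0, "N", 1), (9, "O", -1)
    ]
    with pytest.raises(ValueError):
        el.ChargeAssignment(5, (el.ChargeSite(7, "CB", 1),))
    with pytest.raises(ValueError):
        el.ChargeAssignment(
            5, (el.ChargeSite(1, "CB", 1), el.ChargeSite(1, "CB", -1))
        )


@pytest.mark.parametrize(
    "spec,n_sites",
    [
        ("none", None),
        ("termini", 2),
        ("neg:every:2", 13),
        ("pos:every:1", 25),
        ("alt:every:3", 9),
        ("neg:cluster:3:gap2", 15),
        ("alt:cluster:3", 25),  # gap 0: clusters tile the whole chain
    ],
)
def test_parse_pattern(spec, n_sites):
    got = el.parse_pattern(spec, 25)
    if n_sites is None:
        assert got is None
    else:
        assert len(got) == n_sites
    with pytest.raises(ValueError):
        el.parse_pattern("sideways:3", 25)


def test_load_charges_tsv(tmp_path):
    path = tmp_path / "charges.tsv"
    path.write_text("# residue\tanchor\tsign\n0\tN\t+\n3\tCB\t-1\n9\tO\t-\n")
    a = el.load_charges_tsv(path, 10)
    assert [(s.residue, s.anchor, s.z) for s in a.sites] == [
        (0, "N", 1), (3, "CB", -1), (9, "O", -1)
    ]


def test_nearest_charged_distance():
    rng = np.random.default_rng(4)
    coords, _, _, _ = sim.grow_conformers(sim.uniform_bias(20, 0.2), rng, 200)
    two = el.ChargeAssignment(
        20, (el.ChargeSite(2, "CB", -1), el.ChargeSite(10, "CB", -1))
    )
    d_pair = np.linalg.norm(coords[:, 2, 4] - coords[:, 10, 4], axis=1).mean()
    assert el.nearest_charged_distance(coords, two) == pytest.approx(d_pair)
    # mean adjacent-charge spacing grows with the pattern stride
    d = {
        k: el.nearest_charged_distance(coords, el.every_kth(20, -1, k))
        for k in (1, 2, 3)
    }
    assert d[1] < d[2] < d[3]
    with pytest.raises(ValueError):
        el.nearest_charged_distance(coords, el.termini_only(20))


def test_charged_reweighting_extends_ensemble():
    """Like charges at every residue visibly expand a 15-mer ensemble."""
    un = sim.simulate_ensemble(15, 0.3, rng_seed=11, min_accepted=1500)
    ch = sim.simulate_ensemble(
        15, 0.3, charges=el.every_kth(15, -1, 1), rng_seed=11, min_accepted=1500
    )
    assert ch.rh > un.rh * 1.1
    assert ch.mean_rij is not None and ch.mean_rij > 0
    assert ch.mean_energy > 0
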