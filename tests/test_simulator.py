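"""Hard-sphere ensemble generation: sampling, clash filter, convergence."""

import numpy as np
import pytest

import ppiirh
from ppiirh import geometry as geom
from ppiirh import simulator as sim


def test_bias_validation():
    with pytest.raises(ValueError):
        sim.BiasSpec(np.array([0.5, 1.2]))
    b = sim.patterned_bias(10, 0.6, 3)
    assert b.s_ppii.tolist() == [0.6, 0, 0, 0.6, 0, 0, 0.6, 0, 0, 0.6]


def test_sample_dihedrals_full_bias_all_in_window():
    bias = sim.uniform_bias(12, 1.0)
    phi, psi, _ = sim.sample_dihedrals(bias, np.random.default_rng(0), size=200)
    assert sim.in_ppii_window(phi, psi).all()


def test_sample_dihedrals_mixture_rate():
    """Window occupancy of raw draws matches the closed-form mixture rate."""
    n, draws = 10, 2000
    area_frac = sim.ppii_window_fraction_of_map()
    for s in (0.0, 0.5):
        bias = sim.uniform_bias(n, s)
        phi, psi, _ = sim.sample_dihedrals(bias, np.random.default_rng(1), size=draws)
        frac = sim.in_ppii_window(phi, psi).mean()
        expected = s + (1 - s) * area_frac
        se = np.sqrt(expected * (1 - expected) / (n * draws))
        assert abs(frac - expected) < 5 * se + 1e-9


def test_omega_truncated_about_trans():
    _, _, omega = sim.sample_dihedrals(
        sim.uniform_bias(8, 0.0), np.random.default_rng(2), size=500
    )
    assert np.all(np.abs(omega - 180.0) <= sim.OMEGA_TRUNC)
    assert np.std(omega) == pytest.approx(sim.OMEGA_SIGMA, rel=0.2)


def test_build_conformer_and_counts():
    conf = sim.build_conformer([-75.0, -75.0, -150.0], [145.0, 145.0, 60.0], [180.0] * 3)
    assert conf.n_ppii == 2
    assert conf.coords.shape == (3, 5, 3)
    assert conf.l_max >= 3.0
    with pytest.raises(ValueError):
        sim.build_conformer([], [], [])


def test_clash_check_accepts_extended_rejects_overlap():
    n = 8
    ext = sim.build_conformer(
        np.full(n, -150.0), np.full(n, 155.0), np.full(n, 180.0)
    )
    assert sim.clash_check(ext)
    bad = sim.Conformer(
        phi=ext.phi, psi=ext.psi, omega=ext.omega,
        coords=ext.coords.copy(), l_max=ext.l_max, n_ppii=ext.n_ppii,
    )
    bad.coords[0, 4] = bad.coords[n - 1, 4]  # move a CB onto a distant CB
    assert not sim.clash_check(bad)


def test_whole_chain_acceptance_decreases_with_length():
    rng = np.random.default_rng(3)
    rates = {}
    for n in (15, 35):
        bias = sim.uniform_bias(n, 0.0)
        phi, psi, omega = sim.sample_dihedrals(bias, rng, size=1500)
        coords = geom.build_backbone(phi, psi, omega)
        rates[n] = 1.0 - sim.clash_mask(coords).mean()
    assert rates[35] < rates[15]


def test_ensemble_bookkeeping(coil_ensemble_25):
    ens = coil_ensemble_25
    assert ens.converged
    assert ens.accepted >= 3000
    assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)
    rh, f = ens.recompute()
    assert rh == ens.rh and f == ens.f_ppii_chain
    assert ens.per_position_fppii.shape == (25,)
    assert 0 <= ens.f_ppii_chain < 1


def test_ensemble_seeded_reproducibility():
    a = sim.simulate_ensemble(15, 0.3, rng_seed=5, min_accepted=600)
    b = sim.simulate_ensemble(15, 0.3, rng_seed=5, min_accepted=600)
    assert a.rh == b.rh
    assert np.array_equal(a.l, b.l)
    assert np.array_equal(a.ppii_flags, b.ppii_flags)


def test_convergence_error_carries_partial():
    with pytest.raises(sim.ConvergenceError) as err:
        sim.simulate_ensemble(15, 0.0, rng_seed=6, min_accepted=5000, max_attempts=300)
    partial = err.value.partial
    assert 0 < partial.accepted < 5000
    assert partial.rh > 0


def test_rh_increases_with_uniform_bias():
    rhs = [
        sim.simulate_ensemble(15, s, rng_seed=7, min_accepted=1500).rh
        for s in (0.1, 0.5, 0.9)
    ]
    assert rhs[0] < rhs[1] < rhs[2]


def test_biased_positions_follow_conversion_curve():
    """Patterned bias: observed per-position PPII tracks the applied-rate
    conversion at biased positions; unbiased positions stay at background."""
    s = 0.6
    ens = sim.simulate_ensemble(
        25, sim.patterned_bias(25, s, 3), rng_seed=8, min_accepted=3000
    )
    biased = ens.bias.s_ppii > 0
    f_biased = ens.per_position_fppii[biased].mean()
    assert abs(f_biased - sim.spp_to_fpp(s)) < 0.05
    f_unbiased = ens.per_position_fppii[~biased].mean()
    assert abs(f_unbiased - 0.012) < 0.01


@pytest.mark.parametrize(
    "s,expected",
    [(0.63, 0.568), (0.0, 0.0), (1.0, 0.974)],
)
def test_spp_to_fpp_values(s, expected):
    assert sim.spp_to_fpp(s) == pytest.approx(expected, abs=5e-4)


def test_spp_fpp_inverse_round_trip():
    for s in np.linspace(0.05, 1.0, 9):
        assert sim.fpp_to_spp(sim.spp_to_fpp(s)) == pytest.approx(s, abs=1e-9)
    with pytest.raises(ValueError):
        sim.fpp_to_spp(0.99)


def test_write_pdb_multimodel(tmp_path):
    ens = sim.simulate_ensemble(
        10, 0.2, rng_seed=9, min_accepted=600, keep_coords=5
    )
    path = tmp_path / "ens.pdb"
    sim.write_pdb(ens.kept, path)
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("e", str(path))
    models = list(structure)
    assert len(models) == 5
    atoms = list(models[0].get_atoms())
    assert len(atoms) == 10 * 5
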