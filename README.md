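# ppiirh

Hydrodynamic radii of intrinsically disordered proteins (IDPs) from
sequence-intrinsic polyproline-II (PPII) propensities — plus the
hard-sphere-collision ensemble simulator the prediction model derives from.

## The science

Disordered proteins are hydrodynamically larger than random-coil estimates,
and the excess tracks their content of PPII helix, an extended backbone
conformation near (φ, ψ) = (−75°, 145°) that every residue samples to a
measurable, residue-specific degree.  The package's core is the power-law
scaling relation

    Rh(N, f) = 2.16 Å · N^(0.503 − 0.11·ln(1 − f)),

where N is the chain length and f = f_PPII,chain the chain-averaged PPII
propensity, computed from sequence with an experimental amino-acid
propensity scale (three are packaged: Kallenbach, Creamer, Hilser, plus a
context-dependent composite and null/static controls).  The constants were
derived from excluded-volume ensemble simulations of poly-alanine with
position-specific PPII sampling bias; the simulator (with Debye-screened
Coulomb weighting for charge-pattern studies) is part of the package, and
`ppiirh.fitting` re-derives (v0, β) from a scaled-down simulation grid.
`docs/methods.md` has the full model description and limitations.

For: structural bioinformaticians and biophysicists estimating IDP
hydrodynamic dimensions from sequence, comparing propensity scales against
hydrodynamic data, or studying how PPII bias and charge patterning shape
disordered ensembles.

## Worked example

```python
import ppiirh

records, observed = ppiirh.synthetic_idp_dataset(rng_seed=1, n_idps=6)
hilser = ppiirh.load_builtin_scale("hilser")
for rec in records[:3]:
    res = ppiirh.predict_sequence(rec, hilser)
    print(rec.id, rec.n, round(res.f_ppii_chain, 3),
          round(res.rh_pred, 1), round(ppiirh.random_coil_rh(rec.n), 1))
```

prints (id, N, f_PPII, predicted Rh, random-coil Rh):

    synth-idp-00 79 0.35 23.9 19.6
    synth-idp-01 100 0.391 28.1 22.0
    synth-idp-02 161 0.36 35.7 28.0

Each chain's predicted Rh sits well above its random-coil baseline
(the same relation at the background fraction f = 0.012) because the
sequences carry real PPII propensity.  A simulated ensemble closes the
loop between the relation and the generator it came from:

```python
ens = ppiirh.simulate_ensemble(25, 0.4, rng_seed=42, min_accepted=3000)
print(round(ens.rh, 2), round(ens.f_ppii_chain, 3))   # 13.88 0.376
print(round(ppiirh.predict_rh(25, ens.f_ppii_chain), 2))  # 12.89
```

The `examples/` directory has one short script per capability: sequence
prediction, scale evaluation on a benchmark, ensemble simulation, charge
patterning, the scaling-law refit, and the random-scale survey.  A thin CLI
(`ppiirh predict|simulate|scales|fit-scaling|survey-scales`) wraps the same
functions for shell use.

The published 22-IDP benchmark table is not redistributable; if you have
the supplementary tables, save them as a TSV (columns `id`, `sequence`,
`rh_obs`) and pass it to `ppiirh.datasets.load_idp_dataset` — the synthetic
generator stands in everywhere else.

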