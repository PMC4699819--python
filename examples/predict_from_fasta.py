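"""Predict hydrodynamic radii for disordered sequences from PPII propensity.

Builds a small synthetic benchmark, writes it as FASTA, and predicts Rh for
each sequence under the Hilser propensity scale via
Rh = 2.16 * N^(0.503 - 0.11*ln(1 - f_PPII,chain)).
"""

import tempfile
from pathlib import Path

import ppiirh

records, observed = ppiirh.synthetic_idp_dataset(rng_seed=1, n_idps=6)
fasta = Path(tempfile.mkdtemp()) / "idps.fa"
ppiirh.write_fasta(records, fasta)
records = ppiirh.read_fasta(fasta)

hilser = ppiirh.load_builtin_scale("hilser")
print(f"{'id':<14} {'N':>4} {'f_PPII':>7} {'Rh_pred':>8} {'Rh_coil':>8}")
for rec in records:
    res = ppiirh.predict_sequence(rec, hilser)
    coil = ppiirh.random_coil_rh(rec.n)
    print(f"{res.id:<14} {res.n:>4} {res.f_ppii_chain:>7.3f} "
          f"{res.rh_pred:>7.1f}Å {coil:>7.1f}Å")

print(
    "\nf_PPII is the chain-averaged polyproline-II propensity from the scale; "
    "Rh_pred is the\npredicted hydrodynamic radius and Rh_coil the random-coil "
    "reference (f = 0.012) —\ndisordered chains with real PPII content sit "
    "well above the coil baseline."
)
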