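"""Effect of charge patterning on simulated Rh.

Simulates 25-residue chains at a fixed PPII bias under several charge
patterns — uncharged, charged termini, like charge at every residue, like
charge every third residue, and alternating charges — with Debye-screened
Coulomb Boltzmann weighting at 0.1 M ionic strength.
"""

import ppiirh
from ppiirh import electrostatics as el

N, S, seed = 25, 0.3, 3
patterns = {
    "uncharged": None,
    "charged termini": el.termini_only(N),
    "neg every residue": el.every_kth(N, -1, 1),
    "neg every 3rd": el.every_kth(N, -1, 3),
    "alternating +/-": el.alternating(N, 1),
}

print(f"Debye length at 0.1 M: {el.debye(0.1).debye_length:.1f} Å\n")
print(f"{'pattern':<20} {'Rh (Å)':>7} {'f_PPII':>7} {'<R_ij> (Å)':>11}")
for name, charges in patterns.items():
    ens = ppiirh.simulate_ensemble(N, S, charges=charges, rng_seed=seed,
                                   min_accepted=2000)
    rij = f"{ens.mean_rij:.1f}" if ens.mean_rij else "-"
    print(f"{name:<20} {ens.rh:>7.2f} {ens.f_ppii_chain:>7.3f} {rij:>11}")

print(
    "\nLike charges at adjacent positions (spacing below the ~9.6 Å Debye "
    "length) expand the\nchain and enrich extended PPII structure; separating "
    "or alternating the charges damps\nthe effect, and terminal charges alone "
    "do nothing.  <R_ij> is the mean distance between\nsequence-adjacent "
    "charged side chains."
)
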