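"""Simulate one excluded-volume ensemble with a PPII sampling bias.

Generates a 25-residue poly-alanine ensemble with a 40% per-position PPII
sampling bias, reports its converged Rh and observed PPII fraction, and
compares both against the scaling relation and the applied-to-observed
conversion curve.
"""

import ppiirh

S = 0.4
ens = ppiirh.simulate_ensemble(25, S, rng_seed=42, min_accepted=3000)

print(f"N = {ens.n}, applied S_PPII = {S}")
print(f"accepted conformers : {ens.accepted} (of {ens.attempts} attempts)")
print(f"ensemble Rh         : {ens.rh:.2f} Å")
print(f"observed f_PPII     : {ens.f_ppii_chain:.3f} "
      f"(conversion curve: {ppiirh.spp_to_fpp(S):.3f})")
print(f"scaling-law Rh at f : {ppiirh.predict_rh(ens.n, ens.f_ppii_chain):.2f} Å")

print(
    "\nRh is half the ensemble-averaged maximum CA-CA distance.  The observed "
    "PPII fraction\nsits slightly below the applied sampling rate because "
    "sterically clashing draws are\nrejected; the scaling law evaluated at the "
    "observed fraction should approximate the\ndirectly simulated Rh."
)
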