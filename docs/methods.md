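# Methods

## The model

Intrinsically disordered proteins (IDPs) are hydrodynamically larger than
random-coil estimates for their length, and the excess tracks the chain's
content of polyproline-II (PPII) helix — an extended, left-handed backbone
conformation near (φ, ψ) = (−75°, 145°) that proline favors strongly and
that all residues sample to a measurable, residue-specific degree.  This
package implements the resulting sequence → hydrodynamic-radius model:

    Rh(N, f) = R0 · N^v,    v(f) = v0 + β · ln(1 − f),

with N the residue count and f = f_PPII,chain the chain-averaged PPII
propensity.  The constants R0 = 2.16 Å, v0 = 0.503 and β = −0.11 come from
fitting hard-sphere-collision (HSC) ensemble simulations; f is obtained
from a sequence by averaging per-residue propensities taken from an
experimental scale.  Reference baselines are the random coil (the same
relation at the background fraction f = 0.012), the empirical IDP power law
R0(f_PRO, |Q|) · N^0.509 with R0 = (1.24·f_PRO + 0.904)(0.00759·|Q| +
0.963)·2.49, and the chemically denatured chain 2.2 · N^0.57.

Three measured propensity scales are packaged (Kallenbach, Creamer, Hilser
— named for the groups that reported them), each complete over the 20
standard residues after the documented imputations (Kallenbach PRO = 1.00,
GLY = 0.50; Creamer TRP = TYR = 0.58, the mean of its 18 reported values).
Because each scale was measured in a different host peptide, a composite
lookup uses Hilser values by default, Kallenbach values in a G-X-G context
and Creamer values in a P-X-P context (terminal residues and all other
contexts fall back to Hilser).  Two control scales — `null` (all residues
0.012) and `static` (all residues 0.364, the dataset-averaged apparent
fraction from inverting the scaling law) — support the benchmark analyses.

## Dataset evaluation and charge statistics

For a set of sequences with observed Rh the evaluator reports, per protein:
predicted Rh, absolute error, the length-normalized error
(pred − obs)/(random-coil Rh), net charge Q = (#K + #R) − (#D + #E)
(histidine neutral, termini excluded), net charge density ncd =
|Q|/(random-coil Rh), the net adjacent charge (the absolute difference
between the number of D/E residues with a D/E neighbour and the number of
K/R residues with a K/R neighbour), and the charge bias (ratio of the more
abundant charge type to the less abundant; undefined when a type is
absent).  Dataset summaries include the error moments, R² of predicted vs
observed Rh, and R² of normalized error vs ncd overall and within high/low
charge-bias subsets split at the charge bias of the concatenated dataset
sequence.  R² is always the squared Pearson correlation of the ordinary
least-squares line.

Random-scale surveys draw 20 i.i.d. propensities conditioned on their mean
lying within ±0.05 of a uniformly drawn target.  A literal accept/reject
loop is intractable for extreme targets (the mean of 20 uniform variables
has σ ≈ 0.065, so a target of 0.05 would almost never be hit); the
conditional law is instead sampled exactly-in-distribution by hit-and-run
over the mean-constrained cube (500 sweeps, all chains vectorized), which
serves every target and makes scale means approximately uniform on [0, 1].

## The ensemble simulator

Chains are poly-L-alanine with heavy atoms N, CA, C, O, CB built by
natural-extension-reference-frame placement from standard bond lengths and
angles; ω is a truncated Gaussian about trans (σ = 2.5°, cut at ±5°).
(φ, ψ) pairs are drawn either from the PPII window (−75 ± 10, 145 ± 10) —
with per-position probability S_PPII, the applied sampling bias — or
uniformly by area from a declared allowed-region map: the β/PPII basin
φ ∈ [−180, −45], ψ ∈ [90, 180] ∪ [−180, −150]; the αR basin φ ∈ [−160, −45],
ψ ∈ [−60, 30]; and the αL basin φ ∈ [45, 100], ψ ∈ [0, 90].

Steric acceptability uses the classic hard-sphere contact limits per
element pair (C·C 3.20, C·N 2.90, C·O 2.80, N·N/N·O/O·O 2.70 Å).  Pairs
within four covalent bonds are exempt: their separations are fixed by the
standard geometry (the carbonyl O sits 2.77 Å from the next CA in every
trans peptide) or already constrained by the allowed-region map.  Full
van-der-Waals radius sums would reject every conformer and are not a
usable criterion at fixed ideal geometry.

Generation is residue-by-residue growth with contact-guided candidate
selection.  At each residue the PPII-vs-background branch is drawn once at
the applied rate; 20 candidate (φ, ψ) pairs are then drawn within that
branch, clashing candidates are discarded, and one survivor is chosen with
probability ∝ exp(1.8 · c), where c counts heavy-atom pairs within 2.5 Å
beyond their contact limit.  Chains whose candidates all clash redraw up to
12 rounds and are then abandoned.  The guidance exists because pure
rejection sampling of an excluded-volume chain yields self-avoiding-walk
statistics (effective exponent ≈ 0.6), far more expanded than disordered
proteins; physically, the missing ingredient is the solvation free energy
that population-weights real ensembles toward compact states.  The three
guidance constants were calibrated once against the published random-coil
line Rh = 2.16 · N^0.509 over N = 15–35 and then frozen.  Drawing the
branch before guiding keeps the realised PPII rate at the applied rate up
to clash losses, so the applied→observed conversion

    f_PPII = S_PPII − 0.062 · exp(−(S_PPII − 0.63)² / (2 · 0.28²))

(clipped below at zero; numerically inverted by bisection when a target f
is prescribed) is tracked within about ±0.04 across the bias range.

Ensemble observables: Rh = ⟨L⟩/2 with L the maximum CA–CA distance of a
conformer and ⟨·⟩ the weighted ensemble mean; f_PPII,chain = ⟨N_PPII⟩/N
counting residues with (φ, ψ) inside the PPII window; per-position PPII
occupancies; and, for charged chains, the mean distance ⟨R_ij⟩ between
sequence-adjacent charged CB atoms.  Sampling continues until the running
Rh changes by <0.5% across three consecutive blocks of 500 accepted
conformers (minimum 3,000 accepted; 10⁶ attempted chains at most, after
which a convergence error carrying the partial ensemble is raised).  All
randomness flows from one seeded generator; runs are bit-reproducible.

## Electrostatics

Unit charges sit at the CB of designated residues (a proxy for flexible
charged side chains) or at the backbone N/O of the first/last residue for
terminal charges.  A conformer's energy is the screened Coulomb sum
(332/D) Σ_{i<j} Z_i Z_j e^{−κR_ij}/R_ij kcal/mol with κ = 2.913·√(I/D) Å⁻¹;
at I = 0.1 M and D = 78.3 the Debye length 1/κ is 9.6 Å.  (The source
formulas as typeset — a prefactor reading "332·D·2" and a growing
exponential e^{+κR} — cannot be a screened interaction and do not reproduce
the printed Debye length; the standard Debye–Hückel forms above do, and are
used.)  Ensembles with charges are Boltzmann-weighted at 25 °C
(RT = 0.59248 kcal/mol) with the minimum energy subtracted for stability.
Charge patterns (every k-th residue, like-charged clusters of three,
alternating residues or clusters, termini only) are deterministic site
lists mirroring the simulation protocols of the charge-patterning study.

## Synthetic benchmark

The published 22-IDP benchmark lives in journal supplements not
redistributable here; `ppiirh.synthetic` generates a stand-in matching the
study conditions: 22 sequences of 73–260 residues with a disorder-promoting
composition (S 0.104, E 0.100, L 0.083, P 0.080, D 0.074, G/A 0.073,
T 0.061, K 0.055, Q/V 0.053, aromatics rare), and observed Rh built from
the scaling law under the Hilser scale, inflated by (1 + 0.00788·|Q|) to
emulate net-charge expansion and perturbed by 4% lognormal noise.  Because
the generator shares the predictor's forward model, benchmark-style tests
on it demonstrate pipeline correctness and charge-correlation machinery,
not predictive power on real proteins; real-data comparisons require the
real table (see `ppiirh.datasets`).

## Problem sizes and numerical choices

The scaling-law refit uses a scaled-down grid: uniform S_PPII ∈ {0.1…0.9}
at N ∈ {15, 25, 35} plus every-2nd/every-3rd patterns at S ∈ {0.3, 0.6,
0.9} for N ∈ {15, 25} — 39 ensembles of ≥3,000 accepted conformers each,
about eight minutes on one core (the original study used >250 ensembles up
to N = 75).  The fit is unweighted Levenberg–Marquardt with initial guess
(0.5, −0.1) and parameter tolerance 1e−10; R0 is held at 2.16 Å.  The
random-scale survey defaults to 2,000 scales (it is a matrix product over
scale vectors, so 10⁵ is also quick).

## Known limitations

* The contact-guided growth matches the level of the published coil line
  over N = 15–35 (anchored exponents v = ln(Rh/2.16)/ln N ≈ 0.48–0.52) but
  not its local ln–ln slope, which remains ≈0.6 because the guidance's
  compaction efficiency decays with chain length.  Consequently the refit
  intercept v0 lands near 0.52 rather than 0.503, while β is reproduced
  within its stated uncertainty band.
* With uniform base weights, the Coulomb term is the only energy in the
  population weights, so moderate charge patterns (like charge every third
  residue, ~3 kcal/mol of conformation-dependent energy) expand Rh by
  10–20% where the original study — whose solvation energy dominated the
  weights — reported near-neutral behaviour.  Dense like-charge patterns,
  terminal charges, alternating patterns and the charge-driven PPII
  enrichment all behave as published.
* Poly-alanine only: sequence enters the simulator through bias and charge
  patterning, never through side-chain atoms beyond CB.  No cis-proline,
  no pH/titration, no temperature dependence.
* Scale tables carry the printed two-to-three-digit precision; comparisons
  to their printed averages are made at that precision.
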