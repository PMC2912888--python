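# Methods

## Model

The package scores protein structures with a four-term potential

E = w_ScSc·E_ScSc + w_ScMc·E_ScMc + w_rot·E_rot + w_lj·(E_lja + E_ljr)

whose central object is the **four-distance description** of a
residue–residue interaction: a fixed pair of atoms per residue type and the
four inter-residue distances between the two pairs. The statistical terms
are inverse-Boltzmann log-ratios of binned 4-distance probabilities between
real structures and a **randomized-rotamer reference state** (side chains
rebuilt from uniformly drawn library rotamers, probabilities and clashes
ignored). The natural logarithm is used throughout; any temperature factor
is absorbed into the weights. Lower scores are better — the sign convention
is fixed by requiring native structures to score below decoys.

Assumptions worth stating explicitly:

* heavy atoms only; hydrogens are dropped on reading;
* backbones are taken as given — packing and evaluation never move them;
* atom-pair definitions are symmetric for homotypic pairs (the same two
  atoms on both residues), and Ala, whose side chain is a single atom, uses
  (CA, CB) as its pair so that all 190 Gly-excluded ScSc types exist
  (configurable: pass your own definitions to drop Ala pairs instead);
* ScMc interactions use the backbone (O, N) atoms of the partner residue;
* contacts between sequence neighbours (same chain, |i−j| ≤ 1) are excluded
  from both statistics and scoring: nearest-neighbour geometry is dictated
  by covalent structure, not by interaction preference.

## Statistics

Contacts (any of the four distances < 5 Å, strict) are binned on a
20⁴-cell grid (0.5 Å bins, 0–10 Å); distances beyond 10 Å on
non-triggering axes are clamped into the last bin so a contact is never
discarded for one long distance. Homotypic tables accumulate both residue
orderings, making them exactly swap-symmetric.

**Smoothing.** Each bin is averaged with its *axis-adjacent* neighbours and
itself (a 4-D von Neumann cross of up to 9 bins, truncated at grid
boundaries) and the grid renormalised. A full 3⁴ hypercube box average was
considered and rejected: a flat box filter makes the argmax a near-tie
among every window containing an isolated peak, so smoothing would destroy
peak localisation — measurably, the planted-geometry recovery check fails
for essentially every seed under a box kernel and passes for every seed
under the cross kernel. The cross average is the smallest neighbourhood
that damps single-bin noise while provably keeping an isolated peak's
argmax in place.

**Zero counts.** Probabilities are floored at 1/(10·N_pair) before the
ratio, where N_pair is the pair's real contact count — empty bins yield a
finite penalty that scales with how well-sampled the pair is. The floor is
configurable (`PotentialTables.floor_probability`).

**Pair frequencies.** P(AA) is the pair type's share of contacts,
normalised separately within the ScSc and ScMc families.

## Rotamer libraries

Libraries are backbone-dependent tables on a φ/ψ grid (default 10°; the
synthetic test library uses 120° to stay small). The extended variant
replaces each rotamer having n χ angles by the 3ⁿ combinations
{χ−σ, χ, χ+σ}, weighting offspring by the normal density at the three
points — exp(0) : exp(−½) : exp(−½), i.e. ≈ 0.452/0.274/0.274 — times the
parent probability. The reduced variant drops, within each group, the
largest probability-sorted tail with cumulative mass ≤ 0.03 (at least one
rotamer is always kept) and renormalises.

Side chains are built from χ angles by sequential internal-coordinate
(NeRF) placement using an ideal-geometry table; rebuilt χ reproduce the
input to well under 0.01°. Phe/Tyr rings are regular hexagons so a 180° χ₂
flip maps the ring onto itself exactly with CD/CE names swapped — the
property the symmetry-aware RMSD relies on. Proline is treated as a 2-χ
residue; its ring closure (CD–N) is approximate, which is acceptable
because χ round-trips, not covalent closure, drive packing and evaluation.

## Lennard-Jones term

Heavy atoms map to 20 chemically grouped classes (shipped as
`data/lj_classes.tsv`; backbone N/CA/C/O, aliphatic carbons by branching,
aromatic and N-adjacent ring carbons, carbonyl/carboxyl/amide carbons and
oxygens, hydroxyl O, amide/amine/guanidinium/ring N, thioether S). Well
depths combine as √(εᵢεⱼ) and minima as rᵢ + rⱼ, with explicit pair
overrides available for polar–polar optima. The 12-6 energy is replaced by
its tangent line below d = 0.89·r_min (continuous in value and slope), so
transient clashes during packing cost linearly rather than astronomically.
Negative pair energies accumulate in E_lja, positive in E_ljr. Pairs
excluded: same residue, backbone–backbone (constant under packing), and
1-2/1-3/1-4 paths across the peptide bond (CB–N(+1), C–CB(+1), and
proline's CD/CG reach-back); evaluation cutoff 10 Å, no shift. The shipped
ε are CHARMM19-style seeds and the radii chemically reasonable defaults;
`calibration.fit_lj_radii` refits radii from corpus contact-distance peaks.

## Calibration

Direct contacts are detected internally (no external dot-surface program):
two atoms are in direct contact when their surface gap is under twice a
1 Å probe radius and no third atom's sphere intersects the segment between
their surfaces. Per class-pair distance distributions use 0.05 Å bins;
the peak is the mode after a 3-bin moving average, ties broken toward the
largest raw count (a lone spike otherwise ties with both neighbours).
Pairs with fewer than 10 000 observations are discarded. Radii come from
least squares on rᵢ + rⱼ = peak over non-polar-polar pairs; polar–polar
peaks are kept as r_min overrides because hydrogen bonding makes them
shorter than van der Waals contact.

Weights are fitted hierarchically: λ sweeps (0 to 1, step 0.05) first of
E_rot against E_lj, then E_ScSc against their combination, then E_ScMc
against the rest, minimising mean repacked side-chain RMSD over a fixed
training set with identical per-structure seeds at every λ (a paired
comparison). The shipped defaults (0.13, 0.13, 0.33, 0.41) are the
calibration result used by every consumer.

## Packing

MCSA: random initial rotamers; starting temperature doubled from 1 until
≥ 95 % of 1000 hypothetical probe moves would be accepted; linear cooling
T_k = T₀(1 − k/K) over K = 100 steps (default) of 10 000 uniform
(position, rotamer) proposals; Metropolis acceptance exp(−ΔE/T); the
best-so-far assignment is tracked; finally a greedy quench sweeps all
positions, testing every rotamer, until a full pass improves nothing
(1-substitution local optimality). The optional off-rotamer variant
perturbs one χ of one residue by ±5° once per cooling step under the same
acceptance rule; perturbed rotamers keep their parent's library
probability. Energy updates are residue-local (the moved residue's rotamer
term, its ScSc/ScMc contacts and LJ pairs involving its side chain) and
agree with a full rescore to 10⁻⁶, which the tests assert.

`best_rotameric` rebuilds each residue independently with the group rotamer
minimising symmetry-aware side-chain RMSD to the native — the accuracy
ceiling of any rotamer-based packer under a given library.

## Evaluation

Side-chain RMSD is pooled over heavy atoms (CB included) with the
minimum-RMSD resolution of chemically equivalent namings (Phe/Tyr ring,
Asp/Glu carboxylates, Arg NH, Leu/Val methyls). Burial is relative
side-chain solvent accessibility ≤ 20 % (Shrake–Rupley, 1.4 Å probe,
via biotite), referenced to the residue's area in an extended Gly-X-Gly
tripeptide built by the fixtures module; Gly uses full-residue area. χ
accuracy counts |Δχ| ≤ 15° (inclusive), with 180° terminal symmetries
(Asp/Phe/Tyr χ₂, Glu χ₃) taken at the smaller deviation. nRMSD divides a
residue's RMSD by the probability-weighted expected RMSD of library
rotamers rebuilt on the native backbone — deterministic, no sampling.
The contact score enumerates native ScSc/ScMc atom–atom contacts
(d < vdW sum + 1 Å, radii C 1.548 / O 1.348 / N 1.400 / S 1.808 Å), matches
model contacts by atom identity and awards 4/3/2/1 points for deviations
within (further/closer) 0.125/0.0675, 0.25/0.125, 0.5/0.25, 1.0/0.5 Å,
scaled by 25 over the native contact count. Decoy ranking reports
rank (1 + number of strictly lower scores) and Z = (mean − ref)/σ_pop.

## Synthetic data: what it does and does not show

Generators use ideal covalent geometry and are fully seed-deterministic.
The planted-geometry corpus embeds an exact target quadruple by distance
geometry (two anchored atoms per residue, free roll about each pair axis
randomised), with Gaussian jitter applied to the distances themselves;
noise contacts draw quadruples uniformly from the contact-compatible,
embeddable region of distance space. Default study conditions for recovery
checks: 500 signal + 500 noise contacts, 0.1 Å jitter — enough signal that
the smoothed argmax sits at the planted bin for every tested seed. The
default target quadruple is placed near bin centres; targets near bin
edges split their mass between adjacent bins and are legitimately harder.

Passing tests on these fixtures demonstrate the machinery — harvesting,
normalisation, reference construction, optimisation, metrics — is correct
and deterministic. They do not demonstrate predictive accuracy on real
proteins: toy corpora are tiny (statistics are sparse outside planted
pairs), toy libraries are coarse (3 rotamers per group), and ideal-geometry
"natives" are not energy-minimised, so absolute RMSD/χ numbers printed by
the examples characterise the fixtures, not the method's ceiling.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: corpora of
8–1000 two-residue or 14-residue structures, annealing schedules of 15–20
steps × 120–300 moves for oracle comparisons (the 100 × 10 000 default is
the production schedule), 100-seed repetition for stochastic claims.
Histogram normalisation is asserted to 10⁻⁹; incremental-vs-full scoring
to 10⁻⁶; χ round-trips to 0.01°; PDB coordinates round-trip at the
format's 3-decimal precision. Degenerate inputs are defined, not fatal:
empty contact lists give an uninformative flag, unknown atoms an explicit
unclassified marker, zero-variance decoy sets a missing Z-score, and
single-rotamer groups survive reduction.

## Known limitations

* mmCIF, hydrogens and ligand chemistry are out of scope.
* The 20-class LJ table and its ε/radius seeds are a documented default,
  not a fitted reproduction of any published parameter set; users can
  substitute their own table and refit radii.
* The reference state uses one randomized copy per structure by default
  (configurable); very small corpora therefore have noisy references.
* Proline ring closure is approximate; disulfide-bonded Cys is mutable
  unless frozen.
* The quench termination criterion is full-sweep convergence; with rugged
  toy scorers the annealer can (rarely) end in a 1-substitution-optimal
  non-global state; the test suite bounds this at ≤ 5 % of seeds on
  enumerable systems.
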