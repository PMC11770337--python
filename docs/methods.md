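# Methods

## The design problem

`pottsbind` designs short peptides that adsorb to plastic surfaces
(plastic-binding peptides, PBPs). For a *fixed* adsorbed conformation —
a peptide backbone at a given position and orientation over a plastic
slab — the predicted affinity of a candidate amino-acid sequence
`s = (s_1 … s_n)` is expressed as a Potts model:

```
Score(s) = Σ_i E[i, s_i]  +  λ · Σ_{i<j} E[i, s_i, j, s_j]  +  p
```

* `E[i, α]` (**one-body**): interaction of amino acid α at residue *i*
  with the plastic surface and with itself (kcal/mol).
* `E[i, α, j, β]` (**two-body**): side-chain/side-chain interaction
  between residues *i* and *j*.
* `λ` (dimensionless, default **0.01**): weight of intramolecular
  stability relative to surface affinity.
* `p` (kcal/mol, default **0**): a constant offset carried over from the
  annealer formulation of the problem. A constant cannot change the
  minimizer; we implement it as a pure score shift, record it in solver
  metadata, and verify offset-neutrality by exhaustive enumeration in the
  test suite.

Lower scores mean higher predicted affinity. The default design uses
12 residues and the 19 natural amino acids excluding proline (whose
constrained backbone conflicts with the fixed-backbone assumption).
All indices are 0-based; the alphabet is alphabetical and fixed.

## Energy tables

The tables come from a Coulomb + Lennard-Jones + generalized-Born (GB)
energy evaluated on the conformation (`pottsbind.energies`):

* **Electrostatics**: `k·q_i·q_j/(ε_in·r)`, `k = 332.0636
  kcal·Å/(mol·e²)`, `ε_in = 1`, no cutoff (systems are small).
* **Lennard-Jones**: `ε[(r_min/r)^12 − 2(r_min/r)^6]` with
  Lorentz–Berthelot combination.
* **GB**: Still cross-term
  `−k(1/ε_in − 1/ε_out)·q_i·q_j/f_GB`,
  `f_GB = sqrt(r² + R_i R_j exp(−r²/4R_i R_j))`, `ε_out = 78.5`, plus the
  self term `−k/2(1/ε_in − 1/ε_out)·q²/R`. Born radii `R` come from
  Hawkins–Cramer–Truhlar pairwise descreening (the closed-form
  Coulomb-field integral over neighbour spheres); an isolated atom keeps
  its intrinsic radius, burial strictly increases it. The implementation
  is validated against a Monte-Carlo volume-integral oracle (5%).

Two approximations make the energy decomposable into one- and two-body
terms:

1. **Coarse-graining for Born radii.** Born radii are many-body. When
   residue *i* (or pair *i,j*) is evaluated, every other residue's side
   chain is replaced by a neutral, LJ-inert sphere of radius 3 Å at its
   Cβ, so radii depend only on the backbone, the slab, and the side
   chain(s) being scored. Two-body terms reuse each residue's radii from
   its own one-body context; the residual many-body inconsistency is
   quantified by a finite-difference test against a fully explicit
   (no-CG) energy and stays within ~1 kcal/mol on the toy systems.
2. **Rotamer reduction.** For each (residue, amino acid), candidate side
   chains from a small chi-angle library are built on the backbone and
   the lowest-one-body-energy rotamer is retained after a discrete
   refinement (coordinate-wise ±10° scan per chi angle, two sweeps,
   deterministic ties by library order). Two-body terms use the retained
   rotamer only.

**Parameter set.** The packaged force field is deliberately minimal:
side chains are short pseudo-atom chains (Cβ plus up to two beads placed
by chi dihedrals, bond angles 114°), with a handful of atom types
(aliphatic/aromatic carbon, hydroxyl, sulfur, charged amine/guanidinium/
carboxylate, amide, imidazole). Backbone atoms N/CA/C/O carry small
fixed partial charges summing to zero; the slab is apolar carbon. This
is **not** an Amber-class force field — the pipeline is parameter-file
driven so richer parameters can be dropped in — and absolute energies
should be read as model-internal scores, not physical binding free
energies. Bonded exclusions within a residue: 1-2 and 1-3 pairs
excluded, 1-4 scaled by 0.5 (elec and LJ); GB has no exclusions.
Backbone–side-chain cross terms are assigned to the one-body energy so
that two-body terms are purely side-chain/side-chain.

## Solvers

The Potts model maps to a QUBO with one-hot blocks `s[i,α]` and a
per-residue constraint penalty `A(Σ_α s[i,α] − 1)²`, with
`A = 2(Σ_i max_α|E_iα| + λ Σ_{i<j} max|E_iαjβ|) + 1`, which strictly
dominates any energetic gain from constraint violation (verified
exhaustively on small instances). Three classical solvers replace
annealing hardware:

* **Exhaustive enumeration** (guarded at 10⁷ states) — the oracle.
* **Simulated annealing**: Metropolis walk in feasible space (moves
  change one residue), geometric cooling from `t_start = 10·std` of 1000
  random-sequence scores down to 0.01 over 5·10⁴ steps. Seeds are
  mandatory; no silent clock seeding.
* **Hybrid refiner**: large-neighborhood descent in the spirit of
  decomposition-based hybrid annealer workflows — blocks of k residues
  (default 3) are exhaustively re-optimized with the rest frozen,
  sweeping round-robin windows then random subsets; only improvements
  are accepted, so the score trace is monotone.

Ties are always broken lexicographically by alphabet order, making every
solver deterministic given its seed. A hyperparameter scan over (λ, p)
grids returns one best result per cell plus the deduplicated sequence
set. Annealer-hardware specifics (chain strength, anneal time,
minor-embedding) are intentionally not emulated.

## PPO exploration of degenerate optima

Good landscapes are degenerate: many sequences score within a few
kcal/mol of the optimum. A PPO agent harvests them. The policy embeds
each residue (d_emb = 16), runs the embedded sequence through a GRU
(d_h = 64), and maps the final hidden state to a joint softmax over
(position × amino-acid) substitution actions; a value head shares the
recurrent trunk. Episodes start at the solver optimum and roll a fixed
horizon (default 50). Updates use the clipped surrogate (ε = 0.2) with
GAE (γ = 0.99, λ_GAE = 0.95); the approximate KL is logged and the
remaining epochs of an update are skipped when it exceeds the limit
(0.05).

**Reward sign.** The raw environment signal is the score change of a
substitution. We use `reward = −Δscore` so that score *decreases* are
rewarded and the policy moves toward high-affinity sequences; the
opposite convention is available via `reward_sign_flip=False` for
fidelity experiments.

A visited sequence is an **alternate solution** when its score is within
a window (default **5 score units**) of the best known score; the seed
sequence is excluded and members are deduplicated. Starting rollouts at
the solver optimum rather than a random sequence finds at least as many
alternates under the same budget (property-tested).

The network is implemented in NumPy on a small reverse-mode autodiff
core (`pottsbind._autodiff`) with Adam; gradients are verified against
finite differences in the test suite.

## Geometry and analyses

After rigid alignment of the slab's best-fit plane to +z (SVD; the
peptide is placed on the +z side), the surface frame is `z0 = max z`
over plastic heavy atoms with normal (0,0,1). Three descriptors
characterize a side chain's environment:

1. signed Cβ height above the slab top (Å; negative = below),
2. angle between Cα→Cβ and the surface normal (degrees),
3. SASA of the bare Cβ (rest of that side chain removed), Shrake–Rupley
   with 960 Fibonacci points and probe 1.4 Å.

Glycine has no Cβ and is excluded from environment analysis by default;
an opt-in surrogate places an ideal tetrahedral Cβ instead. Default bin
edges (half-open `[lo, hi)`): distance (−∞,0,2,4,6,8,∞) Å, angle
(0,60,120,180]°, SASA (0,40,80,∞) Å². The environment-preference table
reports a bin's modal amino acid only when it occurs in **more than one
third** of the residues in that bin; ties are suppressed (conservative
reading of "most frequent").

Physicochemical profiles use Henderson–Hasselbalch charges with an
EMBOSS-style pKa set (swappable), bisection for pI (unique because the
charge is strictly decreasing in pH and the termini guarantee a sign
change), average or monoisotopic residue masses plus one water, and a
**solubility proxy** — negated mean Kyte–Doolittle hydropathy plus
0.5·|charge(pH 7)|/n. The proxy is explicitly not CamSol and its values
are not comparable to CamSol scores. Frequency comparisons use Welch's
unequal-variance t-test (SciPy, with Welch–Satterthwaite df; an
independent textbook-formula implementation serves as the test oracle).

## Synthetic fixtures and what they do (not) show

`pottsbind.synthetic` generates all test inputs:

* **Planted tables**: the planted letter costs 0 per position, every
  other letter ≥ gap/n plus uniform noise < gap/(2n); two-body noise is
  clipped so any m-point mutation keeps an excess ≥ 3m·gap/(4n) at the
  assumed λ. Verified by enumeration at build time when |alphabet|^n ≤
  2·10⁵.
* **Degenerate tables**: a base sequence at 0 plus k−1 single-position
  variants with excesses spread over (window/2, window]; all other
  letters cost 4× the window. Because every variant exceeds window/2,
  combining two variants already leaves the window, so exactly the
  planted set lies inside it (enumeration-verified). Note that
  non-planted sequences are therefore separated from the optimum by
  *more than the window*, not by an arbitrarily large gap — for k >
  |alphabet| the two requirements are mutually exclusive.
* **Toy systems**: an extended backbone (N/CA/C/O, optional ideal Cβ)
  parallel to a rectangular carbon-lattice slab, geometric centre of
  mass 4 Å above the slab top, with 0.01 Å coordinate jitter.
* **Environment datasets**: per-bin labels with an exact planted
  fraction, remaining labels uniform.

Default fixture sizes are reduced (n = 4, 5 letters) so the exhaustive
oracle is always available; full-size instances (n = 12, 19 letters) are
used for the stochastic solver checks. The toy structures are idealized:
no solvent, no thermal backbone disorder, no realistic plastic surface
chemistry, single conformation. Passing tests therefore demonstrate the
*machinery* — decomposition consistency, solver optimality, window
bookkeeping — not the accuracy of the minimal force field on real
polymer surfaces.

## Numerical choices

* Score/energy comparisons at 1e-9 relative; SASA at the discretization
  quantum (~0.13 Å²/point at 960 points) with 2% relative elsewhere.
* Born radii: inverse radii clipped at 1e-3 Å⁻¹ to guard extreme burial.
* Degenerate/planted constructions re-verified by enumeration at build
  time; construction failure raises rather than returning a bad fixture.
* The acceptance script (`scripts/acceptance.py`) re-runs the pipeline
  at the sizes above: 50 random solver instances, 20 planted recoveries
  at n = 12, a 3-residue/4-letter energy-table build, 3 PPO seeds with a
  10⁵-step harvest budget, 100 random 12-mers for charge/pI.

## Known limitations

* The packaged force field is a minimal pseudo-atom model; absolute
  scores are not transferable binding free energies.
* The CG/rotamer decomposition error is quantified only on toy systems.
* PPO hyperparameters were not tuned per landscape; very rugged
  landscapes may need more updates or a larger KL budget.
* No conformational sampling: the score is conditional on one adsorbed
  conformation, by construction.
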