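# Methods

## Model

`matepref` implements a deterministic, haploid, five-locus model of two
sympatric species (A and B) in which female preference can target two
display traits that natural selection makes *more similar* between the
species — the opposite of the "magic trait" setting where ecological
selection itself separates them.

Each individual of species A carries one allele (0 or 1) at each of five
freely recombining loci:

* **T1, T2** — the two displayed traits (allele value = trait value);
* **P1, P2** — the trait values the carrier prefers, as a female, at T1
  and T2;
* **M** — the *relative preference weighting* γ: the share of a female's
  attention allocated to T2 versus T1.

Species B is represented only by its fixed male phenotype (trait value 1
at both traits) and its density share Ñ/(N+Ñ); species B females and
genotype bookkeeping are not simulated.

One generation is:

1. **Viability selection.** Genotype *i* survives in proportion to
   w_i = (1 + (T1)_i s1)(1 + (T2)_i s2), renormalised by the mean fitness.
   s1, s2 ≥ 0, so selection within species A pushes both traits toward
   the values fixed in species B.
2. **Mating.** A female's attention on (T1, T2) is (f(1−γ), f(γ)) with the
   trade-off f(x) = x^a. On encountering a male she rejects him with
   probability ρ·(attention) per mismatched trait, so her acceptance
   probability is
   φ(j,k) = (1 − 1[(P1)_j≠(T1)_k] ρ f(1−γ_j)) (1 − 1[(P2)_j≠(T2)_k] ρ f(γ_j)).
   Encounters are sequential and random: conspecific with probability
   N/(N+Ñ), heterospecific otherwise (accepted with probability cri·φ
   against the (1,1) phenotype; such matings are sterile and, because
   females mate at most once, terminal). A female who rejects a male finds
   no further mate with probability c. Summing the geometric series, the
   probability that a female of genotype j ultimately mates with a
   conspecific is 𝒫(j) = T(j) / (c + (1−c)(T(j)+Tri(j))), where T and Tri
   are her encounter-share-weighted conspecific and heterospecific
   acceptance probabilities. Pair (j,k) then contributes
   m_jk = 𝒫(j)·φ(j,k)/Σ_l f'_l φ(j,l) offspring, normalised by the
   population mean m̄ (relative regulation: densities are parameters, not
   state). Offspring genotypes follow free recombination (each locus from
   either parent with probability 1/2).
3. **Mutation.** Symmetric allele flips at T1, T2, P1, P2 with rates
   u_T1, u_T2, u_P1, u_P2. Locus M never mutates during resident dynamics;
   weighting mutants are introduced explicitly by the invasion layer.

Genotype distributions are numpy vectors over the 32 genotypes in a fixed
binary order (T1 the most significant bit). Because every operator
preserves fixation of allele 0 at M, resident dynamics run on the
16-genotype subspace; the full 32-genotype recursion is used only while a
weighting mutant segregates.

## Adaptive dynamics of γ

For a resident γ_r the recursion is iterated to its equilibrium (below),
then a rare mutant allele at M with weighting γ_m = γ_r ± δγ is inserted
at frequency p₀ in linkage equilibrium with the resident background. After
a burn-in of `burn_in` generations — genetic associations relax at the
free-recombination rate of 1/2 per generation, so they reach their
quasi-equilibrium long before allele frequencies move — the selection
gradient is read off one generation's change of the mutant frequency:

    S = ΔP_M / (P_M (1 − P_M) δγ),

averaged between the +δγ and −δγ mutants (central difference; one-sided at
the γ boundaries). S > 0 means selection favors weighting the neutral-side
trait T2 more heavily. Halving δγ changes S by well under 5 % in the
default regime (first-order stability, tested).

Singular weightings are sign changes of S(γ_r) on a grid, refined by
bisection; each is classified by convergence stability (sign of S on
either side) and evolutionary stability (invasion of mutants at ±`es_offset`
into the singular resident): convergent + uninvadable → CSS, non-convergent
→ repeller, convergent + invadable → branching. A boundary with S pointing
outward is reported as a `boundary` attractor, and a slope below numerical
resolution as `inconclusive` — two labels added to the classical triple so
that every outcome the solver can meet has an honest name. The equilibrium
weighting γ\* follows the sign of S from the ancestral γ_t0 in steps of
`flow_step` (the gradient flow of recurrent small-effect substitutions)
until a boundary or a refined interior root is reached. If S already
vanishes at γ_t0 — e.g. under the exact T1↔T2 symmetry with s1 = s2 —
the deterministic flow cannot leave it and γ_t0 is returned; symmetry
breaking would require drift, which the recursion deliberately excludes.

### Gradient decomposition

The mutant's γ deviation enters the life cycle in exactly three places,
obtained by factoring the mating probability 𝒫 = Q·R exactly:

* the conspecific mate-identity kernel Φ(j,k) = φ(j,k)f'_k/Σφf' (which
  male she mates with, given a conspecific mating);
* R = T/(T+Tri), the conspecific share of matings (R ≡ 1 when cri = 0);
* Q = (T+Tri)/(c + (1−c)(T+Tri)), the probability of ever mating
  (Q ≡ 1 when c = 0).

Each component of S = S_os + S_or + S_ri + S_c is measured from a
*pathway-restricted* invasion run in which the mutant expresses γ_m in one
slot only and γ_r everywhere else. The Φ-restricted run is further split
by life-cycle stage within the measured generation: the mutant-frequency
change during viability selection is S_os (offspring survival, via the
M–T associations mate choice builds) and the change during reproduction is
S_or (offspring mating success — the sexy-son pathway). The R-restricted
run gives S_ri (heterospecific-mating exposure) and the Q-restricted run
S_c (cost of choosiness). Because the central difference cancels all
even-order terms, the restricted gradients sum to the independently
measured total to O(δγ²); the identity is enforced at 1e-6·max(1,|S|) and
observed at ~1e-12. When cri = 0 (resp. c = 0) the R (resp. Q) pathway is
provably inert — the restricted mutant is bitwise the resident — and the
component is returned as exactly 0.

## Resident equilibrium

The fixed point is defined by the criterion in the contract: one further
generation changes no genotype frequency by more than `tol` (1e-12 L∞ by
default), starting from linkage equilibrium at allele frequency 1/2 (no
initial genetic association), with a cap of 2×10⁶ generations. Because
the slowest modes relax at the preference-locus mutation rate (2×10⁻⁵ per
generation), plain iteration would need ~10⁵–10⁶ generations; the solver
therefore iterates in chunks and periodically polishes with a damped
Newton solve (`scipy.optimize.root`, hybr) of step(f) = f. A polished root
is accepted only if it is a valid simplex point, lies within 0.05 (L∞) of
the current iterate — so the solver cannot jump to a fixed point the
dynamics were not approaching — and itself passes the 1e-12 fixed-point
criterion. Failing that, plain iteration continues to the cap and
non-convergence is reported, never silently ignored. Frequencies are
clipped at 0 and renormalised each generation to contain round-off.

Within the explored parameter space the equilibrium is independent of the
initialisation (checked from allele frequencies 0.1/0.5/0.9; distances
~1e-12); `check_equilibrium_independence` flags anything above 1e-8.

## Parameters

Defaults (overridable everywhere): s1 = s2 = 0, ρ = 0.01, c = 0, cri = 0,
N = Ñ = 10, u_T1 = u_T2 = 0.002, u_P1 = u_P2 = 2×10⁻⁵, γ_t0 = 1/2, and
a = e⁻¹ ≈ 0.3679 (a weak, concave trade-off; the natural reading on a
log-a axis where a = 1 is the linear midpoint — it is a config default,
not hard-coded). All selective forces are of order 10⁻², so the system is
in the weak-selection regime where genetic associations stay small.

Numerical settings of the invasion layer: δγ = 10⁻³, p₀ = 10⁻⁴,
burn-in 50 generations, flow step 0.01, root tolerance 10⁻⁴ on γ,
|S| < 10⁻⁹ treated as zero, mutant growth below 10⁻¹² per generation
treated as neutral. Mutant frequencies of 10⁻⁴ leave ~12 decimal digits
between signal (ΔP_M ≳ 10⁻¹³ per generation in the weakest regimes) and
double-precision round-off (~10⁻¹⁸).

## Individual-based oracle

`matepref.ibm` realises the identical life cycle in a finite population
(non-overlapping generations, multinomial regulation to constant census
size): binomial viability survival by w_i/max(w), per-female sequential
encounters with the same acceptance rules (search truncated at 10⁴
attempts as a numerical guard), Mendelian free recombination by random
bitmask, symmetric mutation flips. It exists solely to verify the
deterministic recursion: at 10⁵ individuals, 20 replicates and 50
generations the mean T1 trajectory under s1 = 0.02 agrees with the
recursion within 3 standard errors at every generation, the realized
conspecific-mating fraction matches the analytic mean of 𝒫(j), and the
deviation shrinks with population size. The oracle excludes what the
recursion excludes (no overlapping generations, no separate sexes beyond
the female-choice asymmetry, no demographic feedback), so agreement
validates the recursion's algebra, not the model's realism for any
particular organism.

## Behavior worth knowing about

* **Interior γ\* under strong trade-offs with a cost of choosiness.** For
  a > 1, intermediate γ dilutes *total* attention (f(1−γ)+f(γ) < 1), so a
  less extreme weighting rejects fewer males and, whenever c > 0, pays a
  smaller cost of choosiness. In the full recursion this direct force
  (order c·ρ) dominates the indirect, association-mediated forces (order
  s·ρ times associations) and creates an interior attractor — e.g.
  (s1=0.02, cri=0.0025, a=4, c=0.005) settles near γ≈0.49 from either
  extreme. Weak-selection analyses that treat all forces as comparably
  small can rank these forces differently in this corner.
* **History dependence at the linear trade-off.** At a = 1 total attention
  is constant, and the cost of choosiness only asks *which* trait is
  cheaper to attend: sexual selection makes the ancestrally attended trait
  monomorphic, hence cheap, locking preference onto it. With c = 0.02,
  cri = 0.0025, s1 = 0.02 the outcome is γ\* = 0 from γ_t0 = 0.01 and
  γ\* = 1 from γ_t0 = 0.99.
* **Boundary attractors without interference.** With cri = 0 and a < 1,
  γ = 1 can be locally attracting even though T1 is the selected trait: a
  resident attending only T2 keeps P1 at frequency 1/2, so a mutant
  shifting attention to T1 chooses with an un-adapted preference and loses
  viability through the half of its lineage preferring T1 = 0. From the
  balanced ancestral state the flow still reaches γ\* = 0.

## Degenerate inputs and edge conventions

* f(x) = x^a uses the convention 0⁰ = 0, so f(0) = 0 for every a and
  choice stays single-trait at the γ extremes even at a = 0; a = 0 is
  excluded from sweeps by default.
* 𝒫 = 0 when T = Tri = 0 and c = 0 (the Eq. for 𝒫 is otherwise undefined
  there): a female who accepts no one never mates.
* A population whose every pair has zero contribution (m̄ = 0) raises
  `ReproductionError` rather than producing NaNs.
* The relabeling symmetry — swap (T1,P1,s1,u_T1,u_P1) with
  (T2,P2,s2,u_T2,u_P2) and map γ ↦ 1−γ — commutes with every life-cycle
  operation and is enforced by property tests; it is the reason symmetric
  parameter sets give S(1/2) = 0 exactly.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the recursion at its native
size (32 genotypes; equilibria to 1e-12). Stochastic checks use 10⁵
individuals × 20 replicates × 50 generations in the headline
oracle-equivalence test and 1–2×10⁴ individuals elsewhere; sweep-style
checks use coarse 3×3 grids with γ-grids of 11 points. These sizes were
chosen so the whole suite completes in a few minutes on one CPU while
every statistical band stays at 3–4 standard errors; the example configs
include finer grids for longer runs.

## Known limitations

Haploid genetics only; free recombination (no linkage maps); no drift in
the analysis layer (the IBM is a verification harness, not an inference
tool); species B does not coevolve; ρ, c and the genetic architecture do
not evolve; branching points are classified but no polymorphic dynamics
beyond the classification are simulated (none were ever found in the
explored space).
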