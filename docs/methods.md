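# Methods

## Model

`repliq` treats template-directed DNA copying as an equilibrium ordering
problem. The initial state is a pool of free nucleotides at given
concentrations; the final state is a strand y₁…y_N hybridized on a template
x₁…x_N. The copy's statistics are set entirely by the free energies of the
base-pair stacks: ε(yᵢ, xᵢ | yᵢ₋₁, xᵢ₋₁), the cost of adding the pair
(xᵢ, yᵢ) on top of (xᵢ₋₁, yᵢ₋₁), and a boundary term ε₀(y₁|x₁) for the
first site, which has no stacking neighbor. The framework is an equilibrium
idealization: real replication is driven and dissipative, so the entropies
computed here are upper bounds on the final-state entropy and the error
rates are what thermodynamic discrimination alone can deliver.

Assumptions: position invariance (no concentration, temperature or ionic
gradients along the template — probabilities depend on position only through
the local template symbols); a four-letter alphabet with no ambiguity
codes; nearest-neighbor truncation of the sequence dependence (the standard
approximation for duplex secondary structure); dilute, unchanging reservoir.

## Mechanisms

- *Independent* (window 0): p(y|x) ∝ exp(−β ε₀(y|x)). The entropy depends
  on the template only through its composition n_x.
- *Ising* (reversible): the Boltzmann ensemble over whole strands,
  P(y) ∝ exp(−β E(y|x)). Computed exactly with heterogeneous 4×4 transfer
  matrices Tᵢ[y′, y] = exp(−β ε(y, xᵢ | y′, xᵢ₋₁)) — forward-backward
  products give log Z, site marginals, adjacent-pair joints and ⟨E⟩. The
  ensemble is global, so quantities at position n depend on the total chain
  length; per-prefix curves therefore rerun the sweep on each prefix
  (O(N²) work overall, exact, fractions of a second at N = 100).
- *Turing* (irreversible): ancestral Markov chain with step kernels
  qᵢ(y|y′) ∝ exp(−β ε(y, xᵢ | y′, xᵢ₋₁)) and q₁ from ε₀. One forward pass
  yields every prefix exactly; S is the chain-rule sum
  H(q₁) + Σᵢ Σ_y′ μᵢ₋₁(y′) H(qᵢ(·|y′)) with μ the propagated marginals.

For the Markov mechanism no partition function exists, so its Helmholtz free
energy is *defined* as F = U − TS; for the ensemble mechanism
F = −(1/β) log Z and S = β(U − F) coincide with the direct −Σ P ln P (checked
against enumeration). Entropies are reported in nats (units of k_B);
energies in kcal/mol; conversion uses R = 1.98720425 × 10⁻³ kcal/(mol·K).

## Energy table

The shipped table holds ΔG°₃₇ for all 256 (previous pair, current pair)
stacks. Sources: the ten unified Watson-Crick stack parameters
(SantaLucia 1998) and the internal single-mismatch sets of Allawi &
SantaLucia (G·T, G·A, C·T, A·C) and Peyret et al. (A·A, C·C, G·G, T·T),
evaluated as ΔG = ΔH − TΔS at 310.15 K (61 measured stacks). Completion
closes the table under duplex strand symmetry,
ε(cur=(x,y)|prev=(x′,y′)) = ε(cur=(x′,y′)|prev=(y,x)), which fills 55
mirror entries; the remaining 140 stacks with two consecutive mismatches are
unmeasured in the literature and are set to a configurable fill value,
default +1.0 kcal/mol — destabilizing, at least as penalizing as the worst
measured mismatch stack — and flagged `default-filled` in the provenance
column. Double-mismatch stacks matter only for the (rare) consecutive-error
configurations, so results are insensitive to the fill value at the
fidelity levels involved. Initiation and terminal corrections from the
published parameter sets are deliberately excluded: the configuration
energy is a pure sum of stacks. Temperature enters only through β at the
reference 37 °C; no ΔH/ΔS extrapolation to other temperatures is attempted
(the stored quantity is ΔG°₃₇ itself).

### Per-pair (no-neighbor) energies

ε₀(y|x) is the arithmetic mean of ε(cur=(x,y)|prev) over a context set of
previous pairs. The default is **all 16 contexts**: a copier with no
knowledge of the neighbor sees the neighbor marginalized out, and averaging
over every context is the neutral way to do that. The alternative
`wc_contexts` mode (average over the four Watson-Crick previous pairs) is
kept for sensitivity analysis but is not the default, because conditioning
the "no-neighbor" energies on correctly formed neighbors sharpens them so
much that the no-neighbor entropy can drop *below* the Markov-chain entropy
on C/T-rich templates, inverting the defining property of the hierarchy
(conditioning reduces entropy, so the independent mechanism must be the
upper envelope). Under the all-context default the ordering
s_ising ≤ s_turing ≤ s_independent holds at every prefix on all benchmark
templates. With either choice the Watson-Crick partner is the most stable
pairing for every template symbol, and the largest single misincorporation
probability is the G·T wobble (G opposite template T).

## Fidelity quantities

Errors are non-Watson-Crick unions. The per-site error probability is
1 − P(yᵢ = wc(xᵢ)) under the exact site marginals; the reported error rate
is the mean over sites (expected errors per incorporated nucleotide), with
the per-site vector exported so other summaries can be formed. The
entropy-rate bound uses the geometric-mean per-symbol probability exp(−s)
of a typical sequence (Shannon–McMillan–Breiman), giving P_e = 1 − exp(−s);
this package adopts that algebraic form as its definition. It is a
heuristic upper-bound-style estimate — exact at s = 0 and s = ln 4 and
monotone in s, but not a theorem-level bound on the exact rate, and it is
not asserted to dominate the exact rate in general.

Reservoir entropy per nucleotide is the Gibbs mixing value −Σ c_z ln c_z of
the normalized concentrations (ln 4 ≈ 1.386 nats equimolar); the finite-pool
Boltzmann value ln(N!/Π n_z!) is provided via log-gamma and converges to
the Gibbs value (within 1 % at N = 10⁴). Mutual information between
template and copy is S_initial − S_final, reported in nats with a bits
conversion constant available. The stationary uniform-process entropy rate
weights the four template symbols equally (¼ each); a weights argument
exposes the alternative.

## Monte-Carlo samplers

Both samplers draw exact i.i.d. strands, so there is no burn-in,
autocorrelation or proposal tuning: ancestral sampling through the step
kernels for the Markov mechanism, and backward sampling of the reversible
ensemble (draw y_N from its marginal, then yᵢ | yᵢ₊₁ from the
pair-marginal conditionals — valid because the ensemble is Markov along the
chain). A Metropolis mode is intentionally absent: for a 1-D chain exact
sampling dominates MCMC in every respect. All draws come from
`numpy.random.default_rng(seed)` (PCG64) and are reproducible bit-exactly
from (seed, n_samples, inputs). Standard errors are plug-in sample
estimates; cross-checks use 3·SE bands with 10⁴–10⁵ samples.

## Numerical choices

- Boltzmann weights are always max-shifted per row/step before
  exponentiation, and the transfer-matrix sweep rescales the forward vector
  at every site, accumulating log Z in the log domain; results are
  invariant under adding a constant to any energy column and remain finite
  in the ±50 kcal/mol delta-stability limit.
- Tolerances: strand-symmetry closure conflicts and validation 10⁻⁹
  kcal/mol; marginal normalization checks 10⁻¹⁰; F = U − TS identity 10⁻⁸
  kcal/mol; transfer matrices vs enumeration agree to ~10⁻¹⁴ relative in
  practice, asserted at 10⁻⁹.
- In deterministic limits S = β(U − F) can round to a tiny negative
  (~10⁻¹⁴); entropy rates above −10⁻⁹ are clamped to zero before the error
  bound, genuinely negative values are rejected.
- Enumeration is capped at N ≤ 10 (4^N configurations).

## Benchmark templates and what they do (not) show

The six benchmark templates are the four monotonous strands (polydA/C/G/T),
the ACGT-periodic strand, and a uniform-random strand from a named seed —
idealized sequence classes spanning composition extremes, maximal
short-range periodicity and zero correlation. They probe the mechanisms'
sequence dependence, not genomic reality: real genomes have long-range
correlation structure, and real polymerases operate far from equilibrium
with kinetic discrimination and active proofreading, so fidelities here
(≈10⁻³ errors/nt at best, for polydC under the reversible mechanism) are
equilibrium reference points, not predictions for any enzyme. Tests passing
on these templates validate the statistical mechanics exactly, and only
that.

Convergence of the per-nucleotide entropy is assessed on the consecutive-
prefix change |s(n) − s(n−1)|: for monotonous templates it falls below
10⁻³ nats by n ≈ 30 and stays there; for periodic and random templates the
per-prefix mean carries an O(1/n) oscillating term that mirrors the
template (an attenuated periodicity), so the change dips below 10⁻³ within
the first 50 nucleotides without remaining there uniformly.

## Problem sizes

Defaults used throughout the test suite and the acceptance script: curves
at N = 100; the best-case error rate at N = 1000, where the per-nucleotide
rate has converged and the weakly discriminating first site (whose ε₀
column is flatter than any interior kernel) no longer biases the mean;
oracle comparisons at N ≤ 8; goodness-of-fit of sampled joints at N = 6
with 5 × 10⁴–10⁵ strands; Monte-Carlo cross-checks with 10⁴ strands at
N = 200.

## Known limitations

- No salt or temperature extrapolation; the table is ΔG°₃₇ only.
- Double-mismatch stacks are a stated convention, not data.
- No kinetic or time-ordered simulation (no NTP/PPi dependence, no
  translocation mechanics); irreversibility enters only through the
  factorized Markov measure.
- RNA alphabets and translation (codon → amino acid) are out of scope.
- The no-neighbor energies are a derived, convention-dependent object;
  both averaging conventions ship, and conclusions that depend on ε₀
  (independent-mechanism absolute values) should be read with that in mind.
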