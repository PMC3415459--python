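# repliq

Equilibrium statistical mechanics of DNA replication fidelity.

`repliq` computes the Shannon entropy, internal energy, Helmholtz free energy
and copying error rates of a strand replicated from a DNA template in the
limit of no dissipation, for researchers in biophysics and information
thermodynamics who want exact, reproducible numbers for template-directed
copying. Base incorporation is weighted by empirical nearest-neighbor
stacking free energies at 37 °C, so fidelity emerges from the thermodynamic
affinity of the base pairs rather than from kinetic assumptions.

## The model

A template x = (x₁…x_N) over {A, C, G, T} is read 3′→5′ while the copy
y = (y₁…y_N) grows 5′→3′. The energy of a complete copy is

    E(y | x) = ε₀(y₁|x₁) + Σᵢ₌₂..N ε(yᵢ, xᵢ | yᵢ₋₁, xᵢ₋₁)

where ε(yᵢ, xᵢ | yᵢ₋₁, xᵢ₋₁) is the free energy (kcal/mol) of stacking the
current base pair on the previously formed one, taken from the published
unified nearest-neighbor parameters (Watson-Crick stacks) and internal
single-mismatch parameters, and ε₀ is the per-pair energy with the neighbor
averaged out. Three incorporation mechanisms are implemented:

- **independent** — no neighbor influence: each site is an independent
  Boltzmann draw, p(y|x) ∝ exp(−β ε₀(y|x)); the entropy
  S/k_B = Σₓ n_x H(p(·|x)) depends on the template only through its
  composition.
- **ising** — a reversible equilibrium over whole strands with weight
  exp(−β E(y|x)), computed exactly by 4×4 transfer matrices (partition
  function, site and pair marginals). Reversibility lets incorporated
  nucleotides exchange with the pool, which captures the equilibrium effect
  of exonucleolytic proofreading; it yields the lowest entropy and error
  rate.
- **turing** — an irreversible sequential Markov chain: each step draws yᵢ
  with probability ∝ exp(−β ε(yᵢ, xᵢ | yᵢ₋₁, xᵢ₋₁)) given the previous
  pair; the entropy is the chain-rule sum of conditional entropies.

For each mechanism the package reports, per prefix length n: S (nats, units
of k_B), U (kcal/mol) and F = U − TS, plus per-site non-Watson-Crick error
probabilities, the entropy-rate error bound P_e = 1 − exp(−s)
(Shannon–McMillan–Breiman geometric-mean argument), the mixing entropy of
the free-nucleotide reservoir, and the mutual information between template
and copy. Exact i.i.d. Monte-Carlo samplers (ancestral for the Markov
chain, backward marginal-chain sampling for the equilibrium ensemble) and a
brute-force enumeration oracle (N ≤ 10) cross-check every exact quantity.

## Worked example

```python
import repliq as rq

model = rq.IsingReplication(rq.make_template("polyC", 100))
res = model.fit()
print(res.summary())
batch = res.simulate(10_000, seed=42)
print(f"Monte-Carlo error rate: {batch.error_rate:.6g} ± {batch.error_rate_se:.2g}")
```

prints

```
Replication mechanism: ising
Template: polyC (N = 100 nt)
Temperature: 310.15 K
Entropy S/k_B:        0.846232 nats (0.00846232 nats/nt)
Internal energy U:    -180.768 kcal/mol
Free energy F=U-TS:   -181.29 kcal/mol
Expected error rate:  0.00108582 errors/nt
SMB upper bound:      0.00842662
Monte-Carlo error rate: 0.001078 ± 3.4e-05
```

Copying a polydC template under the reversible mechanism stores 180.8
kcal/mol of stacking energy and leaves only 0.0085 k_B of entropy per
nucleotide; the expected fidelity is about one error per thousand
incorporated nucleotides, and 10⁴ exactly sampled strands agree with the
exact rate within sampling error. The same objects exist for
`IndependentReplication` and `TuringReplication`; entropies order
ising ≤ turing ≤ independent on every benchmark template.

A command-line interface mirrors the library:

```sh
repliq entropy-curve --template benchmark --length 100 --out curves.tsv
repliq error-rate --template benchmark --n-samples 10000 --seed 1 --out errors.tsv
repliq sample --template random:7 --mechanism ising --n-samples 100 --seed 2 --out strands.fa
repliq export-table --out nn_table.tsv
```

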