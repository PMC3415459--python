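"""Brute-force enumeration over all 4^N copies — the test oracle.

For short templates (N <= 10) every copied strand can be enumerated, giving
reference values of the partition function, entropy, internal energy and
marginals against which the transfer-matrix and chain-rule computations are
checked to near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alphabet import N_SYMBOLS, TemplateSequence
from .energy import StackEnergyTable, ThermoConditions

MAX_ENUM_LENGTH = 10


@dataclass
class EnumeratedEnsemble:
    """Exact quantities from full enumeration.

    ``sequences[k]`` is the k-th strand as base-4 digits (sequences[k, i] is
    the symbol index at position i); ``probs`` its ensemble probability.
    Energies are kcal/mol, entropies nats.
    """

    template: TemplateSequence
    mechanism: str
    sequences: np.ndarray       # (4^N, N) int8
    energies: np.ndarray        # (4^N,) chain energies
    probs: np.ndarray           # (4^N,)
    log_partition: float        # Ising only; NaN for the product measure
    entropy_nats: float
    internal_energy: float
    free_energy: float
    site_marginals: np.ndarray  # (N, 4)

    def pair_marginal(self, i: int) -> np.ndarray:
        """Joint distribution of (y_i, y_{i+1}), 1-based position i."""
        n = self.sequences.shape[1]
        if not 1 <= i <= n - 1:
            raise ValueError(f"pair position {i} out of range 1..{n - 1}")
        joint = np.zeros((N_SYMBOLS, N_SYMBOLS))
        np.add.at(joint, (self.sequences[:, i - 1], self.sequences[:, i]), self.probs)
        return joint


def _all_sequences(n: int) -> np.ndarray:
    if n > MAX_ENUM_LENGTH:
        raise ValueError(f"enumeration limited to N <= {MAX_ENUM_LENGTH}, got {n}")
    idx = np.arange(N_SYMBOLS**n)
    seqs = np.empty((len(idx), n), dtype=np.int8)
    for i in range(n):
        seqs[:, n - 1 - i] = (idx // N_SYMBOLS**i) % N_SYMBOLS
    return seqs


def _chain_energies(
    seqs: np.ndarray, xs: np.ndarray, table: StackEnergyTable, eps0: np.ndarray
) -> np.ndarray:
    e = eps0[xs[0], seqs[:, 0]].astype(float)
    for i in range(1, len(xs)):
        e += table.nn[xs[i - 1], seqs[:, i - 1], xs[i], seqs[:, i]]
    return e


def _site_marginals(seqs: np.ndarray, probs: np.ndarray) -> np.ndarray:
    n = seqs.shape[1]
    site = np.zeros((n, N_SYMBOLS))
    for i in range(n):
        np.add.at(site[i], seqs[:, i], probs)
    return site


def enumerate_exact(
    template: TemplateSequence,
    table: StackEnergyTable,
    conditions: ThermoConditions | None = None,
    pair_energies: np.ndarray | None = None,
    mechanism: str = "ising",
) -> EnumeratedEnsemble:
    """Enumerate the exact ensemble of one mechanism on a short template.

    ``mechanism='ising'`` sums Boltzmann weights exp(-beta E) over all 4^N
    strands; ``mechanism='turing'`` builds the product measure of the step
    kernels.  Entropy is computed directly as -sum p ln p.
    """
    th = conditions or ThermoConditions()
    xs = template.indices()
    n = len(xs)
    eps0 = table.pair_energies() if pair_energies is None else pair_energies
    seqs = _all_sequences(n)
    energies = _chain_energies(seqs, xs, table, eps0)

    if mechanism == "ising":
        log_w = -th.beta * energies
        log_z = float(logsumexp(log_w))
        probs = np.exp(log_w - log_z)
        free_energy = -log_z / th.beta
    elif mechanism == "turing":
        from .models import step_kernels

        kernels = step_kernels(template, table, th, pair_energies=eps0)
        probs = kernels.initial[seqs[:, 0]].astype(float)
        for i in range(1, n):
            probs *= kernels.kernels[i - 1][seqs[:, i - 1], seqs[:, i]]
        log_z = float("nan")
        internal = float(probs @ energies)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(probs > 0, probs * np.log(probs), 0.0)
        entropy = float(-terms.sum())
        free_energy = internal - th.temperature * th.gas_constant * entropy
        return EnumeratedEnsemble(
            template, mechanism, seqs, energies, probs, log_z,
            entropy, internal, free_energy, _site_marginals(seqs, probs),
        )
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}: expected ising or turing")

    internal = float(probs @ energies)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log(probs), 0.0)
    entropy = float(-terms.sum())
    return EnumeratedEnsemble(
        template, mechanism, seqs, energies, probs, log_z,
        entropy, internal, free_energy, _site_marginals(seqs, probs),
    )
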