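"""Replication mechanisms as fitted-model objects.

Three mechanisms copy a template strand x_1..x_N into y_1..y_N:

``IndependentReplication``
    No neighbor influence: each y_i is drawn independently with Boltzmann
    weight exp(-beta eps0(y_i|x_i)) from the per-pair energies.

``IsingReplication``
    Reversible equilibrium over whole strands with configuration energy
    E(y) = eps0(y_1|x_1) + sum_i eps(y_i, x_i | y_{i-1}, x_{i-1}); computed
    exactly with 4x4 transfer matrices (forward-backward, per-step rescaling).
    Because the ensemble is global, per-nucleotide quantities at position n
    depend on the total chain length.

``TuringReplication``
    Irreversible, sequential Markov chain: each step incorporates y_i with a
    locally Boltzmann-weighted kernel given the previous pair; the entropy is
    the chain-rule sum of conditional entropies.

``model.fit()`` returns a :class:`ReplicationResults` carrying per-prefix
entropy S (nats, i.e. units of k_B), internal energy U and Helmholtz free
energy F = U - T S (kcal/mol), exact site marginals, an error report, a
``summary()`` table and a ``simulate()`` method for drawing strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import (
    ALPHABET,
    N_SYMBOLS,
    WC_INDEX,
    CopiedStrand,
    TemplateSequence,
)
from .energy import StackEnergyTable, ThermoConditions, derive_pair_energies, load_nn_table

__all__ = [
    "IncorporationMatrix",
    "incorporation_matrix",
    "uniform_entropy_rate",
    "chain_energy",
    "ChainEnsemble",
    "ising_ensemble",
    "ising_conditional",
    "StepKernel",
    "step_kernels",
    "ReplicationModel",
    "IndependentReplication",
    "IsingReplication",
    "TuringReplication",
    "ReplicationResults",
    "entropy_independent",
    "ising_thermo",
    "turing_thermo",
    "compare_mechanisms",
]


def _boltzmann_rows(energies: np.ndarray, beta: float) -> np.ndarray:
    """Row-normalized Boltzmann distributions, max-shifted against overflow.

    The result is invariant under adding a constant to any row of energies.
    """
    shifted = energies - energies.min(axis=-1, keepdims=True)
    w = np.exp(-beta * shifted)
    return w / w.sum(axis=-1, keepdims=True)


def _entropy_rows(p: np.ndarray) -> np.ndarray:
    """Shannon entropy of each row in nats; 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=-1)


# ---------------------------------------------------------------------------
# independent (no-neighbor) mechanism primitives


@dataclass(frozen=True)
class IncorporationMatrix:
    """Column-stochastic 4x4 matrix; entry (y, x) = P(incorporate y | template x).

    Rows and columns follow the alphabet order A, C, G, T; the Watson-Crick
    pairs sit on the anti-diagonal and carry the column maxima.
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_SYMBOLS, N_SYMBOLS):
            raise ValueError("incorporation matrix must be 4x4")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-12):
            raise ValueError("incorporation matrix columns must sum to 1")
        object.__setattr__(self, "p", p)

    def column(self, x: int | str) -> np.ndarray:
        """Distribution of the incorporated symbol opposite template x."""
        if isinstance(x, str):
            x = ALPHABET.index(x)
        return self.p[:, x]

    def by_template(self) -> np.ndarray:
        """(x, y)-indexed view: row x is the distribution opposite template x."""
        return self.p.T


def incorporation_matrix(
    pair_energies: np.ndarray, conditions: ThermoConditions | None = None
) -> IncorporationMatrix:
    """Boltzmann incorporation probabilities from per-pair energies.

    p(y|x) = exp(-beta eps0(y|x)) / sum_y' exp(-beta eps0(y'|x)).
    """
    th = conditions or ThermoConditions()
    by_x = _boltzmann_rows(np.asarray(pair_energies, dtype=float), th.beta)  # (x, y)
    return IncorporationMatrix(by_x.T)


def uniform_entropy_rate(matrix: IncorporationMatrix, weights: np.ndarray | None = None) -> float:
    """Entropy per nucleotide of the stationary uniform copying process, nats.

    Averages the column entropies H(p(.|x)) with equal weight 1/4 on each
    template symbol (or with ``weights`` summing to 1).
    """
    w = np.full(N_SYMBOLS, 0.25) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (N_SYMBOLS,) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be 4 probabilities summing to 1")
    return float(w @ _entropy_rows(matrix.by_template()))


# ---------------------------------------------------------------------------
# shared energy primitives


def chain_energy(
    strand: CopiedStrand | str,
    template: TemplateSequence,
    table: StackEnergyTable,
    pair_energies: np.ndarray | None = None,
) -> float:
    """Configuration energy E(y|x) in kcal/mol.

    E = eps0(y_1|x_1) + sum_{i>=2} eps(y_i, x_i | y_{i-1}, x_{i-1}); the first
    site has no stacking neighbor and uses the derived per-pair energy.
    """
    y = CopiedStrand(strand).indices() if isinstance(strand, str) else strand.indices()
    x = template.indices()
    if len(y) != len(x):
        raise ValueError(f"strand length {len(y)} != template length {len(x)}")
    eps0 = table.pair_energies() if pair_energies is None else pair_energies
    e = float(eps0[x[0], y[0]])
    if len(x) > 1:
        e += float(table.nn[x[:-1], y[:-1], x[1:], y[1:]].sum())
    return e


# ---------------------------------------------------------------------------
# Ising (partition-function) mechanism


@dataclass
class ChainEnsemble:
    """Exact equilibrium ensemble of copies of one template.

    ``site_marginals[i]`` is P(y_{i+1}); ``pair_marginals[i]`` the joint
    distribution of (y_{i+1}, y_{i+2}).  Forward/backward vectors are kept
    (rescaled, with log accumulation) for conditionals and exact sampling.
    """

    template: TemplateSequence
    table: StackEnergyTable
    conditions: ThermoConditions
    log_partition: float
    site_marginals: np.ndarray          # (N, 4)
    pair_marginals: np.ndarray          # (N-1, 4, 4)
    internal_energy: float              # kcal/mol

    @property
    def free_energy(self) -> float:
        """Helmholtz free energy -log(Z)/beta, kcal/mol."""
        return -self.log_partition / self.conditions.beta

    @property
    def entropy_nats(self) -> float:
        """S/k_B = beta (U - F)."""
        return self.conditions.beta * (self.internal_energy - self.free_energy)


def _ising_pass(
    xs: np.ndarray, nn: np.ndarray, eps0: np.ndarray, beta: float
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """One exact forward-backward sweep; returns logZ, site & pair marginals, U."""
    n = len(xs)
    # forward, rescaled each step; shifts keep exponents bounded
    e1 = eps0[xs[0]]
    shift = e1.min()
    f = np.exp(-beta * (e1 - shift))
    sc = f.sum()
    log_z = np.log(sc) - beta * shift
    f /= sc
    forwards = [f.copy()]
    transfers: list[np.ndarray | None] = [None]
    for i in range(1, n):
        e = nn[xs[i - 1], :, xs[i], :]  # (y_prev, y)
        shift = e.min()
        t = np.exp(-beta * (e - shift))
        transfers.append(t)
        f = f @ t
        sc = f.sum()
        log_z += np.log(sc) - beta * shift
        f /= sc
        forwards.append(f.copy())
    # backward (normalization-free up to scaling)
    b = np.ones(N_SYMBOLS)
    backwards = [np.empty(0)] * n
    backwards[n - 1] = b.copy()
    for i in range(n - 1, 0, -1):
        b = transfers[i] @ b
        b /= b.sum()
        backwards[i - 1] = b.copy()
    site = np.array([forwards[i] * backwards[i] for i in range(n)])
    site /= site.sum(axis=1, keepdims=True)
    pair = np.empty((n - 1, N_SYMBOLS, N_SYMBOLS))
    u = float(site[0] @ eps0[xs[0]])
    for i in range(1, n):
        joint = forwards[i - 1][:, None] * transfers[i] * backwards[i][None, :]
        joint /= joint.sum()
        pair[i - 1] = joint
        u += float((joint * nn[xs[i - 1], :, xs[i], :]).sum())
    return log_z, site, pair, u


def ising_ensemble(
    template: TemplateSequence,
    table: StackEnergyTable | None = None,
    conditions: ThermoConditions | None = None,
    pair_energies: np.ndarray | None = None,
) -> ChainEnsemble:
    """Exact transfer-matrix ensemble for the reversible mechanism."""
    table = table if table is not None else load_nn_table()
    th = conditions or ThermoConditions()
    eps0 = table.pair_energies() if pair_energies is None else pair_energies
    xs = template.indices()
    log_z, site, pair, u = _ising_pass(xs, table.nn, eps0, th.beta)
    return ChainEnsemble(
        template=template,
        table=table,
        conditions=th,
        log_partition=log_z,
        site_marginals=site,
        pair_marginals=pair,
        internal_energy=u,
    )


def ising_conditional(ensemble: ChainEnsemble, i: int, prev: str | int) -> np.ndarray:
    """P(y_i | y_{i-1} = prev) in the exact joint ensemble; positions 1-based, i >= 2."""
    n = len(ensemble.template)
    if not 2 <= i <= n:
        raise ValueError(f"position {i} out of range 2..{n}")
    if isinstance(prev, str):
        prev = ALPHABET.index(prev)
    joint = ensemble.pair_marginals[i - 2]  # (y_{i-1}, y_i)
    row = joint[prev]
    return row / row.sum()


# ---------------------------------------------------------------------------
# Turing (Markov-chain) mechanism


@dataclass
class StepKernel:
    """Sequential incorporation kernels along one template.

    ``initial`` is q_1(y) from the per-pair energies of the first template
    symbol; ``kernels[i-2]`` (for position i >= 2) is the row-stochastic
    matrix q_i[y', y] = P(y at i | previous copied symbol y').
    """

    template: TemplateSequence
    initial: np.ndarray            # (4,)
    kernels: np.ndarray            # (N-1, 4, 4)

    def __len__(self) -> int:
        return len(self.template)


def step_kernels(
    template: TemplateSequence,
    table: StackEnergyTable | None = None,
    conditions: ThermoConditions | None = None,
    pair_energies: np.ndarray | None = None,
) -> StepKernel:
    """Boltzmann step kernels q_i(y|y') = softmax_y(-beta eps(y, x_i | y', x_{i-1}))."""
    table = table if table is not None else load_nn_table()
    th = conditions or ThermoConditions()
    eps0 = table.pair_energies() if pair_energies is None else pair_energies
    xs = template.indices()
    q1 = _boltzmann_rows(eps0[xs[0]], th.beta)
    if len(xs) > 1:
        energies = table.nn[xs[:-1], :, xs[1:], :]  # (N-1, y_prev, y)
        kernels = _boltzmann_rows(energies, th.beta)
    else:
        kernels = np.empty((0, N_SYMBOLS, N_SYMBOLS))
    return StepKernel(template=template, initial=q1, kernels=kernels)


# ---------------------------------------------------------------------------
# results container


class ReplicationResults:
    """Exact thermodynamic results of one mechanism on one template.

    ``per_prefix`` is a DataFrame with one row per prefix length n: total and
    per-nucleotide entropy (nats), internal energy and free energy (kcal/mol),
    satisfying F = U - T S at every n.
    """

    def __init__(
        self,
        model: "ReplicationModel",
        mechanism: str,
        per_prefix: pd.DataFrame,
        site_marginals: np.ndarray,
        *,
        ensemble: ChainEnsemble | None = None,
        kernels: StepKernel | None = None,
        matrix: IncorporationMatrix | None = None,
    ):
        self.model = model
        self.mechanism = mechanism
        self.per_prefix = per_prefix
        self.site_marginals = site_marginals
        self.ensemble = ensemble
        self.kernels = kernels
        self.matrix = matrix

    # -- headline scalars (full-length values) ----------------------------

    @property
    def template(self) -> TemplateSequence:
        return self.model.template

    @property
    def entropy_total_nats(self) -> float:
        return float(self.per_prefix["S_total_nats"].iloc[-1])

    @property
    def entropy_per_nt_nats(self) -> float:
        return float(self.per_prefix["s_per_nt_nats"].iloc[-1])

    @property
    def internal_energy_kcal_mol(self) -> float:
        return float(self.per_prefix["U_total_kcal_mol"].iloc[-1])

    @property
    def free_energy_kcal_mol(self) -> float:
        return float(self.per_prefix["F_total_kcal_mol"].iloc[-1])

    def error_report(self):
        """Per-site and average non-Watson-Crick incorporation probabilities."""
        from .fidelity import error_report_from_marginals

        return error_report_from_marginals(
            self.site_marginals, self.template, self.entropy_per_nt_nats
        )

    def simulate(self, n_samples: int, seed: int):
        """Draw exact i.i.d. copied strands; see :mod:`repliq.sampling`."""
        from . import sampling

        if self.mechanism == "ising":
            return sampling.sample_ising(self.ensemble, n_samples, seed)
        if self.mechanism == "turing":
            return sampling.sample_turing(
                self.template, self.kernels, self.model.table, n_samples, seed,
                pair_energies=self.model.pair_energies,
            )
        return sampling.sample_independent(
            self.template, self.matrix, self.model.table, n_samples, seed,
            pair_energies=self.model.pair_energies,
        )

    def to_tsv(self, path) -> None:
        from .cli import write_curve_tsv

        write_curve_tsv([self], path)

    def summary(self) -> str:
        rep = self.error_report()
        th = self.model.conditions
        lines = [
            f"Replication mechanism: {self.mechanism}",
            f"Template: {self.template.label} (N = {len(self.template)} nt)",
            f"Temperature: {th.temperature:.2f} K",
            f"Entropy S/k_B:        {self.entropy_total_nats:.6g} nats "
            f"({self.entropy_per_nt_nats:.6g} nats/nt)",
            f"Internal energy U:    {self.internal_energy_kcal_mol:.6g} kcal/mol",
            f"Free energy F=U-TS:   {self.free_energy_kcal_mol:.6g} kcal/mol",
            f"Expected error rate:  {rep.expected_error_rate:.6g} errors/nt",
            f"SMB upper bound:      {rep.smb_upper_bound:.6g}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ReplicationResults {self.mechanism} template={self.template.label!r} "
            f"N={len(self.template)} s={self.entropy_per_nt_nats:.4g} nats/nt>"
        )


def _per_prefix_frame(
    s_tot: np.ndarray, u_tot: np.ndarray, th: ThermoConditions
) -> pd.DataFrame:
    n = np.arange(1, len(s_tot) + 1)
    f_tot = u_tot - th.temperature * th.gas_constant * s_tot
    return pd.DataFrame(
        {
            "n": n,
            "S_total_nats": s_tot,
            "s_per_nt_nats": s_tot / n,
            "U_total_kcal_mol": u_tot,
            "u_per_nt_kcal_mol": u_tot / n,
            "F_total_kcal_mol": f_tot,
            "f_per_nt_kcal_mol": f_tot / n,
        }
    )


# ---------------------------------------------------------------------------
# models


class ReplicationModel:
    """Base class binding a template to an energy table and conditions.

    Parameters
    ----------
    template
        A :class:`TemplateSequence` or plain string over A, C, G, T.
    table
        Completed :class:`StackEnergyTable`; the built-in unified table by
        default.
    conditions
        :class:`ThermoConditions`; 310.15 K by default.
    pair_context
        Averaging mode for the derived per-pair energies (``all_contexts``
        or ``wc_contexts``).
    """

    mechanism: str = "base"

    def __init__(
        self,
        template: TemplateSequence | str,
        table: StackEnergyTable | None = None,
        conditions: ThermoConditions | None = None,
        pair_context: str = "all_contexts",
    ):
        self.template = (
            template if isinstance(template, TemplateSequence) else TemplateSequence(template)
        )
        self.table = table if table is not None else load_nn_table()
        self.conditions = conditions or ThermoConditions()
        self.pair_context = pair_context
        self.pair_energies = derive_pair_energies(self.table, context=pair_context)

    @classmethod
    def from_fasta(cls, path, record: int = 0, **kwargs) -> "ReplicationModel":
        from .io_fasta import read_fasta

        return cls(read_fasta(path)[record], **kwargs)

    def fit(self) -> ReplicationResults:
        raise NotImplementedError


class IndependentReplication(ReplicationModel):
    """No-neighbor mechanism: independent, non-identically distributed sites."""

    mechanism = "independent"

    def fit(self) -> ReplicationResults:
        matrix = incorporation_matrix(self.pair_energies, self.conditions)
        return entropy_independent(self.template, matrix, self.conditions, self)


class IsingReplication(ReplicationModel):
    """Reversible partition-function mechanism (exact transfer matrices)."""

    mechanism = "ising"

    def fit(self, per_prefix: bool = True) -> ReplicationResults:
        ens = ising_ensemble(self.template, self.table, self.conditions, self.pair_energies)
        return ising_thermo(ens, per_prefix=per_prefix, model=self)


class TuringReplication(ReplicationModel):
    """Irreversible sequential Markov-chain mechanism."""

    mechanism = "turing"

    def fit(self) -> ReplicationResults:
        kernels = step_kernels(self.template, self.table, self.conditions, self.pair_energies)
        return turing_thermo(self.template, kernels, self.table, self.conditions, model=self)


# ---------------------------------------------------------------------------
# mechanism computations (functional surface behind the model classes)


def entropy_independent(
    template: TemplateSequence,
    matrix: IncorporationMatrix,
    conditions: ThermoConditions | None = None,
    model: ReplicationModel | None = None,
) -> ReplicationResults:
    """Entropy/energy of the no-neighbor mechanism.

    S/k_B = sum_x n_x H(p(.|x)) depends on the template only through its
    composition; U sums the mean pair energy per site.
    """
    th = conditions or ThermoConditions()
    model = model or IndependentReplication(template, conditions=th)
    xs = template.indices()
    by_x = matrix.by_template()
    h_cols = _entropy_rows(by_x)
    u_cols = (by_x * model.pair_energies).sum(axis=1)
    s_tot = np.cumsum(h_cols[xs])
    u_tot = np.cumsum(u_cols[xs])
    site = by_x[xs]
    return ReplicationResults(
        model, "independent", _per_prefix_frame(s_tot, u_tot, th), site, matrix=matrix
    )


def ising_thermo(
    ensemble: ChainEnsemble,
    per_prefix: bool = True,
    model: ReplicationModel | None = None,
) -> ReplicationResults:
    """Exact S, U, F of the reversible ensemble, per prefix length.

    The ensemble is global, so each prefix length is its own ensemble and is
    recomputed with a full sweep (cost O(N^2), exact).
    """
    template, table, th = ensemble.template, ensemble.table, ensemble.conditions
    model = model or IsingReplication(template, table, th)
    xs = template.indices()
    n_tot = len(xs)
    beta = th.beta
    ns = range(1, n_tot + 1) if per_prefix else [n_tot]
    s_list, u_list = [], []
    for n in ns:
        if n == n_tot:
            log_z, u = ensemble.log_partition, ensemble.internal_energy
        else:
            log_z, _, _, u = _ising_pass(xs[:n], table.nn, model.pair_energies, beta)
        s_list.append(beta * u + log_z)
        u_list.append(u)
    return ReplicationResults(
        model,
        "ising",
        _per_prefix_frame(np.array(s_list), np.array(u_list), th),
        ensemble.site_marginals,
        ensemble=ensemble,
    )


def turing_thermo(
    template: TemplateSequence,
    kernels: StepKernel,
    table: StackEnergyTable | None = None,
    conditions: ThermoConditions | None = None,
    model: ReplicationModel | None = None,
) -> ReplicationResults:
    """Chain-rule S, forward-propagated marginals and U of the Markov mechanism.

    One forward pass gives every prefix exactly (the sequential mechanism has
    no dependence on the total length).
    """
    th = conditions or ThermoConditions()
    model = model or TuringReplication(template, table, conditions=th)
    table = table if table is not None else model.table
    xs = template.indices()
    n = len(xs)
    q1 = kernels.initial
    mu = q1.copy()
    site = np.empty((n, N_SYMBOLS))
    site[0] = mu
    s_tot = np.empty(n)
    u_tot = np.empty(n)
    s_tot[0] = _entropy_rows(q1)
    u_tot[0] = float(q1 @ model.pair_energies[xs[0]])
    for i in range(1, n):
        q = kernels.kernels[i - 1]
        s_tot[i] = s_tot[i - 1] + float(mu @ _entropy_rows(q))
        u_tot[i] = u_tot[i - 1] + float(
            (mu[:, None] * q * table.nn[xs[i - 1], :, xs[i], :]).sum()
        )
        mu = mu @ q
        site[i] = mu
    return ReplicationResults(
        model, "turing", _per_prefix_frame(s_tot, u_tot, th), site, kernels=kernels
    )


def compare_mechanisms(
    template: TemplateSequence | str,
    table: StackEnergyTable | None = None,
    conditions: ThermoConditions | None = None,
    pair_context: str = "all_contexts",
) -> tuple[pd.DataFrame, dict[str, ReplicationResults]]:
    """Per-prefix s, u, f for all three mechanisms plus ordering flags.

    Returns a long-form table with one row per (mechanism, n) and a column
    ``ordering_violation`` marking prefixes where the expected entropy
    ordering ising <= turing <= independent fails.
    """
    kwargs = dict(table=table, conditions=conditions, pair_context=pair_context)
    results = {
        "independent": IndependentReplication(template, **kwargs).fit(),
        "ising": IsingReplication(template, **kwargs).fit(),
        "turing": TuringReplication(template, **kwargs).fit(),
    }
    s = {m: r.per_prefix["s_per_nt_nats"].to_numpy() for m, r in results.items()}
    tol = 1e-12
    violation = (s["ising"] > s["turing"] + tol) | (s["turing"] > s["independent"] + tol)
    frames = []
    for mech, res in results.items():
        frame = res.per_prefix.copy()
        frame.insert(0, "mechanism", mech)
        frame.insert(0, "template_label", res.template.label)
        frame["ordering_violation"] = violation
        frames.append(frame)
    return pd.concat(frames, ignore_index=True), results
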