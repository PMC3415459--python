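"""Error rates, reservoir entropy and information bookkeeping.

An error is any non-Watson-Crick union: the per-site error probability is
1 - P(y_i = wc(x_i)) under the exact site marginals of a mechanism.  The
Shannon-McMillan-Breiman theorem gives a heuristic upper bound on the error
probability from the entropy rate alone, via the geometric-mean probability
per symbol exp(-s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .alphabet import ALPHABET, N_SYMBOLS, WC_INDEX, TemplateSequence


@dataclass(frozen=True)
class ErrorReport:
    """Expected copying errors of one mechanism on one template."""

    per_site_error_prob: np.ndarray
    expected_error_rate: float          # errors per incorporated nucleotide
    entropy_rate_nats: float
    smb_upper_bound: float

    def __post_init__(self) -> None:
        p = np.asarray(self.per_site_error_prob, dtype=float)
        if ((p < -1e-12) | (p > 1 + 1e-12)).any():
            raise ValueError("per-site error probabilities must lie in [0, 1]")


def exact_error_rate(site_marginals: np.ndarray, template: TemplateSequence) -> np.ndarray:
    """Per-site probability of a non-Watson-Crick incorporation.

    ``site_marginals[i]`` is the exact distribution of y_{i+1} under any of
    the three mechanisms; the result is 1 - P(y_i = wc(x_i)) per site.
    """
    xs = template.indices()
    marg = np.asarray(site_marginals, dtype=float)
    if marg.shape != (len(xs), N_SYMBOLS):
        raise ValueError(f"site marginals must be shaped ({len(xs)}, 4), got {marg.shape}")
    return 1.0 - marg[np.arange(len(xs)), WC_INDEX[xs]]


def error_report_from_marginals(
    site_marginals: np.ndarray, template: TemplateSequence, entropy_rate_nats: float
) -> ErrorReport:
    per_site = exact_error_rate(site_marginals, template)
    return ErrorReport(
        per_site_error_prob=per_site,
        expected_error_rate=float(per_site.mean()),
        entropy_rate_nats=float(entropy_rate_nats),
        smb_upper_bound=smb_error_bound(entropy_rate_nats),
    )


def smb_error_bound(entropy_rate_nats: float) -> float:
    """Heuristic error bound P_e = 1 - exp(-s) from the entropy rate s (nats).

    The geometric-mean per-symbol probability of a typical strand is
    exp(-s); treating it as the per-site probability of the correct symbol
    gives an upper-bound-style estimate of the error probability.  It is a
    heuristic (not a theorem-level bound on the exact rate) but is exact in
    the deterministic (s = 0) and uniform (s = ln 4) limits.
    """
    if entropy_rate_nats < 0:
        # S = beta (U - F) can round to a tiny negative in deterministic limits
        if entropy_rate_nats > -1e-9:
            return 0.0
        raise ValueError(f"entropy rate must be >= 0, got {entropy_rate_nats}")
    return float(-np.expm1(-entropy_rate_nats))


@dataclass(frozen=True)
class ReservoirSpec:
    """Free-nucleotide pool; concentrations in arbitrary common units."""

    concentrations: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in ALPHABET}
    )

    def fractions(self) -> np.ndarray:
        c = np.array([self.concentrations.get(s, 0.0) for s in ALPHABET], dtype=float)
        if (c < 0).any():
            raise ValueError("concentrations must be nonnegative")
        total = c.sum()
        if total <= 0:
            raise ValueError("at least one nucleotide concentration must be positive")
        return c / total


def reservoir_entropy(reservoir: ReservoirSpec, n_nucleotides: int) -> tuple[float, float]:
    """Gibbs mixing entropy of the pool: (total, per-nucleotide), nats.

    Per nucleotide: -sum_z c_z ln c_z over normalized fractions; ln 4 for an
    equimolar pool.
    """
    c = reservoir.fractions()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(c > 0, c * np.log(c), 0.0)
    per_nt = float(-terms.sum())
    return n_nucleotides * per_nt, per_nt


def boltzmann_multinomial_entropy(counts: dict[str, int]) -> float:
    """Boltzmann entropy ln(N! / prod n_z!) of a finite pool, nats (log-gamma).

    Converges to N times the Gibbs per-nucleotide value as N grows.
    """
    n_z = np.array([counts.get(s, 0) for s in ALPHABET], dtype=float)
    if (n_z < 0).any():
        raise ValueError("counts must be nonnegative")
    n = n_z.sum()
    if n < 1:
        raise ValueError("total count must be >= 1")
    return float(gammaln(n + 1) - gammaln(n_z + 1).sum())


def information_balance(s_initial_nats: float, s_final_nats: float) -> tuple[float, float]:
    """(delta_S, mutual information) of the copying step, nats.

    The entropy change S_final - S_initial and the information acquired about
    the template are equal and opposite: I = S_initial - S_final.
    """
    if s_initial_nats < 0 or s_final_nats < 0:
        raise ValueError("entropies must be >= 0")
    delta = s_final_nats - s_initial_nats
    return delta, -delta


NATS_TO_BITS = 1.0 / np.log(2.0)
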