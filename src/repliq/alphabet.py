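"""Genetic alphabet, Watson-Crick complementarity and template constructors.

The model works on the four-letter deoxyribonucleotide alphabet in the fixed
order A < C < G < T.  A template is read 3'-to-5' while its copy is
synthesized 5'-to-3'; position ``i`` always counts 1-based in synthesis order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

ALPHABET: str = "ACGT"
N_SYMBOLS: int = 4

#: index of each symbol in the canonical order
SYMBOL_INDEX: dict[str, int] = {s: i for i, s in enumerate(ALPHABET)}

_WC: dict[str, str] = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: wc_index[k] is the index of the Watson-Crick partner of symbol k
WC_INDEX: np.ndarray = np.array([SYMBOL_INDEX[_WC[s]] for s in ALPHABET])

DIRECTION_NOTE = "template read 3prime-to-5prime, copy synthesized 5prime-to-3prime"


def wc_complement(symbol: str) -> str:
    """Watson-Crick partner of a single nucleotide symbol (involutive)."""
    try:
        return _WC[symbol]
    except KeyError:
        raise ValueError(
            f"invalid nucleotide symbol {symbol!r}: expected one of A, C, G, T"
        ) from None


def _validate_symbols(symbols: str, what: str) -> str:
    symbols = symbols.upper()
    for pos, ch in enumerate(symbols, start=1):
        if ch not in SYMBOL_INDEX:
            raise ValueError(
                f"{what} contains invalid symbol {ch!r} at position {pos} "
                "(alphabet is A, C, G, T; ambiguity codes are not supported)"
            )
    return symbols


@dataclass(frozen=True)
class TemplateSequence:
    """An ordered template strand x_1..x_N over {A, C, G, T}.

    Positions are 1-based in synthesis order of the copy (the template is
    traversed 3'-to-5').
    """

    symbols: str
    label: str = "template"
    direction_note: str = field(default=DIRECTION_NOTE, compare=False)

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError("template must contain at least one nucleotide")
        object.__setattr__(self, "symbols", _validate_symbols(self.symbols, f"template {self.label!r}"))

    def __len__(self) -> int:
        return len(self.symbols)

    def indices(self) -> np.ndarray:
        """Template symbols as an int array in alphabet order."""
        return np.fromiter((SYMBOL_INDEX[s] for s in self.symbols), dtype=np.int64, count=len(self.symbols))

    def prefix(self, n: int) -> "TemplateSequence":
        if not 1 <= n <= len(self):
            raise ValueError(f"prefix length {n} out of range 1..{len(self)}")
        return TemplateSequence(self.symbols[:n], label=self.label)


@dataclass(frozen=True)
class CopiedStrand:
    """A realized copy y_1..y_N, same length as its template."""

    symbols: str
    template_label: str = "template"

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", _validate_symbols(self.symbols, "copied strand"))

    def __len__(self) -> int:
        return len(self.symbols)

    def indices(self) -> np.ndarray:
        return np.fromiter((SYMBOL_INDEX[s] for s in self.symbols), dtype=np.int64, count=len(self.symbols))


def make_template(
    kind: str,
    length: int,
    seed: int | None = None,
    period_motif: str = "ACGT",
    label: str | None = None,
) -> TemplateSequence:
    """Construct a template strand.

    Parameters
    ----------
    kind
        One of ``polyA``, ``polyC``, ``polyG``, ``polyT`` (monotonous strands),
        ``periodic`` (repeat ``period_motif`` truncated to ``length``) or
        ``random`` (i.i.d. uniform over the alphabet, drawn from
        ``numpy.random.default_rng(seed)``, i.e. the PCG64 generator, so the
        result is reproducible bit-exactly across platforms).
    length
        Number of nucleotides, >= 1.
    seed
        Required for ``kind='random'``.
    period_motif
        Motif for ``kind='periodic'``; non-empty, over {A, C, G, T}.
    """
    if length < 1:
        raise ValueError(f"template length must be >= 1, got {length}")
    if kind in ("polyA", "polyC", "polyG", "polyT"):
        base = kind[-1]
        seq = base * length
        name = label or kind
    elif kind == "periodic":
        if not period_motif:
            raise ValueError("periodic template requires a non-empty motif")
        motif = _validate_symbols(period_motif, "period motif")
        reps = length // len(motif) + 1
        seq = (motif * reps)[:length]
        name = label or f"periodic_{motif}"
    elif kind == "random":
        if seed is None:
            raise ValueError("random template requires an explicit seed")
        rng = np.random.default_rng(seed)
        seq = "".join(ALPHABET[i] for i in rng.integers(0, N_SYMBOLS, size=length))
        name = label or f"random_seed{seed}"
    else:
        raise ValueError(
            f"unknown template kind {kind!r}: expected polyA/polyC/polyG/polyT/periodic/random"
        )
    return TemplateSequence(seq, label=name)


def count_composition(template: TemplateSequence) -> dict[str, int]:
    """Counts n_x of each nucleotide type; values sum to N."""
    c = Counter(template.symbols)
    return {s: c.get(s, 0) for s in ALPHABET}


def standard_templates(length: int = 100, random_seed: int = 20120809) -> list[TemplateSequence]:
    """The six benchmark templates: four monotonous strands, the ACGT-periodic
    strand and one seeded uniform-random strand."""
    return [
        make_template("polyA", length),
        make_template("polyC", length),
        make_template("polyG", length),
        make_template("polyT", length),
        make_template("periodic", length, period_motif="ACGT"),
        make_template("random", length, seed=random_seed),
    ]
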