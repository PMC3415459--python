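"""Nearest-neighbor stacking free energies and thermodynamic constants.

The replication model weighs each incorporation by the free energy
epsilon(y_i, x_i | y_{i-1}, x_{i-1}) of stacking the current base pair
(template x_i, incorporated y_i) on the previously formed pair, in kcal/mol
at the reference temperature of 37 C.  The shipped default table combines the
unified Watson-Crick parameters (SantaLucia 1998) with the internal
single-mismatch parameters of Allawi & SantaLucia and Peyret et al.;
stacks with two consecutive mismatches are mostly unmeasured and are filled
with a configurable destabilizing default.

Duplex strand symmetry: reading a stack from the opposite strand orientation
gives the same free energy,

    eps(cur=(x, y) | prev=(x', y')) = eps(cur=(x', y') | prev=(y, x)),

and completion closes every table under this relation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .alphabet import ALPHABET, N_SYMBOLS, SYMBOL_INDEX, WC_INDEX

#: gas constant in kcal/(mol K)
GAS_CONSTANT_KCAL: float = 1.98720425e-3

#: default free energy (kcal/mol) for unmeasured double-mismatch stacks;
#: destabilizing, at least as penalizing as the worst measured mismatch stack
DEFAULT_FILL_KCAL: float = 1.0

MEASURED = "measured"
SYMMETRY_FILLED = "symmetry-filled"
DEFAULT_FILLED = "default-filled"

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class ThermoConditions:
    """Reference conditions; beta = 1/(R T) in mol/kcal."""

    temperature: float = 310.15
    gas_constant: float = field(default=GAS_CONSTANT_KCAL, compare=False)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def beta(self) -> float:
        return 1.0 / (self.gas_constant * self.temperature)


def _key_str(px: int, py: int, cx: int, cy: int) -> str:
    a = ALPHABET
    return f"prev=({a[px]}·{a[py]}) cur=({a[cx]}·{a[cy]})"


def _mirror(px: int, py: int, cx: int, cy: int) -> tuple[int, int, int, int]:
    # strand-symmetric reading of the same duplex stack
    return cy, cx, py, px


def _is_wc(x: int, y: int) -> bool:
    return WC_INDEX[x] == y


class StackEnergyTable:
    """All 256 stacking free energies eps(cur pair | prev pair), kcal/mol.

    Axes of ``nn`` are [prev_x, prev_y, cur_x, cur_y] in alphabet order
    A, C, G, T; missing entries are NaN until :func:`complete_table` is run.
    ``provenance`` records, per entry, whether the value was measured,
    implied by strand symmetry, or default-filled.
    """

    def __init__(self, nn: np.ndarray | None = None, provenance: np.ndarray | None = None):
        shape = (N_SYMBOLS,) * 4
        self.nn = np.full(shape, np.nan) if nn is None else np.asarray(nn, dtype=float)
        if provenance is None:
            provenance = np.full(shape, "", dtype=object)
        self.provenance = provenance
        if self.nn.shape != shape or self.provenance.shape != shape:
            raise ValueError("stack energy table must be 4x4x4x4")

    # -- basic access -----------------------------------------------------

    def set_energy(self, prev_pair: str, cur_pair: str, value: float, provenance: str = MEASURED) -> None:
        px, py = (SYMBOL_INDEX[s] for s in prev_pair)
        cx, cy = (SYMBOL_INDEX[s] for s in cur_pair)
        self.nn[px, py, cx, cy] = value
        self.provenance[px, py, cx, cy] = provenance

    def nn_energy(self, prev_pair: str, cur_pair: str) -> float:
        """Energy of stacking cur_pair = (template, copy) on prev_pair."""
        px, py = (SYMBOL_INDEX[s] for s in prev_pair)
        cx, cy = (SYMBOL_INDEX[s] for s in cur_pair)
        v = self.nn[px, py, cx, cy]
        if np.isnan(v):
            raise KeyError(f"no energy for {_key_str(px, py, cx, cy)}")
        return float(v)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.nn).any()

    def n_entries(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.nn)))

    def provenance_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for tag in self.provenance.ravel():
            if tag:
                counts[tag] = counts.get(tag, 0) + 1
        return counts

    def copy(self) -> "StackEnergyTable":
        return StackEnergyTable(self.nn.copy(), self.provenance.copy())

    # -- derived per-pair (no-neighbor) energies --------------------------

    def pair_energies(self, context: str = "all_contexts") -> np.ndarray:
        return derive_pair_energies(self, context=context)


def load_nn_table(source: str = "unified_default", fill_value: float = DEFAULT_FILL_KCAL) -> StackEnergyTable:
    """Load a stacking free-energy table.

    ``source='unified_default'`` returns the completed built-in table (the
    published unified WC and internal-mismatch parameters at 37 C, symmetry
    closed, double mismatches default-filled).  Any other string is a path to
    a TSV with header columns prev_x, prev_y, cur_x, cur_y, dG_kcal_mol and
    an optional provenance column; '#' lines are comments.  Tables loaded
    from a path are returned raw (possibly partial) with entries marked
    measured unless a provenance column says otherwise.
    """
    if source == "unified_default":
        ref = importlib.resources.files("repliq.data").joinpath("unified_nn_dg37.tsv")
        with importlib.resources.as_file(ref) as path:
            raw = _read_table_tsv(str(path))
        return complete_table(raw, fill_value=fill_value)
    return _read_table_tsv(source)


def _read_table_tsv(path: str) -> StackEnergyTable:
    table = StackEnergyTable()
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                required = ["prev_x", "prev_y", "cur_x", "cur_y", "dG_kcal_mol"]
                if header[: len(required)] != required:
                    raise ValueError(
                        f"{path}:{lineno}: expected header columns {required}, got {header}"
                    )
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            px_s, py_s, cx_s, cy_s, val_s = fields[:5]
            prov = fields[5] if len(fields) > 5 and fields[5] else MEASURED
            try:
                px, py, cx, cy = (SYMBOL_INDEX[s] for s in (px_s, py_s, cx_s, cy_s))
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: invalid nucleotide symbol {exc.args[0]!r}") from None
            try:
                value = float(val_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric energy {val_s!r}") from None
            if not np.isnan(table.nn[px, py, cx, cy]):
                raise ValueError(
                    f"{path}:{lineno}: duplicate key {_key_str(px, py, cx, cy)}"
                )
            table.nn[px, py, cx, cy] = value
            table.provenance[px, py, cx, cy] = prov
    if header is None:
        raise ValueError(f"{path}: empty table (header row required)")
    return table


def complete_table(
    raw: StackEnergyTable,
    fill_value: float = DEFAULT_FILL_KCAL,
    tol: float = _SYMMETRY_TOL,
) -> StackEnergyTable:
    """Close a raw table under strand symmetry and fill double mismatches.

    Every present entry implies its strand-symmetric mirror; if both
    orientations were given and disagree by more than ``tol`` the pair of
    keys is reported.  Entries whose previous and current pairs are both
    non-Watson-Crick and that remain unmeasured are set to ``fill_value``
    and flagged ``default-filled``.  The result is total (256 entries).
    """
    table = raw.copy()
    nn, prov = table.nn, table.provenance
    for px in range(N_SYMBOLS):
        for py in range(N_SYMBOLS):
            for cx in range(N_SYMBOLS):
                for cy in range(N_SYMBOLS):
                    v = nn[px, py, cx, cy]
                    if np.isnan(v):
                        continue
                    mk = _mirror(px, py, cx, cy)
                    mv = nn[mk]
                    if np.isnan(mv):
                        nn[mk] = v
                        prov[mk] = SYMMETRY_FILLED
                    elif abs(mv - v) > tol:
                        raise ValueError(
                            "strand-symmetry conflict between measured entries "
                            f"{_key_str(px, py, cx, cy)} ({v:g}) and "
                            f"{_key_str(*mk)} ({mv:g})"
                        )
    missing_non_fillable = []
    for px in range(N_SYMBOLS):
        for py in range(N_SYMBOLS):
            for cx in range(N_SYMBOLS):
                for cy in range(N_SYMBOLS):
                    if not np.isnan(nn[px, py, cx, cy]):
                        continue
                    if _is_wc(px, py) or _is_wc(cx, cy):
                        missing_non_fillable.append(_key_str(px, py, cx, cy))
                    else:
                        nn[px, py, cx, cy] = fill_value
                        prov[px, py, cx, cy] = DEFAULT_FILLED
    if missing_non_fillable:
        raise ValueError(
            "table lacks measured/symmetry values for stacks involving a "
            f"Watson-Crick pair: {missing_non_fillable[:6]}"
            + ("..." if len(missing_non_fillable) > 6 else "")
        )
    return table


def validate_symmetry(table: StackEnergyTable, tol: float = _SYMMETRY_TOL) -> list[dict]:
    """Report every strand-symmetry violation (empty list = table symmetric).

    Each violation names the two keys of the orbit and their difference.
    """
    if not table.is_complete:
        raise ValueError("symmetry validation requires a completed table")
    violations = []
    seen = set()
    for px in range(N_SYMBOLS):
        for py in range(N_SYMBOLS):
            for cx in range(N_SYMBOLS):
                for cy in range(N_SYMBOLS):
                    key = (px, py, cx, cy)
                    mk = _mirror(*key)
                    orbit = tuple(sorted([key, mk]))
                    if orbit in seen:
                        continue
                    seen.add(orbit)
                    delta = table.nn[key] - table.nn[mk]
                    if abs(delta) > tol:
                        violations.append(
                            {
                                "key": _key_str(*key),
                                "mirror_key": _key_str(*mk),
                                "delta_kcal_mol": float(delta),
                            }
                        )
    return violations


def derive_pair_energies(table: StackEnergyTable, context: str = "all_contexts") -> np.ndarray:
    """Per-pair energies eps0[x, y] with the neighbor averaged out, kcal/mol.

    ``all_contexts`` (default) averages the stacking energy of the current
    pair over all 16 possible previous pairs — the marginal energy seen by a
    copier with no knowledge of the neighbor.  ``wc_contexts`` averages over
    the four Watson-Crick previous pairs only.
    """
    if not table.is_complete:
        raise ValueError("pair energies require a completed table")
    if context == "all_contexts":
        return table.nn.mean(axis=(0, 1))
    if context == "wc_contexts":
        cols = np.array(
            [table.nn[x, WC_INDEX[x]] for x in range(N_SYMBOLS)]
        )  # (4 prev contexts, cur_x, cur_y)
        return cols.mean(axis=0)
    raise ValueError(f"unknown context mode {context!r}: expected all_contexts or wc_contexts")


def export_table(table: StackEnergyTable, path: str) -> None:
    """Write the completed table as TSV with a provenance column."""
    with open(path, "w") as fh:
        fh.write("prev_x\tprev_y\tcur_x\tcur_y\tdG_kcal_mol\tprovenance\n")
        for px in range(N_SYMBOLS):
            for py in range(N_SYMBOLS):
                for cx in range(N_SYMBOLS):
                    for cy in range(N_SYMBOLS):
                        v = table.nn[px, py, cx, cy]
                        if np.isnan(v):
                            continue
                        fh.write(
                            "%s\t%s\t%s\t%s\t%.10g\t%s\n"
                            % (
                                ALPHABET[px],
                                ALPHABET[py],
                                ALPHABET[cx],
                                ALPHABET[cy],
                                v,
                                table.provenance[px, py, cx, cy] or MEASURED,
                            )
                        )
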