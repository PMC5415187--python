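"""Discrete morphological character matrices: data model, NEXUS I/O, recoding.

Cells are sets of state indices: a singleton is an unambiguous score, a larger
set a polymorphism or partial uncertainty, and the full state set stands for a
missing (``?``) or inapplicable (``-``) entry.  The two symbols are kept apart
for round-tripping but are computationally identical everywhere downstream,
which is how the parsimony and model-based programs this package mirrors treat
them.

A character's state count ``k`` is the maximum attested state index plus one
(a character scored only 0 and 2 is three-state), matching how NEXUS symbol
declarations are interpreted by Mk-model software.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import dendropy


class MatrixParseError(ValueError):
    pass


class RecodingError(ValueError):
    pass


@dataclass
class CharacterMeta:
    index: int
    n_states: int
    ordered: bool = False
    active: bool = True

    def __post_init__(self):
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")


def _normalize_label(label: str) -> str:
    return label.strip().replace(" ", "_")


class CharacterMatrix:
    """Taxa x characters, each cell a non-empty set of state indices.

    Internally cells are bitmasks (bit ``i`` = state ``i``); ``gap`` records
    which fully-ambiguous cells were written ``-`` rather than ``?``.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        cells: np.ndarray,
        char_meta: Sequence[CharacterMeta],
        gap: np.ndarray | None = None,
        designated_outgroup: str | None = None,
    ):
        self.taxa = [_normalize_label(t) for t in taxa]
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixParseError("duplicate taxon labels")
        self.cells = np.asarray(cells, dtype=np.int64)
        self.char_meta = list(char_meta)
        if self.cells.shape != (len(self.taxa), len(self.char_meta)):
            raise MatrixParseError("cell array shape does not match taxa/characters")
        self.gap = (
            np.zeros(self.cells.shape, dtype=bool) if gap is None else np.asarray(gap, bool)
        )
        self.designated_outgroup = (
            _normalize_label(designated_outgroup) if designated_outgroup else None
        )
        for c, meta in enumerate(self.char_meta):
            full = (1 << meta.n_states) - 1
            col = self.cells[:, c]
            if np.any(col <= 0) or np.any(col & ~full):
                raise MatrixParseError(
                    f"character {c + 1}: cell state set empty or outside 0..{meta.n_states - 1}"
                )

    # -- basics ---------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.char_meta)

    def taxon_index(self, label: str) -> int:
        return self.taxa.index(_normalize_label(label))

    def state_set(self, taxon: int | str, char: int) -> frozenset:
        if isinstance(taxon, str):
            taxon = self.taxon_index(taxon)
        mask = int(self.cells[taxon, char])
        return frozenset(i for i in range(self.char_meta[char].n_states) if mask >> i & 1)

    def is_missing(self, taxon: int, char: int) -> bool:
        return int(self.cells[taxon, char]) == (1 << self.char_meta[char].n_states) - 1

    def missing_fraction(self) -> float:
        full = np.array([(1 << m.n_states) - 1 for m in self.char_meta])
        return float(np.mean(self.cells == full[None, :]))

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and [(m.n_states, m.ordered, m.active) for m in self.char_meta]
            == [(m.n_states, m.ordered, m.active) for m in other.char_meta]
            and np.array_equal(self.cells, other.cells)
            and np.array_equal(self.gap, other.gap)
        )

    __hash__ = None

    # -- construction ---------------------------------------------------

    @classmethod
    def from_rows(
        cls,
        taxa: Sequence[str],
        rows: Sequence[Sequence[object]],
        ordered: Iterable[int] = (),
        designated_outgroup: str | None = None,
        n_states: Sequence[int] | int | None = None,
    ) -> "CharacterMatrix":
        """Build from per-taxon rows of cells.

        Each cell may be an ``int`` state, an iterable of states, ``"?"``
        (missing) or ``"-"`` (inapplicable/gap).  ``n_states`` overrides the
        per-character state count (scalar = same for all) when the caller
        knows it independently of what is attested, e.g. from a simulation's
        generating model; it may only widen the attested count.
        """
        n_taxa = len(taxa)
        n_chars = len(rows[0]) if rows else 0
        sets: list[list[frozenset | None]] = []
        gaps = np.zeros((n_taxa, n_chars), dtype=bool)
        for i, row in enumerate(rows):
            if len(row) != n_chars:
                raise MatrixParseError(f"row {i + 1} has {len(row)} cells, expected {n_chars}")
            out = []
            for c, cell in enumerate(row):
                if isinstance(cell, str) and cell in ("?", "-"):
                    gaps[i, c] = cell == "-"
                    out.append(None)
                elif isinstance(cell, (int, np.integer)):
                    out.append(frozenset([int(cell)]))
                else:
                    out.append(frozenset(int(x) for x in cell))
            sets.append(out)
        ordered = set(ordered)
        if n_states is None:
            k_over: list[int | None] = [None] * n_chars
        elif isinstance(n_states, (int, np.integer)):
            k_over = [int(n_states)] * n_chars
        else:
            k_over = [int(x) for x in n_states]
        metas, cells = [], np.zeros((n_taxa, n_chars), dtype=np.int64)
        for c in range(n_chars):
            attested = frozenset().union(
                *(sets[i][c] for i in range(n_taxa) if sets[i][c] is not None),
                frozenset(),
            )
            # state count: highest attested index + 1, floored at two so that
            # missing entries in (effectively) binary characters stay binary
            k = max(2, max(attested) + 1 if attested else 2)
            if k_over[c] is not None:
                if k_over[c] < k:
                    raise MatrixParseError(
                        f"character {c + 1}: declared {k_over[c]} states but "
                        f"state {k - 1} is attested"
                    )
                k = k_over[c]
            metas.append(CharacterMeta(c, k, ordered=c in ordered))
            full = (1 << k) - 1
            for i in range(n_taxa):
                s = sets[i][c]
                cells[i, c] = full if s is None else sum(1 << x for x in s)
        return cls(taxa, cells, metas, gaps, designated_outgroup)

    def subset_characters(self, keep: Sequence[int]) -> "CharacterMatrix":
        rows = [
            ["-" if self.gap[i, c] else ("?" if self.is_missing(i, c) else self.state_set(i, c))
             for c in keep]
            for i in range(self.n_taxa)
        ]
        ordered = [j for j, c in enumerate(keep) if self.char_meta[c].ordered]
        return CharacterMatrix.from_rows(
            self.taxa, rows, ordered, self.designated_outgroup,
            n_states=[self.char_meta[c].n_states for c in keep],
        )


# -- NEXUS I/O ----------------------------------------------------------


_TYPESET_RE = re.compile(
    r"TYPESET\s+\*?\s*\w+\s*(?:\(\s*\w+\s*\))?\s*=\s*([^;]*);", re.I | re.S
)


def _parse_ordered_from_typeset(text: str) -> set[int]:
    """Indices (0-based) of characters flagged ``ord`` in an ASSUMPTIONS TYPESET."""
    ordered: set[int] = set()
    m = _TYPESET_RE.search(text)
    if not m:
        return ordered
    for part in m.group(1).split(","):
        if ":" not in part:
            continue
        kind, ranges = part.split(":", 1)
        if kind.strip().lower() not in ("ord", "ordered"):
            continue
        for tok in ranges.split():
            if "-" in tok:
                lo, hi = tok.split("-")
                ordered.update(range(int(lo) - 1, int(hi)))
            else:
                ordered.add(int(tok) - 1)
    return ordered


def read_nexus_matrix(path) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block of standard (digit-symbol) data."""
    with open(path) as fh:
        text = fh.read()
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise MatrixParseError(f"could not parse NEXUS matrix {path}: {exc}") from exc
    taxa = [t.label for t in dm.taxon_namespace]
    rows = []
    for tax in dm.taxon_namespace:
        row = []
        for st in dm[tax]:
            if st.symbol == "?":
                row.append("?")
            elif st.symbol == "-":
                row.append("-")
            else:
                vals = [
                    int(f.symbol)
                    for f in st.fundamental_states
                    if f.symbol is not None and f.symbol.isdigit()
                ]
                if not vals:
                    raise MatrixParseError(
                        f"taxon {tax.label}: undecodable symbol {st.symbol!r}"
                    )
                row.append(frozenset(vals))
        rows.append(row)
    ordered = _parse_ordered_from_typeset(text)
    return CharacterMatrix.from_rows(taxa, rows, ordered)


def write_nexus_matrix(
    matrix: CharacterMatrix, path, polymorphism_dialect: str = "paren"
) -> None:
    """Write a NEXUS DATA block; ``polymorphism_dialect`` is ``paren`` or ``brace``."""
    open_, close = ("(", ")") if polymorphism_dialect == "paren" else ("{", "}")
    kmax = max((m.n_states for m in matrix.char_meta), default=2)
    symbols = "".join(str(i) for i in range(max(kmax, 2)))
    width = max(len(t) for t in matrix.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n")
        fh.write(f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\nMATRIX\n')
        for i, tax in enumerate(matrix.taxa):
            toks = []
            for c in range(matrix.n_characters):
                if matrix.is_missing(i, c):
                    toks.append("-" if matrix.gap[i, c] else "?")
                else:
                    states = sorted(matrix.state_set(i, c))
                    if len(states) == 1:
                        toks.append(str(states[0]))
                    else:
                        toks.append(open_ + "".join(map(str, states)) + close)
            fh.write(f"{tax:<{width}}{''.join(toks)}\n")
        fh.write(";\nEND;\n")
        ordered = [m.index + 1 for m in matrix.char_meta if m.ordered]
        if ordered:
            fh.write("BEGIN ASSUMPTIONS;\n")
            fh.write(
                "TYPESET * default = ord: "
                + " ".join(map(str, ordered))
                + ", unord: "
                + " ".join(
                    str(m.index + 1) for m in matrix.char_meta if not m.ordered
                )
                + ";\nEND;\n"
            )


# -- contingent -> multistate recoding ----------------------------------


@dataclass
class Merge:
    """One host character absorbing dependent binary characters.

    ``table`` maps joint tuples ``(host_state, absorbed_1, ...)`` to the new
    host state; ``None`` inside a key is a wildcard for that position.  Joint
    states not covered by the table fall back to the host state unchanged
    (the usual case: the absorbed characters are inapplicable there), unless
    ``identity_fallback`` is disabled.
    """

    host: int
    absorbed: tuple[int, ...]
    table: dict[tuple, int]
    identity_fallback: bool = True

    def resolve(self, joint: tuple) -> int | None:
        if joint in self.table:
            return self.table[joint]
        for key, val in self.table.items():
            if all(k is None or k == j for k, j in zip(key, joint)):
                return val
        if self.identity_fallback:
            return joint[0]
        return None


@dataclass
class RecodingMap:
    merges: list[Merge] = field(default_factory=list)

    def __post_init__(self):
        absorbed = [a for m in self.merges for a in m.absorbed]
        if len(absorbed) != len(set(absorbed)):
            raise RecodingError("a character is absorbed by more than one merge")


def merge_contingent_characters(
    matrix: CharacterMatrix, recoding: RecodingMap
) -> CharacterMatrix:
    """Fold dependent binary characters into their host transformation series.

    The result drops every absorbed column; each host cell becomes the set of
    recoded states over all joint resolutions of the (possibly ambiguous)
    host and absorbed cells.  A cell resolvable to nothing is an error unless
    every component was missing, in which case it stays missing.
    """
    for m in recoding.merges:
        for a in m.absorbed:
            if not (0 <= a < matrix.n_characters):
                raise RecodingError(f"absorbed character index {a} out of range")
            if matrix.char_meta[a].n_states > 2:
                raise RecodingError(f"absorbed character {a + 1} is not binary")
        if not (0 <= m.host < matrix.n_characters):
            raise RecodingError(f"host character index {m.host} out of range")
    absorbed_all = {a for m in recoding.merges for a in m.absorbed}
    by_host = {m.host: m for m in recoding.merges}
    keep = [c for c in range(matrix.n_characters) if c not in absorbed_all]
    rows: list[list] = []
    for i in range(matrix.n_taxa):
        row: list = []
        for c in keep:
            if c not in by_host:
                row.append(
                    "-" if matrix.gap[i, c] else
                    ("?" if matrix.is_missing(i, c) else matrix.state_set(i, c))
                )
                continue
            m = by_host[c]
            parts = [matrix.state_set(i, c)] + [matrix.state_set(i, a) for a in m.absorbed]
            all_missing = matrix.is_missing(i, c) and all(
                matrix.is_missing(i, a) for a in m.absorbed
            )
            out: set[int] = set()
            import itertools

            for joint in itertools.product(*parts):
                val = m.resolve(joint)
                if val is not None:
                    out.add(val)
            if out:
                row.append(frozenset(out))
            elif all_missing:
                row.append("?")
            else:
                raise RecodingError(
                    f"taxon {matrix.taxa[i]}: joint state of characters "
                    f"{[c + 1] + [a + 1 for a in m.absorbed]} not in recoding table"
                )
        rows.append(row)
    ordered = [j for j, c in enumerate(keep) if matrix.char_meta[c].ordered]
    return CharacterMatrix.from_rows(
        matrix.taxa, rows, ordered, matrix.designated_outgroup
    )
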