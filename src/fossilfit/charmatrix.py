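"""Discrete morphological character matrices.

The central object is :class:`CharacterMatrix`: an ordered set of taxa scored
for unordered multistate characters, with explicit support for polymorphic
cells (a taxon showing more than one state) and missing cells (``?``).
Missing data behave as the full state set of their character in all parsimony
computations, which is what makes partially preserved fossils scoreable at
all.

Character indices are 1-based at every user-facing boundary (matching the
convention "characters 5(0), 10(0), ..." used when coding a fossil into a
published matrix); internal storage is 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "CellState",
    "CharacterDef",
    "CharacterMatrix",
    "NexusParseError",
    "read_nexus",
    "write_nexus",
    "append_taxon",
]


class NexusParseError(ValueError):
    """Raised when a NEXUS character block is malformed."""


def normalize_taxon(name: str) -> str:
    """Trim surrounding whitespace and collapse internal runs to ``_``."""
    return re.sub(r"\s+", "_", name.strip())


@dataclass(frozen=True)
class CellState:
    """One matrix cell: observed (singleton), polymorphic (set) or missing.

    ``states`` is a frozenset of integer state codes; empty for missing.
    """

    kind: str  # "observed" | "polymorphic" | "missing"
    states: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.kind == "observed" and len(self.states) != 1:
            raise ValueError("observed cell must hold exactly one state")
        if self.kind == "polymorphic" and len(self.states) < 2:
            raise ValueError("polymorphic cell must hold >= 2 states")
        if self.kind == "missing" and self.states:
            raise ValueError("missing cell holds no explicit states")

    @classmethod
    def observed(cls, state: int) -> "CellState":
        return cls("observed", frozenset({state}))

    @classmethod
    def polymorphic(cls, states) -> "CellState":
        return cls("polymorphic", frozenset(states))

    @classmethod
    def missing(cls) -> "CellState":
        return cls("missing")

    def state_set(self, n_states: int) -> frozenset:
        """Effective state set: missing expands to all states of the character."""
        if self.kind == "missing":
            return frozenset(range(n_states))
        return self.states


@dataclass(frozen=True)
class CharacterDef:
    index: int  # 1-based
    label: str = ""
    n_states: int = 2
    ordered: bool = False

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError(f"character {self.index}: n_states must be >= 2")
        if self.ordered:
            raise ValueError("ordered characters are not supported")


@dataclass
class CharacterMatrix:
    """taxa x characters grid of :class:`CellState`."""

    taxa: list
    characters: list
    cells: list  # list (per taxon) of list (per character) of CellState
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.taxa = [normalize_taxon(t) for t in self.taxa]
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon names must be unique")
        if len(self.cells) != len(self.taxa):
            raise ValueError("cell grid has wrong number of rows")
        for name, row in zip(self.taxa, self.cells):
            if len(row) != len(self.characters):
                raise ValueError(
                    f"taxon {name!r}: row has {len(row)} cells, "
                    f"expected {len(self.characters)}"
                )
        for j, (char, col) in enumerate(zip(self.characters, self.columns())):
            for name, cell in zip(self.taxa, col):
                bad = [s for s in cell.states if not 0 <= s < char.n_states]
                if bad:
                    raise ValueError(
                        f"taxon {name!r}, character {j + 1}: state(s) {bad} "
                        f"outside [0, {char.n_states - 1}]"
                    )
        self._index = {t: i for i, t in enumerate(self.taxa)}

    # -- shape & access ----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def row(self, taxon: str):
        return self.cells[self._index[normalize_taxon(taxon)]]

    def columns(self):
        for j in range(self.n_characters):
            yield [self.cells[i][j] for i in range(self.n_taxa)]

    def cell(self, taxon: str, index: int) -> CellState:
        """Cell by taxon name and 1-based character index."""
        return self.row(taxon)[index - 1]

    def missing_fraction(self, taxon: str) -> float:
        row = self.row(taxon)
        return sum(c.kind == "missing" for c in row) / len(row)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and self.cells == other.cells
        )


# ---------------------------------------------------------------------------
# NEXUS I/O
# ---------------------------------------------------------------------------

def _infer_n_states(columns) -> list:
    """Per-character state count: max observed code + 1, floored at 2."""
    out = []
    for col in columns:
        states = set()
        for cell in col:
            states |= cell.states
        out.append(max(2, (max(states) + 1) if states else 2))
    return out


def read_nexus(path) -> CharacterMatrix:
    """Parse a NEXUS DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    Handles interleaved and non-interleaved matrices, ``(..)``/``{..}``
    polymorphism, and maps both the declared missing symbol and the gap
    symbol to missing (no gap states exist in these matrices).
    """
    try:
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises several error classes
        raise NexusParseError(f"{path}: {exc}") from exc
    if len(dmat) == 0:
        raise NexusParseError(f"{path}: no taxa in matrix")

    taxa, rows = [], []
    lengths = {len(dmat[t]) for t in dmat}
    if len(lengths) != 1:
        offender = next(t.label for t in dmat if len(dmat[t]) != max(lengths))
        raise NexusParseError(
            f"{path}: ragged matrix; taxon {offender!r} row length differs"
        )
    for tax in dmat:
        taxa.append(normalize_taxon(tax.label))
        row = []
        for j, s in enumerate(dmat[tax]):
            # '?' and gap '-' are missing; {..}/(..) compounds are polymorphic
            if s.symbol in ("?", "-"):
                row.append(CellState.missing())
                continue
            members = s.member_states if s.member_states is not None else [s]
            codes = set()
            for m in members:
                if m.symbol in ("?", "-"):
                    continue
                try:
                    codes.add(int(m.symbol))
                except (TypeError, ValueError):
                    raise NexusParseError(
                        f"{path}: unknown symbol {m.symbol!r} at character {j + 1} "
                        f"of taxon {tax.label!r}"
                    ) from None
            if not codes:
                row.append(CellState.missing())
            elif len(codes) == 1:
                row.append(CellState.observed(codes.pop()))
            else:
                row.append(CellState.polymorphic(codes))
        rows.append(row)

    ncols = len(rows[0])
    columns = [[rows[i][j] for i in range(len(rows))] for j in range(ncols)]
    n_states = _infer_n_states(columns)
    chars = [CharacterDef(index=j + 1, n_states=k) for j, k in enumerate(n_states)]
    return CharacterMatrix(taxa=taxa, characters=chars, cells=rows)


def _format_cell(cell: CellState) -> str:
    if cell.kind == "missing":
        return "?"
    if cell.kind == "observed":
        return str(next(iter(cell.states)))
    return "{" + "".join(str(s) for s in sorted(cell.states)) + "}"


def write_nexus(matrix: CharacterMatrix, path) -> None:
    """Write one canonical NEXUS dialect: non-interleaved, {} polymorphism."""
    max_state = max(c.n_states for c in matrix.characters)
    symbols = "".join(str(i) for i in range(max_state))
    width = max((len(t) for t in matrix.taxa), default=1) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for name, row in zip(matrix.taxa, matrix.cells):
        seq = "".join(_format_cell(c) for c in row)
        lines.append(f"    {name:<{width}}{seq}")
    lines += ["    ;", "END;", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def append_taxon(matrix: CharacterMatrix, name: str, codings: dict) -> CharacterMatrix:
    """Insert a partially coded taxon (e.g. a fossil).

    ``codings`` maps 1-based character index -> observed state code; every
    character absent from the map becomes a missing cell.
    """
    name = normalize_taxon(name)
    if name in matrix.taxa:
        raise ValueError(f"taxon {name!r} already present")
    for idx, state in codings.items():
        if not 1 <= idx <= matrix.n_characters:
            raise ValueError(f"character index {idx} out of range 1..{matrix.n_characters}")
        k = matrix.characters[idx - 1].n_states
        if not 0 <= state < k:
            raise ValueError(f"character {idx}: state {state} outside [0, {k - 1}]")
    row = [
        CellState.observed(codings[j + 1]) if (j + 1) in codings else CellState.missing()
        for j in range(matrix.n_characters)
    ]
    return CharacterMatrix(
        taxa=matrix.taxa + [name],
        characters=list(matrix.characters),
        cells=[list(r) for r in matrix.cells] + [row],
    )
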