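import textwrap

import pytest

from fossilfit.charmatrix import (
    CellState,
    CharacterDef,
    CharacterMatrix,
    read_nexus,
)


@pytest.fixture
def toy_nexus(tmp_path):
    """3 taxa x 2 binary characters with one missing and one polymorphic cell."""
    text = textwrap.dedent(
        """\
        #NEXUS
        BEGIN DATA;
        DIMENSIONS NTAX=3 NCHAR=2;
        FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
        MATRIX
        A 01
        B ?1
        C {01}0
        ;
        END;
        """
    )
    path = tmp_path / "toy.nex"
    path.write_text(text)
    return path


@pytest.fixture
def toy_matrix(toy_nexus):
    return read_nexus(toy_nexus)


def binary_matrix(taxa, columns):
    """Matrix from explicit state columns, e.g. columns=[[0,0,1,1],[0,1,0,1]].

    A value of None is missing; a set is polymorphic.
    """
    chars = [CharacterDef(index=j + 1, n_states=2) for j in range(len(columns))]
    cells = []
    for i in range(len(taxa)):
        row = []
        for col in columns:
            v = col[i]
            if v is None:
                row.append(CellState.missing())
            elif isinstance(v, (set, frozenset)):
                row.append(CellState.polymorphic(v))
            else:
                row.append(CellState.observed(v))
        cells.append(row)
    return CharacterMatrix(taxa=list(taxa), characters=chars, cells=cells)


@pytest.fixture
def quartet_matrix():
    """4 taxa, two complementary binary characters: AB|CD and AC|BD."""
    return binary_matrix("ABCD", [[0, 0, 1, 1], [0, 1, 0, 1]])
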