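"""Shared fixtures: small text fixtures are generated at test time."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

# Minimal synthetic 3-residue PDB (poly-alanine backbone, chain A) used for the
# structure-mapping tests. Hand-built coordinates; not a real deposited entry.
TOY_PDB = textwrap.dedent("""\
    ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 50.00           N
    ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 50.00           C
    ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 50.00           C
    ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 50.00           O
    ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00 50.00           N
    ATOM      6  CA  ALA A   2       3.988   2.839   0.000  1.00 50.00           C
    ATOM      7  C   ALA A   2       5.504   2.693   0.000  1.00 50.00           C
    ATOM      8  O   ALA A   2       6.030   1.581   0.000  1.00 50.00           O
    ATOM      9  N   ALA A   3       6.220   3.812   0.000  1.00 50.00           N
    ATOM     10  CA  ALA A   3       7.674   3.790   0.000  1.00 50.00           C
    ATOM     11  C   ALA A   3       8.232   5.201   0.000  1.00 50.00           C
    ATOM     12  O   ALA A   3       7.479   6.178   0.000  1.00 50.00           O
    TER      13      ALA A   3
    END
""")

SPARKY_3LINE = textwrap.dedent("""\
          Assignment         w1         w2

            G109N-H    110.123      8.456
             A42N-H    118.500      7.900
            L205N-H    125.010     10.220
""")


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def sparky_file(tmp_path):
    p = tmp_path / "ref.list"
    p.write_text(SPARKY_3LINE)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
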