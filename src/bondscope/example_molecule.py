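"""A synthetic worked-example molecule for the descriptor documentation.

This amino-ynone (hex-1-yn-3-one skeleton carrying a dibutylamine-like
amine, 14 heavy atoms) is a synthetic construction, built so that the
internal alkyne bond between printed atoms 8 and 9 makes a clean worked
example for sphere assignment and pair descriptors:

* sphere 0 = {8, 9} (the target bond),
* sphere 1 = {5, 10},
* sphere 2 = {4, 6, 11, 14},
* the element pair descriptor (sphere 2, distance 2, C-C) equals 4,
  contributed by exactly the atom pairs 4-6, 4-8, 6-8 and 11-9.

Atom numbering below is 1-based, as printed in a molfile; the library
itself uses 0-based indices (subtract 1).

::

    1   2   3   4    5    6   7        C1-C2-C3-C4-N5(-C6-C7)
                 \\   |   /
                  N5 (tertiary amine, no H)
                  |
    8 # 9         C8 (triple bond) C9
                  |
    10            C10 (=O14 carbonyl) - C11-C12-C13
"""

from __future__ import annotations

from .graph import MolecularGraph, parse_structure

#: 1-based printed numbering of the target bond used in the walkthrough.
TARGET_BOND_PRINTED = (8, 9)

#: The same bond in the library's 0-based indices.
TARGET_BOND = (7, 8)

_ATOMS = ["C", "C", "C", "C", "N", "C", "C", "C", "C", "C", "C", "C", "C", "O"]
_BONDS = [
    (1, 2, 1),
    (2, 3, 1),
    (3, 4, 1),
    (4, 5, 1),
    (5, 6, 1),
    (6, 7, 1),
    (5, 8, 1),
    (8, 9, 3),
    (9, 10, 1),
    (10, 11, 1),
    (11, 12, 1),
    (12, 13, 1),
    (10, 14, 2),
]


def example_molblock() -> str:
    """V2000 molfile of the worked-example molecule (2D coordinates zeroed;
    descriptors are purely topological)."""
    lines = [
        "worked-example amino-ynone",
        "  bondscope",
        "",
        f"{len(_ATOMS):>3}{len(_BONDS):>3}  0  0  0  0  0  0  0  0999 V2000",
    ]
    for symbol in _ATOMS:
        lines.append(
            f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {symbol:<3} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for i, j, order in _BONDS:
        lines.append(f"{i:>3}{j:>3}{order:>3}  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def example_molecule() -> MolecularGraph:
    """Parsed explicit-hydrogen graph of the worked-example molecule."""
    return parse_structure(example_molblock())
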