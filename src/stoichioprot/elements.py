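"""Side-chain elemental composition of protein sequences.

The central quantity of stoichiogenomics is the element content of a
protein: the mean number of atoms of a given element (C, H, N, O or S)
carried on amino-acid *side chains*, per residue,

    [E] = sum_i w_i * p_i / L

where ``w_i`` is the number of atoms of the element on the side chain of
residue type *i*, ``p_i`` is the count of that residue in the sequence and
``L`` the (cleaned) sequence length.  The invariant backbone
(N-Calpha-C=O) and the free termini are excluded, so the content measures
only the variable, selectable part of the molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S")
STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Atom counts on each standard residue's side chain, backbone excluded.
#: Derived from the free amino-acid molecular formula minus H2O (peptide
#: bond) minus the chain backbone C2H2NO.  Proline's ring is charged to the
#: side chain under the same uniform convention (C3H5).
_SIDE_CHAIN_ATOMS: dict[str, dict[str, int]] = {
    "A": {"C": 1, "H": 3},
    "R": {"C": 4, "H": 10, "N": 3},
    "N": {"C": 2, "H": 4, "N": 1, "O": 1},
    "D": {"C": 2, "H": 3, "O": 2},
    "C": {"C": 1, "H": 3, "S": 1},
    "E": {"C": 3, "H": 5, "O": 2},
    "Q": {"C": 3, "H": 6, "N": 1, "O": 1},
    "G": {"H": 1},
    "H": {"C": 4, "H": 5, "N": 2},
    "I": {"C": 4, "H": 9},
    "L": {"C": 4, "H": 9},
    "K": {"C": 4, "H": 10, "N": 1},
    "M": {"C": 3, "H": 7, "S": 1},
    "F": {"C": 7, "H": 7},
    "P": {"C": 3, "H": 5},
    "S": {"C": 1, "H": 3, "O": 1},
    "T": {"C": 2, "H": 5, "O": 1},
    "W": {"C": 9, "H": 8, "N": 1},
    "Y": {"C": 7, "H": 7, "O": 1},
    "V": {"C": 3, "H": 7},
}


class CompositionTableError(ValueError):
    """Raised when a composition table is malformed or incomplete."""


@dataclass(frozen=True)
class ElementCompositionTable:
    """Per-residue side-chain atom counts for the five biogenic elements.

    ``entries`` maps ``(residue, element)`` to a non-negative integer atom
    count.  Exactly the 20 standard residues must be present for every
    element; counts lie in [0, 11].
    """

    entries: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        for res in STANDARD_RESIDUES:
            for elem in ELEMENTS:
                key = (res, elem)
                if key not in self.entries:
                    raise CompositionTableError(
                        f"composition table missing entry for residue {res!r}, "
                        f"element {elem!r}"
                    )
                count = self.entries[key]
                if not isinstance(count, (int, np.integer)) or isinstance(count, bool):
                    raise CompositionTableError(
                        f"count for ({res}, {elem}) is not an integer: {count!r}"
                    )
                if not 0 <= count <= 11:
                    raise CompositionTableError(
                        f"count for ({res}, {elem}) out of range [0, 11]: {count}"
                    )

    def count(self, residue: str, element: str) -> int:
        """Atom count of ``element`` on the side chain of ``residue``."""
        return int(self.entries[(residue, element)])

    def weights(self, element: str) -> dict[str, int]:
        """Residue -> side-chain atom count for one element."""
        if element not in ELEMENTS:
            raise KeyError(f"unknown element {element!r}; expected one of {ELEMENTS}")
        return {res: int(self.entries[(res, element)]) for res in STANDARD_RESIDUES}

    def weight_lut(self, element: str) -> np.ndarray:
        """256-entry lookup of side-chain counts indexed by ASCII byte.

        Non-standard letters map to 0; use :meth:`valid_lut` to exclude
        them from the length denominator.
        """
        lut = np.zeros(256, dtype=np.float64)
        for res, w in self.weights(element).items():
            lut[ord(res)] = w
        return lut

    @staticmethod
    def valid_lut() -> np.ndarray:
        lut = np.zeros(256, dtype=bool)
        for res in STANDARD_RESIDUES:
            lut[ord(res)] = True
        return lut

    @classmethod
    def default(cls) -> "ElementCompositionTable":
        entries = {
            (res, elem): _SIDE_CHAIN_ATOMS[res].get(elem, 0)
            for res in STANDARD_RESIDUES
            for elem in ELEMENTS
        }
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ElementCompositionTable":
        """Load a table from 3-column TSV (residue, element, count)."""
        entries: dict[tuple[str, str], int] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise CompositionTableError(
                        f"{path}:{lineno}: expected 3 tab-separated fields, "
                        f"got {len(parts)}"
                    )
                res, elem, raw = parts
                if res in ("residue",) and elem in ("element",):
                    continue  # header
                try:
                    count = int(raw)
                except ValueError as exc:
                    raise CompositionTableError(
                        f"{path}:{lineno}: non-integer count {raw!r}"
                    ) from exc
                entries[(res, elem)] = count
        return cls(entries)


def load_composition_table(
    source: str | Path | None = None,
) -> ElementCompositionTable:
    """Return the built-in side-chain table, or load an override TSV."""
    if source is None:
        return ElementCompositionTable.default()
    return ElementCompositionTable.from_tsv(source)


@dataclass
class SequenceElementProfile:
    """Element contents and residue composition of one cleaned sequence."""

    sequence_id: str
    length: int
    content: dict[str, float]
    composition: dict[str, int] = field(default_factory=dict)
    dropped: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.sequence_id}: profile length must be positive")


def clean_sequence(sequence: str) -> tuple[str, int]:
    """Uppercase and strip non-standard letters (B, Z, J, X, U, O, gaps, stops).

    Returns the cleaned sequence and the number of dropped characters.
    Selenocysteine (U) is dropped, not remapped to C.
    """
    upper = sequence.upper()
    kept = [c for c in upper if c in _SIDE_CHAIN_ATOMS]
    return "".join(kept), len(upper) - len(kept)


def element_content(
    sequence: str,
    element: str,
    table: ElementCompositionTable | None = None,
) -> float:
    """Mean side-chain atoms of ``element`` per residue of ``sequence``.

    Non-standard letters are dropped before computation and the cleaned
    length is the denominator.  An empty or all-invalid sequence raises
    ``ValueError`` rather than silently returning 0.
    """
    table = table or ElementCompositionTable.default()
    cleaned, _ = clean_sequence(sequence)
    if not cleaned:
        raise ValueError(
            "sequence contains no standard amino-acid letters after cleaning"
        )
    weights = table.weights(element)
    total = sum(weights[res] for res in cleaned)
    return total / len(cleaned)


def sequence_profile(
    sequence_id: str,
    sequence: str,
    table: ElementCompositionTable | None = None,
    elements: Sequence[str] = ("O", "C"),
) -> SequenceElementProfile:
    """Build a :class:`SequenceElementProfile` for the requested elements."""
    table = table or ElementCompositionTable.default()
    cleaned, dropped = clean_sequence(sequence)
    if not cleaned:
        raise ValueError(f"{sequence_id}: no standard residues after cleaning")
    composition: dict[str, int] = {}
    for res in cleaned:
        composition[res] = composition.get(res, 0) + 1
    length = len(cleaned)
    content = {
        elem: sum(table.count(res, elem) * n for res, n in composition.items()) / length
        for elem in elements
    }
    return SequenceElementProfile(
        sequence_id=sequence_id,
        length=length,
        content=content,
        composition=composition,
        dropped=dropped,
    )


def element_content_many(
    sequences: Iterable[str],
    element: str,
    table: ElementCompositionTable | None = None,
) -> np.ndarray:
    """Vectorised ``element_content`` over many sequences.

    Fast path used by the pipeline; semantics identical to calling
    :func:`element_content` per sequence.
    """
    table = table or ElementCompositionTable.default()
    wlut = table.weight_lut(element)
    vlut = ElementCompositionTable.valid_lut()
    out = []
    for seq in sequences:
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        n_valid = int(vlut[arr].sum())
        if n_valid == 0:
            raise ValueError("sequence contains no standard amino-acid letters")
        out.append(float(wlut[arr].sum()) / n_valid)
    return np.asarray(out, dtype=np.float64)


def proteome_content(
    profiles: Sequence[SequenceElementProfile] | Sequence[float],
    element: str | None = None,
) -> dict[str, float]:
    """Unweighted summary of per-sequence contents across a proteome.

    Each sequence contributes equally regardless of length (the proteome
    content is the average of per-sequence contents, not a length-weighted
    pool).  Accepts either profiles (with ``element`` naming which content
    to summarise) or a plain sequence of content values.
    """
    if len(profiles) == 0:
        raise ValueError("cannot summarise an empty collection of profiles")
    if element is not None and isinstance(profiles[0], SequenceElementProfile):
        values = np.asarray([p.content[element] for p in profiles], dtype=np.float64)
    else:
        values = np.asarray(profiles, dtype=np.float64)
    return {
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),
        "n": int(values.size),
    }


def write_content_table(
    path: str | Path,
    profiles: Sequence[SequenceElementProfile],
    elements: Sequence[str] = ("O", "C"),
) -> None:
    """Write per-sequence contents as TSV: sequence_id, length, one column
    per element."""
    with open(path, "w", encoding="utf-8") as fh:
        header = "\t".join(["sequence_id", "length", *elements])
        fh.write(header + "\n")
        for p in profiles:
            row = [p.sequence_id, str(p.length)]
            row += [f"{p.content[e]:.6f}" for e in elements]
            fh.write("\t".join(row) + "\n")
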