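"""Elemental-composition arithmetic, monoisotopic masses, and peptide assembly.

Every species in the model — peptides, fragments, neutral losses, detected
ions — is described by an ordered six-component integer vector: the numbers
of C, H, N, O and S atoms plus the net charge in elementary units. Masses
are monoisotopic; for singly charged cations the monoisotopic mass is
reported directly as the m/z (the electron mass, 0.00055 Da, is neglected —
far below the 0.25 Th instrumental matching tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Composition",
    "Residue",
    "PositionedResidue",
    "MONOISOTOPIC_MASS",
    "WATER",
    "BACKBONE_REMAINDER",
    "load_residue_table",
    "RESIDUES",
    "parse_formula",
    "monoisotopic_mass",
    "assemble_composition",
    "validate_sequence",
]

#: Monoisotopic atomic masses in Da (CODATA-style values).
MONOISOTOPIC_MASS = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

_ELEMENTS = ("C", "H", "N", "O", "S")


@dataclass(frozen=True, slots=True)
class Composition:
    """Integer elemental composition [C, H, N, O, S] plus net charge.

    Counts may go transiently negative during fragment generation (the
    engine filters such species before output); the charge field is carried
    structurally but only |charge| <= 1 species have a defined m/z here.
    """

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0
    charge: int = 0

    def __add__(self, other: "Composition") -> "Composition":
        return Composition(
            self.c + other.c,
            self.h + other.h,
            self.n + other.n,
            self.o + other.o,
            self.s + other.s,
            self.charge + other.charge,
        )

    def __sub__(self, other: "Composition") -> "Composition":
        return Composition(
            self.c - other.c,
            self.h - other.h,
            self.n - other.n,
            self.o - other.o,
            self.s - other.s,
            self.charge - other.charge,
        )

    def replace_charge(self, charge: int) -> "Composition":
        return Composition(self.c, self.h, self.n, self.o, self.s, charge)

    @property
    def atom_counts(self) -> tuple[int, int, int, int, int]:
        return (self.c, self.h, self.n, self.o, self.s)

    def is_nonnegative(self) -> bool:
        """True if every atom count is >= 0 (an emittable species)."""
        return all(v >= 0 for v in self.atom_counts)

    def is_empty(self) -> bool:
        return all(v == 0 for v in self.atom_counts)

    def mass(self) -> float:
        """Monoisotopic mass in Da; equals m/z for |charge| == 1.

        Raises ValueError for |charge| > 1: m/z division for multiply
        charged species is outside this model's detection mode.
        """
        if abs(self.charge) > 1:
            raise ValueError(
                f"|charge| > 1 unsupported for m/z computation (charge={self.charge})"
            )
        m = 0.0
        for el, count in zip(_ELEMENTS, self.atom_counts):
            m += count * MONOISOTOPIC_MASS[el]
        return m

    def formula(self) -> str:
        """Hill-ish compact formula string, e.g. ``C7H7+``."""
        parts = []
        for el, count in zip(_ELEMENTS, self.atom_counts):
            if count == 0:
                continue
            parts.append(el if count == 1 else f"{el}{count}")
        body = "".join(parts) or "(empty)"
        if self.charge > 0:
            body += "+" if self.charge == 1 else f"{self.charge}+"
        elif self.charge < 0:
            body += "-" if self.charge == -1 else f"{-self.charge}-"
        return body

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.formula()


#: Water, lost at each peptide bond formed during assembly.
WATER = Composition(h=2, o=1)

#: The glycyl-like backbone remainder left when a side chain R is removed
#: from a free amino acid: C2H4NO2 (nominal 74 as a cation).
BACKBONE_REMAINDER = Composition(c=2, h=4, n=1, o=2)


def parse_formula(fields: Iterable[int | str]) -> Composition:
    """Build a composition from six C,H,N,O,S,charge integers."""
    vals = [int(v) for v in fields]
    if len(vals) != 6:
        raise ValueError(f"expected 6 integers C,H,N,O,S,charge, got {len(vals)}")
    return Composition(*vals)


def monoisotopic_mass(x: Composition) -> float:
    """Module-level alias for :meth:`Composition.mass`."""
    return x.mass()


@dataclass(frozen=True, slots=True)
class Residue:
    """One proteinogenic amino acid: code, free-molecule and side-chain formulas."""

    code: str
    name: str
    side_chain_class: str
    free_composition: Composition

    @property
    def side_chain(self) -> Composition:
        """The R group: free molecule minus the C2H4NO2 backbone remainder.

        For glycine this is a single hydrogen.
        """
        return self.free_composition - BACKBONE_REMAINDER


@dataclass(frozen=True, slots=True)
class PositionedResidue:
    """A residue at a 1-based sequence position, e.g. ``A1`` for the first Ala."""

    residue: Residue
    position: int

    @property
    def label(self) -> str:
        return f"{self.residue.code}{self.position}"


def load_residue_table(path: str | Path | None = None) -> dict[str, Residue]:
    """Load the residue table from a tab-separated text file.

    Columns: code, name, side-chain class, C, H, N, O, S of the free
    (neutral) amino acid. ``#`` lines are comments. The packaged default
    table covers the 20 proteinogenic residues; users may supply their own
    file for nonstandard residues.
    """
    if path is None:
        src = resources.files("eifrag.data").joinpath("residues.tsv")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    table: dict[str, Residue] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 8:
            raise ValueError(
                f"residue table line {lineno}: expected 8 tab-separated fields, got {len(fields)}"
            )
        code, name, cls = fields[0], fields[1], fields[2]
        comp = Composition(*(int(v) for v in fields[3:8]), 0)
        if code in table:
            raise ValueError(f"residue table line {lineno}: duplicate code {code!r}")
        table[code] = Residue(code, name, cls, comp)
    return table


#: The packaged 20-residue table, loaded once at import.
RESIDUES: dict[str, Residue] = load_residue_table()


def validate_sequence(sequence: str, table: dict[str, Residue] | None = None) -> list[PositionedResidue]:
    """Check a one-letter sequence and return positioned residues.

    The first character is the N-terminus. Unknown codes raise ValueError
    naming the offending character and its position.
    """
    table = RESIDUES if table is None else table
    if not sequence:
        raise ValueError("empty sequence")
    out = []
    for i, ch in enumerate(sequence.upper(), start=1):
        if ch not in table:
            raise ValueError(f"unknown residue code {ch!r} at position {i}")
        out.append(PositionedResidue(table[ch], i))
    return out


def assemble_composition(residues: Iterable[PositionedResidue]) -> Composition:
    """Neutral composition of a peptide: sum of free residues minus (n-1) waters."""
    total = Composition()
    n = 0
    for pr in residues:
        total = total + pr.residue.free_composition
        n += 1
    if n == 0:
        raise ValueError("empty residue list")
    for _ in range(n - 1):
        total = total - WATER
    return total
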