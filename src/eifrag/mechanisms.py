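"""Fragmentation-mechanism catalogue and the plain-text definition-file dialect.

Two kinds of side-chain event exist. *Relative* events subtract a neutral or
radical loss from the parent species, so the observed m/z shifts with the
parent mass (an M−x change) and the product can fragment further. *Charged*
(non-relative) events detect the expelled side-chain piece itself as the
cation: its m/z is fixed regardless of sequence context and it never seeds
further fragmentation.

Three words are reserved. ``type`` marks backbone cleavage and may never
appear in a definition label; ``charged`` in the kind field marks a
non-relative event; ``side`` in a label marks a side-chain event — a
residue-scoped relative label *without* ``side`` is a C-terminal companion
event (currently the K/P/I alkene, which fires only together with a
C-terminal loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .chem import Composition, RESIDUES, parse_formula

__all__ = [
    "MechanismDef",
    "MechanismCatalogue",
    "builtin_catalogue",
    "parse_definition_file",
    "parse_definition_text",
    "serialize_catalogue",
    "nominal_delta",
    "CTERM",
    "RESERVED_BACKBONE_WORD",
]

#: Pseudo-residue code giving a record C-terminus scope.
CTERM = "CTERM"

#: Reserved for backbone cleavage; rejected in definition labels.
RESERVED_BACKBONE_WORD = "type"


@dataclass(frozen=True, slots=True)
class MechanismDef:
    """One fragmentation event.

    ``payload`` is the neutral/radical loss for ``kind == "relative"`` and
    the absolute composition of the detected cation for ``kind == "charged"``.
    """

    label: str
    residues: frozenset[str]  # empty for C-terminus scope
    kind: str  # "relative" | "charged"
    payload: Composition
    side_flag: bool = True  # side-chain event vs C-terminal companion

    def __post_init__(self) -> None:
        if self.kind not in ("relative", "charged"):
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        if RESERVED_BACKBONE_WORD in self.label.lower().split() or "type" in self.label.lower():
            raise ValueError(
                f"label {self.label!r} contains the reserved backbone word "
                f"{RESERVED_BACKBONE_WORD!r}"
            )
        if self.kind == "charged" and self.payload.charge != 1:
            raise ValueError("charged mechanism payloads must carry charge +1")
        if self.kind == "relative" and self.payload.charge != 0:
            raise ValueError("relative mechanism payloads must be neutral")

    @property
    def scope(self) -> str:
        return "C-terminus" if not self.residues else "residue-set"

    @property
    def is_cterm(self) -> bool:
        return not self.residues


@dataclass
class MechanismCatalogue:
    """Ordered collection of mechanism definitions with provenance."""

    entries: list[MechanismDef] = field(default_factory=list)
    provenance: str = "built-in"

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.label, e.residues)
            if key in seen:
                raise ValueError(f"duplicate catalogue entry {key}")
            seen.add(key)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, MechanismCatalogue) and self.entries == other.entries

    def side_events(self, code: str) -> list[MechanismDef]:
        """All side-chain events (relative and charged) defined for a residue code."""
        return [e for e in self.entries if code in e.residues and e.side_flag]

    def relative_side_events(self, code: str) -> list[MechanismDef]:
        return [e for e in self.side_events(code) if e.kind == "relative"]

    def charged_side_events(self, code: str) -> list[MechanismDef]:
        return [e for e in self.side_events(code) if e.kind == "charged"]

    def cterm_events(self) -> list[MechanismDef]:
        """C-terminal carboxyl degradations (whole, partial radical, partial)."""
        return [e for e in self.entries if e.is_cterm]

    def cterm_companions(self, code: str) -> list[MechanismDef]:
        """Residue-scoped events that fire only alongside a C-terminal loss."""
        return [
            e
            for e in self.entries
            if code in e.residues and not e.side_flag and e.kind == "relative"
        ]

    def lookup(self, label: str, code: str | None = None) -> list[MechanismDef]:
        out = []
        for e in self.entries:
            if e.label != label:
                continue
            if code is not None and code not in e.residues and not e.is_cterm:
                continue
            out.append(e)
        return out


def nominal_delta(m: MechanismDef) -> int:
    """Signed nominal M−x change of a relative event (e.g. ammonia → −17)."""
    if m.kind != "relative":
        raise ValueError("nominal_delta is defined only for relative events")
    return -round(m.payload.mass())


# ---------------------------------------------------------------------------
# Built-in catalogue
# ---------------------------------------------------------------------------

#: Residues carrying the generic lost-side-chain event. The list follows the
#: published relative-event table exactly: Ala, Gly, Pro and Tyr are absent.
GENERIC_SIDE_LOSS_RESIDUES = "CDEFHIKLMNQRSTVW"


def _rel(codes: str, label: str, c=0, h=0, n=0, o=0, s=0, side=True) -> MechanismDef:
    return MechanismDef(label, frozenset(codes), "relative", Composition(c, h, n, o, s, 0), side)


def _ion(codes: str, label: str, c=0, h=0, n=0, o=0, s=0) -> MechanismDef:
    return MechanismDef(label, frozenset(codes), "charged", Composition(c, h, n, o, s, 1), True)


def builtin_catalogue() -> MechanismCatalogue:
    """The default mechanism catalogue for the 20 proteinogenic residues."""
    entries: list[MechanismDef] = [
        # relative side-chain events
        _rel("NQ", "side ammonia loss", n=1, h=3),
        _rel("ST", "side beta-elimination", h=2, o=1),
        _rel("C", "side beta-elimination", h=2, s=1),
        _rel("DE", "side carboxyl loss (whole)", c=1, h=1, o=2),
        _rel("DE", "side carboxyl loss (partial radical)", h=1, o=1),
        _rel("DE", "side carboxyl loss (partial)", h=2, o=1),
        _rel("M", "side partial chain loss", c=2, h=5, s=1),
        _rel("K", "side chain cyclization", n=1, h=3),
        _rel("R", "side partial guanidino loss", c=1, h=2, n=2),
        _rel("R", "side guanidino loss + alkene", c=1, h=6, n=3),
        # alkene formation: C-terminal companion (no "side" in label)
        _rel("KPI", "alkene formation", h=1, side=False),
    ]
    # generic lost side chain: payload is each residue's own R group
    for code in GENERIC_SIDE_LOSS_RESIDUES:
        r = RESIDUES[code].side_chain
        entries.append(
            MechanismDef("side chain loss", frozenset(code), "relative", r)
        )
    entries += [
        # charged (non-relative) side-chain ions
        _ion("F", "charged side chain loss", c=7, h=7),
        _ion("F", "charged side chain loss (alkene)", c=8, h=7),
        _ion("Y", "charged side chain loss", c=7, h=7, o=1),
        _ion("Y", "charged side chain loss (alkene)", c=8, h=7, o=1),
        _ion("W", "charged side chain loss", c=9, h=8, n=1),
        _ion("H", "charged side chain loss", c=4, h=5, n=2),
        _ion("H", "charged side chain loss (alkene)", c=5, h=5, n=2),
        _ion("H", "charged side chain loss (radical)", c=4, h=6, n=2),
        _ion("M", "charged side chain loss", c=3, h=7, s=1),
        _ion("M", "charged side chain methylene sub frag loss", c=2, h=5, s=1),
        _ion("L", "charged side chain loss", c=4, h=9),
        # C-terminal carboxyl degradations
        MechanismDef("carboxyl loss (whole)", frozenset(), "relative", Composition(1, 1, 0, 2, 0, 0), False),
        MechanismDef("carboxyl loss (partial radical)", frozenset(), "relative", Composition(0, 1, 0, 1, 0, 0), False),
        MechanismDef("carboxyl loss (partial)", frozenset(), "relative", Composition(0, 2, 0, 1, 0, 0), False),
    ]
    return MechanismCatalogue(entries, provenance="built-in")


# ---------------------------------------------------------------------------
# Definition-file dialect
# ---------------------------------------------------------------------------
# One record per line, fields separated by " | ":
#   residues | label | kind | C,H,N,O,S,z
# residues: concatenated one-letter codes, or CTERM for C-terminus scope.
# "#" starts a comment. Shipped default file reproduces builtin_catalogue().


def parse_definition_text(text: str, provenance: str = "<text>") -> MechanismCatalogue:
    entries: list[MechanismDef] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split("|")]
        if len(fields) != 4:
            raise ValueError(
                f"line {lineno}: expected 4 '|'-separated fields "
                f"(residues | label | kind | C,H,N,O,S,z), got {len(fields)}"
            )
        codes_field, label, kind, formula_field = fields
        if "type" in label.lower():
            raise ValueError(
                f"line {lineno}: label {label!r} contains the reserved word 'type' "
                "(reserved for backbone cleavage)"
            )
        if kind not in ("relative", "charged"):
            raise ValueError(f"line {lineno}: kind must be 'relative' or 'charged', got {kind!r}")
        try:
            payload = parse_formula(formula_field.split(","))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad formula field: {exc}") from None
        if codes_field == CTERM:
            residues: frozenset[str] = frozenset()
            side = False
        else:
            for ch in codes_field:
                if ch not in RESIDUES:
                    raise ValueError(f"line {lineno}: unknown residue code {ch!r}")
            residues = frozenset(codes_field)
            side = "side" in label.lower()
        try:
            entries.append(MechanismDef(label, residues, kind, payload, side))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    return MechanismCatalogue(entries, provenance=provenance)


def parse_definition_file(path: str | Path) -> MechanismCatalogue:
    """Parse a mechanism definition file; see the module docstring for the dialect."""
    p = Path(path)
    return parse_definition_text(p.read_text(encoding="utf-8"), provenance=str(p))


def serialize_catalogue(cat: MechanismCatalogue) -> str:
    """Write a catalogue back out in the definition-file dialect."""
    lines = ["# residues | label | kind | C,H,N,O,S,z"]
    for e in cat.entries:
        codes = CTERM if e.is_cterm else "".join(sorted(e.residues))
        p = e.payload
        formula = f"{p.c},{p.h},{p.n},{p.o},{p.s},{p.charge}"
        lines.append(f"{codes} | {e.label} | {e.kind} | {formula}")
    return "\n".join(lines) + "\n"


def default_definition_path() -> Path:
    """Path of the packaged definition file mirroring the built-in catalogue."""
    return Path(str(resources.files("eifrag.data").joinpath("mechanisms.txt")))
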