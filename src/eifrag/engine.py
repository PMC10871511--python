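"""Combinatorial fragment enumeration.

The engine generates the exhaustive m/z "fingerprint" of a peptide under
electron ionization:

1.  The intact molecular ion M+ (a radical cation; its m/z equals the
    neutral monoisotopic mass at unit positive charge).
2.  Backbone cleavage of the original peptide. Type A cuts the
    Cα–carbonyl bond and Type B the amide bond; both complementary pieces
    are emitted as candidate cations, since the instrument cannot tell
    which side retains the charge and the fingerprint is meant to be
    exhaustive. Type C cuts the N–Cα bond at aromatic positions (F/W/Y)
    and releases the C-terminal piece carrying the aromatic side chain;
    the retained N-side piece is emitted here, while the released
    aromatic piece is covered by the charged side-chain ion catalogue.
    Cleavage is homolytic with no hydrogen rearrangement: each piece keeps
    exactly the atoms on its side of the severed bond. Backbone cleavage
    applies once, to the original peptide only.
3.  C-terminal carboxyl degradations (−CO2H, −OH, −H2O) of the original
    peptide; for sequences containing K, P or I, each degradation is also
    emitted combined with alkene formation (−H), which never fires alone.
4.  Side-chain fragmentation, applied combinatorially to every pooled
    fragment and recursively to all children, with at most one side-chain
    event per residue position. A fragment's eligible positions are the
    residues fully contained in its span (a piece truncated through a
    residue's backbone no longer carries that residue). Charged
    (non-relative) events emit the expelled side-chain cation itself,
    once per residue position; such fragments are terminal.
5.  Duplicate removal and negative-atom-count filtering.

The dedup key is the composition six-vector together with the sorted
multiset of applied mechanism labels, so the same chemistry reached in a
different event order collapses while genuinely different mechanism paths
to the same formula are both kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .chem import (
    Composition,
    PositionedResidue,
    assemble_composition,
    validate_sequence,
)
from .mechanisms import MechanismCatalogue, builtin_catalogue

__all__ = [
    "PeptideFragment",
    "PredictionSet",
    "assemble_peptide",
    "cleave_type_a",
    "cleave_type_b",
    "cleave_type_c",
    "apply_cterm_events",
    "apply_side_events",
    "enumerate_fragments",
    "dedupe_and_filter",
]

_CO2H = Composition(c=1, h=1, o=2)
_OH = Composition(h=1, o=1)
_NH = Composition(h=1, n=1)
_WATER = Composition(h=2, o=1)


@dataclass(frozen=True, slots=True)
class PeptideFragment:
    """One predicted fragment with its mechanism-path bookkeeping.

    ``path`` is the ordered record of applied mechanisms, each tagged with
    the position it acted on (e.g. ``typeA@F2``, ``side ammonia loss@Q1``,
    ``carboxyl loss (whole)@cterm``). ``open_positions`` are residue
    positions fully contained in this fragment whose one-event ledger slot
    is still unused; ``residues`` is the full retained span.
    """

    composition: Composition
    path: tuple[str, ...]
    residues: tuple[PositionedResidue, ...] = ()
    open_positions: tuple[PositionedResidue, ...] = ()
    has_original_cterm: bool = False
    terminal: bool = False  # charged-ion product; never fragments further

    @property
    def mz(self) -> float:
        return self.composition.mass()

    @property
    def path_text(self) -> str:
        return " > ".join(self.path) if self.path else "M+"

    def dedup_key(self) -> tuple:
        return (
            self.composition.atom_counts,
            self.composition.charge,
            tuple(sorted(self.path)),
        )


@dataclass
class PredictionSet:
    """All unique predicted fragments for one sequence, sorted by m/z."""

    sequence: str
    fragments: list[PeptideFragment]
    catalogue_provenance: str = "built-in"

    @property
    def mz_values(self) -> list[float]:
        return [f.mz for f in self.fragments]

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[PeptideFragment]:
        return iter(self.fragments)

    def to_rows(self) -> list[tuple[float, str, str]]:
        """(m/z, formula, path) rows for tabular output, m/z ascending."""
        return [(round(f.mz, 4), f.composition.formula(), f.path_text) for f in self.fragments]


def assemble_peptide(sequence: str) -> PeptideFragment:
    """Build the intact molecular-ion fragment for a one-letter sequence.

    The first character is the N-terminus; the composition is the free
    residue sum minus (n−1) waters, flagged charge +1 for the M+
    convention. Unknown residue codes raise ValueError naming the
    offending character.
    """
    prs = tuple(validate_sequence(sequence))
    comp = assemble_composition(prs).replace_charge(1)
    return PeptideFragment(
        composition=comp,
        path=(),
        residues=prs,
        open_positions=prs,
        has_original_cterm=True,
    )


def _chain(prs: tuple[PositionedResidue, ...], i: int) -> Composition:
    """Neutral composition of the 1..i sub-peptide (1-based, i >= 1)."""
    c = Composition()
    for pr in prs[:i]:
        c = c + pr.residue.free_composition
    for _ in range(i - 1):
        c = c - _WATER
    return c


def _piece(
    comp: Composition,
    tag: str,
    span: tuple[PositionedResidue, ...],
    has_cterm: bool,
) -> PeptideFragment:
    return PeptideFragment(
        composition=comp.replace_charge(1),
        path=(tag,),
        residues=span,
        open_positions=span,
        has_original_cterm=has_cterm,
    )


def cleave_type_a(f: PeptideFragment) -> list[PeptideFragment]:
    """Type A: cut between Cα(i) and the carbonyl carbon of residue i.

    Both complementary pieces are emitted per position. The N-side piece
    keeps CαH and the side chain of residue i (for a free amino acid this
    is the M−45 carboxyl-radical loss); the C-side piece runs from residue
    i's carbonyl through the C-terminal carboxyl.
    """
    prs = f.residues
    total = f.composition.replace_charge(0)
    out = []
    for i in range(1, len(prs) + 1):
        tag = f"typeA@{prs[i - 1].label}"
        nside = _chain(prs, i) - _CO2H
        out.append(_piece(nside, tag, prs[: i - 1], has_cterm=False))
        out.append(_piece(total - nside, tag, prs[i:], has_cterm=True))
    return out


def cleave_type_b(f: PeptideFragment) -> list[PeptideFragment]:
    """Type B: cut the peptide (amide) bond between residues i and i+1.

    Emits the acylium-type N-terminal piece (keeps the carbonyl) and the
    amine-type C-terminal piece; empty for single-residue fragments.
    """
    prs = f.residues
    total = f.composition.replace_charge(0)
    out = []
    for i in range(1, len(prs)):
        tag = f"typeB@{prs[i - 1].label}-{prs[i].label}"
        nside = _chain(prs, i) - _OH
        out.append(_piece(nside, tag, prs[:i], has_cterm=False))
        out.append(_piece(total - nside, tag, prs[i:], has_cterm=True))
    return out


def cleave_type_c(f: PeptideFragment) -> list[PeptideFragment]:
    """Type C: cut between N(i) and Cα(i); aromatic residues (F/W/Y) only.

    The C-terminal piece carrying the aromatic side chain is released (its
    detectable forms are the charged side-chain ions of the catalogue);
    the retained N-side piece, ending in the upstream carbonyl plus the
    severed NH, is emitted here.
    """
    prs = f.residues
    out = []
    for i in range(1, len(prs) + 1):
        if prs[i - 1].residue.code not in ("F", "W", "Y"):
            continue
        tag = f"typeC@{prs[i - 1].label}"
        if i == 1:
            nside = Composition(h=2, n=1)  # the free N-terminal amine
        else:
            nside = _chain(prs, i - 1) - _OH + _NH
        out.append(_piece(nside, tag, prs[: i - 1], has_cterm=False))
    return out


def apply_cterm_events(
    f: PeptideFragment, cat: MechanismCatalogue | None = None
) -> list[PeptideFragment]:
    """C-terminal carboxyl degradations of one eligible fragment.

    Emits one child per carboxyl event (−CO2H, −OH, −H2O) plus, for each
    open K/P/I position, the event combined with alkene formation (−H,
    consuming that position's ledger slot); alkene formation never fires
    on its own. Children no longer carry an intact original C-terminus.
    Fragments without the original C-terminal carboxyl yield nothing.
    """
    cat = cat or builtin_catalogue()
    if not f.has_original_cterm:
        return []
    out = []
    for ev in cat.cterm_events():
        child_comp = f.composition - ev.payload
        out.append(
            PeptideFragment(
                composition=child_comp,
                path=f.path + (f"{ev.label}@cterm",),
                residues=f.residues,
                open_positions=f.open_positions,
                has_original_cterm=False,
            )
        )
        for j, pos in enumerate(f.open_positions):
            for comp_ev in cat.cterm_companions(pos.residue.code):
                out.append(
                    PeptideFragment(
                        composition=child_comp - comp_ev.payload,
                        path=f.path + (f"{ev.label}@cterm", f"{comp_ev.label}@{pos.label}"),
                        residues=f.residues,
                        open_positions=f.open_positions[:j] + f.open_positions[j + 1 :],
                        has_original_cterm=False,
                    )
                )
    return out


def apply_side_events(
    f: PeptideFragment, cat: MechanismCatalogue | None = None
) -> list[PeptideFragment]:
    """One generation of side-chain children of a fragment.

    For every open residue position: each matching relative event yields a
    child with the payload subtracted and that position's ledger slot
    consumed; each matching charged event yields a terminal fragment whose
    composition *is* the detected ion (its m/z does not depend on the
    parent, so its path records only the event and position).
    """
    cat = cat or builtin_catalogue()
    if f.terminal:
        return []
    out = []
    for j, pos in enumerate(f.open_positions):
        code = pos.residue.code
        remaining = f.open_positions[:j] + f.open_positions[j + 1 :]
        for ev in cat.relative_side_events(code):
            out.append(
                PeptideFragment(
                    composition=f.composition - ev.payload,
                    path=f.path + (f"{ev.label}@{pos.label}",),
                    residues=f.residues,
                    open_positions=remaining,
                    has_original_cterm=f.has_original_cterm,
                )
            )
        for ev in cat.charged_side_events(code):
            out.append(
                PeptideFragment(
                    composition=ev.payload,
                    path=(f"{ev.label}@{pos.label}",),
                    terminal=True,
                )
            )
    return out


def dedupe_and_filter(frags: Iterable[PeptideFragment]) -> list[PeptideFragment]:
    """Drop unphysical fragments, collapse duplicates, sort stably.

    Fragments with any negative atom count (overlapping predicted losses)
    or an empty composition are removed. Duplicates are fragments with
    identical composition *and* identical mechanism-label multiset — the
    same chemistry applied in a different order; distinct mechanism paths
    to the same formula are kept. Output is ordered by (m/z, path text),
    making the operation idempotent and deterministic.
    """
    seen: set[tuple] = set()
    kept = []
    for f in frags:
        if not f.composition.is_nonnegative() or f.composition.is_empty():
            continue
        key = f.dedup_key()
        if key in seen:
            continue
        seen.add(key)
        kept.append(f)
    kept.sort(key=lambda f: (f.mz, f.path_text))
    return kept


def enumerate_fragments(
    sequence: str, cat: MechanismCatalogue | None = None
) -> PredictionSet:
    """Full combinatorial enumeration for one sequence.

    The pool is the molecular ion, all Type A, B and C cleavage products
    of the original peptide (in that order), and the C-terminal
    degradations of the original peptide; side-chain fragmentation then
    recurses over the entire pool until no fragment has an open ledger
    slot with an applicable event. Duplicates and negative-count species
    are filtered before output.
    """
    cat = cat or builtin_catalogue()
    parent = assemble_peptide(sequence)

    pool: list[PeptideFragment] = [parent]
    pool.extend(cleave_type_a(parent))
    pool.extend(cleave_type_b(parent))
    pool.extend(cleave_type_c(parent))
    pool.extend(apply_cterm_events(parent, cat))

    results: list[PeptideFragment] = []
    queue = list(pool)
    while queue:
        f = queue.pop(0)
        results.append(f)
        queue.extend(apply_side_events(f, cat))

    frags = dedupe_and_filter(results)
    return PredictionSet(sequence, frags, catalogue_provenance=cat.provenance)
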