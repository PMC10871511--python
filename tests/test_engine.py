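"""Backbone cleavage, combinatorial side-chain application, and enumeration."""

import itertools

import pytest

from eifrag.chem import Composition, RESIDUES
from eifrag.engine import (
    apply_cterm_events,
    apply_side_events,
    assemble_peptide,
    cleave_type_a,
    cleave_type_b,
    cleave_type_c,
    dedupe_and_filter,
    enumerate_fragments,
)
from eifrag.mechanisms import MechanismCatalogue, MechanismDef, builtin_catalogue

CO2H = Composition(c=1, h=1, o=2)


def keyset(fragments):
    return {f.dedup_key() for f in fragments}


class TestTypeA:
    def test_single_residue_n_side_is_m_minus_45(self):
        ala = assemble_peptide("A")
        nside, cside = cleave_type_a(ala)
        assert abs(nside.mz - (ala.mz - 44.9977)) < 1e-3
        assert cside.composition == CO2H.replace_charge(1)

    def test_glycine_aminomethylene_cation(self):
        nside, _ = cleave_type_a(assemble_peptide("G"))
        assert nside.composition == Composition(c=1, h=4, n=1, charge=1)
        assert round(nside.mz) == 30

    def test_pieces_are_complementary(self):
        f = assemble_peptide("QFA")
        pieces = cleave_type_a(f)
        assert len(pieces) == 6
        for nside, cside in zip(pieces[::2], pieces[1::2]):
            total = nside.composition + cside.composition
            assert total.atom_counts == f.composition.atom_counts

    def test_n_side_loses_cterm_c_side_keeps_it(self):
        pieces = cleave_type_a(assemble_peptide("QFA"))
        assert [p.has_original_cterm for p in pieces] == [False, True] * 3


class TestTypeB:
    def test_alanyl_acylium_ion(self):
        pieces = cleave_type_b(assemble_peptide("AA"))
        assert pieces[0].composition == Composition(3, 6, 1, 1, 0, 1)
        assert abs(pieces[0].mz - 72.0444) < 1e-3

    def test_single_residue_yields_nothing(self):
        assert cleave_type_b(assemble_peptide("A")) == []

    @pytest.mark.parametrize("seq", ["AA", "QFA", "SEQA"])
    def test_bond_count_and_conservation(self, seq):
        f = assemble_peptide(seq)
        pieces = cleave_type_b(f)
        assert len(pieces) == 2 * (len(seq) - 1)
        for nside, cside in zip(pieces[::2], pieces[1::2]):
            assert (nside.composition + cside.composition).atom_counts == f.composition.atom_counts


class TestTypeC:
    def test_cleaves_only_aromatic_positions(self):
        assert cleave_type_c(assemble_peptide("QKA")) == []
        (piece,) = cleave_type_c(assemble_peptide("QFA"))
        assert piece.path == ("typeC@F2",)
        # N-side piece: Q1's acyl group plus the severed NH
        assert piece.composition == Composition(5, 10, 3, 2, 0, 1)

    def test_released_aromatic_piece_is_covered_by_charged_ions(self, catalogue):
        """The C-side piece released by Type C is not emitted as a backbone
        fragment; its detectable forms are the charged side-chain ions."""
        ps = enumerate_fragments("QFA", catalogue)
        charged = {f.composition for f in ps if f.terminal}
        assert Composition(c=7, h=7, charge=1) in charged
        assert Composition(c=8, h=7, charge=1) in charged

    def test_n_terminal_aromatic_gives_free_amine(self):
        (piece,) = cleave_type_c(assemble_peptide("F"))
        assert piece.composition == Composition(h=2, n=1, charge=1)


class TestCTermEvents:
    def test_water_loss_from_free_alanine(self, catalogue):
        ala = assemble_peptide("A")
        children = apply_cterm_events(ala, catalogue)
        deltas = {round(ala.mz - c.mz) for c in children}
        assert deltas == {45, 17, 18}

    def test_ile_combined_carboxyl_plus_alkene_is_m_minus_46(self, catalogue):
        ile = assemble_peptide("I")
        children = apply_cterm_events(ile, catalogue)
        combined = [c for c in children if len(c.path) == 2]
        assert {round(ile.mz - c.mz) for c in combined} == {46, 18, 19}
        m46 = [c for c in combined if round(ile.mz - c.mz) == 46]
        assert m46 and m46[0].path == ("carboxyl loss (whole)@cterm", "alkene formation@I1")

    def test_alkene_never_fires_alone(self, catalogue):
        for f in enumerate_fragments("I", catalogue):
            labels = [p.split("@")[0] for p in f.path]
            if "alkene formation" in labels:
                assert any(l.startswith("carboxyl loss") for l in labels)

    def test_ineligible_fragment_yields_nothing(self, catalogue):
        nside = cleave_type_a(assemble_peptide("QFA"))[0]
        assert not nside.has_original_cterm
        assert apply_cterm_events(nside, catalogue) == []


class TestSideEvents:
    def test_gln_ammonia_plus_carboxyl_double_degradation(self, catalogue):
        """The combined ammonia + whole-carboxyl loss from free Gln."""
        ps = enumerate_fragments("Q", catalogue)
        target = Composition(4, 6, 1, 1, 0, 1)  # Gln − NH3 − CO2H
        hits = [f for f in ps if f.composition == target]
        assert hits
        labels = {p.split("@")[0] for p in hits[0].path}
        assert labels == {"side ammonia loss", "carboxyl loss (whole)"}

    @pytest.mark.parametrize("seq", ["AFA", "WFA", "QFA"])
    def test_phe_ion_mz_independent_of_context(self, catalogue, seq):
        ps = enumerate_fragments(seq, catalogue)
        ions = [f for f in ps if f.terminal and f.composition == Composition(c=7, h=7, charge=1)]
        assert len(ions) == 1
        assert round(ions[0].mz, 1) == 91.1

    def test_at_most_one_side_event_per_position(self, catalogue):
        for f in enumerate_fragments("EEA", catalogue):
            positions = [p.split("@")[1] for p in f.path if p.split("@")[0].startswith("side")]
            assert len(positions) == len(set(positions))

    def test_consumed_slot_blocks_second_event(self, catalogue):
        gln = assemble_peptide("Q")
        child = next(
            f for f in apply_side_events(gln, catalogue)
            if f.path[-1].startswith("side ammonia loss")
        )
        assert child.open_positions == ()
        assert apply_side_events(child, catalogue) == []


class TestDedupeAndFilter:
    def test_negative_and_empty_compositions_removed(self):
        good = assemble_peptide("A")
        bad = assemble_peptide("A")
        bad = type(bad)(composition=Composition(c=1, o=-1, charge=1), path=("x@A1",))
        empty = type(bad)(composition=Composition(charge=1), path=("y@A1",))
        assert dedupe_and_filter([good, bad, empty]) == [good]

    def test_identical_multiset_collapses_order(self):
        a = assemble_peptide("A")
        f1 = type(a)(composition=a.composition, path=("p@A1", "q@A1"))
        f2 = type(a)(composition=a.composition, path=("q@A1", "p@A1"))
        assert len(dedupe_and_filter([f1, f2])) == 1

    def test_distinct_paths_to_same_formula_kept(self, qfa_predictions):
        # M−45 arises both from Type A at the last residue and from the
        # whole-carboxyl C-terminal loss; both mechanism paths survive
        target = [f for f in qfa_predictions if round(f.mz, 2) == 319.18]
        assert len(target) == 2

    def test_idempotent(self, qfa_predictions):
        once = list(qfa_predictions.fragments)
        assert dedupe_and_filter(once) == once


class TestEnumeration:
    def test_qfa_produces_55_unique_fragments(self, qfa_predictions):
        assert len(qfa_predictions) == 55
        assert any(f.path == () for f in qfa_predictions)  # intact M+

    def test_glycine_closed_set(self, catalogue):
        """Gly has no side events: molecular ion, two Type A pieces, three
        C-terminal degradations and nothing else."""
        ps = enumerate_fragments("G", catalogue)
        assert len(ps) == 6
        tags = sorted(f.path_text for f in ps)
        assert tags == [
            "M+",
            "carboxyl loss (partial radical)@cterm",
            "carboxyl loss (partial)@cterm",
            "carboxyl loss (whole)@cterm",
            "typeA@G1",
            "typeA@G1",
        ]

    def test_cterminal_pieces_of_ala_recur_in_ala_ala(self, catalogue):
        a = enumerate_fragments("A", catalogue)
        aa = enumerate_fragments("AA", catalogue)
        aa_mzs = {round(mz, 4) for mz in aa.mz_values}
        cterm_pieces = [f for f in a if f.path and f.path[0].startswith("typeA") and f.has_original_cterm]
        assert cterm_pieces
        for f in cterm_pieces:
            assert round(f.mz, 4) in aa_mzs

    def test_determinism(self, catalogue, qfa_predictions):
        again = enumerate_fragments("QFA", catalogue)
        assert [f.dedup_key() for f in again] == [f.dedup_key() for f in qfa_predictions]

    def test_unknown_residue_propagates(self, catalogue):
        with pytest.raises(ValueError, match="'X'"):
            enumerate_fragments("QXA", catalogue)

    def test_adding_a_mechanism_never_removes_fragments(self, catalogue, qfa_predictions):
        extra = MechanismCatalogue(
            list(catalogue.entries)
            + [MechanismDef("side test loss", frozenset("A"), "relative", Composition(h=2))],
            provenance="test",
        )
        grown = enumerate_fragments("QFA", extra)
        assert keyset(qfa_predictions) <= keyset(grown)
        assert len(grown) > len(qfa_predictions)


def _payload_of(catalogue, label_at: str, parent_sequence: str):
    label, pos = label_at.rsplit("@", 1)
    if pos == "cterm":
        (ev,) = catalogue.lookup(label)
        return ev.payload
    code = pos.rstrip("0123456789")
    candidates = [
        e for e in catalogue.entries if e.label == label and code in e.residues
    ]
    assert len(candidates) == 1, label_at
    return candidates[0].payload


@pytest.mark.parametrize("seq", ["Q", "KMA", "QFA", "SEQA"])
def test_mass_conservation_along_every_path(catalogue, seq):
    """Each fragment's composition equals its backbone starting piece minus
    the summed payloads of the relative events recorded on its path."""
    parent = assemble_peptide(seq)
    piece_comps = {}
    for p in cleave_type_a(parent) + cleave_type_b(parent) + cleave_type_c(parent):
        piece_comps.setdefault(p.path[0], set()).add(p.composition)
    for f in enumerate_fragments(seq, catalogue):
        if f.terminal:
            (ev,) = [
                e for e in catalogue.entries
                if e.label == f.path[0].rsplit("@", 1)[0] and e.kind == "charged"
                and f.path[0].rsplit("@", 1)[1].rstrip("0123456789") in e.residues
            ] or [None]
            assert ev is not None and f.composition == ev.payload
            continue
        labels = list(f.path)
        start_options = {parent.composition}
        if labels and labels[0].startswith("type"):
            start_options = piece_comps[labels.pop(0)]
        reconstructed = f.composition
        for lab in labels:
            reconstructed = reconstructed + _payload_of(catalogue, lab, seq)
        assert reconstructed in start_options, f.path_text


def _brute_force_single_residue(code: str, catalogue) -> set:
    """Independent oracle: exhaustive subset application of the event rules
    to one free amino acid, written without the engine's recursion.

    Bases are the molecular ion, the two Type A pieces, the (aromatic-only)
    Type C amine piece and the C-terminal degradations (with the K/P/I
    alkene combination). Side events then apply as a plain choice of at
    most one relative event, or one charged ion, at the single position.
    """
    free = RESIDUES[code].free_composition.replace_charge(1)
    co2h, oh, h2o = (
        Composition(1, 1, 0, 2, 0, 0),
        Composition(0, 1, 0, 1, 0, 0),
        Composition(0, 2, 0, 1, 0, 0),
    )
    pos = f"{code}1"
    # (composition, labels, position slot still open)
    bases = [(free, (), True)]
    bases.append((free - co2h, ("typeA@" + pos,), False))
    bases.append((co2h.replace_charge(1), ("typeA@" + pos,), False))
    if code in "FWY":
        bases.append((Composition(h=2, n=1, charge=1), ("typeC@" + pos,), False))
    cterm = {
        "carboxyl loss (whole)@cterm": co2h,
        "carboxyl loss (partial radical)@cterm": oh,
        "carboxyl loss (partial)@cterm": h2o,
    }
    for lab, payload in cterm.items():
        bases.append((free - payload, (lab,), True))
        if code in "KPI":
            bases.append(
                (free - payload - Composition(h=1), (lab, f"alkene formation@{pos}"), False)
            )
    keys = set()

    def record(comp, labels):
        if comp.is_nonnegative() and not comp.is_empty():
            keys.add((comp.atom_counts, comp.charge, tuple(sorted(labels))))

    for comp, labels, open_slot in bases:
        record(comp, labels)
        if not open_slot:
            continue
        for ev in catalogue.relative_side_events(code):
            record(comp - ev.payload, labels + (f"{ev.label}@{pos}",))
        for ev in catalogue.charged_side_events(code):
            record(ev.payload, (f"{ev.label}@{pos}",))
    return keys


@pytest.mark.parametrize("code", sorted(RESIDUES))
def test_engine_matches_brute_force_oracle_for_single_residues(catalogue, code):
    engine_keys = keyset(enumerate_fragments(code, catalogue))
    assert engine_keys == _brute_force_single_residue(code, catalogue)
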