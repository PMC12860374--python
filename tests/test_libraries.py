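"""Candidate libraries: loaders, precursor index, "A + nB" generator."""

import itertools
import math

import pytest

from npannotate import libraries
from npannotate.chem import adduct_mz, parse_formula, round_mass
from npannotate.libraries import (
    CombinatorialConfig,
    CompoundRecord,
    GroupFragment,
    count_combinations,
    expand_precursors,
    generate_combinations,
    load_compound_library,
    load_signature_library,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestCompoundLoader:
    def test_basic_row(self, tmp_path):
        p = _write(tmp_path, "c.csv", "name,formula,class\nhyperoside,C21H20O12,flavonol\n")
        recs = load_compound_library(p)
        assert len(recs) == 1
        assert round_mass(adduct_mz(recs[0].formula, "[M-H]-")) == 463.0877

    def test_empty_file(self, tmp_path):
        p = _write(tmp_path, "c.csv", "name,formula,class\n")
        assert load_compound_library(p) == []

    def test_invalid_element_rejected(self, tmp_path):
        p = _write(tmp_path, "c.csv", "name,formula,class\nx,C21H20O12X,flavonol\n")
        with pytest.raises(Exception):
            load_compound_library(p)

    def test_unknown_class_rejected(self, tmp_path):
        p = _write(tmp_path, "c.csv", "name,formula,class\nx,C6H12O6,sterol\n")
        with pytest.raises(ValueError):
            load_compound_library(p)

    def test_duplicates_dropped_with_warning(self, tmp_path, caplog):
        p = _write(
            tmp_path, "c.csv",
            "name,formula,class\nx,C6H12O6,flavonol\nx,C6H12O6,flavonol\n",
        )
        recs = load_compound_library(p)
        assert len(recs) == 1


class TestPrecursorIndex:
    def test_one_compound_five_adducts(self):
        rec = CompoundRecord("x", parse_formula("C6H12O6"), "other")
        assert len(expand_precursors([rec])) == 5

    def test_kaempferol_positive(self):
        rec = CompoundRecord("kaempferol", parse_formula("C15H10O6"), "flavonol")
        idx = expand_precursors([rec], adducts=["[M+H]+"])
        (mz, _, adduct), = list(idx)
        assert round_mass(mz) == 287.0556 and adduct == "[M+H]+"

    def test_window_query_matches_linear_scan(self, compound_library):
        idx = expand_precursors(compound_library)
        entries = list(idx)
        for center, tol in [(463.0877, 0.02), (285.0, 0.5), (100.0, 0.01), (739.21, 0.02)]:
            got = idx.query(center, tol)
            want = [e for e in entries if abs(e[0] - center) <= tol]
            assert got == want  # both follow index order

    def test_hyperoside_window_hits(self, compound_library):
        idx = expand_precursors(compound_library, polarity="negative")
        names = {r.name for _, r, a in idx.query(463.0877, 0.02) if a == "[M-H]-"}
        assert "Hyperoside" in names


def _dummy_parents(p):
    return [
        CompoundRecord(f"P{i}", parse_formula(f"C{10+i}H{8+2*i}O4"), "other")
        for i in range(p)
    ]


def _dummy_groups(g):
    return [GroupFragment(f"G{i}", parse_formula(f"C{i+1}H{2*(i+1)}O"), frozenset()) for i in range(g)]


class TestCombinatorialGenerator:
    def test_single_parent_single_group(self):
        cands = generate_combinations(_dummy_parents(1), _dummy_groups(1),
                                      CombinatorialConfig(n_max=5))
        assert len(cands) == 6  # 0..5 copies

    def test_two_parents_three_groups(self):
        cands = generate_combinations(_dummy_parents(2), _dummy_groups(3),
                                      CombinatorialConfig(n_max=5))
        assert len(cands) == 112

    @pytest.mark.parametrize("p", range(1, 6))
    @pytest.mark.parametrize("g", range(0, 7))
    def test_generator_equals_closed_form_and_enumeration(self, p, g):
        for n_max in range(6):
            cands = generate_combinations(
                _dummy_parents(p), _dummy_groups(g), CombinatorialConfig(n_max=n_max)
            )
            closed = count_combinations(p, g, n_max)
            # independent oracle: count distinct sorted label tuples
            brute = p * sum(
                len({tuple(sorted(t)) for t in itertools.product(range(g), repeat=i)})
                if i else 1
                for i in range(n_max + 1)
            )
            assert len(cands) == closed == brute

    def test_closed_form_reference_values(self):
        assert count_combinations(1, 0, 5) == 1
        assert count_combinations(4, 9, 5) == 8008
        assert count_combinations(8, 3, 5) == 448

    def test_no_duplicate_candidates(self, compound_library, group_library):
        cands = generate_combinations(
            compound_library[:4], group_library, CombinatorialConfig(n_max=2)
        )
        keys = [(c.parent, c.groups) for c in cands]
        assert len(keys) == len(set(keys))

    def test_candidate_mz_rederivable_from_formula(self, compound_library, group_library):
        cands = generate_combinations(
            compound_library[:4], group_library, CombinatorialConfig(n_max=2)
        )
        for c in cands:
            for adduct, mz in c.mz.items():
                assert mz == pytest.approx(adduct_mz(c.formula, adduct), abs=1e-9)

    def test_quercetin_caffeoyl_glucoside_formula(self, group_library):
        quercetin = CompoundRecord("quercetin", parse_formula("C15H10O7"), "flavonol")
        cands = generate_combinations([quercetin], group_library, CombinatorialConfig(n_max=2))
        by_groups = {c.groups: c for c in cands}
        c = by_groups[("Caffeoyl", "Hexosyl")]
        assert str(c.formula) == "C30H26O15"

    def test_class_compatibility_respected(self, group_library):
        alkaloid = CompoundRecord("a", parse_formula("C15H14N2O3"), "alkaloid")
        cands = generate_combinations([alkaloid], group_library, CombinatorialConfig(n_max=1))
        used = {g for c in cands for g in c.groups}
        assert used <= {"Methyl", "Formyl"}

    def test_no_repetition_flag(self):
        cands = generate_combinations(
            _dummy_parents(1), _dummy_groups(3),
            CombinatorialConfig(n_max=5, repetition=False),
        )
        assert len(cands) == count_combinations(1, 3, 5, repetition=False) == 8

    def test_mass_range_filter(self):
        cands = generate_combinations(
            _dummy_parents(1), _dummy_groups(1),
            CombinatorialConfig(n_max=5, mass_range=(50.0, 250.0)),
        )
        assert all(50 <= c.formula.mass <= 250 for c in cands)
        assert len(cands) < 6


class TestSignatureLoader:
    def test_quinic_acid_diagnostic_mass(self, tmp_path):
        p = _write(
            tmp_path, "s.csv",
            "name,kind,polarity,formula,exact_mass,class\n"
            "quinic acid,diagnostic,negative,C7H12O6,,phenolic acid\n",
        )
        lib = load_signature_library(p)
        assert round_mass(lib.entries[0].mass) == 191.0556

    def test_hexosyl_neutral_loss_mass(self, tmp_path):
        p = _write(
            tmp_path, "s.csv",
            "name,kind,polarity,formula,exact_mass,class\n"
            "hexosyl,neutral_loss,both,C6H10O5,,flavonol\n",
        )
        lib = load_signature_library(p)
        assert round_mass(lib.entries[0].mass) == 162.0528

    def test_consistent_mass_and_formula_accepted(self, tmp_path):
        p = _write(
            tmp_path, "s.csv",
            "name,kind,polarity,formula,exact_mass,class\n"
            "quinic acid,diagnostic,negative,C7H12O6,191.0556,phenolic acid\n",
        )
        assert len(load_signature_library(p)) == 1

    def test_inconsistent_mass_rejected(self, tmp_path):
        p = _write(
            tmp_path, "s.csv",
            "name,kind,polarity,formula,exact_mass,class\n"
            "quinic acid,diagnostic,negative,C7H12O6,191.0600,phenolic acid\n",
        )
        with pytest.raises(ValueError):
            load_signature_library(p)

    def test_missing_both_mass_and_formula_rejected(self, tmp_path):
        p = _write(
            tmp_path, "s.csv",
            "name,kind,polarity,formula,exact_mass,class\n"
            "mystery,diagnostic,negative,,,phenolic acid\n",
        )
        with pytest.raises(ValueError):
            load_signature_library(p)


PRINTED_SIGNATURES = [
    # (name, polarity, printed m/z or loss mass)
    ("Caffeic acid anion", "negative", 179.0344),
    ("Cinnamic acid anion", "negative", 147.0446),
    ("Coumaric acid anion", "negative", 163.0395),
    ("Quinic acid anion", "negative", 191.0556),
    ("Quinic acid-H2O anion", "negative", 173.0450),
    ("Ferulic acid anion", "negative", 193.0501),
    ("Coumaroylquinic acid anion", "negative", 337.0923),
    ("Caffeoylquinic acid anion", "negative", 353.0873),
    ("Feruloylquinic acid anion", "negative", 367.1029),
    ("Kaempferol anion", "negative", 285.0399),
    ("Quercetin anion", "negative", 301.0348),
    ("Isorhamnetin anion", "negative", 315.0505),
    ("Flavonol RDA fragment anion", "negative", 151.0031),
    ("Kaempferol cation", "positive", 287.0556),
    ("Quercetin cation", "positive", 303.0505),
    ("Isorhamnetin cation", "positive", 317.0661),
    ("Flavonol RDA fragment cation", "positive", 153.0188),
    ("Phosphocholine cation", "positive", 184.0739),
    ("Phosphocholine-H2O cation", "positive", 166.0633),
    ("Cyclic ethylene phosphate cation", "positive", 125.0004),
    ("Choline cation", "positive", 104.1075),
    ("Trimethylethenaminium cation", "positive", 86.0970),
    ("Hydroxytetradecanoic acid anion", "negative", 243.1960),
]


@pytest.mark.parametrize("name,polarity,mz", PRINTED_SIGNATURES)
def test_packaged_signatures_reproduce_reference_masses(signature_library, name, polarity, mz):
    matches = [
        e for e in signature_library.diagnostics(polarity) if e.name == name
    ]
    assert matches, f"missing diagnostic {name}"
    assert round_mass(matches[0].mass) == mz


def test_packaged_loss_masses(signature_library):
    losses = {(e.name, round_mass(e.mass)) for e in signature_library.loss_masses()}
    for name, mass in [
        ("Hexosyl loss", 162.0528),
        ("Feruloyl loss", 176.0473),
        ("Caffeoyl loss", 162.0317),
        ("Quinic acid loss", 192.0634),
        ("Sulfo loss", 79.9568),
        ("Glucuronosyl loss", 176.0321),
        ("Water loss", 18.0106),
    ]:
        assert (name, mass) in losses


def test_packaged_fixture_is_a_subset_not_the_full_library(signature_library):
    # The curated fixture carries only literature-printed signatures, far
    # fewer than a full platform library would hold.
    assert 10 < len(signature_library.diagnostics("positive") +
                    signature_library.diagnostics("negative")) < 41 + 46
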