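"""Chemical model: parsing, derivatization, symmetry, fragments, factors."""

import itertools

import pytest
from hypothesis import given, strategies as st

from pmaalink import linkage as L
from pmaalink.errors import (
    DerivatizationError,
    LinkageParseError,
    MissingFactorError,
    UnsupportedDerivativeError,
)

from oracles import oracle_mass


def _all_library_labels(rt_lib):
    return sorted(rt_lib.entries)


# ---------------------------------------------------------------------------
# Parsing

@pytest.mark.parametrize("code,sugar,ring,positions,bridge", [
    ("4-Glc*p*", "Glc", "p", {4}, None),
    ("t-Xylp", "Xyl", "p", set(), None),
    ("2,4-AnGalp", "Gal", "p", {2, 4}, (3, 6)),
    ("t-Araf", "Ara", "f", set(), None),
    ("t-Ara", "Ara", "f", set(), None),   # furanose default for arabinose
    ("3-Gal", "Gal", "p", {3}, None),     # pyranose default otherwise
])
def test_parse_linkage(code, sugar, ring, positions, bridge):
    link = L.parse_linkage(code)
    assert link.sugar == sugar
    assert link.ring == ring
    assert link.linked_positions == frozenset(positions)
    assert link.anhydro_bridge == bridge


@pytest.mark.parametrize("bad", [
    "4-Qux",            # unknown sugar
    "7-Galp",           # out of range
    "5-Xylp",           # ring-closure carbon cannot be linked
    "1-Galp",           # anomeric carbon cannot be linked
    "3-AnGalp",         # collides with the 3,6 bridge
    "4-AnXylp",         # anhydro only on hexoses
    "Galp",             # missing position part
    "",
])
def test_parse_errors(bad):
    with pytest.raises(LinkageParseError):
        L.parse_linkage(bad)


def test_roundtrip_through_library(rt_lib):
    """Every shipped library label survives parse -> format unchanged."""
    for label in _all_library_labels(rt_lib):
        assert L.format_linkage(L.parse_linkage(label)) == label


# ---------------------------------------------------------------------------
# Derivatization

@pytest.mark.parametrize("code,deut,acetyl,methyl,anhydro,mass", [
    ("4-Glcp", True, {1, 4, 5}, {2, 3, 6}, set(), 351),
    ("t-Xylp", True, {1, 5}, {2, 3, 4}, set(), 279),
    ("4-AnGalp", False, {1, 4, 5}, {2}, {3, 6}, 304),
])
def test_derivatize_patterns_and_masses(code, deut, acetyl, methyl, anhydro, mass):
    d = L.derivatize(L.parse_linkage(code), deuterate=deut)
    assert d.acetyl_positions == frozenset(acetyl)
    assert d.methyl_positions == frozenset(methyl)
    assert d.anhydro_positions == frozenset(anhydro)
    assert d.nominal_mass == mass
    assert d.nominal_mass == oracle_mass(d.source.sugar, acetyl, methyl,
                                         bool(anhydro), deut)


def test_derivative_masses_match_oracle_across_library(rt_lib):
    for label in _all_library_labels(rt_lib):
        link = L.parse_linkage(label)
        deut = link.anhydro_bridge is None
        d = L.derivatize(link, deuterate=deut)
        assert d.nominal_mass == oracle_mass(
            link.sugar, d.acetyl_positions, d.methyl_positions,
            bool(d.anhydro_positions), deut,
        ), label


def test_substituents_partition_oxygen_carbons(rt_lib):
    for label in _all_library_labels(rt_lib):
        link = L.parse_linkage(label)
        d = L.derivatize(link)
        union = d.acetyl_positions | d.methyl_positions | d.anhydro_positions
        assert union == link.oxygen_positions
        assert not (d.acetyl_positions & d.methyl_positions)
        assert not (d.acetyl_positions & d.anhydro_positions)
        assert 1 in d.acetyl_positions


def test_deuteration_of_anhydro_rejected():
    with pytest.raises(DerivatizationError):
        L.derivatize(L.parse_linkage("4-AnGalp"), deuterate=True)


_HEXOSE_POSITIONS = st.sets(st.sampled_from([2, 3, 4, 6]), max_size=4)


@given(positions=_HEXOSE_POSITIONS)
def test_mass_additivity_per_linked_position(positions):
    """Each acetyl-for-methyl swap adds 42 - 14 = 28 Da to the PMAA."""
    link = L.LinkageCode("Gal", "p", frozenset(positions))
    terminal = L.LinkageCode("Gal", "p", frozenset())
    delta = (L.derivatize(link).nominal_mass
             - L.derivatize(terminal).nominal_mass)
    assert delta == 28 * len(positions)


# ---------------------------------------------------------------------------
# Symmetry

def test_named_symmetric_pairs():
    assert L.is_symmetric_pair(L.parse_linkage("2-Xylp"), L.parse_linkage("4-Xylp"))
    assert L.is_symmetric_pair(L.parse_linkage("2,3,6-Galp"), L.parse_linkage("2,4,6-Galp"))
    assert not L.is_symmetric_pair(L.parse_linkage("3-Galp"), L.parse_linkage("4-Galp"))


def test_symmetric_pairs_in_library_are_exactly_the_known_two(rt_lib):
    labels = _all_library_labels(rt_lib)
    found = {
        frozenset((a, b))
        for a, b in itertools.combinations(labels, 2)
        if L.is_symmetric_pair(L.parse_linkage(a), L.parse_linkage(b))
    }
    assert found == {
        frozenset({"2-Xylp", "4-Xylp"}),
        frozenset({"2,3,6-Galp", "2,4,6-Galp"}),
    }


def test_symmetry_is_an_involution_with_unique_partner(rt_lib):
    labels = _all_library_labels(rt_lib)
    codes = {lab: L.parse_linkage(lab) for lab in labels}
    for a, b in itertools.combinations(labels, 2):
        assert (L.is_symmetric_pair(codes[a], codes[b])
                == L.is_symmetric_pair(codes[b], codes[a]))
    for a in labels:
        partners = [b for b in labels if b != a
                    and L.is_symmetric_pair(codes[a], codes[b])]
        assert len(partners) <= 1, (a, partners)


def test_self_pair_and_cross_sugar_are_not_symmetric():
    assert not L.is_symmetric_pair(L.parse_linkage("3-Xylp"), L.parse_linkage("3-Xylp"))
    assert not L.is_symmetric_pair(L.parse_linkage("2-Xylp"), L.parse_linkage("4-Galp"))


# ---------------------------------------------------------------------------
# Fragments

def test_fragment_count_terminal_xylose():
    d = L.derivatize(L.parse_linkage("t-Xylp"), deuterate=True)
    frags = L.predict_fragments(d)
    assert len(frags) == 8  # 4 C-C bonds x 2 retained sides


def test_fragment_pair_sums_equal_parent_mass(rt_lib):
    for label in _all_library_labels(rt_lib):
        link = L.parse_linkage(label)
        if link.anhydro_bridge:
            continue
        d = L.derivatize(link, deuterate=True)
        frags = L.predict_fragments(d)
        by_cut = {}
        for f in frags:
            cut = f.carbons[1] if f.carbons[0] == 1 else f.carbons[0] - 1
            by_cut.setdefault(cut, []).append(f.mz)
        for cut, masses in by_cut.items():
            assert sum(masses) == d.nominal_mass, (label, cut)


def test_deuterium_shifts_only_c1_fragments():
    link = L.parse_linkage("4-Glcp")
    plain = {f.carbons: f.mz for f in L.predict_fragments(L.derivatize(link, False))}
    labeled = {f.carbons: f.mz for f in L.predict_fragments(L.derivatize(link, True))}
    for carbons, mz in plain.items():
        if carbons[0] == 1:
            assert labeled[carbons] == mz + 1
        else:
            assert labeled[carbons] == mz


def test_symmetric_pair_fragments_distinguishable_when_labeled():
    a = L.derivatize(L.parse_linkage("2-Xylp"), deuterate=True)
    b = L.derivatize(L.parse_linkage("4-Xylp"), deuterate=True)
    multiset_a = sorted(f.mz for f in L.predict_fragments(a))
    multiset_b = sorted(f.mz for f in L.predict_fragments(b))
    assert multiset_a != multiset_b
    # without the label the mirror derivatives are indistinguishable
    a0 = L.derivatize(L.parse_linkage("2-Xylp"), deuterate=False)
    b0 = L.derivatize(L.parse_linkage("4-Xylp"), deuterate=False)
    assert (sorted(f.mz for f in L.predict_fragments(a0))
            == sorted(f.mz for f in L.predict_fragments(b0)))


def test_fragments_of_anhydro_rejected():
    with pytest.raises(UnsupportedDerivativeError):
        L.predict_fragments(L.derivatize(L.parse_linkage("4-AnGalp")))


def test_diagnostic_ions_are_unique_to_each_member():
    a, b = L.parse_linkage("2,3,6-Galp"), L.parse_linkage("2,4,6-Galp")
    ions = L.diagnostic_ions(a, b)
    fa = {f.mz for f in L.predict_fragments(L.derivatize(a, True))}
    fb = {f.mz for f in L.predict_fragments(L.derivatize(b, True))}
    assert ions["2,3,6-Galp"] in fa - fb
    assert ions["2,4,6-Galp"] in fb - fa


# ---------------------------------------------------------------------------
# Response factors

def test_reference_factors(rf_lib):
    assert rf_lib.factor("3-Galp") == pytest.approx(0.74)
    assert rf_lib.factor("4-AnGalp") == pytest.approx(0.49)


def test_increment_rule_derives_disubstituted_anhydro(rf_lib):
    # 2,4-AnGalp is deliberately absent from the entries: the O-2
    # acetyl-for-methyl rule must derive it from the 4-AnGalp base.
    assert "2,4-AnGalp" not in rf_lib.entries
    assert rf_lib.factor("2,4-AnGalp") == pytest.approx(0.54)


def test_missing_factor_raises(rf_lib):
    with pytest.raises(MissingFactorError, match="3-Manp"):
        rf_lib.factor("3-Manp")  # absent, and the O-2 rule does not apply
    with pytest.raises(MissingFactorError, match="2,3-Rhap"):
        rf_lib.factor("2,3-Rhap")  # rule applies but the base entry is absent


def test_factor_range_validated():
    with pytest.raises(ValueError):
        L.ResponseFactorLibrary(entries={"4-Glcp": 2.5})
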