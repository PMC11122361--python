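"""Chemical model of partially methylated alditol acetates (PMAAs).

A glycosidic-linkage shorthand such as ``"2,4-AnGalp"`` describes one
residue of a polysaccharide: the sugar, its ring form, the carbon
positions engaged in glycosidic bonds in the polymer, and an optional
3,6-anhydro bridge.  Methylation analysis turns each residue into a
PMAA whose methyl/acetyl substitution pattern encodes exactly that
information: free hydroxyls are methylated during permethylation, while
the anomeric carbon, the ring-closure carbon and every glycosidically
linked position emerge from hydrolysis/reduction as hydroxyls that are
subsequently acetylated.

This module parses and formats the shorthand, derives the substitution
pattern, molecular formula and nominal mass of each PMAA, predicts
primary electron-impact fragments, detects chain-reversal symmetric
pairs (which co-elute and are only distinguishable through C-1
deuterium labelling), and serves FID response factors.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

from .errors import (
    DerivatizationError,
    LinkageParseError,
    MissingFactorError,
    UnsupportedDerivativeError,
)

__all__ = [
    "LinkageCode",
    "PMAADerivative",
    "Fragment",
    "ResponseFactorLibrary",
    "parse_linkage",
    "format_linkage",
    "derivatize",
    "is_symmetric_pair",
    "predict_fragments",
    "diagnostic_ions",
    "response_factor",
    "nominal_mass_for_label",
]

# backbone length, oxygen-bearing carbons
_SUGARS: dict[str, tuple[int, frozenset[int]]] = {
    "Gal": (6, frozenset({1, 2, 3, 4, 5, 6})),
    "Glc": (6, frozenset({1, 2, 3, 4, 5, 6})),
    "Man": (6, frozenset({1, 2, 3, 4, 5, 6})),
    "Xyl": (5, frozenset({1, 2, 3, 4, 5})),
    "Ara": (5, frozenset({1, 2, 3, 4, 5})),
    "Rha": (6, frozenset({1, 2, 3, 4, 5})),  # 6-deoxy: C-6 is a methyl group
    "Fuc": (6, frozenset({1, 2, 3, 4, 5})),
}

_NOMINAL_MASS = {"C": 12, "H": 1, "O": 16, "D": 2}

_LABEL_RE = re.compile(
    r"^(?P<pos>t|\d+(?:,\d+)*)-(?P<an>An)?(?P<sugar>[A-Z][a-z]{2})(?P<ring>[pf])?$"
)


@dataclass(frozen=True)
class LinkageCode:
    """A parsed glycosidic-linkage shorthand.

    ``linked_positions`` are the backbone carbons whose oxygens carry
    glycosidic bonds in the intact polymer (empty for a terminal,
    non-reducing residue).  ``anhydro_bridge`` is the internal ether
    bridge of 3,6-anhydro sugars; only (3, 6) on hexoses is supported.
    """

    sugar: str
    ring: str  # "p" (pyranose) or "f" (furanose)
    linked_positions: frozenset[int] = frozenset()
    anhydro_bridge: tuple[int, int] | None = None

    @property
    def terminal(self) -> bool:
        return not self.linked_positions

    @property
    def backbone_length(self) -> int:
        return _SUGARS[self.sugar][0]

    @property
    def oxygen_positions(self) -> frozenset[int]:
        return _SUGARS[self.sugar][1]

    @property
    def ring_carbon(self) -> int:
        return 5 if self.ring == "p" else 4

    @property
    def label(self) -> str:
        return format_linkage(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def format_linkage(link: LinkageCode) -> str:
    """Canonical string form, e.g. ``"2,4-AnGalp"`` or ``"t-Xylp"``."""
    pos = "t" if link.terminal else ",".join(str(p) for p in sorted(link.linked_positions))
    an = "An" if link.anhydro_bridge else ""
    return f"{pos}-{an}{link.sugar}{link.ring}"


def parse_linkage(code: str) -> LinkageCode:
    """Parse linkage shorthand into a validated :class:`LinkageCode`.

    The grammar is ``[t|p1,p2,...]-[An]Sugar[p|f]``.  Markdown emphasis
    markers around the ring letter (``4-Glc*p*``) are tolerated.  The
    ring letter defaults to pyranose, except arabinose which defaults to
    furanose.

    Raises
    ------
    LinkageParseError
        On an unknown sugar token, a position out of range, or an
        anhydro bridge colliding with a linked position.
    """
    cleaned = code.replace("*", "").strip()
    m = _LABEL_RE.match(cleaned)
    if m is None:
        raise LinkageParseError(f"cannot parse linkage code {code!r}")
    sugar = m.group("sugar")
    if sugar not in _SUGARS:
        raise LinkageParseError(f"unknown sugar token {sugar!r} in {code!r}")
    ring = m.group("ring") or ("f" if sugar == "Ara" else "p")

    if m.group("pos") == "t":
        positions: frozenset[int] = frozenset()
    else:
        positions = frozenset(int(tok) for tok in m.group("pos").split(","))

    bridge: tuple[int, int] | None = (3, 6) if m.group("an") else None
    link = LinkageCode(sugar=sugar, ring=ring, linked_positions=positions,
                       anhydro_bridge=bridge)
    _validate(link, code)
    return link


def _validate(link: LinkageCode, code: str) -> None:
    n, oxygens = _SUGARS[link.sugar]
    allowed = oxygens - {1, link.ring_carbon}
    for p in sorted(link.linked_positions):
        if p not in allowed:
            raise LinkageParseError(
                f"position {p} out of range for {link.sugar}{link.ring} in {code!r}"
            )
    if link.anhydro_bridge is not None:
        if n != 6 or link.anhydro_bridge != (3, 6):
            raise LinkageParseError(
                f"anhydro bridge only supported as (3,6) on hexoses; got {code!r}"
            )
        collision = set(link.anhydro_bridge) & link.linked_positions
        if collision:
            raise LinkageParseError(
                f"anhydro position {sorted(collision)} collides with a linked "
                f"position in {code!r}"
            )


# ---------------------------------------------------------------------------
# Derivatization

@dataclass(frozen=True)
class PMAADerivative:
    """A PMAA: the partially methylated alditol acetate of one residue."""

    source: LinkageCode
    acetyl_positions: frozenset[int]
    methyl_positions: frozenset[int]
    anhydro_positions: frozenset[int]
    deuterated_c1: bool
    formula: Mapping[str, int] = field(repr=False)
    nominal_mass: int = 0

    @property
    def label(self) -> str:
        return self.source.label


def _formula_of(link: LinkageCode, acetyl: frozenset[int], methyl: frozenset[int],
                deuterate: bool) -> dict[str, int]:
    """Molecular formula by increments from the parent alditol.

    Backbone alditol; +CH2 per methyl ether, +C2H2O per acetyl ester,
    -H2O per anhydro bridge, one H replaced by D at C-1 when labelled.
    """
    n = link.backbone_length
    f = {"C": n, "H": 2 * n + 2, "O": len(link.oxygen_positions)}
    f["C"] += len(methyl)
    f["H"] += 2 * len(methyl)
    f["C"] += 2 * len(acetyl)
    f["H"] += 2 * len(acetyl)
    f["O"] += len(acetyl)
    if link.anhydro_bridge:
        f["H"] -= 2
        f["O"] -= 1
    if deuterate:
        f["H"] -= 1
        f["D"] = 1
    return f


def _nominal_mass(formula: Mapping[str, int]) -> int:
    return sum(_NOMINAL_MASS[el] * cnt for el, cnt in formula.items())


def derivatize(link: LinkageCode, deuterate: bool = False) -> PMAADerivative:
    """Derive the PMAA substitution pattern and formula for a linkage.

    Acetyl groups sit at C-1 (anomeric), the ring-closure carbon and
    every linked position; all remaining oxygen-bearing carbons carry
    methyl ethers, except those consumed by an anhydro bridge.

    Deuteration models NaBD4 reduction (one D at C-1) and is invalid for
    anhydro linkages: the reductive-hydrolysis route that preserves the
    3,6-anhydro ring uses a non-deuterating reductant.
    """
    if deuterate and link.anhydro_bridge is not None:
        raise DerivatizationError(
            f"{link.label}: anhydro sugars come from reductive hydrolysis and "
            "cannot carry a C-1 deuterium label"
        )
    anhydro = frozenset(link.anhydro_bridge or ())
    acetyl = frozenset({1, link.ring_carbon} | link.linked_positions)
    methyl = link.oxygen_positions - acetyl - anhydro
    formula = _formula_of(link, acetyl, methyl, deuterate)
    return PMAADerivative(
        source=link,
        acetyl_positions=acetyl,
        methyl_positions=methyl,
        anhydro_positions=anhydro,
        deuterated_c1=deuterate,
        formula=formula,
        nominal_mass=_nominal_mass(formula),
    )


def nominal_mass_for_label(label: str) -> int:
    """Nominal PMAA mass used for TIC quantitation.

    Non-anhydro PMAAs come from the NaBD4 route and carry the C-1
    deuterium; anhydro PMAAs come from reductive hydrolysis and do not.
    """
    link = parse_linkage(label)
    return derivatize(link, deuterate=link.anhydro_bridge is None).nominal_mass


# ---------------------------------------------------------------------------
# Symmetry

def _substituent_sequence(link: LinkageCode) -> tuple[str | None, ...]:
    d = derivatize(link, deuterate=False)
    seq = []
    for c in range(1, link.backbone_length + 1):
        if c in d.acetyl_positions:
            seq.append("Ac")
        elif c in d.methyl_positions:
            seq.append("Me")
        else:
            seq.append(None)  # non-oxygenated carbon (C-6 of deoxyhexoses)
    return tuple(seq)


def is_symmetric_pair(a: LinkageCode, b: LinkageCode) -> bool:
    """True iff the two PMAAs are mirror images under chain reversal.

    Such pairs (e.g. 2-Xylp/4-Xylp, 2,3,6-Galp/2,4,6-Galp) are
    chromatographically indistinguishable without the C-1 deuterium
    label, because reversing the alditol chain (position i -> n+1-i)
    maps one substitution pattern onto the other.  Mismatched sugars or
    ring forms, anhydro sugars and identical linkages return False.
    """
    if a.sugar != b.sugar or a.ring != b.ring:
        return False
    if a.anhydro_bridge is not None or b.anhydro_bridge is not None:
        return False
    if a == b:
        return False
    return _substituent_sequence(a) == _substituent_sequence(b)[::-1]


# ---------------------------------------------------------------------------
# EI fragments

@dataclass(frozen=True)
class Fragment:
    """A primary EI fragment: one C-C cleavage, one retained side."""

    mz: int
    carbons: tuple[int, int]  # inclusive (first, last) retained backbone carbon

    @property
    def contains_c1(self) -> bool:
        return self.carbons[0] == 1


_OME_MASS = 31  # OCH3
_OAC_MASS = 59  # OC(=O)CH3


def predict_fragments(d: PMAADerivative) -> list[Fragment]:
    """Primary EI fragments of a non-anhydro PMAA.

    Electron-impact spectra of PMAAs are dominated by single backbone
    C-C cleavages; the charge-retaining side keeps its substituents
    without hydrogen transfer, so each fragment mass is the plain
    atomic-composition sum of the retained contiguous carbon run.  Every
    cleavage yields two fragments (the C-1 side and the C-n side); the
    C-1 side carries the +1 deuterium shift when labelled.  Secondary
    losses (AcOH, MeOH) are deliberately not modelled — the predictor
    exists to pick label-discriminating diagnostic ions for symmetric
    pairs, not to simulate full spectra.
    """
    if d.anhydro_positions:
        raise UnsupportedDerivativeError(
            f"{d.label}: fragment prediction is undefined for anhydro PMAAs"
        )
    n = d.source.backbone_length
    out: list[Fragment] = []
    for cut in range(1, n):
        out.append(Fragment(_fragment_mass(d, 1, cut), (1, cut)))
        out.append(Fragment(_fragment_mass(d, cut + 1, n), (cut + 1, n)))
    return out


def _fragment_mass(d: PMAADerivative, first: int, last: int) -> int:
    n = d.source.backbone_length
    oxygens = d.source.oxygen_positions
    mass = 0
    for c in range(first, last + 1):
        mass += 12
        if c in (1, n):
            mass += 2 if c in oxygens else 3  # CH2-OR terminus, or CH3 of deoxy
        else:
            mass += 1
        if c in d.methyl_positions:
            mass += _OME_MASS
        elif c in d.acetyl_positions:
            mass += _OAC_MASS
        if c == 1 and d.deuterated_c1:
            mass += 1  # one H replaced by D
    return mass


def diagnostic_ions(a: LinkageCode, b: LinkageCode) -> dict[str, int]:
    """Pick one discriminating EI fragment m/z per member of a symmetric pair.

    Both members are considered in their C-1 deuterated form (the form
    in which the pair is distinguishable at all).  For each member the
    largest fragment mass absent from the partner's fragment set is
    chosen; the masses of the chosen pair are maximally separated among
    the single-ion-per-member choices in practice, and are flagged as a
    heuristic rather than a literature-prescribed ion list.
    """
    if not is_symmetric_pair(a, b):
        raise ValueError(f"{a.label} and {b.label} are not a symmetric pair")
    frags_a = {f.mz for f in predict_fragments(derivatize(a, deuterate=True))}
    frags_b = {f.mz for f in predict_fragments(derivatize(b, deuterate=True))}
    only_a = frags_a - frags_b
    only_b = frags_b - frags_a
    if not only_a or not only_b:
        raise ValueError(
            f"no discriminating fragments between {a.label} and {b.label}"
        )
    return {a.label: max(only_a), b.label: max(only_b)}


# ---------------------------------------------------------------------------
# Response factors

@dataclass(frozen=True)
class ResponseFactorLibrary:
    """Relative FID molar response factors keyed by canonical PMAA label.

    ``increment_rules`` encode position-substitution adjustments, e.g.
    an acetyl replacing a methyl at O-2 adds 0.05 to the base factor.
    Factors are dimensionless and relative; moles are proportional to
    area / factor, so an under-responding PMAA (small factor) has its
    molar share inflated accordingly.
    """

    entries: Mapping[str, float]
    increment_rules: tuple[tuple[int, float], ...] = ((2, 0.05),)

    def __post_init__(self) -> None:
        for label, factor in self.entries.items():
            if not 0.0 < factor <= 2.0:
                raise ValueError(f"response factor for {label} out of (0, 2]: {factor}")

    @classmethod
    def from_json(cls, path) -> "ResponseFactorLibrary":
        with open(path) as fh:
            raw = json.load(fh)
        rules = tuple((int(r["position"]), float(r["delta"]))
                      for r in raw.get("increment_rules", []))
        return cls(entries=dict(raw["entries"]), increment_rules=rules)

    @classmethod
    def default(cls) -> "ResponseFactorLibrary":
        with resources.files("pmaalink.data").joinpath("response_factors.json").open() as fh:
            raw = json.load(fh)
        rules = tuple((int(r["position"]), float(r["delta"]))
                      for r in raw.get("increment_rules", []))
        return cls(entries=dict(raw["entries"]), increment_rules=rules)

    def factor(self, item: "LinkageCode | PMAADerivative | str") -> float:
        """Resolve a factor by exact label, else by one increment rule.

        The rule path strips one linked position named by a rule and
        looks the reduced label up directly, applying the increment at
        most once per position substitution (e.g. 2,4-AnGalp resolves
        from 4-AnGalp + 0.05).
        """
        if isinstance(item, PMAADerivative):
            link = item.source
        elif isinstance(item, LinkageCode):
            link = item
        else:
            link = parse_linkage(item)
        label = link.label
        if label in self.entries:
            return float(self.entries[label])
        for position, delta in self.increment_rules:
            if position in link.linked_positions:
                base = replace(link, linked_positions=link.linked_positions - {position})
                if base.label in self.entries:
                    return float(self.entries[base.label]) + delta
        raise MissingFactorError(
            f"no response factor for {label!r} and no increment rule applies"
        )


def response_factor(d: "PMAADerivative | LinkageCode | str",
                    lib: ResponseFactorLibrary) -> float:
    """Functional form of :meth:`ResponseFactorLibrary.factor`."""
    return lib.factor(d)


def library_labels(labels: Iterable[str]) -> list[LinkageCode]:
    """Parse a collection of labels, preserving order."""
    return [parse_linkage(lab) for lab in labels]
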