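"""Roll-ups from linkage composition to monosaccharide and polysaccharide level.

A linkage table says how much of each glycosidic linkage a sample
contains; grouping those values by parent sugar gives the
monosaccharide composition, and an ordered, user-editable rule table
maps linkages onto polysaccharide structures (Floridean starch,
cellulose, agarose, mixed-linkage xylan, other galactans) with a
residual bucket absorbing whatever no rule consumes, so totals are
conserved at 100.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from . import linkage
from .errors import UndefinedRatioError
from .quantify import CompositionTable

__all__ = [
    "AssignmentTable",
    "monosaccharide_rollup",
    "estimate_polysaccharides",
    "linkage_ratio",
]


def monosaccharide_rollup(table: CompositionTable,
                          split_anhydro: bool = False) -> dict[str, float]:
    """Sum linkage percentages per parent sugar.

    3,6-anhydro-galactose counts under galactose unless
    ``split_anhydro`` reports it separately as ``"AnGal"``.  The total
    is preserved (100).
    """
    out: dict[str, float] = {}
    for label, pct in table.entries.items():
        link = linkage.parse_linkage(label)
        sugar = link.sugar
        if split_anhydro and link.anhydro_bridge:
            sugar = "An" + sugar
        out[sugar] = out.get(sugar, 0.0) + pct
    return out


@dataclass(frozen=True)
class AssignmentTable:
    """Ordered linkage-to-polysaccharide assignment rules.

    Three rule types cover the default table: ``branch_expand`` (a
    branch-point linkage implies ``degree`` backbone residues, drawn
    from a backbone pool), ``sum`` (a polysaccharide is the remaining
    total of listed linkages), ``min_pair`` (an alternating-disaccharide
    polymer is twice the limiting member, consuming equal shares of
    both), and ``sugar_remainder`` (everything left of the listed
    sugars).  Rules run in order against a shared mutable pool.
    """

    rules: tuple[dict, ...]
    residual: str = "residual"

    @classmethod
    def from_json(cls, path) -> "AssignmentTable":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(rules=tuple(raw["rules"]), residual=raw.get("residual", "residual"))

    @classmethod
    def default(cls) -> "AssignmentTable":
        with resources.files("pmaalink.data").joinpath("assignment_rules.json").open() as fh:
            raw = json.load(fh)
        return cls(rules=tuple(raw["rules"]), residual=raw.get("residual", "residual"))


def estimate_polysaccharides(table: CompositionTable,
                             rules: AssignmentTable | None = None
                             ) -> dict[str, float]:
    """Estimate relative polysaccharide composition from a linkage table.

    With the default rules: Floridean starch is 4.8x its 4,6-Glcp
    branch-point share (one branch per 4.8 residues), drawing 3.8x from
    the 4-Glcp pool (floored at what is available); cellulose is the
    remaining 4-Glcp; agarose is twice the limiting member of the
    alternating 4-AnGalp/3-Galp pair; mixed-linkage xylan sums the
    backbone and branch xylose linkages; remaining galactose linkages
    are "other galactans"; everything else lands in the residual bucket.
    The output sums to the input total (100).
    """
    if rules is None:
        rules = AssignmentTable.default()
    pool = dict(table.entries)
    out: dict[str, float] = {}

    for rule in rules.rules:
        name, kind = rule["name"], rule["type"]
        if kind == "branch_expand":
            branch, backbone = rule["branch"], rule["backbone"]
            degree = float(rule["degree"])
            if pool.get(branch, 0.0) <= 0.0:
                warnings.warn(f"rule {name!r} skipped: no {branch} available")
                continue
            b = pool.pop(branch)
            from_backbone = min((degree - 1.0) * b, pool.get(backbone, 0.0))
            if backbone in pool:
                pool[backbone] -= from_backbone
            out[name] = b + from_backbone
        elif kind == "sum":
            present = [l for l in rule["labels"] if pool.get(l, 0.0) > 0.0]
            if not present:
                warnings.warn(f"rule {name!r} skipped: none of {rule['labels']} available")
                continue
            out[name] = sum(pool.pop(l) for l in present)
        elif kind == "min_pair":
            la, lb = rule["labels"]
            a, b = pool.get(la, 0.0), pool.get(lb, 0.0)
            take = min(a, b)
            if take <= 0.0:
                warnings.warn(f"rule {name!r} skipped: {la} or {lb} absent")
                continue
            pool[la] = a - take
            pool[lb] = b - take
            out[name] = 2.0 * take
        elif kind == "sugar_remainder":
            sugars = set(rule["sugars"])
            taken = 0.0
            for label in list(pool):
                if linkage.parse_linkage(label).sugar in sugars and pool[label] > 0:
                    taken += pool.pop(label)
            if taken > 0.0:
                out[name] = out.get(name, 0.0) + taken
        else:
            raise ValueError(f"unknown rule type {kind!r} in rule {name!r}")

    residual = sum(v for v in pool.values() if v > 0.0)
    if residual > 1e-12:
        out[rules.residual] = out.get(rules.residual, 0.0) + residual
    return out


def linkage_ratio(table: CompositionTable | Mapping[str, float],
                  num_label: str, den_label: str,
                  ndigits: int | None = 1) -> float:
    """Ratio of two linkage percentages, one decimal by default.

    Diagnostic ratios such as 4-Xylp:3-Xylp (xylan backbone pattern) or
    3-Galp:4-AnGalp (agarose stoichiometry) are plain ratios of table
    entries; a zero or absent denominator is an error.
    """
    entries = table.entries if isinstance(table, CompositionTable) else table
    den = entries.get(den_label, 0.0)
    if den == 0:
        raise UndefinedRatioError(f"denominator {den_label!r} is zero or absent")
    ratio = entries.get(num_label, 0.0) / den
    return round(ratio, ndigits) if ndigits is not None else ratio
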