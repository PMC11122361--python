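"""Detector-specific quantitation of assigned PMAA peak areas.

Two response laws are supported.  FID: moles are proportional to
area / response factor (effective-carbon-number factors; the anhydro
sugars under-respond, so their small factors inflate their molar
share).  TIC: moles are proportional to area / nominal molecular mass
of the PMAA (C-1 deuterated masses for non-anhydro sugars, plain masses
for anhydro sugars, matching the two derivatization routes).

Shared peaks of co-eluting symmetric pairs are split in proportion to
their diagnostic extracted-ion areas before quantitation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import linkage
from .errors import IndeterminateSplitError, UnsupportedSplitError

__all__ = [
    "CompositionTable",
    "fid_composition",
    "tic_composition",
    "split_shared_peak",
    "determine_rf_from_standard",
    "compare_detectors",
    "replicate_summary",
]

MINOR_FLOOR = 0.5  # percent; entries below are flagged, never dropped


@dataclass
class CompositionTable:
    """Relative molar linkage composition of one sample (percent).

    entries sum to 100 (within 1e-6); provenance records whether each
    entry came from its own peak or from a split share of a shared peak.
    """

    sample_id: str
    detector: str
    entries: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("composition entries must be non-negative")
        total = sum(self.entries.values())
        if total <= 0:
            raise ValueError("composition total must be positive")
        if abs(total - 100.0) > 1e-6:
            self.entries = {k: 100.0 * v / total for k, v in self.entries.items()}

    @classmethod
    def from_molar_amounts(cls, amounts: Mapping[str, float], sample_id: str,
                           detector: str,
                           provenance: Mapping[str, str] | None = None
                           ) -> "CompositionTable":
        total = float(sum(amounts.values()))
        if total <= 0:
            raise ValueError("molar amounts sum to zero")
        entries = {k: 100.0 * v / total for k, v in amounts.items()}
        return cls(sample_id=sample_id, detector=detector, entries=entries,
                   provenance=dict(provenance or {}))

    def to_frame(self, round_to: int | None = None,
                 minor_floor: float = MINOR_FLOOR) -> pd.DataFrame:
        """Long-format report; rounding mirrors integer-percent tables by
        default when ``round_to=0``; minor entries are flagged, never
        dropped."""
        rows = []
        for label in sorted(self.entries):
            pct = self.entries[label]
            rows.append({
                "sample_id": self.sample_id,
                "label": label,
                "detector": self.detector,
                "mol_percent": round(pct, round_to) if round_to is not None else pct,
                "minor": pct < minor_floor,
                "provenance": self.provenance.get(label, "direct peak"),
            })
        return pd.DataFrame(rows)


def _areas_from(peaks) -> dict[str, float]:
    if isinstance(peaks, Mapping):
        return dict(peaks)
    out: dict[str, float] = {}
    for p in peaks:
        if p.assigned_label is None:
            continue
        out[p.assigned_label] = out.get(p.assigned_label, 0.0) + p.area
    return out


def fid_composition(peaks, lib: linkage.ResponseFactorLibrary,
                    sample_id: str = "",
                    provenance: Mapping[str, str] | None = None
                    ) -> CompositionTable:
    """Relative molar composition from FID areas: mol_i ∝ area_i / factor_i.

    Every label must resolve to a factor; a missing one raises rather
    than silently quantitating with 1.0.
    """
    areas = _areas_from(peaks)
    moles = {label: area / lib.factor(label) for label, area in areas.items()}
    return CompositionTable.from_molar_amounts(moles, sample_id, "FID", provenance)


def tic_composition(peaks, masses: Mapping[str, float] | None = None,
                    sample_id: str = "",
                    provenance: Mapping[str, str] | None = None
                    ) -> CompositionTable:
    """Relative molar composition from TIC areas: mol_i ∝ area_i / mass_i.

    Masses default to the nominal PMAA masses from the chemical model
    (deuterated for non-anhydro, plain for anhydro linkages).
    """
    areas = _areas_from(peaks)
    if masses is None:
        masses = {label: linkage.nominal_mass_for_label(label) for label in areas}
    moles = {label: area / masses[label] for label, area in areas.items()}
    return CompositionTable.from_molar_amounts(moles, sample_id, "TIC", provenance)


def split_shared_peak(shared_area: float,
                      eic_areas: Mapping[str, float]) -> dict[str, float]:
    """Split a co-eluting pair's shared area by its extracted-ion ratio.

    Shares are proportional to the diagnostic EIC areas and sum exactly
    to ``shared_area``.  Exactly two members are supported; if both EIC
    areas are zero the split is indeterminate.
    """
    if len(eic_areas) != 2:
        raise UnsupportedSplitError(
            f"shared-peak splitting needs exactly 2 members, got {len(eic_areas)}"
        )
    (la, a), (lb, b) = eic_areas.items()
    if a < 0 or b < 0:
        raise ValueError("EIC areas must be non-negative")
    total = a + b
    if total == 0:
        raise IndeterminateSplitError(
            f"both diagnostic EIC areas are zero for ({la}, {lb})"
        )
    share_a = shared_area * a / total
    # exact float conservation: x + (s - x) can land 1 ulp off (or on a
    # round-to-even midpoint), so search a few-ulp neighbourhood of the
    # proportional split for a pair whose float sum equals shared_area
    best = (math.inf, share_a, shared_area - share_a)
    for k in (0, -1, 1, -2, 2, -3, 3, -4, 4):
        sa = share_a
        for _ in range(abs(k)):
            sa = math.nextafter(sa, math.copysign(math.inf, k))
        sb = shared_area - sa
        if sa < 0.0 or sb < 0.0:
            continue
        gap = abs(shared_area - (sa + sb))
        if gap == 0.0:
            return {la: sa, lb: sb}
        if gap < best[0]:
            best = (gap, sa, sb)
    return {la: best[1], lb: best[2]}


def determine_rf_from_standard(areas: Mapping[str, float], ref_label: str,
                               ref_factor: float, molar_ratio: float = 1.0,
                               target_label: str | None = None) -> float:
    """Response factor of the non-reference PMAA in a two-component standard.

    ``molar_ratio`` is mol(target)/mol(reference) in the standard (1.0
    for an equimolar mixture such as agarose's alternating units):

        factor_target = ref_factor * (area_target / area_ref) / molar_ratio
    """
    if ref_label not in areas:
        raise KeyError(f"reference label {ref_label!r} not among areas")
    others = [l for l in areas if l != ref_label]
    if target_label is None:
        if len(others) != 1:
            raise ValueError("standard must contain exactly two labels, or pass target_label")
        target_label = others[0]
    area_ref = areas[ref_label]
    if area_ref == 0:
        raise ZeroDivisionError("reference area is zero")
    return ref_factor * (areas[target_label] / area_ref) / molar_ratio


def compare_detectors(fid: CompositionTable, tic: CompositionTable,
                      threshold: float = 0.2) -> pd.DataFrame:
    """Per-label FID%/TIC% ratios, flagging labels with ratio > 1 + threshold.

    Anhydro-galactose linkages under-respond in the total-ion trace, so
    their FID share exceeds their TIC share; the flag surfaces exactly
    this pattern.  Labels missing from either table are omitted with a
    warning.
    """
    shared = sorted(set(fid.entries) & set(tic.entries))
    if not shared:
        raise ValueError("composition tables share no labels")
    missing = sorted(set(fid.entries) ^ set(tic.entries))
    if missing:
        warnings.warn(f"labels present in only one table omitted: {missing}")
    rows = []
    for label in shared:
        f, t = fid.entries[label], tic.entries[label]
        ratio = np.inf if t == 0 else f / t
        rows.append({
            "label": label,
            "fid_percent": f,
            "tic_percent": t,
            "fid_tic_ratio": ratio,
            "flagged": bool(ratio > 1.0 + threshold),
        })
    return pd.DataFrame(rows)


def replicate_summary(tables: Iterable[CompositionTable]) -> pd.DataFrame:
    """Mean ± SD per label across replicate quantifications.

    Labels absent from a replicate count as 0% there, so n is constant
    across labels; SD uses the sample convention (ddof=1), as in
    reporting two separate experiments per sample.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no composition tables given")
    labels = sorted(set().union(*(t.entries for t in tables)))
    rows = []
    for label in labels:
        vals = np.array([t.entries.get(label, 0.0) for t in tables])
        rows.append({
            "label": label,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n": len(vals),
        })
    return pd.DataFrame(rows)
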