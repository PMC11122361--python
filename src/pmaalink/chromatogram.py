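"""Chromatogram containers, text I/O, peak detection and integration.

Chromatograms are plain two-column time/intensity traces (minutes,
arbitrary detector units) tagged with their detector (FID, TIC, or an
extracted-ion EIC with its m/z).  Peak detection is built on
scipy.signal; integration is trapezoidal above an optional linear
baseline; assignment matches peak apexes against a retention-time
library, with co-eluting symmetric pairs flagged as shared groups to be
split downstream by their extracted-ion ratios.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from . import linkage
from .errors import (
    AmbiguousAssignmentError,
    ChromatogramFormatError,
    IntegrationError,
)

__all__ = [
    "Chromatogram",
    "Peak",
    "RtLibrary",
    "read_chromatogram",
    "write_chromatogram",
    "detect_peaks",
    "integrate_peak",
    "assign_peaks",
    "estimate_noise",
]

_DETECTORS = {"FID", "TIC", "EIC"}


@dataclass
class Chromatogram:
    """A time/intensity trace from one detector.

    times are minutes and strictly increasing; intensities are arbitrary
    detector units (negative values are allowed — baseline-subtracted
    traces can dip below zero).  EIC traces must carry their m/z.
    """

    times: np.ndarray
    intensities: np.ndarray
    detector: str = "FID"
    sample_id: str = ""
    eic_mz: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        if self.times.size < 2:
            raise ValueError("a chromatogram needs at least two points")
        if not np.all(np.diff(self.times) > 0):
            bad = int(np.argmin(np.diff(self.times) > 0)) + 1
            raise ValueError(f"times must be strictly increasing (first violation at index {bad})")
        if self.detector not in _DETECTORS:
            raise ValueError(f"unknown detector {self.detector!r}")
        if self.detector == "EIC" and self.eic_mz is None:
            raise ValueError("EIC chromatograms must carry their m/z")

    @property
    def dt(self) -> float:
        """Median sampling interval, minutes."""
        return float(np.median(np.diff(self.times)))


@dataclass
class Peak:
    """A detected, optionally assigned chromatographic peak."""

    apex_time: float
    left: float
    right: float
    height: float
    area: float = 0.0
    apex_index: int = 0
    assigned_label: str | None = None
    shared_group: str | None = None

    def __post_init__(self) -> None:
        if not (self.left < self.apex_time <= self.right):
            raise ValueError(
                f"peak bounds must satisfy left < apex <= right "
                f"({self.left}, {self.apex_time}, {self.right})"
            )


# ---------------------------------------------------------------------------
# Text I/O

def write_chromatogram(chrom: Chromatogram, path) -> None:
    """Write a chromatogram as CSV with '#' metadata lines, full precision."""
    with open(path, "w") as fh:
        fh.write(f"# detector={chrom.detector}\n")
        if chrom.sample_id:
            fh.write(f"# sample_id={chrom.sample_id}\n")
        if chrom.eic_mz is not None:
            fh.write(f"# mz={chrom.eic_mz}\n")
        fh.write("time_min,intensity\n")
        for t, y in zip(chrom.times, chrom.intensities):
            fh.write(f"{float(t)!r},{float(y)!r}\n")


def read_chromatogram(path, delimiter: str | None = None,
                      detector: str | None = None,
                      sample_id: str | None = None) -> Chromatogram:
    """Read a two-column delimited time/intensity text file.

    Leading ``#`` lines may carry ``key=value`` metadata (detector,
    sample_id, mz); a single non-numeric header row is tolerated.
    Explicit ``detector``/``sample_id`` arguments override metadata.
    """
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                if "=" in stripped:
                    key, _, value = stripped.lstrip("# ").partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if stripped:
                body_lines.append(line)
    if not body_lines:
        raise ChromatogramFormatError(f"{path}: no data rows")

    if delimiter is None:
        delimiter = "\t" if "\t" in body_lines[0] else ","
    first_is_header = any(
        not _is_number(tok) for tok in body_lines[0].strip().split(delimiter)[:2]
    )
    try:
        df = pd.read_csv(
            io.StringIO("".join(body_lines)),
            sep=delimiter,
            header=0 if first_is_header else None,
            usecols=[0, 1],
            float_precision="round_trip",
        )
        times = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(float)
        intens = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise ChromatogramFormatError(f"{path}: non-numeric cell ({exc})") from exc

    diffs = np.diff(times)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 1 + (1 if first_is_header else 0)
        raise ChromatogramFormatError(
            f"{path}: non-increasing time at data row {row + 1}"
        )
    mz = meta.get("mz")
    return Chromatogram(
        times=times,
        intensities=intens,
        detector=detector or meta.get("detector", "FID"),
        sample_id=sample_id if sample_id is not None else meta.get("sample_id", ""),
        eic_mz=int(mz) if mz is not None else None,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Detection

def estimate_noise(chrom: Chromatogram) -> float:
    """Robust noise SD from the median absolute first difference.

    Peaks are sparse in a GC trace, so the median |Δy| reflects the
    baseline; MAD/0.6745 converts to an SD and the sqrt(2) accounts for
    differencing.
    """
    d = np.abs(np.diff(chrom.intensities))
    return float(np.median(d) / 0.6745 / math.sqrt(2.0))


def detect_peaks(
    chrom: Chromatogram,
    min_height: float | None = None,
    min_prominence: float | None = None,
    smooth_window: int = 7,
    min_distance: float = 0.35,
    bound_mode: str = "sigma",
    bound_sigmas: float = 4.0,
    fixed_sigma: float | None = None,
) -> list[Peak]:
    """Detect peaks as smoothed local maxima above height/prominence thresholds.

    When thresholds are omitted they default to 3x the robust noise
    estimate of the smoothed trace (effectively zero on a noiseless
    trace), balancing missed minor peaks against spurious noise maxima
    landing in assignment windows; ``min_distance`` (minutes) keeps
    noise maxima on the flank of a real peak from registering as
    separate peaks.  Bounds are apex
    +/- ``bound_sigmas`` * sigma, with sigma estimated from the
    half-height width or fixed via ``fixed_sigma`` (minutes) when the
    method's peak width is known, clipped at the valley toward any
    neighbouring peak (``bound_mode="valley"`` uses the plain
    valley-to-valley bounds instead).  Returns peaks in time order,
    non-overlapping; an empty list on a flat trace.
    """
    y_raw = chrom.intensities
    n = y_raw.size
    if smooth_window >= 5 and n > smooth_window:
        y = savgol_filter(y_raw, smooth_window, 2)
        from scipy.signal import savgol_coeffs
        noise_reduction = float(np.sqrt(np.sum(savgol_coeffs(smooth_window, 2) ** 2)))
    else:
        y = y_raw.astype(float)
        noise_reduction = 1.0

    noise = estimate_noise(chrom) * noise_reduction
    tiny = max(1e-12, 1e-9 * float(np.max(np.abs(y), initial=0.0)))
    if min_height is None:
        min_height = max(3.0 * noise, tiny)
    if min_prominence is None:
        min_prominence = max(3.0 * noise, tiny)
    distance = max(1, int(round(min_distance / chrom.dt)))

    idx, props = find_peaks(y, height=min_height, prominence=min_prominence,
                            distance=distance)
    if idx.size == 0:
        return []

    widths = _half_height_widths(y, idx)
    dt = chrom.dt
    peaks: list[Peak] = []
    for k, i in enumerate(idx):
        lo_valley = _valley_index(y, idx[k - 1], i) if k > 0 else 0
        hi_valley = _valley_index(y, i, idx[k + 1]) if k < idx.size - 1 else n - 1
        if bound_mode == "sigma":
            sigma_pts = fixed_sigma / dt if fixed_sigma else widths[k] / 2.3548
            lo = max(lo_valley, int(math.floor(i - bound_sigmas * sigma_pts)), 0)
            hi = min(hi_valley, int(math.ceil(i + bound_sigmas * sigma_pts)), n - 1)
        elif bound_mode == "valley":
            lo, hi = lo_valley, hi_valley
        else:
            raise ValueError(f"unknown bound_mode {bound_mode!r}")
        if lo >= i:
            lo = i - 1
        if hi <= i:
            hi = i + 1 if i + 1 < n else n - 1
        peaks.append(
            Peak(
                apex_time=float(chrom.times[i]),
                left=float(chrom.times[lo]),
                right=float(chrom.times[hi]),
                height=float(y_raw[i]),
                apex_index=int(i),
            )
        )
    return peaks


def _half_height_widths(y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    from scipy.signal import peak_widths

    widths, *_ = peak_widths(y, idx, rel_height=0.5)
    return widths


def _valley_index(y: np.ndarray, left_apex: int, right_apex: int) -> int:
    seg = y[left_apex:right_apex + 1]
    return left_apex + int(np.argmin(seg))


# ---------------------------------------------------------------------------
# Integration

def integrate_peak(chrom: Chromatogram, peak: Peak,
                   baseline: str = "linear") -> float:
    """Trapezoidal peak area above an optional linear baseline, units·min.

    The linear baseline is anchored at the local medians (5 samples)
    around each bound, which keeps single-point noise from tilting the
    baseline.  The result is clipped at zero.
    """
    t, y = chrom.times, chrom.intensities
    if peak.left < t[0] - 1e-12 or peak.right > t[-1] + 1e-12:
        raise IntegrationError(
            f"bounds ({peak.left}, {peak.right}) outside trace domain "
            f"({t[0]}, {t[-1]})"
        )
    lo = int(np.searchsorted(t, peak.left, side="left"))
    hi = int(np.searchsorted(t, peak.right, side="right")) - 1
    if hi <= lo:
        return 0.0
    tt, yy = t[lo:hi + 1], y[lo:hi + 1]
    if baseline == "linear":
        y0 = _local_median(y, lo)
        y1 = _local_median(y, hi)
        base = y0 + (y1 - y0) * (tt - tt[0]) / (tt[-1] - tt[0])
        yy = yy - base
    elif baseline != "none":
        raise ValueError(f"unknown baseline {baseline!r}")
    return max(0.0, float(np.trapezoid(yy, tt)))


def _local_median(y: np.ndarray, i: int, half: int = 2) -> float:
    lo = max(0, i - half)
    hi = min(y.size, i + half + 1)
    return float(np.median(y[lo:hi]))


# ---------------------------------------------------------------------------
# Retention-time library and assignment

@dataclass(frozen=True)
class RtLibrary:
    """Expected retention times (minutes, with tolerances) per PMAA label.

    ``coelution_groups`` name sets of labels sharing a single peak; the
    members of each group must be a chain-reversal symmetric pair.
    """

    entries: Mapping[str, tuple[float, float]]  # label -> (rt, tolerance)
    coelution_groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, (rt, tol) in self.entries.items():
            if tol <= 0:
                raise ValueError(f"tolerance for {label} must be > 0")
        for gid, members in self.coelution_groups.items():
            if len(members) < 2:
                raise ValueError(f"co-elution group {gid} needs >= 2 labels")
            codes = [linkage.parse_linkage(m) for m in members]
            for a in codes:
                for b in codes:
                    if a != b and not linkage.is_symmetric_pair(a, b):
                        raise ValueError(
                            f"co-elution group {gid}: {a.label} and {b.label} "
                            "are not a symmetric pair"
                        )

    @classmethod
    def from_json(cls, path) -> "RtLibrary":
        with open(path) as fh:
            raw = json.load(fh)
        return cls._from_raw(raw)

    @classmethod
    def default(cls) -> "RtLibrary":
        with resources.files("pmaalink.data").joinpath("retention_times.json").open() as fh:
            raw = json.load(fh)
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: dict) -> "RtLibrary":
        entries = {
            label: (float(e["rt"]), float(e.get("tolerance", 0.15)))
            for label, e in raw["entries"].items()
        }
        groups = {
            gid: tuple(members)
            for gid, members in raw.get("coelution_groups", {}).items()
        }
        return cls(entries=entries, coelution_groups=groups)

    def group_of(self, label: str) -> str | None:
        for gid, members in self.coelution_groups.items():
            if label in members:
                return gid
        return None

    def rt(self, label: str) -> float:
        return self.entries[label][0]


def assign_peaks(peaks: Sequence[Peak], lib: RtLibrary) -> list[Peak]:
    """Assign each peak to the nearest library entry within its tolerance.

    Peaks matching a co-elution group get ``shared_group`` set (their
    area belongs to all group members until split); unmatched peaks keep
    ``assigned_label`` empty.  Two peaks claiming the same label raise
    :class:`AmbiguousAssignmentError`.
    """
    assigned: list[Peak] = []
    claims: dict[str, list[float]] = {}
    for p in peaks:
        candidates = sorted(
            (
                (abs(p.apex_time - rt), label)
                for label, (rt, tol) in lib.entries.items()
                if abs(p.apex_time - rt) <= tol
            ),
        )
        if not candidates:
            assigned.append(replace(p, assigned_label=None, shared_group=None))
            continue
        best_label = candidates[0][1]
        gid = lib.group_of(best_label)
        if gid is not None:
            assigned.append(replace(p, assigned_label=None, shared_group=gid))
            claims.setdefault(gid, []).append(p.apex_time)
        else:
            assigned.append(replace(p, assigned_label=best_label, shared_group=None))
            claims.setdefault(best_label, []).append(p.apex_time)
    for key, apexes in claims.items():
        if len(apexes) > 1:
            raise AmbiguousAssignmentError(
                f"{len(apexes)} peaks (apexes at {sorted(apexes)}) within "
                f"tolerance of {key!r}"
            )
    return assigned


# ---------------------------------------------------------------------------
# Optional mzML ingestion (adapter; core pipeline only sees Chromatogram)

def read_mzml_tic(path, sample_id: str = "", eic_mz: int | None = None,
                  mz_tol: float = 0.5) -> Chromatogram:
    """Render an mzML file's TIC (or one EIC) into a :class:`Chromatogram`.

    Requires pyteomics; times are converted to minutes.
    """
    from pyteomics import mzml  # deferred: optional dependency

    times: list[float] = []
    intens: list[float] = []
    with mzml.MzML(str(path)) as reader:
        for spectrum in reader:
            if spectrum.get("ms level", 1) != 1:
                continue
            scan = spectrum["scanList"]["scan"][0]
            start = scan["scan start time"]  # pyteomics unitfloat
            t = float(start)
            if getattr(start, "unit_info", "minute") == "second":
                t /= 60.0
            times.append(t)
            if eic_mz is None:
                intens.append(float(spectrum.get("total ion current",
                                                 np.sum(spectrum["intensity array"]))))
            else:
                mz_arr = spectrum["m/z array"]
                it_arr = spectrum["intensity array"]
                sel = np.abs(mz_arr - eic_mz) <= mz_tol
                intens.append(float(np.sum(it_arr[sel])))
    order = np.argsort(times)
    return Chromatogram(
        times=np.asarray(times)[order],
        intensities=np.asarray(intens)[order],
        detector="TIC" if eic_mz is None else "EIC",
        sample_id=sample_id,
        eic_mz=eic_mz,
    )
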