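"""Chemometric differentiation of samples: anchor normalization and PCA.

Whole chromatograms can separate species without any peak assignment:
each trace is made commensurable by dividing both axes by the apex
coordinates of a reference peak (the 4-Glcp cellulose peak, present in
every sample), resampling to a common relative-time grid, Z-scoring
each grid column, and projecting with PCA.  Linkage composition tables
go through the same Z-score + PCA route with labels as variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chromatogram import Chromatogram, RtLibrary, detect_peaks
from .errors import NormalizationError
from .quantify import CompositionTable

__all__ = [
    "NormalizedTrace",
    "PCAResult",
    "normalize_trace",
    "resample_to_grid",
    "zscore",
    "pca",
    "composition_matrix",
]


@dataclass
class NormalizedTrace:
    """A chromatogram in anchor-relative coordinates.

    Both axes are dimensionless: the anchor apex maps to (1.0, 1.0), so
    a uniform time stretch or an intensity scale factor leaves the
    normalized trace unchanged.
    """

    rel_times: np.ndarray
    rel_intensities: np.ndarray
    sample_id: str = ""
    detector: str = "FID"

    def __post_init__(self) -> None:
        self.rel_times = np.asarray(self.rel_times, dtype=float)
        self.rel_intensities = np.asarray(self.rel_intensities, dtype=float)
        if not np.all(np.diff(self.rel_times) > 0):
            raise ValueError("relative times must be strictly increasing")


def normalize_trace(chrom: Chromatogram, rt_lib: RtLibrary | None = None,
                    anchor_label: str = "4-Glcp",
                    window: tuple[float, float] | None = (25.0, 110.0),
                    anchor_search: float = 0.5,
                    **detect_kwargs) -> NormalizedTrace:
    """Normalize a trace to its anchor peak's apex time and intensity.

    The anchor is located by peak detection within ``anchor_search``
    minutes of its library retention time; the trace is truncated to
    ``window`` (absolute minutes, pass None to keep everything), then
    both axes are divided by the anchor apex coordinates.
    """
    if rt_lib is None:
        rt_lib = RtLibrary.default()
    try:
        expected_rt = rt_lib.rt(anchor_label)
    except KeyError as exc:
        raise NormalizationError(f"anchor {anchor_label!r} not in RT library") from exc

    peaks = detect_peaks(chrom, **detect_kwargs)
    near = [p for p in peaks if abs(p.apex_time - expected_rt) <= anchor_search]
    if not near:
        raise NormalizationError(
            f"anchor peak {anchor_label!r} not found within {anchor_search} min "
            f"of {expected_rt} min"
        )
    anchor = max(near, key=lambda p: p.height)
    t_star = anchor.apex_time
    i_star = float(chrom.intensities[anchor.apex_index])
    if i_star == 0:
        raise NormalizationError(f"anchor peak {anchor_label!r} has zero apex intensity")

    t, y = chrom.times, chrom.intensities
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, y = t[sel], y[sel]
    return NormalizedTrace(
        rel_times=t / t_star,
        rel_intensities=y / i_star,
        sample_id=chrom.sample_id,
        detector=chrom.detector,
    )


def resample_to_grid(traces: Sequence[NormalizedTrace],
                     n_points: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto a shared uniform relative-time grid.

    The grid spans the intersection of all traces' relative-time ranges;
    returns (grid, matrix) with one row per trace.
    """
    lo = max(tr.rel_times[0] for tr in traces)
    hi = min(tr.rel_times[-1] for tr in traces)
    if hi <= lo:
        raise ValueError("traces have disjoint relative-time ranges")
    grid = np.linspace(lo, hi, n_points)
    matrix = np.vstack([
        np.interp(grid, tr.rel_times, tr.rel_intensities) for tr in traces
    ])
    return grid, matrix


def zscore(matrix: np.ndarray) -> np.ndarray:
    """Column-wise Z-score standardization with the population (n) SD.

    Zero-variance columns become all-zero with a warning rather than
    dividing by zero.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("zscore needs a 2-D matrix with at least 2 rows")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} zero-variance column(s) set to zero")
    safe_sd = np.where(flat, 1.0, sd)
    z = (x - mean) / safe_sd
    z[:, flat] = 0.0
    return z


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA."""

    scores: np.ndarray              # samples x components
    loadings: np.ndarray            # variables x components, orthonormal
    explained_variance_ratio: np.ndarray
    n_components: int
    mean: np.ndarray                # column means removed before the SVD

    def reconstruct(self) -> np.ndarray:
        """Back-project: scores @ loadings.T + mean."""
        return self.scores @ self.loadings.T + self.mean


def pca(matrix: np.ndarray, n_components: int | None = None,
        standardize: bool = False) -> PCAResult:
    """PCA via singular-value decomposition of the column-centered matrix.

    Sign convention: the largest-magnitude loading of each component is
    positive, which makes results deterministic across SVD backends.
    Pass ``standardize=True`` to Z-score internally first.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("pca needs a 2-D matrix with at least 2 rows")
    if standardize:
        x = zscore(x)
    max_comp = min(x.shape[0] - 1, x.shape[1])
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, cols)={max_comp}"
        )
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    ratios = s**2 / total_var if total_var > 0 else np.zeros_like(s)

    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-|loading| positive per component
    for k in range(n_components):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    return PCAResult(
        scores=u * s,
        loadings=vt.T,
        explained_variance_ratio=ratios[:n_components],
        n_components=n_components,
        mean=mean,
    )


def composition_matrix(tables: Iterable[CompositionTable],
                       drop_empty: bool = True) -> pd.DataFrame:
    """Samples x labels feature matrix from composition tables.

    Absent labels fill with 0; columns that are zero across all samples
    are dropped before PCA (they carry no variance).
    """
    tables = list(tables)
    labels = sorted(set().union(*(t.entries for t in tables)))
    df = pd.DataFrame(
        [[t.entries.get(l, 0.0) for l in labels] for t in tables],
        index=[t.sample_id for t in tables],
        columns=labels,
    )
    if drop_empty:
        df = df.loc[:, (df != 0).any(axis=0)]
    return df


def plot_scores(result: PCAResult, labels: Sequence[str], path,
                components: tuple[int, int] = (0, 1)) -> None:
    """Save a 2-D score plot (optional matplotlib output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = components
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab in sorted(set(labels)):
        sel = [k for k, l in enumerate(labels) if l == lab]
        ax.scatter(result.scores[sel, i], result.scores[sel, j], label=lab, s=40)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC{i + 1} ({100 * evr[i]:.0f}%)")
    ax.set_ylabel(f"PC{j + 1} ({100 * evr[j]:.0f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
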