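"""Synthetic GC chromatogram generator with ground-truth bookkeeping.

Every pipeline stage is testable against this module: it renders
Gaussian peaks at library retention times with areas following the
detector response laws (FID: moles x response factor; TIC: moles x
nominal mass, optionally suppressed for anhydro sugars to emulate their
poor electron-impact ionization), adds seeded Gaussian noise and linear
baseline drift, emits diagnostic extracted-ion traces for co-eluting
symmetric pairs, and builds multi-species replicate datasets together
with their true compositions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from . import linkage
from .chromatogram import Chromatogram, RtLibrary

__all__ = [
    "SimulationSpec",
    "SimulatedSample",
    "SimulatedDataset",
    "simulate_chromatogram",
    "simulate_sample",
    "simulate_pair_eics",
    "simulate_dataset",
    "true_areas",
    "default_species_profiles",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one synthetic chromatogram.

    ``composition`` maps linkage labels to mol fractions (must sum to
    1; use :meth:`from_percent` for percent tables).  ``sigma`` is the
    Gaussian peak SD in minutes; ``anhydro_tic_suppression`` scales TIC
    areas of anhydro-sugar PMAAs (1.0 = no detector discrepancy; the
    default 0.5 is an illustrative choice, the true magnitude of the
    under-response being unquantified).  The seed fixes the output
    bitwise.
    """

    composition: Mapping[str, float]
    detector: str = "FID"
    sigma: float = 0.05
    total_moles: float = 100.0
    anhydro_tic_suppression: float = 0.5
    noise_sd: float = 0.0
    baseline_slope: float = 0.0
    seed: int = 0
    time_start: float = 20.0
    time_end: float = 115.0
    dt: float = 0.01
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mol fractions must sum to 1, got {total}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.anhydro_tic_suppression <= 1.0:
            raise ValueError("anhydro_tic_suppression must be in (0, 1]")

    @classmethod
    def from_percent(cls, percent: Mapping[str, float], **kwargs) -> "SimulationSpec":
        total = float(sum(percent.values()))
        return cls(composition={k: v / total for k, v in percent.items()}, **kwargs)

    @classmethod
    def from_json(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            raw = json.load(fh)
        if "seed" not in raw:
            raise ValueError("simulation spec files must state a seed")
        return cls.from_percent(raw.pop("composition"), **raw)


def _time_axis(spec: SimulationSpec) -> np.ndarray:
    n = int(round((spec.time_end - spec.time_start) / spec.dt)) + 1
    return spec.time_start + spec.dt * np.arange(n)


def _response_area(label: str, moles: float, spec: SimulationSpec,
                   rf_lib: linkage.ResponseFactorLibrary) -> float:
    link = linkage.parse_linkage(label)
    if spec.detector == "FID":
        return moles * rf_lib.factor(link)
    if spec.detector == "TIC":
        mass = linkage.derivatize(link, deuterate=link.anhydro_bridge is None).nominal_mass
        suppress = spec.anhydro_tic_suppression if link.anhydro_bridge else 1.0
        return moles * mass * suppress
    raise ValueError(f"cannot simulate detector {spec.detector!r}")


def true_areas(spec: SimulationSpec,
               rt_lib: RtLibrary | None = None,
               rf_lib: linkage.ResponseFactorLibrary | None = None
               ) -> dict[str, float]:
    """Noise-free per-label areas implied by the response law (the oracle)."""
    rf_lib = rf_lib or linkage.ResponseFactorLibrary.default()
    return {
        label: _response_area(label, frac * spec.total_moles, spec, rf_lib)
        for label, frac in spec.composition.items()
    }


def _gaussian(t: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    return area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
        -0.5 * ((t - center) / sigma) ** 2
    )


def _render(spec: SimulationSpec, rt_lib: RtLibrary,
            rf_lib: linkage.ResponseFactorLibrary,
            rng: np.random.Generator) -> Chromatogram:
    t = _time_axis(spec)
    y = np.zeros_like(t)
    for label, frac in spec.composition.items():
        if label not in rt_lib.entries:
            raise KeyError(f"label {label!r} missing from retention-time library")
        area = _response_area(label, frac * spec.total_moles, spec, rf_lib)
        y += _gaussian(t, rt_lib.rt(label), spec.sigma, area)
    if spec.baseline_slope:
        y += spec.baseline_slope * (t - t[0])
    if spec.noise_sd > 0:
        y += rng.normal(0.0, spec.noise_sd, size=t.size)
    return Chromatogram(times=t, intensities=y, detector=spec.detector,
                        sample_id=spec.sample_id)


def simulate_chromatogram(spec: SimulationSpec,
                          rt_lib: RtLibrary | None = None,
                          rf_lib: linkage.ResponseFactorLibrary | None = None
                          ) -> Chromatogram:
    """Render one chromatogram; deterministic under the spec's seed."""
    rt_lib = rt_lib or RtLibrary.default()
    rf_lib = rf_lib or linkage.ResponseFactorLibrary.default()
    rng = np.random.default_rng(spec.seed)
    return _render(spec, rt_lib, rf_lib, rng)


def simulate_sample(spec: SimulationSpec,
                    rt_lib: RtLibrary | None = None,
                    rf_lib: linkage.ResponseFactorLibrary | None = None
                    ) -> tuple[Chromatogram, dict[str, dict[str, Chromatogram]]]:
    """Render a chromatogram plus diagnostic EICs for its co-eluting pairs.

    For every co-elution group with members in the composition, one EIC
    per member is rendered at the shared retention time, with area
    proportional to that member's molar amount (symmetric pairs share
    mirrored fragment chemistry, so equal diagnostic-ion response per
    mole is assumed).  EICs carry the discriminating fragment m/z chosen
    by the chemical model.
    """
    rt_lib = rt_lib or RtLibrary.default()
    rf_lib = rf_lib or linkage.ResponseFactorLibrary.default()
    seq = np.random.SeedSequence(spec.seed)
    rng_main, rng_eic = (np.random.default_rng(s) for s in seq.spawn(2))
    chrom = _render(spec, rt_lib, rf_lib, rng_main)

    eics: dict[str, dict[str, Chromatogram]] = {}
    t = _time_axis(spec)
    for gid, members in rt_lib.coelution_groups.items():
        present = [m for m in members if m in spec.composition]
        if not present:
            continue
        codes = [linkage.parse_linkage(m) for m in members]
        ions = linkage.diagnostic_ions(codes[0], codes[1])
        group: dict[str, Chromatogram] = {}
        for member in members:
            moles = spec.composition.get(member, 0.0) * spec.total_moles
            y = _gaussian(t, rt_lib.rt(member), spec.sigma, moles)
            if spec.noise_sd > 0:
                y = y + rng_eic.normal(0.0, spec.noise_sd, size=t.size)
            group[member] = Chromatogram(
                times=t, intensities=y, detector="EIC",
                sample_id=spec.sample_id, eic_mz=ions[member],
            )
        eics[gid] = group
    return chrom, eics


def simulate_pair_eics(pair: tuple[str, str], molar_ratio: tuple[float, float],
                       shared_rt: float, spec: SimulationSpec,
                       rf_lib: linkage.ResponseFactorLibrary | None = None
                       ) -> tuple[Chromatogram, dict[str, Chromatogram]]:
    """One co-eluting composite peak plus the pair's diagnostic EICs.

    ``molar_ratio`` gives the two members' molar proportions (e.g.
    (3, 1)); the composite peak on the requested detector carries the
    response-weighted total area, while each EIC area is proportional to
    its member's moles.  A 0 share yields an empty (flat) EIC.
    """
    a, b = (linkage.parse_linkage(p) for p in pair)
    if not linkage.is_symmetric_pair(a, b):
        raise ValueError(f"{pair[0]} and {pair[1]} are not a symmetric pair")
    rf_lib = rf_lib or linkage.ResponseFactorLibrary.default()
    ra, rb = molar_ratio
    if ra < 0 or rb < 0 or ra + rb == 0:
        raise ValueError("molar_ratio parts must be non-negative, not both zero")
    moles = {
        pair[0]: spec.total_moles * ra / (ra + rb),
        pair[1]: spec.total_moles * rb / (ra + rb),
    }
    t = _time_axis(spec)
    total_area = sum(
        _response_area(lab, m, spec, rf_lib) for lab, m in moles.items()
    )
    rng = np.random.default_rng(spec.seed)
    y = _gaussian(t, shared_rt, spec.sigma, total_area)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=t.size)
    chrom = Chromatogram(times=t, intensities=y, detector=spec.detector,
                         sample_id=spec.sample_id)

    ions = linkage.diagnostic_ions(a, b)
    eics = {
        lab: Chromatogram(
            times=t,
            intensities=_gaussian(t, shared_rt, spec.sigma, m),
            detector="EIC", sample_id=spec.sample_id, eic_mz=ions[lab],
        )
        for lab, m in moles.items()
    }
    return chrom, eics


# ---------------------------------------------------------------------------
# Datasets

@dataclass
class SimulatedSample:
    sample_id: str
    species: str
    replicate: int
    detector: str
    chromatogram: Chromatogram
    eics: dict[str, dict[str, Chromatogram]]
    truth: dict[str, float]  # true mol percent per label


@dataclass
class SimulatedDataset:
    samples: list[SimulatedSample]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            if s.detector != self.samples[0].detector:
                continue  # truth is detector-independent; keep one copy
            for label, pct in s.truth.items():
                rows.append({
                    "sample_id": s.sample_id, "species": s.species,
                    "replicate": s.replicate, "label": label,
                    "true_mol_percent": pct,
                })
        return pd.DataFrame(rows)


def default_species_profiles() -> dict[str, dict[str, float]]:
    """The shipped six-species linkage profiles (percent, each sums to 100)."""
    with resources.files("pmaalink.data").joinpath("species_profiles.json").open() as fh:
        raw = json.load(fh)
    return {k: dict(v) for k, v in raw["profiles"].items()}


def simulate_dataset(species_profiles: Mapping[str, Mapping[str, float]] | None = None,
                     replicates: int = 2,
                     within_noise: float = 0.0006,
                     seed: int = 0,
                     detectors: tuple[str, ...] = ("FID", "TIC"),
                     base_spec: SimulationSpec | None = None,
                     rt_lib: RtLibrary | None = None,
                     rf_lib: linkage.ResponseFactorLibrary | None = None
                     ) -> SimulatedDataset:
    """Simulate a replicate design of chromatograms with truth tables.

    Replicate compositions are Dirichlet perturbations of each species
    profile with concentration 1/``within_noise`` (the default gives a
    replicate SD of roughly one percentage point on a 20% component,
    emulating the repeatability of duplicate derivatizations);
    ``within_noise=0`` reproduces the profile exactly.
    """
    if species_profiles is None:
        species_profiles = default_species_profiles()
    if len(species_profiles) < 2:
        raise ValueError("need at least two species profiles")
    if replicates < 1:
        raise ValueError("replicate count must be >= 1")
    rt_lib = rt_lib or RtLibrary.default()
    rf_lib = rf_lib or linkage.ResponseFactorLibrary.default()
    if base_spec is None:
        base_spec = SimulationSpec(composition={"4-Glcp": 1.0})

    seq = np.random.SeedSequence(seed)
    samples: list[SimulatedSample] = []
    for species, profile in species_profiles.items():
        labels = sorted(profile)
        fracs = np.array([profile[l] for l in labels], dtype=float)
        fracs = fracs / fracs.sum()
        for rep in range(1, replicates + 1):
            child = seq.spawn(1)[0]
            rng = np.random.default_rng(child)
            if within_noise > 0:
                perturbed = rng.dirichlet(fracs / within_noise)
            else:
                perturbed = fracs
            comp = {l: float(f) for l, f in zip(labels, perturbed)}
            sid = f"{species.replace(' ', '_')}_r{rep}"
            truth = {l: 100.0 * f for l, f in comp.items()}
            for detector in detectors:
                spec = replace(
                    base_spec, composition=comp, detector=detector,
                    sample_id=sid,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                chrom, eics = simulate_sample(spec, rt_lib, rf_lib)
                samples.append(SimulatedSample(
                    sample_id=sid, species=species, replicate=rep,
                    detector=detector, chromatogram=chrom, eics=eics,
                    truth=truth,
                ))
    return SimulatedDataset(samples=samples)
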