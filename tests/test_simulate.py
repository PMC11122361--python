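"""Simulator response laws, determinism, datasets, and pipeline round trips."""

import warnings

import numpy as np
import pytest

from pmaalink.chromatogram import detect_peaks, integrate_peak
from pmaalink.pipeline import quantify_sample
from pmaalink.quantify import compare_detectors, split_shared_peak
from pmaalink.simulate import (
    SimulationSpec,
    default_species_profiles,
    simulate_chromatogram,
    simulate_dataset,
    simulate_pair_eics,
    simulate_sample,
    true_areas,
)


# ---------------------------------------------------------------------------
# Response laws

def test_fid_area_ratio_follows_response_factors(rf_lib):
    spec = SimulationSpec(composition={"4-AnGalp": 0.5, "3-Galp": 0.5},
                          detector="FID", seed=0)
    chrom = simulate_chromatogram(spec)
    peaks = detect_peaks(chrom)
    assert len(peaks) == 2
    a_an, a_gal = (integrate_peak(chrom, p, baseline="none") for p in peaks)
    assert a_an / a_gal == pytest.approx(0.49 / 0.74, rel=1e-3)


def test_tic_without_suppression_proportional_to_moles_times_mass():
    spec = SimulationSpec(composition={"4-AnGalp": 0.25, "4-Glcp": 0.75},
                          detector="TIC", anhydro_tic_suppression=1.0, seed=0)
    areas = true_areas(spec)
    # masses: 304 (anhydro, non-deuterated) and 351 (deuterated)
    assert areas["4-AnGalp"] / areas["4-Glcp"] == pytest.approx(
        (0.25 * 304) / (0.75 * 351))


def test_suppression_scales_only_anhydro_tic_areas():
    kw = dict(composition={"4-AnGalp": 0.5, "4-Glcp": 0.5}, detector="TIC", seed=0)
    full = true_areas(SimulationSpec(anhydro_tic_suppression=1.0, **kw))
    half = true_areas(SimulationSpec(anhydro_tic_suppression=0.5, **kw))
    assert half["4-AnGalp"] == pytest.approx(0.5 * full["4-AnGalp"])
    assert half["4-Glcp"] == pytest.approx(full["4-Glcp"])


def test_same_seed_bitwise_identical():
    spec = SimulationSpec(composition={"3-Galp": 1.0}, noise_sd=2.0,
                          baseline_slope=0.01, seed=11)
    c1 = simulate_chromatogram(spec)
    c2 = simulate_chromatogram(spec)
    assert np.array_equal(c1.intensities, c2.intensities)
    c3 = simulate_chromatogram(SimulationSpec(composition={"3-Galp": 1.0},
                                              noise_sd=2.0, baseline_slope=0.01,
                                              seed=12))
    assert not np.array_equal(c1.intensities, c3.intensities)


def test_composition_must_sum_to_one():
    with pytest.raises(ValueError):
        SimulationSpec(composition={"3-Galp": 0.7})


# ---------------------------------------------------------------------------
# Pair EICs

def test_pair_eics_equal_ratio():
    spec = SimulationSpec(composition={"2-Xylp": 0.5, "4-Xylp": 0.5}, seed=0)
    _, eics = simulate_pair_eics(("2-Xylp", "4-Xylp"), (1, 1), 31.5, spec)
    a = np.trapezoid(eics["2-Xylp"].intensities, eics["2-Xylp"].times)
    b = np.trapezoid(eics["4-Xylp"].intensities, eics["4-Xylp"].times)
    assert a == pytest.approx(b, rel=1e-9)


def test_pair_eics_three_to_one_split_recovers_shares():
    spec = SimulationSpec(composition={"2-Xylp": 0.75, "4-Xylp": 0.25}, seed=0)
    chrom, eics = simulate_pair_eics(("2-Xylp", "4-Xylp"), (3, 1), 31.5, spec)
    (peak,) = detect_peaks(chrom)
    shared = integrate_peak(chrom, peak, baseline="none")
    eic_areas = {
        lab: np.trapezoid(e.intensities, e.times) for lab, e in eics.items()
    }
    shares = split_shared_peak(shared, eic_areas)
    assert shares["2-Xylp"] == pytest.approx(0.75 * shared, rel=1e-6)
    assert shares["4-Xylp"] == pytest.approx(0.25 * shared, rel=1e-6)


def test_pair_eics_degenerate_ratio_gives_empty_eic():
    spec = SimulationSpec(composition={"2-Xylp": 1.0}, seed=0)
    _, eics = simulate_pair_eics(("2-Xylp", "4-Xylp"), (1, 0), 31.5, spec)
    assert np.all(eics["4-Xylp"].intensities == 0.0)


def test_pair_eics_requires_symmetry():
    spec = SimulationSpec(composition={"3-Galp": 1.0}, seed=0)
    with pytest.raises(ValueError):
        simulate_pair_eics(("3-Galp", "4-Galp"), (1, 1), 50.0, spec)


def test_eics_carry_discriminating_mz():
    spec = SimulationSpec(composition={"2-Xylp": 0.5, "4-Xylp": 0.5}, seed=0)
    _, eics = simulate_pair_eics(("2-Xylp", "4-Xylp"), (1, 1), 31.5, spec)
    assert eics["2-Xylp"].eic_mz != eics["4-Xylp"].eic_mz


# ---------------------------------------------------------------------------
# Round trips

def test_noiseless_round_trip_recovers_composition(species_profiles):
    profile = species_profiles["Gracilariopsis sp."]
    spec = SimulationSpec.from_percent(profile, detector="FID", seed=2)
    chrom, eics = simulate_sample(spec)
    table = quantify_sample(chrom, eics=eics, fixed_sigma=spec.sigma)
    for label, frac in spec.composition.items():
        assert table.entries[label] == pytest.approx(100 * frac, abs=0.1), label


def test_detector_consistency_without_suppression(species_profiles):
    profile = species_profiles["Mazzaella splendens"]
    tables = {}
    for detector in ("FID", "TIC"):
        spec = SimulationSpec.from_percent(profile, detector=detector, seed=4,
                                           anhydro_tic_suppression=1.0)
        chrom, eics = simulate_sample(spec)
        tables[detector] = quantify_sample(chrom, eics=eics, fixed_sigma=spec.sigma)
    for label in tables["FID"].entries:
        assert tables["FID"].entries[label] == pytest.approx(
            tables["TIC"].entries[label], abs=0.05), label


def test_fid_exceeds_tic_for_anhydro_when_suppressed(species_profiles):
    profile = species_profiles["Mastocarpus papillatus"]
    tables = {}
    for detector in ("FID", "TIC"):
        spec = SimulationSpec.from_percent(profile, detector=detector, seed=5,
                                           anhydro_tic_suppression=0.5)
        chrom, eics = simulate_sample(spec)
        tables[detector] = quantify_sample(chrom, eics=eics, fixed_sigma=spec.sigma)
    df = compare_detectors(tables["FID"], tables["TIC"]).set_index("label")
    for label in ("4-AnGalp", "2,4-AnGalp"):
        assert df.loc[label, "fid_percent"] > df.loc[label, "tic_percent"]
        assert bool(df.loc[label, "flagged"])


# ---------------------------------------------------------------------------
# Datasets

def test_dataset_bookkeeping(species_profiles):
    ds = simulate_dataset(species_profiles, replicates=2, within_noise=0.001,
                          seed=0)
    assert len(ds.samples) == 6 * 2 * 2  # species x replicates x detectors
    fid = [s for s in ds.samples if s.detector == "FID"]
    assert len(fid) == 12
    truth = ds.truth_frame()
    sums = truth.groupby("sample_id")["true_mol_percent"].sum()
    assert np.allclose(sums, 100.0)


def test_zero_within_noise_gives_identical_replicates(species_profiles):
    two = dict(list(species_profiles.items())[:2])
    ds = simulate_dataset(two, replicates=2, within_noise=0.0, seed=0,
                          detectors=("FID",))
    by_species = {}
    for s in ds.samples:
        by_species.setdefault(s.species, []).append(s.truth)
    for truths in by_species.values():
        assert truths[0] == truths[1]


def test_dataset_validation(species_profiles):
    with pytest.raises(ValueError):
        simulate_dataset({"only one": {"4-Glcp": 100.0}})
    with pytest.raises(ValueError):
        simulate_dataset(species_profiles, replicates=0)


def test_dataset_round_trip_within_tolerance(species_profiles):
    two = {k: species_profiles[k] for k in ("Gracilariopsis sp.",
                                            "Mastocarpus papillatus")}
    ds = simulate_dataset(two, replicates=1, within_noise=0.001, seed=3,
                          detectors=("FID",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in ds.samples:
            table = quantify_sample(s.chromatogram, eics=s.eics, fixed_sigma=0.05)
            for label, pct in s.truth.items():
                assert table.entries.get(label, 0.0) == pytest.approx(pct, abs=0.1)
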