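# Methods

## The measurement being modelled

Methylation (glycosidic-linkage) analysis permethylates the free
hydroxyls of a polysaccharide, hydrolyses it, reduces the released
partially methylated monosaccharides to alditols, and peracetylates
them.  In the resulting PMAA (partially methylated alditol acetate),
methyl ethers mark hydroxyls that were free in the polymer, while
acetates mark the anomeric carbon, the ring-closure carbon and every
glycosidically linked position.  Red-seaweed cell walls add two
complications this package models explicitly:

1. **Two reduction routes.**  Non-anhydro sugars go through NaBD4
   reduction and carry one deuterium at C-1; 3,6-anhydro-galactose
   survives only the reductive-hydrolysis route (4-methylmorpholine
   borane), which does not label.  TIC quantitation therefore uses
   deuterated nominal masses for non-anhydro PMAAs and plain masses for
   anhydro PMAAs.
2. **Chain-reversal symmetric pairs.**  The PMAAs of 2-Xylp/4-Xylp and
   2,3,6-Galp/2,4,6-Galp are mirror images under alditol-chain reversal:
   chromatographically identical, and spectrally identical *unless* the
   C-1 deuterium breaks the symmetry.  The pair shares one peak; its
   area is split in proportion to the areas of one discriminating
   (label-bearing) extracted-ion trace per member.

## Chemical model

- **Formula/mass.**  Nominal (integer) masses throughout: alditol
  backbone, +14 per methyl ether, +42 per acetyl ester, −18 per anhydro
  bridge, +1 for the C-1 deuterium.  Nominal masses are what the
  area/mass TIC quantitation divides by; isotopic fine structure is
  irrelevant at that resolution.  Every shipped derivative is checked in
  the tests against an independent atom-by-atom composition oracle
  (e.g. 351 for deuterated 4-Glcp PMAA, 279 for t-Xylp, 304 for
  4-AnGalp).
- **Fragments.**  The EI model enumerates primary fragments only: each
  backbone C–C cleavage yields the two retained sides with their
  substituents, as even-electron cations, with no hydrogen transfer and
  no secondary AcOH/MeOH losses.  This is sufficient to select
  label-discriminating diagnostic ions for the symmetric pairs (the
  chosen ion per member is the largest fragment mass absent from its
  partner's fragment set — a heuristic, flagged as such, since no
  authoritative per-pair ion list is modelled).  It is *not* a spectrum
  simulator.
- **Response factors.**  FID molar response factors are curated data
  (JSON), keyed by canonical label.  The three anchored values are
  3-Galp 0.74, 4-AnGalp 0.49 (derivable from an equimolar agarose
  standard against the 3-Galp reference) and 2,4-AnGalp 0.54 (0.49 +
  0.05 for the acetyl-for-methyl substitution at O-2).  The remaining
  entries extend per-sugar-class terminal baselines (hexose 0.69,
  pentose 0.59, deoxyhexose 0.66) by +0.05 per linked position, which
  keeps the whole table consistent with the shipped increment rule.
  Unknown labels raise; there is deliberately no silent 1.0 default,
  because a unit factor would bias every composition it touches.
  Convention: **moles ∝ area / factor** — the only direction consistent
  with deriving 0.49 from an equimolar standard whose anhydro peak is
  the smaller one.

## Chromatogram processing

- **Detection** uses Savitzky–Golay smoothing (window 7, order 2) and
  `scipy.signal.find_peaks` with height and prominence thresholds
  defaulting to 3× a robust noise estimate (median absolute first
  difference, scaled for the smoothing gain).  The 3× default balances
  two failure modes measured on simulated data: lower thresholds let
  baseline noise maxima fall inside assignment windows of absent
  analytes (phantom assignments that bias every true share downward
  after normalization), higher thresholds start missing ~1% peaks
  whose apex S/N is only ≈2.  A minimum peak separation of 0.35 min
  (well below the ≥1.4 min spacing of the retention-time library, well
  above its ±0.15 min assignment tolerance) prevents flank noise from
  registering as second peaks and triggering spurious ambiguity errors.
- **Bounds** default to apex ± 4σ with σ from the smoothed half-height
  width, clipped at the valley toward any neighbouring peak;
  valley-to-valley bounds are available (`bound_mode="valley"`) but are
  not the default because on well-separated GC peaks they span long
  baseline stretches whose noise dominates minor-peak areas.  When the
  method's peak width is known (`fixed_sigma`), assigned peaks are
  integrated over windows centered at the *library* retention time
  rather than the detected apex: an apex-centered window sits wherever
  smoothed noise happens to peak and collects a small positive area
  bias on low peaks; a noise-independent center removes it.  This
  targeted mode presumes calibrated retention times, which holds for
  simulated data and for RT-locked methods.
- **Integration** is trapezoidal above an optional linear baseline
  anchored at 5-sample local medians around each bound (median anchors
  keep single-point noise from tilting the baseline); areas are clipped
  at zero.
- **Assignment** matches each peak to the nearest library entry within
  its tolerance (±0.15 min default).  Peaks matching a co-elution group
  are marked shared; two peaks claiming one label raise an ambiguity
  error rather than guessing.

## Quantitation and roll-ups

Compositions are normalized to 100% and carry per-label provenance
(direct peak vs split share).  Entries below 0.5% are flagged "minor"
but never dropped.  Replicate experiments are quantified independently
and summarized as mean ± SD (ddof = 1).  Detector comparison reports
FID%/TIC% per label and flags ratios above 1.2, the signature of the
anhydro under-response in the total-ion trace.

Polysaccharide estimation is an ordered rule table (user-editable
JSON) over a shared pool of linkage percentages: Floridean starch =
4.8 × the 4,6-Glcp branch-point share (one branch per 4.8 residues),
drawing the 3.8× backbone complement from the 4-Glcp pool, floored at
what is available; cellulose = remaining 4-Glcp; agarose = 2 ×
min(4-AnGalp, 3-Galp) consuming equal shares of both, so excess
3-Galp falls to "other galactans" rather than inflating agarose;
mixed-linkage xylan = 3- + 4- + 2,4- + 3,4-Xylp; a residual bucket
absorbs the rest, so the output always sums to 100.  Carrageenan
repeat-unit inference (κ/ι/λ/µ pairing hypotheses) is deliberately not
computed: linkage data carry no sequence information.

## Chemometrics

Chromatograms are made commensurable by dividing both axes by the apex
coordinates of the 4-Glcp peak (present in every sample as the
cellulose marker), truncated to the 25–110 min window, then linearly
interpolated onto a uniform relative-time grid (2000 points by
default; no smoothing).  Columns are Z-scored with the **population
(n) denominator** — fixed and documented for reproducibility —
zero-variance columns are zeroed with a warning, and PCA is the SVD of
the column-centered matrix with a deterministic sign convention (the
largest-magnitude loading of each component is positive).  Linkage
tables go through the identical Z-score + PCA route with labels as
variables.  The tests cross-check the SVD route against scikit-learn's
PCA on random matrices.

## Simulator: what it emulates, and what it does not

Peaks are strictly Gaussian (σ = 0.05 min) at library retention times;
FID areas are moles × factor, TIC areas are moles × nominal mass ×
an anhydro suppression factor (default 0.5 — an illustrative,
clearly-labelled choice: the real magnitude of the anhydro EI
under-response is not quantified, only its direction).  Noise is
additive i.i.d. Gaussian plus optional linear baseline drift; every
trace is bitwise reproducible from its seed.  The retention-time
library is invented (monotone, plausibly ordered) and claims no match
to any real column.

Replicate datasets perturb each species profile with a Dirichlet draw
at concentration 1/`within_noise`; the default (0.0006, κ ≈ 1667)
gives a replicate SD of about one percentage point on a 20% component,
emulating the good repeatability of duplicate derivatizations.  The
six shipped species profiles anchor the prominent published values for
these taxa and fill unreported minor linkages so each sums to 100;
they are simulator ground truths, not measurements.

Passing the synthetic-recovery tests therefore demonstrates that the
*computational* chain — detection, integration, splitting, response
laws, roll-ups, PCA — is self-consistent and unbiased under the stated
noise model.  It says nothing about peak tailing, co-elution beyond
the symmetric pairs, baseline artifacts, derivatization losses or
ionization physics of real instruments, and no claim is made of
reproducing any instrument-derived composition table or PCA variance
percentage, which depend on raw data not shipped here.

## Numerical choices

- Shared-peak splitting conserves the composite area **exactly** in
  floating point (a few-ulp neighbourhood search fixes the
  `x + (s−x) ≠ s` rounding case).
- Composition tables renormalize to 100 on construction; sums are
  asserted to 1e−6 in the tests.
- Problem sizes: simulated traces span 20–115 min at 0.01 min sampling
  (9501 points); the statistical recovery property uses 100 seeds at
  noise SD = 1% of the tallest peak; PCA designs use 6 species × 2
  replicates.
- Degenerate inputs fail loudly: empty chromatograms, non-monotone
  time axes, zero reference areas, both-zero EIC splits, missing
  response factors and missing anchors all have dedicated exceptions.

## Known limitations

- No peak tailing or general deconvolution; overlapped peaks other
  than the modelled symmetric pairs are out of scope.
- The fragment model ignores secondary losses, so predicted diagnostic
  ions may differ from the ions an analyst would pick from full
  spectra.
- Response factors for PMAAs outside the shipped table must be
  supplied by the user; the increment rule covers only O-2
  substitution.
- Absolute configuration (D/L), uronic acids, amino sugars and
  sulfation-site inference are not modelled.
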