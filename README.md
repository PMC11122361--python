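# pmaalink

Glycosidic-linkage analysis of red-seaweed polysaccharides from
GC-FID/GC-MS chromatograms of partially methylated alditol acetates
(PMAAs).

Methylation analysis converts every sugar residue of a polysaccharide
into a volatile PMAA whose methyl/acetyl substitution pattern encodes
which hydroxyls were free and which carried glycosidic bonds in the
polymer.  For unfractionated red-seaweed cell walls — sulfated
galactans (agarose, carrageenans) with their characteristic
3,6-anhydro-galactose, mixed-linkage xylan, cellulose and Floridean
starch — this package implements the computational half of that
workflow:

- **Chemical model** (`pmaalink.linkage`): parse linkage shorthand
  (`4-Glcp`, `t-Xylp`, `2,4-AnGalp`), derive each PMAA's substitution
  pattern, molecular formula and nominal mass, predict primary EI
  fragments, detect chain-reversal symmetric pairs (2-Xylp/4-Xylp,
  2,3,6-Galp/2,4,6-Galp) that co-elute and are distinguishable only via
  the C-1 deuterium label, and serve FID response factors.
- **Chromatogram handling** (`pmaalink.chromatogram`): two-column CSV
  I/O, peak detection and trapezoidal integration, retention-time
  assignment with co-elution groups (plus an optional mzML adapter).
- **Quantitation** (`pmaalink.quantify`): relative molar compositions
  under the two detector response laws — FID, `mol ∝ area / response
  factor` with effective-carbon-number factors (3-Galp 0.74, 4-AnGalp
  0.49, 2,4-AnGalp 0.54 via the +0.05 O-2 acetyl rule); TIC, `mol ∝
  area / nominal mass`.  Shared symmetric-pair peaks are split by their
  diagnostic extracted-ion ratios; response factors can be re-derived
  from standards (e.g. equimolar agarose).
- **Roll-ups** (`pmaalink.composition`): monosaccharide sums,
  rule-based polysaccharide estimates (Floridean starch via the 4.8
  average degree of branching of its 4,6-Glcp branch points, cellulose,
  agarose by min-pairing 4-AnGalp with 3-Galp, mixed-linkage xylan),
  and diagnostic ratios (4-Xylp:3-Xylp, 3-Galp:4-AnGalp).
- **Chemometrics** (`pmaalink.chemometrics`): chromatogram
  normalization to the 4-Glcp anchor peak (both axes divided by the
  anchor apex), resampling to a common relative-time grid, Z-score
  standardization and SVD-based PCA.
- **Simulator** (`pmaalink.simulate`): seeded synthetic FID/TIC/EIC
  chromatograms (Gaussian peaks obeying the response laws, optional
  anhydro TIC suppression emulating the poor EI ionization of anhydro
  sugars, noise and baseline drift) plus six-species replicate datasets
  with ground-truth tables, so every pipeline stage is testable without
  instrument data.

## Worked example

Quantify a simulated agarophyte-like sample (40% 3-Galp, 27% 4-AnGalp,
30% 4-Glcp, 1% 2-Xylp, 2% 4-Xylp), including the EIC split of the
co-eluting xylose pair:

```python
from pmaalink.simulate import SimulationSpec, simulate_sample
from pmaalink.pipeline import quantify_sample
from pmaalink.composition import estimate_polysaccharides, linkage_ratio

spec = SimulationSpec.from_percent(
    {"3-Galp": 40, "4-AnGalp": 27, "4-Glcp": 30, "2-Xylp": 1, "4-Xylp": 2},
    detector="FID", sample_id="agarophyte_demo", seed=7)
chrom, eics = simulate_sample(spec)
table = quantify_sample(chrom, eics=eics, fixed_sigma=spec.sigma)
print(table.to_frame(round_to=1).to_string(index=False))
print("3-Galp : 4-AnGalp =", linkage_ratio(table, "3-Galp", "4-AnGalp"))
for name, pct in sorted(estimate_polysaccharides(table).items()):
    print(f"{name:20s} {pct:5.1f}%")
```

prints

```
      sample_id    label detector  mol_percent  minor  provenance
agarophyte_demo   2-Xylp      FID          1.0  False split share
agarophyte_demo   3-Galp      FID         40.0  False direct peak
agarophyte_demo 4-AnGalp      FID         27.0  False direct peak
agarophyte_demo   4-Glcp      FID         30.0  False direct peak
agarophyte_demo   4-Xylp      FID          2.0  False split share
3-Galp : 4-AnGalp = 1.5
agarose               54.0%
cellulose             30.0%
mixed-linkage xylan    2.0%
other galactans       13.0%
residual               1.0%
```

The detector law cancels out exactly on a noiseless round trip: the
recovered mol% equal the simulated composition; the 1.5 ratio is the
excess of 3-Galp over the 1:1 agarose stoichiometry, and min-pairing
puts 2 × 27 = 54% into agarose while the 13-point 3-Galp excess falls
to "other galactans".

The same workflow is scriptable from the shell:

```sh
pmaalink simulate --spec spec.json --out sim/
pmaalink quantify --input sim/demo.FID.csv --out quant/
pmaalink report --compositions quant/demo.FID.composition.csv --out report/
pmaalink chemometrics --mode linkage --input quant/*.composition.csv --out pca/
```

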