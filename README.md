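# biospot

Compound-resolved, bioactivity-based metabolomics for micro-fractionated
LC runs.

## The problem

Finding which compound in a complex extract carries a biological
activity traditionally means iterating fractionation and re-assaying —
slow, and blind to co-eluting compounds. A faster route splits the LC
flow post-column: a small share goes to the mass spectrometer, the rest
is spotted at ~1 Hz onto a wax-patterned paper device (a μPAD) whose
printed circles each capture one second of eluate. Incubating the μPAD
with a luciferase bioreporter strain makes the bioactive fractions glow
(sometimes with annular *halos* around growth-inhibition zones). Because
every spot corresponds to a known retention-time window, the
luminescence image is itself a chromatogram — one recorded in units of
biological activity.

`biospot` implements the dry-lab half of that workflow:

1. **Image analysis** — detect the spot lattice in one or more
   luminescence images (dark, inactive spots get their positions imputed
   from a least-squares lattice fit), measure each spot's mean pixel
   intensity and optional halo radius, combine them into an activity
   score, and normalize by the image median.
2. **Bioactivity chromatogram** — map the serpentine spotting order back
   to retention time (fraction *i* collected over
   \[t₀ + i/f, t₀ + (i+1)/f\] gets the midpoint RT), smooth with a 1-D
   Gaussian kernel (σ = 1 fraction), and pick bioactivity peaks by
   prominence.
3. **LC-MS features** — read the centroided mzML, chain centroids of
   consistent m/z across scans into mass traces, and split traces into
   elution peaks; or import a feature table from an external untargeted
   workflow.
4. **Correlation** — gate feature/peak pairs by retention time
   (|Δt − bias| ≤ window), score each by the Pearson correlation *r*
   between the activity values and the feature's elution profile
   interpolated onto the fraction grid, keep *r* > 0.8, and rank per
   activity peak. Retained features drive an MS2 filter that writes a
   networking-ready mzML.

The statistic at the core is plain Pearson peak-shape correlation

    r = Σ(aᵢ − ā)(xᵢ − x̄) / √( Σ(aᵢ − ā)² · Σ(xᵢ − x̄)² )

computed over the fraction times inside one bioactivity peak, where *aᵢ*
is median-normalized activity and *xᵢ* the (bias-shifted, interpolated)
feature intensity. Co-elution in *time* is necessary but not sufficient;
matching *shape* is what separates the causal compound from bystanders.

A seeded synthetic-fixture generator (`biospot.synthetic`) renders
ground-truthed μPAD images (Gaussian spots on a rotated lattice, halos,
background gradient, noise) and matching mzML runs (Gaussian elution
profiles, decoy features, data-dependent MS2), linked through planted
active compounds — so the whole pipeline is testable without any
instrument data.

## Worked example

Generate a fixture emulating a three-antibiotic validation mixture
(200 fractions at 1 Hz, spotted from 1.00 min, imaged as two 10×10
blocks; three active compounds plus 20 decoy features), then run the
full pipeline:

```bash
biospot fixtures --preset three-antibiotics --seed 7 -o demo/
biospot run demo/block_00.png demo/block_01.png --mzml demo/run.mzML -o demo/out
```

which prints

```
n_spots: 200
n_peaks: 3
n_features: 23
n_retained: 3
n_ms2_exported: 9
```

— all 200 fractions measured, three bioactivity peaks found, 23 LC-MS
features detected (3 planted actives + 20 decoys), and exactly one
feature retained per peak. `demo/out/ranked.csv` holds the candidate
list:

```
activity_peak_apex_rt  feature_id  mz        feature_apex_rt  pearson_r  rank
1.792                  F5          291.1452  1.806            0.9989     1
2.558                  F11         332.1404  2.550            0.9990     1
3.592                  F13         401.1717  3.600            0.9988     1
```

Each planted active compound is the rank-1 candidate of its own
bioactivity peak with r ≈ 0.999; every decoy is rejected by the RT gate
or the 0.8 correlation threshold. `demo/out/ms2_filtered.mzML` contains
only the MS2 scans acquired on those three precursors within their
elution windows — the file you would hand to molecular networking.

The same stages are available piecemeal (`biospot image`, `biospot
chrom`, `biospot features`, `biospot correlate`) and as library
functions; see the module docstrings.

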