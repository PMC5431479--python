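# gliaspat

Quantitative phenotyping of microglia — the CNS's resident immune cells —
from fluorescence whole-mount images, combining image analysis with spatial
point-pattern statistics.

Microglia react to injury by proliferating, migrating, retracting their
processes and enlarging their somata. `gliaspat` turns a labelled
whole-mount (e.g. an Iba-1 stained retina) into a marked spatial point
pattern and quantifies that activation along five axes:

1. **Soma segmentation** — grey-scale attribute (area) opening, an
   octagonal morphological opening to detach processes, a maximum-entropy
   (Kapur) threshold, connected-component particle extraction, and a
   nearest-neighbour-distance gate. Each soma yields area *A*, centroid and
   roundness 4*A*/(π*M*²), with *M* the major axis of the second-moment
   ellipse fit.
2. **Population descriptors** — density (cells/mm²), nearest-neighbour
   distance (NND), the regularity index RI = X̄₍NND₎/δ₍NND₎, and
   percentage-frequency eccentricity profiles of the distance
   d = √((x−a)² + (y−b)²) to the optic nerve head (a, b). A Bland–Altman
   percentage-agreement routine supports validation against manual counts.
3. **Phenotype clustering** — cells pooled across retinas, soma area and
   roundness 90%-winsorized and z-scored, split into 'low'/'high' activity
   phenotypes by Hartigan–Wong k-means (k = 2); the larger-soma cluster is
   'high' by definition, never by cluster index.
4. **Territory analysis** — Ripley's K(r), its variance-stabilized
   L(r) = √(K/π) and centred H(r) = L(r) − r in the retina's polygonal
   window, with translation (default) or border edge correction; under
   complete spatial randomness K(r) = πr², and H < 0 flags the dispersal
   characteristic of territorial microglia. The territory ("domain" or
   exclusion) radius is read from the first non-artefactual minimum of
   H(r); self- (K_ii, K_jj) and cross-K (K_ij) repeat the analysis per
   phenotype.
5. **Segregation testing** — Dixon's nearest-neighbour contingency-table
   χ² test: within-type z-scores z_ii, z_jj and the overall 2-df statistic
   C per retina, summed with their degrees of freedom across retinas into
   a process-wide test.

A synthetic-data module generates Poisson (CSR) and Matérn type-II
hard-core patterns with optional clustered binary marks, and renders them
to 8-bit images with ground truth, so the entire pipeline is testable
without microscopy data.

## Worked example

Simulate a territorial ("hard-core", exclusion radius 45 μm) pattern with
contagiously clustered activity marks in a 2×2 mm window, then analyse it:

```sh
gliaspat simulate --process hardcore --intensity 300 --hardcore-radius 45 \
    --marks clustered --seed 7 --out points.csv --boundary-out boundary.csv
gliaspat stats points.csv boundary.csv --onh 1000 1000 --out stats.csv
gliaspat ripley points.csv boundary.csv --out ripley.csv
gliaspat dixon points.csv boundary.csv --out dixon.csv
```

which prints (abridged):

```
557 points -> points.csv
retina_id,n_cells,area_mm2,density_per_mm2,nnd_mean_um,nnd_sd_um,regularity_index
synthetic,557,4.0,139.25,60.10,11.37,5.29
domain radius 43.0 μm
aggregate C=51.57 df=2 p=<1e-06
```

Reading the numbers: 139 cells/mm² at a mean NND of 60.1 μm with RI 5.3 —
far above the ≈1.91 of a random (Poisson) pattern, i.e. strongly regular
spacing, as expected for mutually exclusive territories. The H(r) minimum
puts the territory radius at 43 μm, recovering the generator's 45 μm
within the grid/smoothing resolution. Dixon's test rejects random
labelling decisively (C = 51.6, 2 df, p < 10⁻⁶; z_jj = 6.5), detecting the
simulated self-association of 'high'-activity cells.

`gliaspat run-all config.json` runs every stage (segmentation → statistics
→ pooled clustering → Ripley → Dixon, per retina and per treatment group)
from a single JSON config and writes a machine-readable manifest; the same
functionality is available as a library via `gliaspat.pipeline.run_pipeline`.

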