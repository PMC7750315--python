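# pollicolor

Pollinator-vision analysis of floral reflectance with phylogenetic
comparative methods.

The package takes raw corolla and leaf reflectance spectra, a time-calibrated
phylogeny and per-species metadata (pollination mode, ordered environmental
zone) and runs a complete flower-color evolution analysis:

1. **Spectral preprocessing** (`pollicolor.spectra`) — ingestion onto a
   common 1-nm grid, trimming to the insect-vision window (300–700 nm),
   LOESS smoothing (degree 2, tricube weights, span 0.25), averaging by
   individual/species (color morphs kept separate), mean-centering and
   binning into 10 × 40-nm intervals.
2. **Visual models** (`pollicolor.vision`) — quantum catches by trapezoidal
   integration of reflectance × receptor sensitivity × illuminant, von Kries
   adaptation to the mean leaf background; a trichromatic nocturnal hawkmoth
   (λmax 357/450/520 nm, receptor densities 0.1/0.23/0.67) with Maxwell-
   triangle coordinates, receptor-noise-limited chromatic distances (Weber
   fraction 0.1, JND units) and long-wavelength achromatic contrast; a
   categorical tetrachromatic fly model (blowfly/hoverfly) with pale/yellow
   opponency coordinates, four-quadrant categories and Euclidean
   conspicuousness distances. Receptor curves are generated from an
   A1-pigment alpha-band nomogram; measured curves can be supplied.
3. **Color statistics** (`pollicolor.colorstats`) — bootstrapped
   centroid-to-centroid distances with percentile CIs and permutation tests
   of between-group mean distance (add-one Monte-Carlo p).
4. **Ordination** (`pollicolor.pca`) — covariance PCA of the binned,
   row-centered spectra and a phylomorphospace projection via BM ancestral
   states.
5. **Comparative methods** (`pollicolor.phylo`) — ML fits of BM/OU/EB with
   AICc, joint ML ancestral states, Mk (ER/SYM/ARD) fits via the pruning
   algorithm, stochastic character mapping (rejection sampling with a
   uniformization fallback), a Gibbs-sampled Bayesian threshold model for
   ordered environmental zones, and bivariate PGLS correlations between
   zone liabilities and perceptual color vectors under BM or OU.
6. **Synthetic data** (`pollicolor.simulate`) — Yule trees, parametric
   spectral templates (UV-absorbing white, dark carrion-mimic, green leaf),
   BM traits and threshold-trait generators, and a default two-clade
   scenario at the empirical scale (11 species, 4–11 individuals each,
   tree height 8).

## CLI

```sh
pollicolor simulate --seed 1 --out data/            # synthetic inputs
pollicolor preprocess data/spectra.csv --out proc.csv
pollicolor pca proc.csv --out pca_out/
pollicolor vismodel data/spectra.csv --viewer blowfly --out loci.csv
pollicolor colstats data/spectra.csv --metadata data/metadata.csv --out stats.csv
pollicolor ancestral data/tree.nwk --trait pc1.csv --out anc.csv
pollicolor threshold data/tree.nwk --zones zones.csv --out thr.csv
pollicolor pgls data/tree.nwk --x liab.csv --y colorvec.csv --out pgls.csv
pollicolor run-all --synthetic --seed 1 --out run_out/   # all 10 stages
```

`run-all` also accepts `--config cfg.yaml`; CLI flags override config keys.
Every stage writes a tidy CSV and the run ends with a `manifest.json`
recording config hash, seed and stage outputs; reruns with the same config
and seed are byte-identical.

## Bundled data

`src/pollicolor/data/` ships a CIE D65 table (300–700 nm), a low
color-temperature "sunset" irradiance stand-in (2500 K Planck photon
spectrum) and default receptor definitions (`receptors.yaml`). All three are
overridable: illuminants by CSV path, receptor curves via
`load_receptor_set(..., curves=...)`.
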