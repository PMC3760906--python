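# nucshell

Radial positioning analysis of FISH signals in equal-volume concentric
nuclear shells, for studies of nuclear architecture during cell
differentiation (e.g. myoblast → myocyte).

During *in vitro* myogenesis, nuclei become smaller and flatter and
chromosomal centromeres reposition toward the nuclear periphery.  The
standard way to quantify such radial repositioning from 3-D FISH
confocal stacks is to segment each nucleus, divide it into K = 5
co-centric shells of equal volume (shell 1 = innermost), assign each
hybridisation signal to the shell containing it, and compare the
resulting per-chromosome shell distributions between conditions with a
2×K Pearson chi-square test of homogeneity.  Nucleus morphometry
(volume V = N·v<sub>voxel</sub>, flattening a/c of the
inertia-equivalent ellipsoid) is compared with the two-sided
Mann-Whitney U test, after a Shapiro-Wilk check documents that the
samples are non-normal.

`nucshell` implements this pipeline end to end:

- **synthetic data** — ellipsoidal nuclei with condition-dependent size
  and flattening, spots placed with known per-shell probabilities,
  rendering with anisotropic Gaussian PSF, Poisson photon noise and
  Gaussian background, plus two-group triplicate log2 expression
  matrices with spiked ≥2-fold effects; everything carries ground truth.
- **imaging** — Otsu + 26-connected-components nucleus segmentation and
  Laplacian-of-Gaussian spot detection with sub-voxel centroids.
- **radial geometry** — inertia-ellipsoid morphometry, a distance-
  transform (or ellipsoid-radius) radial coordinate, volume-quantile
  equal-volume shells and spot-to-shell assignment.
- **statistics** — chi-square homogeneity, Mann-Whitney U,
  Shapiro-Wilk, exact reconstruction of integer counts from 2-decimal
  percentage tables, fusion index FI = N<sub>d</sub>/N<sub>ud</sub>.
- **expression** — quantile normalisation, per-gene t-test with
  Benjamini-Hochberg adjustment and 2-fold filtering
  (up iff log2FC ≥ 1 and q < 0.01), chromosome tallies of up/down genes.

## Worked example

The package ships the published-style percentage table of centromere
shell distributions for seven chromosomes in myoblasts (24 h) and
myocytes (7 d).  Percentages alone cannot feed a chi-square test, so
`reconstruct_counts` searches for the smallest integer total whose
rounded percentages match the printed row exactly:

```python
>>> from nucshell import reconstruct_counts, chi_square_homogeneity
>>> rec = reconstruct_counts([19.77, 31.40, 30.23, 9.30, 9.30])  # HSA1, 24 h
>>> rec.n, rec.counts.tolist(), rec.exact
(86, [17, 27, 26, 8, 8], True)
>>> rec7d = reconstruct_counts([4.55, 39.77, 31.82, 18.18, 5.68])  # HSA1, 7 d
>>> res = chi_square_homogeneity(rec.counts, rec7d.counts)
>>> round(res.statistic, 3), res.df, round(res.p_value, 4)
(12.492, 4, 0.014)
```

The HSA1 centromere distribution differs significantly between
myoblasts and myocytes (p = 0.014 < 0.05); the shell-1 drop from 19.77%
to 4.55% reflects movement away from the nuclear interior.  Running the
same comparison over all seven chromosomes flags HSA1, HSA3, HSA12,
HSA17 and HSAX as repositioning (p < 0.05) and HSA7 (p = 0.052) and
HSA11 (p = 0.079) as stable.

A full synthetic run from a YAML config:

```sh
nucshell run --config config.yaml --out results/
```

with

```yaml
seed: 11
simulate:
  n_nuclei_per_condition: 50
  shell_probs:
    HSA3:
      myoblast: [0.2568, 0.4459, 0.1486, 0.0676, 0.0811]
      myocyte:  [0.0789, 0.4123, 0.2544, 0.1754, 0.0790]
```

simulates, renders, re-segments and re-measures 100 nuclei, writes
`distributions.tsv`, `morphometry.tsv`, the statistical reports and a
`manifest.json` with the config hash and per-stage counts.  Individual
stages are available as `nucshell simulate | segment | spots | shells |
assign | compare | morphstats | de | chrommap`.

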