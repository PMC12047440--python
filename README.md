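# rnpq

Quantitative analysis of LINE-1 ORF1p ribonucleoprotein (RNP) condensates.

LINE-1 is the only autonomously active human retrotransposon. Its RNA-binding
protein ORF1p forms homotrimers that coat the LINE-1 mRNA into an RNP
condensate, and the condensate acquires DNA-binding activity only once the
RNA is *super-saturated* with protein — more trimers than the RNA's direct
binding sites can hold. `rnpq` implements the analysis stack needed to
quantify that behaviour across four single-molecule and imaging assays, plus
synthetic-data generators with exact ground truth so every estimator is
testable without raw experimental data:

- **`rnpq.massphot`** — mass photometry: contrast-to-mass calibration, the
  fixed 100-bin/8-kDa mass histogram with Savitzky–Golay smoothing, Gaussian
  deconvolution of oligomer species (monomer/trimer/hexamer/higher), the
  cooperative Hill model of RNA-induced hexamer dissociation, and the
  footprint occupancy model (30-nt footprint, 45-nt periodicity) that sets
  the super-saturation threshold.
- **`rnpq.binding`** — fluorescence anisotropy: blank subtraction and
  min–max normalization, Hill fits for K_d, and the exact coupled
  mass-action solution of two nucleic acids competing for one shared site.
- **`rnpq.curtains`** — DNA curtains: binding events per DNA strand with
  per-nM normalization and weighted averaging, two-color colocalization,
  24-bin position histograms against TTTTTAA-motif and A/T-content genome
  tracks with a permutation enrichment test, Kaplan–Meier dwell-time
  survival with bootstrap bands, and kymograms.
- **`rnpq.spots`** — 3D cell imaging: multiscale Laplacian-of-Gaussian spot
  detection, ROI assignment, nuclear/cytoplasmic classification,
  count-matched randomized-spot nulls, per-ROI median normalization with a
  Mann–Whitney comparison, and puncta–chromatin colocalization fractions.
- **`rnpq.simulate`** — seeded generators for all of the above, each
  emitting a ground-truth record alongside the data.

The core models, in the field's notation: Hill saturation
θ(P) = Pʰ/(K_dʰ + Pʰ); hexamer dissociation
p₃(c) = f_min + (f_max − f_min)·cʰ/(K_halfʰ + cʰ) with h > 1 indicating
cooperativity; trimer capacity of an RNA of length L nt,
N(L) = ⌊(L − 30)/45⌋ + 1 for L ≥ 30 (else 0), with saturating monomer
excess 3·N(L); the Kaplan–Meier product-limit estimator
Ŝ(t) = ∏_{tᵢ≤t} (1 − dᵢ/nᵢ) under right censoring at movie end.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run each stage end to end on
synthetic data and write tables to `results/`. For example:

```bash
python analysis/02_mass_deconvolution.py --seed 1
```

prints

```
calibration: slope 1007.3 kDa/contrast, intercept -0.73 kDa
species fractions: {'1': 0.0, '3': 0.303, '6': 0.697, '>6': 0.0} (truth: trimer 0.3, hexamer 0.7)
trimer peak 119.7 kDa -> monomer 39.9 kDa (truth 40)
hexamer dissociation: h = 1.93 +/- 0.18 (truth 2.1), K_half = 53.0 nM
```

Reading this: from 20,000 simulated landing events of a 30% trimer / 70%
hexamer mixture of a 40-kDa monomer, the calibration recovers the true
1000 kDa/contrast slope within 1%; the Gaussian deconvolution recovers the
mixture fractions within half a percentage point and places the trimer peak
at 119.7 kDa, i.e. a 39.9-kDa monomer; and the Hill fit of a
replicate-averaged dissociation titration recovers the cooperative
coefficient within its standard error. The other drivers cover the footprint
model (`01`, capacity 44 and 132-fold ≈ 130-fold saturating excess for the
1970-nt RNA), K_d recovery and competition (`03`), the full curtain analysis
on a λ-length substrate with 12 planted TTTTTAA sites (`04`), and the
randomized-spot colocalization pipeline with its null calibration (`05`).

The same functionality is exposed on the command line via the `rnpq`
umbrella command (`rnpq simulate`, `rnpq mass deconvolve`, `rnpq mass
footprint --length 1970`, `rnpq binding fit`, `rnpq curtains
positions|survival|motifs`, `rnpq run --config cfg.yaml`).

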