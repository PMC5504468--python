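# scalpmap

Cranio-cortical correspondence analysis for the developing infant head.

EEG and fNIRS place sensors on the scalp, so developmental neuroscientists
need to know how reliably scalp positions of the international 10-20/10-10
system predict the underlying cortical macroanatomy while both the brain
and the head are growing rapidly.  `scalpmap` implements the full analysis
chain for this question as a reusable, tested library and CLI:

1. **Virtual 10-20/10-10 positioning** (`scalpmap.montage`) — from the four
   cranial fiducials Nz, Iz, AL, AR on a triangulated scalp mesh, Cz is the
   fixed point of an alternating arc-midpoint construction, and all other
   positions are placed at standard fractions of plane-section scalp curves.
2. **Procrustes shape analysis** (`scalpmap.shape`) — landmark
   configurations are translated to a common centroid, scaled to unit
   centroid size S = sqrt(sum_i ||x_i - x_bar||^2), and rotated by proper
   rotations to a consensus (generalized Procrustes); PCA of the Procrustes
   coordinates yields shape modes whose per-subject scores are regressed on
   age.
3. **Distance-ratio statistics** (`scalpmap.metrics`) — for landmark
   triples (a, b, c), the ratio d(a,b)/d(b,c) (direct, or projected to the
   sagittal/coronal plane) is correlated with age using Pearson r and the
   exact two-tailed p from t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 df.  A
   declining anterior-share ratio means an anterior shift of the middle
   landmark.
4. **Cortical-to-scalp transfer** (`scalpmap.transfer`) — a cortical point
   CP is expressed through the three vectors from the pre-auricular
   midpoint M to its neighboring 10-10 positions,
   `CP - M = a1(L1-M) + a2(L2-M) + a3(L3-M)`,
   the coefficients are re-applied on a template head, and the result is
   back-projected to the template scalp by scaling all three coefficients
   by one common factor.  Per-landmark scatter (Tukey box statistics of
   distances from the centroid) is compared with the montage's
   nearest-neighbor pitch.

Because no infant MRI data ship with the package, `scalpmap.synthetic`
generates a cohort of superellipsoid heads with anisotropic growth
(length > height > width), injected age-dependent landmark drifts, and
landmark noise matched to a 4.87 mm inter-rater distance — every downstream
stage is testable against this known ground truth.  See `docs/methods.md`
for the model and its assumptions.

## Worked example

```sh
scalpmap run --seed 1 --outdir out
```

simulates 16 subjects aged 3-22 months, places their 10-10 montages, and
runs all analyses.  Excerpt of the printed summary:

```
cortex: PC1-4 variance fractions 21.7%, 11.7%, 10.2%, 8.5%
cortex: PC1 score vs age r = +0.930 (p = 0.000, n = 16)

ratio/age correlations (r, p by hemisphere):
     (2-8)/(8-5) L  r = -0.664  p = 0.005
     (2-9)/(9-5) L  r = -0.684  p = 0.003
   (2-12)/(12-5) L  r = -0.655  p = 0.006
   (1-14)/(14-4) L  r = -0.770  p = 0.000

transfer to template sub08: max per-landmark dispersion median = 11.0 mm,
  max upper quartile = 16.6 mm
10-10 nearest-neighbor pitch: median = 19.9 mm (quartiles 17.7 / 20.4 mm)
```

Reading this: the cortical shape space has a leading mode that tracks age;
the negative ratio/age correlations recover the injected anterior drifts of
the precentral/intraparietal junction landmarks (8, 9, 12) and the dorsal
drift of the calcarine landmark (14); and every transferred cortical
landmark scatters far less on the template scalp (medians <= 11 mm) than
the spacing between neighboring 10-10 positions (~20 mm) — the property
that makes the 10-10 system a usable reference frame for infant work.
Full tables are written under `out/` (`shape/`, `ratios/`, `transfer/`).

Other subcommands: `simulate`, `tenten`, `procrustes`, `ratios`,
`transfer`, `validate` (all accept `--seed`, `--config`, `--outdir`; config
files are YAML with keys mirroring `PipelineConfig`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch at the given seed — cohort
simulation, montage placement, Procrustes/PCA with age regression, the
ratio correlation table, and the transfer with dispersion statistics —
prints the summary, and writes the target-value JSON to `--out`.
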