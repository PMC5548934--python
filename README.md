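# satb2phenomics

Computational companions of a clinical–molecular study of de novo *SATB2*
mutations, for researchers in dysmorphology image analysis, variant
interpretation and nuclear-protein dynamics. The package implements, as a
tested library, the four bespoke analyses such a study needs:

1. **Average-face synthesis with asymmetry preservation.** Faces are
   represented by 36-point landmark constellations (8 midline points,
   14 left/right pairs). Each face is aligned to a population target mesh by
   an orientation-preserving least-squares similarity fit over the midline
   points; left–right asymmetry is scored as
   `(L − R) / (L + R)` over the summed per-point Euclidean deviations of the
   paired landmarks, and faces are mirrored so the more deviant side is
   canonical. Composites are built by Delaunay-mesh piecewise-affine warping
   onto the group mean constellation, in-hull illumination normalization,
   then per-subject averaging before the group average — making the
   composite exactly invariant to how many photographs any individual
   contributed.
2. **Variant spectrum over the SATB2 ORF** (733 aa; CUT1 aa 352–437, CUT2
   aa 482–560, homeodomain aa 614–677): consequence classification of
   HGVS-like records, last-exon NMD-escape prediction, truncated-product
   prediction, reflected Gaussian missense-density tracks, and detection of
   variant-depleted intervals.
3. **Recurrent-photobleach (FLIP/FRAP) quantitation**: per-cycle
   mono-exponential recovery fits `F(t) = P − (P − F0)e^{−kt}` and residual
   fluorescence relative to the pre-bleach baseline, summarized per
   construct.
4. **Phenotype tabulation**: recurrent HPO-style term counts, k/n feature
   fractions with observed denominators, and a missense-vs-LoF comparison by
   two-sided exact tests with Benjamini–Hochberg correction.

A synthetic-data module generates every input with known ground truth —
stylized face cohorts with controllable asymmetry and illumination, a
two-state photobleach simulator, variant tables and phenotype matrices — so
all stages are testable without any data downloads. Packaged fixtures
transcribe the study's 19-variant table and 19-individual phenotype matrix.

## Worked example

```sh
python examples/02_variant_spectrum.py
```

prints

```
classes: {'frameshift': 5, 'missense': 8, 'nonsense': 4, 'splice_acceptor': 1, 'splice_donor': 1}
loss-of-function total: 11 of 19
missense by domain: {'CUT1': 6, 'CUT2': 1, 'inter_CUT2_HOX': 1}
DDD cohort fraction: 0.3%  (14/4294)
genomic span: 195.6 kb
p.Glu693Ter: last-exon stop, escapes NMD; truncated product 692 aa, all DNA-binding domains intact: True
```

Of the 19 de novo variants, 11 are predicted to abolish protein production
(nonsense, frameshift or essential-splice); 6 of the 8 missense changes
cluster in the first CUT domain. The one stop-gain in the final exon escapes
nonsense-mediated decay and yields a 692-aa protein retaining all three
DNA-binding domains but lacking the final 41 residues.

The other examples build a face composite from a synthetic asymmetric cohort
(`01_average_faces.py`), recover mobility parameters from a simulated
four-construct photobleach panel (`03_flip_kinetics.py` — the CUT1-analog
construct keeps the highest residual fluorescence at a near-wild-type
recovery rate, the low-mobility analogs lose the most signal and recover
slowest), and tabulate the cohort phenotypes (`04_phenotypes.py` — e.g.
cleft palate 9/19, absent/near-absent speech 16/19, and no significant
missense-vs-LoF differences).

A thin CLI wraps the same functions:

```sh
satb2phenomics demo --seed 7 --out-dir runs/demo
satb2phenomics simulate faces --seed 1 --out-dir faces/
satb2phenomics spectrum --out-dir spec/
```

## Layout

- `src/satb2phenomics/` — library modules: `synthetic_data`, `face_geometry`,
  `face_average`, `variant_spectrum`, `flip_quant`, `phenotype_stats`,
  `pipeline`, `io`, `cli`, with packaged fixtures under `data/`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
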