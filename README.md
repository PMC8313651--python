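# regqa

Automated quality assessment of low-dose-CT → diagnostic-CT image
registration for functional virtual bronchoscopy (fVB).

## The problem

In fVB, PET activity is rendered on the airway surface segmented from a
high-resolution diagnostic CT (hdCT). Because the PET is inherently
co-registered only with the low-dose CT (ldCT) of the PET/CT scan, the
ldCT → hdCT registration is the critical step, and with low-dose inputs it
sometimes fails. Traditionally a radiologist inspects every registered pair;
`regqa` replaces that subjective, labour-intensive check with a calibrated,
fully automatic decision.

Two quality measures are connected:

* **Landmark score D.** An expert marks 25 bronchial landmarks (Boyden
  nomenclature). For the trachea and main bronchi the centre-to-centre
  distance *d* between hdCT and registered ldCT is converted to a
  distance-type quantity *q* ∈ {1, ½, 0} by comparison with 10% / 20% of the
  bronchial diameter (trachea: 1.8 / 3.6 mm, main bronchi: 1.22 / 2.44 mm);
  every smaller bronchus contributes an in-lumen indicator *q* ∈ {1, 0}.
  Then

  D = Σᵢ wᵢ qᵢ,  w = 16 (trachea), 7 (main bronchi), 3 (lobar), 1 (segmental),

  so D ∈ [0, 62]. Missing landmarks (NA = not identifiable in ldCT,
  NULL = absent/obscured in hdCT) contribute 0.

* **Voxel similarity.** Six (dis)similarity parameters of the registered
  pair — Pearson r, mutual information MI, normalised mutual information
  NMI = (H(A)+H(B))/H(A,B), a directed Kullback–Leibler divergence of the
  marginal intensity histograms, L1‑norm and squared L2‑norm — computed on a
  support chosen by a masking mode: **α** (no mask), **β** (one shared
  "functioning lung-mask"), or **γ** (union of the two per-image
  10‑mm‑extended airway masks). MI under γ masking correlates best with D
  (Pearson ρ ≈ 0.60 on the reference cohort).

* **Decision model.** The cohort is split into the 7 lowest-score
  (insufficient) and 15 highest-score (acceptable) registrations; the mean
  γ-masked MI of each subset is bootstrapped (10,000 resamples, 95%
  percentile intervals). A new registration is **accepted** if its MI
  reaches the acceptable interval (≈ [0.28, 0.37] on the reference cohort),
  **rejected** inside or below the insufficient interval (≈ [0.15, 0.22]),
  and **repeated** in the gap between them.

Supporting machinery: HU-window lung segmentation with exterior-air removal,
the hole-free mediastinum-bridged "functioning lung-mask", seeded
region-growing airway segmentation, slice-wise centre-of-gravity airway
skeletonization with short-branch pruning, perpendicular 10-mm PET surface
projection, and a synthetic thorax/landmark phantom generator so the whole
pipeline is testable without patient data.

## Worked example

Score the packaged reference landmark table, calibrate the decision model
and triage a new MI value:

```sh
$ regqa fixtures export --out fx
exported 4 fixtures to fx
$ regqa score --landmarks fx/table1_landmarks.csv --out scores.csv
scored 22 patients -> scores.csv
$ head -3 scores.csv
patient,TB,RMB,LMB,RULB,RMLB,RLLB,RB1,RB2,RB3,RB4,RB5,RB6,RB8,RB9,RB10,LULB,LLLB,LB1/2,LB3,LB4,LB5,LB6,LB8,LB9,LB10,score
p01,16,7,7,3,3,3,NA,1,1,0,1,1,1,0,0,3,3,0,0,NA,NA,1,1,1,1,54
p03,16,7,7,3,3,3,NA,1,1,1,1,1,1,1,1,3,3,1,1,1,1,1,1,1,1,61
```

Each row holds the weighted contribution wᵢqᵢ per landmark (NA where the
landmark was missing) and the final score D: patient p01's trachea was off
by 1.7 mm (≤ 1.8 mm, so q = 1 and contribution 16), and the row sums to
D = 54 of a possible 62.

```sh
$ regqa calibrate --seed 1 --out model.json
accept [0.2787, 0.3707], reject [0.1514, 0.2229] -> model.json
$ regqa classify --mi 0.25 --model model.json
repeat
$ echo $?
3
```

An MI of 0.25 falls between the reject interval (up to ≈ 0.22) and the
accept interval (from ≈ 0.28), so the registration should be repeated; exit
codes (0 accept, 3 repeat, 4 reject) make the triage scriptable. The same
decision is available per image pair through `regqa pipeline --config
cfg.json`, which builds the masks, computes the six parameters and
classifies in one run, and the pieces are importable from Python
(`regqa.similarity_vector`, `regqa.calibrate`, `regqa.classify`, …).

Synthetic data for experimentation:

```sh
regqa phantom --seed 0 --out phantom/      # CT + PET + ground-truth masks
regqa airway skeleton --mask phantom/airway.nii.gz --out skeleton.txt
```

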