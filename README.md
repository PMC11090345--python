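# micclust

Tumor-vs-blood DNA copy-number analysis by maximal information coefficient
(MIC) feature reduction and kernel K-means clustering.

## The problem

In a paired-sample lung-cancer cohort (63 early-stage NSCLC patients, one
tumor and one blood sample each), every chromosome contributes thousands of
per-locus copy-number (CN) scores — e.g. 19,873 loci on chromosome 1 — so
the space in which one would try to separate tumor from blood samples is
enormous, while the two groups overlap heavily (most loci are diploid noise
around CN 2). The analysis implemented here asks: can the handful of loci
where tumor and blood CN are *statistically dependent* carry the
discriminative signal?

Per chromosome, for each locus *j* with paired vectors
(blood<sub>j</sub>, cancer<sub>j</sub>) over the n patients:

```
MIC_j = max { I(blood_j, cancer_j) / log2 min(nblood_j, ncancer_j) }
```

where the maximum runs over all two-way grids with
`nblood_j x ncancer_j < B(n)`, `B(n) = n^0.6`, and
`I = H(blood_j) + H(cancer_j) - H(blood_j, cancer_j)` is the grid mutual
information in bits. MIC is in [0, 1] and captures linear and nonlinear
association. Loci with `MIC > γ` (γ = 0.65, γ = 0.52, or a γ learned so
every chromosome keeps ≥ 2 loci) form the reduced feature set (RFS); the
2n = 126 unlabeled samples are then clustered into K = 2 groups with kernel
K-means (centers live only in kernel space; distances via
`M_ii - 2·mean_{j∈π_k} M_ij + mean_{j,l∈π_k} M_jl`), with Lloyd's K-means
and fuzzy c-means as baselines. Performance against the held-out tissue
labels is scored by the best-of-two-mappings true rate (TR) and normalized
mutual information (NMI), and the entire-vs-reduced comparison by

```
PD  = (TR_RFS - TR_EFS) x 100          (percentage points)
APD = (TR_RFS - TR_EFS) / TR_EFS x 100 (percent of EFS performance)
```

positive values meaning the reduced set clusters better.

The patient data are not public, so the package ships a synthetic
paired-cohort generator (`micclust.simulate`) that plants contiguous
segments of loci where a shared germline aberration makes tumor and blood
CN dependent and a recurrent somatic shift displaces the tumor group —
exactly the structure the MIC selection is supposed to find.

## Worked example

```bash
python analysis/01_simulate_cohorts.py --seed 1   # 5 chromosomes, study sizes
python analysis/02_mic_profiles.py
python analysis/03_select_features.py
python analysis/04_cluster_and_evaluate.py --seed 1
python analysis/05_compare_feature_sets.py
```

With seed 1 the last step prints:

```
chromosome  efs_features  tr_efs  rfs_features  tr_rfs  pd_pct  apd_pct  prop_size_pct
     chr20          5838  0.5079            55  0.6667    15.9       31           0.94
     chr19          2693  0.5238            29  0.6270    10.3       20           1.08
     chr21          3936  0.5556            42  0.6270     7.1       13           1.07
     chr17          4854  0.6032            52  0.6349     3.2        5           1.07
     chr22          2520  0.5714            25  0.5714     0.0        0           0.99

4/5 chromosomes improve with the reduced set
```

Reading chr20's row: clustering on all 5,838 loci is barely better than
chance (TR 0.508), but the 55 loci with MIC > 0.52 — under 1% of the
feature set — raise the true rate to 0.667, a +15.9 point PD and +31% APD.
This mirrors the regime of the real cohort, where the strongest chromosome
gained +29% APD from 2 selected loci and reduced sets spanned 0.06–1.76%
of their chromosomes.

The same pipeline is scriptable (`micclust simulate`, `micclust run
--input DIR --seed N --out DIR`) and usable as a library; see
`micclust.pipeline.RunConfig`.

## Layout

- `src/micclust/` — library: `cohort` (paired-cohort I/O), `mic` (MIC
  engine + oracle), `selection`, `cluster`, `evaluate`, `simulate`,
  `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing under `results/`
- `docs/methods.md` — model, parameters, numerical choices, limitations
- `tests/` — pytest suite (unit, property, acceptance)
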