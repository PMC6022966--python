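# ptdyn — pseudotime dynamics of single-cell expression

`ptdyn` reconstructs how transcriptional programs wax and wane as cells
progress through a biological process, from nothing but an expression
matrix. It was built around the analysis style used for melanoma
short-term cultures profiled by single-cell RNA-seq: small plates
(50–100 cells) of FPKM-quantified transcriptomes, in which progression
from a stromal/extracellular-matrix-high state toward a highly
proliferative state is recovered as a one-dimensional **pseudotime
(PT)** — a unit-free ordering of cells by transcriptional similarity.

The pipeline:

1. **Preprocessing** — cells expressing *neither* housekeeping gene
   (ACTB, GAPDH) are discarded as failed libraries; quantile
   normalization forces an identical value distribution on every cell;
   gene-level scores are per-gene z-scores of log2(FPKM + 1).
2. **Pseudotime** (Wanderlust-style) — an ensemble of k-nearest-neighbor
   graphs over cells (default k = 16; each graph keeps a random l = 8 of
   each cell's neighbors), PT = the across-graph mean of weighted
   shortest-path distances from a start cell, rescaled to [0, 1]. The
   start cell carries the maximal stromal signature; orientation puts
   proliferative cells at high PT. A two-segment fit of PT against cell
   rank detects an initial "slow component" and its breakpoint PT*.
3. **Signature scoring** — per-cell **gene set Z-score (GSZ)**: for a
   set of m genes among N scored genes with per-cell gene scores x_g,

       GSZ = (S − m·μ) / sqrt(m·σ²·(N − m)/(N − 1) + λ),

   with S the set sum and μ, σ² the mean and variance of all gene
   scores in that cell — the exact z-statistic of the observed set sum
   against random same-size sets.
4. **Profiles** — LOESS (tri-cube local polynomial, degree 2, span 0.5)
   smooths PT-ranked GSZ values; profiles are rescaled to a *relative
   activity* in [0, 1]; two profiles paired point-wise along PT form a
   biaxial trajectory.
5. **Association** — a GAM likelihood-ratio test (natural cubic spline
   in PT vs intercept-only, Gaussian likelihood, exact finite-sample
   reference) ranks genes/sets by PT dependence with Benjamini–Hochberg
   FDR control, split into PT-correlated and anti-correlated lists.
6. **Typology** — biaxial trajectories are classified into five modes:
   switch-like, parallel anti-correlated, divergent (across branches),
   orthogonal, and curved, from committed geometric statistics
   (correlation, lag, curvature, plateau fraction).

A synthetic-data generator with a known latent pseudotime and
temporally patterned gene modules (decreasing stromal sigmoid, delayed
proliferation ramp, saturating oxphos, late-rising glycolysis, a
bipolar MITF/AXL pair, opposing active/poised-promoter trends) provides
ground truth for every stage.

## Worked example

```python
import scipy.stats
from ptdyn import (generate_dataset, default_modules, WanderlustPseudotime,
                   PseudotimeAssociation)
from ptdyn.preprocessing import filter_cells, quantile_normalize, log_standardize
from ptdyn.scoring import score_collection

ds = generate_dataset(84, default_modules(), noise_sd=0.5, dropout_rate=0.2,
                      frac_failed_cells=0.05, seed=42)
filtered, removed = filter_cells(ds.matrix)
std = log_standardize(quantile_normalize(filtered))

model = WanderlustPseudotime(std, ds.gmt["stromal"], ds.gmt["cellcycle"])
results = model.fit(seed=1)
print(results.summary())

rho = scipy.stats.spearmanr(results.pt, ds.true_pt.loc[results.pt.index]).statistic
print(f"Spearman(inferred PT, true PT) = {rho:.3f}")

gsz = score_collection(std, ds.gmt)
print(PseudotimeAssociation(gsz, results.pt).fit().summary(top=8))
```

Output:

```
Ensemble k-NN pseudotime
================================================
cells                 80
start cell            cell_0028
oriented              True
k / l / n_graphs      16 / 8 / 20
metric                spearman
seed                  1
------------------------------------------------
slow component        absent
PT*                   --
early / late slope    0.966 / 0.372
2-segment RSS gain    0.202

Spearman(inferred PT, true PT) = 0.919

Pseudotime association (GAM likelihood-ratio test)
============================================================
targets tested        8
spline df             3
significant at fdr <= 0.05    8
------------------------------------------------------------
target                        LR          p        fdr  direction
AXL                       132.92   2.42e-27   1.63e-26  anti-correlated
stromal                   131.81   4.07e-27   1.63e-26  anti-correlated
MITF                      126.54   4.94e-26   1.32e-25  correlated
TssP                       93.88   2.53e-19   5.06e-19  anti-correlated
cellcycle                  90.09   1.51e-18   2.42e-18  correlated
glycolysis                 76.58   8.86e-16   1.18e-15  correlated
TssA                       53.85   3.87e-11   4.42e-11  correlated
oxphos                     27.26   9.24e-06   9.24e-06  correlated
```

Reading it: 4 of 84 simulated cells failed their housekeeping check and
were removed. The inferred ordering agrees with the hidden ground truth
at Spearman ρ = 0.92 despite log-scale noise (SD 0.5) and 20% dropout.
Every synthetic program is strongly PT-dependent; the antagonistic AXL
(falling) and MITF (rising) programs top the two direction lists, and
the late-PT curve is steep enough that no slow component is declared on
this run.

## Command line

Each stage is a subcommand of the `ptdyn` entry point:

```bash
ptdyn simulate  --config sim.json --out data/ --seed 1
ptdyn preprocess --matrix data/matrix.tsv --out norm.tsv
ptdyn score     --matrix norm.tsv --gmt data/modules.gmt --out gsz.tsv
ptdyn pseudotime --matrix norm.tsv --gmt data/modules.gmt --seed 1 --out pt/
ptdyn profiles  --gsz gsz.tsv --pt pt/pt.tsv --out profiles.tsv
ptdyn associate --gsz gsz.tsv --pt pt/pt.tsv --out association.tsv
ptdyn typology  --profiles profiles.tsv --pairs pairs.txt --out typology.tsv
ptdyn run       --config run.json          # everything, with provenance
```

`run` consumes a JSON configuration naming the matrix, the GMT file,
the output directory, the mandatory seed, and any parameter overrides
(`k`, `l`, `n_graphs`, `metric`, `span`, `degree`, `spline_df`,
`fdr_threshold`, `typology_pairs`, ...); every parameter is echoed into
`provenance.json` beside the outputs. Example:

```json
{
  "matrix_path": "data/matrix.tsv",
  "gmt_path": "data/modules.gmt",
  "out_dir": "run1",
  "seed": 1,
  "stromal_set": "stromal",
  "proliferative_set": "cellcycle",
  "typology_pairs": [["oxphos", "cellcycle"], ["TssP", "TssA"]]
}
```

## Layout

```
src/ptdyn/
  synthetic.py      generator: latent PT, shaped modules, dropout, failed cells
  preprocessing.py  housekeeping filter, quantile normalization, z-scores
  scoring.py        gene set Z-score (GSZ)
  pseudotime.py     k-NN ensemble, shortest-path PT, anchoring, PT* breakpoint
  profiles.py       LOESS smoothing, relative activity, biaxial trajectories
  association.py    GAM likelihood-ratio test, BH-FDR ranking
  typology.py       five-mode trajectory classifier
  pipeline.py       configured end-to-end runs with provenance
  cli.py            the ptdyn command line
  io.py             TSV / MatrixMarket / GMT readers and writers
```

See `docs/methods.md` for the modelling assumptions, parameter
defaults, and known limitations.
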