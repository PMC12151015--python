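# Methods

## Problem and model

The quantity modelled is ΔΔG_bind: the change in binding free energy of
a two-partner protein complex caused by one or two point substitutions,
in kcal/mol, with positive values denoting weakened binding. The
predictor is a regression on a fixed 1792-entry feature vector per
mutation:

* **Sequence delta (entries 1–1280).** Per-residue embeddings from a
  transformer protein language model are computed for the wild-type and
  the mutant sequences of both chains, mean-pooled over all positions of
  both partners jointly (length-weighted, no per-chain reweighting), and
  subtracted: pooled mutant minus pooled wild type. The sign convention
  (mutant − wild type) is a free choice; it only flips learned weights.
  For double mutants both substitutions are applied to one mutant
  sequence and embedded in a single pass, so the model can learn
  coupling between sites; no additive single-mutant approximation is
  used. Each chain is embedded in its own forward pass and the backend's
  special/boundary tokens are excluded before pooling; including them
  would shift every pooled vector by a constant sequence-dependent term.
* **Wild-type structural block (entries 1281–1792).** Per-residue
  outputs of an inverse-folding encoder on the wild-type backbone of
  both partners, mean-pooled. Backbone coordinates are nearly identical
  for wild type and point mutants, so only the wild-type structure is
  embedded; consequently this block is constant across all mutations of
  a complex and is computed once and cached.

The regressor is a gradient-boosted decision-tree ensemble with
squared-error loss. Training is deterministic given (data,
hyperparameters, seed) on a single thread.

### Hyperparameters

| parameter | default | notes |
|---|---|---|
| trees | 500 | with learning rate 0.06; equivalent accuracy to 1000 trees at 0.03 on synthetic linear benchmarks at roughly half the single-CPU cost |
| learning rate | 0.06 | |
| max depth / leaves | 6 / 31 | |
| min samples per leaf | 20 | lower it (e.g. 5) for training sets under ~50 rows, otherwise no split is admissible and the ensemble collapses to the training mean |
| seed | 42 | every protocol repeat reseeds both the split and the learner |
| threads | 1 | determinism; increase freely for exploration |

All values are recorded in the saved model bundle and overridable from
the configuration file.

### Embedding providers

The real sequence backend is the 1280-wide, 650M-parameter ESM-2
checkpoint (final-layer per-token representations; the checkpoint id is
configurable and recorded in outputs); the real structural backend is
the 512-wide ESM-IF1 encoder driven through its multichain interface.
Both require optional heavy dependencies and are never needed by the
test suite.

The mock providers advertise the same widths and satisfy the same
alignment contract (one row per residue, in partner order). A mock row
is a pure function of (residue letter, chain, position, seed) with
entries uniform in [−1, 1]: bitwise-reproducible across processes, and
*local* — a point mutation perturbs exactly one row. Real transformer
embeddings are not local, so no test asserts locality for real
backends; locality is exploited only to make unit expectations sharp on
the mock path.

## Data handling

* Two tabular dialects are supported and must be declared (never
  sniffed): a semicolon-separated SKEMPI-like layout with chain letters
  embedded in mutation tokens (`KI15A`), and a plain CSV with an
  optional chain column. Every row either yields a validated record or
  is rejected with a logged file/line/reason.
* Cross-source duplicates keep the in-house measurement; exact
  duplicates within one source collapse to their mean ΔΔG (the mean is
  this package's choice; only the cross-source rule is externally
  prescribed).
* Records whose declared wild-type residue disagrees with the structure
  sequence are rejected and counted, not repaired.
* Residues without a resolved Cα are excluded from both the sequence
  string and the embedding input, keeping sequence and structural rows
  index-aligned. Modified residues with a known parent (MSE → M, etc.)
  are mapped; unknown polymer residues are skipped with a warning;
  waters and ligands are ignored.
* Author numbering is kept as opaque strings (insertion codes ride
  along); no arithmetic is ever done on positions.
* Interface positions use an inclusive Cα–Cα ≤ 4.0 Å cutoff. This is
  deliberately strict for a Cα-based definition; the cutoff is a
  parameter so users can relax it.
* `MutationRecord.ddg_exp` may be `None` only to represent a synthetic
  record awaiting target generation; any present value must be finite.

## Evaluation protocols

* **random_within** — uniform 80/20 split; repeated 3 times for
  single-complex runs, 5 times for whole-dataset runs (fixed published
  seed list 101, 102, … so repeats are reproducible). Each repeat
  resamples both the split and the learner seed. Reported: per-repeat
  Pearson/Spearman/RMSE and mean ± SD across repeats.
* **leave_one_pdb_out** — all records of one complex form the test set;
  the train/test complex-ID intersection is asserted empty on every
  call, not assumed.
* **cross_pdb** — train on one complex, test on another.
* **learning_curve** — records are halved once; the test half is
  frozen; training subsets grow from 5% to 50% of the dataset in 5%
  increments and are nested across fractions (nesting reduces
  point-to-point variance; independent redraws would be equally valid).
* **noise_ceiling** — for measurements with per-point experimental SDs,
  Gaussian replicates are simulated and correlated with the originals;
  for homoscedastic noise the mean simulated r matches the closed form
  σ_s/√(σ_s² + σ_n²).
* **outlier_enrichment** — ordinary least squares of predicted on
  experimental values; residual = predicted − line; outliers are points
  with |residual| > k·SD (k = 1 by default, SD taken over all residuals
  without degrees-of-freedom correction). Positive residuals are
  "over-destabilizing" predictions under the destabilizing-positive
  sign convention. For each direction and residue class — hydrophobic
  {F,I,L,Y,M,V}, polar {D,E,K,N,Q,R}, structure-disrupting {P,G,N},
  classified by the *mutant* residue — an exact binomial tail p-value is
  computed against the class frequency among all evaluated mutations
  (the dataset's own composition is the null; a uniform null over 20
  letters would be indefensible for curated data). P-values are raw by
  default; a flag adds Holm adjustment.

RMSE is the standard √(n⁻¹ Σ (Yᵢ − Ŷᵢ)²). Correlations require n ≥ 3
and non-zero variance and otherwise raise.

## Synthetic fixtures: what they emulate and what they do not

The generator builds a two-chain complex with idealized geometry (a
straight Cα trace per chain at 3.8 Å spacing; the partner chain offset
so facing Cα pairs sit at 3.98 Å, guaranteeing interface contacts at
the 4 Å cutoff), draws unique single and double substitutions from its
sequences, and assigns targets y = w·x + ε where w is sparse
(20 informative dimensions by default) over the mock-embedding features
and ε is Gaussian. The weight vector is rescaled so the noiseless
signal SD is 3.0 kcal/mol, putting the target range near the
±12 kcal/mol span of real single-mutation data; the default noise SD is
0.25 × signal SD.

Default study conditions: 2000 mutations (1600 single + 400 double) in
one 105-residue complex. Under these conditions the repeated 80/20
protocol recovers the planted signal with mean test Pearson r ≈ 0.92–0.95
(ceiling ≈ 0.97), and at signal:noise = 2 the measured r tracks the
attenuation product closely.

What passing these tests shows: the pipeline is leak-free, aligned,
deterministic, and able to recover a known signal near its noise
ceiling. What it does not show: anything about the realism of mock
embeddings — they are uniform noise keyed to residue identity, with
none of the correlation structure, anisotropy or context dependence of
real transformer embeddings — so accuracy numbers on fixtures are not
forecasts of accuracy on experimental data.

## Numerical choices and degenerate inputs

* Pooling and deltas are plain float64 arithmetic; metric oracles agree
  with direct-formula evaluation to 1e−12.
* Boosting determinism requires single-threaded training
  (`deterministic=true, force_row_wise=true` in the backend).
* Empty embedding matrices, empty design matrices, zero-variance
  correlation inputs, negative measurement errors and degenerate
  regressions all raise instead of returning NaN.
* Model bundles are single JSON files (text model dump + hyperparameters
  + schema + training digest) with a format version; mismatched versions
  and truncated files are refused at load.
* The embedding cache stores one `.npz` per (provider, input digest);
  corrupt entries are recomputed and overwritten with a warning.

## Known limitations

* Structural features describe the wild-type backbone only; mutations
  acting through backbone rearrangement (notably to proline, or small →
  aromatic at the interface rim) are systematically mis-scored — the
  outlier-enrichment analysis exists to quantify exactly this.
* No uncertainty quantification on predictions; repeats quantify
  protocol variance only.
* mmCIF input, homology-aware splitting, and per-position (non-pooled)
  feature variants are out of scope.
* Multi-chain binding partners are supported by the data model, but the
  partner grouping must be given explicitly per complex; there is no
  automatic inference.
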