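# nnaaindex

Factor-analysis amino-acid scales and peptide QSAR modelling for natural
**and non-natural** residues.

Most peptide QSAR descriptor sets cover only the 20 canonical amino acids,
which rules out the non-natural side chains that make peptidomimetics
proteolytically stable and bioactive.  This toolkit implements the full
workflow for building and using an index over an arbitrary residue catalog:

1. **Scale derivation** — compress a residue × property matrix (hundreds of
   computed physicochemical descriptors per residue) into a handful of
   interpretable factors by principal-component extraction and
   Kaiser-normalized promax rotation, then score every residue on each
   factor.  The six default factor names follow the conventional property
   patterns (geometric, H-bond, connectivity, accessible surface area,
   integy moment, volume/shape).
2. **Encoding** — any peptide, natural or mimetic (`WW`, `TLTRV108W`,
   `512-439`), becomes an m·L descriptor vector by positional concatenation
   of factor scores.
3. **Modelling** — NIPALS partial least squares with leave-one-out
   validation (R², Q² = 1 − PRESS/SS, RMS), genetic-algorithm variable
   selection maximizing LOO Q², and stepwise linear discriminant analysis
   with partial-F thresholds (enter 3.84 / remove 2.71) for two-class data.
4. **Validation** — Y-randomization with the 0.300/0.050 intercept limits,
   k-means odd/even rational train/test splitting, external-set Q².
5. **Design** — enumerate candidate peptidomimetics by factor-score
   threshold rules, score them with a fitted model, rank, and keep those
   predicted above the best training activity.

Audience: computational chemists and peptide engineers who want a
self-contained, scriptable implementation of this modelling pipeline with
reproducible seeds and plain CSV/JSON interfaces.

## Worked example

Derive nothing, simulate everything: build a 615-residue synthetic scale
table, a 48-dipeptide training set whose activity is linear in five of the
twelve descriptors, then model, validate and design.

```python
import numpy as np
import nnaaindex as nx

scales = nx.synthetic_scale_table(n_residues=615, n_factors=6, seed=20)
spec = nx.QSARFixtureSpec(n_peptides=48, length=2, n_informative=5,
                          activity_noise_sd=0.2, seed=21)
peptides, _ = nx.make_qsar_dataset(scales, spec)
X = nx.encode_dataset(peptides, scales)
y = np.array([p.activity for p in peptides])

A = nx.select_components(X, y, 3)          # LOO-PRESS optimum
stats = nx.loo_q2(X, y, A)
print(f"PLS: A={A}  R2={stats.r2:.3f}  Q2={stats.q2:.3f}  RMS={stats.rms:.3f}")

ga = nx.run_gapls(X, y, nx.GAConfig(seed=22))
print(f"GA-PLS: {len(ga.selected)} of 12 variables, Q2={ga.best_fitness:.3f}")

rep = nx.y_randomization(
    X.values, y,
    nx.pls_modeler(mask=ga.best_mask, n_components=ga.n_components),
    n_perm=50, seed=23)
print(f"Y-randomization intercepts: R2={rep.r2_intercept:.3f} "
      f"Q2={rep.q2_intercept:.3f}  validates={rep.validates_model}")

rules = [nx.DesignRule(1, [("integy_moment", ">", 1.0),
                           ("volume_shape", ">", 1.0)]),
         nx.DesignRule(2, [("geometric", ">", 1.0),
                           ("h_bond", "<", -0.5)])]
cands = nx.enumerate_candidates(nx.parse_sequence("WW"), rules, scales)
ranked = nx.score_and_rank(cands, nx.fit_pls(X, y, A), scales)
best = ranked[0]
print(f"{len(cands)} candidates; top: {best.sequence} "
      f"predicted {best.predicted_activity:.2f} (training max {y.max():.2f})")
print("above training max:", len(nx.above_training_max(ranked, y)))
```

Output:

```
PLS: A=3  R2=0.985  Q2=0.968  RMS=0.404
GA-PLS: 5 of 12 variables, Q2=0.991
Y-randomization intercepts: R2=0.027 Q2=-0.278  validates=True
260 candidates; top: 592-443 predicted 7.26 (training max 6.09)
above training max: 4
```

Reading the numbers: the calibration R² and the leave-one-out Q² are close,
so the 3-component model is not overfitting; dropping seven uninformative
descriptors by GA raises Q² further.  The permutation intercepts sit well
below the 0.300/0.050 limits, so the relationship is not a chance
correlation.  Enumeration under the two position rules yields 260 dipeptide
mimetics, four of which are predicted more active than anything in the
training set — the shortlist a bench chemist would consider next.

The same pipeline is available from the shell:

```sh
nnaaindex synth qsar-dataset --seed 5 --peptides 48 \
    --scales-out scales.csv -o train.csv
nnaaindex fit-pls train.csv --scales scales.csv --components auto
nnaaindex fit-gapls train.csv --scales scales.csv --seed 7
nnaaindex validate train.csv --scales scales.csv --seed 9 --mask 0,3,5
nnaaindex split train.csv --scales scales.csv --seed 2 --out-prefix sp
nnaaindex design rules.json --template WW --scales scales.csv \
    --model pls.json -o designs.tsv
```

Real datasets use the same CSV forms: `id,sequence,activity` (or `class`)
for peptides, `id,f1..fm` for scale tables, `id,<property names...>` for
property tables fed to `derive-scales`.

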