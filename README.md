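# mismatchlab

Quantitative tools for studying **hybrid trait mismatch**: when two
populations adapt to different environments and then hybridize, the hybrids
can inherit trait combinations that neither parent carries — a long head
from one parent with small fins from the other. `mismatchlab` implements
the geometry and statistics for testing whether such mismatch grows with
the phenotypic divergence between the parents, in the setting of
experimental marine × freshwater stickleback crosses (one shared marine
ancestor crossed to many freshwater populations, with F1 and F2 hybrid
generations raised in families).

## The statistic

All analysis happens in standardized trait space (traits ln-transformed
where linear, size-corrected against standard length, fixation-corrected,
and z-scored over the whole dataset). For a cross with marine and
freshwater mean phenotypes $\bar P_M, \bar P_F \in \mathbb{R}^p$
(unweighted means of family means):

* **divergence** $D = \lVert \bar P_F - \bar P_M \rVert_2$;
* **mismatch** of a hybrid with trait vector $F$ is its perpendicular
  distance to the line through the parental means,

$$d_{mm}(F) = \left\lVert (F-\bar P_M) - \big[(F-\bar P_M)\cdot u\big]\,u \right\rVert, \qquad u = \frac{\bar P_F-\bar P_M}{\lVert \bar P_F-\bar P_M\rVert};$$

* the mean mismatch of a hybrid generation decomposes into a **dominance
  effect** (the mismatch of the generation's mean phenotype — nonzero only
  when net dominance pushes the mean off the parent line) and a **variance
  effect** (the average excess of individual mismatch over the dominance
  effect, driven by phenotypic and segregation variation);
* per-trait line-cross genetics fit standardized trait values on an
  additive index (expected freshwater genome fraction: parents 0/1, hybrids
  ½) and a dominance index (expected heterozygosity: parents 0, F1 1, F2 ½)
  with a family random intercept;
* mixed-model regressions test whether mean mismatch, the dominance effect
  and the variance effect increase with divergence across crosses, with the
  freshwater population as a random effect.

A synthetic-data generator (`mismatchlab.simulate`) mirrors the study
design with known truth — planted dominance displacement, Castle–Wright
segregation variance scaling, family structure — so every stage can be
validated end to end without the archived field data.

## Worked example

```python
import mismatchlab as ml

matrix, truth = ml.simulate_study(seed=1)         # 12 crosses, 1542 fish
dec = ml.decomposition_table(matrix)              # 24 rows: cross x generation
mm = ml.fit_divergence_mismatch(dec)
dom, var = ml.fit_effect_regressions(dec)

print(f"mismatch slope per unit divergence: {mm.slope:.3f}")
print(f"F1 dominance-effect slope: {dom.per_generation['F1']['slope']:.3f}")
print(f"F2 variance-effect slope:  {var.per_generation['F2']['slope']:.3f}")
```

prints

```
mismatch slope per unit divergence: 0.131
F1 dominance-effect slope: 0.111
F2 variance-effect slope:  0.138
```

Mean hybrid mismatch rises by ~0.13 standardized units per unit of
parental divergence in this realization. The two mechanism slopes sit near
their planted values (0.16 and 0.12): the F1 slope is attenuated a little
because the dominance effect is the norm of an estimated mean vector and
therefore biased upward more strongly for weakly diverged crosses (see
`docs/methods.md`).

The same analyses run from the shell:

```bash
mismatchlab simulate --seed 1 --out out/          # simulate + full analysis
mismatchlab run --input fish.csv --out out/       # from a raw wide CSV
mismatchlab decompose --matrix out/simulated_standardized.csv --out dec.csv
```

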