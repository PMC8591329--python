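# tactqg

Quantitative genetics of alternative reproductive tactics in two-generation
wild pedigrees: tactic-specific selection gradients on length at maturity
and variance-corrected parent–offspring heritabilities, with a forward
pedigree simulator for validation.

## The problem

In many salmonids, males mature either as large, fighting **hooknose**
males or as small, early-maturing, sneaking **jacks**, while females form a
third "tactic" with their own fitness landscape. If length at maturity is
under different selection in females, hooknose males and jacks but shares a
genetic basis across those classes, intralocus sexual/tactical conflict can
constrain each class's evolution toward its own optimum. Two ingredients
decide whether that conflict exists:

1. **Selection gradients per tactic and year.** With length standardized
   within the analysed subset (mean 0, SD 1) and relative fitness
   *w* = RS / mean(RS), the directional gradient β is the OLS slope of
   *w* ~ StdLength, and the quadratic gradient γ is **twice** the OLS
   coefficient on StdLength² in a model retaining the linear term (its SE
   is doubled too). Significance comes from Poisson log-link GLMs of
   absolute reproductive success via analysis of deviance (likelihood-ratio
   χ² tests), including a backward scan of the tactic × year × length
   interaction structure.

2. **Intra- and intertactical heritabilities.** For each parent tactic
   (dam, jack sire, hooknose sire) × offspring tactic (daughter, jack son,
   hooknose son) cell, the mean length of a parent's same-tactic offspring
   is regressed on the parent's length; *h*² = 2·*b*<sub>op</sub>. When the
   two tactics' phenotypic variances differ (two-sided variance-ratio F
   test; a Bartlett test screens all tactics at once), Falconer's
   correction applies: *h*² = 2·*b*<sub>op</sub>·(σ<sub>p</sub>/σ<sub>o</sub>),
   and the slope corresponding to *h*² = 1 becomes 0.5/(σ<sub>p</sub>/σ<sub>o</sub>).
   Each cell carries a t test of slope = 0 and an F test against the
   *h*² = 1 null.

Because real deposited pedigrees are not always at hand, the package ships
a forward simulator with a tactic-structured genetic architecture: each
individual carries breeding values for the female-, hooknose- and
jack-expressed trait (correlation matrix **r**<sub>G</sub>) plus an
additive liability that sets male tactic by a threshold. Under this model
the grid's diagonal cells recover the generative *h*² and the off-diagonal
cells recover r<sub>G</sub>·h<sub>o</sub>·h<sub>p</sub>, so the whole
estimation chain is testable against closed-form expectations.

## Worked example

`examples/heritability_grid.py` simulates 2000 parents and 8000 offspring
with *h*² = 0.4/0.8/0.5 (female/hooknose/jack) and
r<sub>G</sub>(female, hooknose) = 0.5, then runs the grid:

```
parent_tactic offspring_tactic  n_families   b_op  corrected     h2  ci95
       female           female         881  0.231      False  0.462 0.085
       female         hooknose         811  0.264       True  0.330 0.107
       female             jack         550 -0.003      False -0.006 0.138
     hooknose           female         588  0.084       True  0.260 0.097
     hooknose         hooknose         573  0.417      False  0.835 0.096
     hooknose             jack         378 -0.002       True  -0.008 0.172
         jack           female         222  0.030       True  0.054 0.204
         jack         hooknose         188  0.051       True  0.058 0.247
         jack             jack         169  0.294      False  0.588 0.242
```

The diagonal recovers the generative heritabilities (0.46, 0.84, 0.59
against 0.4/0.8/0.5, each within its 95% CI), the corrected
female↔hooknose cells land near the expectation
r<sub>G</sub>·h<sub>f</sub>·h<sub>h</sub> = 0.5·√0.4·√0.8 ≈ 0.28 (0.33 and
0.26), and every cell involving jacks — where r<sub>G</sub> = 0 — sits
near zero. `corrected` flags the cells whose variance-ratio test rejected
homogeneity, exactly the female↔hooknose and hooknose↔jack pairs given the
default variance structure.

The other examples cover the simulator (`simulate_pedigree.py`), the
selection-gradient table and interaction scan (`selection_gradients.py`),
corrected-heritability arithmetic from printed regression results
(`printed_table_arithmetic.py`) and the end-to-end report bundle
(`full_pipeline.py`). A thin CLI wraps the same calls:

```bash
tactqg simulate --seed 42 --out ped.csv
tactqg validate ped.csv
tactqg selection ped.csv --out table1.csv
tactqg heritability ped.csv --out table2.csv
tactqg run --outdir report --seed 42
```

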