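# bfhs — a Bayesian family history score for breast-cancer risk

Family history of breast cancer is usually summarised for risk prediction as
a three-level count of affected first-degree relatives (0 / 1 / >1).  That
throws away most of what a pedigree says: a sister diagnosed at 40 and a
mother cancer-free at 85 both move a woman's risk, in opposite directions,
and neither is captured by a case count.  This package implements a
continuous alternative for epidemiologists and biostatisticians building
screening-stratification models: the **Bayesian Family History Score
(BFHS)**, the posterior mean of a family's lifetime *pure* breast-cancer
risk given each first-degree female relative's age at diagnosis or
censoring.

## The model

Each family carries a latent lifetime pure risk *p* with a Beta(α, β) prior
anchored at the population risk p₀ = α/(α+β) = 0.197 (invasive + in situ,
SEER-style back-calculation from one-year hazards) and calibrated so that
risk roughly doubles given an affected first-degree relative, giving
α = 1.184, β = 4.828.  Family members' onset times follow the multiplicative
family hazard

```
λ_p(t) = f(p) λ₀(t),      f(p) = log(1−p) / log(1−p₀),
```

which makes each member's own lifetime pure risk exactly *p*.  For a family
with relatives observed to ages X₁…X_n with event indicators d₁…d_n, the
censored-survival likelihood collapses the data to two numbers — the case
count m = Σdᵢ and the exposure parameter

```
c = Σᵢ Λ₀(Xᵢ) / log(1−p₀)   ≤ 0,
```

— and the posterior density is p^(α−1) (1−p)^(β−c−1) (−log(1−p))^m.  The
BFHS is its mean, evaluated in closed form through polygamma derivatives of
the Beta function (and cross-checked by adaptive quadrature).  Because the
score *is* a lifetime risk, it plugs directly into age-interval risks via
λ_p, converts to absolute (competing-mortality) risks by Gail-style
lifetable algebra, and updates trivially as relatives age or are diagnosed.

The package also ships the surrounding machinery: hazard-table arithmetic
with LOESS smoothing, prior calibration variants, 1%-bin calibration tables
with exact binomial intervals and the 9-df goodness-of-fit χ², ROC summaries
(AUC, partial AUC on the 90–100% specificity band, sensitivity at 90%
specificity), ten-fold cross-validation partitions, likelihood-ratio tests,
and a model-faithful synthetic-cohort simulator so everything is testable
without access to any real cohort.

## Worked example

A 51-year-old woman reports three first-degree female relatives: two
cancer-free at ages 78 and 53, and one diagnosed at 55.

```python
from bfhs import BetaPrior, Family, RelativeRecord, bfhs, toy_disease_hazard

hazard = toy_disease_hazard()          # synthetic SEER-like table, p0 = 0.197
prior = BetaPrior(1.184, 4.828)
family = Family("w", [RelativeRecord(78, 0), RelativeRecord(53, 0),
                      RelativeRecord(55, 1)])
result = bfhs(family, hazard, prior, p0=0.197)
print(f"c = {result.c:.4f}, m = {result.m}, BFHS = {result.p_hat:.4f}")
```

prints

```
c = -1.1678, m = 1, BFHS = 0.2829
```

Her family's posterior lifetime pure risk is 0.283 — well above the
population's 0.197, pulled up by the age-55 diagnosis and tempered by the
relative who stayed cancer-free to 78.  If she misremembers the diagnosis
age as 52 the score moves only to 0.2844, and additionally misreporting the
78-year-old as 76 gives 0.2861: age misreporting (as opposed to status
misreporting) has minor impact.

The same objects drive the command line:

```sh
bfhs simulate --n-families 1000 --seed 1 --out sim/
bfhs compute --families sim/families.csv --hazard hazard.csv --out scores.csv
bfhs evaluate --records records.csv --out report/
```

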