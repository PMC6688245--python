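# obdecomp

Oaxaca–Blinder decomposition of binary health-outcome gaps, built for the
question of **why urban women deliver in health institutions far more often
than rural women** in DHS-style survey data. The package fits group-wise
binary-outcome regressions (logit/probit/linear), corrects for selection
into the birth sample with the Heckman two-step procedure, splits the
urban−rural gap under the four classical weighting schemes, allocates the
explained part across covariates, and attaches bootstrap uncertainty — all
exercised end to end against a fully specified synthetic data generator
with known ground truth.

It is intended for health-inequality analysts working with flat
one-row-per-birth tables (e.g. exported from DHS recode files), and for
methodologists who want a tested reference implementation of non-linear
decompositions with a simulation harness.

## The method

Let $y_i \in \{0,1\}$ be institutional delivery and fit, separately for the
urban ($U$) and rural ($R$) groups,

$$y_i^j = F(\beta^{j\top} x_i^j) + e_i^j, \qquad j \in \{U, R\},$$

with $F$ the inverse link and $x$ the covariates (age band, education,
wealth quintile, parity, pregnancy complications, distance barrier, reform
period, antenatal care, ethnicity, religion, survey year, and optionally
the inverse Mills ratio $\lambda(\hat\gamma^\top w_i)$ from a first-stage
selection probit). Writing $m(\beta, X) = \tfrac1n \sum_i F(\beta^\top x_i)$
for the counterfactual mean, the three-fold decomposition with the urban
reference is

$$\bar y^U - \bar y^R =
\underbrace{m(\beta_U, X_U) - m(\beta_U, X_R)}_{\text{explained}} +
\underbrace{m(\beta_U, X_U) - m(\beta_R, X_U)}_{\text{unexplained}} +
\text{interaction},$$

and the two-fold decomposition replaces the reference with the blend
$\beta^* = \omega\beta_U + (1-\omega)\beta_R$, splitting the residual into
urban *advantage* and rural *disadvantage*. The schemes fix $\omega$:
Oaxaca 1, Blinder 0, Reimers 0.5, Cotton the urban sample share. The
explained part is allocated across covariate groups with linearization
weights $W_k = \Delta\bar x_k \beta^*_k / \sum_j \Delta\bar x_j \beta^*_j$
(exact under the linear link). Significance at the 5% level comes from a
pairs bootstrap stratified by residence and survey year.

## Worked example

```python
from obdecomp import decompose_table, default_ghana_spec, generate_survey, window_exclusions
from obdecomp.design import OUTCOME_TERMS

table = generate_survey(default_ghana_spec(), n=13_802, seed=1)
excl = window_exclusions(table, list(OUTCOME_TERMS))
for scheme in ("oaxaca", "blinder", "reimers", "cotton"):
    res, _, _ = decompose_table(table, scheme, exclude_terms=excl)
    comps = ", ".join(f"{k}={v:+.3f} ({res.percent_of_total[k]:.1f}%)"
                      for k, v in res.components().items())
    print(f"{scheme:8s} omega={res.omega:.2f}  total={res.total:.3f}  {comps}")
```

prints

```
oaxaca   omega=1.00  total=0.409  explained=+0.293 (71.7%), unexplained=+0.046 (11.2%), interaction=+0.070 (17.1%)
blinder  omega=0.00  total=0.409  explained=+0.363 (88.8%), unexplained=+0.116 (28.3%), interaction=-0.070 (-17.1%)
reimers  omega=0.50  total=0.409  explained=+0.331 (80.9%), advantage=+0.021 (5.2%), disadvantage=+0.057 (13.9%)
cotton   omega=0.41  total=0.409  explained=+0.337 (82.4%), advantage=+0.025 (6.2%), disadvantage=+0.047 (11.4%)
```

Read: urban women's delivery rate exceeds rural women's by 40.9 percentage
points in this synthetic sample; every weighting scheme agrees on that
total (an exact identity under the logit link) and attributes most of it to
endowment differences — the rural deficit in wealth, education and
antenatal care — rather than to differing coefficients. The detailed
decomposition (`examples/03_detailed_contributions.py`) shows wealth alone
carrying ~53% of the explained component.

The `examples/` directory has one short script per capability: simulation,
overall decomposition, detailed contributions, selection correction,
bootstrap inference. A thin CLI covers the same workflow from a shell:

```bash
obdecomp simulate -n 13802 --seed 1 -o survey.csv
obdecomp decompose --csv survey.csv -o out/
obdecomp report out/report.json
```

## Layout

- `src/obdecomp/popspec.py`, `simulate.py` — population specs, synthetic
  generator, Monte-Carlo oracle
- `src/obdecomp/estimation.py` — group fits, inverse Mills ratio, Heckman
  two-step
- `src/obdecomp/decompose.py` — overall and detailed decomposition algebra
- `src/obdecomp/inference.py` — stratified pairs bootstrap
- `src/obdecomp/pipeline.py`, `io.py`, `descriptives.py`, `cli.py` —
  end-to-end analyses, CSV interchange, descriptive tables, CLI
- `docs/methods.md` — model assumptions, defaults and limitations
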