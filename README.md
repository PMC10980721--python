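# pvsignal

Disproportionality signal detection for spontaneous adverse-event
reports in the FAERS dialect.

Pharmacovigilance teams mine spontaneous-report databases such as the
FDA Adverse Event Reporting System (FAERS) for drug safety signals:
drug–event pairs reported more often than the rest of the database
would predict. `pvsignal` implements that workflow end to end for
FAERS-format data — quarterly `$`-delimited ASCII tables (DEMO, DRUG,
REAC, OUTC, THER), FDA-style deduplication by CASEID/FDA_DT/PRIMARYID,
deleted-case removal, primary-suspect cohort extraction for a target
drug, descriptive constituent-ratio summaries, and four-method
disproportionality analysis at MedDRA Preferred Term (PT) and System
Organ Class (SOC) level — plus a synthetic report generator with known
injected signals so the whole pipeline can be validated without access
to the real database.

## The statistics

Each drug–event pair is summarised by a 2×2 contingency table

|                | target event | other events |
|----------------|--------------|--------------|
| target drug    | a            | b            |
| all other drugs| c            | d            |

with N = a+b+c+d, and scored with four methods:

- **ROR** (reporting odds ratio): `ROR = ad/bc`,
  95% CI `exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`.
  Signal: a ≥ 3 and CI lower bound > 1.
- **PRR** (proportional reporting ratio): `PRR = [a/(a+b)] / [c/(c+d)]`,
  `SE(ln PRR) = √(1/a − 1/(a+b) + 1/c − 1/(c+d))`, with a Pearson χ²
  (Yates-corrected by default). Signal: a ≥ 3 and CI lower bound > 1.
- **BCPNN** information component: `IC = log₂[aN/((a+b)(a+c))]`, with
  Bayesian shrinkage moments E(IC) and V(IC) under Dirichlet priors and
  the lower bound `IC025 = E(IC) − 2√V(IC)`. Signal: IC025 > 0.
- **EBGM** (empirical-Bayes geometric mean, closed form):
  `EBGM = aN/((a+c)(a+b))` with a log-scale Wald CI.
  Signal: EBGM05 > 2.

The default combined policy declares a signal only when all four
methods agree.

## Worked example

```python
from pvsignal import compute_signal_stats
from pvsignal.contingency import ContingencyTable

table = ContingencyTable(event_label="Somnolence", level="PT", a=6, b=4, c=3, d=8)
s = compute_signal_stats(table)
```

Running `python examples/disproportionality_basics.py` prints:

```
table: a=6 b=4 c=3 d=8 (N=21)
ROR  = 4.00  (95% CI 0.64-25.02)   flag: False
PRR  = 2.20  (95% CI 0.74-6.54)   chi2(Yates) = 1.15
IC   = 0.49   E(IC) = 0.38  IC025 = -0.91   flag: False
EBGM = 1.40  (EBGM05 = 0.22)   flag: False
signal under the all-four policy: False
```

All four point estimates exceed 1 — the event is disproportionally
reported with the target drug — but with only 6 co-reports every lower
bound stays below its threshold, so nothing is flagged. See
`examples/simulate_and_detect.py` for recovering an injected λ = 20
signal from a 6,000-case synthetic corpus, and
`examples/descriptive_summary.py` for the cohort demographics table.

## Command line

```sh
pvsignal simulate --out corpus/ --n-reports 5000 --seed 1 --signal 5:30:20
pvsignal dedup --input corpus/
pvsignal describe --input corpus/ --drug drug005
pvsignal signals --input corpus/ --drug drug005 --out results/
pvsignal run --config run.yaml
```

`simulate` writes DEMO/DRUG/REAC/OUTC/THER tables, a deleted-case
list, a PT→SOC fixture map and a ground-truth JSON; `signals` runs
dedup → cohort → contingency → statistics and writes per-level TSVs,
top-N tables (by case reports and by EBGM) and a JSON manifest with
per-stage row accounting.

MedDRA is licensed and not bundled: for real data, supply your own
two-column PT→SOC TSV via `--meddra`.

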