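# liferisk

Age-inhomogeneous multistate modelling of cardiometabolic disease
progression and lifetime coronary-artery-disease risk from longitudinal
health records.

The model tracks ten health states — Health, three single risk factors
(hypertension `Ht`, hyperlipidemia `HyperLip`, diabetes `Dm`), their three
pairwise combinations, the triple combination, CAD, and Death — with strictly
monotone one-year transitions. For every legal transition and every integer
age, a binary logistic regression is fitted on the at-risk set; the raw
coefficient series are then smoothed across age with cubic distance-decay,
inverse-variance weighted local polynomial regression; the smoothed annual
probabilities are composed into 10-year, remaining-lifetime, treated
(per-year relative risk reduction, default 0.20), and marginal (any-path)
absolute risks with person-level bootstrap uncertainty. An evaluation
battery (stratified calibration RMSE, net reclassification, threshold ages,
interval expansion, time-dependent concordance, cumulative AUROC/PR) and a
synthetic cohort simulator with exact ground-truth risks round out the
package.

## Layout

| module | role |
| --- | --- |
| `liferisk.state_space` | state alphabet and legal one-year transition topology |
| `liferisk.ehr_timeline` | person records → annual person-year rows; delimited-text I/O |
| `liferisk.transition_fitting` | per-age, per-transition logistic fits; coefficient table |
| `liferisk.coefficient_smoothing` | tricube/inverse-variance local polynomial smoothing |
| `liferisk.risk_engine` | interval/lifetime/treated/marginal risks, bootstrap SE |
| `liferisk.evaluation` | RMSE, NRI, threshold ages, interval expansion, concordance, AUC |
| `liferisk.synthetic_cohort` | ground-truth simulator for end-to-end testing |
| `liferisk.cli_io`, `liferisk.cli` | run configuration, staged pipeline, click CLI |

## CLI

```bash
# simulate a cohort with known generating coefficients
liferisk simulate --config sim.yaml --out records.csv

# expand to person-years, fit per-age models, smooth across age
liferisk expand --records records.csv --out person_years.csv
liferisk fit --person-years person_years.csv --out raw.csv
liferisk smooth --coefficients raw.csv --out smoothed.csv

# project absolute risk for one covariate profile
liferisk predict --coefficients smoothed.csv --start-age 40 --prs 1.5 \
    --treated --mode fixed-path

# assessment battery on externally supplied score columns
liferisk evaluate --person-years person_years.csv --scores scores.csv \
    --outcomes outcomes.csv --comparator-score comp --out report.csv

# full staged pipeline (expand → split → fit → smooth) with manifest
liferisk run --config run.yaml
```

A `simulate` config lists transitions as `From->To` keys with coefficient
terms (`intercept`, `sex`, `prs`, `smoker`, `statin_use`, `antihtn_use`):

```yaml
n_persons: 10000
seed: 1
coefficients:
  Health->CAD: {intercept: -5.29}
  Health->Ht:  {intercept: -4.60, prs: 0.2}
```

## Conventions

Tabular artifacts are headered CSV (UTF-8, missing values as `NA`);
coefficient tables round-trip to 17 significant digits. All randomness flows
from explicit seeds; refitting identical input is bit-reproducible.
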