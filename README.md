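# gpkinetics

Nonlinear modelling and BIC-based model selection for in vitro gas-production
(GP) kinetics of ruminant feeds.

The package provides:

* **`gpkinetics.catalog`** — a fixed catalogue of 21 cumulative gas-production
  models (scaled CDFs: Burr III/XII, Dagum, log-logistic and paralogistic
  family, exponential/Weibull/Gompertz/Rayleigh variants, location families
  such as Cauchy, Gumbel, Logistic, …), each with its rate curve, analytic
  inflection time `t*` and half-life `t0.5`, parameter constraints and time
  domain.
* **`gpkinetics.fitting`** — constrained nonlinear least squares per
  profile × model (log / shifted-log reparameterisation, seeded multistart),
  with RSS, R², RMSE, Gaussian ML log-likelihood, `BIC = k ln n − 2 ln L̂`, a
  failure taxonomy (no-convergence / NaN estimates / negative predictions /
  constraint violation), and residual diagnostics.
* **`gpkinetics.selection`** — the selection layer on the profile × model BIC
  table: Type-II two-factor ANOVA, per-category Tukey–Kramer comparisons with
  a compact letter display, a CART regression tree (70/30 split, tuned on
  validation RMSE) with leaf report and per-predictor split sum-of-squares
  contribution shares, and the relative performance improvement statistic
  `RPI = 100 · (lower-set mean BIC − top-set mean BIC) / all-model mean BIC`.
* **`gpkinetics.synthetic`** — seeded profile generation (additive
  homoscedastic Gaussian noise, zero at t = 0, truncated at zero) from
  published per-category parameter presets, including a paper-scale preset
  (849 profiles, six feed categories, 3–7 replicates per feed).
* **`gpkinetics.cli` / `gpkinetics.io`** — a `gpkin` command-line pipeline
  with CSV/YAML/JSON dialects and reproducible run manifests.

## Command line

```bash
gpkin models                                   # print the 21-model catalogue
gpkin simulate --preset paper --seed 1 --out profiles.csv
gpkin fit --input profiles.csv --models all --seed 1 --out fits.csv
gpkin select --fits fits.csv --alpha 0.05 --seed 1 --out report.json
gpkin run --preset default --seed 1 --outdir out/   # simulate -> fit -> select
gpkin report --report out/report.json
```

Profiles travel as long-format CSV (`sample_id,feed_category,time_h,gp_ml`);
fits as one wide CSV row per profile × model; the selection report as JSON
(ANOVA, Tukey letters, tree leaves and shares, per-category RPI). Every
command writes a JSON manifest with the seeds needed to reproduce its output
bit for bit. One global `--seed` is fanned out deterministically to the
stages via spawned seed sequences.

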