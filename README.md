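# phenoswitch

Stochastic modelling of a two-phenotype cancer-cell population: drug-sensitive
`E` cells and drug-tolerant `M` cells that divide, die, and reversibly switch
phenotype.  The package provides

* **model core** (`phenoswitch.model`) — the six kinetic constants, the
  composite rates of both phases (drug exposure with births suppressed, and
  free growth), and initial-composition specifications (fixed fraction,
  Beta-distributed, or empirical);
* **analytics** (`phenoswitch.analytics`) — closed-form single-cell occupancy
  probabilities and generating functions, bi-exponential mean-survival
  curves, the drug-phase Fano factor with its initial-heterogeneity term, and
  exact first/second moments of the growth phase via a closed 5-dimensional
  linear moment system;
* **simulator** (`phenoswitch.simulate`) — exact direct-method Gillespie
  simulation over the six reaction channels (numba-compiled inner loop),
  seeded ensembles, cross-replicate moment summaries with bootstrap errors,
  and empirical tolerant-fraction distributions;
* **estimation** (`phenoswitch.estimate`) — the designed-initial-condition
  protocol: fit the all-sensitive and all-tolerant drug-phase mean curves,
  invert the composite rates for the switching rates, estimate the
  initial-fraction mean and variance from the mixed condition's mean and
  Fano factor, and recover all six rates in the growth phase from mean plus
  variance trajectories; bootstrap confidence intervals throughout, plus an
  adaptation-versus-selection phase comparison;
* **beta characterization** (`phenoswitch.beta`) — moment-matched Beta fits
  of fraction distributions with Kolmogorov–Smirnov diagnostics;
* **synthetic data** (`phenoswitch.synthetic`) — seeded multi-condition
  in-silico experiments with ground truth written to a separate file;
* **CLI** (`phenoswitch.cli`) — reproducible runs with JSON provenance
  sidecars.

A note on the heterogeneity signal (`script_F_theory`): the regrouped
published form of the Fano-factor decomposition carries growing exponentials,
which is inconsistent with the closed form it regroups and diverges in time.
This package uses the decaying sign convention throughout, under which the
theoretical signal and its measurable counterpart
(`script_F_empirical`) agree exactly.

## CLI

```bash
# closed-form moment trajectories
phenoswitch moments --params params.json --e0 200 --m0 0 --times 0,1,5,10 --out moments.csv

# seeded SSA ensemble
phenoswitch simulate --params params.json --init init.json --times 0,1,2 \
    --replicates 1000 --seed 1 --out traj.csv

# synthetic experiment -> full drug-phase estimation protocol
phenoswitch generate --phase drug --replicates 10000 --seed 1 --out exp.csv
phenoswitch fit-drug --counts exp.csv --n0 200 --seed 1 --out fit.json
phenoswitch estimate-heterogeneity --counts exp.csv --n0 200 --out het.json

# growth phase, Beta fit, phase comparison
phenoswitch fit-growth --counts growth.csv --e0 200 --m0 200 --full --out gfit.json
phenoswitch beta-fit --fractions fractions.csv --out beta.json
phenoswitch compare-phases --pre gfit.json --post fit.json --out cmp.json
```

`params.json` holds `{"k_E":…, "k_M":…, "mu_E":…, "mu_M":…, "k_EM":…,
"k_ME":…}`; `init.json` holds `{"N0":…, "p0": scalar | {"beta":[a,b]} |
{"empirical":[…]}, "mode":"binomial"|"deterministic"}`.  Exit codes:
0 success, 2 usage, 3 numerical failure, 4 identifiability failure.

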