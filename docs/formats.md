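# File formats

## Panel data CSV (input to `fit`, `fit-localised`, `diagnose`)

Long format, one row per area-period:

| column | type | meaning |
|---|---|---|
| `area` | string | areal-unit label (any string; mapped to indices by sorted order) |
| `time` | int | period label; labels must form a contiguous integer sequence |
| `Y` | non-negative int | observed count |
| `E` | positive float | expected count (Poisson offset) |
| *others* | float | covariates, one column each |

The panel must be complete: every `area` × `time` combination exactly once.
An intercept column is prepended automatically; covariates are used as given
(standardise beforehand if per-sd effects are wanted).

## Spatial weights

* **GAL**: first line the number of units; then for each unit a line
  `<label> <degree>` followed (when degree > 0) by a line of neighbour
  labels.  Asymmetric lists are symmetrised with a warning.
* **Edge-list CSV**: header `area_a,area_b`, one undirected border pair per
  row; reversed duplicates are merged.

## Adjacency-state CSV (`edgeset.csv`)

One row per estimable element: `kind` (`spatial`|`temporal`), `period`
(0-based; for temporal elements the earlier of the two linked periods),
`area_a`, `area_b` (equal for temporal self-links), `w` (0/1).  Round-trips
the estimated structure bit-exactly.

## Fit-result directory

`posterior_summary.csv` (parameter, mean, sd, q2.5, q97.5, ess, rhat),
`cpo.csv`, `residuals.csv` (K rows × T columns), `metrics.json`
(dic, pD, mean_cpo, converged, backend fields), `config.yaml` (the model
specification), `run_config.yaml` (the command-line invocation snapshot).
`fit-localised` additionally writes `edgeset.csv` and `trajectory.csv`
(iteration, n_zero_elements, moran_abs, dic).

## Model specification YAML

`family`, `beta_prior_variance`, `tau_prior: {shape, rate}`, `n_periods`,
optionally `adjacency_file`; see `stcar.models.ModelSpec.to_yaml`.
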