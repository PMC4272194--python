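# stcar — localised spatio-temporal CAR smoothing for areal disease counts

`stcar` estimates covariate effects (typically air-pollution relative risks)
from small-area disease counts observed over consecutive years, while
controlling for residual spatio-temporal autocorrelation with Gaussian Markov
random field (GMRF) random effects.  Its distinguishing feature is *localised*
smoothing: instead of fixing the spatio-temporal adjacency structure of the
random effects, each adjacency relation is a binary quantity estimated from
the data, so geographically or temporally adjacent effects may be smoothed
towards each other or left conditionally independent.  It is written for
biostatisticians and spatial epidemiologists running ecological regression
studies on areal panel data.

## The model

All models share the Poisson log-linear first level for counts `Y_kt` in area
`k = 1..K` and period `t = 1..T`, with expected counts `E_kt` as offset:

    Y_kt | E_kt, R_kt ~ Poisson(E_kt · R_kt),      ln R_kt = x_kt' β + φ_kt.

The model families differ in the prior for the random-effect surface `φ`:

| family | structure |
|---|---|
| `glm` | none (quasi-Poisson baseline) |
| `bym_separable` | common spatial surface (ICAR + iid) + common temporal trend (RW1 + iid) |
| `bym_nonseparable` | spatio-temporal ICAR on the KT×KT block adjacency `W` + iid |
| `localised_separable` | extended-LCAR spatial surface with estimable adjacency + RW1 + iid trend |
| `localised_nonseparable` | single `φ̃ = (φ, φ*)` with every element of `W` estimable |

For the localised families the adjacency is extended with a global effect
`φ*`: the link `w_kt,* = 1[at least one permitted relation of cell (k,t) is
currently 0]`, which keeps every cell's full-conditional variance
`1/(τ·degree)` finite however many relations are switched off.  The prior is
the intrinsic CAR `φ̃ ~ N(0, [τ Q(W̃)]⁻¹)` with `Q(W̃) = diag(W̃1) − W̃`,
`β ~ N(0, 1000)` and `τ ~ Gamma(1, 0.0005)`.

The adjacency structure itself is estimated by an iterative algorithm: fit the
independence model; then alternately (a) set each estimable element to 1
exactly when the marginal 95% credible intervals of its two random effects
overlap, and (b) refit under the implied structure; stop at a fixed point
(Case 1) or on a revisited state (Case 2, resolved by the minimum mean
per-period |Moran's I| of the residuals).  See `docs/methods.md` for the full
account.

## A worked example

```python
import stcar
from stcar import localise
from stcar.inference import SamplerControl
import numpy as np

# a 5x5 lattice whose random-effect surface has a sharp vertical boundary
graph = stcar.make_lattice(5, 5)
vals = np.zeros((25, 3), dtype=int)
for k in range(25):
    vals[k, :] = -1 if k % 5 < 2 else (1 if k % 5 > 2 else 0)
template = stcar.ClusterTemplate(vals)
scen = stcar.Scenario(M=1.5, E_interval=(150, 200), separable=True, n_datasets=1)
data, truth = stcar.generate_dataset(scen, graph, 3, template=template, seed=7)

state = localise.run("localised_nonseparable", data, graph,
                     control=SamplerControl(1, 2500, 1250, 5, seed=7), max_iter=15)
print(state.terminated, state.n_iterations, state.chosen.n_zero(), len(state.chosen))
```

This prints

```
case1 3 31 170
```

— the algorithm reached a fixed point after 3 structure estimates and set 31
of the 170 estimable adjacency relations to 0.  Comparing those cuts with the
generating template (`examples/02_localised_smoothing.py` does this) shows 30
of 30 boundary-crossing relations were cut against 1 of 90 cluster-interior
ones: the model stopped smoothing almost exactly where the risk surface
jumps.  The refitted pollution coefficient was 0.053 with 95% interval
(−0.080, 0.218), covering the generating value ln(1.03) ≈ 0.0296.

The other scripts in `examples/` each demonstrate one capability: model
fitting and DIC/CPO comparison (`01`), residual diagnostics — per-year
Moran's I permutation tests, space–time separability correlations,
overdispersion (`03`), and a slice of the coverage/RMSE simulation study
(`04`).

A thin command line mirrors the library:

```sh
stcar fit --data data.csv --graph graph.gal --family bym_nonseparable --out fit/
stcar fit-localised --data data.csv --graph graph.gal --family nonseparable --seed 1 --out loc/
stcar simulate --scenario separable,M=0.5,E=50-100 --reps 20 --lattice 8x8 --models glm,bym_separable --seed 1 --out sim/
stcar diagnose --fit-dir loc/final_fit --data data.csv --graph graph.gal
```

Data enter as long-format CSV (`area,time,Y,E,<covariates...>`), spatial
structure as a GAL file or edge-list CSV.

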