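"""Estimate the spatio-temporal adjacency structure itself.

Builds a panel whose random-effect surface has a sharp vertical cluster
boundary, runs the iterative credible-interval-overlap algorithm, and shows
that the relations estimated as conditionally independent (w = 0) concentrate
on pairs straddling the generating boundary.
"""

import warnings

import numpy as np

import stcar
from stcar import localise
from stcar.inference import SamplerControl

warnings.filterwarnings("ignore")

graph = stcar.make_lattice(5, 5)
T = 3
# left block of columns at level -1, right block at +1, middle column 0
vals = np.zeros((25, T), dtype=int)
for k in range(25):
    vals[k, :] = -1 if k % 5 < 2 else (1 if k % 5 > 2 else 0)
template = stcar.ClusterTemplate(vals)
scenario = stcar.Scenario(M=1.5, E_interval=(150, 200), separable=True, n_datasets=1)
data, truth = stcar.generate_dataset(scenario, graph, T, template=template, seed=7)

state = localise.run(
    "localised_nonseparable",
    data,
    graph,
    control=SamplerControl(1, 2500, 1250, 5, seed=7),
    max_iter=15,
)
print(f"terminated: {state.terminated} after {state.n_iterations} structure estimates")
print(f"{state.chosen.n_zero()} of {len(state.chosen)} estimable relations set to 0")

flat = template.flat()
K = 25
cz = ct = iz = it_ = 0
for entry, v in zip(state.chosen.entries, state.chosen.values):
    kind, t, a, b = entry
    if kind != "spatial":
        continue
    if flat[t * K + a] != flat[t * K + b]:
        ct += 1
        cz += v == 0
    else:
        it_ += 1
        iz += v == 0
print(f"boundary-crossing relations cut: {cz}/{ct} ({cz/ct:.0%})")
print(f"interior relations cut:          {iz}/{it_} ({iz/it_:.0%})")
print("A much higher cut rate across the generating boundary means the "
      "algorithm recovered where smoothing is inappropriate.")

row = state.final_fit.posterior.table.loc["beta_pm10"]
print(f"\nbeta_pm10 from the refitted chosen structure: "
      f"{row['mean']:.4f} ({row['q2.5']:.4f}, {row['q97.5']:.4f}); "
      f"truth {np.log(1.03):.4f}")
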