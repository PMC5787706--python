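"""Map the gradual/binary phenotypic landscape and the bistable zone.

Scans the (rho_Gal3, Kgal) plane at two galactose concentrations: the
stochastic classifier labels each cell of the grid gradual, binary,
intermediate or non-responding, and the deterministic steady-state scan
marks where the network is truly bistable (with rho_Gal1 = 100 and
rho_Gal80 = 250).  The gradual domain expands with galactose; the bistable
zone is a narrow band whose Kgal location tracks the concentration.

Writes results/landscape/*.csv
"""

from pathlib import Path

import numpy as np
import pandas as pd

from galnet import default_parameters
from galnet import meanfield as mf

OUT = Path("results/landscape")
OUT.mkdir(parents=True, exist_ok=True)

params = default_parameters()
rho_grid = np.logspace(1, 3, 9)
kgal_grid = np.logspace(np.log10(0.005), np.log10(0.605), 9)

rows = []
for gal in (0.05, 0.5):
    lsc = mf.landscape(rho_grid, kgal_grid, gal, params, n_cells=400, seed=11,
                       include_bistability=True)
    for i, r in enumerate(rho_grid):
        for j, k in enumerate(kgal_grid):
            rows.append(dict(gal=gal, rho=r, kgal=k, label=lsc.labels[i, j],
                             bistable=bool(lsc.bistable_mask[i, j])))
    counts = pd.Series(lsc.labels.ravel()).value_counts().to_dict()
    print(f"gal={gal}: labels {counts}; bistable cells "
          f"{int(lsc.bistable_mask.sum())}")

df = pd.DataFrame(rows)
df.to_csv(OUT / "landscape.csv", index=False)

gradual_area = df.groupby("gal").apply(
    lambda d: (d.label == "gradual").sum(), include_groups=False)
print("gradual cells by gal:", gradual_area.to_dict())
print(f"wrote {OUT}/landscape.csv")
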