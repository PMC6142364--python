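#!/usr/bin/env python
"""ES-incidence landscape over genome architectures and ancestral projection.

Sweeps I_ES (fraction of internal exons with p_ES above the optimal
threshold) over a 20 x 20 intron-density x mean-intron-length grid (a
reduced rendering of the full 40 x 40 = 1600-genome sweep), pairs
independently simulated "real" genomes with their nearest grid cell, and
places ancestral genomes on the surface using printed intron densities
(converted from introns/CDS kbp by the 1.422-kbp mean CDS length) and
PIC-estimated ancestral intron lengths on a toy phylogeny.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from splicearch.predictor import (
    EsModel,
    SimGenomeParams,
    compute_ies,
    density_units_convert,
    ies_grid_sweep,
    pic_ancestral,
    real_vs_simulated_ies,
    simulate_architectures,
)

BASE = Path(__file__).resolve().parent.parent / "results"

# printed ancestral densities (introns/CDS kbp) to place on the landscape
ANCESTRAL_DENSITIES = {"LECA": 4.3, "Urholozoa": 5.52, "Urmetazoa": 8.8, "Urbilateria": 7.7}


def main():
    model = EsModel.from_json(BASE / "es_model.json")
    grid = ies_grid_sweep(model, 20, 20, n_genes=3000, n_exons=2000, seed=50)
    grid.to_csv(BASE / "ies_grid.tsv", sep="\t", index=False)
    for axis in ("intron_density", "intron_len_mean"):
        rho = stats.spearmanr(grid[axis], grid["ies"])
        print(f"I_ES vs {axis}: Spearman rho={rho.statistic:.3f} p={rho.pvalue:.2g}")

    rng = np.random.default_rng(51)
    rows = []
    for k in range(15):
        d, L = float(rng.uniform(1.5, 14)), float(rng.uniform(50, 7000))
        feats = simulate_architectures(SimGenomeParams(d, L, n_genes=3000), n_exons=2000, seed=52 + k)
        rows.append((k, d, L, compute_ies(feats, model)))
    real = pd.DataFrame(rows, columns=["genome_id", "intron_density", "intron_len_mean", "ies"])
    paired, fit = real_vs_simulated_ies(real, grid)
    paired.to_csv(BASE / "ies_real_vs_simulated.tsv", sep="\t", index=False)
    print(f"real vs simulated I_ES: R^2={fit['r_squared']:.3f} slope={fit['slope']:.2f}")

    # ancestral intron lengths by PIC on a toy 4-tip holozoan-like phylogeny
    newick = "((vertebrate:1,invertebrate:1):1,(ichthyosporean:1.5,filasterean:1.5):0.5);"
    tips = pd.DataFrame(
        {"mean_intron_len": [3100.0, 900.0, 400.0, 250.0]},
        index=["vertebrate", "invertebrate", "ichthyosporean", "filasterean"],
    )
    anc = pic_ancestral(newick, tips)
    print("\nPIC ancestral mean intron lengths (toy tree):")
    print(anc.round(1).to_string())

    print("\nancestral genomes on the I_ES landscape:")
    d_axis = np.sort(grid.intron_density.unique())
    for name, dens_kbp in ANCESTRAL_DENSITIES.items():
        d = density_units_convert(dens_kbp)
        dn = d_axis[np.argmin(np.abs(d_axis - d))]
        col = grid[grid.intron_density == dn].sort_values("intron_len_mean")
        print(f"  {name:12s} {dens_kbp:.2f} introns/CDS kbp = {d:5.2f} introns/gene; "
              f"I_ES range over lengths: {col.ies.min():.2f}-{col.ies.max():.2f}")


if __name__ == "__main__":
    main()
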