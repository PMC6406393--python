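#!/usr/bin/env python
"""Structural order signatures of the three PAGE4 phospho-form ensembles.

Generates synthetic Cα ensembles for the WT, HIPK1- and CLK2-phosphorylated
presets and computes the order metrics: Rg free-energy profiles, the
FRET-probed inter-residue distances, the N-motif/central-region contact
block, contact-PCA loop loadings, and region-averaged turn propensity.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from page4.ensemble_metrics import (REGIONS, contact_map, contact_pca,
                                    ensemble_rg, free_energy_profile,
                                    pair_distances, region_mean,
                                    turn_propensity)
from page4.synthetic_ensembles import default_presets, generate_ensemble

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

N_CONF, SEED = 150, 42
presets = default_presets()
ens = {name: generate_ensemble(p, N_CONF, seed=SEED + k)
       for k, (name, p) in enumerate(presets.items())}

summary = {"n_conformers": N_CONF, "seed": SEED, "forms": {}}
profiles = []
for name, e in ens.items():
    rg = ensemble_rg(e)
    centers, F = free_energy_profile(rg, n_bins=20)
    profiles += [{"form": name, "rg_A": c, "F_kT": f}
                 for c, f in zip(centers, F)]
    cm = contact_map(e)
    np.savetxt(OUT / f"contact_map_{name.lower()}.tsv", cm.matrix,
               fmt="%.4f", delimiter="\t")
    tp = turn_propensity(e)
    summary["forms"][name] = {
        "rg_mean_A": round(float(rg.mean()), 2),
        "d_18_63_A": round(float(pair_distances(e, 18, 63).mean()), 2),
        "d_63_102_A": round(float(pair_distances(e, 63, 102).mean()), 2),
        "nloop_contact_block": round(
            cm.block_mean(REGIONS["n_motif"], REGIONS["central_acidic"]), 4),
        "turn_transient_helix": round(
            region_mean(tp, REGIONS["transient_helix"]), 4),
    }
pd.DataFrame(profiles).to_csv(OUT / "rg_free_energy_profiles.csv", index=False)

pca = contact_pca(ens["HIPK1"])
pi = pca.pair_index
blk = lambda rows, cols: float(pca.modes[0, (
    (pi[:, 0] >= rows[0]) & (pi[:, 0] <= rows[1])
    & (pi[:, 1] >= cols[0]) & (pi[:, 1] <= cols[1]))].mean())
summary["hipk1_pc1_mean_loading"] = {
    "n_loop_block": round(blk(REGIONS["n_motif"], REGIONS["central_acidic"]), 4),
    "c_loop_block": round(blk(REGIONS["central_acidic"], REGIONS["c_motif"]), 4),
}
(OUT / "ensemble_signatures.json").write_text(
    json.dumps(summary, indent=2) + "\n")

print(f"{N_CONF} conformers per phospho-form preset:")
for name, row in summary["forms"].items():
    print(f"  {name:<6} Rg = {row['rg_mean_A']:5.1f} A   "
          f"d(18,63) = {row['d_18_63_A']:5.1f} A   "
          f"N-loop contact block = {row['nloop_contact_block']:.3f}")
pc = summary["hipk1_pc1_mean_loading"]
print("HIPK1 contact-PCA PC1 mean loadings: "
      f"N-loop {pc['n_loop_block']:+.3f} vs C-loop {pc['c_loop_block']:+.3f} "
      "(opposite signs = anti-correlated loop formation)")
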