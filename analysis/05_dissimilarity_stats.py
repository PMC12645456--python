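#!/usr/bin/env python
"""Mantel regressions and PCO linking energy, geochemistry and community.

Builds Euclidean matrices from per-window energy and precipitation and from
the scaled geochemistry, a Bray-Curtis matrix from the singleton-filtered
OTU table, then runs the three Mantel permutation regressions
(energy~geochem, precip~geochem, geochem~community; exact p over all 120
relabelings of 5 samples), ordinates the geochemical matrix and regresses
axis 1 on window energy. Writes results/stats.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from seismobiome import community, diststats, io as sio
from seismobiome.diststats import DistanceMatrix

ap = argparse.ArgumentParser()
ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
ap.add_argument("--windows", type=Path, default=Path("results/windows.csv"))
ap.add_argument("--scaled", type=Path, default=Path("results/geochem_scaled.csv"))
ap.add_argument("--out", type=Path, default=Path("results/stats.json"))
args = ap.parse_args()

windows = pd.read_csv(args.windows)
scaled = pd.read_csv(args.scaled, index_col=0)
otus = sio.read_otu_table(args.inputs / "otus.tsv", args.inputs / "annotations.tsv")
otus_f, _ = community.drop_single_date_otus(otus)

labels = [str(d) for d in scaled.index]
dm_geo = diststats.euclidean_matrix(scaled)
dm_energy = diststats.euclidean_matrix(windows.energy_J.to_numpy() / 1e3, labels=labels)
dm_precip = diststats.euclidean_matrix(windows.precip_mm.to_numpy(), labels=labels)
dm_comm = DistanceMatrix(diststats.braycurtis_matrix(otus_f).data, ids=labels)

results = {}
for name, (a, b) in {
    "energy~geochem": (dm_energy, dm_geo),
    "precip~geochem": (dm_precip, dm_geo),
    "geochem~community": (dm_geo, dm_comm),
}.items():
    res = diststats.mantel(a, b)
    results[name] = {"r": round(res.r, 4), "p": round(res.p, 4), "method": res.method}
    print(f"Mantel {name:19s} r = {res.r:+.3f}, p = {res.p:.4f} ({res.method})")

ordn = diststats.pco(dm_geo)
axis1 = diststats.axis_regression(
    ordn.scores["PCO1"].to_numpy(), windows.energy_J.to_numpy() / 1e3
)
print(f"PCO axis 1 explains {ordn.pct_variance[0]:.1f}% of geochemical variance")
print(f"axis 1 vs window energy: adj R = {axis1.adj_r:+.3f}, adj P = {axis1.adj_p:.4f}")
results["pco"] = {
    "axis1_pct_variance": round(float(ordn.pct_variance[0]), 4),
    "pct_variance": [round(float(v), 4) for v in ordn.pct_variance],
    "axis1_vs_energy": {"adj_r": round(axis1.adj_r, 4), "adj_p": round(axis1.adj_p, 4)},
}
args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(results, indent=2, sort_keys=True))
print(f"wrote {args.out}")
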