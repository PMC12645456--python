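# seismobiome

Does seismic energy reshape the chemistry — and hence the microbiology — of a
subsurface aquifer? `seismobiome` is a tested, reusable implementation of the
inference chain behind that question: it turns an earthquake catalog into
distance-attenuated kinetic energy absorbed at a borehole, accumulates it
(alongside precipitation) over groundwater sampling windows, and relates it to
temporal change in aquifer geochemistry and planktonic MAG-OTU community
composition with Mantel permutation regressions and principal coordinates
analysis. A companion module analyses rock-comminution (wet-crush)
experiments that measure how fast pulverised rhyolite generates H₂ on contact
with water.

It is written for groundwater geochemists and environmental microbiologists
who have an earthquake catalog, a sampling schedule, an analyte table, and a
community table, and want the whole chain — including a synthetic-data
generator so every stage runs and is testable with no external downloads.

## The model

For each catalogued event with local magnitude *M*, radiated energy follows
the Richter relation

&nbsp;&nbsp;&nbsp;&nbsp;log₁₀ *J* = 4.4 + 1.5 *M*

and is attenuated to the borehole's sampling point by an inverse-square law,
*E* = *J* / *D*², where *D* (km) is the slant distance: the WGS-84 Vincenty
geodesic surface distance combined by the Pythagorean theorem with the
vertical separation between the hypocentre (km below sea level) and the
sampled depth (wellhead elevation − sampling depth). Absorbed energies are
summed over half-open windows `(start, end]` ending at each sampling date;
the first window reaches back by the rounded mean inter-sampling interval
(40 days for the default 2021 schedule {147, 174, 237, 279, 307}, so the
record opens on Julian day 107).

Window energy and precipitation series become 1-D Euclidean dissimilarity
matrices; analytes (filtered by stated exclusion rules, scaled to [0, 1] by
column maxima) become a multivariate Euclidean matrix; the singleton-filtered
OTU table becomes a Bray-Curtis matrix, BC = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ). The Mantel
statistic *r* is the Pearson correlation of corresponding lower-triangle
entries, with a permutation p-value (exact, over all n! relabelings, for
n ≤ 5 samples). PCO double-centres −½D∘D (Gower) and eigendecomposes; axis-1
scores are regressed on window energy, reported as adj R = sign(slope)·√(adj R²)
with the two-sided slope-t p-value. Crush kinetics are least-squares slopes
of replicate-mean H₂ (nmol g⁻¹) over the linear phase (0–48 h by default).

## Worked example

The analysis is organised as numbered drivers under `analysis/`
(`01_simulate_inputs.py` … `06_crush_kinetics.py`), each a thin narrative
script over the library; the same chain is available as one command:

```bash
seismobiome run --simulate-seed 0 --seed 7 --out demo/
```

which prints (abridged):

```
Per-window absorbed energy (kJ) / precipitation (mm):
  (107, 147]  E = 1906.0 kJ  (301 events)  P = 80.0 mm
  (147, 174]  E = 5526.9 kJ  (354 events)  P = 28.4 mm
  (174, 237]  E = 14367.6 kJ  (895 events)  P = 88.1 mm
  (237, 279]  E = 1391.1 kJ  (328 events)  P = 33.0 mm
  (279, 307]  E = 1667.4 kJ  (210 events)  P = 44.5 mm

Total absorbed energy: 24.859 MJ
Mantel energy~geochem:    r = +0.644, p = 0.0083
Mantel precip~geochem:    r = +0.013, p = 0.9750
Mantel geochem~community: r = +0.680, p = 0.0250
PCO axis 1: 39.6% of variance; vs energy adj R = -0.791, adj P = 0.0693
OTU richness 61–70; 39 shared across all dates
Crush H2 rate (altered): 2.77 nmol g-1 h-1
```

Reading: the swarm-bearing third window (Julian days 174–237) dominates the
energy record; the geochemical dissimilarity structure tracks the energy
matrix (Mantel r = +0.64, exact p = 0.0083 over 120 relabelings) but not
precipitation (r ≈ 0); the leading geochemical ordination axis carries 39.6%
of the variance and correlates with window energy (a PCO axis sign is
arbitrary); and the wet-crush H₂ rate recovers the planted linear-phase slope.
`demo/report.json` holds the full machine-readable report with config hash
and seeds; identical config + seed reruns are byte-identical.

Other verbs (`simulate`, `energy`, `geochem`, `stats mantel|pco`,
`crush rates`) expose each stage on plain CSV/TSV files — see
`seismobiome --help`.

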