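# Methods

This note documents the models, conventions and design choices behind
`seismobiome`, in the order the pipeline runs them.

## Seismic energy absorbed at the receiver

Radiated energy per event is 10^(4.4 + 1.5·M) joules from the local Richter
magnitude M; the 1.5 slope means a two-unit magnitude step is a 1000-fold
energy step, so window totals are dominated by the few largest events.
Attenuation is a bare inverse-square law over the slant distance D (km) —
no frequency-dependent attenuation, site response, or radiation-pattern
terms. The "absorbed" quantity J/D² formally carries km⁻²; following the
reporting convention of the source study it is treated as joules and
converted to kJ/MJ.

**Geodesy.** The surface leg is the Vincenty inverse geodesic on WGS-84
(a = 6 378 137 m, f = 1/298.257223563), implemented in `_geodesy.py` and
validated against an independent geodesic implementation (R `geosphere`) to
sub-metre agreement on test baselines from 17 km to 5 853 km. Vincenty's
iteration famously fails for nearly antipodal pairs; those fall back to
Lambert's flattening-corrected great-circle formula (~10 m global accuracy),
which is irrelevant for any regional catalog but keeps the function total.

**Vertical separation.** The receiver is the *sampled point*, not the
wellhead: Δv = event depth (km bsl) + (elevation − sampling depth)/1000.
For the default borehole (2365 m asl, sampled at 99.1 m) the sampled point
sits 2.27 km above sea level, which *increases* slant distances to shallow
events and so *decreases* absorbed energy relative to a sea-level receiver
convention. The pipeline reports the total-energy ratio between the two
conventions (≈ +13–15% for the sea-level convention on default synthetic
catalogs) because the convention is not uniquely determined by the phrase
"considering the depth of sampling"; ours is stated and configurable via
`ReceiverSite`.

**Windows.** Half-open `(start, end]`: an event on a sampling day belongs to
the window that ends that day. The first window reaches back by
round(mean of *all* consecutive inter-sampling gaps). For the 2021 schedule
{147, 174, 237, 279, 307} the gaps (27, 63, 42, 28) average exactly 40, so
the record opens at day 107 — this reproduces the study's stated 40-day
lookback and April-17 start, which the alternative reading (mean of the
gaps among dates 2–5 only, 44.3 d) does not. Schedules must lie within one
calendar year; cross-year schedules are rejected rather than silently
wrapped. Catalog rows with missing magnitude are dropped and counted.

## Geochemistry

Exclusion rules run in a fixed order and are logged per column: (i) columns
constant across dates (exact equality after rounding to 6 decimals;
configurable), (ii) columns detected on ≤ 1 date, (iii) the 0.22-µm-filtered
member of each filtered/unfiltered pair, (iv) an explicit list (defaults:
DOC and δ13C-DOC, measured on only three of five dates; δ18O/δ2H of water).
The rules are idempotent. Below-detection cells are imputed as 0 before
variance screening and scaling — the natural reading of "below detection"
as absent; the imputation value is configurable (e.g. half the detection
limit) since the source study does not state its choice. Scaling divides
each retained column by its maximum, so every column's maximum is exactly 1
and Euclidean distances weight analytes comparably regardless of units.

The bubble-strip conversion uses a closed-vessel two-compartment mass
balance: gas in the injected bubble (ideal gas at 1 atm) plus water at
Henry equilibrium, H_cp(T) = H° · exp[C·(1/T − 1/298.15)], with H°
(mol m⁻³ Pa⁻¹) and C (K) from Sander's compilation: H₂ (7.7×10⁻⁶, 530),
CH₄ (1.4×10⁻⁵, 1750), CO₂ (3.3×10⁻⁴, 2400), N₂ (6.4×10⁻⁶, 1300),
O₂ (1.3×10⁻⁵, 1500). Mass is conserved to 1e−10 relative by construction.
No speciation or charge-balance modelling is attempted.

## Community tables

"Detected" means relative abundance > 0 after read mapping; no abundance
floor. Singleton filtering removes OTUs detected on exactly one date and
reports the per-day percent of abundance retained. Richness is reported on
the unfiltered table (the headline convention), with post-filter richness
alongside, since the source material does not state which it counts. Guild
sums accept an annotation column name or an arbitrary predicate over the
annotation row; sums are additive over disjoint predicates by construction.

## Dissimilarity statistics

Mantel r is the Pearson correlation of lower-triangle entries; the null
permutes rows+columns of the second matrix simultaneously. With n ≤ 5
samples (the pipeline's native case: 120 relabelings) the p-value is exact
by enumeration, the identity permutation included, so the smallest
attainable p is 1/n!. Monte-Carlo sampling (default 9 999 draws, seeded,
add-one correction) is used above that. The default tail is two-sided on r;
`greater`/`less` are available because the upstream software's tail
convention is not documented. Zero-variance triangles raise an error rather
than propagate NaN. Calibration: at n = 6, 500 null replicates and 999
permutations, the empirical type-I error at p ≤ 0.05 falls within
[0.03, 0.08] (asserted in the test suite).

PCO is plain Gower double-centering (−½ J D∘D J) with a symmetric
eigendecomposition; axes sort by eigenvalue, negative eigenvalues are
reported unmodified (no Lingoes/Cailliez correction), and percent variance
is relative to the sum of positive eigenvalues. Eigenvector signs are fixed
by making each axis's largest-magnitude loading positive — note an
ordination axis sign is still scientifically arbitrary, so the sign of the
axis-1-vs-energy regression coefficient can flip between datasets while its
magnitude is stable. "adj R" is implemented as sign(slope)·√max(adj R², 0)
with adj R² = 1 − (1 − R²)(n−1)/(n−2), and "adj P" as the two-sided
slope-t p-value; this is the stated convention, made explicit because the
upstream report does not define its statistic. The implementation is
cross-checked in the test suite against scikit-bio's independent `mantel`
and `pcoa`.

## Crush kinetics

Rates are least-squares slopes of the replicate-mean H₂ series over the
linear window, default [0, 48] h (the plateau begins at 48 h), with
per-replicate slopes and their sd carried along; the 0-h dry-crush value is
the series origin, and slopes are offset-invariant. The optional
subsampling-dilution correction models each sampling event as: inject N₂
(mole fraction × h/(h+i), default 13/23), measure, withdraw at the
equilibrated fraction (fraction unchanged). The correction is the exact
algebraic inverse of that forward process (single event: ×23/13, compounding
across events). It is **off by default** so reported rates match the
face-value measured series, since the source experiments report uncorrected
values; the analysis driver prints both.

## Synthetic-data generator

The generator encodes the study conditions as a generative model; its
defaults were fixed once from the reported record:

- **Catalog**: homogeneous Poisson background (8.4 events/day over days
  (107, 307]) plus swarms of exactly 139 events (days 172–173) and 369
  events (days 196–197) near the southern caldera boundary — ≈ 2 180 events
  in expectation, matching the reported count. Magnitudes are truncated
  Gutenberg–Richter (b = 1, M ∈ [0.5, 3.6]; mean ≈ 0.93 vs the reported
  0.9), depths U(0, 10) km bsl, epicentres Gaussian about their centres.
  No Omori/ETAS clustering beyond the fixed swarm blocks.
- **Precipitation**: Bernoulli(0.35) wet days with Gamma(0.7, 4.2 mm)
  amounts ≈ 1.0 mm/day, matching the ~208 mm six-window total.
- **Geochemistry**: analyte value = baseline + sensitivity·E(kJ) + N(0, sd),
  floored at 0, BD-masked below the detection limit. The default panel
  leaves 36 columns after filtering (12 responders at 3×10⁻⁴ units/kJ, 23
  inert, plus the unfiltered sulfide of a generated pair), and includes the
  pathological columns the exclusion rules target (constant, all-BD,
  detected-once, filtered variant, DOC/isotopes).
- **Community**: per-OTU log-normal abundances closed to 100%, with a
  two-tier occupancy mixture (55% core at 0.95/day, transients at 0.5/day)
  sized so per-day richness (~mid-60s of 90 OTUs), the all-dates core
  (high 30s–low 40s), singleton count (~6) and post-filter retention
  (≥ ~95%) resemble the reported turnover. Ten responders (always detected,
  annotated as hydrogenase-encoding autotrophs) get a log-abundance shift
  of 1.5×10⁻⁵ per kJ.
- **Crush**: mean curve origin + slope·min(t, 48 h) at hours {0, 24, 48,
  120}, origins 0.41/0.37 nmol g⁻¹ (dry-crush values), slopes 2.77/1.54
  nmol g⁻¹ h⁻¹ (altered/unaltered), Gaussian replicate scatter sd 0.3 —
  real replicate scatter was larger, but 0.3 keeps the recovery studies'
  sampling error interpretable.

What the generator does **not** emulate: spatially heterogeneous attenuation
or depth–magnitude correlation in the catalog; analyte covariance beyond the
shared energy driver (real analytes co-vary through redox chemistry);
compositional correlation among OTUs beyond closure; autocorrelated
hydrology. Passing recovery tests therefore demonstrates that the
*statistical machinery* detects planted effects at realistic sizes — not
that the geochemical mechanism in real aquifers is confirmed.

## Problem sizes and numerical choices

The test suite and acceptance script run the pipeline at the study's native
scale (a ~2 100-event catalog, 5 sampling dates, 36 analytes, 90 OTUs),
Mantel calibration at 500 × 999 permutations, and recovery studies at
100–200 replicates — all chosen as the smallest sizes at which the Monte
Carlo error of the asserted proportions is negligible. Vectorised and
scalar energy paths agree to 1e−10 relative; window accumulation totals are
exact sums; PCO reconstruction of Euclidean inputs is asserted at 1e−8.
Degenerate inputs (event at the receiver, all-zero samples, zero-variance
covariates or triangles, zero-max columns) raise typed errors rather than
NaN.

## Known limitations

- The 1/D² law with a dimensionless km divisor is a reporting convention,
  not a physical attenuation model; absolute "absorbed energy" values are
  only meaningful relative to one another under a fixed convention.
- With five samples the Mantel test has a 1/120 floor on exact p-values and
  the axis regression has 3 residual degrees of freedom; quoted p-values are
  fragile and the package reports them raw, without multiple-testing
  correction across the three Mantel tests (matching the source analysis).
- Henry constants are tabulated for H₂, CH₄, CO₂, N₂ and O₂ only.
- The exact analyte panel behind the study's "36 analytes" lives in its
  supplementary data; the exclusion rules are implemented generically and
  produce 36 on the default synthetic panel by construction, not by
  replaying the original table.
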