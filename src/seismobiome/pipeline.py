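"""End-to-end orchestration: energy → filtering/scaling → matrices → tests.

``run_pipeline`` executes the full inference chain on real input files or
on a synthetic bundle, producing an AnalysisReport dict (also written as
JSON + CSVs + a human-readable summary): per-window absorbed energy and
precipitation, the analyte exclusion log, three Mantel regressions
(energy~geochemistry, precipitation~geochemistry,
geochemistry~community), the PCO eigen-table with the axis-1-vs-energy
regression, community turnover, crush rates when crush data are present,
and a sensitivity check of total energy to the vertical-separation
convention. Outputs embed the config hash, seed and package version, and
identical config+seed reruns produce byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, community, crush as crush_mod, diststats, geochem, io as sio, seismic, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "load_inputs"]


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    Either file paths or ``simulate_seed`` must be provided; a given path
    always wins over simulation for that input.
    """

    site: tuple = (44.389669, -110.543722, 2365.0, 99.1)  # lat, lon, elev m, depth m
    schedule: tuple = seismic.PAPER_SCHEDULE
    catalog_path: str | None = None
    precip_path: str | None = None
    geochem_path: str | None = None
    otu_path: str | None = None
    otu_annotations_path: str | None = None
    crush_path: str | None = None
    simulate_seed: int | None = 0
    n_perm: int = 9999
    seed: int = 7
    outdir: str | None = None

    def receiver(self) -> seismic.ReceiverSite:
        lat, lon, elev, depth = self.site
        return seismic.ReceiverSite(lat=lat, lon=lon, elevation=elev, sampling_depth=depth)

    def config_hash(self) -> str:
        # outdir is presentation, not analysis: identical analyses hash equal
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_inputs(config: PipelineConfig) -> dict:
    """Assemble the input bundle from files and/or the synthetic generator."""
    bundle = (
        synthetic.simulate_bundle(config.simulate_seed)
        if config.simulate_seed is not None
        else {}
    )
    if config.catalog_path:
        bundle["catalog"] = sio.read_catalog(config.catalog_path)
    if config.precip_path:
        bundle["precip"] = sio.read_precip(config.precip_path)
    if config.geochem_path:
        bundle["geochem"] = sio.read_analyte_table(config.geochem_path)
    if config.otu_path:
        bundle["otus"] = sio.read_otu_table(config.otu_path, config.otu_annotations_path)
    if config.crush_path:
        bundle["crush"] = sio.read_crush(config.crush_path)
    missing = {"catalog", "precip", "geochem", "otus"} - set(bundle)
    if missing:
        raise ValueError(f"missing inputs (no path and no simulate_seed): {sorted(missing)}")
    return bundle


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Schema and consistency diagnostics; empty list means all checks pass."""
    diags: list[str] = []
    try:
        bundle = load_inputs(config)
    except Exception as exc:  # surface load failures as diagnostics
        return [f"input loading failed: {exc}"]
    schedule = seismic.SamplingSchedule(config.schedule)
    catalog = bundle["catalog"]
    for col in ("day", "lat", "lon", "depth_km", "magnitude"):
        if col not in catalog.columns:
            diags.append(f"catalog: missing column {col!r}")
    if catalog.attrs.get("n_dropped"):
        lines = catalog.attrs.get("dropped_lines", [])
        diags.append(
            f"catalog: {catalog.attrs['n_dropped']} row(s) with non-numeric magnitude "
            f"dropped (file lines {lines})"
        )
    windows = seismic.build_windows(schedule)
    lo, hi = windows[0][0], windows[-1][1]
    n_outside = int(((catalog["day"] <= lo) | (catalog["day"] > hi)).sum())
    if n_outside:
        diags.append(f"catalog: {n_outside} event(s) outside windows ({lo}, {hi}]")
    geo_days = list(bundle["geochem"].values.index)
    for d in schedule.days:
        if d not in geo_days:
            diags.append(f"geochem: schedule day {d} absent from analyte table")
    otu_days = list(bundle["otus"].abundance.columns)
    for d in schedule.days:
        if d not in otu_days:
            diags.append(f"otus: schedule day {d} absent from OTU table")
    return diags


def _mantel_dict(res: diststats.MantelResult) -> dict:
    return {
        "r": round(res.r, 6),
        "p": round(res.p, 6),
        "n_perm": res.n_perm,
        "tail": res.tail,
        "method": res.method,
    }


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute the full analysis chain; returns (and optionally writes) the report."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None and (outdir / "report.json").exists() and not force:
        return json.loads((outdir / "report.json").read_text())

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    bundle = _stage("load-inputs", load_inputs, config)
    receiver = config.receiver()
    schedule = seismic.SamplingSchedule(config.schedule)
    windows = seismic.build_windows(schedule)

    # --- seismic energy and precipitation per window -----------------------
    energies = _stage("energy", seismic.catalog_energies, bundle["catalog"], receiver)
    acc_e, diag_e = seismic.accumulate(
        energies["day"].to_numpy(), energies["absorbed_J"].to_numpy(), windows
    )
    acc_p, diag_p = seismic.accumulate(
        bundle["precip"]["day"].to_numpy(), bundle["precip"]["mm"].to_numpy(), windows
    )
    energy_kJ = np.array([a.total for a in acc_e]) / 1e3
    precip_mm = np.array([a.total for a in acc_p])

    # Δv-convention sensitivity: sampled point (default) vs sea-level receiver
    sea_level = seismic.ReceiverSite(
        lat=receiver.lat, lon=receiver.lon, elevation=0.0, sampling_depth=0.0
    )
    total_default = float(energies["absorbed_J"].sum())
    total_sea = float(seismic.catalog_energies(bundle["catalog"], sea_level)["absorbed_J"].sum())

    # --- geochemistry: filter, scale, matrices -----------------------------
    filtered, exclusion_log = _stage("geochem-filter", geochem.apply_exclusion_rules, bundle["geochem"])
    scaled = _stage("geochem-scale", geochem.scale_01, filtered)
    dm_geo = diststats.euclidean_matrix(scaled)
    labels = list(dm_geo.ids)
    dm_energy = diststats.euclidean_matrix(energy_kJ, labels=labels)
    dm_precip = diststats.euclidean_matrix(precip_mm, labels=labels)

    # --- community ---------------------------------------------------------
    otus = bundle["otus"]
    turnover = community.richness_and_shared(otus)
    otus_f, retained = community.drop_single_date_otus(otus)
    dm_comm = diststats.braycurtis_matrix(otus_f)
    dm_comm = diststats.DistanceMatrix(dm_comm.data, ids=labels)
    guilds = {}
    if otus.annotations is not None and "autotroph" in otus.annotations.columns:
        guilds["autotroph_pct"] = community.guild_abundance(otus, "autotroph").round(4).to_dict()
        if "fefe_hydrogenases" in otus.annotations.columns:
            guilds["autotroph_hydrogenase_pct"] = (
                community.guild_abundance(
                    otus,
                    lambda r: bool(r["autotroph"])
                    and (r.get("fefe_hydrogenases", 0) + r.get("nife_hydrogenases", 0)) > 0,
                )
                .round(4)
                .to_dict()
            )

    # --- Mantel, PCO, axis regression --------------------------------------
    m_energy = _stage(
        "mantel-energy-geochem", diststats.mantel, dm_energy, dm_geo, config.n_perm, config.seed
    )
    m_precip = _stage(
        "mantel-precip-geochem", diststats.mantel, dm_precip, dm_geo, config.n_perm, config.seed
    )
    m_comm = _stage(
        "mantel-geochem-community", diststats.mantel, dm_geo, dm_comm, config.n_perm, config.seed
    )
    ord_res = _stage("pco", diststats.pco, dm_geo)
    axis1 = _stage(
        "axis1-regression", diststats.axis_regression, ord_res.scores["PCO1"].to_numpy(), energy_kJ
    )

    report = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_perm": config.n_perm,
            "simulate_seed": config.simulate_seed,
        },
        "windows": [
            {
                "start_day": a.window_start_day,
                "end_day": a.window_end_day,
                "energy_kJ": round(e.total / 1e3, 6),
                "n_events": e.n_events,
                "precip_mm": round(p.total, 4),
            }
            for a, e, p in zip(acc_e, acc_e, acc_p)
        ],
        "energy": {
            "total_MJ": round(total_default / 1e6, 6),
            "n_events_in_windows": int(sum(a.n_events for a in acc_e)),
            "n_events_outside": diag_e["n_outside"],
            "total_MJ_sea_level_receiver": round(total_sea / 1e6, 6),
            "dv_convention_ratio": round(total_sea / total_default, 6),
        },
        "precip": {"total_mm": round(float(precip_mm.sum()), 4), "n_outside": diag_p["n_outside"]},
        "geochem": {
            "n_analytes_retained": int(scaled.shape[1]),
            "exclusion_log": [{"analyte": a, "rule": r} for a, r in exclusion_log],
        },
        "community": {
            "richness": turnover.richness,
            "n_shared_all_days": turnover.n_shared_all_days,
            "retained_pct_after_singleton_filter": {
                str(k): round(float(v), 4) for k, v in retained.items()
            },
            "guilds": {k: {str(d): v for d, v in g.items()} for k, g in guilds.items()},
        },
        "mantel": {
            "energy_geochem": _mantel_dict(m_energy),
            "precip_geochem": _mantel_dict(m_precip),
            "geochem_community": _mantel_dict(m_comm),
        },
        "pco": {
            "eigenvalues": [round(float(v), 8) for v in ord_res.eigenvalues],
            "pct_variance": [round(float(v), 4) for v in ord_res.pct_variance],
            "axis1_pct_variance": round(float(ord_res.pct_variance[0]), 4),
            "axis1_vs_energy": {
                "slope": round(axis1.slope, 8),
                "adj_r": round(axis1.adj_r, 6),
                "adj_p": round(axis1.adj_p, 6),
            },
        },
    }

    if "crush" in bundle and bundle["crush"]:
        report["crush"] = {
            rock: {
                "rate_nmol_g_h": round(crush_mod.linear_rate(exp).rate, 6),
                "replicate_sd": round(crush_mod.linear_rate(exp).sd, 6),
            }
            for rock, exp in bundle["crush"].items()
        }

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        pd.DataFrame(report["windows"]).to_csv(outdir / "windows.csv", index=False)
        ord_res.scores.to_csv(outdir / "pco_scores.csv", index_label="day")
        (outdir / "config.json").write_text(
            json.dumps(asdict(config), indent=2, sort_keys=True, default=str)
        )
        (outdir / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: dict) -> str:
    m = report["mantel"]
    lines = [
        f"seismobiome {report['provenance']['package_version']} "
        f"(config {report['provenance']['config_hash']}, seed {report['provenance']['seed']})",
        "",
        "Per-window absorbed energy (kJ) / precipitation (mm):",
    ]
    for w in report["windows"]:
        lines.append(
            f"  ({w['start_day']:.0f}, {w['end_day']:.0f}]  "
            f"E = {w['energy_kJ']:.1f} kJ  ({w['n_events']} events)  P = {w['precip_mm']:.1f} mm"
        )
    lines += [
        "",
        f"Total absorbed energy: {report['energy']['total_MJ']:.3f} MJ",
        f"Mantel energy~geochem:    r = {m['energy_geochem']['r']:+.3f}, p = {m['energy_geochem']['p']:.4f}",
        f"Mantel precip~geochem:    r = {m['precip_geochem']['r']:+.3f}, p = {m['precip_geochem']['p']:.4f}",
        f"Mantel geochem~community: r = {m['geochem_community']['r']:+.3f}, p = {m['geochem_community']['p']:.4f}",
        f"PCO axis 1: {report['pco']['axis1_pct_variance']:.1f}% of variance; "
        f"vs energy adj R = {report['pco']['axis1_vs_energy']['adj_r']:+.3f}, "
        f"adj P = {report['pco']['axis1_vs_energy']['adj_p']:.4f}",
        f"OTU richness {min(report['community']['richness'].values())}–"
        f"{max(report['community']['richness'].values())}; "
        f"{report['community']['n_shared_all_days']} shared across all dates",
    ]
    if "crush" in report:
        for rock, v in report["crush"].items():
            lines.append(f"Crush H2 rate ({rock}): {v['rate_nmol_g_h']:.2f} nmol g-1 h-1")
    return "\n".join(lines) + "\n"
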