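"""End-to-end orchestration of the LD and DD analyses from a single TOML
config, with a reproducible run manifest.

Input modes: a directory of DAM2 monitor files with a genotype→channel
map, or a simulation scenario (one ``[genotypes.<name>]`` table per
genotype understood by :mod:`circavar.synthetic_data`).  Every report
embeds the resolved config and all seeds; reruns with identical config
and seeds produce identical outputs.
"""

from __future__ import annotations

import json
import time
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity_hmm as hmm
from . import entrainment as ei_mod
from . import phase_circular as circ
from . import rhythmicity as rhythm_mod
from .dam_io import ActivitySeries, PhotoRegime, annotate_regime, bin_counts, read_dam_monitor
from .synthetic_data import GenotypeSimParams, simulate_activity

__all__ = ["AnalysisConfig", "load_config", "load_series",
           "run_ld_analysis", "run_dd_analysis", "write_report"]


@dataclass
class AnalysisConfig:
    regime: PhotoRegime
    control: str
    genotypes: dict  # name -> sim params dict or channel map dict
    input_mode: str  # "simulation" | "dam"
    dam_dir: str | None = None
    bin_width: int = 30
    seed: int = 0
    harmonics: int = 2
    n_quad: int = 7
    n_restarts: int = 2
    rs_threshold: float = 1.5
    startle_correction: bool = True
    fit_hmm: bool = True
    hmm_maxiter: int = 400
    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.control not in self.genotypes:
            raise ValueError(f"control genotype {self.control!r} not in genotype map")
        if not self.genotypes:
            raise ValueError("genotype map is empty")


def load_config(path) -> AnalysisConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    exp = raw["experiment"]
    opts = raw.get("options", {})
    regime = PhotoRegime(
        lights_on=exp.get("lights_on", 8.0),
        lights_off=exp.get("lights_off", 20.0),
        n_ld_days=exp.get("n_ld_days", 4),
        n_dd_days=exp.get("n_dd_days", 6),
        ld_analysis_days=exp.get("ld_analysis_days", 3),
        dd_analysis_days=exp.get("dd_analysis_days", 5))
    genotypes = raw.get("genotypes", {})
    mode = "dam" if "dam_dir" in exp else "simulation"
    return AnalysisConfig(
        regime=regime, control=exp["control"], genotypes=genotypes,
        input_mode=mode, dam_dir=exp.get("dam_dir"),
        bin_width=exp.get("bin_width", 30), seed=exp.get("seed", 0),
        harmonics=opts.get("harmonics", 2), n_quad=opts.get("n_quad", 7),
        n_restarts=opts.get("n_restarts", 2),
        rs_threshold=opts.get("rs_threshold", 1.5),
        startle_correction=opts.get("startle_correction", True),
        fit_hmm=opts.get("fit_hmm", True),
        hmm_maxiter=opts.get("hmm_maxiter", 400), raw=raw)


def load_series(config: AnalysisConfig) -> dict[str, list[ActivitySeries]]:
    """Materialize annotated per-fly series per genotype."""
    out: dict[str, list[ActivitySeries]] = {}
    if config.input_mode == "simulation":
        for i, (name, table) in enumerate(sorted(config.genotypes.items())):
            params = GenotypeSimParams(genotype=name, **{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in table.items()})
            sim = simulate_activity(params, config.regime,
                                    seed=config.seed + 1000 * i,
                                    bin_width=config.bin_width)
            out[name] = sim.series_set
    else:
        dam_dir = Path(config.dam_dir)
        for name, table in config.genotypes.items():
            monitor = read_dam_monitor(dam_dir / table["monitor"])
            series = []
            for ch in table["channels"]:
                s = bin_counts(monitor, ch, config.bin_width,
                               fly_id=f"{name}_ch{ch}", genotype=name)
                series.append(annotate_regime(s, config.regime))
            out[name] = series
    return out


def _stage(report: dict, name: str):
    """Record stage status; failures are logged, later stages still run."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            entry = {"status": "ok" if exc is None else "failed",
                     "seconds": round(time.perf_counter() - self.t0, 3)}
            if exc is not None:
                entry["error"] = f"{exc_type.__name__}: {exc}"
            report["stages"][name] = entry
            return exc is not None  # swallow, keep pipeline going
    return _Ctx()


def _fit_genotype_hmms(series_by_geno, config: AnalysisConfig, segment: str):
    control_series = series_by_geno[config.control]
    emissions, _ = hmm.fit_emissions(
        control_series, segment, n_harmonics=config.harmonics,
        bin_width=config.bin_width, n_restarts=config.n_restarts,
        seed=config.seed)
    fits, curves = {}, {}
    for name, series in series_by_geno.items():
        fit = hmm.fit_hmm(series, emissions, segment=segment,
                          n_harmonics=config.harmonics,
                          bin_width=config.bin_width, n_quad=config.n_quad,
                          n_restarts=config.n_restarts, seed=config.seed,
                          maxiter=config.hmm_maxiter)
        fits[name] = fit
        curves[name] = [hmm.occupancy_curve(fit, fid) for fid in fit.u_hat]
    return emissions, fits, curves


def run_ld_analysis(config: AnalysisConfig) -> dict:
    """EI summaries, % entrained, HMM fits and occupancy variability in LD."""
    report = {"segment": "LD", "config": config.raw, "seed": config.seed,
              "stages": {}, "tables": {}, "warnings": []}
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        series_by_geno = load_series(config)
        with _stage(report, "entrainment"):
            rows, summary = [], []
            for name, series in series_by_geno.items():
                for transition in ("lights_on", "lights_off"):
                    results = [ei_mod.fly_ei(
                        s, transition, config.regime,
                        startle_correction=config.startle_correction)
                        for s in series]
                    rows.extend(results)
                    n_ent, n_tot, pct = ei_mod.percent_entrained(results)
                    eis = [r.ei for r in results if r.ei is not None]
                    summary.append({
                        "genotype": name, "transition": transition,
                        "n_entrained": n_ent, "n": n_tot,
                        "pct_entrained": pct,
                        "ei_mean": float(np.mean(eis)),
                        "ei_sd": float(np.std(eis, ddof=1)) if len(eis) > 1 else np.nan})
            report["tables"]["ei"] = ei_mod.ei_table(rows)
            report["tables"]["ei_summary"] = pd.DataFrame(summary)
        if config.fit_hmm:
            with _stage(report, "hmm"):
                emissions, fits, curves = _fit_genotype_hmms(
                    series_by_geno, config, "LD")
                report["emissions_LD"] = {
                    "mu": emissions.mu.tolist(), "phi": emissions.phi.tolist()}
                report["hmm_fits"] = fits
                stats = hmm.occupancy_sd_at_peaks(
                    curves, config.control, config.regime.lights_on,
                    config.regime.lights_off, segment="LD")
                report["tables"]["variability"] = pd.DataFrame(
                    [vars(v) for v in stats])
                occ_rows = []
                for name, cs in curves.items():
                    for c in cs:
                        for zt, p in zip(c.grid, c.p_active):
                            occ_rows.append({"genotype": name, "fly_id": c.fly_id,
                                             "zt": zt, "p_active": p})
                report["tables"]["occupancy"] = pd.DataFrame(occ_rows)
        report["warnings"] = [str(w.message) for w in wlist]
    return report


def run_dd_analysis(config: AnalysisConfig) -> dict:
    """Rhythmicity, phase coherence and DD occupancy variability."""
    report = {"segment": "DD", "config": config.raw, "seed": config.seed,
              "stages": {}, "tables": {}, "warnings": []}
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        series_by_geno = load_series(config)
        rhythmic_ids: dict[str, set] = {}
        with _stage(report, "rhythmicity"):
            results = []
            for name, series in series_by_geno.items():
                geno_results = [rhythm_mod.classify_rhythmic(
                    s, rs_threshold=config.rs_threshold) for s in series]
                results.extend(geno_results)
                rhythmic_ids[name] = {r.fly_id for r in geno_results if r.rhythmic}
            report["tables"]["rhythm"] = rhythm_mod.rhythm_table(results)
            report["tables"]["rhythm_summary"] = \
                rhythm_mod.genotype_rhythm_summary(results)
        with _stage(report, "phase"):
            phase_rows, summaries, groups = [], [], {}
            for name, series in series_by_geno.items():
                samples = []
                for s in series:
                    if s.fly_id not in rhythmic_ids.get(name, set()):
                        continue  # arrhythmic flies never get a phase
                    ps = circ.fly_phase(s)
                    if ps is not None:
                        samples.append(ps)
                if not samples:
                    report.setdefault("notices", []).append(
                        f"{name}: no rhythmic flies, phase stage skipped")
                    continue
                groups[name] = samples
                phase_rows.extend(samples)
                if len(samples) >= 2:
                    summ = circ.circular_summary(samples)
                    summaries.append({"genotype": name, **vars(summ)})
            report["tables"]["phases"] = pd.DataFrame(
                [{"fly_id": p.fly_id, "genotype": p.genotype,
                  "phase": p.phase, "source_days": str(p.source_days)}
                 for p in phase_rows])
            report["tables"]["circular_summary"] = pd.DataFrame(summaries)
        with _stage(report, "circular_tests"):
            tests = []
            for name, samples in groups.items():
                if len(samples) >= 5:
                    res = circ.watson_gof(samples, seed=config.seed)
                    tests.append({"name": res.name, "groups": name,
                                  "statistic": res.statistic,
                                  "p_value": res.p_value,
                                  "p_adjusted": res.p_adjusted,
                                  "note": res.note})
            if len(groups) >= 2:
                for res in circ.equal_kappa_pairwise(groups):
                    tests.append({"name": res.name,
                                  "groups": " vs ".join(res.groups),
                                  "statistic": res.statistic,
                                  "p_value": res.p_value,
                                  "p_adjusted": res.p_adjusted,
                                  "note": res.note})
            report["tables"]["tests"] = pd.DataFrame(tests)
        if config.fit_hmm:
            with _stage(report, "hmm"):
                emissions, fits, curves = _fit_genotype_hmms(
                    series_by_geno, config, "DD")
                report["emissions_DD"] = {
                    "mu": emissions.mu.tolist(), "phi": emissions.phi.tolist()}
                report["hmm_fits"] = fits
                stats = hmm.occupancy_sd_at_peaks(
                    curves, config.control, config.regime.lights_on,
                    config.regime.lights_off, segment="DD")
                report["tables"]["variability"] = pd.DataFrame(
                    [vars(v) for v in stats])
        report["warnings"] = [str(w.message) for w in wlist]
    return report


def write_report(report: dict, out_dir) -> None:
    """Write every table as CSV plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = report["segment"].lower()
    for name, df in report["tables"].items():
        df.to_csv(out / f"{prefix}_{name}.csv", index=False)
    manifest = {k: v for k, v in report.items()
                if k not in ("tables", "hmm_fits")}
    if "hmm_fits" in report:
        manifest["hmm_fits"] = {
            g: {"log_likelihood": f.log_likelihood,
                "sigma_u": f.spec.sigma_u,
                "beta12": f.spec.beta12.tolist(),
                "beta21": f.spec.beta21.tolist(),
                "converged": f.converged,
                "boundary_sigma": f.boundary_sigma,
                "n_flies": f.n_flies}
            for g, f in report["hmm_fits"].items()}
    with open(out / f"{prefix}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
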