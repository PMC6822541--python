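"""End-to-end orchestration: data -> QC -> models -> tabular outputs.

``run_full_analysis`` reads hormone (and optionally plate/validation)
CSVs, fits the progesterone mixture, the testosterone location model
and the seasonal model, and writes plot-ready CSV outputs plus a JSON
run manifest.  A single root seed fans out to per-stage seeds through
``numpy.random.SeedSequence(root, spawn_key=(stage_index,))`` so each
stage is independently reproducible.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    Dataset,
    Hormone,
    Sex,
    read_assay_csv,
    read_hormone_csv,
    write_hormone_csv,
    write_summary_table,
)
from .mcmc import ChainConfig, retained_sample_count
from .mixture import cluster_occurrence, cluster_source_probability, fit_mixture, fit_lognormal_mean
from .qc import accuracy_test, duplicate_cv
from .seasonal import (
    DEFAULT_WINTER_WINDOW,
    augment_winter_replication,
    bayesian_r2,
    fit_seasonal,
    predict_band,
    seasonal_summaries,
)
from .synthetic import (
    AssaySimParams,
    MixtureSimParams,
    SeasonalSimParams,
    gen_assay_series,
    gen_mixture_concentrations,
    gen_seasonal_concentrations,
)

__all__ = ["RunConfig", "run_full_analysis", "simulate_fixtures", "stage_seed"]

_STAGES = ("qc", "validate", "cluster", "location", "seasonal")


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a deterministic, documented per-stage seed (< 2**31)."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(root_seed, spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class RunConfig:
    """Inputs and knobs for a full pipeline run."""

    hormone_csv: str
    output_dir: str
    plate_csv: str | None = None
    validation_csv: str | None = None  # columns: added, measured
    chains: ChainConfig = field(default_factory=ChainConfig)
    winter_window: tuple[int, int] = DEFAULT_WINTER_WINDOW
    seed: int = 0


def _chains_for(config: RunConfig, stage: str) -> ChainConfig:
    c = config.chains
    return ChainConfig(c.n_chains, c.n_iterations, c.burn_in_fraction, c.thin,
                       seed=stage_seed(config.seed, stage))


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole analysis and write the report bundle.

    Outputs (CSV unless noted): ``qc_table.csv`` (if plate data),
    ``validation.json`` (if a validation series), ``table1.csv``
    (cluster means and testosterone geometric mean, ng/g),
    ``occurrence.csv``, ``source_probability.csv`` (value grid with
    P(A|v), P(B|v)), ``seasonal_summary.csv``, ``seasonal_scalars.json``
    (p_positive_amplitude, BR2), ``prediction_band.csv`` and
    ``manifest.json``.  Deterministic given the config seed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = Path(config.hormone_csv)
    if not path.exists():
        raise FileNotFoundError(f"hormone CSV not found: {path}")
    data = read_hormone_csv(path)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "chains": asdict(config.chains),
        "retained_samples": retained_sample_count(config.chains),
        "winter_window": list(config.winter_window),
        "inputs": {"hormone_csv": str(path)},
        "stages": {},
    }

    if config.plate_csv:
        plate = read_assay_csv(config.plate_csv)
        rows = []
        for m in plate:
            q = duplicate_cv(m)
            rows.append({"sample_id": q.sample_id,
                         "cv_percent": q.cv_percent,
                         "rerun_flag": q.rerun_flag,
                         "range_status": q.range_status.value})
        pd.DataFrame(rows).to_csv(outdir / "qc_table.csv", index=False)
        manifest["stages"]["qc"] = {"n_samples": len(plate)}

    if config.validation_csv:
        vdf = pd.read_csv(config.validation_csv)
        res = accuracy_test(vdf["added"].to_numpy(), vdf["measured"].to_numpy(),
                            _chains_for(config, "validate"))
        (outdir / "validation.json").write_text(json.dumps({
            "slope": res.slope, "slope_ci95": list(res.slope_ci95),
            "intercept": res.intercept,
            "br2": res.br2, "br2_ci95": list(res.br2_ci95),
            "interpretation": res.interpretation,
        }, indent=2))
        manifest["stages"]["validate"] = {"n_points": int(len(vdf))}

    summaries = []

    prog = data.filter(hormone=Hormone.PROGESTERONE)
    if len(prog) >= 4:
        fit = fit_mixture(prog.concentrations, _chains_for(config, "cluster"))
        summaries.extend(fit.summaries())
        occ = cluster_occurrence(fit)
        pd.DataFrame([
            {"cluster": "A", "fraction_mean": occ["fraction_A_mean"],
             "ci_2.5%": occ["fraction_A_ci95"][0],
             "ci_97.5%": occ["fraction_A_ci95"][1]},
            {"cluster": "B", "fraction_mean": occ["fraction_B_mean"],
             "ci_2.5%": occ["fraction_B_ci95"][0],
             "ci_97.5%": occ["fraction_B_ci95"][1]},
        ]).to_csv(outdir / "occurrence.csv", index=False)
        conc = prog.concentrations
        grid = np.exp(np.linspace(np.log(conc.min()), np.log(conc.max()), 200))
        p_b = np.array([cluster_source_probability(fit, v) for v in grid])
        pd.DataFrame({"concentration": grid, "P_cluster_A": 1 - p_b,
                      "P_cluster_B": p_b}).to_csv(
            outdir / "source_probability.csv", index=False)
        manifest["stages"]["cluster"] = {"n_records": len(prog)}

    test = data.filter(hormone=Hormone.TESTOSTERONE)
    if len(test) >= 2:
        loc = fit_lognormal_mean(test.concentrations,
                                 _chains_for(config, "location"))
        summaries.append(loc.summary("mu_testosterone"))
        manifest["stages"]["location"] = {"n_records": len(test)}

    if len(test) >= 5:
        aug = augment_winter_replication(test, config.winter_window)
        sfit = fit_seasonal(aug, _chains_for(config, "seasonal"))
        write_summary_table(seasonal_summaries(sfit),
                            outdir / "seasonal_summary.csv")
        br2 = bayesian_r2(sfit)
        band = predict_band(sfit)
        pd.DataFrame({
            "day": band.days, "mean": band.mean,
            "lo75": band.band75[0], "hi75": band.band75[1],
            "lo95": band.band95[0], "hi95": band.band95[1],
        }).to_csv(outdir / "prediction_band.csv", index=False)
        (outdir / "seasonal_scalars.json").write_text(json.dumps({
            "p_positive_amplitude": sfit.p_positive_amplitude,
            "br2_mean": br2["mean"], "br2_ci95": list(br2["ci95"]),
            "peak_day_of_mean_curve": band.peak_day_of_mean_curve,
        }, indent=2))
        manifest["stages"]["seasonal"] = {
            "n_records": len(test),
            "n_after_replication": len(aug),
        }

    if summaries:
        write_summary_table(summaries, outdir / "table1.csv")

    rhats = [s.rhat for s in summaries if np.isfinite(s.rhat)]
    manifest["max_rhat"] = max(rhats) if rhats else None
    if rhats and max(rhats) > 1.01:
        manifest["warnings"] = ["some R-hat > 1.01: chains may not have mixed"]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


_PRESETS = ("mixture", "seasonal", "assay", "all")


def simulate_fixtures(preset: str, seed: int, outdir: str | Path,
                      n: int | None = None) -> list[Path]:
    """Materialise canonical synthetic CSV fixtures plus a parameter
    manifest; byte-identical across reruns with the same seed."""
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose one of "
                         + ", ".join(_PRESETS))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    params: dict = {}

    if preset in ("mixture", "all"):
        p = MixtureSimParams(seed=seed, **({"n": n} if n else {}))
        ds, labels = gen_mixture_concentrations(p)
        f = outdir / "mixture.csv"
        write_hormone_csv(ds, f)
        np.savetxt(outdir / "mixture_labels.csv", labels, fmt="%d",
                   header="true_cluster_B", comments="")
        written += [f, outdir / "mixture_labels.csv"]
        params["mixture"] = asdict(p)
    if preset in ("seasonal", "all"):
        p = SeasonalSimParams(seed=seed, **({"n": n} if n else {}))
        ds = gen_seasonal_concentrations(p)
        f = outdir / "seasonal.csv"
        write_hormone_csv(ds, f)
        written.append(f)
        params["seasonal"] = asdict(p)
    if preset in ("assay", "all"):
        p = AssaySimParams(seed=seed)
        series = gen_assay_series(p)
        f = outdir / "assay_accuracy.csv"
        pd.DataFrame({"added": series.added,
                      "measured": series.measured}).to_csv(f, index=False)
        f2 = outdir / "assay_parallelism.csv"
        k = series.standard_curve.shape[0]
        m = series.dilution_series.shape[0]
        pd.DataFrame({
            "curve": ["standard"] * k + ["dilution"] * m,
            "log_conc": np.concatenate([series.standard_curve[:, 0],
                                        series.dilution_series[:, 0]]),
            "response": np.concatenate([series.standard_curve[:, 1],
                                        series.dilution_series[:, 1]]),
        }).to_csv(f2, index=False)
        written += [f, f2]
        params["assay"] = asdict(p)

    mf = outdir / "fixture_manifest.json"
    mf.write_text(json.dumps({"preset": preset, "seed": seed,
                              "parameters": params}, indent=2, default=list))
    written.append(mf)
    return written
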