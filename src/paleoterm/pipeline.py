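"""End-to-end pipeline: calibrate -> extinction estimates -> vole/pollen
reconstructions -> biomization -> diversity, from one config file.

The config is a single YAML document; every stochastic stage takes its seed
from the top-level ``seed`` (stage sub-seeds are derived deterministically).
Outputs are CSV files plus a JSON run manifest recording input checksums,
settings, seeds, package version and all warnings.  A stage failure is
recorded and its dependents are skipped; completed outputs stay on disk.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomization import biomize, read_biome_matrix, read_pft_matrix
from .calibration import RadiocarbonDetermination, calibrate, hpd_interval, point_estimate
from .diversity import diversity_table
from .extinction import PhaseSettings, SightingSeries, griwm, phase_fit
from .io import read_calcurve, read_counts, read_dated_records
from .transfer import (
    TrainingSet,
    loo_crossvalidate,
    mat_reconstruct,
    select_component,
    wapls_fit,
    wapls_predict,
)
from .vole import reconstruct_series

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "calibration",
    "extinction",
    "vole",
    "transfer",
    "biomization",
    "diversity",
}


class ConfigError(ValueError):
    pass


class RunConfig(dict):
    """Validated pipeline configuration (a dict with strict keys)."""

    def __init__(self, data: dict):
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ConfigError("config must set an explicit seed")
        if "out_dir" not in data:
            raise ConfigError("config must set out_dir")
        super().__init__(data)
        for stage in ("calibration", "extinction", "vole", "transfer",
                      "biomization", "diversity"):
            for key, val in (data.get(stage) or {}).items():
                if key in ("curve", "records", "counts", "training", "climate",
                           "fossil", "pft", "biomes") and not Path(val).exists():
                    raise ConfigError(f"{stage}.{key}: file not found: {val}")


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return RunConfig(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, name: str) -> int:
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages in dependency order.

    Returns the manifest (also written to ``out_dir/manifest.json``).
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "settings": {k: v for k, v in config.items() if k not in ("seed",)},
        "inputs": {},
        "outputs": {},
        "warnings": [],
        "errors": {},
    }

    def record_inputs(stage: str, cfg: dict) -> None:
        for key, val in cfg.items():
            p = Path(str(val))
            if p.is_file():
                manifest["inputs"][f"{stage}.{key}"] = _sha256(p)

    def record_output(name: str, path: Path) -> None:
        manifest["outputs"][name] = _sha256(path)

    def run_stage(name: str, fn) -> bool:
        cfg = config.get(name)
        if not cfg:
            return False
        record_inputs(name, cfg)
        try:
            fn(cfg)
            return True
        except Exception as exc:  # recorded, downstream skipped
            manifest["errors"][name] = f"{type(exc).__name__}: {exc}"
            manifest["warnings"].append(f"stage {name} failed: {exc}")
            traceback.print_exc()
            return False

    calibrated: dict[str, pd.DataFrame] = {}

    def do_calibration(cfg: dict) -> None:
        curve = read_calcurve(cfg["curve"], cfg.get("dialect", "simple"))
        records = read_dated_records(cfg["records"]).filter(included_only=True)
        rows = []
        for _, r in records.frame.iterrows():
            if r["age_type"] == "c14":
                dens = calibrate(
                    RadiocarbonDetermination(r["age"], r["sigma"]), curve,
                    grid_step=float(cfg.get("grid_step", 1.0)),
                )
                med = point_estimate(dens, "median")
                ivs, _ = hpd_interval(dens, 0.95)
                sd = float(np.sqrt(np.sum(dens.mass * (dens.cal_age - np.sum(dens.mass * dens.cal_age)) ** 2)))
            else:
                med, sd = r["age"], r["sigma"]
                ivs = [(med - 1.96 * sd, med + 1.96 * sd)]
            rows.append(
                {
                    "taxon": r["taxon"],
                    "lab_code": r["lab_code"],
                    "median": med,
                    "sd": sd,
                    "hpd95": ";".join(f"{a:.0f}-{b:.0f}" for a, b in ivs),
                }
            )
        df = pd.DataFrame(rows)
        path = out_dir / "calibrated.csv"
        df.to_csv(path, index=False)
        record_output("calibrated.csv", path)
        for taxon, g in df.groupby("taxon"):
            calibrated[taxon] = g

    def do_extinction(cfg: dict) -> None:
        taxon = cfg.get("taxon")
        if "records" in cfg:
            records = read_dated_records(cfg["records"]).filter(
                taxon=taxon, included_only=True
            )
            df = records.frame
            if (df["age_type"] == "c14").any():
                raise ConfigError(
                    "extinction stage needs calibrated ages; run calibration first"
                )
            ages, sds = df["age"].to_numpy(), df["sigma"].to_numpy()
        elif taxon in calibrated:
            g = calibrated[taxon]
            ages, sds = g["median"].to_numpy(), g["sd"].to_numpy()
        else:
            raise ConfigError("extinction stage needs records or a calibrated taxon")
        series = SightingSeries(ages=ages, sds=sds, taxon=taxon or "")
        method = cfg.get("method", "both")
        out: dict = {"taxon": taxon, "n": len(series)}
        if method in ("griwm", "both"):
            est = griwm(
                series,
                alpha=float(cfg.get("alpha", 0.05)),
                iterations=int(cfg.get("iterations", 10_000)),
                seed=_stage_seed(seed, "griwm"),
            )
            manifest["warnings"].extend(est.warnings)
            out["griwm"] = {
                "terminal": est.terminal,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
            }
        if method in ("phase", "both"):
            post = phase_fit(
                series,
                PhaseSettings(
                    iterations=int(cfg.get("phase_iterations", 20_000)),
                    burn_in=int(cfg.get("burn_in", 2_000)),
                ),
                seed=_stage_seed(seed, "phase"),
            )
            if not post.converged:
                manifest["warnings"].append(
                    f"phase model not converged (R-hat start {post.r_hat_start:.3f},"
                    f" end {post.r_hat_end:.3f})"
                )
            lo, hi = post.end_interval(0.95)
            out["phase"] = {
                "end_median": post.end_median(),
                "end_95_lower": lo,
                "end_95_upper": hi,
                "start_median": post.start_median(),
                "acceptance_rate": post.acceptance_rate,
                "converged": post.converged,
            }
        path = out_dir / "extinction.json"
        path.write_text(json.dumps(out, indent=1))
        record_output("extinction.json", path)

    def do_vole(cfg: dict) -> None:
        matrix = read_counts(cfg["counts"])
        df = reconstruct_series(matrix)
        if df["low_n"].any():
            manifest["warnings"].append(
                f"vole thermometer: {int(df['low_n'].sum())} low-n assemblages"
            )
        path = out_dir / "tjuly.csv"
        df.to_csv(path, index=False)
        record_output("tjuly.csv", path)

    def do_transfer(cfg: dict) -> None:
        modern = read_counts(cfg["training"])
        clim = pd.read_csv(cfg["climate"], comment="#")
        clim_map = dict(zip(clim.iloc[:, 0].astype(str), clim.iloc[:, 1]))
        climate = np.array([clim_map[s] for s in modern.sample_ids], float)
        training = TrainingSet(counts=modern, climate=climate)
        fossil = read_counts(cfg["fossil"])
        method = cfg.get("method", "wapls")
        if method == "wapls":
            max_c = int(cfg.get("components", 5))
            cv = loo_crossvalidate(training, max_components=max_c)
            comp = select_component(
                cv,
                n_randomizations=int(cfg.get("randomizations", 999)),
                seed=_stage_seed(seed, "select_component"),
            )
            model = wapls_fit(training, n_components=max_c)
            df = wapls_predict(model, fossil, component=comp)
            df["component"] = comp
            df["rmsep"] = cv.rmsep[comp - 1]
        elif method == "mat":
            df = mat_reconstruct(training, fossil, k=int(cfg.get("k", 6)),
                                 threshold=cfg.get("threshold"))
        else:
            raise ConfigError(f"unknown transfer method: {method}")
        path = out_dir / f"reconstruction_{method}.csv"
        df.to_csv(path, index=False)
        record_output(path.name, path)

    def do_biomization(cfg: dict) -> None:
        matrix = read_counts(cfg["counts"])
        pft = read_pft_matrix(cfg["pft"])
        biomes = read_biome_matrix(cfg["biomes"])
        results = biomize(
            matrix, pft, biomes,
            threshold=float(cfg.get("threshold", 0.5)),
            ap_cutoff=float(cfg.get("ap_cutoff", 70.0)),
        )
        rows = []
        for sid, r in zip(matrix.sample_ids, results):
            row = {"sample_id": sid, "biome": r.assigned,
                   "arboreal_percent": r.arboreal_percent, "override": r.override}
            row.update({f"A_{b}": s for b, s in r.scores.items()})
            rows.append(row)
            for t in r.unassigned_taxa:
                manifest["warnings"].append(f"biomization: unassigned taxon {t}")
        path = out_dir / "biomes_out.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        record_output("biomes_out.csv", path)

    def do_diversity(cfg: dict) -> None:
        matrix = read_counts(cfg["counts"])
        base = cfg.get("base_n", "auto")
        df = diversity_table(matrix, None if base == "auto" else int(base))
        path = out_dir / "diversity.csv"
        df.to_csv(path, index=False)
        record_output("diversity.csv", path)

    cal_ok = run_stage("calibration", do_calibration)
    ext_cfg = config.get("extinction") or {}
    if ext_cfg and "records" not in ext_cfg and config.get("calibration") and not cal_ok:
        manifest["errors"]["extinction"] = "skipped: calibration failed"
    else:
        run_stage("extinction", do_extinction)
    run_stage("vole", do_vole)
    run_stage("transfer", do_transfer)
    run_stage("biomization", do_biomization)
    run_stage("diversity", do_diversity)

    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
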