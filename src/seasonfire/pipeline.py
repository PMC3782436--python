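"""Pipeline orchestration: inputs -> descriptors -> transforms -> SEM fits ->
specification searches -> effect tables, with provenance in every artifact.

The fire analysis couples each fire year t to the climate that preceded it:
the dry season labeled t-1 (it spans October of t-1 through May of t, i.e. the
fire season's fuel-drying period) and the wet season of t-1.  The one-year
shift drops the first fire year and is logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import load_entry
from .enso import read_monthly_index, seasonal_nino
from .search import ModelFramework, search
from .seasons import build_descriptor_table, load_daily_csv, write_descriptor_table
from .sem import SEMFit, effects_table, fit_ml, sample_covariance, significance_tier
from .simulate import ClimateGenConfig, FireGenConfig, generate_daily_climate, generate_fire_records
from .transforms import DEFAULT_TRANSFORMS, apply_transforms

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "descriptor_wide_table", "fire_analysis_table", "fit_to_dot"]

SEASONAL_VARS = ["nino", "onset", "duration", "rainfall", "tc"]
FIRE_VARS = ["nino", "tc_wet", "rain_dry", "n_fires", "area"]


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "seasonfire_out"
    simulate: dict | None = None       # ClimateGenConfig overrides; None => use inputs
    inputs: dict | None = None         # {"rainfall": csv, "nino": csv, "fires": csv}
    fire_simulate: dict | None = None  # FireGenConfig overrides
    seasonal_framework: str = "seasonal_saturated"
    fire_framework: str = "fire_saturated"
    run_searches: bool = True
    top: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        # analysis parameters only: where the outputs land is not part of
        # the scientific configuration
        payload = {k: v for k, v in self.__dict__.items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def descriptor_wide_table(descriptors: pd.DataFrame, nino_monthly: pd.Series) -> pd.DataFrame:
    """Pivot the long descriptor table to one row per year and attach the
    season-weighted ENSO index for each season span."""
    ok = descriptors[descriptors["ok"]].copy()
    nino_vals = []
    for _, row in ok.iterrows():
        try:
            nino_vals.append(seasonal_nino(nino_monthly, row["onset"], row["cessation"]))
        except KeyError:
            nino_vals.append(np.nan)
    ok["nino"] = nino_vals
    wide = None
    for season in ("wet", "dry"):
        sub = ok[ok["season"] == season].set_index("year")
        part = pd.DataFrame(
            {
                f"onset_{season}": sub["onset_doy"],
                f"duration_{season}": sub["duration_days"],
                f"rainfall_{season}": sub["rainfall_cm"],
                f"tc_{season}": sub["trend_r2"],
                f"nino_{season}": sub["nino"],
            }
        )
        wide = part if wide is None else wide.join(part, how="outer")
    wide.index.name = "year"
    return wide


def seasonal_analysis_table(wide_t: pd.DataFrame, season: str) -> pd.DataFrame:
    """Generic-name (nino, onset, duration, rainfall, tc) table for one season,
    on the transformed scale."""
    cols = {
        "nino": f"nino_{season}",
        "onset": f"onset_{season}_t",
        "duration": f"duration_{season}_t",
        "rainfall": f"rainfall_{season}" + ("_t" if season == "wet" else ""),
        "tc": f"tc_{season}_t",
    }
    out = pd.DataFrame({k: wide_t[v] for k, v in cols.items()})
    return out.dropna()


def fire_analysis_table(wide_t: pd.DataFrame, fires: pd.DataFrame) -> pd.DataFrame:
    """Join fire records with lagged climate drivers on the transformed scale.

    Fire year t pairs with dry-season year t-1 and wet season t-1; the first
    fire year (no preceding season in range) is dropped.
    """
    fires = fires.set_index("year")
    clim = pd.DataFrame(
        {
            "nino": wide_t["nino_dry"],
            "tc_wet": wide_t["tc_wet_t"],
            "rain_dry": wide_t["rainfall_dry"],
        }
    )
    clim.index = clim.index + 1  # dry/wet season y drives fire year y+1
    joined = fires.join(clim, how="inner")
    dropped = len(fires) - len(joined.dropna())
    if dropped:
        logger.info("fire analysis: %d fire year(s) dropped by the one-year climate lag", dropped)
    joined["n_fires_t"] = np.sqrt(joined["n_fires"])
    joined["area_t"] = np.sqrt(joined["area_burned"])
    out = pd.DataFrame(
        {
            "nino": joined["nino"],
            "tc_wet": joined["tc_wet"],
            "rain_dry": joined["rain_dry"],
            "n_fires": joined["n_fires_t"],
            "area": joined["area_t"],
        }
    ).dropna()
    return out


def fit_to_dot(fit: SEMFit) -> str:
    """Graphviz DOT of a fitted diagram: standardized labels, significance
    line weights (dashed / gray / thin / medium / thick)."""
    width = {"thick": 3.0, "medium": 2.0, "thin": 1.0, "gray": 1.0, "dashed": 1.0, "none": 1.0}
    lines = [f'digraph "{fit.model.name or "model"}" {{', "  rankdir=LR;"]
    for v in fit.model.variables:
        label = v
        if v in fit.r2:
            label += f"\\nR2={fit.r2[v]:.2f}"
        lines.append(f'  "{v}" [label="{label}"];')
    for e in fit.model.edges:
        p = fit.z_pvalues.get(f"beta:{e.name}")
        tier = significance_tier(p if p is not None else float("nan"))
        style = "dashed" if tier == "dashed" else "solid"
        color = "gray" if tier == "gray" else "black"
        lines.append(
            f'  "{e.source}" -> "{e.target}" [label="{fit.standardized[e.name]:.2f}", '
            f"style={style}, color={color}, penwidth={width[tier]}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: list[str] = []
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "version": __version__,
        "stages": stage_log,
    }

    # ---- stage 1: inputs -------------------------------------------------
    try:
        if config.inputs:
            rain = load_daily_csv(config.inputs["rainfall"])
            nino = read_monthly_index(config.inputs["nino"])
            fires = pd.read_csv(config.inputs["fires"])
            truth = None
        else:
            over = dict(config.simulate or {})
            over.setdefault("seed", config.seed)
            clim_cfg = ClimateGenConfig(**over)
            rain, nino, truth = generate_daily_climate(clim_cfg)
            (out / "ground_truth.json").write_text(
                json.dumps(
                    {
                        "seed": clim_cfg.seed,
                        "calendar": [
                            {
                                "year": int(r.year),
                                "wet_onset": str(r.wet_onset),
                                "wet_cessation": str(r.wet_cessation),
                            }
                            for r in truth.itertuples()
                        ],
                    },
                    indent=1,
                )
            )
        stage_log.append("inputs")
    except Exception as exc:
        raise RuntimeError(f"[stage inputs] {exc}") from exc

    # ---- stage 2: season descriptors ------------------------------------
    try:
        descriptors = build_descriptor_table(rain)
        write_descriptor_table(descriptors, out / "descriptors.tsv")
        n_failed = int((~descriptors["ok"]).sum())
        manifest["descriptor_rows"] = len(descriptors)
        manifest["descriptor_failures"] = n_failed
        wide = descriptor_wide_table(descriptors, nino)
        stage_log.append("descriptors")
    except Exception as exc:
        raise RuntimeError(f"[stage descriptors] {exc}") from exc

    # ---- stage 3: transforms --------------------------------------------
    try:
        specs = {k: v for k, v in DEFAULT_TRANSFORMS.items() if k in wide.columns}
        wide_t = apply_transforms(wide, specs)
        wide_t.to_csv(out / "descriptors_wide.tsv", sep="\t")
        stage_log.append("transforms")
    except Exception as exc:
        raise RuntimeError(f"[stage transforms] {exc}") from exc

    # ---- stage 4: fire records ------------------------------------------
    try:
        if config.inputs is None:
            drivers = pd.DataFrame(
                {
                    "year": wide_t.index + 1,
                    "rain_dry": wide_t["rainfall_dry"],
                    "tc_wet": wide_t["tc_wet_t"],
                    "nino": wide_t["nino_dry"],
                }
            ).dropna()
            fire_over = dict(config.fire_simulate or {})
            fire_over.setdefault("seed", config.seed + 1)
            fires = generate_fire_records(drivers, FireGenConfig(**fire_over))
            fires = fires.rename(columns={"area_burned": "area_burned"})
        fires.to_csv(out / "fires.csv", index=False)
        stage_log.append("fires")
    except Exception as exc:
        raise RuntimeError(f"[stage fires] {exc}") from exc

    # ---- stage 5: starting-model fits ------------------------------------
    fit_reports = {}
    try:
        tables = {
            "dry": seasonal_analysis_table(wide_t, "dry"),
            "wet": seasonal_analysis_table(wide_t, "wet"),
            "fire": fire_analysis_table(wide_t, fires),
        }
        starting = {"dry": "dry_start", "wet": "wet_start", "fire": "fire_start"}
        for key, entry_name in starting.items():
            entry = load_entry(entry_name)
            data = tables[key]
            fit = fit_ml(sample_covariance(data, entry.model.variables), entry.model, len(data))
            fit_reports[entry_name] = fit.to_dict()
            (out / f"fit_{entry_name}.dot").write_text(fit_to_dot(fit))
        stage_log.append("starting-fits")
    except Exception as exc:
        raise RuntimeError(f"[stage starting-fits] {exc}") from exc

    # ---- stage 6: specification searches ---------------------------------
    search_best = {}
    if config.run_searches:
        try:
            for key, fw_name in (("dry", config.seasonal_framework), ("wet", config.seasonal_framework), ("fire", config.fire_framework)):
                fw = ModelFramework.from_catalog(load_entry(fw_name))
                res = search(tables[key], fw)
                res.table(config.top).to_csv(out / f"search_{key}.tsv", sep="\t", index=False)
                best = res.best
                fit_reports[f"best_{key}"] = best.fit.to_dict()
                (out / f"fit_best_{key}.dot").write_text(fit_to_dot(best.fit))
                search_best[key] = {"mask": best.mask, "bcc": best.fit.bcc, "chisq": best.fit.chisq, "df": best.fit.df}
                # effect decomposition of the winning model
                eff = effects_table(best.model, best.fit.standardized)
                eff.to_csv(out / f"effects_best_{key}.tsv", sep="\t")
            stage_log.append("searches")
        except Exception as exc:
            raise RuntimeError(f"[stage searches] {exc}") from exc

    manifest["fits"] = fit_reports
    manifest["search_best"] = search_best
    (out / "run.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=float))
    stage_log.append("report")
    return manifest
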