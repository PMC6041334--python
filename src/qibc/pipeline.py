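"""End-to-end orchestration: config, pipeline run, manifest.

A run executes simulate -> background correction -> segmentation -> feature
extraction -> staging -> quantification (and optionally plate screening) from
a single JSON config with per-module blocks, and writes a manifest recording
seed, parameter hash, package versions and per-stage row counts, so identical
config + seed reproduce identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import imaging, io, quantify, screen, staging
from .simulate import (
    DrugEffects,
    FociModel,
    RenderParams,
    SimulationParams,
    render_population,
    simulate_plate_features,
)

__all__ = ["RunConfig", "ConfigError", "DataError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """A pipeline stage failed on its input (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Typed view of the JSON run configuration."""

    seed: int = 0
    conditions: list[dict] = field(default_factory=lambda: [{"name": "untreated"}])
    generator: dict = field(default_factory=dict)
    render: dict = field(default_factory=dict)
    cells_per_field: int = 150
    channel_map: dict = field(default_factory=lambda: {"dapi": "dapi"})
    staging: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=lambda: {"marker": "gh2ax"})
    foci_channels: list = field(default_factory=list)
    screen: dict | None = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def validate(self) -> None:
        if "dapi" not in self.channel_map:
            raise ConfigError("channel_map must map a 'dapi' channel")
        names = [c.get("name") for c in self.conditions]
        if len(set(names)) != len(names) or any(not n for n in names):
            raise ConfigError("conditions need unique non-empty names")
        marker = self.quantify.get("marker", "gh2ax")
        markers = tuple(self.generator.get("markers", ("gh2ax", "edu", "cyclin_a", "h3ps10")))
        if marker not in markers:
            raise ConfigError(
                f"quantify.marker {marker!r} is not among simulated markers {markers}"
            )

    def simulation_params(self, condition: dict, seed: int) -> SimulationParams:
        gen = dict(self.generator)
        effects = {**gen.pop("drug_effects", {}), **condition.get("drug_effects", {})}
        gen.pop("seed", None)
        gen["markers"] = tuple(gen.get("markers", ("gh2ax", "edu", "cyclin_a", "h3ps10")))
        if "stage_fractions" in gen:
            gen["stage_fractions"] = tuple(gen["stage_fractions"])
        if "foci_models" in gen:
            gen["foci_models"] = {
                name: model if isinstance(model, FociModel) else FociModel(**model)
                for name, model in gen["foci_models"].items()
            }
        try:
            return SimulationParams(
                drug_effects=DrugEffects(**effects),
                pre_extraction=bool(condition.get(
                    "pre_extraction", gen.pop("pre_extraction", False))),
                seed=seed,
                **gen,
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid generator block: {exc}") from exc

    def render_params(self) -> RenderParams:
        ren = dict(self.render)
        if "shape" in ren:
            ren["shape"] = tuple(ren["shape"])
        if "channels" in ren and ren["channels"] is not None:
            ren["channels"] = tuple(ren["channels"])
        try:
            return RenderParams(**ren)
        except TypeError as exc:
            raise ConfigError(f"invalid render block: {exc}") from exc


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _condition_seed(root: int, index: int) -> int:
    ss = np.random.SeedSequence(root, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Writes features.csv, staged.csv, summaries.csv (+ dynamic_range.csv,
    comparisons.csv when a reference condition exists, screen outputs when a
    plate is configured) and manifest.json under ``out_dir``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    render = config.render_params()
    stage_params = staging.StagingParams(
        **{k: v for k, v in config.staging.items() if k != "markers"}
    )
    available = tuple(config.staging.get(
        "markers", ("dapi",) + tuple(config.generator.get(
            "markers", ("gh2ax", "edu", "cyclin_a", "h3ps10")))
    ))

    counts: dict[str, int] = {}
    features_all, staged_all = [], []
    for i, condition in enumerate(config.conditions):
        params = config.simulation_params(condition, _condition_seed(config.seed, i))
        try:
            fields = render_population(
                params, render, cells_per_field=config.cells_per_field,
                meta={"condition": condition["name"]},
            )
        except Exception as exc:
            raise DataError(f"simulate failed for {condition['name']}: {exc}") from exc
        feats = []
        for j, fov in enumerate(fields):
            try:
                corrected = {
                    name: imaging.correct_background(img)
                    for name, img in fov.channels.items()
                }
                seg = imaging.segment_nuclei(corrected["dapi"])
                foci = {
                    ch: imaging.detect_foci(corrected[ch], seg)
                    for ch in config.foci_channels
                    if ch in corrected
                }
                feats.append(
                    imaging.extract_features(
                        corrected, seg, foci=foci or None,
                        meta={**fov.meta, "condition": condition["name"],
                              "field": j,
                              "pre_extraction": params.pre_extraction},
                    )
                )
            except Exception as exc:
                raise DataError(
                    f"segment failed on condition {condition['name']} "
                    f"field {j}: {exc}"
                ) from exc
        feat = pd.concat([f for f in feats if len(f)], ignore_index=True)
        try:
            staged = staging.stage_cells(feat, available, params=stage_params)
            staged = staging.bin_s_phase(staged)
        except Exception as exc:
            raise DataError(f"stage failed for {condition['name']}: {exc}") from exc
        features_all.append(feat)
        staged_all.append(staged)
        counts[f"cells_extracted[{condition['name']}]"] = len(feat)
        counts[f"cells_staged[{condition['name']}]"] = int(
            (staged["stage"] != "excluded").sum()
        )

    features = pd.concat(features_all, ignore_index=True)
    staged = pd.concat(staged_all, ignore_index=True)
    io.write_table(features, out / "features.csv")
    io.write_table(staged, out / "staged.csv")

    marker = config.quantify.get("marker", "gh2ax")
    summaries = quantify.summarize_by_stage(staged, marker)
    io.write_table(summaries, out / "summaries.csv")
    reference = config.quantify.get("reference")
    if reference is not None:
        dr_rows, cmp_rows = [], []
        col = f"mean_{marker}"
        ref_df = staged[staged["condition"] == reference]
        for condition in config.conditions:
            name = condition["name"]
            if name == reference:
                continue
            dr = quantify.dynamic_range(staged, name, reference, marker)
            dr["condition"] = name
            dr_rows.append(dr)
            t_df = staged[staged["condition"] == name]
            for gate in ("all", "S", "mid_S"):
                a = t_df.loc[quantify.gate_mask(t_df, gate), col]
                b = ref_df.loc[quantify.gate_mask(ref_df, gate), col]
                if len(a) and len(b):
                    res = quantify.compare_conditions(a, b, gate=gate)
                    cmp_rows.append(
                        {"condition": name, "gate": gate, "u": res.u,
                         "p": res.p_two_sided, "n1": res.n1, "n2": res.n2,
                         "effect_size": res.effect_size}
                    )
        if dr_rows:
            io.write_table(pd.concat(dr_rows, ignore_index=True),
                           out / "dynamic_range.csv")
        if cmp_rows:
            cmp_df = pd.DataFrame(cmp_rows)
            cmp_df["p_bh"] = quantify.adjust_pvalues(cmp_df["p"])
            io.write_table(cmp_df, out / "comparisons.csv")

    if config.screen is not None:
        try:
            plate = screen.PlateSpec.grid(
                genes=config.screen["genes"],
                n_sirna=int(config.screen.get("n_sirna", 3)),
            )
            base = config.simulation_params(
                {"name": "screen",
                 "drug_effects": config.screen.get("drug_effects", {})},
                config.seed,
            )
            base = dataclasses.replace(
                base, n_cells=int(config.screen.get("cells_per_well", 500))
            )
            plate_feats = simulate_plate_features(
                plate, config.screen.get("effects", {}), base, seed=config.seed
            )
            plate_staged = staging.stage_cells(
                plate_feats, available, params=stage_params, batch_col="arm"
            )
            wells = screen.analyze_wells(
                plate, plate_staged,
                min_cells=int(config.screen.get("min_cells", 200)),
            )
            scores = screen.score_genes(wells, plate)
            io.write_table(wells, out / "screen_wells.csv")
            io.write_table(scores, out / "screen_scores.csv")
            io.write_table(screen.replicate_concordance(wells),
                           out / "screen_concordance.csv")
            counts["screen_wells"] = len(wells)
        except (KeyError, ValueError) as exc:
            raise DataError(f"screen failed: {exc}") from exc

    manifest = {
        "qibc_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config),
        "row_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
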