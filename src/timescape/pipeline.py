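"""Config-driven orchestration: simulate → phenotype → neighborhoods →
G-cross → compare → survive, with a run manifest for exact reproduction.

The pipeline is deterministic under a fixed config + seed: outputs are CSVs
with fixed float formatting and stable row ordering, and the manifest echoes
the full configuration so a run can be repeated identically from it alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .composition import compare_cohorts
from .neighborhoods import (
    NeighborhoodSpec,
    DEFAULT_COMBOS,
    assign_neighborhoods,
    neighborhood_proportions,
)
from .phenotyping import (
    cell_type_proportions,
    classify_cells,
    default_thresholds,
    CELL_TYPES,
    PHENOTYPE_MARKERS,
    INFLAMMATORY_MARKERS,
)
from .simulate import stage_iii_config, stage_iv_config, generate_cohort
from .spatial import Window, gcross_feature_table
from .survival import spatial_survival_scan

log = logging.getLogger("timescape")

__all__ = ["PipelineConfig", "run_pipeline", "demo_config", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "window": {"width": 1000.0, "height": 1000.0},
    "simulate": {
        "arms": [
            {"stage": "III", "n_patients": 20, "cores_per_patient": 2},
            {"stage": "IV", "n_patients": 30, "cores_per_patient": 1},
        ]
    },
    "thresholds": {},  # per-marker overrides; default 3.0
    "neighborhoods": {"radius": 40.0, "combos": None},  # None -> the 7 defaults
    "gcross": {
        "pairs": [["CTL", "Tumor"], ["B", "NK"], ["Th", "TAM"]],
        "radii_report": [20.0, 40.0, 60.0, 80.0],
        "correction": "border",
    },
    "survival": {"feature_radius": 40.0, "adjust": False},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


class PipelineConfig:
    """Validated pipeline configuration (nested dict semantics, YAML on disk)."""

    def __init__(self, data: dict | None = None):
        self.data = _merge(DEFAULT_CONFIG, data or {})
        self.validate()

    def validate(self) -> None:
        radii = self.data["gcross"]["radii_report"]
        if sorted(radii) != list(radii):
            raise PipelineError("[config] gcross radii_report must be ascending")
        known = set(CELL_TYPES) | {"other"}
        for pair in self.data["gcross"]["pairs"]:
            if len(pair) != 2 or not set(pair) <= known:
                raise PipelineError(f"[config] unknown cell type in gcross pair {pair}")
        combos = self.data["neighborhoods"]["combos"]
        if combos is not None:
            markers = set(PHENOTYPE_MARKERS) | set(INFLAMMATORY_MARKERS)
            for name, ms in combos.items():
                bad = set(ms) - markers
                if bad:
                    raise PipelineError(
                        f"[config] neighborhood {name!r} uses unknown marker(s) {sorted(bad)}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_yaml(path)


def demo_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig({"seed": seed})


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig | dict | None, outdir, seed: int | None = None) -> Path:
    """Run the full pipeline into ``outdir``; returns the output directory.

    Writes cells.csv, clinical.csv, proportions CSVs, membership.csv,
    gcross_features.csv, comparisons.csv, survival_scan.csv and
    manifest.json. On failure, partial outputs are retained alongside a
    FAILED marker naming the stage.
    """
    if config is None:
        config = demo_config()
    elif isinstance(config, dict):
        config = PipelineConfig(config)
    if seed is not None:
        config.data["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        manifest = _run(config, outdir)
    except PipelineError as exc:
        failed_marker.write_text(str(exc) + "\n")
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def _run(config: PipelineConfig, outdir: Path) -> dict:
    cfg = config.data
    seed = int(cfg["seed"])
    window = Window(**cfg["window"])
    manifest: dict = {"seed": seed, "config": cfg, "rows": {}}
    import timescape

    manifest["version"] = timescape.__version__

    @_stage("simulate")
    def do_simulate():
        ss = np.random.SeedSequence(seed)
        arm_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(cfg["simulate"]["arms"]))]
        cells_parts, clin_parts = [], []
        for arm, s in zip(cfg["simulate"]["arms"], arm_seeds):
            maker = stage_iii_config if arm["stage"] == "III" else stage_iv_config
            arm_kwargs = {k: v for k, v in arm.items() if k != "stage"}
            c = maker(seed=s, window=window, **arm_kwargs)
            cells, clinical, truth = generate_cohort(c)
            truth.write(outdir / f"ground_truth_{arm['stage']}.json")
            cells_parts.append(cells)
            clin_parts.append(clinical)
        cells = pd.concat(cells_parts, ignore_index=True)
        clinical = pd.concat(clin_parts, ignore_index=True)
        tio.write_cells(cells, outdir / "cells.csv")
        tio.write_clinical(clinical, outdir / "clinical.csv")
        return cells, clinical

    cells, clinical = do_simulate()
    manifest["rows"]["cells"] = len(cells)
    manifest["rows"]["clinical"] = len(clinical)

    thresholds = default_thresholds()
    thresholds.update(cfg["thresholds"] or {})

    @_stage("phenotype")
    def do_phenotype():
        ph = classify_cells(cells, thresholds=thresholds)
        tio.write_cells(ph, outdir / "cells_phenotyped.csv")
        props = cell_type_proportions(ph)
        tio.write_results(props.reset_index(), outdir / "proportions.csv", ["sample_id"])
        return ph, props

    ph_cells, ct_props = do_phenotype()
    manifest["rows"]["proportions"] = len(ct_props)

    @_stage("neighborhoods")
    def do_neighborhoods():
        combos = cfg["neighborhoods"]["combos"] or DEFAULT_COMBOS
        specs = [
            NeighborhoodSpec(name, tuple(ms), cfg["neighborhoods"]["radius"])
            for name, ms in combos.items()
        ]
        mem = assign_neighborhoods(ph_cells, specs, thresholds)
        mem_out = pd.concat([ph_cells[["sample_id"]], mem], axis=1)
        mem_out.insert(1, "cell_index", mem_out.index)
        tio.write_results(mem_out, outdir / "membership.csv")
        nb_props = neighborhood_proportions(ph_cells, mem)
        tio.write_results(
            nb_props.reset_index(), outdir / "neighborhood_proportions.csv", ["sample_id"]
        )
        return mem, nb_props

    membership, nb_props = do_neighborhoods()
    manifest["rows"]["membership"] = len(membership)

    @_stage("gcross")
    def do_gcross():
        feats = gcross_feature_table(
            ph_cells,
            pairs=[tuple(p) for p in cfg["gcross"]["pairs"]],
            radii_report=tuple(cfg["gcross"]["radii_report"]),
            window=window,
            correction=cfg["gcross"]["correction"],
        )
        tio.write_results(feats.reset_index(), outdir / "gcross_features.csv", ["sample_id"])
        return feats

    gfeats = do_gcross()
    manifest["rows"]["gcross_features"] = len(gfeats)

    @_stage("compare")
    def do_compare():
        stages = clinical.set_index("patient_id")["stage"]
        ct = ct_props.copy()
        ct["group"] = ph_cells.groupby("sample_id")["patient_id"].first().map(stages)
        res_ct = compare_cohorts(
            ct.drop(columns="group"), ct["group"], family="cell_types"
        )
        nb = nb_props.copy()
        nb["group"] = ph_cells.groupby("sample_id")["patient_id"].first().map(stages)
        res_nb = compare_cohorts(
            nb.drop(columns="group"), nb["group"], family="neighborhoods"
        )
        res = pd.concat([res_ct, res_nb], ignore_index=True)
        tio.write_results(res, outdir / "comparisons.csv", ["family", "feature"])
        return res

    comparisons = do_compare()
    manifest["rows"]["comparisons"] = len(comparisons)

    @_stage("survive")
    def do_survive():
        r = cfg["survival"]["feature_radius"]
        cols = [c for c in gfeats.columns if c.endswith(f"_{r:g}")]
        scan = spatial_survival_scan(
            gfeats, clinical, feature_cols=cols,
            family=f"gcross_{r:g}um", adjust=cfg["survival"]["adjust"],
        )
        tio.write_results(scan, outdir / "survival_scan.csv", ["family", "feature"])
        return scan

    scan = do_survive()
    manifest["rows"]["survival_scan"] = len(scan)
    return manifest
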