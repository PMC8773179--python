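"""End-to-end orchestration: design -> simulate -> score -> integrate -> qc.

Every stage reads/writes plain CSV/JSON under one output directory, is
runnable standalone from prior outputs, and derives its randomness from the
single run seed so reruns are byte-identical. A manifest with content
digests is written last.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

import gsis_screen
from gsis_screen.errors import ScreenError
from gsis_screen import library_layout as ll
from gsis_screen import qpcr_ddct
from gsis_screen import ssmd_hit_calling as shc
from gsis_screen import synthetic_screen as ss

DEFAULT_CONFIG: dict[str, Any] = {
    "library": {"path": None, "n_genes": 521},
    "design": {
        "replicates": 3,
        "capacity": 75,
        "conditions": list(ll.DEFAULT_CONDITIONS),
        "nt_wells": 33,
        "control_wells": {g: 8 for g in ll.CONTROL_GENES},
        "zero_pad_wells": False,
        "volume_nl": 100.0,
    },
    "noise": {
        "well_cv": 0.15,
        "plate_sigma": 0.1,
        "base_signal": 1000.0,
        "condition_fold": {"0mM": 1.0, "20mM": 2.5, "20mM+IBMX": 5.5},
        "base_cells": 3000.0,
        "cell_cv": 0.12,
        "row_gradient": 0.0,
    },
    "effects": {
        "n_up": 23,
        "n_down": 68,
        "up_multiplier": 2.5,
        "down_multiplier": 0.4,
        "n_killed": 10,
    },
    "scoring": {"up_cut": 1.5, "down_cut": -1.5, "viability_cut": -1.5},
}


def merge_config(overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Defaults deep-merged with ``overrides`` (overrides win)."""

    def _merge(base: dict, over: Mapping) -> dict:
        out = copy.deepcopy(base)
        for k, v in over.items():
            if isinstance(v, Mapping) and isinstance(out.get(k), dict):
                out[k] = _merge(out[k], v)
            else:
                out[k] = copy.deepcopy(v)
        return out

    return _merge(DEFAULT_CONFIG, overrides or {})


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the run seed and stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**63)


class StageError(ScreenError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stages


def stage_design(config: dict, seed: int, outdir: Path) -> dict[str, Path]:
    d = config["design"]
    lib_cfg = config["library"]
    if lib_cfg.get("path"):
        library = ll.load_library(lib_cfg["path"])
    else:
        library = ss.make_synthetic_library(
            n_genes=int(lib_cfg.get("n_genes", 521)),
            seed=derive_seed(seed, "library"),
        )
    controls = ll.ControlSpec(
        nt_wells=int(d["nt_wells"]),
        control_wells={k: int(v) for k, v in d["control_wells"].items()},
    )
    plate_sets = ll.assign_wells(
        library,
        replicates=int(d["replicates"]),
        capacity=int(d["capacity"]),
        controls=controls,
        seed=derive_seed(seed, "design"),
        conditions=tuple(d["conditions"]),
    )
    report = ll.validate_layout(plate_sets, replicates=int(d["replicates"]), controls=controls)
    if not report.ok:
        raise ScreenError(f"generated layout invalid: {report.violations[:5]}")
    picklist = ll.generate_picklist(plate_sets, library, volume_nl=float(d["volume_nl"]))

    paths = {
        "library": outdir / "library.csv",
        "layout": outdir / "layout.csv",
        "picklist": outdir / "picklist.csv",
    }
    ll.write_library(library, paths["library"])
    ll.write_layout(plate_sets, paths["layout"])
    ll.write_picklist(picklist, paths["picklist"], zero_pad=bool(d["zero_pad_wells"]))
    return paths


def stage_simulate(config: dict, seed: int, outdir: Path) -> dict[str, Path]:
    d = config["design"]
    conditions = tuple(d["conditions"])
    plate_sets = ll.read_layout(outdir / "layout.csv", conditions=conditions)
    genes = sorted({g for ps in plate_sets for g in ps.genes(("candidate", "control"))})
    e = config["effects"]
    rng = np.random.default_rng(derive_seed(seed, "killed"))
    pool = [g for g in genes if g not in ll.CONTROL_GENES]
    n_killed = min(int(e.get("n_killed", 0)), len(pool))
    killed = (
        [pool[i] for i in rng.choice(len(pool), size=n_killed, replace=False)]
        if n_killed
        else []
    )
    effects = ss.plant_effects(
        genes,
        n_up=int(e["n_up"]),
        n_down=int(e["n_down"]),
        up_multiplier=float(e["up_multiplier"]),
        down_multiplier=float(e["down_multiplier"]),
        viability_killed=killed,
        seed=derive_seed(seed, "effects"),
        conditions=conditions,
    )
    noise = ss.NoiseConfig(**config["noise"])
    measurements = ss.simulate_screen(
        plate_sets, effects, noise, seed=derive_seed(seed, "simulate")
    )
    paths = {
        "measurements": outdir / "measurements.csv",
        "effects": outdir / "effects.csv",
    }
    measurements.to_csv(paths["measurements"], index=False)
    effects.to_frame(conditions).to_csv(paths["effects"], index=False)
    return paths


def stage_score(config: dict, seed: int, outdir: Path) -> dict[str, Path]:
    d = config["design"]
    s = config["scoring"]
    conditions = tuple(d["conditions"])
    plate_sets = ll.read_layout(outdir / "layout.csv", conditions=conditions)
    measurements = pd.read_csv(outdir / "measurements.csv")
    scores = shc.score_screen(measurements, plate_sets)
    hits = shc.call_hits(
        scores,
        up_cut=float(s["up_cut"]),
        down_cut=float(s["down_cut"]),
        viability_cut=float(s["viability_cut"]),
        conditions=conditions,
    )
    venn = shc.integrate_conditions(hits, conditions=conditions)
    folds = shc.fold_induction(measurements, plate_sets)
    qc = shc.qc_controls(scores, folds)
    qc["viability_cut"] = float(s["viability_cut"])

    paths = {
        "scores": outdir / "scores.csv",
        "hits": outdir / "hits.csv",
        "venn": outdir / "venn.json",
        "qc": outdir / "qc.json",
    }
    scores.to_csv(paths["scores"], index=False)
    hits.to_csv(paths["hits"], index=False)
    paths["venn"].write_text(json.dumps(venn, indent=2, sort_keys=True))
    paths["qc"].write_text(json.dumps(qc, indent=2, sort_keys=True))
    return paths


def render_summary(outdir: Path, conditions: tuple[str, ...]) -> str:
    """Human-readable markdown summary of a scored run."""
    hits = pd.read_csv(outdir / "hits.csv")
    venn = json.loads((outdir / "venn.json").read_text())
    qc = json.loads((outdir / "qc.json").read_text())

    lines = ["# Screen summary", ""]
    lines.append("## Hit counts")
    lines.append("")
    lines.append("| condition | up | down |")
    lines.append("|---|---|---|")
    for c in conditions:
        col = f"direction_{c}"
        if len(hits) and col in hits.columns:
            up = int((hits[col] == "up").sum())
            down = int((hits[col] == "down").sum())
        else:
            up = down = 0
        lines.append(f"| {c} | {up} | {down} |")
    up_union = venn["directions"]["up"]["union_count"]
    down_union = venn["directions"]["down"]["union_count"]
    lines.append("")
    lines.append(
        f"Union over conditions: {up_union} up, {down_union} down, "
        f"{up_union + down_union} total hits."
    )
    excluded = int(hits["viability_excluded"].sum()) if len(hits) else 0
    lines.append(f"Viability-excluded genes: {excluded}.")
    lines.append("")
    lines.append("## Control QC")
    lines.append("")
    n_checks = len(qc["controls"])
    n_pass = sum(1 for c in qc["controls"] if c["status"] == "pass")
    lines.append(f"Control checks passed: {n_pass}/{n_checks}.")
    if qc["folds"]:
        by_cond: dict[str, list[float]] = {}
        for f in qc["folds"]:
            by_cond.setdefault(f["condition"], []).append(f["fold"])
        for c, vals in by_cond.items():
            lines.append(
                f"Mean NT fold induction {c}: {sum(vals) / len(vals):.2f} "
                f"(n={len(vals)} sets)"
            )
    lines.append("")
    return "\n".join(lines)


def run_pipeline(
    config: Mapping[str, Any] | None,
    seed: int,
    outdir: str | Path,
) -> dict[str, Any]:
    """Run design -> simulate -> score -> report; write manifest last."""
    cfg = merge_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    conditions = tuple(cfg["design"]["conditions"])

    produced: dict[str, Path] = {}
    for stage_name, fn in (
        ("design", stage_design),
        ("simulate", stage_simulate),
        ("score", stage_score),
    ):
        try:
            produced.update(fn(cfg, seed, out))
        except Exception as exc:  # partial outputs are retained on disk
            raise StageError(stage_name, exc) from exc

    summary_path = out / "summary.md"
    summary_path.write_text(render_summary(out, conditions))
    produced["summary"] = summary_path

    manifest = {
        "package_version": gsis_screen.__version__,
        "seed": seed,
        "stage_seeds": {
            s: derive_seed(seed, s)
            for s in ("library", "design", "killed", "effects", "simulate")
        },
        "config": cfg,
        "outputs": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in produced.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_qpcr(
    ct_path: str | Path, calibrator: str, outdir: str | Path
) -> dict[str, Path]:
    """Standalone ddCt stage from a Ct CSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records = pd.read_csv(ct_path)
    rel = qpcr_ddct.relative_expression(records, calibrator_condition=calibrator)
    summary = qpcr_ddct.knockdown_summary(rel)
    paths = {
        "relative_expression": out / "relative_expression.csv",
        "knockdown_summary": out / "knockdown_summary.csv",
    }
    rel.to_csv(paths["relative_expression"], index=False)
    summary.to_csv(paths["knockdown_summary"], index=False)
    return paths
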