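"""Configuration-driven orchestration of the full analysis.

The pipeline either simulates a cohort or ingests template-space fiducial
files plus an electrode tip table, then runs: registration error ->
summaries -> r2 map -> stacked PCA -> variance attribution -> analytic VTA
context. Outputs are CSV tables printed at fixed precision (so reruns are
byte-identical) plus a ``report.json`` validated against a bundled schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, simulate_cohort
from .covariance import (
    attribute_variance,
    center_targets,
    pca,
    r2_map,
    stacked_pca,
)
from .errors import DegenerateStatisticsError, InputError
from .io import FiducialSet, load_template_consensus, read_fcsv
from .metrics import global_afre, registration_error, rmse_by_axis, summarize
from .vta import dice_after_shift, sphere_radius_from_volume

log = logging.getLogger("afidreg")

FLOAT_FORMAT = "%.6f"


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    outdir: Path
    seed: int | None = None
    simulate: dict | None = None
    fiducials_dir: Path | None = None
    tips_csv: Path | None = None
    template_fcsv: Path | None = None
    alpha: float = 0.05
    bonferroni_afids: int = 32
    bonferroni_axes: int = 6
    analysis_afids: tuple[int, ...] = (2, 3, 4, 14)
    n_afre_prcs: int = 4
    vta_volume_mm3: float = 100.0
    vta_shifts_mm: tuple[float, ...] = (1.0, 2.0, 3.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InputError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.simulate is None:
            if self.fiducials_dir is None or self.tips_csv is None:
                raise InputError(
                    "config must either simulate or provide fiducials_dir and tips_csv"
                )
            for p in (self.fiducials_dir, self.tips_csv, self.template_fcsv):
                if p is not None and not Path(p).exists():
                    raise InputError(f"input path does not exist: {p}")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise InputError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fiducials_dir", "tips_csv", "template_fcsv"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        for key in ("analysis_afids", "vta_shifts_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    payload = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in vars(config).items()
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_schema() -> dict:
    raw = resources.files("afidreg.data").joinpath("report.schema.json").read_text()
    return json.loads(raw)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "null": type(None),
}


def validate_report(report: dict, schema: dict | None = None, path: str = "$") -> None:
    """Minimal structural validation against the bundled JSON schema.

    Supports the subset the schema uses: type, required, properties, items.
    Raises :class:`InputError` on the first violation.
    """
    if schema is None:
        schema = _load_schema()
    typ = schema.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        ok = False
        for t in allowed:
            if t == "number":
                ok = ok or (isinstance(report, (int, float)) and not isinstance(report, bool))
            elif t == "integer":
                ok = ok or (isinstance(report, int) and not isinstance(report, bool))
            else:
                ok = ok or isinstance(report, _TYPES[t])
        if not ok:
            raise InputError(f"report schema violation at {path}: expected {typ}, "
                             f"got {type(report).__name__}")
    if isinstance(report, dict):
        for key in schema.get("required", []):
            if key not in report:
                raise InputError(f"report schema violation at {path}: missing {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{path}.{key}")
    if isinstance(report, list) and "items" in schema:
        for i, item in enumerate(report):
            validate_report(item, schema["items"], f"{path}[{i}]")


def _load_inputs(config: RunConfig) -> tuple[list[FiducialSet], pd.DataFrame]:
    paths = sorted(Path(config.fiducials_dir).glob("*.fcsv"))
    if not paths:
        raise InputError(f"no .fcsv files under {config.fiducials_dir}")
    sets = [
        read_fcsv(p, subject_id=p.stem, rater_id="transformed", space="template")
        for p in paths
    ]
    tips = pd.read_csv(config.tips_csv)
    required = {"subject", "side", "x_mm", "y_mm", "z_mm"}
    missing = required - set(tips.columns)
    if missing:
        raise InputError(f"tips table is missing columns: {sorted(missing)}")
    fid_subjects = {s.subject_id for s in sets}
    tip_subjects = set(tips["subject"])
    if fid_subjects != tip_subjects:
        only_fid = sorted(fid_subjects - tip_subjects)
        only_tip = sorted(tip_subjects - fid_subjects)
        raise InputError(
            "subject ids disagree between fiducials and tips; "
            f"fiducials-only={only_fid}, tips-only={only_tip}"
        )
    return sets, tips


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the CSV bundle plus ``report.json``.

    Returns the report dict. Deterministic given the config (and seed when
    simulating); rerunning into a fresh directory reproduces the outputs
    byte for byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    outputs: dict[str, str] = {}

    def save(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        p = outdir / name
        frame.to_csv(p, float_format=FLOAT_FORMAT, index=index)
        outputs[name.removesuffix(".csv")] = str(p)

    # --- stage: cohort -----------------------------------------------------
    if config.simulate is not None:
        spec_kwargs = dict(config.simulate)
        if config.seed is not None:
            spec_kwargs.setdefault("seed", config.seed)
        for key in ("pattern_centers", "pattern_amplitudes", "residual_centers"):
            if key in spec_kwargs:
                spec_kwargs[key] = tuple(tuple(c) for c in spec_kwargs[key])
        for key in ("pattern_widths", "electrode_target", "analysis_afids"):
            if key in spec_kwargs:
                spec_kwargs[key] = tuple(spec_kwargs[key])
        spec = CohortSpec(**spec_kwargs)
        sets, tips, _ = simulate_cohort(spec)
        log.info("simulated cohort: %d subjects", spec.n_subjects)
    else:
        sets, tips = _load_inputs(config)
        log.info("loaded %d fiducial sets, %d tips", len(sets), len(tips))
    stages.append("cohort")

    # --- stage: registration error ----------------------------------------
    consensus = (
        read_fcsv(config.template_fcsv, subject_id="template",
                  rater_id="consensus", space="template")
        if config.template_fcsv is not None
        else load_template_consensus()
    )
    afre = pd.concat(
        [registration_error(s, consensus) for s in sets], ignore_index=True
    )
    save("afre.csv", afre)
    stages.append("afre")
    log.info("AFRE rows: %d", len(afre))

    # --- stage: summaries --------------------------------------------------
    per_afid = []
    for afid, grp in afre.groupby("afid"):
        s = summarize(grp["euclidean_mm"].to_numpy())
        per_afid.append(dict(afid=int(afid), **s.__dict__))
    save("afre_summary.csv", pd.DataFrame(per_afid))
    g = global_afre(afre)
    save("global_afre.csv", g.reset_index())
    gsum = summarize(g.to_numpy())
    rmse = rmse_by_axis(afre)
    stages.append("summaries")

    # --- stage: tips + r2 map ---------------------------------------------
    centered = center_targets(tips, grouping="pooled_after_per_side_centering")
    save("tips_centered.csv", centered)
    grid = r2_map(
        afre, centered, alpha=config.alpha, bonferroni_m=config.bonferroni_afids
    )
    save("r2_map.csv", grid)
    stages.append("r2_map")

    # --- stage: stacked PCA + attribution ---------------------------------
    report_pca: dict[str, Any] = {"skipped": False, "reason": None}
    report_attr: dict[str, Any] = {"skipped": False, "reason": None}
    analysis_afids = [a for a in config.analysis_afids
                      if a in set(afre["afid"])]
    afre_var = float(
        afre.loc[afre["afid"].isin(analysis_afids),
                 ["dx_mm", "dy_mm", "dz_mm"]].var().sum()
    ) if analysis_afids else 0.0
    if len(analysis_afids) < 2 or afre_var < 1e-12:
        reason = "degenerate variance" if analysis_afids else "no analysis landmarks"
        report_pca = {"skipped": True, "reason": reason}
        report_attr = {"skipped": True, "reason": reason}
        log.info("stacked PCA / attribution skipped: %s", reason)
    else:
        axes = stacked_pca(afre, analysis_afids)
        loadings = pd.DataFrame(
            axes.components,
            index=axes.feature_labels,
            columns=[f"PrC{i + 1}" for i in range(axes.n_components)],
        )
        save("stacked_pca_loadings.csv", loadings, index=True)
        scores = pd.DataFrame(
            axes.scores,
            index=pd.Index(axes.sample_ids, name="subject"),
            columns=loadings.columns,
        )
        save("stacked_pca_scores.csv", scores, index=True)
        report_pca.update(
            explained_fraction=[float(f) for f in axes.explained_fraction],
            landmarks=[int(a) for a in analysis_afids],
        )
        tip_matrix = centered.set_index(["subject", "side"])[
            ["dx_mm", "dy_mm", "dz_mm"]
        ]
        tip_axes = pca(
            tip_matrix,
            feature_labels=["x", "y", "z"],
            sample_ids=list(tip_matrix.index),
        )
        try:
            attr = attribute_variance(
                axes, tip_axes, n_afre_components=config.n_afre_prcs
            )
            save("attribution_r2.csv", attr.r2_matrix, index=True)
            ids = list(attr.explained_mm.index)
            explained = pd.DataFrame(
                {
                    "subject": [i[0] for i in ids],
                    "side": [i[1] for i in ids],
                    "explained_mm": attr.explained_mm.to_numpy(),
                }
            )
            save("explained_mm.csv", explained)
            report_attr.update({k: v for k, v in attr.summary.items()})
        except DegenerateStatisticsError as exc:
            report_attr = {"skipped": True, "reason": str(exc)}
            log.info("attribution skipped: %s", exc)
    stages.append("attribution")

    # --- stage: VTA context ------------------------------------------------
    radius = sphere_radius_from_volume(config.vta_volume_mm3)
    vta_rows = [
        dict(
            volume_mm3=float(config.vta_volume_mm3),
            shift_mm=float(shift),
            radius_mm=float(radius),
            dice=float(dice_after_shift(config.vta_volume_mm3, shift)),
        )
        for shift in config.vta_shifts_mm
    ]
    save("vta_dice.csv", pd.DataFrame(vta_rows))
    stages.append("vta")

    report = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_subjects": int(len(sets)),
        "n_electrodes": int(len(tips)),
        "stages": stages,
        "global_afre": {
            "median": gsum.median,
            "iqr_low": gsum.iqr_low,
            "iqr_high": gsum.iqr_high,
            "n": gsum.n,
        },
        "rmse_by_axis": {ax: float(v) for ax, v in rmse.items()},
        "stacked_pca": report_pca,
        "attribution": report_attr,
        "vta": vta_rows,
        "outputs": outputs,
        "versions": {
            "afidreg": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    validate_report(report)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    outputs["report"] = str(report_path)
    log.info("report written to %s", report_path)
    return report
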