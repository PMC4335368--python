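"""End-to-end reproducible runs: simulate -> segment -> quantify -> flow -> stats.

A run writes, under its output directory:

* ``measures.csv`` — one row per subject and method with all measures;
* ``summary.csv`` / ``summary.json`` — cohort table (mean +/- SEM, p-values);
* ``flow_concordance.json`` — volumetric-vs-aortic SV per group and method;
* ``bland_altman.json`` — simulated repeatability (optional);
* ``reclassification.json`` — counts above a user-supplied indexed-LVM
  cutoff per group and method (only when a cutoff is given: the upper limit
  of normal depends on the external reference range in use and is therefore
  a required user input);
* ``run.log`` — config echo and progress (not part of the deterministic
  output contract).

Identical config and seed produce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .phantom import generate_cohort
from .quantify import QuantConfig
from .segmentation import SegmentationConfig
from .stats import (
    SubjectMeasures,
    cohort_table,
    flow_concordance,
    measure_cohort,
    measures_frame,
    observer_repeatability,
)


@dataclass
class RunConfig:
    n_control: int = 20
    n_fabry: int = 20
    seed: int = 0
    out_dir: str = "pntquant_run"
    seg: SegmentationConfig = field(default_factory=SegmentationConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    with_flow: bool = True
    with_repeatability: bool = False
    lvm_indexed_cutoff: float | None = None  # g/m^2; enables reclassification counts
    no_noise: bool = False
    supersample: int | None = None

    def validate(self) -> None:
        if self.n_control < 0 or self.n_fabry < 0:
            raise ValidationError("cohort sizes must be >= 0")
        if not float(self.seed).is_integer():
            raise ValidationError("seed must be an integer")


def _spec_overrides(config: RunConfig) -> dict:
    overrides: dict = {}
    if config.no_noise:
        overrides["noise_sd"] = 0.0
        overrides["velocity_noise_sd"] = 0.0
    if config.supersample is not None:
        overrides["supersampling_factor"] = config.supersample
    return overrides


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits) if math.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(float(obj), ndigits)
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_round_floats(payload), indent=1, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study design; returns a map of output artifact paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config: {dataclasses.asdict(config)}", f"seed: {config.seed}"]

    overrides = _spec_overrides(config)
    cohorts = []
    for offset, (name, n) in enumerate((("control", config.n_control), ("fabry", config.n_fabry))):
        if n > 0:
            log_lines.append(f"simulating {n} {name} subjects")
            cohorts.append(generate_cohort(name, n, config.seed + offset, **overrides))
    records = [rec for cohort in cohorts for rec in cohort]
    if not records:
        raise ValidationError("nothing to run: both cohort sizes are zero")

    measured = measure_cohort(records, config.seg, config.quant, with_flow=config.with_flow)
    frame = measures_frame(measured)
    paths = {"measures": out / "measures.csv"}
    frame.to_csv(paths["measures"], index=False, float_format="%.6f")

    by_group: dict[str, list[SubjectMeasures]] = {}
    for m in measured:
        by_group.setdefault(m.record.group, []).append(m)

    if all(len(ms) >= 2 for ms in by_group.values()):
        summary = cohort_table(measured)
        paths["summary_csv"] = out / "summary.csv"
        paths["summary_json"] = out / "summary.json"
        summary.to_frame().to_csv(paths["summary_csv"], float_format="%.6f")
        _write_json(
            paths["summary_json"],
            {
                "n_per_group": summary.n_per_group,
                "table": summary.to_frame().reset_index().to_dict(orient="records"),
            },
        )
    else:
        log_lines.append("warning: groups too small for a cohort summary table")

    if config.with_flow:
        conc = {}
        for group, ms in by_group.items():
            for method in ("minc", "mex"):
                mean, sem, p = flow_concordance(ms, method)
                conc[f"{group}_{method}"] = {"mean_diff_ml": mean, "sem_ml": sem, "p": p}
        paths["flow_concordance"] = out / "flow_concordance.json"
        _write_json(paths["flow_concordance"], conc)
    else:
        log_lines.append("warning: flow disabled; concordance section omitted")

    if config.with_repeatability:
        ba = {}
        for group, ms in by_group.items():
            if len(ms) < 2:
                continue
            results = observer_repeatability(
                [m.record for m in ms], perturbation_seed=config.seed + 100,
                seg_config=config.seg, quant_config=config.quant,
            )
            for (measure, method), res in results.items():
                ba[f"{group}_{measure}_{method}"] = dataclasses.asdict(res)
        paths["bland_altman"] = out / "bland_altman.json"
        _write_json(paths["bland_altman"], ba)

    if config.lvm_indexed_cutoff is not None:
        counts = {}
        for group, ms in by_group.items():
            for method in ("minc", "mex"):
                above = sum(
                    1 for m in ms if m.by_method(method).lvm_indexed > config.lvm_indexed_cutoff
                )
                counts[f"{group}_{method}"] = {"above_cutoff": above, "n": len(ms)}
        counts["cutoff_g_m2"] = config.lvm_indexed_cutoff
        paths["reclassification"] = out / "reclassification.json"
        _write_json(paths["reclassification"], counts)

    log_lines.append("done")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    paths["log"] = out / "run.log"
    return {k: str(v) for k, v in paths.items()}
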