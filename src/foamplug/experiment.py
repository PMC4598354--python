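"""Multi-condition study orchestration and replicate aggregation.

A *condition* is one cell of the multi-parametric design: tube diameter,
inclination, foam production method (DSS / Tessari / PEM), gaseous phase,
liquid:gas ratio (LGR), and injection delay, with N replicate injections
(default 4). Each replicate yields a dwell time DT via the kinetics model;
a condition is summarised by the mean DT over *successful* replicates and
its percentage deviation of the mean, with failed plugs counted separately
rather than imputed.

``run_study`` drives the whole pipeline from a declarative YAML config
(simulation parameters or series files per condition) and writes
per-replicate JSON, per-condition CSVs, a study-level comparison table and
a run log; identical config + seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import AllPlugsFailed, InvalidParameterError, NoPlugFormed
from .kinetics import PlugKineticsModel, PlugKineticsResults, normalise_dt
from .series import PlugLengthSeries
from .simulate import SimKinetics, simulate_series

Method = Literal["DSS", "Tessari", "PEM"]
Gas = Literal["RA", "CO2", "CO2_O2_65_35", "CO2_O2_35_65"]
Lgr = Literal["1:3", "1:4", "1:5", "1:7"]
Delay = Literal["immediate", "delayed"]

#: Column order of the study comparison table.
_KEY_COLUMNS = ["tube_id_mm", "method", "gas", "lgr", "delay"]


class FoamCondition(BaseModel):
    """One experimental condition of the study design.

    PEM is a fixed formulation (canister-generated 35:65 CO2:O2 microfoam
    at LGR 1:7), so configs declaring PEM with any other LGR or gas are
    rejected up front.
    """

    model_config = {"frozen": True}

    tube_id_mm: float = Field(4.0, gt=0)
    inclination_deg: float = Field(25.0, ge=0, lt=90)
    method: Method = "DSS"
    gas: Gas = "RA"
    lgr: Lgr = "1:3"
    delay: Delay = "immediate"
    n_replicates: int = Field(4, ge=1)

    @model_validator(mode="after")
    def _pem_is_fixed(self) -> "FoamCondition":
        if self.method == "PEM":
            if self.lgr != "1:7":
                raise ValueError("PEM has a fixed LGR of 1:7")
            if self.gas != "CO2_O2_35_65":
                raise ValueError("PEM gas is fixed at 35:65 CO2:O2")
        return self

    def key(self) -> str:
        """Stable condition identifier used in file names and tables."""
        return (
            f"{self.tube_id_mm:g}mm_{self.method}_{self.gas}_"
            f"{self.lgr.replace(':', '-')}_{self.delay}"
        )


def pct_deviation(values, method: str = "mad") -> float:
    """Percentage deviation of the mean over replicate values.

    ``method="mad"`` (default): mean absolute deviation from the mean,
    divided by the mean, x100. ``method="cv"``: coefficient of variation
    (sample SD / mean x100). Requires at least 2 positive values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidParameterError("need >= 2 values for a deviation")
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise InvalidParameterError("values must be finite and > 0")
    mean = values.mean()
    if method == "mad":
        spread = np.abs(values - mean).mean()
    elif method == "cv":
        spread = values.std(ddof=1)
    else:
        raise InvalidParameterError(f"unknown deviation method {method!r}")
    return float(spread / mean * 100.0)


@dataclass
class ConditionResult:
    """Replicate-aggregated dwell-time statistics for one condition."""

    condition: FoamCondition
    dts: list[float]  # s/cm, successful replicates only
    mean_dt: float  # s/cm
    pct_deviation: float  # %; NaN when < 2 successes
    n_failed: int
    replicates: list[Optional[PlugKineticsResults]]  # None where failed


def run_condition(
    condition: FoamCondition,
    series_inputs: list[PlugLengthSeries],
    plug_gate: float = 5.0,
    deviation_method: str = "mad",
) -> ConditionResult:
    """Fit kinetics for every replicate series and aggregate.

    Replicates raising :class:`NoPlugFormed` are counted in ``n_failed``
    and excluded from the mean; a condition where every plug fails raises
    :class:`AllPlugsFailed` (as observed for every foam in the wide phantom
    at steep inclination).
    """
    if len(series_inputs) != condition.n_replicates:
        raise InvalidParameterError(
            f"expected {condition.n_replicates} replicate series, "
            f"got {len(series_inputs)}"
        )
    replicates: list[Optional[PlugKineticsResults]] = []
    dts: list[float] = []
    n_failed = 0
    for series in series_inputs:
        try:
            res = PlugKineticsModel(series, plug_gate=plug_gate).fit()
        except NoPlugFormed:
            replicates.append(None)
            n_failed += 1
            continue
        replicates.append(res)
        dts.append(res.dwell_time_s_cm)
    if not dts:
        raise AllPlugsFailed(
            f"all {condition.n_replicates} replicates of {condition.key()} "
            "failed to form a plug"
        )
    dev = pct_deviation(dts, method=deviation_method) if len(dts) >= 2 else float("nan")
    return ConditionResult(
        condition=condition,
        dts=dts,
        mean_dt=float(np.mean(dts)),
        pct_deviation=dev,
        n_failed=n_failed,
        replicates=replicates,
    )


def comparison_table(results, normalise: bool = False) -> pd.DataFrame:
    """Long-format study comparison table, stably sorted by condition key.

    One row per condition with the design fields, mean DT, percentage
    deviation and failure count; with ``normalise=True`` an extra column
    gives DT normalised to the highest mean DT.
    """
    results = list(results)
    if not results:
        raise InvalidParameterError("no condition results to tabulate")
    rows = []
    for r in results:
        c = r.condition
        rows.append(
            {
                "tube_id_mm": c.tube_id_mm,
                "inclination_deg": c.inclination_deg,
                "method": c.method,
                "gas": c.gas,
                "lgr": c.lgr,
                "delay": c.delay,
                "n_replicates": c.n_replicates,
                "n_failed": r.n_failed,
                "mean_dt_s_cm": r.mean_dt,
                "pct_deviation": r.pct_deviation,
            }
        )
    df = pd.DataFrame(rows)
    if df.duplicated(subset=_KEY_COLUMNS).any():
        dupes = df.loc[df.duplicated(subset=_KEY_COLUMNS), _KEY_COLUMNS]
        raise InvalidParameterError(f"duplicate condition keys: {dupes.to_dict('records')}")
    df = df.sort_values(_KEY_COLUMNS, kind="stable").reset_index(drop=True)
    if normalise:
        df["dt_normalised"] = normalise_dt(df["mean_dt_s_cm"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Declarative study configuration


class SimulationSpec(BaseModel):
    """Ground-truth kinetics for simulated replicates of one condition."""

    model_config = {"frozen": True}

    formation_rate_mm_s: float = Field(gt=0)
    degradation_rate_mm_s: float = Field(gt=0)
    max_length_mm: float = Field(100.0, gt=0)
    start_time_s: float = Field(1.0, ge=0)
    noise_sigma_mm: float = Field(0.5, ge=0)
    frame_interval_s: float = Field(0.03, gt=0)
    plug_fails: bool = False


class ConditionSpec(BaseModel):
    """A condition plus its data source: simulation parameters or paths to
    per-replicate series CSVs (exactly one of the two)."""

    model_config = {"frozen": True}

    condition: FoamCondition
    simulate: Optional[SimulationSpec] = None
    series_paths: Optional[list[str]] = None

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "ConditionSpec":
        if (self.simulate is None) == (self.series_paths is None):
            raise ValueError("provide exactly one of 'simulate' or 'series_paths'")
        if self.series_paths is not None and len(self.series_paths) != (
            self.condition.n_replicates
        ):
            raise ValueError("one series path per replicate required")
        return self


class StudyConfig(BaseModel):
    """Top-level study file."""

    model_config = {"frozen": True}

    name: str = "study"
    seed: int = 0
    plug_gate_mm: float = Field(5.0, gt=0)
    deviation_method: Literal["mad", "cv"] = "mad"
    normalise: bool = True
    conditions: list[ConditionSpec] = Field(min_length=1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(raw)


def _replicate_seed(base_seed: int, cond_idx: int, rep_idx: int) -> int:
    """Deterministic per-replicate noise seed below 2^31."""
    ss = np.random.SeedSequence([base_seed, cond_idx, rep_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def run_study(
    config: StudyConfig | str | Path, out_dir: str | Path
) -> pd.DataFrame:
    """Execute a whole study and write its outputs.

    Per replicate a JSON record is written under ``replicates/``; per
    condition a CSV of replicate kinetics under ``conditions/``; the study
    comparison table to ``comparison.csv``; and a run log (config hash,
    seeds, one line per replicate) to ``run.log``. Conditions where every
    plug fails are logged and excluded from the comparison table. Returns
    the comparison table.
    """
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    out_dir = Path(out_dir)
    (out_dir / "replicates").mkdir(parents=True, exist_ok=True)
    (out_dir / "conditions").mkdir(exist_ok=True)

    config_json = config.model_dump_json()
    config_hash = hashlib.sha256(config_json.encode()).hexdigest()
    log_lines = [f"study={config.name} config_sha256={config_hash} seed={config.seed}"]

    results: list[ConditionResult] = []
    for ci, spec in enumerate(config.conditions):
        cond = spec.condition
        series_list: list[PlugLengthSeries] = []
        seeds: list[int | None] = []
        for ri in range(cond.n_replicates):
            if spec.simulate is not None:
                seed = _replicate_seed(config.seed, ci, ri)
                kin = SimKinetics(
                    formation_rate=spec.simulate.formation_rate_mm_s,
                    degradation_rate=spec.simulate.degradation_rate_mm_s,
                    max_length=spec.simulate.max_length_mm,
                    start_time=spec.simulate.start_time_s,
                    noise_sigma=spec.simulate.noise_sigma_mm,
                    seed=seed,
                    plug_fails=spec.simulate.plug_fails,
                )
                series_list.append(
                    simulate_series(kin, frame_interval=spec.simulate.frame_interval_s)
                )
                seeds.append(seed)
            else:
                series_list.append(PlugLengthSeries.from_csv(spec.series_paths[ri]))
                seeds.append(None)
        try:
            res = run_condition(
                cond,
                series_list,
                plug_gate=config.plug_gate_mm,
                deviation_method=config.deviation_method,
            )
        except AllPlugsFailed:
            log_lines.append(f"{cond.key()} status=all_plugs_failed")
            for ri, seed in enumerate(seeds):
                log_lines.append(
                    f"{cond.key()} rep={ri} seed={seed} status=no_plug"
                )
            continue
        results.append(res)

        rep_rows = []
        for ri, (rep, seed) in enumerate(zip(res.replicates, seeds)):
            record: dict = {"condition": cond.key(), "replicate": ri, "seed": seed}
            if rep is None:
                record["status"] = "no_plug"
                log_lines.append(f"{cond.key()} rep={ri} seed={seed} status=no_plug")
            else:
                record["status"] = "ok"
                record.update(rep.to_dict())
                log_lines.append(
                    f"{cond.key()} rep={ri} seed={seed} status=ok "
                    f"dr={rep.degradation_rate:.4f} dt={rep.dwell_time_s_cm:.4f} "
                    f"r2={rep.r2_degradation:.4f}"
                )
                rep_rows.append(
                    {
                        "tube_id": cond.tube_id_mm,
                        "method": cond.method,
                        "gas": cond.gas,
                        "lgr": cond.lgr,
                        "delay": cond.delay,
                        "replicate": ri,
                        "dr_mm_s": rep.degradation_rate,
                        "dt_s_cm": rep.dwell_time_s_cm,
                        "r2": rep.r2_degradation,
                    }
                )
            (out_dir / "replicates" / f"{cond.key()}_rep{ri}.json").write_text(
                json.dumps(record, indent=2, sort_keys=True)
            )
        pd.DataFrame(rep_rows).to_csv(
            out_dir / "conditions" / f"{cond.key()}.csv",
            index=False,
            float_format="%.6f",
        )

    if not results:
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise AllPlugsFailed("no condition produced a measurable plug")
    table = comparison_table(results, normalise=config.normalise)
    table.to_csv(out_dir / "comparison.csv", index=False, float_format="%.6f")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return table
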