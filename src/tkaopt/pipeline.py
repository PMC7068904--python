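"""Design → evaluation → range analysis → verification workflow.

``run_pipeline`` chains the stages the screening study prescribes: build
the L9 design over the implantation-angle factors, obtain one peak-pressure
response per run (from the contact surrogate, the planted bowl, or an
external response file), perform the range analysis, evaluate the predicted
optimal combination as a verification run, and render plain-text and JSON
reports.  All outputs are deterministic given the config and seed; logging
goes to the standard logging machinery, never into the result files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ranges as ra
from .config import PipelineConfig, dump_config
from .contact import ImplantAlignment, compartment_loads, peak_pressure, solve_equilibrium
from .design import build_orthogonal_array, instantiate_design
from .planted import evaluate_design_planted, planted_response
from .ranges import RESPONSE_COLUMN, RangeAnalysisResult, SpreadSummary

logger = logging.getLogger("tkaopt.pipeline")

__all__ = [
    "VerificationRecord",
    "PipelineResult",
    "join_external_responses",
    "evaluate_design",
    "verify_optimum",
    "render_report",
    "run_pipeline",
]


@dataclass
class VerificationRecord:
    """Outcome of re-evaluating the predicted optimal combination."""

    combination: str
    angles_deg: dict[str, float]
    peak_pressure_mpa: float
    worst_run_id: int
    worst_combination: str
    worst_response_mpa: float
    reduction_mpa: float
    reduction_percent: float
    best_of_all: bool
    medial_lateral_peak_difference_mpa: float | None = None


@dataclass
class PipelineResult:
    design: pd.DataFrame
    responses: pd.DataFrame
    analysis: RangeAnalysisResult
    spread: SpreadSummary
    verification: VerificationRecord | None
    report_text: str
    report_data: dict


def join_external_responses(design: pd.DataFrame, path) -> pd.DataFrame:
    """Match an external response file to the design, run by run.

    Responses are matched on ``run_id``; combination labels and angle
    columns are cross-checked, and any missing run, duplicate run, or
    label/angle mismatch is an error naming the offending run.
    """
    ext = ra.read_responses(path)
    dup = ext["run_id"][ext["run_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"response file {path}: duplicate run_id(s) {sorted(set(dup))}")
    by_run = ext.set_index("run_id")
    out = design.copy()
    values = []
    for _, row in design.iterrows():
        rid = int(row["run_id"])
        if rid not in by_run.index:
            raise ValueError(f"response file {path}: missing run {rid}")
        match = by_run.loc[rid]
        if str(match["combination"]) != str(row["combination"]):
            raise ValueError(
                f"response file {path}: run {rid} label mismatch "
                f"({match['combination']!r} != design {row['combination']!r})"
            )
        for col in design.columns:
            if col.endswith("_deg") and col in match.index:
                if abs(float(match[col]) - float(row[col])) > 1e-9:
                    raise ValueError(
                        f"response file {path}: run {rid} angle mismatch in {col} "
                        f"({match[col]} != design {row[col]})"
                    )
        values.append(float(match[RESPONSE_COLUMN]))
    extra = set(by_run.index) - set(design["run_id"].astype(int))
    if extra:
        raise ValueError(f"response file {path}: unexpected run_id(s) {sorted(extra)}")
    out[RESPONSE_COLUMN] = values
    return out


def _surrogate_peak(config: PipelineConfig, varus: float, slope: float, rotation: float):
    alignment = ImplantAlignment(
        varus_deg=varus,
        cut_slope_deg=slope,
        inherent_slope_deg=config.inherent_slope_deg,
        external_rotation_deg=rotation,
    )
    state, pmap = solve_equilibrium(
        config.geometry,
        alignment,
        material=config.liner_material,
        ligaments=config.ligaments,
        load=config.load,
        free_tilts=config.free_tilts,
    )
    return peak_pressure(pmap), pmap, state


def evaluate_design(design: pd.DataFrame, config: PipelineConfig, seed: int | None = None) -> pd.DataFrame:
    """Evaluate every design run with the configured evaluator."""
    if config.evaluator == "external":
        return join_external_responses(design, config.responses_file)
    if config.evaluator == "planted":
        return evaluate_design_planted(
            design, config.bowl, seed=seed, inherent_slope_deg=config.inherent_slope_deg
        )
    values = []
    for _, row in design.iterrows():
        rid = int(row["run_id"])
        try:
            (pk, comp, _), _, state = _surrogate_peak(
                config, row["varus_deg"], row["slope_deg"], row["rotation_deg"]
            )
        except Exception as exc:
            raise RuntimeError(f"evaluation failed on run {rid}: {exc}") from exc
        logger.info(
            "run %d %s: peak %.3f MPa (%s compartment, %d iterations)",
            rid, row["combination"], pk, comp, state.iterations,
        )
        values.append(pk)
    out = design.copy()
    out[RESPONSE_COLUMN] = values
    return out


def verify_optimum(
    analysis: RangeAnalysisResult,
    responses: pd.DataFrame,
    config: PipelineConfig,
    seed: int | None = None,
    optimum_response_mpa: float | None = None,
) -> VerificationRecord:
    """Evaluate (or accept) the predicted optimum and compare it to the
    design runs.

    The reduction is measured from the worst design run, absolute and as a
    percentage of the optimum's own value.  In external-response mode the
    optimum's response cannot be computed and must be supplied.
    """
    angles = analysis.optimal_angles
    ml_diff = None
    if optimum_response_mpa is not None:
        opt_value = float(optimum_response_mpa)
    elif config.evaluator == "surrogate":
        (opt_value, _, _), pmap, _ = _surrogate_peak(
            config, angles["varus_deg"], angles["slope_deg"], angles["rotation_deg"]
        )
        med = pmap.pressure[pmap.compartment == 1]
        lat = pmap.pressure[pmap.compartment == 2]
        if med.size and lat.size:
            ml_diff = abs(float(med.max()) - float(lat.max()))
    elif config.evaluator == "planted":
        rng = np.random.default_rng(seed) if config.bowl.noise_sd_mpa > 0 else None
        opt_value = planted_response(
            ImplantAlignment(
                varus_deg=angles["varus_deg"],
                cut_slope_deg=angles["slope_deg"],
                inherent_slope_deg=config.inherent_slope_deg,
                external_rotation_deg=angles["rotation_deg"],
            ),
            config.bowl,
            rng,
        )
    else:
        raise ValueError(
            "no evaluator available for verification and no optimum response supplied; "
            "pass optimum_response_mpa (the verification-run value) in external mode"
        )

    vals = responses[RESPONSE_COLUMN].to_numpy(dtype=float)
    worst_i = int(np.argmax(vals))
    worst = float(vals[worst_i])
    return VerificationRecord(
        combination=analysis.optimal_combination,
        angles_deg=dict(angles),
        peak_pressure_mpa=opt_value,
        worst_run_id=int(responses["run_id"].iloc[worst_i]),
        worst_combination=str(responses["combination"].iloc[worst_i]),
        worst_response_mpa=worst,
        reduction_mpa=worst - opt_value,
        reduction_percent=100.0 * (worst - opt_value) / opt_value,
        best_of_all=bool(opt_value <= float(vals.min())),
        medial_lateral_peak_difference_mpa=ml_diff,
    )


def render_report(
    analysis: RangeAnalysisResult,
    spread: SpreadSummary,
    verification: VerificationRecord | None,
    factors,
    precision: int = 2,
) -> tuple[str, dict]:
    """Plain-text and JSON-serializable renderings of the analysis.

    Numbers in the text are displayed at ``precision`` decimals; the data
    dict keeps full precision, so re-parsing the JSON report reproduces the
    computed values exactly.
    """
    factors = tuple(factors)
    K = analysis.level_means
    trend = ra.trend_table(K, factors)
    p = precision

    lines = []
    lines.append("Range analysis of peak contact pressure (MPa)")
    lines.append("=" * 46)
    lines.append("")
    lines.append("Level means K[factor, level]:")
    lines.append(K.round(p).to_string())
    lines.append("")
    rng_s = analysis.ranges.round(p)
    lines.append("Ranges R[factor]: " + ", ".join(f"{s}={rng_s[s]:.{p}f}" for s in K.index))
    lines.append("Ranking: " + analysis.ranking_string())
    angle_bits = ", ".join(f"{k} = {v:g}" for k, v in analysis.optimal_angles.items())
    lines.append(
        f"Optimal combination ({analysis.direction}): "
        f"{analysis.optimal_combination} ({angle_bits})"
    )
    lines.append("")
    lines.append(
        f"Response spread: max {spread.max_mpa:.{p}f}, min {spread.min_mpa:.{p}f}, "
        f"max-min {spread.spread_mpa:.{p}f} MPa ({spread.spread_percent:.1f}% of min)"
    )
    lines.append("")
    lines.append("Trend table (level means per factor level):")
    lines.append(trend.round(p).to_string(index=False))
    if verification is not None:
        v = verification
        lines.append("")
        lines.append("Verification of the predicted optimum")
        lines.append("-" * 37)
        lines.append(f"Combination {v.combination}: peak pressure {v.peak_pressure_mpa:.{p}f} MPa")
        lines.append(
            f"Reduction vs worst design run (run {v.worst_run_id}, {v.worst_combination}, "
            f"{v.worst_response_mpa:.{p}f} MPa): {v.reduction_mpa:.{p}f} MPa "
            f"({v.reduction_percent:.1f}% of the optimum value)"
        )
        lines.append(f"Best of all evaluated runs: {'yes' if v.best_of_all else 'NO'}")
        if v.medial_lateral_peak_difference_mpa is not None:
            lines.append(
                "Medial-lateral peak difference: "
                f"{v.medial_lateral_peak_difference_mpa:.{p}f} MPa"
            )
    text = "\n".join(lines) + "\n"

    data = {
        "level_means_mpa": {
            sym: [float(K.loc[sym, i]) for i in K.columns] for sym in K.index
        },
        "ranges_mpa": {sym: float(analysis.ranges[sym]) for sym in K.index},
        "ranking": list(analysis.ranking),
        "optimal_combination": analysis.optimal_combination,
        "optimal_levels": dict(analysis.optimal_levels),
        "optimal_angles_deg": dict(analysis.optimal_angles),
        "direction": analysis.direction,
        "grand_mean_mpa": analysis.grand_mean,
        "spread": {
            "max_mpa": spread.max_mpa,
            "min_mpa": spread.min_mpa,
            "spread_mpa": spread.spread_mpa,
            "spread_percent": spread.spread_percent,
        },
        "trend": trend.to_dict(orient="records"),
        "display_precision": precision,
    }
    if verification is not None:
        data["verification"] = {
            "combination": verification.combination,
            "angles_deg": verification.angles_deg,
            "peak_pressure_mpa": verification.peak_pressure_mpa,
            "worst_run_id": verification.worst_run_id,
            "worst_combination": verification.worst_combination,
            "worst_response_mpa": verification.worst_response_mpa,
            "reduction_mpa": verification.reduction_mpa,
            "reduction_percent": verification.reduction_percent,
            "best_of_all": verification.best_of_all,
            "medial_lateral_peak_difference_mpa": verification.medial_lateral_peak_difference_mpa,
        }
    return text, data


def run_pipeline(
    config: PipelineConfig,
    outdir=None,
    seed: int | None = None,
    verify: bool = True,
) -> PipelineResult:
    """Execute the full screening workflow.

    Writes (when ``outdir`` is given) ``design.csv``, ``responses.csv``,
    ``report.txt``, ``report.json`` and ``config_resolved.yaml``.  Identical
    config and seed produce byte-identical files.  ``seed`` overrides the
    config's seed and feeds every stochastic feature (planted noise only;
    surrogate and external modes are fully deterministic).
    """
    if seed is None:
        seed = config.seed
    factors = config.factors
    logger.info("building L9 design over %d factors", len(factors))
    array = build_orthogonal_array(factors[0].n_levels, len(factors))
    design = instantiate_design(array, factors)

    logger.info("evaluating %d runs with the '%s' evaluator", len(design), config.evaluator)
    responses = evaluate_design(design, config, seed=seed)

    analysis = ra.analyze(responses, factors, config.direction)
    logger.info("ranking %s, optimal %s", analysis.ranking_string(), analysis.optimal_combination)

    verification = None
    if verify:
        verification = verify_optimum(
            analysis, responses, config, seed=seed,
            optimum_response_mpa=config.optimum_response_mpa,
        )
    spread = ra.response_spread(
        responses,
        extra_response=verification.peak_pressure_mpa if verification else None,
    )
    text, data = render_report(analysis, spread, verification, factors, config.precision)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        design.to_csv(outdir / "design.csv", index=False)
        responses.to_csv(outdir / "responses.csv", index=False)
        (outdir / "report.txt").write_text(text, encoding="utf-8")
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        dump_config(config, outdir / "config_resolved.yaml")
        logger.info("wrote results to %s", outdir)

    return PipelineResult(
        design=design,
        responses=responses,
        analysis=analysis,
        spread=spread,
        verification=verification,
        report_text=text,
        report_data=data,
    )
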