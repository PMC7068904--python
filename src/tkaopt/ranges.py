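"""Taguchi range analysis of a design's responses.

Given a balanced design whose response is the peak contact pressure on the
polyethylene liner (MPa), range analysis screens factor influence without
any distributional machinery: for factor ``j`` the level mean ``K[j][i]`` is
the mean response over the runs where ``j`` sits at level ``i``, the range
``R[j] = max_i K[j][i] - min_i K[j][i]`` measures influence, factors are
ranked by descending range, and the predicted optimum takes, per factor, the
level whose mean extremizes the objective (minimization by default, since
lower peak pressure means less polyethylene wear).

All statistics are computed in full floating precision; rounding is a
display concern only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import FactorSpec, decode_combination

__all__ = [
    "RESPONSE_COLUMN",
    "RangeAnalysisResult",
    "SpreadSummary",
    "attach_level_indices",
    "level_means",
    "compute_ranges",
    "rank_factors",
    "optimal_combination",
    "analyze",
    "response_spread",
    "trend_table",
    "write_responses",
    "read_responses",
]

RESPONSE_COLUMN = "peak_pressure_mpa"


@dataclass
class SpreadSummary:
    """Max/min spread of a set of responses (MPa and percent of the min)."""

    max_mpa: float
    min_mpa: float
    spread_mpa: float
    spread_percent: float


@dataclass
class RangeAnalysisResult:
    """Level-mean matrix, ranges, ranking and predicted optimum.

    Attributes
    ----------
    level_means
        DataFrame indexed by factor symbol, columns = 1-based level index.
    ranges
        Series of ``R[j]`` per factor symbol (MPa).
    ranking
        Factor symbols in descending range; ties keep declaration order.
    optimal_levels
        1-based argmin (or argmax) level index per factor symbol.
    optimal_combination
        Label such as ``"A1B1C2"``.
    optimal_angles
        Decoded angle per factor column (degrees).
    direction
        ``"minimize"`` or ``"maximize"``.
    grand_mean
        Mean of all responses (MPa).
    """

    level_means: pd.DataFrame
    ranges: pd.Series
    ranking: list[str]
    optimal_levels: dict[str, int]
    optimal_combination: str
    optimal_angles: dict[str, float]
    direction: str
    grand_mean: float

    def ranking_string(self) -> str:
        return " > ".join(self.ranking)


def _as_factor_tuple(factors) -> tuple[FactorSpec, ...]:
    factors = tuple(factors)
    if not factors:
        raise ValueError("at least one factor is required")
    return factors


def attach_level_indices(responses: pd.DataFrame, factors) -> pd.DataFrame:
    """Return a copy of ``responses`` with one ``level_<symbol>`` column per
    factor, decoded from the combination labels."""
    factors = _as_factor_tuple(factors)
    out = responses.copy()
    decoded = [decode_combination(lbl, factors) for lbl in out["combination"]]
    for f in factors:
        out[f"level_{f.symbol}"] = [d[f.symbol] for d in decoded]
    return out


def _validate_responses(responses: pd.DataFrame, factors) -> pd.DataFrame:
    if RESPONSE_COLUMN not in responses.columns:
        raise ValueError(f"response table lacks a {RESPONSE_COLUMN!r} column")
    vals = responses[RESPONSE_COLUMN].to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError("response table is empty")
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("responses must be finite and positive")
    tagged = attach_level_indices(responses, factors)
    # balance: every level of every factor must cover the same number of runs
    for f in _as_factor_tuple(factors):
        counts = tagged[f"level_{f.symbol}"].value_counts()
        if counts.nunique() != 1 or len(counts) != f.n_levels:
            raise ValueError(
                f"design is unbalanced in factor {f.symbol}: "
                f"level run-counts {counts.to_dict()}"
            )
    return tagged


def level_means(responses: pd.DataFrame, factors) -> pd.DataFrame:
    """Level-mean matrix ``K[j][i]``: mean response of factor ``j`` at level
    ``i``, for a balanced design.  Rows are factor symbols, columns 1..m."""
    factors = _as_factor_tuple(factors)
    tagged = _validate_responses(responses, factors)
    m = factors[0].n_levels
    rows = {}
    for f in factors:
        grouped = tagged.groupby(f"level_{f.symbol}")[RESPONSE_COLUMN].mean()
        rows[f.symbol] = [float(grouped.loc[i]) for i in range(1, m + 1)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(1, m + 1))


def compute_ranges(K: pd.DataFrame) -> pd.Series:
    """Per-factor range ``R[j] = max_i K[j][i] - min_i K[j][i]`` (MPa)."""
    if K.isna().any().any():
        raise ValueError("level-mean matrix is incomplete")
    return K.max(axis=1) - K.min(axis=1)


def rank_factors(R: pd.Series) -> list[str]:
    """Factors in descending range; ties resolve to declaration order."""
    order = sorted(range(len(R)), key=lambda i: (-float(R.iloc[i]), i))
    return [str(R.index[i]) for i in order]


def optimal_combination(
    K: pd.DataFrame, factors, direction: str = "minimize"
) -> tuple[dict[str, int], str, dict[str, float]]:
    """Per-factor extremizing level under ``direction``; ties resolve to the
    lowest level index.  Returns (levels, label, decoded angles)."""
    factors = _as_factor_tuple(factors)
    if direction not in ("minimize", "maximize"):
        raise ValueError(f"direction must be 'minimize' or 'maximize', got {direction!r}")
    levels: dict[str, int] = {}
    angles: dict[str, float] = {}
    for f in factors:
        row = K.loc[f.symbol].to_numpy(dtype=float)
        idx = int(np.argmin(row) if direction == "minimize" else np.argmax(row)) + 1
        levels[f.symbol] = idx
        angles[f.column] = f.levels[idx - 1]
    label = "".join(f"{f.symbol}{levels[f.symbol]}" for f in factors)
    return levels, label, angles


def analyze(
    responses: pd.DataFrame, factors, direction: str = "minimize"
) -> RangeAnalysisResult:
    """Full range analysis of a balanced response table."""
    factors = _as_factor_tuple(factors)
    K = level_means(responses, factors)
    R = compute_ranges(K)
    levels, label, angles = optimal_combination(K, factors, direction)
    return RangeAnalysisResult(
        level_means=K,
        ranges=R,
        ranking=rank_factors(R),
        optimal_levels=levels,
        optimal_combination=label,
        optimal_angles=angles,
        direction=direction,
        grand_mean=float(responses[RESPONSE_COLUMN].mean()),
    )


def response_spread(
    responses: pd.DataFrame, extra_response: float | None = None
) -> SpreadSummary:
    """Spread of the responses, optionally augmented with a verification-run
    value: max, min, max - min, and 100 * (max - min) / min."""
    vals = list(responses[RESPONSE_COLUMN].to_numpy(dtype=float))
    if extra_response is not None:
        vals.append(float(extra_response))
    if len(vals) < 2:
        raise ValueError("need at least two responses to compute a spread")
    hi, lo = max(vals), min(vals)
    spread = hi - lo
    return SpreadSummary(
        max_mpa=hi,
        min_mpa=lo,
        spread_mpa=spread,
        spread_percent=100.0 * spread / lo,
    )


def trend_table(K: pd.DataFrame, factors) -> pd.DataFrame:
    """Long-form (factor, level index, level value, mean response) table, one
    row per factor level — the data behind a level-mean trend plot."""
    factors = _as_factor_tuple(factors)
    records = []
    for f in factors:
        for i in range(1, f.n_levels + 1):
            records.append(
                {
                    "factor": f.symbol,
                    "factor_name": f.name,
                    "level_index": i,
                    "level_value_deg": f.levels[i - 1],
                    "mean_peak_pressure_mpa": float(K.loc[f.symbol, i]),
                }
            )
    return pd.DataFrame.from_records(records)


def write_responses(responses: pd.DataFrame, path) -> None:
    """Write a response table as comma-separated UTF-8 text."""
    responses.to_csv(path, index=False)


def read_responses(path) -> pd.DataFrame:
    """Read a response table (design columns + ``peak_pressure_mpa``)."""
    frame = pd.read_csv(path)
    for col in ("run_id", "combination", RESPONSE_COLUMN):
        if col not in frame.columns:
            raise ValueError(f"response file {path} lacks required column {col!r}")
    return frame
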