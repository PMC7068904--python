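"""Orthogonal arrays and factorial designs for implantation-angle studies.

The alignment of a tibial component is described here by three angular
factors — coronal varus/valgus, sagittal posterior slope of the tibial cut,
and axial external rotation — each screened at three levels.  A Taguchi
L9(3^4) orthogonal array covers all pairwise level combinations of up to
four 3-level factors in nine runs instead of the 27 of a full factorial,
which is what makes a simulation-per-run screening affordable.

Only the tabulated L9 array (plus full factorials) is constructed; general
Galois-field array synthesis is out of scope for a three-factor screening.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "OrthogonalArray",
    "OrthogonalityReport",
    "DEFAULT_FACTORS",
    "DESIGN_COLUMNS",
    "build_orthogonal_array",
    "validate_orthogonality",
    "instantiate_design",
    "full_factorial",
    "decode_combination",
    "write_design",
    "read_design",
]

#: Canonical L9(3^4) array, 1-based level indices.  Rows are the standard
#: Taguchi ordering; every column is balanced and every ordered level pair
#: occurs exactly once per column pair.
_L9_CELLS = np.array(
    [
        [1, 1, 1, 1],
        [1, 2, 2, 2],
        [1, 3, 3, 3],
        [2, 1, 2, 3],
        [2, 2, 3, 1],
        [2, 3, 1, 2],
        [3, 1, 3, 2],
        [3, 2, 1, 3],
        [3, 3, 2, 1],
    ],
    dtype=np.int64,
)


def _default_column(name: str) -> str:
    slug = re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")
    return f"{slug}_deg"


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor: an implantation angle and its levels.

    Parameters
    ----------
    name
        Human-readable factor name, e.g. ``"varus angle"``.
    symbol
        Single uppercase letter used in combination labels (``A``/``B``/``C``).
    levels
        Ordered level values in degrees.  The ordering is the label ordering
        (level indices are 1-based); it need not be monotone — the default
        varus sequence is (0, 3, -3).
    sign_convention
        Free-text note on what a positive angle means.
    column
        Column name used in design tables (defaults to a slug of ``name``).
    """

    name: str
    symbol: str
    levels: tuple[float, ...]
    sign_convention: str = ""
    column: str = ""

    def __post_init__(self) -> None:
        if not (len(self.symbol) == 1 and self.symbol.isalpha()):
            raise ValueError(f"factor symbol must be a single letter, got {self.symbol!r}")
        levels = tuple(float(v) for v in self.levels)
        if len(levels) < 2:
            raise ValueError(f"factor {self.name!r} needs at least 2 levels")
        if len(set(levels)) != len(levels):
            raise ValueError(f"factor {self.name!r} has duplicate level values {levels}")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "symbol", self.symbol.upper())
        if not self.column:
            object.__setattr__(self, "column", _default_column(self.name))

    @property
    def n_levels(self) -> int:
        return len(self.levels)


#: The three implantation-angle factors at their clinically acceptable levels:
#: varus/valgus within +-3 deg, tibial-cut posterior slope 1-3 deg (the component
#: itself adds an inherent 3 deg), external rotation 3-5 deg.
DEFAULT_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec(
        name="varus angle",
        symbol="A",
        levels=(0.0, 3.0, -3.0),
        sign_convention="varus positive, valgus negative",
        column="varus_deg",
    ),
    FactorSpec(
        name="posterior slope angle",
        symbol="B",
        levels=(1.0, 2.0, 3.0),
        sign_convention="posterior slope of the tibial cut, excludes the component's inherent slope",
        column="slope_deg",
    ),
    FactorSpec(
        name="external rotation angle",
        symbol="C",
        levels=(3.0, 4.0, 5.0),
        sign_convention="external rotation positive",
        column="rotation_deg",
    ),
)

DESIGN_COLUMNS = ("run_id", "combination", "varus_deg", "slope_deg", "rotation_deg")


@dataclass(frozen=True)
class OrthogonalArray:
    """A fixed orthogonal array of 1-based level indices."""

    designation: str
    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int64)
        if cells.ndim != 2 or cells.size == 0:
            raise ValueError("array cells must be a non-empty runs x columns matrix")
        object.__setattr__(self, "cells", cells)
        self.cells.setflags(write=False)

    @property
    def runs(self) -> int:
        return self.cells.shape[0]

    @property
    def columns(self) -> int:
        return self.cells.shape[1]

    @property
    def n_levels(self) -> int:
        return int(self.cells.max())


def build_orthogonal_array(levels_per_factor: int, n_factors: int) -> OrthogonalArray:
    """Return the canonical L9(3^4) array for up to four 3-level factors.

    Raises
    ------
    ValueError
        If ``(levels_per_factor, n_factors)`` is not served by L9(3^4); only
        that tabulated array is supported.
    """
    if levels_per_factor != 3 or not (1 <= n_factors <= 4):
        raise ValueError(
            "unsupported orthogonal array request "
            f"({levels_per_factor} levels, {n_factors} factors); "
            "supported arrays: L9(3^4) for 3-level designs with at most 4 factors"
        )
    return OrthogonalArray(designation="L9(3^4)", cells=_L9_CELLS.copy())


@dataclass
class OrthogonalityReport:
    """Balance and pairwise-orthogonality audit of an orthogonal array."""

    passed: bool
    level_counts: dict[int, dict[int, int]]
    pair_counts: dict[tuple[int, int], dict[tuple[int, int], int]]
    failures: list[str] = field(default_factory=list)


def validate_orthogonality(array: OrthogonalArray) -> OrthogonalityReport:
    """Check column balance and pairwise orthogonality of ``array``.

    Balance: each level index appears ``runs / m`` times in every column.
    Orthogonality: for every column pair each ordered level pair appears
    ``runs / m**2`` times (exactly once for L9 with m = 3).  Failures are
    listed in the report rather than raised.
    """
    cells = array.cells
    m = array.n_levels
    runs = array.runs
    levels = range(1, m + 1)
    failures: list[str] = []

    level_counts: dict[int, dict[int, int]] = {}
    expected = runs / m
    for j in range(array.columns):
        counts = {lv: int(np.sum(cells[:, j] == lv)) for lv in levels}
        level_counts[j + 1] = counts
        bad = {lv: c for lv, c in counts.items() if c != expected}
        if bad:
            failures.append(f"column {j + 1} unbalanced: level counts {counts}")

    pair_counts: dict[tuple[int, int], dict[tuple[int, int], int]] = {}
    expected_pair = runs / m**2
    for j, k in itertools.combinations(range(array.columns), 2):
        counts = {
            (a, b): int(np.sum((cells[:, j] == a) & (cells[:, k] == b)))
            for a in levels
            for b in levels
        }
        pair_counts[(j + 1, k + 1)] = counts
        bad = {p: c for p, c in counts.items() if c != expected_pair}
        if bad:
            failures.append(
                f"column pair ({j + 1}, {k + 1}) not orthogonal: "
                f"offending level pairs {sorted(bad)}"
            )

    return OrthogonalityReport(
        passed=not failures,
        level_counts=level_counts,
        pair_counts=pair_counts,
        failures=failures,
    )


def _label(factors: tuple[FactorSpec, ...], level_indices: tuple[int, ...]) -> str:
    return "".join(f"{f.symbol}{i}" for f, i in zip(factors, level_indices))


def decode_combination(label: str, factors: list[FactorSpec] | tuple[FactorSpec, ...]) -> dict[str, int]:
    """Decode a combination label like ``"A1B2C2"`` to 1-based level indices."""
    pairs = re.findall(r"([A-Za-z])(\d+)", label)
    if "".join(s + d for s, d in pairs) != label.strip():
        raise ValueError(f"malformed combination label {label!r}")
    decoded = {sym.upper(): int(d) for sym, d in pairs}
    expected = [f.symbol for f in factors]
    if list(decoded) != expected:
        raise ValueError(f"label {label!r} does not match factor symbols {expected}")
    for f in factors:
        if not 1 <= decoded[f.symbol] <= f.n_levels:
            raise ValueError(f"label {label!r}: level index out of range for factor {f.symbol}")
    return decoded


def _design_frame(
    factors: tuple[FactorSpec, ...], index_rows: list[tuple[int, ...]]
) -> pd.DataFrame:
    records = []
    for run_id, idx in enumerate(index_rows, start=1):
        rec: dict[str, object] = {
            "run_id": run_id,
            "combination": _label(factors, idx),
        }
        for f, i in zip(factors, idx):
            rec[f.column] = f.levels[i - 1]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def instantiate_design(
    array: OrthogonalArray, factors: list[FactorSpec] | tuple[FactorSpec, ...]
) -> pd.DataFrame:
    """Assign factors to the leading array columns and decode concrete angles.

    Factors occupy the first ``len(factors)`` columns of the array; trailing
    unassigned columns (the L9 error column in a three-factor study) are
    dropped.  Returns a design table with one row per run: ``run_id``,
    ``combination`` label, and one angle column per factor.
    """
    factors = tuple(factors)
    if not factors:
        raise ValueError("at least one factor is required")
    if len(factors) > array.columns:
        raise ValueError(
            f"{len(factors)} factors exceed the array's {array.columns} columns"
        )
    for f in factors:
        if f.n_levels != array.n_levels:
            raise ValueError(
                f"factor {f.symbol} has {f.n_levels} levels but the array "
                f"{array.designation} has {array.n_levels}"
            )
    rows = [tuple(int(v) for v in row[: len(factors)]) for row in array.cells]
    return _design_frame(factors, rows)


def full_factorial(factors: list[FactorSpec] | tuple[FactorSpec, ...]) -> pd.DataFrame:
    """Full-factorial design: one run per element of the level Cartesian
    product, ordered lexicographically by factor then level index."""
    factors = tuple(factors)
    if not factors:
        raise ValueError("at least one factor is required")
    rows = list(itertools.product(*(range(1, f.n_levels + 1) for f in factors)))
    return _design_frame(factors, rows)


def write_design(design: pd.DataFrame, path) -> None:
    """Write a design table as comma-separated UTF-8 text."""
    design.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    """Read a design table written by :func:`write_design`."""
    frame = pd.read_csv(path)
    missing = [c for c in ("run_id", "combination") if c not in frame.columns]
    if missing:
        raise ValueError(f"design file {path} lacks required columns {missing}")
    return frame
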