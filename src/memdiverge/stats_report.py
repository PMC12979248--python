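"""Shared statistics, configuration and result serialization.

The significance convention follows the star scheme: ns for p > 0.05,
then ∗ / ∗∗ / ∗∗∗ / ∗∗∗∗ at p ≤ 0.05 / 0.01 / 0.001 / 0.0001, with the
smallest satisfied threshold reported.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

STAR_THRESHOLDS = (
    (0.0001, "∗∗∗∗"),
    (0.001, "∗∗∗"),
    (0.01, "∗∗"),
    (0.05, "∗"),
)


def star_label(p: float) -> str:
    """Map a p value onto the ns/∗/∗∗/∗∗∗/∗∗∗∗ scheme (inclusive ≤)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p value {p} outside [0, 1]")
    for threshold, label in STAR_THRESHOLDS:
        if p <= threshold:
            return label
    return "ns"


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    star: str


def students_t(
    group_a, group_b, welch: bool = False
) -> TTestResult:
    """Two-sided unpaired t test (pooled variance by default, Welch by flag).

    Degenerate case: both groups with zero variance and equal means gives
    t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        df = len(a) + len(b) - 2
        return TTestResult(t=0.0, df=float(df), p=1.0, star="ns")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if welch else float(len(a) + len(b) - 2)
    p = float(res.pvalue)
    return TTestResult(t=float(res.statistic), df=df, p=p, star=star_label(p))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Fully resolved run configuration; round-trips losslessly via YAML.

    ``seed`` must be set explicitly for any stochastic stage — there is no
    hidden default.
    """

    inputs: dict = field(default_factory=dict)
    selections: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    out_dir: str = "."

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError(
                "stochastic stage requires an explicit seed in the config"
            )
        return int(self.seed)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def export_table(
    df: pd.DataFrame,
    path: str | Path,
    schema: list[str] | None = None,
    sidecar: dict | None = None,
) -> None:
    """Write a CSV table with an optional JSON sidecar of parameters.

    When a schema is given the frame must carry exactly those columns, in
    order — a violation is a hard error before anything is written.
    """
    if schema is not None and list(df.columns) != list(schema):
        raise ValueError(
            f"schema violation: expected columns {schema}, got {list(df.columns)}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if sidecar is not None:
        export_json(sidecar, path.with_suffix(".params.json"))


def export_json(payload: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, ensure_ascii=False))


class RunLog:
    """Per-stage timing log written beside the outputs."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.entries: list[dict] = []
        self._start: dict[str, float] = {}

    def start(self, stage: str) -> None:
        self._start[stage] = time.perf_counter()

    def stop(self, stage: str) -> None:
        elapsed = time.perf_counter() - self._start.pop(stage)
        self.entries.append({"stage": stage, "seconds": round(elapsed, 3)})
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(
            "\n".join(f"{e['stage']}\t{e['seconds']}s" for e in self.entries) + "\n"
        )
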