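"""Parameter sweeps over gamma* and structured result output.

A sweep evaluates the equilibrium weighting gamma* on a one- or
two-dimensional parameter grid, one row per (cell, ancestral gamma_t0).
Results are written as tidy TSV plus a JSON manifest sufficient to
reproduce the run; completed cells are skipped on resume.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import __version__
from .invasion import GradientSettings, equilibrium_weighting
from .params import ModelParams

log = logging.getLogger(__name__)

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}

COLUMNS = ["axis1_name", "axis1_value", "axis2_name", "axis2_value",
           "gamma_t0", "gamma_star", "status"]


@dataclasses.dataclass(frozen=True)
class SweepSpec:
    """One sweep: axis parameter names and grids, fixed overrides, starts."""

    axis1_name: str
    axis1_values: Sequence[float]
    axis2_name: str | None = None
    axis2_values: Sequence[float] = ()
    gamma_t0: Sequence[float] = (0.5,)
    fixed: dict[str, Any] = dataclasses.field(default_factory=dict)
    output: str | None = None

    def __post_init__(self) -> None:
        for name in filter(None, (self.axis1_name, self.axis2_name)):
            if name not in _PARAM_FIELDS | {"gamma_t0"}:
                raise ValueError(f"axis names a non-existent parameter: {name!r}")
        if len(self.axis1_values) == 0:
            raise ValueError("axis1 grid must be non-empty")
        if self.axis2_name is not None and len(self.axis2_values) == 0:
            raise ValueError("axis2 grid must be non-empty")
        bad = set(self.fixed) - _PARAM_FIELDS
        if bad:
            raise ValueError(f"fixed overrides name non-existent parameters: {sorted(bad)}")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SweepSpec":
        known = {"axis1", "axis2", "gamma_t0", "fixed", "output"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown sweep key(s): {sorted(unknown)}")
        ax1 = data["axis1"]
        ax2 = data.get("axis2")
        return cls(axis1_name=ax1["name"], axis1_values=list(ax1["values"]),
                   axis2_name=ax2["name"] if ax2 else None,
                   axis2_values=list(ax2["values"]) if ax2 else (),
                   gamma_t0=list(data.get("gamma_t0", [0.5])),
                   fixed=dict(data.get("fixed", {})),
                   output=data.get("output"))

    def cells(self) -> list[dict[str, float]]:
        """All grid cells as {axis name: value} mappings."""
        if self.axis2_name is None:
            return [{self.axis1_name: v} for v in self.axis1_values]
        return [{self.axis1_name: v1, self.axis2_name: v2}
                for v1 in self.axis1_values for v2 in self.axis2_values]


def run_sweep(spec: SweepSpec, base_params: ModelParams | None = None,
              settings: GradientSettings = GradientSettings(),
              resume: bool = True) -> pd.DataFrame:
    """Evaluate gamma* for every grid cell and ancestral gamma_t0.

    Deterministic for a given spec.  Per-cell failures are logged and
    recorded with ``status='failed'`` rather than aborting the sweep.  If
    ``spec.output`` exists and ``resume`` is set, completed rows are kept
    and only missing cells are computed.
    """
    base = (base_params or ModelParams()).replace(**spec.fixed)
    done: dict[tuple, dict] = {}
    out_path = Path(spec.output) if spec.output else None
    if resume and out_path is not None and out_path.exists():
        prev = pd.read_csv(out_path, sep="\t")
        for _, row in prev.iterrows():
            if row["status"] == "ok":
                key = (row["axis1_value"],
                       row["axis2_value"] if spec.axis2_name else None,
                       row["gamma_t0"])
                done[key] = row.to_dict()

    rows = []
    for cell in spec.cells():
        overrides = {k: v for k, v in cell.items() if k != "gamma_t0"}
        params = base.replace(**overrides)
        for gt0 in spec.gamma_t0:
            g0 = cell.get("gamma_t0", gt0)
            key = (cell[spec.axis1_name],
                   cell.get(spec.axis2_name) if spec.axis2_name else None, g0)
            if key in done:
                rows.append(done[key])
                continue
            row = {"axis1_name": spec.axis1_name, "axis1_value": cell[spec.axis1_name],
                   "axis2_name": spec.axis2_name or "",
                   "axis2_value": cell.get(spec.axis2_name, "") if spec.axis2_name else "",
                   "gamma_t0": g0}
            try:
                gstar = equilibrium_weighting(params, gamma_t0=g0, settings=settings)
                row.update(gamma_star=gstar, status="ok")
                log.info("cell %s gamma_t0=%s -> gamma*=%.4f", cell, g0, gstar)
            except Exception as exc:  # per-cell failures are non-fatal
                row.update(gamma_star=float("nan"), status="failed")
                log.warning("cell %s gamma_t0=%s failed: %s", cell, g0, exc)
            rows.append(row)

    grid = pd.DataFrame(rows, columns=COLUMNS)
    if out_path is not None:
        write_results(grid, out_path,
                      manifest={"spec": dataclasses.asdict(spec),
                                "params": base.to_dict(),
                                "settings": dataclasses.asdict(settings)})
    return grid


def write_results(grid: pd.DataFrame, path: str | Path,
                  manifest: dict[str, Any] | None = None) -> None:
    """Write a sweep grid as TSV plus a JSON run manifest alongside it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid.to_csv(path, sep="\t", index=False)
    if manifest is not None:
        manifest = dict(manifest)
        manifest["tool"] = {"name": "matepref", "version": __version__}
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
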