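"""Structured run configuration and deterministic CSV serialization.

Configurations are YAML mappings with four blocks (``medium``, ``grid``,
``source``, ``run``) plus global ``seed``, ``output_dir`` and
``log_level``.  Every key is validated against the module preconditions
before any computation starts: unknown keys are listed by name, and
out-of-range values name the violated constraint (e.g. the alpha
stability range).

Numeric output is serialized at 12 significant digits with infinity
written as the literal ``inf``, so identical configurations and seeds
reproduce byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dispersion import FractionalDrudeMedium
from .fdtd import COUPLINGS, Grid1D, SourceSpec, ade_coefficients

__all__ = ["RunConfig", "parse_config", "serialize_config", "write_table",
           "format_number"]

_DEFAULTS = {
    "medium": {
        # accuracy-experiment set: wp = 0.3, gamma_beta = 0.1, gamma_alpha = 1
        "omega_p_sq": 0.09, "gamma_alpha": 1.0, "gamma_beta": 0.1,
        "alpha": 1.0, "beta": 1.0, "eps_inf": 1.0, "sigma_dc": 0.0,
    },
    "grid": {
        "n_cells": 2000, "dt": 0.5, "n_terms": 32,
        "coupling": "trapezoidal",
        # medium occupies [start, stop); null means the whole grid
        "medium_start": None, "medium_stop": None,
    },
    "source": {
        "position": None,           # null -> grid centre
        "omega": 0.21, "amplitude": 1.0, "ramp_cycles": 10.0,
        "kind": "monochromatic_soft", "center_time": 30.0, "width": 10.0,
    },
    "run": {"n_steps": 2000, "probes": None},   # null -> centre + 4
    "seed": 0,
    "output_dir": ".",
    "log_level": "INFO",
}

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration with defaults applied."""

    medium: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    source: dict = field(default_factory=dict)
    run: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def make_medium(self) -> FractionalDrudeMedium:
        return FractionalDrudeMedium(**self.medium)

    def make_grid(self) -> Grid1D:
        g = self.grid
        n = g["n_cells"]
        mask = None
        if g["medium_start"] is not None or g["medium_stop"] is not None:
            import numpy as np
            mask = np.zeros(n, dtype=bool)
            mask[g["medium_start"] or 0: g["medium_stop"] or n] = True
        return Grid1D.at_rest(n, g["dt"], g["n_terms"], medium_mask=mask)

    def make_source(self) -> SourceSpec:
        s = dict(self.source)
        if s["position"] is None:
            s["position"] = self.grid["n_cells"] // 2
        return SourceSpec(**s)

    def make_coefficients(self):
        return ade_coefficients(self.make_medium(), self.grid["dt"],
                                self.grid["n_terms"],
                                coupling=self.grid["coupling"])

    def probe_cells(self) -> list:
        p = self.run["probes"]
        if p is None:
            p = [self.grid["n_cells"] // 2 + 4]
        return list(p)


def _merge_block(name: str, user: dict, errors: list) -> dict:
    block = dict(_DEFAULTS[name])
    unknown = set(user) - set(block)
    if unknown:
        errors.append(f"unknown keys in '{name}': {sorted(unknown)}")
    for k, v in user.items():
        if k in block:
            block[k] = v
    return block


def parse_config(text: str) -> RunConfig:
    """Parse and validate a YAML configuration (empty text -> defaults)."""
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    errors: list[str] = []
    unknown_top = set(raw) - set(_DEFAULTS)
    if unknown_top:
        errors.append(f"unknown top-level keys: {sorted(unknown_top)}")
    blocks = {name: _merge_block(name, raw.get(name, {}) or {}, errors)
              for name in ("medium", "grid", "source", "run")}
    seed = raw.get("seed", _DEFAULTS["seed"])
    output_dir = raw.get("output_dir", _DEFAULTS["output_dir"])
    log_level = raw.get("log_level", _DEFAULTS["log_level"])

    med, grid, src, run_blk = (blocks["medium"], blocks["grid"],
                               blocks["source"], blocks["run"])
    if not 0 < med["alpha"] < 2:
        errors.append(
            f"medium.alpha={med['alpha']} outside the stable range "
            "0 < alpha < 2")
    if not 0 <= med["beta"] <= 2:
        errors.append(f"medium.beta={med['beta']} outside [0, 2]")
    if med["gamma_alpha"] <= 0:
        errors.append("medium.gamma_alpha must be > 0")
    if med["gamma_beta"] < 0 or med["sigma_dc"] < 0:
        errors.append("medium.gamma_beta and medium.sigma_dc must be >= 0")
    if grid["dt"] <= 0:
        errors.append("grid.dt must be > 0")
    if grid["n_cells"] < 3:
        errors.append("grid.n_cells must be >= 3")
    if grid["n_terms"] < 1:
        errors.append("grid.n_terms must be >= 1")
    if grid["coupling"] not in COUPLINGS:
        errors.append(f"grid.coupling must be one of {COUPLINGS}")
    if src["kind"] == "monochromatic_soft" and src["omega"] <= 0:
        errors.append("source.omega must be > 0 for a monochromatic source")
    if src["position"] is not None and not (
            0 <= src["position"] < grid["n_cells"]):
        errors.append("source.position outside the grid")
    if run_blk["n_steps"] < 1:
        errors.append("run.n_steps must be >= 1")
    if run_blk["probes"] is not None:
        for p in run_blk["probes"]:
            if not 0 <= p < grid["n_cells"]:
                errors.append(f"probe cell {p} outside the grid")
    if log_level not in _LOG_LEVELS:
        errors.append(f"log_level must be one of {_LOG_LEVELS}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(medium=med, grid=grid, source=src, run=run_blk,
                     seed=int(seed), output_dir=str(output_dir),
                     log_level=str(log_level))


def serialize_config(cfg: RunConfig) -> str:
    """YAML text such that ``parse_config(serialize_config(c)) == c``."""
    return yaml.safe_dump(
        {"medium": cfg.medium, "grid": cfg.grid, "source": cfg.source,
         "run": cfg.run, "seed": cfg.seed, "output_dir": cfg.output_dir,
         "log_level": cfg.log_level},
        sort_keys=True)


def format_number(x) -> str:
    """12-significant-digit formatting; infinity as the literal ``inf``."""
    if isinstance(x, str):
        return x
    xf = float(x)
    if math.isinf(xf):
        return "inf" if xf > 0 else "-inf"
    if math.isnan(xf):
        return "nan"
    return f"{xf:.12g}"


def write_table(header, rows, path) -> None:
    """Write a rectangular table as CSV.

    ``header`` is a sequence of column names; ``rows`` an iterable of row
    sequences.  Numbers are written with 12 significant digits, infinities
    as ``inf``, and the file ends with a newline.  An empty ``rows`` gives
    a header-only file.
    """
    header = list(header)
    lines = [",".join(str(h) for h in header)]
    for row in rows:
        row = list(row)
        if len(row) != len(header):
            raise ValueError(
                f"row length {len(row)} != header length {len(header)}")
        lines.append(",".join(format_number(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
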