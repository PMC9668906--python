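"""CSV schemas and run-configuration handling.

All interchange formats are plain CSV with registered, exactly-matched
headers; the run configuration is one YAML document with ``scenario`` /
``physics`` / ``ecology`` / ``run`` blocks whose unknown keys are rejected
(typo safety). Output files embed the configuration hash and the package
version so hash-identical configs reproduce hash-identical data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .ecosystem import EcoParams
from .forcing import RiverConfig, ScenarioConfig
from .physics import ColumnGrid, PhysicsParams

#: registered CSV schemas: name -> (columns, date columns)
SCHEMAS = {
    "forcing": (["date", "air_temp_c", "wind_ms", "cloud_frac", "precip_mm",
                 "shortwave_wm2"], ["date"]),
    "loading": (["year", "tn_load", "tp_load"], []),
    "river": (["date", "flow_m3d", "temp_c", "din_mgm3", "dip_mgm3",
               "poc_mgm3"], ["date"]),
    "monitoring": (["date", "depth_m", "temp_c", "do_mgl"], ["date"]),
    "output": (["time", "depth_m", "var", "value"], ["time"]),
    "turnover": (["year", "timing_days", "failed", "delta_t", "delta_do"], []),
    "importance": (["variable", "pct_inc_mse", "node_purity"], []),
    "regression": (["period", "slope", "intercept", "r2", "n", "ci_lo",
                    "ci_hi"], []),
}


class FormatError(ValueError):
    """A CSV file does not match its registered schema."""


def read_series_csv(path, schema: str) -> pd.DataFrame:
    """Read a CSV against a registered schema.

    The header must match the schema exactly (a mismatch error names both
    the missing and the unexpected columns); dates must be ISO-8601; an
    unparseable value reports its line number. Only an explicitly empty
    cell becomes NaN.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; "
                       f"registered: {sorted(SCHEMAS)}")
    cols, date_cols = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    head = pd.read_csv(path, nrows=0, comment="#")
    got = list(head.columns)
    if got != cols:
        missing = [c for c in cols if c not in got]
        extra = [c for c in got if c not in cols]
        raise FormatError(
            f"{path}: header mismatch for schema {schema!r}: "
            f"missing {missing}, unexpected {extra}")
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    out = {}
    for i, col in enumerate(cols):
        raw = df[col].replace("", None)
        try:
            if col in date_cols:
                out[col] = pd.to_datetime(raw, format="ISO8601")
            elif col in ("var", "period"):
                out[col] = raw
            elif col in ("failed",):
                out[col] = raw.map({"True": True, "False": False,
                                    "true": True, "false": False, None: None})
            else:
                out[col] = pd.to_numeric(raw)
        except (ValueError, TypeError) as exc:
            bad = None
            for ln, v in enumerate(raw, start=2):
                if v is None:
                    continue
                try:
                    pd.to_datetime(v) if col in date_cols else float(v)
                except (ValueError, TypeError):
                    bad = ln
                    break
            raise FormatError(
                f"{path}: cannot parse column {col!r}"
                + (f" at line {bad}" if bad else "") + f": {exc}") from exc
    return pd.DataFrame(out)


def write_series_csv(df: pd.DataFrame, path, schema: str,
                     meta: dict | None = None) -> None:
    """Write a CSV in a registered schema, with metadata comment lines."""
    cols, _ = SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"frame lacks columns {missing} for schema {schema!r}")
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df[cols].to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# run configuration

_BLOCKS = {
    "scenario": ScenarioConfig,
    "physics": PhysicsParams,
    "ecology": EcoParams,
    "river": RiverConfig,
}
_RUN_KEYS = {"dt", "archive_every", "eco_on", "rivers_on", "suppress_mixing",
             "n_layers", "dz", "verbose"}


class RunConfig:
    """Parsed run configuration: typed blocks plus run options.

    Unknown blocks or keys raise immediately; absent keys take the package
    defaults. ``hash`` is a stable digest of the fully-resolved
    configuration.
    """

    def __init__(self, scenario=None, physics=None, ecology=None,
                 river=None, run=None):
        self.scenario = scenario or ScenarioConfig()
        self.physics = physics or PhysicsParams()
        self.ecology = ecology or EcoParams()
        self.river = river or RiverConfig()
        run = dict(run or {})
        unknown = set(run) - _RUN_KEYS
        if unknown:
            raise KeyError(f"unknown run keys: {sorted(unknown)}")
        self.run = {"dt": 600.0, "archive_every": 1, "eco_on": True,
                    "rivers_on": True, "suppress_mixing": False,
                    "n_layers": 37, "dz": 2.5, "verbose": False}
        self.run.update(run)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no such config file: {path}")
        doc = yaml.safe_load(path.read_text()) or {}
        unknown = set(doc) - set(_BLOCKS) - {"run"}
        if unknown:
            raise KeyError(f"unknown config blocks: {sorted(unknown)}")
        kwargs = {}
        for name, cls_ in _BLOCKS.items():
            block = doc.get(name)
            if block is not None:
                if name == "river":
                    known = set(RiverConfig().__dataclass_fields__)
                    bad = set(block) - known
                    if bad:
                        raise KeyError(f"unknown river keys: {sorted(bad)}")
                    block = {k: (tuple(v) if k == "river_weights" else v)
                             for k, v in block.items()}
                    kwargs[name] = RiverConfig(**block)
                else:
                    kwargs[name] = cls_.from_dict(block)
        return cls(run=doc.get("run"), **kwargs)

    def grid(self) -> ColumnGrid:
        return ColumnGrid(n_layers=int(self.run["n_layers"]),
                          dz=float(self.run["dz"]))

    @property
    def hash(self) -> str:
        payload = {
            "scenario": asdict(self.scenario), "physics": asdict(self.physics),
            "ecology": asdict(self.ecology), "river": asdict(self.river),
            "run": self.run,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
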