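"""File formats, per-mouse normalisation and run configuration.

CSV dialect is fixed: UTF-8, comma separator, '.' decimal, header
required.  Topology and rate-set JSON schemas round-trip bit-stably;
every written artifact embeds the seed and a configuration hash so a
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .topology import LineageTopology
from .odes import RateSet
from .simulate import ObservationTable, OBS_COLUMNS

__all__ = [
    "read_observations",
    "write_observations",
    "read_topology",
    "write_topology",
    "read_rates",
    "write_rates",
    "RunConfig",
    "load_run_config",
    "normalize_to_reference",
    "config_hash",
    "write_report_json",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# observation tables
# ---------------------------------------------------------------------------


def read_observations(path) -> ObservationTable:
    """Read an observation CSV, reporting malformed rows with line numbers."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_lines = []
    for col in ("time_days", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        bad_lines += [(int(i) + 2, col) for i in bad]  # +2: header + 1-based
        df[col] = coerced
    if bad_lines:
        raise ValueError(f"{path}: non-numeric values at (line, column): {bad_lines}")
    df["sem"] = pd.to_numeric(df["sem"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce").fillna(1).astype(int)
    return ObservationTable(df)


def write_observations(table: ObservationTable, path) -> None:
    table.df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# topology and rates
# ---------------------------------------------------------------------------


def read_topology(path) -> LineageTopology:
    with open(path, encoding="utf-8") as fh:
        return LineageTopology.from_dict(json.load(fh))


def write_topology(topology: LineageTopology, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(topology.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_rates(path) -> RateSet:
    with open(path, encoding="utf-8") as fh:
        return RateSet.from_dict(json.load(fh))


def write_rates(rates: RateSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(rates.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# per-mouse normalisation
# ---------------------------------------------------------------------------


def normalize_to_reference(
    obs: ObservationTable, reference_compartment: str
) -> ObservationTable:
    """Normalise each mouse's label fractions to its reference compartment.

    Every mouse's label-fraction values are divided by that mouse's
    reference-compartment label fraction at its final bone-marrow
    timepoint (the sacrifice timepoint in a cross-sectional design, or
    the row flagged ``final_bm`` if that column is present); rows are
    re-tagged ``label_fraction_normalized``.  Mice whose reference value
    is missing or zero are excluded, with the exclusion count logged and
    stored on the returned table as ``n_excluded``.
    """
    df = obs.df.copy()
    label_kinds = ("label_fraction", "label_fraction_normalized")
    out_rows = []
    n_excluded = 0
    for (cond, mouse), g in df.groupby(["condition", "mouse"], sort=True):
        lab = g[g.observable.isin(label_kinds)]
        ref_rows = lab[lab.compartment == reference_compartment]
        if "final_bm" in g.columns and ref_rows.final_bm.any():
            ref_rows = ref_rows[ref_rows.final_bm]
        elif len(ref_rows):
            ref_rows = ref_rows[ref_rows.time_days == ref_rows.time_days.max()]
        if len(ref_rows) == 0 or not np.isfinite(ref_rows.value.iloc[0]) \
                or ref_rows.value.iloc[0] == 0:
            n_excluded += 1
            continue
        ref = float(ref_rows.value.iloc[0])
        g = g.copy()
        is_lab = g.observable.isin(label_kinds)
        g.loc[is_lab, "value"] = g.loc[is_lab, "value"] / ref
        g.loc[is_lab & g["sem"].notna(), "sem"] = \
            g.loc[is_lab & g["sem"].notna(), "sem"] / ref
        g.loc[is_lab, "observable"] = "label_fraction_normalized"
        out_rows.append(g)
    if n_excluded:
        log.info("normalize_to_reference: excluded %d mice with zero/missing "
                 "reference labelling", n_excluded)
    if not out_rows:
        raise ValueError("no mouse had a usable reference measurement")
    out = ObservationTable(pd.concat(out_rows).reset_index(drop=True), validate=False)
    out.n_excluded = n_excluded
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative run description loaded from YAML."""

    preset: str | None = None
    topology_path: str | None = None
    rates_path: str | None = None
    observations_path: str | None = None
    seed: int = 0
    output_dir: str = "."
    verbosity: str = "INFO"
    fit: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "topology_path": self.topology_path,
            "rates_path": self.rates_path,
            "observations_path": self.observations_path,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
            "fit": self.fit,
            "noise": self.noise,
            "design": self.design,
        }


def load_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**raw)
    for key in ("topology_path", "rates_path", "observations_path"):
        p = getattr(cfg, key)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{path}: {key} = {p!r} does not exist")
    return cfg


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def write_report_json(payload: dict, path, seed: int, config: dict | None = None) -> None:
    """Write an artifact with embedded seed, config hash and version."""
    from . import __version__

    meta = {
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "lineageflux_version": __version__,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"meta": meta, **payload}, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
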