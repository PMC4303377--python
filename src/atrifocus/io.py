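"""Readers and writers for the package's plain-text artifact formats.

Signals travel as delimited text (first column time in ms, one column per
lead in mV, header row of lead ids); electrode layouts and results as
JSON; correlation tables and run configs as YAML or JSON. Every result
file embeds the seed and a hash of the configuration that produced it, and
writes are atomic (temp file + rename).
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

try:  # importlib.resources is the supported access path for package data
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

from .errors import ParseError, SchemaError
from .locator import CorrelationTable, QA_IDS, QT_IDS
from .pwave import PWaveTrace
from .simulate import ElectrodeLayout

#: Relative tolerance when verifying a uniform sampling step.
UNIFORM_STEP_RTOL = 1e-6


# ---------------------------------------------------------------------------
# Lead traces (delimited text)


def read_lead_traces(
    path: str | Path,
    dialect: str = "csv",
    baseline_window: tuple[float, float] | None = None,
) -> list[PWaveTrace]:
    """Parse a wide-format signal file into one trace per lead.

    The first column is time (ms), every further column one lead (mV).
    Ragged rows, non-monotone or non-uniform time axes and duplicate lead
    ids are rejected with the offending location in the message.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ParseError(f"unknown dialect {dialect!r} (use 'csv' or 'tsv')")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a time column plus at least one lead")
    leads = list(df.columns[1:])
    dupes = sorted({l for l in leads if leads.count(l) > 1})
    # pandas mangles duplicate headers to name.1 etc.; catch both spellings
    dupes += sorted({l.rsplit(".", 1)[0] for l in leads if l.rsplit(".", 1)[-1].isdigit()})
    if dupes:
        raise ParseError(f"{path}: duplicate lead ids {sorted(set(dupes))}")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2  # +1 header, +1 next row
        raise ParseError(f"{path}: time not strictly increasing at line {bad}")
    if len(t) > 2:
        steps = np.diff(t)
        if np.any(np.abs(steps - steps[0]) > UNIFORM_STEP_RTOL * abs(steps[0])):
            bad = int(np.argmax(np.abs(steps - steps[0]) > UNIFORM_STEP_RTOL * abs(steps[0]))) + 2
            raise ParseError(f"{path}: non-uniform time step near line {bad}")
    return [
        PWaveTrace(
            lead_id=str(lead),
            t=t,
            v=df[lead].to_numpy(dtype=float),
            baseline_window=baseline_window,
        )
        for lead in leads
    ]


def write_lead_traces(
    path: str | Path,
    times: np.ndarray,
    traces: Mapping[str, np.ndarray],
    dialect: str = "csv",
) -> None:
    """Write lead traces in the wide delimited-text format (atomically)."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ParseError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame({"time_ms": np.asarray(times, dtype=float)})
    for lead, v in traces.items():
        df[lead] = np.asarray(v, dtype=float)
    _atomic_write(path, df.to_csv(sep=sep, index=False, float_format="%.17g"))


# ---------------------------------------------------------------------------
# Electrode layout (JSON)


def read_layout(path: str | Path) -> ElectrodeLayout:
    """Load an electrode layout from JSON with schema validation."""
    doc = _load_structured(path)
    for key in ("leads", "wct_positions"):
        if key not in doc:
            raise SchemaError(f"{path}: missing field {key!r}")
    positions, faces = {}, {}
    for lead, entry in doc["leads"].items():
        if "position" not in entry or "face" not in entry:
            raise SchemaError(f"{path}: lead {lead}: needs 'position' and 'face'")
        pos = np.asarray(entry["position"], dtype=float)
        if pos.shape != (3,):
            raise SchemaError(f"{path}: lead {lead}: position must have 3 numbers")
        if entry["face"] not in ("anterior", "posterior"):
            raise SchemaError(
                f"{path}: lead {lead}: invalid face {entry['face']!r}"
            )
        positions[lead] = pos
        faces[lead] = entry["face"]
    wct = np.asarray(doc["wct_positions"], dtype=float)
    if wct.shape != (3, 3):
        raise SchemaError(f"{path}: wct_positions must be 3 points of 3 numbers")
    return ElectrodeLayout(
        positions=positions,
        faces=faces,
        wct_positions=wct,
        name=doc.get("name", Path(path).stem),
    )


def write_layout(path: str | Path, layout: ElectrodeLayout) -> None:
    doc = {
        "name": layout.name,
        "leads": {
            lead: {
                "position": [float(x) for x in layout.positions[lead]],
                "face": layout.faces[lead],
            }
            for lead in layout.lead_ids
        },
        "wct_positions": layout.wct_positions.tolist(),
    }
    _atomic_write(path, json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# Correlation table (YAML/JSON)


def read_table(path: str | Path) -> CorrelationTable:
    """Load a torso-to-atria correlation table (YAML or JSON)."""
    doc = _load_structured(path)
    return _table_from_dict(doc, source=str(path))


def _table_from_dict(doc: Mapping, source: str = "<table>") -> CorrelationTable:
    if "variants" not in doc:
        raise SchemaError(f"{source}: missing field 'variants'")
    variants = {}
    for name, entries in doc["variants"].items():
        missing = [qa for qa in QA_IDS if qa not in entries]
        if missing:
            raise SchemaError(f"{source}: variant {name}: missing {missing}")
        variants[name] = {
            qa: tuple(str(r) for r in entries[qa]) for qa in QA_IDS
        }
    qt_to_qa = doc.get("qt_to_qa", {f"Qt{i}": f"Qa{i}" for i in range(1, 9)})
    if sorted(qt_to_qa) != sorted(QT_IDS) or sorted(qt_to_qa.values()) != sorted(QA_IDS):
        raise SchemaError(f"{source}: qt_to_qa must be a bijection Qt1-8 -> Qa1-8")
    return CorrelationTable(variants=variants, qt_to_qa=dict(qt_to_qa))


def load_default_table() -> CorrelationTable:
    """The correlation table shipped with the package (both variants)."""
    text = (_pkg_files("atrifocus") / "data" / "correlation_table.yaml").read_text()
    return _table_from_dict(yaml.safe_load(text), source="packaged table")


# ---------------------------------------------------------------------------
# Results and generic structured text


def config_hash(config: Mapping) -> str:
    """Stable short hash of a (JSON-serialisable) configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    result: Mapping,
    path: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> None:
    """Write a result document as JSON with provenance (atomic)."""
    doc = dict(result)
    doc["provenance"] = {
        "config_hash": config_hash(config or {}),
        "seed": seed,
    }
    _atomic_write(path, json.dumps(doc, indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    return doc


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
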