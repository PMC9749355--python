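"""Tabular result writers (CSV/JSON) with deterministic layout."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .econ import CEAResult
from .engine import INTERVENTION, USUAL_CARE


def _fmt(x) -> float:
    return float(x) if x is not None else float("nan")


def cea_presentation_table(result: CEAResult) -> pd.DataFrame:
    """Rounded presentation view: totals, components, events per 10,000."""
    a = result.arms.get(INTERVENTION, {})
    b = result.arms.get(USUAL_CARE, {})
    rows = [
        ("Total cost", round(a.get("cost", 0)), round(b.get("cost", 0)),
         round(result.increments["cost"])),
        ("QALY", round(a.get("qaly", 0), 3), round(b.get("qaly", 0), 3),
         round(result.increments["qaly"], 4)),
        ("LY", round(a.get("ly", 0), 3), round(b.get("ly", 0), 3),
         round(result.increments["ly"], 4)),
        ("Cost of intervention", round(a.get("cost_intervention", 0)),
         round(b.get("cost_intervention", 0)),
         round(result.increments["cost_intervention"])),
        ("Cost of CVD-related hospitalisation", round(a.get("cost_acute", 0)),
         round(b.get("cost_acute", 0)), round(result.increments["cost_acute"])),
        ("Cost of CVD management", round(a.get("cost_mgmt", 0)),
         round(b.get("cost_mgmt", 0)), round(result.increments["cost_mgmt"])),
    ]
    if result.events_per_10000:
        ev_i = result.events_per_10000[INTERVENTION].set_index(["class", "subtype"])
        ev_u = result.events_per_10000[USUAL_CARE].set_index(["class", "subtype"])
        for idx in ev_u.index:
            vi = ev_i.loc[idx, "per_10000"] if idx in ev_i.index else 0.0
            vu = ev_u.loc[idx, "per_10000"]
            label = f"Events per 10,000 ({idx[0]}: {idx[1]})"
            rows.append((label, round(vi), round(vu), round(vi - vu)))
    return pd.DataFrame(
        rows, columns=["quantity", "lifestyle_modification", "usual_care",
                       "difference"]
    )


def write_results(result, path: str | Path, format: str = "csv") -> Path:
    """Write an analysis output to disk.

    ``CEAResult`` -> full-precision JSON or a rounded Table-style CSV;
    DataFrames (tornado, PSA draws, CEAC) -> CSV with their column order;
    other dataclasses -> JSON.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, CEAResult):
        if format == "json":
            payload = result.to_dict()
            payload["icer_qaly"] = _fmt(result.icer_qaly)
            payload["icer_ly"] = _fmt(result.icer_ly)
            path.write_text(json.dumps(payload, indent=2, default=float))
        else:
            cea_presentation_table(result).to_csv(path, index=False)
        return path
    if isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False)
        return path
    if isinstance(result, list) and result and dataclasses.is_dataclass(result[0]):
        df = pd.DataFrame([dataclasses.asdict(e) for e in result])
        if hasattr(result[0], "span"):
            df["span"] = [e.span for e in result]
        df.to_csv(path, index=False)
        return path
    if dataclasses.is_dataclass(result):
        path.write_text(json.dumps(dataclasses.asdict(result), indent=2,
                                   default=float))
        return path
    raise TypeError(f"do not know how to write {type(result)!r}")
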