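"""File formats: distributions (TSV/JSON), trials, AP grids, result tables.

Distribution dialects
---------------------
TSV: header ``y\tb\ta\tp``, one row per supported cell; alphabets are
ordered by first appearance. JSON: explicit alphabets plus a list of
``[y, b, a, p]`` cells. Both round-trip losslessly to 15+ significant
digits (probabilities are written with 17 significant digits).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import InvalidDistributionError, TrivariateDistribution
from .pipeline import APGrid, TrialRecord

__all__ = [
    "read_distribution", "write_distribution",
    "read_ap_grid", "write_ap_grid",
    "read_trials", "write_trials",
    "report_results", "RunConfig", "file_sha256", "ParseError",
]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line."""


def _coerce_label(text: str):
    """Labels are ints when they look like ints, else strings."""
    try:
        return int(text)
    except ValueError:
        return text


def read_distribution(path: str | Path) -> TrivariateDistribution:
    """Read a distribution from the TSV or JSON dialect (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_distribution_json(path)
    return _read_distribution_tsv(path)


def _read_distribution_tsv(path: Path) -> TrivariateDistribution:
    cells: dict[tuple, float] = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if [h.strip().lower() for h in header] != ["y", "b", "a", "p"]:
            raise ParseError(f"{path}:1: expected header 'y\\tb\\ta\\tp', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
            key = tuple(_coerce_label(t) for t in parts[:3])
            try:
                mass = float(parts[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad probability {parts[3]!r}")
            if mass < 0:
                raise ParseError(f"{path}:{lineno}: negative probability {mass!r}")
            if key in cells:
                raise ParseError(f"{path}:{lineno}: duplicate cell {key!r}")
            cells[key] = mass
    try:
        return TrivariateDistribution.from_dict(cells)
    except InvalidDistributionError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_distribution_json(path: Path) -> TrivariateDistribution:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        cells = {}
        for row in doc["cells"]:
            y, b, a, mass = row
            key = (y, b, a)
            if key in cells:
                raise ParseError(f"{path}: duplicate cell {key!r}")
            cells[key] = mass
        return TrivariateDistribution.from_dict(
            cells,
            alphabet_y=doc["alphabet_y"],
            alphabet_b=doc["alphabet_b"],
            alphabet_a=doc["alphabet_a"],
        )
    except (KeyError, TypeError, InvalidDistributionError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_distribution(dist: TrivariateDistribution, path: str | Path) -> None:
    """Write the supported cells in the TSV or JSON dialect (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "alphabet_y": list(dist.alphabet_y),
            "alphabet_b": list(dist.alphabet_b),
            "alphabet_a": list(dist.alphabet_a),
            "cells": [[y, b, a, p] for (y, b, a), p in dist.as_dict().items()],
        }
        path.write_text(json.dumps(doc, indent=1))
        return
    lines = ["y\tb\ta\tp"]
    for (y, b, a), p in dist.as_dict().items():
        lines.append(f"{y}\t{b}\t{a}\t{p:.17g}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# AP grid and trials

def read_ap_grid(path: str | Path) -> APGrid:
    """CSV with columns basal, apical, ap_count."""
    df = pd.read_csv(path)
    need = {"basal", "apical", "ap_count"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(need)}")
    counts = {
        (int(r.basal), int(r.apical)): int(r.ap_count) for r in df.itertuples()
    }
    return APGrid(
        basal_levels=tuple(sorted(df["basal"].unique())),
        apical_levels=tuple(sorted(df["apical"].unique())),
        counts=counts,
    )


def write_ap_grid(grid: APGrid, path: str | Path) -> None:
    rows = [
        {"basal": b, "apical": a, "ap_count": c}
        for (b, a), c in sorted(grid.counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_trials(trials: list[TrialRecord], trace_path: str | Path,
                 ap_path: str | Path) -> None:
    """Trial CSV (one row per sample) plus companion AP-times CSV."""
    trace_rows, ap_rows = [], []
    for idx, tr in enumerate(trials):
        t = np.arange(tr.basal_trace.size) * tr.dt_ms
        trace_rows.append(pd.DataFrame({
            "unit_id": tr.unit_id, "condition": tr.condition, "trial": idx,
            "basal_amp": tr.basal_amp, "apical_amp": tr.apical_amp,
            "time_ms": t, "basal_pA": tr.basal_trace, "apical_pA": tr.apical_trace,
        }))
        for ap in tr.ap_times:
            ap_rows.append({"unit_id": tr.unit_id, "condition": tr.condition,
                            "trial": idx, "ap_time_ms": ap})
    pd.concat(trace_rows, ignore_index=True).to_csv(trace_path, index=False)
    pd.DataFrame(ap_rows, columns=["unit_id", "condition", "trial", "ap_time_ms"]
                 ).to_csv(ap_path, index=False)


def read_trials(trace_path: str | Path, ap_path: str | Path) -> list[TrialRecord]:
    traces = pd.read_csv(trace_path)
    aps = pd.read_csv(ap_path)
    need = {"unit_id", "condition", "trial", "basal_amp", "apical_amp",
            "time_ms", "basal_pA", "apical_pA"}
    if not need <= set(traces.columns):
        raise ParseError(f"{trace_path}: expected columns {sorted(need)}")
    out = []
    for (unit, cond, trial), g in traces.groupby(["unit_id", "condition", "trial"], sort=True):
        g = g.sort_values("time_ms")
        t = g["time_ms"].to_numpy()
        dt = float(t[1] - t[0]) if t.size > 1 else 1.0
        sel = aps[(aps["unit_id"] == unit) & (aps["condition"] == cond)
                  & (aps["trial"] == trial)]
        out.append(TrialRecord(
            unit_id=str(unit), condition=str(cond),
            basal_amp=float(g["basal_amp"].iloc[0]),
            apical_amp=float(g["apical_amp"].iloc[0]),
            basal_trace=g["basal_pA"].to_numpy(),
            apical_trace=g["apical_pA"].to_numpy(),
            ap_times=sel["ap_time_ms"].to_numpy(dtype=float),
            dt_ms=dt,
        ))
    return out


# ---------------------------------------------------------------------------
# results and configuration

def report_results(results, path: str | Path) -> pd.DataFrame:
    """Write PID results as CSV with raw values and 1-dp percentages.

    ``results`` is an iterable of PIDResult. Percentages (of the joint
    mutual information) are rounded to one decimal as in the study tables;
    raw values are retained in parallel columns.
    """
    rows = []
    for r in results:
        row = {"method": r.method, "jmi": r.jmi, "normalized": r.normalized}
        for comp in ("unq_b", "unq_a", "shd", "syn"):
            val = getattr(r, comp)
            row[comp] = val
            frac = val if r.normalized else (val / r.jmi if r.jmi > 0 else np.nan)
            row[f"{comp}_pct"] = round(100 * frac, 1)
        row["residual"] = r.solver_info.residual
        rows.append(row)
    if not rows:
        raise ValueError("no results to report")
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunConfig:
    """Declarative run configuration; every field has a working default."""

    methods: tuple[str, ...] = ("broja", "dep", "ccs", "pm", "sx")
    window_ms: float = 120.0
    input_bins: int = 4
    output_categories: tuple = ((0, 0), (1, 1), (2, None))
    ccs_drive: float = 0.20
    ccs_ctx: float = 0.05
    ccs_joint: float = 0.10
    broja_tol: float = 1e-9
    ipf_tol: float = 1e-10
    bonferroni_m: int | None = None
    seed: int = 0
    input_path: str | None = None
    output_path: str | None = None

    def to_json(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        cfg = cls(**doc)
        cfg.methods = tuple(cfg.methods)
        cfg.output_categories = tuple(
            tuple(c) for c in cfg.output_categories
        )
        return cfg
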