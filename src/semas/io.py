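"""Shared I/O: delimited response tables, profile/report CSVs, run manifests.

All files are UTF-8, comma-delimited, period decimal separator.  Locale
decimal commas are rejected with a clear error rather than silently
mis-parsed.  Written tables have fixed column order and fixed numeric
formatting (ratios to 3 decimals, percentages to 1, half-up), so identical
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .instrument import BarrierCategory, InstrumentDefinition
from .psychometrics import ValidationReport
from .scoring import ResponseRecord, SemasProfile

__all__ = [
    "ResponseFileError",
    "read_responses",
    "read_table",
    "profiles_to_frame",
    "write_profiles",
    "write_report",
    "write_manifest",
]


class ResponseFileError(ValueError):
    pass


def _decimal(value: str, context: str) -> float:
    v = value.strip()
    if "," in v:
        raise ResponseFileError(
            f"{context}: {value!r} uses a decimal comma; files must use the "
            "period decimal separator"
        )
    try:
        return float(v)
    except ValueError as exc:
        raise ResponseFileError(f"{context}: {value!r} is not numeric") from exc


def read_responses(
    path: str | Path,
    instrument: InstrumentDefinition,
) -> tuple[list[ResponseRecord], list[str]]:
    """Read a respondent x item CSV into typed response records.

    The file needs a ``respondent_id`` column and one column per item; blank
    cells are missing.  Unknown columns are reported (not fatal); duplicate
    respondent ids and a missing id column are errors.

    Returns (records, warnings).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    notes: list[str] = []
    if "respondent_id" not in df.columns:
        raise ResponseFileError(f"{path}: missing mandatory 'respondent_id' column")
    items = instrument.items
    unknown = [c for c in df.columns if c != "respondent_id" and c not in items]
    if unknown:
        notes.append(f"unknown columns ignored: {', '.join(unknown)}")
    dupes = df["respondent_id"][df["respondent_id"].duplicated()].unique()
    if len(dupes):
        raise ResponseFileError(f"{path}: duplicate respondent_id values: {', '.join(dupes)}")
    records = []
    for _, row in df.iterrows():
        rid = row["respondent_id"].strip()
        resp: dict[str, float | int | None] = {}
        for col in df.columns:
            if col == "respondent_id" or col in unknown:
                continue
            cell = row[col].strip()
            if cell == "":
                resp[col] = None
            elif items[col].is_vas:
                resp[col] = _decimal(cell, f"{path}:{rid}:{col}")
            else:
                value = _decimal(cell, f"{path}:{rid}:{col}")
                if value != int(value):
                    raise ResponseFileError(
                        f"{path}:{rid}:{col}: Likert code {cell!r} is not an integer"
                    )
                resp[col] = int(value)
        records.append(ResponseRecord(respondent_id=rid, responses=resp))
    return records, notes


def read_table(path: str | Path, index_col: str = "respondent_id") -> pd.DataFrame:
    """Read a numeric CSV (criterion responses, PAM scores) indexed by
    respondent, blank = missing, decimal commas rejected."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if index_col not in df.columns:
        raise ResponseFileError(f"{path}: missing {index_col!r} column")
    df = df.set_index(index_col)
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        out[col] = [
            np.nan if v.strip() == "" else _decimal(v, f"{path}:{col}")
            for v in df[col]
        ]
    return out


def _fmt_ratio(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "N.A."
    # half-up at 3 decimals
    return f"{np.floor(x * 1000 + 0.5) / 1000:.3f}"


def _fmt_pct(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "N.A."
    return f"{np.floor(x * 1000 + 0.5) / 10:.1f}"


def profiles_to_frame(
    profiles: Sequence[SemasProfile], instrument: InstrumentDefinition
) -> pd.DataFrame:
    """Flatten scored profiles to a table: sums, categories, styles,
    orientation, guidance levels, barrier count."""
    units = instrument.barrier_units()
    rows = []
    for p in profiles:
        row: dict[str, object] = {"respondent_id": p.respondent_id}
        for u in units:
            sc = p.scores[u]
            row[f"{u}_sum"] = "" if sc.sum_score is None else f"{sc.sum_score:g}"
            row[f"{u}_category"] = sc.category.value
        row["coping_styles"] = "" if not p.coping_styles else "+".join(sorted(p.coping_styles))
        row["locus_orientation"] = p.locus_orientation or ""
        for gid, level in p.guidance_flags.items():
            row[gid] = "" if level is None else level
        row["barrier_count"] = p.barrier_count
        row["n_issues"] = len(p.issues)
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(
    profiles: Sequence[SemasProfile],
    instrument: InstrumentDefinition,
    path: str | Path,
) -> None:
    df = profiles_to_frame(profiles, instrument)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


REPORT_COLUMNS = ("construct", "n", "PPV", "NPV", "alpha", "corr", "corr_method", "p")


def write_report(report: ValidationReport, path: str | Path) -> None:
    """Write a validation report as CSV (fixed columns, stable formatting),
    one row per barrier construct plus indented coping-style rows, followed
    by a regression block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [",".join(REPORT_COLUMNS)]
    for row in report.rows:
        lines.append(
            ",".join(
                [
                    row.construct_id,
                    str(row.n),
                    _fmt_pct(row.ppv),
                    _fmt_pct(row.npv),
                    _fmt_ratio(row.alpha) if row.alpha is not None else "N.A.",
                    _fmt_ratio(row.corr),
                    row.corr_method if row.corr is not None else "N.A.",
                    _fmt_ratio(row.p_value),
                ]
            )
        )
        for style in sorted(row.styles):
            s = row.styles[style]
            lines.append(
                ",".join(
                    [
                        f"{row.construct_id} ({style})",
                        str(s.n),
                        "N.A.",
                        "N.A.",
                        _fmt_ratio(s.alpha),
                        _fmt_ratio(s.corr),
                        s.corr_method if s.corr is not None else "N.A.",
                        _fmt_ratio(s.p_value),
                    ]
                )
            )
    if report.regression is not None:
        reg = report.regression
        lines.append("")
        lines.append("regression,beta,SE_beta,standardized_beta,p,r_squared,n")
        lines.append(
            f"intercept,{_fmt_ratio(reg.intercept)},,,,,{reg.n}"
        )
        for name, eff in reg.effects.items():
            lines.append(
                ",".join(
                    [
                        name,
                        _fmt_ratio(eff.beta),
                        _fmt_ratio(eff.se_beta),
                        _fmt_ratio(eff.standardized_beta),
                        _fmt_ratio(eff.p_value),
                        _fmt_ratio(reg.r_squared),
                        str(reg.n),
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_manifest(
    out_dir: str | Path,
    command: str,
    inputs: Iterable[str | Path] = (),
    instrument: InstrumentDefinition | None = None,
    seed: int | None = None,
) -> Path:
    """Write the run manifest (exactly one per output directory): command,
    input content digests, instrument version, seed, tool version, UTC
    timestamp."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digests = {}
    for p in inputs:
        p = Path(p)
        digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "command": command,
        "inputs": digests,
        "instrument": None
        if instrument is None
        else {"name": instrument.name, "version": instrument.version},
        "seed": seed,
        "tool_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
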