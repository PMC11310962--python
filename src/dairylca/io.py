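"""Reading and writing the structured-text formats the pipeline consumes.

Farm systems and reports live in versioned YAML documents (human-diffable
key/value text); emission-factor tables are comma-delimited text with a
one-line header (``item_key,category,factor,gsd``)."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .categories import SOURCE_LABELS, SOURCES
from .compare import ComparisonReport
from .datamodel import EmissionFactorTable, FarmSystem
from .errors import EmptyReportError, InvalidInputError, SchemaError

SCHEMA_VERSION = 1
PathLike = Union[str, Path]


def _format_validation_error(exc: ValidationError) -> str:
    paths = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        paths.append(f"{loc}: {err['msg']}")
    return "; ".join(paths)


def _load_yaml(path: PathLike) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    return data


def _check_schema(data: dict, path: PathLike) -> None:
    version = data.get("schema_version")
    if version is None:
        raise SchemaError(f"{path}: missing schema_version field")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported schema_version {version!r}")


def read_farm_system(path: PathLike) -> FarmSystem:
    """Parse and validate a farm-system file; invariants are checked eagerly
    and violations are reported with their field paths."""
    data = _load_yaml(path)
    _check_schema(data, path)
    payload = {k: v for k, v in data.items() if k != "schema_version"}
    try:
        return FarmSystem.model_validate(payload)
    except ValidationError as exc:
        raise InvalidInputError(
            f"{path}: invalid farm system: {_format_validation_error(exc)}"
        ) from exc


def write_farm_system(system: FarmSystem, path: PathLike) -> Path:
    path = Path(path)
    doc = {"schema_version": SCHEMA_VERSION, **system.model_dump(mode="json")}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def read_ef_table(path: PathLike) -> EmissionFactorTable:
    """Read a delimited emission-factor table; absent gsd cells default to 1.0
    (no spread)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    try:
        return EmissionFactorTable.from_frame(frame)
    except InvalidInputError as exc:
        raise InvalidInputError(f"{path}: {exc}") from exc


def write_ef_table(table: EmissionFactorTable, path: PathLike) -> Path:
    path = Path(path)
    # %.17g keeps write -> read an exact identity on the factor values
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def render_contribution_table(report: ComparisonReport) -> str:
    """Plain-text carbon-footprint contribution table (standard row layout:
    feed compounds, roughages, on-farm gas flows, utilities, additive, LUC)."""
    bd_c = report.cc_breakdown_control
    bd_t = report.cc_breakdown_treatment
    if bd_c is None or bd_t is None:
        raise EmptyReportError("report carries no CC breakdown to render")
    lines = [
        f"Carbon footprint contribution (kg CO2 eq/kg FPCM): {report.label}",
        f"{'Source':<18}{'Control':>10}{'Treatment':>11}",
    ]
    total_c = sum(bd_c.values())
    total_t = sum(bd_t.values())
    lines.append(f"{'Total':<18}{total_c:>10.4f}{total_t:>11.4f}")
    for source in SOURCES:
        if source in bd_c:
            lines.append(
                f"{SOURCE_LABELS[source]:<18}{bd_c[source]:>10.4f}{bd_t.get(source, 0.0):>11.4f}"
            )
    return "\n".join(lines)


def write_report(report: ComparisonReport, path: PathLike) -> tuple[Path, Path]:
    """Emit the machine-readable report (YAML) and, beside it, a plain-text
    contribution table (``.txt``). Returns both paths."""
    if not report.categories:
        raise EmptyReportError("comparison report has no categories")
    path = Path(path)
    doc = {"schema_version": SCHEMA_VERSION, **report.model_dump(mode="json")}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    txt_path = path.with_suffix(".txt")
    lines = [f"Comparison report: {report.label}"]
    if report.window_only:
        lines.append("(supplementation window only)")
    lines.append(f"{'Category':<10}{'Control':>12}{'Treatment':>12}{'Diff':>9}")
    for cat, comp in report.categories.items():
        lines.append(
            f"{cat:<10}{comp.control:>12.4g}{comp.treatment:>12.4g}{comp.diff_pct:>8.2f}%"
        )
    if report.cc_breakdown_control is not None and report.cc_breakdown_treatment is not None:
        lines.append("")
        lines.append(render_contribution_table(report))
    with open(txt_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path, txt_path


def read_report(path: PathLike) -> ComparisonReport:
    data = _load_yaml(path)
    _check_schema(data, path)
    payload = {k: v for k, v in data.items() if k != "schema_version"}
    try:
        return ComparisonReport.model_validate(payload)
    except ValidationError as exc:
        raise InvalidInputError(
            f"{path}: invalid report: {_format_validation_error(exc)}"
        ) from exc
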