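"""Analysis configuration: schema, YAML/JSON loading, CSV matrices.

A configuration mirrors the SWOT-AHP hierarchy — goal, four groups, factors —
as data: each of the groups S, W, O, T carries an ordered factor list (id,
label, optional description, estimated strength on 0-5) and one pairwise
comparison matrix, either inline as row lists (cells may be fraction strings
like ``"1/3"``) or as a CSV side-file resolved relative to the config file.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .ahp import ComparisonMatrix, validate_comparison_matrix
from .errors import ConfigError, MatrixValidationError

__all__ = [
    "FactorSpec",
    "GroupSpec",
    "AnalysisOptions",
    "AnalysisConfig",
    "load_config",
    "save_config",
    "config_to_dict",
    "read_matrix_csv",
    "bundled_example_path",
]

GROUP_KEYS = ("S", "W", "O", "T")


@dataclass(frozen=True)
class FactorSpec:
    id: str
    label: str
    strength: float
    description: str = ""


@dataclass(frozen=True)
class GroupSpec:
    key: str
    factors: tuple[FactorSpec, ...]
    #: None for single-factor groups (the weight is trivially 1)
    matrix: ComparisonMatrix | None


@dataclass(frozen=True)
class AnalysisOptions:
    reciprocity_tol: float = 1e-6
    strict_saaty: bool = False
    cr_gate: str = "error"  # "error" | "warn"
    rounding: int = 4
    theta_rounding: int = 2


@dataclass(frozen=True)
class AnalysisConfig:
    title: str
    groups: Mapping[str, GroupSpec]
    options: AnalysisOptions = field(default_factory=AnalysisOptions)
    analyst: str = ""
    date: str = ""


def read_matrix_csv(path: str | Path) -> tuple[list[list[str]], list[str]]:
    """Read a comparison matrix from CSV with a header row and header column.

    Returns (rows-of-cells, labels); cells stay strings so fraction judgments
    are parsed exactly downstream.
    """
    path = Path(path)
    try:
        with path.open(newline="") as fh:
            rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    except OSError as exc:
        raise ConfigError(f"cannot read matrix CSV {path}: {exc}") from exc
    if len(rows) < 3:
        raise ConfigError(f"{path}: expected header row/column plus >= 2 data rows")
    labels = [c.strip() for c in rows[0][1:] if c.strip()]
    body = []
    for r in rows[1:]:
        body.append([c.strip() for c in r[1 : len(labels) + 1]])
    row_labels = [r[0].strip() for r in rows[1:]]
    if row_labels != labels:
        raise ConfigError(
            f"{path}: header column {row_labels} does not match header row {labels}"
        )
    return body, labels


def _require(mapping: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"{path}: missing required field {key!r}")
    return mapping[key]


def _parse_options(raw: Mapping[str, Any] | None) -> AnalysisOptions:
    raw = dict(raw or {})
    opts = AnalysisOptions(
        reciprocity_tol=float(raw.pop("reciprocity_tol", 1e-6)),
        strict_saaty=bool(raw.pop("strict_saaty", False)),
        cr_gate=str(raw.pop("cr_gate", "error")),
        rounding=int(raw.pop("rounding", 4)),
        theta_rounding=int(raw.pop("theta_rounding", 2)),
    )
    if opts.cr_gate not in ("error", "warn"):
        raise ConfigError(f"options.cr_gate: expected 'error' or 'warn', got {opts.cr_gate!r}")
    if raw:
        raise ConfigError(f"options: unknown field(s) {sorted(raw)}")
    return opts


def _parse_group(key: str, raw: Mapping[str, Any], base_dir: Path, opts: AnalysisOptions) -> GroupSpec:
    where = f"groups.{key}"
    raw_factors = _require(raw, "factors", where)
    if not isinstance(raw_factors, Sequence) or not raw_factors:
        raise ConfigError(f"{where}.factors: expected a non-empty list")
    factors = []
    for k, rf in enumerate(raw_factors):
        fw = f"{where}.factors[{k}]"
        if not isinstance(rf, Mapping):
            raise ConfigError(f"{fw}: expected a mapping with id/label/strength")
        factors.append(
            FactorSpec(
                id=str(_require(rf, "id", fw)),
                label=str(rf.get("label", rf.get("id"))),
                strength=float(_require(rf, "strength", fw)),
                description=str(rf.get("description", "")),
            )
        )
    ids = [f.id for f in factors]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"{where}: duplicate factor ids {ids}")

    if "matrix" in raw and "matrix_csv" in raw:
        raise ConfigError(f"{where}: give either matrix or matrix_csv, not both")
    if len(factors) == 1:
        # a single factor needs no pairwise comparisons; weight is 1
        entries = raw.get("matrix")
        if entries is not None and list(map(len, entries)) != [1]:
            raise ConfigError(
                f"{where}: single-factor group admits only the trivial matrix [[1]]"
            )
        return GroupSpec(key=key, factors=tuple(factors), matrix=None)
    if "matrix" in raw:
        entries = raw["matrix"]
        labels = ids
    elif "matrix_csv" in raw:
        entries, labels = read_matrix_csv(base_dir / str(raw["matrix_csv"]))
        if labels != ids:
            raise ConfigError(
                f"{where}: CSV labels {labels} do not match factor ids {ids}"
            )
    else:
        raise ConfigError(f"{where}: missing matrix (inline rows or matrix_csv)")
    try:
        matrix = validate_comparison_matrix(
            entries, labels=labels, tol=opts.reciprocity_tol, strict_saaty=opts.strict_saaty
        )
    except MatrixValidationError as exc:
        raise ConfigError(f"{where}.matrix: {exc}") from exc
    if matrix.n != len(factors):
        raise ConfigError(
            f"{where}: matrix order {matrix.n} does not match {len(factors)} factors"
        )
    return GroupSpec(key=key, factors=tuple(factors), matrix=matrix)


def parse_config(raw: Mapping[str, Any], base_dir: Path | None = None) -> AnalysisConfig:
    """Validate a raw mapping (already parsed YAML/JSON) into an AnalysisConfig."""
    if not isinstance(raw, Mapping):
        raise ConfigError("top level: expected a mapping")
    base_dir = base_dir or Path(".")
    opts = _parse_options(raw.get("options"))
    raw_groups = _require(raw, "groups", "top level")
    if not isinstance(raw_groups, Mapping):
        raise ConfigError("groups: expected a mapping with keys S, W, O, T")
    normalized = {str(k).upper(): v for k, v in raw_groups.items()}
    missing = [k for k in GROUP_KEYS if k not in normalized]
    if missing:
        raise ConfigError(f"groups: missing group(s) {missing}")
    extra = [k for k in normalized if k not in GROUP_KEYS]
    if extra:
        raise ConfigError(f"groups: unknown group key(s) {extra}")
    groups = {k: _parse_group(k, normalized[k], base_dir, opts) for k in GROUP_KEYS}
    return AnalysisConfig(
        title=str(raw.get("title", "SWOT-AHP analysis")),
        analyst=str(raw.get("analyst", "")),
        date=str(raw.get("date", "")),
        groups=groups,
        options=opts,
    )


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: parse error: {exc}") from exc
    return parse_config(raw, base_dir=path.parent)


def config_to_dict(config: AnalysisConfig) -> dict[str, Any]:
    """Serializable mapping in the same schema load_config consumes."""
    out: dict[str, Any] = {
        "title": config.title,
        "analyst": config.analyst,
        "date": config.date,
        "options": {
            "reciprocity_tol": config.options.reciprocity_tol,
            "strict_saaty": config.options.strict_saaty,
            "cr_gate": config.options.cr_gate,
            "rounding": config.options.rounding,
            "theta_rounding": config.options.theta_rounding,
        },
        "groups": {},
    }
    for key in GROUP_KEYS:
        g = config.groups[key]
        out["groups"][key] = {
            "factors": [
                {
                    "id": f.id,
                    "label": f.label,
                    "description": f.description,
                    "strength": f.strength,
                }
                for f in g.factors
            ],
            "matrix": (
                [[1.0]]
                if g.matrix is None
                else [[float(x) for x in row] for row in g.matrix.values]
            ),
        }
    return out


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write a config as YAML (deterministic field order)."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False, default_flow_style=None)
    )


def bundled_example_path() -> Path:
    """Path to the bundled home-based-exercise case-study configuration."""
    return Path(resources.files("swotahp").joinpath("data/homebased_exercise_cn.yaml"))
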