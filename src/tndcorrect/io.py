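"""CSV / YAML input-output for count tables, line lists and scenarios.

All formats are plain text: comma-separated UTF-8 with a mandatory header row
for tables, and a flat key-value YAML mapping for scenario configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .classification import CountTable2x2, TestPerformance
from .simulate import CovariateSpec, Scenario, default_covariates

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_line_list",
    "read_scenario",
    "write_report",
]

_REQUIRED_TABLE_COLS = {"test_result", "vaccinated", "count"}


class DataFormatError(ValueError):
    """Malformed input data (as opposed to bad command-line usage)."""


def read_count_table(path: str | Path) -> CountTable2x2:
    """Read an observed 2x2 table from long-format CSV.

    Columns: ``test_result`` in {pos, neg}, ``vaccinated`` in {0, 1},
    ``count``. Duplicate cells are summed; missing cells default to zero.
    """
    df = pd.read_csv(path)
    missing = _REQUIRED_TABLE_COLS - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    cells = {("pos", 1): 0.0, ("pos", 0): 0.0, ("neg", 1): 0.0, ("neg", 0): 0.0}
    for idx, row in df.iterrows():
        key = (str(row["test_result"]).strip().lower(), int(row["vaccinated"]))
        if key not in cells:
            raise DataFormatError(
                f"{path}: line {idx + 2}: test_result must be pos/neg and "
                f"vaccinated 0/1, got {row['test_result']!r}/{row['vaccinated']!r}"
            )
        count = float(row["count"])
        if count < 0:
            raise DataFormatError(f"{path}: line {idx + 2}: negative count")
        cells[key] += count
    return CountTable2x2(
        pos_vacc=cells[("pos", 1)],
        pos_unvacc=cells[("pos", 0)],
        neg_vacc=cells[("neg", 1)],
        neg_unvacc=cells[("neg", 0)],
    )


def write_count_table(table: CountTable2x2, path: str | Path) -> None:
    pd.DataFrame(
        {
            "test_result": ["pos", "pos", "neg", "neg"],
            "vaccinated": [1, 0, 1, 0],
            "count": [table.pos_vacc, table.pos_unvacc, table.neg_vacc, table.neg_unvacc],
        }
    ).to_csv(path, index=False)


def read_line_list(
    path: str | Path,
    outcome_col: str = "outcome",
    vaccinated_col: str = "vaccinated",
) -> pd.DataFrame:
    """Read a per-patient line list: outcome, vaccinated, free covariates."""
    df = pd.read_csv(path)
    for col in (outcome_col, vaccinated_col):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing column {col!r}")
        values = set(pd.unique(df[col].dropna()))
        if not values <= {0, 1}:
            raise DataFormatError(f"{path}: column {col!r} must be binary 0/1")
    if df[[outcome_col, vaccinated_col]].isna().any().any():
        raise DataFormatError(f"{path}: missing values in outcome/vaccination")
    return df


def read_scenario(path: str | Path) -> Scenario:
    """Load a Scenario from flat YAML key-values.

    Keys: true_ve, (delta | case_ratio), sensitivity, specificity,
    mean_total, attendance_ratio, covariates (``default`` or a list of
    {name, kind, rr_td, rr_nd, prevalence} mappings), name.
    """
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise DataFormatError(f"{path}: scenario file must be a mapping")
    try:
        if "delta" in raw:
            delta = float(raw["delta"])
        else:
            cr = float(raw["case_ratio"])
            delta = cr / (1.0 - cr)
        cov_raw = raw.get("covariates", [])
        if cov_raw == "default":
            covs = default_covariates()
        else:
            covs = [CovariateSpec(**c) for c in cov_raw]
        return Scenario(
            true_ve=float(raw["true_ve"]),
            delta=delta,
            performance=TestPerformance(float(raw["sensitivity"]), float(raw["specificity"])),
            mean_total=float(raw.get("mean_total", 3000.0)),
            attendance_ratio=float(raw.get("attendance_ratio", 1.0)),
            covariates=tuple(covs),
            name=raw.get("name"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise DataFormatError(f"{path}: invalid scenario: {exc}") from exc


def write_report(report: dict[str, Any], path: str | Path | None) -> str:
    """Serialise a report dict to JSON (stdout when path is None)."""
    text = json.dumps(report, indent=2, default=float)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
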