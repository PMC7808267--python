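"""Reading and writing trial data, SIM tables, and reports.

Trial data are wide-format CSV, one row per completed patient, with
columns ``A1, O2, A2, Y`` (``O1`` optional).  Extra columns such as
patient identifiers or sequence labels are ignored with a logged notice;
a missing required column is an error instructing the user to rename the
variables.  SIM tables carry the exact header
``SEQ,A1,PI1,O2,P2,A2,PI2,MEAN,SD``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SIM_COLUMNS, DesignValidationError, SmartDesign

logger = logging.getLogger(__name__)

__all__ = ["read_trial_csv", "read_sim_csv", "write_report_json"]

REQUIRED = ["A1", "O2", "A2", "Y"]
OPTIONAL = ["O1"]


def read_trial_csv(
    path: str | Path,
    design: SmartDesign | None = None,
    family: str = "gaussian",
) -> pd.DataFrame:
    """Load wide-format trial records.

    Returns a data frame with the recognized columns only.  Validates
    that Y is numeric (0/1 for the binomial family) and, when a design is
    supplied, that every treatment/response code appears in it.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DesignValidationError(f"{path}: no records") from None
    if len(raw) == 0:
        raise DesignValidationError(f"{path}: no records")
    missing = [c for c in REQUIRED if c not in raw.columns]
    if missing:
        raise DesignValidationError(
            f"{path}: missing required column(s) {missing}; rename your "
            f"variables to {REQUIRED} (O1 optional)"
        )
    extra = [c for c in raw.columns if c not in REQUIRED + OPTIONAL]
    if extra:
        logger.info("%s: ignoring extra column(s) %s", path, extra)
    keep = [c for c in OPTIONAL if c in raw.columns] + REQUIRED
    data = raw[keep].copy()
    y = pd.to_numeric(data["Y"], errors="coerce")
    if y.isna().any():
        bad = data.index[y.isna()][0]
        raise DesignValidationError(f"{path}: non-numeric Y at row {bad}")
    data["Y"] = y.astype(float)
    for c in ("A1", "O2", "A2"):
        v = pd.to_numeric(data[c], errors="coerce")
        if v.isna().any() or (v % 1 != 0).any():
            raise DesignValidationError(f"{path}: column {c} must be integer codes")
        data[c] = v.astype(int)
    if family == "binomial" and not data["Y"].isin([0.0, 1.0]).all():
        raise DesignValidationError(f"{path}: binomial family requires Y in {{0,1}}")
    if design is not None:
        for a1 in data["A1"].unique():
            if a1 not in design.stage1_arms:
                raise DesignValidationError(f"{path}: unknown stage-1 code {a1}")
        for (a1, o2, a2), _ in data.groupby(["A1", "O2", "A2"]):
            if not (0 <= o2 < design.n_categories(a1)):
                raise DesignValidationError(
                    f"{path}: response category {o2} outside arm {a1}"
                )
            if a2 not in design.options(a1, o2):
                raise DesignValidationError(
                    f"{path}: stage-2 code {a2} not an option in branch ({a1},{o2})"
                )
    return data


def read_sim_csv(path: str | Path) -> pd.DataFrame:
    """Load a sequence information matrix; the header must be exactly
    ``SEQ,A1,PI1,O2,P2,A2,PI2,MEAN,SD``."""
    path = Path(path)
    sim = pd.read_csv(path)
    if list(sim.columns) != SIM_COLUMNS:
        raise DesignValidationError(
            f"{path}: SIM header must be exactly {','.join(SIM_COLUMNS)}"
        )
    return sim


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    return obj


def write_report_json(report: dict, path: str | Path) -> None:
    """Serialize a report dictionary (possibly containing numpy scalars,
    arrays, or data frames) to JSON."""
    Path(path).write_text(json.dumps(_jsonify(report), indent=2) + "\n")
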