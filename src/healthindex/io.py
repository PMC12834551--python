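"""Readers and writers for respondent records, cohorts and results.

Formats: a JSON object (or JSON-lines / a JSON array) per respondent with
profile fields at top level, nested ``family_history`` / ``medical_history``
flag objects and questionnaire answers under ``dass21`` / ``ipaq_sf`` /
``sfffq`` / ``frail``; or a flat CSV dialect with one column per item
(``dass21_q1`` .. ``dass21_q21``, ``ipaq_sf_vigorous_days``, ``sfffq_fruit``,
``frail_fatigue``, ...). Units are fixed (cm, kg, mmHg, mmol/L, %).

In batch mode malformed rows are collected, not fatal: readers return the
parsed records together with (row number, message) pairs for skipped rows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Optional

import numpy as np
import pandas as pd

from .composite import HealthIndexResult, InstrumentResponses
from .config import RiskLevel
from .errors import HealthIndexError, InputValidationError
from .instruments import (
    Dass21Responses,
    FrailResponses,
    IpaqResponses,
    SfffqResponses,
    SFFFQ_COMPONENTS,
)
from .physical import FamilyHistory, MedicalHistory, RespondentProfile

logger = logging.getLogger("healthindex")

_PROFILE_NUMERIC_OPTIONAL = ("waist", "std_drinks_per_week", "sbp", "dbp", "ldl", "fbg", "hba1c")
_PROFILE_BOOLS = (
    "drinks_alcohol",
    "diagnosed_hypertension",
    "diagnosed_dyslipidemia",
    "diagnosed_t2dm",
)
_FH_FLAGS = ("diabetes", "premature_cvd", "familial_hyperlipidemia")
_MH_FLAGS = ("cvd", "cerebrovascular", "cancer", "hypertension", "diabetes", "unsure")
_IPAQ_FIELDS = (
    "vigorous_days",
    "vigorous_min_per_day",
    "moderate_days",
    "moderate_min_per_day",
    "walking_days",
    "walking_min_per_day",
    "sitting_min_per_day",
)
_FRAIL_BOOLS = ("fatigue", "resistance", "ambulation", "weight_loss_over_5pct")


@dataclass(frozen=True)
class RespondentRecord:
    """One parsed respondent: an opaque caller-supplied id plus inputs."""

    record_id: str
    profile: RespondentProfile
    responses: InstrumentResponses


def _as_bool(v: Any) -> bool:
    if isinstance(v, np.generic):
        v = v.item()
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, float)) and v in (0, 1):
        return bool(v)
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("true", "yes", "1"):
            return True
        if s in ("false", "no", "0", ""):
            return False
    raise InputValidationError(f"cannot interpret {v!r} as a boolean")


def _as_opt_float(v: Any) -> Optional[float]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return float(v)


def _as_opt_int(v: Any, name: str) -> int:
    f = float(v)
    if f != int(f):
        raise InputValidationError(f"{name} must be an integer, got {v!r}")
    return int(f)


def profile_from_dict(d: dict[str, Any]) -> RespondentProfile:
    fh = d.get("family_history") or {}
    mh = d.get("medical_history") or {}
    return RespondentProfile(
        age=float(d["age"]),
        sex=str(d["sex"]),
        ethnicity=str(d.get("ethnicity", "")),
        height=float(d["height"]),
        weight=float(d["weight"]),
        waist=_as_opt_float(d.get("waist")),
        smoking=str(d.get("smoking", "never")),
        drinks_alcohol=_as_bool(d.get("drinks_alcohol", False)),
        std_drinks_per_week=_as_opt_float(d.get("std_drinks_per_week")),
        family_history=FamilyHistory(**{k: _as_bool(fh.get(k, False)) for k in _FH_FLAGS}),
        medical_history=MedicalHistory(**{k: _as_bool(mh.get(k, False)) for k in _MH_FLAGS}),
        sbp=_as_opt_float(d.get("sbp")),
        dbp=_as_opt_float(d.get("dbp")),
        diagnosed_hypertension=_as_bool(d.get("diagnosed_hypertension", False)),
        ldl=_as_opt_float(d.get("ldl")),
        diagnosed_dyslipidemia=_as_bool(d.get("diagnosed_dyslipidemia", False)),
        diagnosed_t2dm=_as_bool(d.get("diagnosed_t2dm", False)),
        fbg=_as_opt_float(d.get("fbg")),
        hba1c=_as_opt_float(d.get("hba1c")),
        emr_prefilled=frozenset(d.get("emr_prefilled", ())),
    )


def responses_from_dict(d: dict[str, Any]) -> InstrumentResponses:
    dass = d.get("dass21")
    ipaq = d.get("ipaq_sf")
    sfffq = d.get("sfffq")
    frail = d.get("frail")
    return InstrumentResponses(
        dass21=(
            Dass21Responses(items=tuple(_as_opt_int(x, "dass21 item") for x in (
                dass["items"] if isinstance(dass, dict) else dass
            )))
            if dass is not None
            else None
        ),
        ipaq_sf=(
            IpaqResponses(
                **{
                    k: (_as_opt_int(ipaq.get(k, 0), k) if k.endswith("_days") else float(ipaq.get(k, 0)))
                    for k in _IPAQ_FIELDS
                }
            )
            if ipaq is not None
            else None
        ),
        sfffq=(
            SfffqResponses(**{k: _as_opt_int(sfffq[k], k) for k in SFFFQ_COMPONENTS})
            if sfffq is not None
            else None
        ),
        frail=(
            FrailResponses(
                fatigue=_as_bool(frail["fatigue"]),
                resistance=_as_bool(frail["resistance"]),
                ambulation=_as_bool(frail["ambulation"]),
                illnesses_count=_as_opt_int(frail["illnesses_count"], "illnesses_count"),
                weight_loss_over_5pct=_as_bool(frail["weight_loss_over_5pct"]),
            )
            if frail is not None
            else None
        ),
    )


def record_from_dict(d: dict[str, Any], default_id: str = "") -> RespondentRecord:
    return RespondentRecord(
        record_id=str(d.get("id", default_id)),
        profile=profile_from_dict(d),
        responses=responses_from_dict(d),
    )


def record_to_dict(record: RespondentRecord) -> dict[str, Any]:
    p = record.profile
    d: dict[str, Any] = {"id": record.record_id}
    for name in (
        "age",
        "sex",
        "ethnicity",
        "height",
        "weight",
        "waist",
        "smoking",
        "drinks_alcohol",
        "std_drinks_per_week",
        "sbp",
        "dbp",
        "diagnosed_hypertension",
        "ldl",
        "diagnosed_dyslipidemia",
        "diagnosed_t2dm",
        "fbg",
        "hba1c",
    ):
        d[name] = getattr(p, name)
    d["family_history"] = dataclasses.asdict(p.family_history)
    d["medical_history"] = dataclasses.asdict(p.medical_history)
    d["emr_prefilled"] = sorted(p.emr_prefilled)
    r = record.responses
    if r.dass21 is not None:
        d["dass21"] = {"items": list(r.dass21.items)}
    if r.ipaq_sf is not None:
        d["ipaq_sf"] = {k: getattr(r.ipaq_sf, k) for k in _IPAQ_FIELDS}
    if r.sfffq is not None:
        d["sfffq"] = {k: getattr(r.sfffq, k) for k in SFFFQ_COMPONENTS}
    if r.frail is not None:
        d["frail"] = {
            **{k: getattr(r.frail, k) for k in _FRAIL_BOOLS},
            "illnesses_count": r.frail.illnesses_count,
        }
    return d


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def _row_to_nested(row: dict[str, Any]) -> dict[str, Any]:
    """Lift the flat CSV columns into the nested JSON record shape."""
    d: dict[str, Any] = {}
    for key, value in row.items():
        if value is None or (isinstance(value, float) and pd.isna(value)):
            continue
        if key.startswith("family_history_"):
            d.setdefault("family_history", {})[key[len("family_history_"):]] = value
        elif key.startswith("medical_history_"):
            d.setdefault("medical_history", {})[key[len("medical_history_"):]] = value
        elif key.startswith("dass21_q"):
            d.setdefault("_dass_items", {})[int(key[len("dass21_q"):])] = value
        elif key.startswith("ipaq_sf_"):
            d.setdefault("ipaq_sf", {})[key[len("ipaq_sf_"):]] = value
        elif key.startswith("sfffq_"):
            d.setdefault("sfffq", {})[key[len("sfffq_"):]] = value
        elif key.startswith("frail_"):
            d.setdefault("frail", {})[key[len("frail_"):]] = value
        else:
            d[key] = value
    dass = d.pop("_dass_items", None)
    if dass:
        if set(dass) != set(range(1, 22)):
            raise InputValidationError(
                f"CSV row has dass21 columns {sorted(dass)}; expected q1..q21"
            )
        d["dass21"] = [dass[i] for i in range(1, 22)]
    return d


def read_respondents(
    path: str | Path, fmt: Optional[str] = None
) -> tuple[list[RespondentRecord], list[tuple[int, str]]]:
    """Read respondents from JSON, JSON-lines or CSV.

    Returns ``(records, errors)``: row-level failures are logged and
    collected as (1-based row number, message), never fatal. An unreadable
    file is fatal.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".json": "json", ".jsonl": "jsonl", ".csv": "csv"}.get(path.suffix.lower())
        if fmt is None:
            raise InputValidationError(f"cannot infer format of {path}; pass fmt=")
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputValidationError(f"cannot read {path}: {exc}") from exc

    raw_rows: list[dict[str, Any]]
    if fmt == "json":
        data = json.loads(text)
        raw_rows = data if isinstance(data, list) else [data]
    elif fmt == "jsonl":
        raw_rows = [json.loads(line) for line in text.splitlines() if line.strip()]
    elif fmt == "csv":
        frame = pd.read_csv(path)
        raw_rows = [_safe_nested(rec) for rec in frame.to_dict(orient="records")]
    else:
        raise InputValidationError(f"unknown format {fmt!r} (json | jsonl | csv)")

    records: list[RespondentRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(raw_rows, start=1):
        try:
            if isinstance(row, Exception):
                raise row
            records.append(record_from_dict(row, default_id=f"row{i}"))
        except (HealthIndexError, KeyError, TypeError, ValueError) as exc:
            msg = f"{type(exc).__name__}: {exc}"
            logger.warning("skipping row %d: %s", i, msg)
            errors.append((i, msg))
    return records, errors


def _safe_nested(row: dict[str, Any]):
    try:
        return _row_to_nested(row)
    except HealthIndexError as exc:
        return exc


def write_records(records: Iterable[RespondentRecord], path: str | Path) -> None:
    """Write respondent records as JSON-lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_dict(rec), sort_keys=False) + "\n")


def write_records_csv(records: Iterable[RespondentRecord], path: str | Path) -> None:
    """Flat CSV export of respondent records (one column per item)."""
    rows = []
    for rec in records:
        d = record_to_dict(rec)
        flat: dict[str, Any] = {}
        for k, v in d.items():
            if k in ("family_history", "medical_history", "ipaq_sf", "sfffq", "frail"):
                for kk, vv in v.items():
                    flat[f"{k}_{kk}"] = vv
            elif k == "dass21":
                for j, item in enumerate(v["items"], start=1):
                    flat[f"dass21_q{j}"] = item
            elif k == "emr_prefilled":
                flat[k] = ";".join(v)
            else:
                flat[k] = v
        rows.append(flat)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result serialization (fixed key order for byte-stable output)
# ---------------------------------------------------------------------------


def result_to_dict(result: HealthIndexResult, record_id: str = "") -> dict[str, Any]:
    return {
        "id": record_id,
        "composite": result.composite,
        "composite_rounded": result.composite_rounded,
        "category": result.category.value,
        "domain_scores": {
            d: {
                "raw": s.raw,
                "band": s.band.value,
                "completeness": s.completeness,
            }
            for d, s in result.domain_scores.items()
        },
        "factor_bands": {
            f: (None if rb.missing else rb.band.value) for f, rb in result.factor_bands.items()
        },
        "advice": [
            {
                "factor_id": c.factor_id,
                "band": c.band.value,
                "message_key": c.message_key,
                "message_text": c.message_text,
            }
            for c in result.advice
        ],
        "completeness": result.completeness,
        "config_digest": result.config_digest,
        "package_version": result.package_version,
    }


def write_results(results: Iterable[tuple[str, HealthIndexResult]], path: str | Path) -> None:
    """Write (record_id, result) pairs as JSON-lines with fixed key order."""
    with open(path, "w") as fh:
        for record_id, res in results:
            fh.write(json.dumps(result_to_dict(res, record_id), sort_keys=False) + "\n")
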