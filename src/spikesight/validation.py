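"""Rule-based plausibility checks, cross-session consistency, structured export.

The plausibility layer compares observed cell-type proportions against an
editable reference table of region-specific expected ranges.  The default
table ships with the cortical SST interneuron range (4-9% of neurons,
from transcriptomic surveys).  ``Unknown`` is reported as its own
category: it is excluded from range checking but governed by an excess
threshold, since a large Unknown mass is itself diagnostic.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from spikesight.ephys_features import CELL_TYPE_VOCABULARY
from spikesight.fewshot import ClassificationResult


@dataclass(frozen=True)
class ProportionReference:
    """Expected percentage range of one cell type in one region."""

    region: str
    cell_type: str
    low_pct: float
    high_pct: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.low_pct <= self.high_pct <= 100:
            raise ValueError("need 0 <= low_pct <= high_pct <= 100")


DEFAULT_REFERENCE_TABLE = (
    ProportionReference("cortex", "SST", 4.0, 9.0, "typical cortical SST interneuron fraction (transcriptomic surveys)"),
)


@dataclass
class PlausibilityReport:
    region: str
    observed_pct: dict
    verdicts: dict  # cell_type -> within | below | above | no_reference
    unknown_pct: float
    overall_flag: bool


@dataclass
class SessionAgreement:
    per_type_agreement: dict
    overall_agreement: float
    n_matched_units: int


def compute_type_proportions(labels) -> dict:
    """Percentage of each vocabulary type (including Unknown); sums to 100."""
    labels = list(labels)
    if not labels:
        raise ValueError("no labels")
    n = len(labels)
    return {t: 100.0 * sum(1 for l in labels if l == t) / n for t in CELL_TYPE_VOCABULARY}


def check_plausibility(
    proportions: dict,
    reference=DEFAULT_REFERENCE_TABLE,
    region: str = "cortex",
    unknown_threshold_pct: float = 50.0,
) -> PlausibilityReport:
    """Range-check observed proportions against the reference table.

    Typed verdicts are pure range checks; ``overall_flag`` is raised when
    any typed verdict is out of range or the Unknown fraction exceeds
    ``unknown_threshold_pct``.
    """
    rows = {r.cell_type: r for r in reference if r.region == region}
    if not rows:
        raise ValueError(f"region {region!r} absent from the reference table")
    verdicts = {}
    flag = False
    for cell_type, pct in proportions.items():
        if cell_type == "Unknown":
            continue
        row = rows.get(cell_type)
        if row is None:
            verdicts[cell_type] = "no_reference"
        elif pct < row.low_pct:
            verdicts[cell_type] = "below"
            flag = True
        elif pct > row.high_pct:
            verdicts[cell_type] = "above"
            flag = True
        else:
            verdicts[cell_type] = "within"
    unknown_pct = float(proportions.get("Unknown", 0.0))
    if unknown_pct > unknown_threshold_pct:
        flag = True
    return PlausibilityReport(
        region=region,
        observed_pct=dict(proportions),
        verdicts=verdicts,
        unknown_pct=unknown_pct,
        overall_flag=flag,
    )


def cross_session_agreement(labels_a: dict, labels_b: dict, matched_ids) -> SessionAgreement:
    """Label consistency of matched units across two sessions.

    Per-type agreement is computed over the session-A type assignment:
    of the matched units called type T on session A, the fraction still
    called T on session B.
    """
    matched_ids = list(matched_ids)
    if not matched_ids:
        raise ValueError("no overlap: empty matched unit set")
    for uid in matched_ids:
        if uid not in labels_a or uid not in labels_b:
            raise ValueError(f"unit {uid!r} missing from a session label map")
    per_type_total: dict = {}
    per_type_kept: dict = {}
    n_same = 0
    for uid in matched_ids:
        t = labels_a[uid]
        per_type_total[t] = per_type_total.get(t, 0) + 1
        same = labels_b[uid] == t
        per_type_kept[t] = per_type_kept.get(t, 0) + int(same)
        n_same += int(same)
    return SessionAgreement(
        per_type_agreement={t: per_type_kept[t] / per_type_total[t] for t in per_type_total},
        overall_agreement=n_same / len(matched_ids),
        n_matched_units=len(matched_ids),
    )


def load_reference_table(path: str | Path):
    """Load a reference table from CSV (region, cell_type, low_pct, high_pct, source_note)."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                ProportionReference(
                    row["region"], row["cell_type"],
                    float(row["low_pct"]), float(row["high_pct"]),
                    row.get("source_note", ""),
                )
            )
    return tuple(rows)


def _fmt(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")  # 6 significant digits for diff-stable files
    return x


def export_results(objects, path: str | Path, fmt: str = "json") -> Path:
    """Write report objects to JSON (lossless round trip) or CSV.

    Supported objects: PlausibilityReport, SessionAgreement, and
    ``(unit_id, ClassificationResult)`` tables.  Classification CSV rows
    carry one probability column per vocabulary label in fixed order.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = [_to_payload(obj) for obj in objects]
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path
    if fmt == "csv":
        rows = []
        for obj in objects:
            rows.extend(_to_rows(obj))
        fieldnames = ["unit_id", "predicted_label", "unknown_flag", "tie_flag"] + [
            f"p_{t}" for t in CELL_TYPE_VOCABULARY
        ]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            writer.writerows(rows)
        return path
    raise ValueError("format must be 'json' or 'csv'")


def _to_payload(obj):
    if isinstance(obj, (PlausibilityReport, SessionAgreement)):
        d = asdict(obj)
        d["_kind"] = type(obj).__name__
        return json.loads(json.dumps(d))
    if isinstance(obj, tuple) and len(obj) == 2 and isinstance(obj[1], ClassificationResult):
        uid, res = obj
        return {
            "_kind": "ClassificationResult",
            "unit_id": str(uid),
            "predicted_label": res.predicted_label,
            "probabilities": {k: _fmt(v) for k, v in res.probabilities.items()},
            "unknown_flag": res.unknown_flag,
            "tie_flag": res.tie_flag,
        }
    raise TypeError(f"cannot export object of type {type(obj).__name__}")


def _to_rows(obj):
    if isinstance(obj, tuple) and len(obj) == 2 and isinstance(obj[1], ClassificationResult):
        uid, res = obj
        row = {
            "unit_id": str(uid),
            "predicted_label": res.predicted_label,
            "unknown_flag": int(res.unknown_flag),
            "tie_flag": int(res.tie_flag),
        }
        for t in CELL_TYPE_VOCABULARY:
            row[f"p_{t}"] = _fmt(res.probabilities.get(t, 0.0))
        return [row]
    raise TypeError("CSV export supports (unit_id, ClassificationResult) rows")


def import_results(path: str | Path):
    """Re-import a JSON export written by :func:`export_results`."""
    payload = json.loads(Path(path).read_text())
    out = []
    for item in payload:
        kind = item.pop("_kind")
        if kind == "PlausibilityReport":
            out.append(PlausibilityReport(**item))
        elif kind == "SessionAgreement":
            item["per_type_agreement"] = dict(item["per_type_agreement"])
            out.append(SessionAgreement(**item))
        else:
            out.append(item)
    return out
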