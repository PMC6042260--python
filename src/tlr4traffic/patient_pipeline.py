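"""Patient cohort pipeline: qPCR measurements -> phi -> regime -> prognosis.

Each patient contributes one pre-treatment measurement of *tlr4* mRNA,
supplied in one of three ways (in order of precedence): a model rate phi
directly, a precomputed relative-expression fold change, or raw qPCR cycle
thresholds for the target and reference genes in the patient and a
calibrator sample (standard 2^-ddCt relative quantification).  The mapping
to the model is linear in fold change, anchored at the calibrated baseline
rate: ``phi = phi_baseline * fold_change`` with ``phi_baseline = 1.2``.

Predictions are tallied against recorded outcomes; a ``not_applicable``
prediction (near-baseline phi) never counts as correct for a patient with
a recorded outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .regime_rules import (
    DEFAULT_THRESHOLD,
    DEFAULT_TOL,
    Outcome,
    prognosis,
    regime_from_phi,
)

__all__ = [
    "PatientRecord",
    "CohortResult",
    "CohortError",
    "phi_from_qpcr",
    "classify_cohort",
    "read_cohort",
    "write_result",
    "reference_cohort",
    "PHI_BASELINE",
    "CSV_COLUMNS",
]

PHI_BASELINE = 1.2

OUTCOMES = ("survived", "deceased", "unknown")

CSV_COLUMNS = [
    "patient_id",
    "ct_tlr4",
    "ct_ref",
    "ct_tlr4_cal",
    "ct_ref_cal",
    "fold_change",
    "phi",
    "outcome",
    "pathogen_note",
]

RESULT_COLUMNS = ["patient_id", "phi", "regime", "prediction", "outcome", "agree"]


class CohortError(ValueError):
    """A cohort-level failure; ``errors`` lists per-record messages."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class PatientRecord:
    """One patient's *tlr4* measurement, outcome, and pathogen annotation.

    At least one measurement pathway must be present: ``phi``,
    ``fold_change``, or all four cycle-threshold values (cycles, in
    (0, 50)).  ``pathogen_note`` is carried through for reporting only —
    the pipeline applies no pathogen-specific logic.
    """

    patient_id: str
    ct_tlr4: float | None = None
    ct_ref: float | None = None
    ct_tlr4_cal: float | None = None
    ct_ref_cal: float | None = None
    fold_change: float | None = None
    phi: float | None = None
    outcome: str = "unknown"
    pathogen_note: str = ""

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.outcome not in OUTCOMES:
            raise ValueError(
                f"patient {self.patient_id}: outcome {self.outcome!r} not one of {OUTCOMES}"
            )
        cts = (self.ct_tlr4, self.ct_ref, self.ct_tlr4_cal, self.ct_ref_cal)
        has_ct = all(c is not None for c in cts)
        for c in cts:
            if c is not None and not (0 < c < 50):
                raise ValueError(
                    f"patient {self.patient_id}: Ct value {c} outside (0, 50) cycles"
                )
        if self.fold_change is not None and not (self.fold_change > 0):
            raise ValueError(f"patient {self.patient_id}: fold_change must be > 0")
        if self.phi is not None and not (self.phi > 0):
            raise ValueError(f"patient {self.patient_id}: phi must be > 0")
        if self.phi is None and self.fold_change is None and not has_ct:
            raise ValueError(
                f"patient {self.patient_id}: need phi, fold_change, or all four Ct values"
            )


def phi_from_qpcr(record: PatientRecord, phi_baseline: float = PHI_BASELINE) -> float:
    """Convert a patient's measurement to the model's mRNA-production rate.

    Precedence: an explicit ``phi`` wins; else ``phi_baseline * fold_change``;
    else the ddCt pathway ``phi_baseline * 2^-ddCt`` with
    ``ddCt = (ct_tlr4 - ct_ref) - (ct_tlr4_cal - ct_ref_cal)``.
    Always positive by construction.
    """
    if not (phi_baseline > 0):
        raise ValueError("phi_baseline must be > 0")
    if record.phi is not None:
        return float(record.phi)
    if record.fold_change is not None:
        return phi_baseline * float(record.fold_change)
    cts = (record.ct_tlr4, record.ct_ref, record.ct_tlr4_cal, record.ct_ref_cal)
    if any(c is None for c in cts):
        raise ValueError(
            f"patient {record.patient_id}: no usable measurement "
            "(need phi, fold_change, or all four Ct values)"
        )
    ddct = (record.ct_tlr4 - record.ct_ref) - (record.ct_tlr4_cal - record.ct_ref_cal)
    return phi_baseline * 2.0 ** (-ddct)


@dataclass(frozen=True)
class CohortResult:
    """Per-patient predictions and the agreement tally against outcomes."""

    table: pd.DataFrame  # columns RESULT_COLUMNS, row order = input order
    n_total: int
    n_correct: int
    n_incorrect: int
    disagreeing: tuple[str, ...]
    failed: tuple[str, ...] = ()  # patient_ids whose conversion failed

    def __post_init__(self) -> None:
        known = self.table[self.table["outcome"] != "unknown"]
        if self.n_correct + self.n_incorrect != len(known):
            raise ValueError("agreement tally inconsistent with outcome rows")


def _agrees(prediction: str, outcome: str) -> bool:
    return (prediction == Outcome.SURVIVAL and outcome == "survived") or (
        prediction == Outcome.DEATH and outcome == "deceased"
    )


def classify_cohort(
    records: Sequence[PatientRecord],
    threshold: float = DEFAULT_THRESHOLD,
    tol: float = DEFAULT_TOL,
    phi_baseline: float = PHI_BASELINE,
) -> CohortResult:
    """Run the full pipeline over a cohort and tally outcome agreement.

    Each record is mapped through phi conversion, regime assignment and
    prognosis; rows keep the input order.  Per-record conversion errors
    are collected (the run continues, failing rows are marked); duplicate
    patient_ids or an empty cohort raise immediately.
    """
    if not records:
        raise ValueError("cohort is empty")
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient_ids: {dupes}")

    rows, errors, failed = [], [], []
    for rec in records:
        try:
            phi = phi_from_qpcr(rec, phi_baseline)
            regime = regime_from_phi(phi, threshold, tol)
            pred = prognosis(regime)
            agree = _agrees(pred.prediction, rec.outcome)
            rows.append(
                dict(
                    patient_id=rec.patient_id,
                    phi=phi,
                    regime=regime.label,
                    prediction=pred.prediction,
                    outcome=rec.outcome,
                    agree=agree,
                )
            )
        except ValueError as exc:
            errors.append(f"patient {rec.patient_id}: {exc}")
            failed.append(rec.patient_id)
            rows.append(
                dict(
                    patient_id=rec.patient_id,
                    phi=float("nan"),
                    regime="error",
                    prediction="error",
                    outcome=rec.outcome,
                    agree=False,
                )
            )

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    known = table[table["outcome"] != "unknown"]
    n_correct = int(known["agree"].sum())
    disagreeing = tuple(known.loc[~known["agree"], "patient_id"])
    return CohortResult(
        table=table,
        n_total=len(table),
        n_correct=n_correct,
        n_incorrect=len(known) - n_correct,
        disagreeing=disagreeing,
        failed=tuple(failed),
    )


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

_NUMERIC_COLS = ["ct_tlr4", "ct_ref", "ct_tlr4_cal", "ct_ref_cal", "fold_change", "phi"]


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a patient cohort from CSV (columns as in :data:`CSV_COLUMNS`).

    Empty cells are permitted where the record invariant allows; unknown
    columns are ignored with a warning; a missing ``patient_id`` column,
    unparsable numbers or an unrecognized outcome token raise with the
    offending row number.
    """
    import warnings

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: mandatory column 'patient_id' missing")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)

    records = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # header is line 1
        kwargs: dict = {"patient_id": row["patient_id"].strip()}
        for col in _NUMERIC_COLS:
            raw = row.get(col, "").strip() if col in df.columns else ""
            if raw:
                try:
                    kwargs[col] = float(raw)
                except ValueError:
                    raise ValueError(
                        f"{path} row {rownum}: cannot parse {col}={raw!r} as a number"
                    ) from None
        outcome = (row.get("outcome", "") or "unknown").strip() or "unknown"
        if outcome not in OUTCOMES:
            raise ValueError(
                f"{path} row {rownum}: outcome token {outcome!r} not one of {OUTCOMES}"
            )
        kwargs["outcome"] = outcome
        kwargs["pathogen_note"] = row.get("pathogen_note", "").strip()
        try:
            records.append(PatientRecord(**kwargs))
        except ValueError as exc:
            raise ValueError(f"{path} row {rownum}: {exc}") from None
    return records


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records to CSV; round-trips field-for-field via read_cohort."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                **{
                    c: ("" if getattr(r, c) is None else f"{getattr(r, c):.6g}")
                    for c in _NUMERIC_COLS
                },
                "outcome": r.outcome,
                "pathogen_note": r.pathogen_note,
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def write_result(result: CohortResult, path: str | Path) -> None:
    """Write per-patient results to CSV with 6-significant-digit floats."""
    out = result.table.copy()
    out["phi"] = out["phi"].map(lambda v: f"{v:.6g}")
    out["agree"] = out["agree"].map(lambda b: str(bool(b)).lower())
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# The printed ten-patient cohort
# ---------------------------------------------------------------------------

def reference_cohort() -> list[PatientRecord]:
    """The ten-patient sepsis cohort encoded from its published categories.

    The per-patient supplementary measurements are not machine-available,
    so each patient carries a representative phi for their reported
    attractor category: patients 1, 4, 5 and 8 resolved (fixed-point
    regime, phi < 1.2) and survived; patients 3, 6, 7 and 10 were
    non-resolving (double-attractor regime, phi > 1.2) and died within
    days of ICU admission.  Patient 2 (Candida albicans, a fungal pathogen
    outside the Gram-negative LPS/TLR4 axis) had a resolving-range phi but
    died; patient 9 (culture-negative) measured near-baseline phi, giving
    a not_applicable prediction, but survived.  The pipeline therefore
    disagrees with the recorded outcome for exactly patients 2 and 9.
    """
    mk = PatientRecord
    return [
        mk("1", phi=0.70, outcome="survived", pathogen_note="Gram-negative"),
        mk("2", phi=0.90, outcome="deceased", pathogen_note="fungal (Candida albicans)"),
        mk("3", phi=1.80, outcome="deceased", pathogen_note="Gram-negative"),
        mk("4", phi=0.85, outcome="survived", pathogen_note="Gram-negative"),
        mk("5", phi=0.60, outcome="survived", pathogen_note="Gram-negative"),
        mk("6", phi=2.10, outcome="deceased", pathogen_note="Gram-negative"),
        mk("7", phi=1.60, outcome="deceased", pathogen_note="Gram-negative"),
        mk("8", phi=1.00, outcome="survived", pathogen_note="Gram-negative"),
        mk("9", phi=1.20, outcome="survived", pathogen_note="culture-negative"),
        mk("10", phi=2.50, outcome="deceased", pathogen_note="Gram-negative"),
    ]
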