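"""From an event table to the filtered, truncated co-occurrence tensor.

The observed tensor O holds, at entry (i, j, k), the number of co-occurrences
of diagnosis j and prescription k for patient i within the admission used for
that patient: the product of the within-admission diagnosis count and
prescription count.  A diagnosis recorded once alongside a drug ordered twice
therefore co-occurs twice.  Rare codes are filtered by per-patient prevalence
first, and extreme counts are capped so that frequently re-dosed small-dose
drugs do not dominate the decomposition.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .data import CooccurrenceTensor, EventTable
from .errors import EmptyResultError, ParameterError

log = logging.getLogger(__name__)

AdmissionPolicy = Literal["first", "last", "sum"]


@dataclass
class FilterSpec:
    """Prevalence and exclusion rules applied before tensor construction.

    Defaults mirror an ICU study setup: diagnoses kept when charted for at
    least 5% of patients, prescriptions for at least 10%; ICD-9 supplementary
    'V'/'E' diagnosis codes and trivial base-type fluids excluded.
    """

    diag_min_prevalence: float = 0.05
    rx_min_prevalence: float = 0.10
    excluded_code_prefixes: tuple[str, ...] = ("V", "E")
    excluded_rx_codes: tuple[str, ...] = (
        "0.9% Sodium Chloride",
        "5% Dextrose",
        "Sterile Water",
    )

    def __post_init__(self) -> None:
        for p in (self.diag_min_prevalence, self.rx_min_prevalence):
            if not (0.0 <= p <= 1.0):
                raise ParameterError("prevalence thresholds must lie in [0, 1]")


def filter_codes(events: EventTable, spec: FilterSpec | None = None) -> EventTable:
    """Drop excluded codes and codes below their modality's per-patient
    prevalence threshold.

    Prevalence of a code is the fraction of *distinct patients* (over all
    patients in the table) with at least one event carrying it.  Patients left
    with no events disappear from the event rows but keep their outcome label.
    """
    spec = spec or FilterSpec()
    df = events.events
    n_patients = df["patient_id"].nunique()

    is_dx = df["modality"] == "diagnosis"
    excluded = is_dx & df["code"].str.startswith(tuple(spec.excluded_code_prefixes) or ("\0",))
    excluded |= (~is_dx) & df["code"].isin(spec.excluded_rx_codes)
    df = df[~excluded]

    keep_codes: set[tuple[str, str]] = set()
    for modality, thresh in (
        ("diagnosis", spec.diag_min_prevalence),
        ("prescription", spec.rx_min_prevalence),
    ):
        sub = df[df["modality"] == modality]
        prev = sub.groupby("code")["patient_id"].nunique() / n_patients
        for code, p in prev.items():
            if p >= thresh:
                keep_codes.add((modality, code))

    mask = [
        (m, c) in keep_codes for m, c in zip(df["modality"], df["code"])
    ]
    kept = df[np.asarray(mask, dtype=bool)] if len(df) else df
    if kept.empty:
        raise EmptyResultError(
            f"filtering removed all events ({len(events.events)} in, 0 out; "
            f"{n_patients} patients)"
        )
    dropped = n_patients - kept["patient_id"].nunique()
    if dropped:
        log.info("filter_codes: %d patient(s) left with no events", dropped)
    return EventTable(events=kept.reset_index(drop=True), outcome=dict(events.outcome))


def _pick_admissions(adm_first_ts: pd.Series, policy: AdmissionPolicy) -> list[str]:
    """Order admissions by earliest timestamp (ties: admission id) and select
    per policy."""
    order = sorted(adm_first_ts.index, key=lambda a: (adm_first_ts[a], a))
    if policy == "first":
        return order[:1]
    if policy == "last":
        return order[-1:]
    if policy == "sum":
        return order
    raise ParameterError(f"unknown admission policy {policy!r}")


def count_cooccurrences(
    events: EventTable, admission_policy: AdmissionPolicy = "first"
) -> CooccurrenceTensor:
    """Build the co-occurrence tensor O.

    For each used admission, entry (i, j, k) accumulates
    ``count(diagnosis j) * count(prescription k)`` within that admission.
    ``admission_policy`` selects which admissions count: the chronologically
    first (default, the study's convention for survivors), the last, or the
    sum over all admissions.
    """
    df = events.events
    patients = sorted(df["patient_id"].unique())
    diagnoses = sorted(df.loc[df["modality"] == "diagnosis", "code"].unique())
    prescriptions = sorted(df.loc[df["modality"] == "prescription", "code"].unique())
    p_idx = {p: i for i, p in enumerate(patients)}
    d_idx = {c: j for j, c in enumerate(diagnoses)}
    r_idx = {c: k for k, c in enumerate(prescriptions)}

    entries: Counter[tuple[int, int, int]] = Counter()
    for pid, pat_df in df.groupby("patient_id", sort=False):
        adm_first_ts = pat_df.groupby("admission_id")["timestamp"].min()
        for adm in _pick_admissions(adm_first_ts, admission_policy):
            adm_df = pat_df[pat_df["admission_id"] == adm]
            dx = Counter(adm_df.loc[adm_df["modality"] == "diagnosis", "code"])
            rx = Counter(adm_df.loc[adm_df["modality"] == "prescription", "code"])
            i = p_idx[pid]
            for code_j, n_d in dx.items():
                for code_k, n_r in rx.items():
                    entries[(i, d_idx[code_j], r_idx[code_k])] += n_d * n_r

    coords = np.array(sorted(entries), dtype=np.int64).reshape(-1, 3)
    values = np.array([entries[tuple(c)] for c in coords], dtype=np.int64)
    return CooccurrenceTensor(
        shape=(len(patients), len(diagnoses), len(prescriptions)),
        coords=coords,
        values=values,
        patients=patients,
        diagnoses=diagnoses,
        prescriptions=prescriptions,
    )


def truncate_values(t: CooccurrenceTensor, cap: int | str = 10) -> CooccurrenceTensor:
    """Cap every entry at ``cap``; ``"p99"`` uses the top-1% value of the
    nonzero count distribution (smallest value whose cumulative fraction
    reaches 0.99) as the cap.  Support never changes."""
    if isinstance(cap, str):
        if cap != "p99":
            raise ParameterError(f"cap must be a positive integer or 'p99', got {cap!r}")
        if t.nnz == 0:
            return t
        vals = np.sort(t.values)
        idx = int(np.ceil(0.99 * vals.size)) - 1
        cap_value = int(vals[max(idx, 0)])
    else:
        cap_value = int(cap)
        if cap_value < 1:
            raise ParameterError(f"cap must be >= 1, got {cap_value}")
    return CooccurrenceTensor(
        shape=t.shape,
        coords=t.coords.copy(),
        values=np.minimum(t.values, cap_value),
        patients=list(t.patients),
        diagnoses=list(t.diagnoses),
        prescriptions=list(t.prescriptions),
    )


def build_tensor(
    events: EventTable,
    spec: FilterSpec | None = None,
    cap: int | str = 10,
    admission_policy: AdmissionPolicy = "first",
) -> CooccurrenceTensor:
    """Convenience pipeline: filter -> count -> truncate."""
    return truncate_values(count_cooccurrences(filter_codes(events, spec), admission_policy), cap)
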