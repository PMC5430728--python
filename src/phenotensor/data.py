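"""Shared domain types and plain-text readers/writers.

The on-disk conventions are deliberately boring: CSV for event tables and
outcomes, line-oriented text for the sparse tensor (COO triples) and the
similarity matrices, CSV for phenotype reports.  Outcome labels are stored on
disk as ``died in {0,1}`` (the common clinical-file convention) and mapped to
``y in {-1,+1}`` in memory, which is the encoding the logistic likelihood uses.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, LabelingError, ParameterError, SchemaError

MODALITIES = ("diagnosis", "prescription")

EVENT_COLUMNS = ["patient_id", "admission_id", "timestamp", "code", "modality"]


def _canonical_event_sort(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic event order: admission, then time with ties broken by
    modality (diagnosis before prescription) and code lexicographically."""
    key = df.assign(_m=(df["modality"] != "diagnosis").astype(int))
    key = key.sort_values(
        ["patient_id", "admission_id", "timestamp", "_m", "code"],
        kind="mergesort",
    )
    return key.drop(columns="_m").reset_index(drop=True)


@dataclass
class EventTable:
    """Long-format coded clinical events plus a per-patient binary outcome.

    Parameters
    ----------
    events : DataFrame with columns ``patient_id, admission_id, timestamp,
        code, modality``; modality is ``"diagnosis"`` or ``"prescription"``.
    outcome : mapping ``patient_id -> y`` with ``y = +1`` (died) or ``-1``
        (survived).  Every patient appearing in ``events`` must be labeled.
    """

    events: pd.DataFrame
    outcome: dict[str, int]

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise SchemaError(f"event table missing columns: {missing}")
        self.events = self.events[EVENT_COLUMNS].copy()
        for col in ("patient_id", "admission_id", "code", "modality"):
            self.events[col] = self.events[col].astype(str)
        bad = set(self.events["modality"]) - set(MODALITIES)
        if bad:
            raise SchemaError(f"unknown modality value(s): {sorted(bad)}")
        bad_y = {v for v in self.outcome.values() if v not in (-1, 1)}
        if bad_y:
            raise SchemaError(f"outcome values must be -1/+1, got {sorted(bad_y)}")
        unlabeled = sorted(set(self.events["patient_id"]) - set(self.outcome))
        if unlabeled:
            raise LabelingError(
                f"{len(unlabeled)} patient(s) have events but no outcome label, "
                f"e.g. {unlabeled[:5]}"
            )
        self.events = _canonical_event_sort(self.events)

    @property
    def patients(self) -> list[str]:
        return sorted(set(self.events["patient_id"]))

    def codes(self, modality: str) -> list[str]:
        sub = self.events.loc[self.events["modality"] == modality, "code"]
        return sorted(set(sub))

    def equals(self, other: "EventTable") -> bool:
        return self.events.equals(other.events) and self.outcome == other.outcome


@dataclass
class CooccurrenceTensor:
    """Sparse third-order nonnegative integer tensor O (patients x diagnoses x
    prescriptions) with axis dictionaries.

    ``coords`` is an (nnz, 3) int array of (i, j, k) indices; ``values`` the
    matching positive integer counts.  Duplicate triples are forbidden.
    """

    shape: tuple[int, int, int]
    coords: np.ndarray
    values: np.ndarray
    patients: list[str]
    diagnoses: list[str]
    prescriptions: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=np.int64).reshape(-1)
        if self.coords.shape[0] != self.values.shape[0]:
            raise FormatError("coords/values length mismatch")
        if len(self.patients) != self.shape[0] or len(self.diagnoses) != self.shape[1] \
                or len(self.prescriptions) != self.shape[2]:
            raise FormatError("axis dictionary lengths do not match tensor shape")
        if self.values.size:
            if self.values.min() <= 0:
                raise FormatError("stored tensor values must be positive")
            if self.coords.min() < 0 or (self.coords >= np.array(self.shape)).any():
                raise FormatError("tensor index out of bounds")
            flat = np.ravel_multi_index(self.coords.T, self.shape)
            if np.unique(flat).size != flat.size:
                raise FormatError("duplicate (i,j,k) triples in tensor")
        order = np.lexsort((self.coords[:, 2], self.coords[:, 1], self.coords[:, 0]))
        self.coords = self.coords[order]
        self.values = self.values[order]

    @property
    def nnz(self) -> int:
        return int(self.values.size)

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.shape, dtype=float)
        if self.nnz:
            dense[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = self.values
        return dense

    def equals(self, other: "CooccurrenceTensor") -> bool:
        return (
            self.shape == other.shape
            and np.array_equal(self.coords, other.coords)
            and np.array_equal(self.values, other.values)
            and self.patients == other.patients
            and self.diagnoses == other.diagnoses
            and self.prescriptions == other.prescriptions
        )


@dataclass
class RunConfig:
    """All tunable knobs of the pipeline with the study defaults.

    rank : number of phenotypes R (study default 50; synthetic work uses the
        planted rank).
    omega : weight of the supervised logistic term (default 1; it acts per
        patient row, hence small).
    mu : weight of the similarity / symmetric-NMF term (default 1000; it acts
        on whole factor matrices).
    ridge_c : ridge weight on the logistic parameters theta (unspecified in
        the source method; default 1.0).
    embed_dim, window : code-embedding dimensionality (500) and symmetric
        context window (30).
    cap : co-occurrence truncation cap (default 10 = the study's top-1%
        value).
    tol : convergence threshold on |fit_old - fit| (5e-4).
    eps_a, eps_bc : post-normalization membership thresholds (1e-6 for the
        patient mode, 1e-3 for code modes).
    """

    rank: int = 50
    omega: float = 1.0
    mu: float = 1000.0
    ridge_c: float = 1.0
    embed_dim: int = 500
    window: int = 30
    cap: int = 10
    tol: float = 5e-4
    eps_a: float = 1e-6
    eps_bc: float = 1e-3
    max_iter: int = 200
    min_iter: int = 10
    seed: int = 0
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ParameterError("rank must be >= 1")
        if min(self.omega, self.mu, self.ridge_c) < 0:
            raise ParameterError("omega, mu, ridge_c must be >= 0")
        if self.tol <= 0:
            raise ParameterError("tol must be > 0")
        for eps in (self.eps_a, self.eps_bc):
            if not (0 <= eps < 1):
                raise ParameterError("thresholds must lie in [0, 1)")
        if self.max_iter < 1 or self.cv_folds < 2:
            raise ParameterError("max_iter >= 1 and cv_folds >= 2 required")
        if self.min_iter < 1:
            raise ParameterError("min_iter >= 1 required")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON (by extension)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Event table I/O


def read_event_table(path: str | Path, outcome_path: str | Path) -> EventTable:
    """Read an events CSV (`patient_id,admission_id,timestamp,code,modality`)
    and an outcomes CSV (`patient_id,died` with died in {0,1})."""
    events = pd.read_csv(path, dtype={"patient_id": str, "admission_id": str, "code": str, "modality": str})
    outcomes = pd.read_csv(outcome_path, dtype={"patient_id": str})
    for col in ("patient_id", "died"):
        if col not in outcomes.columns:
            raise SchemaError(f"outcome file missing column {col!r}")
    bad = set(outcomes["died"]) - {0, 1}
    if bad:
        raise SchemaError(f"outcome 'died' must be 0/1, got {sorted(bad)}")
    outcome = {p: (1 if d == 1 else -1) for p, d in zip(outcomes["patient_id"], outcomes["died"])}
    return EventTable(events=events, outcome=outcome)


def write_event_table(table: EventTable, path: str | Path, outcome_path: str | Path) -> None:
    table.events.to_csv(path, index=False)
    rows = sorted(table.outcome.items())
    pd.DataFrame(
        {"patient_id": [p for p, _ in rows], "died": [1 if y == 1 else 0 for _, y in rows]}
    ).to_csv(outcome_path, index=False)


# ---------------------------------------------------------------------------
# Tensor I/O (plain-text COO)

_TENSOR_MAGIC = "%coo-tensor 1"


def write_coo_tensor(t: CooccurrenceTensor, path: str | Path) -> None:
    """Serialize as text: header (shape + axis dictionaries), then one
    ``i j k value`` line per nonzero."""
    lines = [_TENSOR_MAGIC, "%shape " + " ".join(map(str, t.shape))]
    for name, axis in (("patients", t.patients), ("diagnoses", t.diagnoses), ("prescriptions", t.prescriptions)):
        lines.append(f"%{name} " + "\t".join(axis))
    for (i, j, k), v in zip(t.coords, t.values):
        lines.append(f"{i} {j} {k} {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_coo_tensor(path: str | Path) -> CooccurrenceTensor:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _TENSOR_MAGIC:
        raise FormatError(f"{path}: not a coo-tensor file")
    header: dict[str, str] = {}
    body_start = 1
    for n, line in enumerate(lines[1:], start=1):
        if not line.startswith("%"):
            body_start = n
            break
        key, _, rest = line[1:].partition(" ")
        header[key] = rest
        body_start = n + 1
    try:
        shape = tuple(int(x) for x in header["shape"].split())
        axes = {
            name: (header[name].split("\t") if header[name] else [])
            for name in ("patients", "diagnoses", "prescriptions")
        }
    except KeyError as exc:
        raise FormatError(f"{path}: corrupted header (missing {exc})") from exc
    if len(shape) != 3:
        raise FormatError(f"{path}: shape must have 3 entries")
    coords, values = [], []
    for line in lines[body_start:]:
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}: malformed data line {line!r}")
        i, j, k, v = map(int, parts)
        coords.append((i, j, k))
        values.append(v)
    coords_arr = np.array(coords, dtype=np.int64).reshape(-1, 3)
    return CooccurrenceTensor(
        shape=shape,
        coords=coords_arr,
        values=np.array(values, dtype=np.int64),
        patients=axes["patients"],
        diagnoses=axes["diagnoses"],
        prescriptions=axes["prescriptions"],
    )


# ---------------------------------------------------------------------------
# Similarity matrix I/O (symmetric sparse triplets)

_SIM_MAGIC = "%similarity 1"


def write_similarity_matrix(sim, path: str | Path) -> None:
    """Write a SimilarityMatrix as triplet text (upper triangle only)."""
    lines = [
        _SIM_MAGIC,
        f"%mode {sim.mode}",
        f"%n {sim.matrix.shape[0]}",
        f"%normalized_cut_applied {int(sim.normalized_cut_applied)}",
        "%tokens " + "\t".join(sim.tokens),
    ]
    mat = sim.matrix
    r, c = np.nonzero(mat)
    for a, b in zip(r, c):
        if a <= b:
            lines.append(f"{a} {b} {float(mat[a, b])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_similarity_matrix(path: str | Path):
    from .similarity import SimilarityMatrix  # local import: avoid cycle

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _SIM_MAGIC:
        raise FormatError(f"{path}: not a similarity file")
    header: dict[str, str] = {}
    body = []
    for line in lines[1:]:
        if line.startswith("%"):
            key, _, rest = line[1:].partition(" ")
            header[key] = rest
        elif line.strip():
            body.append(line)
    try:
        n = int(header["n"])
        mode = header["mode"]
        nc = bool(int(header["normalized_cut_applied"]))
        tokens = header["tokens"].split("\t") if header["tokens"] else []
    except KeyError as exc:
        raise FormatError(f"{path}: corrupted header (missing {exc})") from exc
    mat = np.zeros((n, n))
    for line in body:
        a_s, b_s, v_s = line.split()
        a, b, v = int(a_s), int(b_s), float(v_s)
        if not (0 <= a < n and 0 <= b < n):
            raise FormatError(f"{path}: index out of bounds in {line!r}")
        mat[a, b] = v
        mat[b, a] = v
    return SimilarityMatrix(mode=mode, matrix=mat, tokens=tokens, normalized_cut_applied=nc)


# ---------------------------------------------------------------------------
# Phenotype report I/O


def write_phenotype_report(report, path: str | Path) -> None:
    """Write a PhenotypeReport as three CSVs under the directory ``path``:
    summary.csv (one row per phenotype), members.csv (ranked member lists) and
    bins.csv (membership-bin mortality table)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    report.summary_frame().to_csv(path / "summary.csv", index=False, float_format="%.17g")
    report.members_frame().to_csv(path / "members.csv", index=False, float_format="%.17g")
    report.bins_frame().to_csv(path / "bins.csv", index=False, float_format="%.17g")


def read_phenotype_report(path: str | Path):
    from .reporting import PhenotypeReport  # local import: avoid cycle

    path = Path(path)
    summary = pd.read_csv(path / "summary.csv")
    members = pd.read_csv(path / "members.csv")
    bins = pd.read_csv(path / "bins.csv")
    return PhenotypeReport.from_frames(summary, members, bins)
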