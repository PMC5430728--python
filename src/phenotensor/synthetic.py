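"""Seeded synthetic-EHR generator with planted phenotype structure.

The generator emulates, at desk scale, the data shape the phenotyping
pipeline consumes: a nonnegative low-rank count tensor (admission-level
diagnosis/prescription co-occurrence), a binary outcome driven by a logistic
model on the planted patient memberships, and time-ordered code sequences
whose windowed co-occurrence reflects the planted block structure.

Default world: 400 patients, 60 diagnosis and 80 prescription codes, 6
planted phenotypes occupying disjoint code blocks, Poisson count noise
(counts are nonnegative integers; Poisson is the standard noise model for
count-valued phenotyping tensors), phenotype magnitudes chosen so most
nonzero counts are small integers — mirroring real co-occurrence data where
most nonzero values are 1 — and an outcome that depends on two of the six
phenotypes with a balanced (half died / half survived) cohort, as in a
case-control ICU mortality design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CooccurrenceTensor, EventTable
from .errors import ParameterError, PhenotensorError
from .similarity import SequenceCorpus, build_sequences

log = logging.getLogger(__name__)


def _even_blocks(n: int, r: int) -> np.ndarray:
    """Assign n codes to r contiguous blocks of (near-)equal size."""
    return np.repeat(np.arange(r), np.diff(np.linspace(0, n, r + 1).astype(int)))


@dataclass
class PlantSpec:
    """Planted world for the synthetic generator.

    I, J, K : axis sizes (patients, diagnoses, prescriptions).
    R_true : planted rank.  Code blocks partition each code axis.
    lam_true : per-phenotype magnitudes; the default 400 yields mean counts
        of order one at the default sizes.
    n_outcome_phenotypes : how many leading phenotypes carry outcome signal
        (alternating sign), used when ``theta_true`` is not given explicitly.
    noise : Poisson sampling of counts when True, deterministic rounding
        otherwise.
    """

    I: int = 400
    J: int = 60
    K: int = 80
    R_true: int = 6
    diag_blocks: np.ndarray | None = None
    rx_blocks: np.ndarray | None = None
    lam_true: np.ndarray | None = None
    theta_true: np.ndarray | None = None
    n_outcome_phenotypes: int = 2
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.R_true < 1 or self.R_true > min(self.J, self.K):
            raise ParameterError("need 1 <= R_true <= min(J, K)")
        if self.diag_blocks is None:
            self.diag_blocks = _even_blocks(self.J, self.R_true)
        if self.rx_blocks is None:
            self.rx_blocks = _even_blocks(self.K, self.R_true)
        self.diag_blocks = np.asarray(self.diag_blocks)
        self.rx_blocks = np.asarray(self.rx_blocks)
        if self.diag_blocks.size != self.J or self.rx_blocks.size != self.K:
            raise ParameterError("block assignments must cover the code axes")
        for blocks in (self.diag_blocks, self.rx_blocks):
            present = set(blocks.tolist())
            if not present <= set(range(self.R_true)):
                raise ParameterError("block labels must be in [0, R_true)")
            if len(present) < self.R_true:
                raise ParameterError("every phenotype needs at least one code per mode")
        if self.lam_true is None:
            self.lam_true = np.full(self.R_true, 400.0)
        self.lam_true = np.asarray(self.lam_true, dtype=float)
        if self.lam_true.size != self.R_true or (self.lam_true < 0).any():
            raise ParameterError("lam_true must be R_true nonnegative magnitudes")


def plant_factors(spec: PlantSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw block-sparse nonnegative ground-truth factors.

    Code memberships within a phenotype's block are uniform(0.5, 1), zero
    elsewhere; patient rows are Dirichlet(0.5) mixtures over phenotypes.
    Columns are rescaled so lambda_r = ||A_:r|| ||B_:r|| ||C_:r|| equals
    ``spec.lam_true[r]``.
    """
    rng = np.random.default_rng(spec.seed)
    a = rng.dirichlet(np.full(spec.R_true, 0.5), size=spec.I)
    b = np.zeros((spec.J, spec.R_true))
    c = np.zeros((spec.K, spec.R_true))
    for r in range(spec.R_true):
        jb = spec.diag_blocks == r
        kb = spec.rx_blocks == r
        b[jb, r] = rng.uniform(0.5, 1.0, size=int(jb.sum()))
        c[kb, r] = rng.uniform(0.5, 1.0, size=int(kb.sum()))
    cur = (
        np.linalg.norm(a, axis=0) * np.linalg.norm(b, axis=0) * np.linalg.norm(c, axis=0)
    )
    if (cur == 0).any():
        raise ParameterError("degenerate planted factor column")
    scale = (spec.lam_true / cur) ** (1.0 / 3.0)
    return a * scale, b * scale, c * scale


def _axis_names(spec_or_shape) -> tuple[list[str], list[str], list[str]]:
    i, j, k = spec_or_shape
    return (
        [f"p{n:04d}" for n in range(i)],
        [f"D{n:03d}" for n in range(j)],
        [f"P{n:03d}" for n in range(k)],
    )


def sample_tensor(
    factors: tuple[np.ndarray, np.ndarray, np.ndarray],
    noise: bool = True,
    seed: int = 0,
) -> CooccurrenceTensor:
    """Counts from the planted mean M = sum_r A_:r o B_:r o C_:r: Poisson(M)
    draws when ``noise``, deterministic rounding otherwise."""
    a, b, c = factors
    mean = np.einsum("ir,jr,kr->ijk", a, b, c)
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(mean)
    else:
        counts = np.round(mean).astype(np.int64)
    coords = np.argwhere(counts > 0)
    values = counts[counts > 0]
    patients, diagnoses, prescriptions = _axis_names(mean.shape)
    return CooccurrenceTensor(
        shape=mean.shape,
        coords=coords,
        values=values,
        patients=patients,
        diagnoses=diagnoses,
        prescriptions=prescriptions,
    )


def sample_outcomes(A_true: np.ndarray, theta_true: np.ndarray, seed: int = 0) -> np.ndarray:
    """Labels y_i in {-1, +1}: +1 with probability sigmoid([A_i:, 1] . theta)."""
    A_true = np.asarray(A_true, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_true.size != A_true.shape[1] + 1:
        raise ParameterError("theta_true must have length R_true + 1 (intercept last)")
    logits = A_true @ theta_true[:-1] + theta_true[-1]
    rng = np.random.default_rng(seed)
    prob = 1.0 / (1.0 + np.exp(-logits))
    return np.where(rng.random(A_true.shape[0]) < prob, 1, -1)


def default_theta_true(A_true: np.ndarray, n_link: int = 2, effect_sd: float = 2.0) -> np.ndarray:
    """Outcome parameters for the planted world: the first ``n_link``
    phenotypes carry alternating-sign effects scaled so each contributes
    logits of standard deviation ``effect_sd`` (a strong but not separable
    signal); the intercept centers the logits, giving the balanced cohort of
    a case-control design."""
    r = A_true.shape[1]
    if not (1 <= n_link <= r):
        raise ParameterError("need 1 <= n_link <= R_true")
    theta = np.zeros(r + 1)
    for m in range(n_link):
        sd = float(np.std(A_true[:, m]))
        if sd == 0:
            raise ParameterError(f"planted memberships for phenotype {m} are constant")
        theta[m] = (1 if m % 2 == 0 else -1) * effect_sd / sd
    theta[-1] = -float(np.mean(A_true @ theta[:-1]))
    return theta


def emit_events(
    t: CooccurrenceTensor,
    labels: np.ndarray,
    seed: int = 0,
    diag_blocks: np.ndarray | None = None,
    rx_blocks: np.ndarray | None = None,
    emission_cap: int = 1000,
) -> tuple[EventTable, SequenceCorpus]:
    """Invert the tensor builder on synthetic data.

    Each nonzero diagnosis row (patient i, diagnosis j) becomes one
    admission holding diagnosis j once plus v_{ijk} copies of each
    prescription k, ordered so codes of the same planted block sit adjacent
    in time (windowed co-occurrence then carries the block structure).
    Rebuilding the tensor with ``admission_policy="sum"`` reproduces t
    exactly, since every diagnosis appears exactly once per admission.
    """
    labels = np.asarray(labels)
    if labels.size != t.shape[0]:
        raise ParameterError("labels length must equal patient count")
    if t.nnz and t.values.max() > emission_cap:
        raise PhenotensorError(
            f"tensor value {t.values.max()} exceeds emission cap {emission_cap}"
        )
    diag_blocks = (
        np.asarray(diag_blocks) if diag_blocks is not None else np.zeros(t.shape[1], dtype=int)
    )
    rx_blocks = (
        np.asarray(rx_blocks) if rx_blocks is not None else np.zeros(t.shape[2], dtype=int)
    )

    rows: list[tuple[str, str, int, str, str]] = []
    # group nonzeros by (patient, diagnosis)
    by_admission: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for (i, j, k), v in zip(t.coords, t.values):
        by_admission.setdefault((int(i), int(j)), []).append((int(k), int(v)))
    for (i, j), rx_list in sorted(by_admission.items()):
        pid = t.patients[i]
        adm = f"{pid}-a{j:03d}"
        block_j = int(diag_blocks[j])
        # same-block prescriptions first (adjacent to the diagnosis), then the
        # rest ordered by block so each block's codes are contiguous in time
        rx_sorted = sorted(
            rx_list, key=lambda kv: (int(rx_blocks[kv[0]]) != block_j, int(rx_blocks[kv[0]]), kv[0])
        )
        ts = 0
        rows.append((pid, adm, ts, t.diagnoses[j], "diagnosis"))
        for k, v in rx_sorted:
            for _ in range(v):
                ts += 1
                rows.append((pid, adm, ts, t.prescriptions[k], "prescription"))
    events = pd.DataFrame(
        rows, columns=["patient_id", "admission_id", "timestamp", "code", "modality"]
    )
    outcome = {t.patients[i]: int(labels[i]) for i in range(t.shape[0])}
    table = EventTable(events=events, outcome=outcome)
    return table, build_sequences(table)


def simulate(spec: PlantSpec | None = None, seed: int | None = None) -> dict:
    """Generate one complete synthetic world.

    Returns a dict with the planted factors and parameters, the sampled
    tensor and outcome labels, and the emitted event table / sequence corpus.
    """
    spec = spec or PlantSpec()
    if seed is not None:
        spec = PlantSpec(
            I=spec.I, J=spec.J, K=spec.K, R_true=spec.R_true,
            diag_blocks=spec.diag_blocks, rx_blocks=spec.rx_blocks,
            lam_true=spec.lam_true, theta_true=spec.theta_true,
            n_outcome_phenotypes=spec.n_outcome_phenotypes, noise=spec.noise, seed=seed,
        )
    factors = plant_factors(spec)
    a_true, b_true, c_true = factors
    theta_true = (
        np.asarray(spec.theta_true, dtype=float)
        if spec.theta_true is not None
        else default_theta_true(a_true, spec.n_outcome_phenotypes)
    )
    tensor = sample_tensor(factors, noise=spec.noise, seed=spec.seed + 1)
    labels = sample_outcomes(a_true, theta_true, seed=spec.seed + 2)
    events, corpus = emit_events(
        tensor, labels, seed=spec.seed + 3,
        diag_blocks=spec.diag_blocks, rx_blocks=spec.rx_blocks,
    )
    return {
        "spec": spec,
        "A_true": a_true,
        "B_true": b_true,
        "C_true": c_true,
        "theta_true": theta_true,
        "tensor": tensor,
        "labels": labels,
        "events": events,
        "corpus": corpus,
    }
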