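"""Post-hoc phenotype selection, categorization and report tables.

After fitting, phenotypes are screened by forward stepwise logistic
regression on the patient memberships (entry when the Wald p-value of the
added feature is below 0.05, greedy on deviance), the survivors are
categorized into frequency/risk quadrants, and each phenotype gets a
membership-bin mortality table showing how the death rate moves with
membership strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import _penalized_logistic
from .errors import DegenerateLabelsError, ParameterError

log = logging.getLogger(__name__)

QUADRANTS = ("common-high", "common-low", "rare-high", "rare-low")


@dataclass
class SelectionResult:
    """Forward-selection outcome: phenotype indices in entry order with final
    refit coefficients and Wald p-values; ``intercept`` from the same refit."""

    order: list[int]
    coefficients: dict[int, float]
    p_values: dict[int, float]
    intercept: float
    ridge_fallback: bool = False

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phenotype": self.order,
                "coefficient": [self.coefficients[i] for i in self.order],
                "p_value": [self.p_values[i] for i in self.order],
            }
        )


def _logistic_with_stats(X: np.ndarray, y: np.ndarray, c: float = 0.0):
    """Fit (optionally ridge-penalized) logistic regression and return
    coefficients, Wald p-values, deviance and a separation flag.

    Separation-induced runaway coefficients (|coef| beyond 1e3) trigger a
    small-ridge refit (c = 1e-4) so reported coefficients stay finite.
    """
    design = np.hstack([X, np.ones((X.shape[0], 1))])
    theta, hess = _penalized_logistic(design, y, c)
    fallback = False
    deviance0 = 2.0 * float(np.sum(np.logaddexp(0.0, -y * (design @ theta))))
    separated = (
        not np.all(np.isfinite(theta))
        or np.max(np.abs(theta)) > 100.0
        or deviance0 < 1e-6 * y.size  # perfectly fitted: coefficients unbounded
    )
    if c == 0 and separated:
        log.info("separation detected; refitting with ridge c=1e-4")
        theta, hess = _penalized_logistic(design, y, 1e-4)
        fallback = True
    cov = np.linalg.inv(hess + 1e-12 * np.eye(hess.shape[0]))
    se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    z = theta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    deviance = 2.0 * float(np.sum(np.logaddexp(0.0, -y * (design @ theta))))
    return theta, p, deviance, fallback


def forward_select_phenotypes(
    A_bar: np.ndarray, y: np.ndarray, alpha: float = 0.05, max_features: int | None = None
) -> SelectionResult:
    """Forward stepwise logistic regression on membership columns.

    Starting from the intercept-only model, each step adds the candidate that
    minimizes the deviance of the augmented model, provided its Wald p-value
    in that model is below ``alpha``; selection stops when no candidate
    qualifies.  Coefficients and p-values come from the final refit.
    """
    A_bar = np.asarray(A_bar, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("forward selection requires both outcome classes")
    n, r = A_bar.shape
    limit = max_features if max_features is not None else r
    selected: list[int] = []
    remaining = list(range(r))
    while remaining and len(selected) < limit:
        best = None
        for cand in remaining:
            cols = selected + [cand]
            _, p, dev, _ = _logistic_with_stats(A_bar[:, cols], y)
            p_cand = p[len(cols) - 1]  # the newly added column
            if p_cand < alpha and (best is None or dev < best[1]):
                best = (cand, dev)
        if best is None:
            break
        selected.append(best[0])
        remaining.remove(best[0])
    if not selected:
        return SelectionResult(order=[], coefficients={}, p_values={}, intercept=0.0)
    theta, p, _, fallback = _logistic_with_stats(A_bar[:, selected], y)
    return SelectionResult(
        order=selected,
        coefficients={idx: float(theta[pos]) for pos, idx in enumerate(selected)},
        p_values={idx: float(p[pos]) for pos, idx in enumerate(selected)},
        intercept=float(theta[-1]),
        ridge_fallback=fallback,
    )


def representative_phenotypes(selection: SelectionResult, coef_threshold: float = 20.0) -> list[int]:
    """Phenotypes whose selection coefficient is large in magnitude
    (|coefficient| > threshold): the ones that actually move the risk."""
    return [i for i in selection.order if abs(selection.coefficients[i]) > coef_threshold]


def phenotype_quadrants(
    lam: np.ndarray | dict[int, float],
    prev: np.ndarray | dict[int, float],
    coefficients: dict[int, float],
) -> dict[int, str]:
    """Frequency/risk quadrants over the *selected* phenotypes.

    "Common" marks the top five by lambda (ties broken by prevalence, then by
    index for determinism); the rest are "rare".  Positive coefficient means
    high risk, negative low risk.
    """
    ids = sorted(coefficients)
    lam_of = (lambda i: lam[i]) if not isinstance(lam, dict) else lam.__getitem__
    prev_of = (lambda i: prev[i]) if not isinstance(prev, dict) else prev.__getitem__
    ranked = sorted(ids, key=lambda i: (-lam_of(i), -prev_of(i), i))
    common = set(ranked[:5])
    out = {}
    for i in ids:
        freq = "common" if i in common else "rare"
        risk = "high" if coefficients[i] > 0 else "low"
        out[i] = f"{freq}-{risk}"
    return out


def mortality_by_membership_bin(
    memberships: np.ndarray,
    y: np.ndarray,
    bin_width: float = 0.1,
    min_count: int = 10,
) -> pd.DataFrame:
    """Death rate by membership decile for one phenotype.

    Bins partition [0, 1) into width-``bin_width`` intervals (a membership of
    exactly 1 falls in the last bin); bins holding fewer than ``min_count``
    patients report NaN mortality.
    """
    memberships = np.asarray(memberships, dtype=float)
    y = np.asarray(y)
    if memberships.min() < 0 or memberships.max() > 1:
        raise ParameterError("memberships must lie in [0, 1]")
    n_bins = int(round(1.0 / bin_width))
    idx = np.minimum((memberships / bin_width).astype(int), n_bins - 1)
    rows = []
    for m in range(n_bins):
        in_bin = idx == m
        count = int(in_bin.sum())
        mort = float(np.mean(y[in_bin] == 1)) if count >= min_count else np.nan
        rows.append(
            {"bin_lo": m * bin_width, "bin_hi": (m + 1) * bin_width, "count": count, "mortality": mort}
        )
    return pd.DataFrame(rows)


def prevalence(memberships: np.ndarray) -> float:
    """Percent of patients with nonzero membership to the phenotype."""
    memberships = np.asarray(memberships)
    return float(100.0 * np.count_nonzero(memberships) / memberships.size)


@dataclass
class PhenotypeReport:
    """Tables describing the fitted phenotypes.

    summary : one row per phenotype (id, lambda, prevalence, coefficient,
        p-value, selected/representative flags, quadrant).
    members : ranked (phenotype, mode, code, membership) rows.
    bins : membership-bin mortality rows per selected phenotype.
    """

    summary: pd.DataFrame
    members: pd.DataFrame
    bins: pd.DataFrame

    def summary_frame(self) -> pd.DataFrame:
        return self.summary

    def members_frame(self) -> pd.DataFrame:
        return self.members

    def bins_frame(self) -> pd.DataFrame:
        return self.bins

    @classmethod
    def from_frames(cls, summary: pd.DataFrame, members: pd.DataFrame, bins: pd.DataFrame):
        summary = summary.copy()
        if "quadrant" in summary.columns:
            summary["quadrant"] = summary["quadrant"].fillna("")
        if "code" in members.columns:
            members = members.astype({"code": str}) if len(members) else members
        return cls(summary=summary, members=members, bins=bins)


def build_report(
    model,
    y: np.ndarray,
    diagnoses: list[str] | None = None,
    prescriptions: list[str] | None = None,
    coef_threshold: float = 20.0,
    alpha: float = 0.05,
    min_count: int = 10,
    top_members: int = 15,
) -> PhenotypeReport:
    """Assemble the full phenotype report from a fitted model and outcomes."""
    if model.A_bar is None:
        raise ParameterError("build_report requires a normalized, thresholded model")
    r = model.rank
    diagnoses = diagnoses or [f"D{j}" for j in range(model.B_bar.shape[0])]
    prescriptions = prescriptions or [f"P{k}" for k in range(model.C_bar.shape[0])]

    selection = forward_select_phenotypes(model.A_bar, y, alpha=alpha)
    rep = set(representative_phenotypes(selection, coef_threshold))
    prev = {i: prevalence(model.A_bar[:, i]) for i in range(r)}
    quad = phenotype_quadrants(
        {i: float(model.lam[i]) for i in selection.order},
        {i: prev[i] for i in selection.order},
        selection.coefficients,
    )

    summary = pd.DataFrame(
        {
            "phenotype": np.arange(r),
            "lam": model.lam,
            "prevalence": [prev[i] for i in range(r)],
            "coefficient": [selection.coefficients.get(i, np.nan) for i in range(r)],
            "p_value": [selection.p_values.get(i, np.nan) for i in range(r)],
            "selected": [i in selection.coefficients for i in range(r)],
            "representative": [i in rep for i in range(r)],
            "quadrant": [quad.get(i, "") for i in range(r)],
        }
    )

    member_rows = []
    for i in range(r):
        for mode, codes, mat in (
            ("diagnosis", diagnoses, model.B_bar),
            ("prescription", prescriptions, model.C_bar),
        ):
            col = mat[:, i]
            order = np.argsort(-col)
            for pos in order[:top_members]:
                if col[pos] <= 0:
                    break
                member_rows.append(
                    {"phenotype": i, "mode": mode, "code": codes[pos], "membership": float(col[pos])}
                )
    members = pd.DataFrame(member_rows, columns=["phenotype", "mode", "code", "membership"])

    bin_rows = []
    for i in selection.order:
        tab = mortality_by_membership_bin(model.A_bar[:, i], y, min_count=min_count)
        tab.insert(0, "phenotype", i)
        bin_rows.append(tab)
    bins = (
        pd.concat(bin_rows, ignore_index=True)
        if bin_rows
        else pd.DataFrame(columns=["phenotype", "bin_lo", "bin_hi", "count", "mortality"])
    )
    return PhenotypeReport(summary=summary, members=members, bins=bins)
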