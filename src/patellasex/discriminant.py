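"""Two-group linear discriminant analysis for osteometric sex estimation.

Implements the classical forensic-anthropology workflow: fit a linear
discriminant function y = w'x + c on male/female measurement groups with the
coefficients scaled so the pooled within-group variance of the score is 1
(the "unstandardized canonical discriminant function" convention of the
major statistics packages), place the sectioning point at 0 (the midpoint of
the group centroids under equal priors), classify by the sign of the score,
validate by leave-one-out refitting, and select variables stepwise by
Wilks' lambda with F-to-enter / F-to-remove thresholds.

Under this scaling a univariate function has coefficient 1/s_pooled and
constant -(mean_M + mean_F) / (2 s_pooled), which is what makes published
discriminant equations recomputable from printed group means and SDs alone.

The module also carries a registry of the published pooled South African
patella discriminant functions (six univariate, one stepwise, five direct
multivariate) so they can be applied to new cases as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import VARIABLES


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled within-group covariance is singular; remove collinear variables."""


@dataclass
class DiscriminantFunction:
    """A fitted or published linear discriminant function.

    ``score = sum(coefficients * x) + constant``; score > 0 classifies male,
    score < 0 female, with the sectioning point fixed at 0. Centroids are the
    mean scores of each sex group (unknown for published functions).
    """

    variables: tuple[str, ...]
    coefficients: np.ndarray
    constant: float
    centroid_male: float | None = None
    centroid_female: float | None = None
    sectioning_point: float = 0.0
    provenance: str = "fitted"
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.coefficients = np.asarray(self.coefficients, dtype=float)

    def score(self, record) -> float:
        """Discriminant score of one record (mapping or Series)."""
        missing = [v for v in self.variables if v not in record or pd.isna(record[v])]
        if missing:
            raise KeyError(f"record is missing required variable(s): {missing}")
        x = np.array([float(record[v]) for v in self.variables])
        return float(self.coefficients @ x + self.constant)


@dataclass
class Classification:
    score: float
    sex: str
    on_boundary: bool = False


@dataclass
class AccuracyReport:
    """Per-sex and average correct-classification rates, in percent."""

    male_pct: float
    female_pct: float
    average_pct: float
    variant: str  # "O" (original/resubstitution) or "C" (cross-validated)


@dataclass
class StepwiseStep:
    action: str  # "enter" | "remove"
    variable: str
    wilks_lambda: float
    f_statistic: float


@dataclass
class StepwiseTrace:
    entered: list[str]
    steps: list[StepwiseStep] = field(default_factory=list)


def _group_matrices(table: pd.DataFrame, variables: tuple[str, ...]):
    data = table[list(variables) + ["sex"]].dropna()
    Xm = data.loc[data["sex"] == "M", list(variables)].to_numpy(dtype=float)
    Xf = data.loc[data["sex"] == "F", list(variables)].to_numpy(dtype=float)
    if len(Xm) < 2 or len(Xf) < 2:
        raise ValueError("need at least 2 complete rows per sex")
    return Xm, Xf


def _pooled_cov(Xm: np.ndarray, Xf: np.ndarray) -> np.ndarray:
    # pooled within-group covariance, denominator N - 2
    n = len(Xm) + len(Xf)
    ss = np.zeros((Xm.shape[1], Xm.shape[1]))
    for X in (Xm, Xf):
        d = X - X.mean(axis=0)
        ss += d.T @ d
    return ss / (n - 2)


def fit_lda(
    table: pd.DataFrame,
    variables: tuple[str, ...] | list[str],
) -> DiscriminantFunction:
    """Fit the two-group discriminant function on a measurement table.

    w is proportional to S_pooled^-1 (mu_M - mu_F), rescaled so that
    w' S_pooled w = 1 with the male centroid positive; the constant centres
    the centroid midpoint at 0, making 0 the sectioning point.

    Raises
    ------
    SingularCovarianceError
        If the pooled within-group covariance cannot be inverted.
    ValueError
        If a sex group has fewer than 2 complete rows.
    """
    variables = tuple(variables)
    if len(variables) == 0:
        raise ValueError("need at least one variable")
    Xm, Xf = _group_matrices(table, variables)
    mu_m, mu_f = Xm.mean(axis=0), Xf.mean(axis=0)
    S = _pooled_cov(Xm, Xf)
    delta = mu_m - mu_f
    degenerate = bool(np.allclose(delta, 0.0))
    direction = delta if not degenerate else np.eye(len(variables))[0]
    try:
        w0 = np.linalg.solve(S, direction)
    except np.linalg.LinAlgError as err:
        raise SingularCovarianceError(
            f"pooled covariance of {variables} is singular; "
            "remove collinear or constant variables"
        ) from err
    scale = float(w0 @ S @ w0)
    if scale <= 0 or not np.isfinite(scale):
        raise SingularCovarianceError(
            f"pooled covariance of {variables} is numerically singular"
        )
    w = w0 / np.sqrt(scale)
    constant = float(-w @ (mu_m + mu_f) / 2.0)
    cm = float(w @ mu_m + constant)
    cf = float(w @ mu_f + constant)
    if cm < cf:  # enforce male-positive orientation
        w, constant, cm, cf = -w, -constant, -cm, -cf
    return DiscriminantFunction(
        variables=variables,
        coefficients=w,
        constant=constant,
        centroid_male=cm,
        centroid_female=cf,
        provenance="fitted",
        degenerate=degenerate,
    )


def classify(df: DiscriminantFunction, record) -> Classification:
    """Classify one record: positive score → male, negative → female.

    A score of exactly 0 sits on the sectioning point; it is assigned female
    and flagged ``on_boundary`` (a deterministic convention for a
    measure-zero event).
    """
    s = df.score(record)
    if s > 0:
        return Classification(s, "M")
    if s < 0:
        return Classification(s, "F")
    return Classification(s, "F", on_boundary=True)


def classify_table(df: DiscriminantFunction, table: pd.DataFrame) -> pd.DataFrame:
    """Score and classify every row; returns columns ``score`` and ``predicted_sex``."""
    out = table.copy()
    results = [classify(df, row) for _, row in table.iterrows()]
    out["score"] = [r.score for r in results]
    out["predicted_sex"] = [r.sex for r in results]
    return out


def _rates(true_sex: np.ndarray, pred_sex: np.ndarray, variant: str) -> AccuracyReport:
    male = true_sex == "M"
    female = true_sex == "F"
    m_pct = 100.0 * np.mean(pred_sex[male] == "M") if male.any() else float("nan")
    f_pct = 100.0 * np.mean(pred_sex[female] == "F") if female.any() else float("nan")
    return AccuracyReport(
        male_pct=float(m_pct),
        female_pct=float(f_pct),
        average_pct=float((m_pct + f_pct) / 2.0),
        variant=variant,
    )


def loocv(
    table: pd.DataFrame, variables: tuple[str, ...] | list[str]
) -> tuple[AccuracyReport, AccuracyReport]:
    """Resubstitution (O) and leave-one-out cross-validated (C) accuracy.

    The O rates apply the full-sample fit back to the sample. The C rates
    refit the discriminant n times, each time classifying only the excluded
    case — a full honest refit of means and pooled covariance per iteration.
    Average accuracy is the unweighted mean of the two sex-specific rates.
    """
    variables = tuple(variables)
    data = table[list(variables) + ["sex"]].dropna().reset_index(drop=True)
    full = fit_lda(data, variables)
    true_sex = data["sex"].to_numpy()
    pred_o = np.array([classify(full, row).sex for _, row in data.iterrows()])
    report_o = _rates(true_sex, pred_o, "O")

    pred_c = []
    for i in range(len(data)):
        rest = data.drop(index=i)
        fn = fit_lda(rest, variables)
        pred_c.append(classify(fn, data.iloc[i]).sex)
    report_c = _rates(true_sex, np.array(pred_c), "C")
    return report_o, report_c


# ---------------------------------------------------------------------------
# stepwise selection by Wilks' lambda


def _wilks_lambda(Xm: np.ndarray, Xf: np.ndarray, idx: list[int]) -> float:
    if not idx:
        return 1.0
    Wm = Xm[:, idx]
    Wf = Xf[:, idx]
    within = np.zeros((len(idx), len(idx)))
    for X in (Wm, Wf):
        d = X - X.mean(axis=0)
        within += d.T @ d
    allx = np.vstack([Wm, Wf])
    d = allx - allx.mean(axis=0)
    total = d.T @ d
    det_t = np.linalg.det(total)
    if det_t <= 0:
        return float("nan")
    return float(np.linalg.det(within) / det_t)


def stepwise_select(
    table: pd.DataFrame,
    candidates: tuple[str, ...] | list[str] = VARIABLES,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    max_steps: int = 100,
) -> StepwiseTrace:
    """Greedy Wilks'-lambda stepwise variable selection for the two-group LDA.

    At each step the candidate whose entry minimizes the lambda is entered if
    its partial F-to-enter is at least ``f_enter``; entered variables whose
    F-to-remove falls below ``f_remove`` are removed; iterated to a fixpoint.
    For two groups the partial F at current model size p is
    ``(n - 2 - p) * (lambda_small / lambda_large - 1)``.

    An empty trace (no variable passes entry) is a valid outcome.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate variables")
    Xm, Xf = _group_matrices(table, tuple(candidates))
    n = len(Xm) + len(Xf)
    entered: list[int] = []
    steps: list[StepwiseStep] = []

    for _ in range(max_steps):
        changed = False
        # entry phase
        lam_now = _wilks_lambda(Xm, Xf, entered)
        best = None
        for j in range(len(candidates)):
            if j in entered:
                continue
            lam_new = _wilks_lambda(Xm, Xf, entered + [j])
            if not np.isfinite(lam_new) or lam_new <= 0:
                continue
            f = (n - 2 - len(entered)) * (lam_now / lam_new - 1.0)
            if best is None or lam_new < best[1]:
                best = (j, lam_new, f)
        if best is not None and best[2] >= f_enter:
            entered.append(best[0])
            steps.append(
                StepwiseStep("enter", candidates[best[0]], best[1], best[2])
            )
            changed = True
        # removal phase
        while len(entered) > 1:
            lam_full = _wilks_lambda(Xm, Xf, entered)
            worst = None
            for j in entered:
                reduced = [k for k in entered if k != j]
                lam_red = _wilks_lambda(Xm, Xf, reduced)
                f = (n - 2 - len(reduced)) * (lam_red / lam_full - 1.0)
                if worst is None or f < worst[1]:
                    worst = (j, f, lam_red)
            if worst is not None and worst[1] < f_remove:
                entered.remove(worst[0])
                steps.append(
                    StepwiseStep("remove", candidates[worst[0]], worst[2], worst[1])
                )
                changed = True
            else:
                break
        if not changed:
            break
    return StepwiseTrace(entered=[candidates[j] for j in entered], steps=steps)


# ---------------------------------------------------------------------------
# published discriminant functions (pooled South African patella sample)


def _published(pid: str, coeffs: dict[str, float], constant: float) -> DiscriminantFunction:
    return DiscriminantFunction(
        variables=tuple(coeffs),
        coefficients=np.array(list(coeffs.values())),
        constant=constant,
        provenance=pid,
    )


_PUBLISHED: dict[str, DiscriminantFunction] = {
    # univariate functions
    "maxh": _published("published:univariate", {"maxh": 0.336}, -13.320),
    "maxb": _published("published:univariate", {"maxb": 0.307}, -12.675),
    "maxt": _published("published:univariate", {"maxt": 0.593}, -11.420),
    "mafb": _published("published:univariate", {"mafb": 0.471}, -8.749),
    "haf": _published("published:univariate", {"haf": 0.368}, -10.602),
    "lafb": _published("published:univariate", {"lafb": 0.377}, -9.374),
    # stepwise-selected function
    "stepwise": _published(
        "published:stepwise",
        {"maxh": 0.163, "maxb": 0.09, "maxt": 0.144, "haf": 0.099},
        -15.860,
    ),
    # direct multivariate functions
    "D1": _published("published:direct", {"maxh": 0.213, "maxb": 0.146}, -14.476),
    "D2": _published(
        "published:direct", {"maxh": 0.188, "maxb": 0.110, "maxt": 0.149}, -14.849
    ),
    "D3": _published(
        "published:direct",
        {
            "lafb": -0.021,
            "maxb": 0.087,
            "maxh": 0.158,
            "maxt": 0.136,
            "haf": 0.097,
            "mafb": 0.066,
        },
        -15.969,
    ),
    "D4": _published("published:direct", {"maxh": 0.248, "maxt": 0.233}, -14.322),
    "D5": _published("published:direct", {"maxh": 0.294, "lafb": 0.076}, -13.568),
}


def published_equations() -> dict[str, DiscriminantFunction]:
    """Registry of the published pooled discriminant functions.

    Keys: the six measurement names (univariate functions), ``stepwise``, and
    ``D1``–``D5`` (direct multivariate functions). Coefficients and constants
    are the printed values; apply with :func:`classify`.
    """
    return dict(_PUBLISHED)
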