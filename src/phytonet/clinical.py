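"""Postprandial clinical-marker derivation for the four-arm crossover trial.

Each subject's 0/3/6-h time series is normalized to its own t = 0
baseline, summarized as a trapezoidal AUC, and arms are compared with a
repeated-measures one-way ANOVA whose p-value comes from a within-subject
permutation of arm labels (the parametric F is reported alongside).
qPCR expression uses the comparative-Ct method (2^-ddCt against a
reference gene and control condition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARMS = ("placebo", "dose300", "dose600", "dose900")

CLINICAL_COLUMNS = ("subject", "arm", "marker", "time_h", "value")


@dataclass
class MarkerResponse:
    subject: str
    arm: str
    marker: str
    times: np.ndarray
    values: np.ndarray
    normalized: np.ndarray
    auc: float


@dataclass
class ArmComparison:
    marker: str
    arms: list[str]
    means: dict[str, float]
    sems: dict[str, float]
    f_statistic: float
    p_permutation: float
    n_subjects: int
    n_permutations: int
    letters: dict[str, str] = field(default_factory=dict)


def baseline_normalize(values, mode: str = "ratio") -> np.ndarray:
    """Normalize a time series to its first (t = 0) value.

    ``ratio`` divides by baseline (default; the series then starts at 1);
    ``difference`` subtracts it (starts at 0).  A zero baseline in ratio
    mode raises so the caller can exclude the subject with a log entry.
    """
    v = np.asarray(values, dtype=float)
    if mode == "ratio":
        if v[0] == 0:
            raise ZeroDivisionError("zero t=0 baseline in ratio mode")
        return v / v[0]
    if mode == "difference":
        return v - v[0]
    raise ValueError(f"unknown normalization mode {mode!r}")


def trapezoid_auc(times, values) -> float:
    """Trapezoidal area under the curve over the actual time spacing."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def marker_responses(
    table: pd.DataFrame,
    normalization: str = "ratio",
    incremental: bool = False,
) -> list[MarkerResponse]:
    """Per-(subject, arm, marker) normalized series and AUC from a long table.

    ``incremental`` subtracts the baseline level of the *normalized* series
    before integrating (area above baseline rather than total area).
    Subjects with a zero baseline in ratio mode are excluded with a log
    entry rather than poisoning the whole run.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clinical table missing column(s) {missing}")
    out: list[MarkerResponse] = []
    for (subject, arm, marker), grp in table.groupby(
        ["subject", "arm", "marker"], sort=True
    ):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(dtype=float)
        values = grp["value"].to_numpy(dtype=float)
        if times[0] != 0:
            raise ValueError(
                f"{subject}/{arm}/{marker}: first sampling time must be 0 h"
            )
        try:
            norm = baseline_normalize(values, mode=normalization)
        except ZeroDivisionError:
            logger.warning(
                "excluding %s/%s/%s: zero baseline in ratio mode", subject, arm, marker
            )
            continue
        integrand = norm - norm[0] if incremental else norm
        out.append(
            MarkerResponse(
                subject=str(subject),
                arm=str(arm),
                marker=str(marker),
                times=times,
                values=values,
                normalized=norm,
                auc=trapezoid_auc(times, integrand),
            )
        )
    return out


def auc_table(responses: list[MarkerResponse]) -> pd.DataFrame:
    """Long AUC table (subject, arm, marker, auc) from marker responses."""
    return pd.DataFrame(
        [(r.subject, r.arm, r.marker, r.auc) for r in responses],
        columns=["subject", "arm", "marker", "auc"],
    )


def comparative_ct(records: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Relative expression by the comparative-Ct method.

    Input columns: subject, condition, gene, ct_target, ct_reference.
    dCt = ct_target - ct_reference; ddCt is taken against the mean dCt of
    the control condition for the same gene; fold change = 2^-ddCt.
    """
    required = {"subject", "condition", "gene", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s) {sorted(missing)}")
    records = records.copy()
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("Ct values must be finite")
    records["dct"] = records["ct_target"] - records["ct_reference"]
    control = records[records["condition"] == control_condition]
    if control.empty:
        raise ValueError(f"control condition {control_condition!r} absent")
    control_mean = control.groupby("gene")["dct"].mean()
    genes_without_control = set(records["gene"]) - set(control_mean.index)
    if genes_without_control:
        raise ValueError(
            f"no control-condition records for gene(s) {sorted(genes_without_control)}"
        )
    records["ddct"] = records["dct"] - records["gene"].map(control_mean)
    records["fold_change"] = 2.0 ** (-records["ddct"])
    return records[
        ["subject", "condition", "gene", "dct", "ddct", "fold_change"]
    ].reset_index(drop=True)


def _rm_anova_f_batch(mats: np.ndarray) -> np.ndarray:
    """Repeated-measures one-way F for a (batch, subjects, arms) stack."""
    _, n, k = mats.shape
    grand = mats.mean(axis=(1, 2))
    subj_means = mats.mean(axis=2)
    arm_means = mats.mean(axis=1)
    ss_subjects = k * np.sum((subj_means - grand[:, None]) ** 2, axis=1)
    ss_treat = n * np.sum((arm_means - grand[:, None]) ** 2, axis=1)
    ss_total = np.sum((mats - grand[:, None, None]) ** 2, axis=(1, 2))
    ss_error = ss_total - ss_subjects - ss_treat
    ms_error = ss_error / ((n - 1) * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_treat / (k - 1)) / ms_error
    return np.where(ms_error <= 0, np.where(ss_treat == 0, 0.0, np.inf), f)


def _rm_anova_f(matrix: np.ndarray) -> float:
    """Repeated-measures one-way F from a subjects x arms matrix."""
    return float(_rm_anova_f_batch(matrix[None, :, :])[0])


def _letter_groups(order: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: arms sharing a letter are not distinguishable."""
    groups: list[set[str]] = []
    for arm in order:
        placed = False
        for grp in groups:
            if all((min(arm, other), max(arm, other)) not in distinct for other in grp):
                grp.add(arm)
                placed = True
        if not placed:
            groups.append({arm})
    letters = {arm: "" for arm in order}
    for i, grp in enumerate(groups):
        for arm in grp:
            letters[arm] += chr(ord("a") + i)
    return {arm: "".join(sorted(set(s))) for arm, s in letters.items()}


def compare_arms(
    aucs: pd.DataFrame,
    marker: str,
    n_permutations: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ArmComparison:
    """Compare per-arm AUC means for one marker in the crossover design.

    The F statistic comes from the within-subject decomposition; its
    p-value from permuting arm labels independently within each subject
    (exchangeability under the null of no arm effect).  Pairwise paired
    permutation tests feed a Tukey-style compact letter display.  Subjects
    missing any arm are dropped listwise with a warning.
    """
    sub = aucs[aucs["marker"] == marker]
    if sub.empty:
        raise ValueError(f"no AUC rows for marker {marker!r}")
    wide = sub.pivot_table(index="subject", columns="arm", values="auc")
    arms = sorted(wide.columns)
    if len(arms) < 2:
        raise ValueError("need at least two arms to compare")
    complete = wide.dropna()
    if len(complete) < len(wide):
        logger.warning(
            "%s: dropping %d subject(s) without all arms",
            marker,
            len(wide) - len(complete),
        )
    matrix = complete[arms].to_numpy(dtype=float)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least two complete subjects")

    f_obs = _rm_anova_f(matrix)
    rng = np.random.default_rng(seed)
    k = len(arms)
    # permute arm labels independently within each subject, all draws at once
    perm_idx = rng.random((n_permutations, n, k)).argsort(axis=2)
    permuted = np.take_along_axis(
        np.broadcast_to(matrix, (n_permutations, n, k)), perm_idx, axis=2
    )
    f_null = _rm_anova_f_batch(permuted)
    p_perm = (1 + int(np.sum(f_null >= f_obs))) / (1 + n_permutations)

    # pairwise paired permutation (sign-flip) tests for the letter display
    distinct: set[tuple[str, str]] = set()
    n_pair_perm = max(1000, n_permutations // 10)
    for a, b in combinations(arms, 2):
        diff = matrix[:, arms.index(a)] - matrix[:, arms.index(b)]
        t_obs = abs(diff.mean())
        signs = rng.choice([-1.0, 1.0], size=(n_pair_perm, n))
        t_null = np.abs((signs * diff).mean(axis=1))
        p_pair = (1 + np.sum(t_null >= t_obs)) / (1 + n_pair_perm)
        if p_pair < alpha:
            distinct.add((min(a, b), max(a, b)))
    order = sorted(arms, key=lambda a: -complete[a].mean())
    letters = _letter_groups(order, distinct)

    return ArmComparison(
        marker=marker,
        arms=arms,
        means={a: float(complete[a].mean()) for a in arms},
        sems={a: float(complete[a].sem()) for a in arms},
        f_statistic=f_obs,
        p_permutation=p_perm,
        n_subjects=n,
        n_permutations=n_permutations,
        letters=letters,
    )


def comparison_table(comparisons: list[ArmComparison]) -> pd.DataFrame:
    """Arm-comparison summary ready for TSV export (one row per marker/arm)."""
    rows = []
    for c in comparisons:
        for arm in c.arms:
            rows.append(
                (
                    c.marker,
                    arm,
                    c.means[arm],
                    c.sems[arm],
                    c.letters.get(arm, ""),
                    c.f_statistic,
                    c.p_permutation,
                    c.n_subjects,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "marker",
            "arm",
            "mean_auc",
            "sem_auc",
            "letters",
            "f_statistic",
            "p_permutation",
            "n_subjects",
        ],
    )
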