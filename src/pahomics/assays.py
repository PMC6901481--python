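"""Statistics for the functional bioenergetics assays.

Basal oxygen-consumption rates are compared with an exact Wilcoxon rank-sum
test (full enumeration for small samples, tie-corrected normal
approximation otherwise). Glucose dose-response curves are compared through
the area under the curve on a log10-shifted dose axis, with a subject-level
bootstrap of the group-mean AUC difference.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class AssayError(ValueError):
    pass


_ENUMERATION_LIMIT = 200_000


@dataclass
class DoseResponseCurve:
    """One subject's ordered (dose, response) measurements."""

    subject_id: str
    group: str
    doses: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.size < 2:
            raise AssayError("a curve needs at least two points")
        if self.doses.size != self.responses.size:
            raise AssayError("dose and response lengths differ")
        if np.any(np.diff(self.doses) <= 0):
            raise AssayError("doses must be strictly increasing")
        if self.group not in ("case", "control"):
            raise AssayError(f"unknown group {self.group!r}")


def curves_from_table(table: pd.DataFrame) -> list[DoseResponseCurve]:
    """Split a long-format (subject_id, group, dose, response) table into
    per-subject curves, sorted by subject id."""
    required = ["subject_id", "group", "dose", "response"]
    for col in required:
        if col not in table.columns:
            raise AssayError(f"table lacks column {col!r}")
    curves = []
    for subject, sub in table.groupby("subject_id", sort=True):
        sub = sub.sort_values("dose")
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise AssayError(f"subject {subject!r} has mixed group labels")
        curves.append(DoseResponseCurve(
            subject_id=str(subject), group=str(groups[0]),
            doses=sub["dose"].to_numpy(), responses=sub["response"].to_numpy()))
    return curves


# --------------------------------------------------------------------------
# exact Wilcoxon rank-sum

def wilcoxon_exact(x: Sequence[float], y: Sequence[float],
                   method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test returning (rank sum of x, p).

    Mid-ranks handle ties. Full enumeration of all C(n1+n2, n1) group
    assignments is used while that count stays at or below 200,000;
    otherwise a tie-corrected normal approximation with continuity
    correction. ``method`` forces one code path ("exact" / "normal").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise AssayError("both samples need at least one observation")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    w = float(ranks[:n1].sum())
    if method == "auto":
        method = "exact" if comb(n1 + n2, n1) <= _ENUMERATION_LIMIT else "normal"
    if method == "exact":
        total = comb(n1 + n2, n1)
        n_le = n_ge = 0
        eps = 1e-9
        for idx in combinations(range(n1 + n2), n1):
            s = ranks[list(idx)].sum()
            if s <= w + eps:
                n_le += 1
            if s >= w - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    elif method == "normal":
        n = n1 + n2
        mean = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts ** 3) - tie_counts).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            return w, 1.0
        z = (abs(w - mean) - 0.5) / np.sqrt(var)
        z = max(z, 0.0)
        p = min(1.0, 2.0 * float(stats.norm.sf(z)))
    else:
        raise AssayError(f"unknown method {method!r}")
    return w, p


# --------------------------------------------------------------------------
# AUC and bootstrap

def auc_trapezoid(curve: DoseResponseCurve,
                  x_transform: str = "log10_shifted",
                  shift: float | None = None) -> float:
    """Trapezoid-rule area under the curve on the (transformed) dose axis.

    ``log10_shifted`` integrates over log10(dose + shift) with the shift
    defaulting to the smallest positive dose so a 0-dose point stays finite.
    """
    if x_transform == "identity":
        xs = curve.doses
    elif x_transform == "log10_shifted":
        if shift is None:
            positive = curve.doses[curve.doses > 0]
            if positive.size == 0:
                raise AssayError("no positive dose to derive the log shift")
            shift = float(positive.min())
        if np.any(curve.doses + shift <= 0):
            raise AssayError("shift leaves non-positive dose values")
        xs = np.log10(curve.doses + shift)
    else:
        raise AssayError(f"unknown x_transform {x_transform!r}")
    return float(np.trapezoid(curve.responses, xs))


@dataclass
class BootstrapAUCResult:
    delta_auc: float      # mean case AUC minus mean control AUC
    p: float
    n_boot: int
    n_case: int
    n_control: int
    seed: int | None


def _group_stream(seed: int | None, subject_ids: Sequence[str]
                  ) -> np.random.Generator:
    """Substream keyed to the subject set, not the group label, so that
    relabeling the two groups flips only the sign of every bootstrap
    difference and the p-value is exactly symmetric."""
    digest = hashlib.sha256("|".join(sorted(subject_ids)).encode()).digest()
    key = int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
    return np.random.default_rng([0 if seed is None else int(seed), key])


def bootstrap_auc_compare(case_curves: Sequence[DoseResponseCurve],
                          control_curves: Sequence[DoseResponseCurve],
                          n_boot: int = 10_000, seed: int | None = None,
                          x_transform: str = "log10_shifted"
                          ) -> BootstrapAUCResult:
    """Bootstrap comparison of group-mean dose-response AUCs.

    Subjects (cell lines) are resampled with replacement within each group;
    each replicate's statistic is the difference of group-mean AUCs. The
    two-sided sign-crossing p is 2*min(#{D >= 0}+1, #{D <= 0}+1)/(n_boot+1),
    capped at 1.
    """
    if len(case_curves) < 2 or len(control_curves) < 2:
        raise AssayError("need at least two subjects per group")
    grids = [c.doses for c in (*case_curves, *control_curves)]
    if any(not np.array_equal(g, grids[0]) for g in grids[1:]):
        raise AssayError("all curves must share one dose grid")
    auc_case = np.array([auc_trapezoid(c, x_transform) for c in case_curves])
    auc_ctrl = np.array([auc_trapezoid(c, x_transform)
                         for c in control_curves])
    delta_obs = float(auc_case.mean() - auc_ctrl.mean())
    rng_case = _group_stream(seed, [c.subject_id for c in case_curves])
    rng_ctrl = _group_stream(seed, [c.subject_id for c in control_curves])
    idx_case = rng_case.integers(0, auc_case.size, (n_boot, auc_case.size))
    idx_ctrl = rng_ctrl.integers(0, auc_ctrl.size, (n_boot, auc_ctrl.size))
    delta = auc_case[idx_case].mean(axis=1) - auc_ctrl[idx_ctrl].mean(axis=1)
    n_ge = int((delta >= 0).sum())
    n_le = int((delta <= 0).sum())
    p = min(1.0, 2.0 * min(n_ge + 1, n_le + 1) / (n_boot + 1))
    return BootstrapAUCResult(delta_auc=delta_obs, p=p, n_boot=n_boot,
                              n_case=len(case_curves),
                              n_control=len(control_curves), seed=seed)
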