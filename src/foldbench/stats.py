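"""Group-comparison tests, rank correlations, and distribution profiling.

This module is the glue between the fold-change estimators and classical
two-group statistics: Wilcoxon-Mann-Whitney and t tests per variable,
Spearman correlation between effect size (|log2 FC|) and significance
(-log10 p) across variables, and a Box-Cox profile that snaps the fitted
power-transform exponent onto Tukey's ladder to label each variable's
distribution shape.

The Wilcoxon test is invariant under any strictly monotone transform of the
pooled data; the t test is not.  Keeping both in every experiment is
deliberate: the contrast shows which conclusions depend on the measurement
scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .core import DomainError, FCResult, GroupedSample, InputError

__all__ = [
    "GroupTest",
    "TestResult",
    "DistributionProfile",
    "NormalityReport",
    "TUKEY_LADDER",
    "compare_groups",
    "spearman_abs_fc_vs_significance",
    "profile_distribution",
    "normality_fraction",
    "benjamini_hochberg",
    "snap_to_ladder",
]


class GroupTest(str, enum.Enum):
    WILCOXON_MWU = "wilcoxon_mwu"
    T_TEST = "t_test"


#: Tukey's classical ladder-of-powers grid; 0 stands for the log transform.
TUKEY_LADDER: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class TestResult:
    variable_id: str
    test: GroupTest
    p_value: float
    neg_log10_p: float
    degenerate: bool = False


@dataclass(frozen=True)
class DistributionProfile:
    """Box-Cox shape label for one positive variable."""

    variable_id: str
    lambda_hat: float
    ladder_step: float
    is_normal_raw: bool
    is_normal_logged: bool
    p_shapiro_raw: float
    p_shapiro_logged: float


@dataclass(frozen=True)
class NormalityReport:
    """Panel-level normality fractions and ladder histogram."""

    summary: pd.DataFrame  # rows: scope; cols: n, frac_normal_raw, frac_normal_logged
    ladder: pd.DataFrame  # rows: scope; cols: ladder steps; values: counts
    n_skipped_nonpositive: int = 0


def compare_groups(
    sample: GroupedSample,
    test: GroupTest | str,
    *,
    equal_var: bool = False,
) -> TestResult:
    """Two-sided p-value for a difference between the two groups.

    WILCOXON_MWU uses the rank-sum statistic with tie correction (exact
    enumeration when scipy selects it for small tie-free samples).  T_TEST
    defaults to the Welch unequal-variance form; ``equal_var=True`` selects
    the pooled Student form.  Degenerate data (zero pooled variance) yields
    p = 1 with the ``degenerate`` flag set rather than an exception.
    """
    test = GroupTest(test)
    sample.check()
    a, b = sample.a, sample.b

    degenerate = False
    if test is GroupTest.WILCOXON_MWU:
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            p = 1.0
            degenerate = True
        else:
            p = float(sps.mannwhitneyu(b, a, alternative="two-sided").pvalue)
    else:
        if a.size < 2 or b.size < 2:
            raise InputError(
                f"t-test requires >= 2 observations per group for variable "
                f"{sample.variable_id!r}"
            )
        p = float(sps.ttest_ind(b, a, equal_var=equal_var).pvalue)
        if math.isnan(p):  # both groups constant
            p = 1.0
            degenerate = True

    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return TestResult(
        variable_id=sample.variable_id,
        test=test,
        p_value=p,
        neg_log10_p=-math.log10(p),
        degenerate=degenerate,
    )


def spearman_abs_fc_vs_significance(
    fc_results: Iterable[FCResult],
    test_results: Iterable[TestResult],
) -> pd.DataFrame:
    """Spearman rho of |log2 FC| against -log10 p, per (method, test).

    Results are aligned on ``variable_id``; at least three aligned variables
    are required.  Returns a tidy frame with columns method, test, rho,
    p_value, n.
    """
    fc_rows = pd.DataFrame(
        {
            "variable_id": r.variable_id,
            "method": r.method.name,
            "abs_log2_fc": abs(r.log_ratio),
        }
        for r in fc_results
    )
    test_rows = pd.DataFrame(
        {
            "variable_id": r.variable_id,
            "test": r.test.name,
            "neg_log10_p": r.neg_log10_p,
        }
        for r in test_results
    )
    if fc_rows.empty or test_rows.empty:
        raise InputError("need fold-change and test results to correlate")
    merged = fc_rows.merge(test_rows, on="variable_id")
    out = []
    for (method, test), grp in merged.groupby(["method", "test"], sort=True):
        if len(grp) < 3:
            raise InputError(
                f"fewer than 3 aligned variables for {method} x {test}"
            )
        rho, p = sps.spearmanr(grp["abs_log2_fc"], grp["neg_log10_p"])
        out.append(
            {"method": method, "test": test, "rho": float(rho),
             "p_value": float(p), "n": len(grp)}
        )
    return pd.DataFrame(out)


def snap_to_ladder(lambda_hat: float) -> float:
    """Nearest Tukey-ladder step; equidistant ties break toward 1 (identity)."""
    grid = np.asarray(TUKEY_LADDER)
    dist = np.abs(grid - lambda_hat)
    candidates = grid[dist == dist.min()]
    return float(candidates[np.argmin(np.abs(candidates - 1.0))])


def profile_distribution(
    values: Sequence[float] | np.ndarray,
    alpha: float = 0.05,
    *,
    variable_id: str = "",
    lambda_bounds: tuple[float, float] = (-3.0, 3.0),
) -> DistributionProfile:
    """Box-Cox lambda (MLE on [-3, 3]), ladder label, and normality flags.

    ``lambda_hat`` maximises the Box-Cox log-likelihood; a value near 0 means
    the log transform normalises the variable, near 1 means it already looks
    normal on the raw scale.  Normality is judged by Shapiro-Wilk at level
    ``alpha`` on the raw and on the log2-transformed values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise InputError(
            f"profiling variable {variable_id!r} needs a 1-D vector of >= 8 values"
        )
    if not np.all(np.isfinite(x)):
        raise InputError(f"variable {variable_id!r} contains non-finite values")
    if np.any(x <= 0):
        raise DomainError(
            f"variable {variable_id!r} contains non-positive values; "
            "the Box-Cox transform requires strictly positive data"
        )
    if np.all(x == x[0]):
        raise DomainError(
            f"variable {variable_id!r} is constant; its distribution shape "
            "is undefined"
        )
    res = optimize.minimize_scalar(
        lambda lam: -sps.boxcox_llf(lam, x),
        bounds=lambda_bounds,
        method="bounded",
    )
    lambda_hat = float(res.x)
    p_raw = float(sps.shapiro(x).pvalue)
    p_logged = float(sps.shapiro(np.log2(x)).pvalue)
    return DistributionProfile(
        variable_id=variable_id,
        lambda_hat=lambda_hat,
        ladder_step=snap_to_ladder(lambda_hat),
        is_normal_raw=p_raw > alpha,
        is_normal_logged=p_logged > alpha,
        p_shapiro_raw=p_raw,
        p_shapiro_logged=p_logged,
    )


def normality_fraction(
    panel,
    alpha: float = 0.05,
    *,
    per_group: bool = True,
) -> NormalityReport:
    """Fraction of panel variables that look normal, raw and after log2.

    ``panel`` is a :class:`~foldbench.simulate.VariablePanel` or any iterable
    of :class:`~foldbench.core.GroupedSample`.  Each variable is profiled on
    its pooled values ("complete") and, when ``per_group`` is set, separately
    on the reference and treatment halves.  Variables containing non-positive
    values cannot be Box-Cox profiled and are skipped (counted).
    """
    samples = list(getattr(panel, "samples", panel))
    if not samples:
        raise InputError("cannot profile an empty panel")

    scopes: dict[str, list[np.ndarray]] = {"complete": []}
    ids: dict[str, list[str]] = {"complete": []}
    if per_group:
        scopes.update({"reference": [], "treatment": []})
        ids.update({"reference": [], "treatment": []})
    skipped = 0
    for s in samples:
        if s.contains_nonpositive:
            skipped += 1
            continue
        scopes["complete"].append(np.concatenate([s.a, s.b]))
        ids["complete"].append(s.variable_id)
        if per_group:
            scopes["reference"].append(s.a)
            ids["reference"].append(s.variable_id)
            scopes["treatment"].append(s.b)
            ids["treatment"].append(s.variable_id)
    if not scopes["complete"]:
        raise InputError("no profileable (strictly positive) variables in panel")

    summary_rows = []
    ladder_rows = []
    for scope, vectors in scopes.items():
        profiles = [
            profile_distribution(v, alpha, variable_id=vid)
            for v, vid in zip(vectors, ids[scope])
        ]
        n = len(profiles)
        summary_rows.append(
            {
                "scope": scope,
                "n": n,
                "frac_normal_raw": sum(p.is_normal_raw for p in profiles) / n,
                "frac_normal_logged": sum(p.is_normal_logged for p in profiles) / n,
            }
        )
        counts = {step: 0 for step in TUKEY_LADDER}
        for p in profiles:
            counts[p.ladder_step] += 1
        ladder_rows.append({"scope": scope, **counts})

    summary = pd.DataFrame(summary_rows).set_index("scope")
    ladder = pd.DataFrame(ladder_rows).set_index("scope")
    return NormalityReport(
        summary=summary, ladder=ladder, n_skipped_nonpositive=skipped
    )


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; no experiment applies
    multiplicity correction by default, matching the uncorrected volcano
    convention)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
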