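"""Fold-change estimators and the signed fold-change error metric.

Fold change (FC) summarises how much larger or smaller a variable is in a
treatment group ``b`` than in a reference group ``a``.  Every variant in use
reduces to a log2 ratio of two *group expected values*,

    logRatio = log2 E[b] - log2 E[a],

and the variants differ only in what "expected value" means: arithmetic
mean, median, geometric mean (equivalently the mean of the logs), or an
aggregate over all pairwise ratios b_i/a_j.  The log ratio is mapped to a
signed, symmetric fold change

    FC = 2**logRatio        if logRatio >= 0
       = -2**(-logRatio)    otherwise

so a 3-fold increase prints as +3 and a one-third ratio as -3.  Recovery of
a known true ratio is scored on the same signed-fold scale:

    ErrorFC = signedFold(FC_calculated) - signedFold(FC_true).

All estimators demand strictly positive measurements; zeros or negative
values are a hard error rather than being offset or dropped, because a log
ratio of a non-positive quantity has no biological reading.
"""

from __future__ import annotations

import enum
import math
from dataclasses import InitVar, dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FoldbenchError",
    "DomainError",
    "InputError",
    "FCMethod",
    "GroupedSample",
    "FCResult",
    "FCError",
    "log_ratio",
    "fc_from_log_ratio",
    "signed_fold",
    "error_fc",
    "fc_all_methods",
    "DEFAULT_BOOTSTRAP_REPS",
    "PAIR_BRUTE_LIMIT",
]


class FoldbenchError(Exception):
    """Base class for all foldbench errors."""


class DomainError(FoldbenchError, ValueError):
    """Input is numerically valid but outside the method's domain (e.g. x <= 0)."""


class InputError(FoldbenchError, ValueError):
    """Structurally invalid input (empty vector, non-finite value, bad shape)."""


class FCMethod(str, enum.Enum):
    """Registry of fold-change estimators.

    Each member is one way of defining the group expected value entering the
    log ratio.  ``GEOMETRIC_MEAN`` is an alias of ``MEAN_OF_LOGS``: the log2
    of the geometric mean *is* the mean of the log2 values.
    """

    LOG_OF_MEANS = "log_of_means"
    LOG_OF_MEDIANS = "log_of_medians"
    MEAN_OF_LOGS = "mean_of_logs"
    GEOMETRIC_MEAN = "mean_of_logs"  # alias: same estimator, Table-ology differs
    MEDIAN_OF_LOGS = "median_of_logs"
    PAIRS_MEAN = "pairs_mean"
    PAIRS_MEDIAN = "pairs_median"
    PAIRS_MEAN_BOOTSTRAP = "pairs_mean_bootstrap"
    PAIRS_MEDIAN_BOOTSTRAP = "pairs_median_bootstrap"


#: Methods whose pair aggregate is re-evaluated on resampled groups.
BOOTSTRAP_METHODS = frozenset(
    {FCMethod.PAIRS_MEAN_BOOTSTRAP, FCMethod.PAIRS_MEDIAN_BOOTSTRAP}
)

#: Default number of bootstrap replicates for the *_BOOTSTRAP variants.
DEFAULT_BOOTSTRAP_REPS = 100

#: Below this many ordered (a_j, b_i) pairs the pairwise aggregate is computed
#: by explicit enumeration; above it, by exact closed forms (mean) or an exact
#: value-space selection (median) on the sorted log vectors.
PAIR_BRUTE_LIMIT = 1_000_000


@dataclass(eq=False)
class GroupedSample:
    """One variable's measurements under two conditions.

    Parameters
    ----------
    a
        Reference-condition values (length >= 1).
    b
        Treatment-condition values (length >= 1), same measurement units.
    variable_id
        Opaque label carried through results.
    fc_true
        Known generating ratio, if the sample is synthetic.
    validate
        When False the length/finiteness checks are skipped at construction;
        they are still enforced when an estimator is applied.
    """

    a: np.ndarray
    b: np.ndarray
    variable_id: str = ""
    fc_true: float | None = None
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if validate:
            self.check()

    def check(self) -> None:
        for name, v in (("a", self.a), ("b", self.b)):
            if v.ndim != 1:
                raise InputError(
                    f"group {name!r} of variable {self.variable_id!r} must be 1-D"
                )
            if v.size < 1:
                raise InputError(
                    f"group {name!r} of variable {self.variable_id!r} is empty"
                )
            if not np.all(np.isfinite(v)):
                raise InputError(
                    f"group {name!r} of variable {self.variable_id!r} "
                    "contains non-finite values"
                )

    @property
    def n_a(self) -> int:
        return int(self.a.size)

    @property
    def n_b(self) -> int:
        return int(self.b.size)

    @property
    def contains_nonpositive(self) -> bool:
        """True if any measurement is <= 0 (log-domain methods will reject)."""
        return bool(np.any(self.a <= 0) or np.any(self.b <= 0))

    def swapped(self) -> "GroupedSample":
        """Return the sample with reference and treatment roles exchanged."""
        return GroupedSample(
            a=self.b, b=self.a, variable_id=self.variable_id, fc_true=None
        )


@dataclass(frozen=True)
class FCResult:
    """A single estimator's output for one variable."""

    method: FCMethod
    log_ratio: float
    fc: float
    variable_id: str = ""


@dataclass(frozen=True)
class FCError:
    """Signed recovery error on the symmetric fold scale."""

    error: float
    fc_calculated: float
    fc_true: float


def _require_positive(values: np.ndarray, group: str, variable_id: str) -> np.ndarray:
    if values.size < 1:
        raise InputError(f"group {group!r} of variable {variable_id!r} is empty")
    if np.any(values <= 0):
        raise DomainError(
            f"group {group!r} of variable {variable_id!r} contains non-positive "
            "values; fold change is defined for strictly positive measurements"
        )
    return values


def _pairs_mean(la: np.ndarray, lb: np.ndarray) -> float:
    """Mean of log2(b_i/a_j) over all ordered cross pairs.

    Enumerated explicitly when the pair count is modest; otherwise the exact
    algebraic identity mean_pairs(lb_i - la_j) = mean(lb) - mean(la) is used,
    which is the full Cartesian-product value, not an approximation.
    """
    if la.size * lb.size <= PAIR_BRUTE_LIMIT:
        return float(np.subtract.outer(lb, la).mean())
    return float(lb.mean() - la.mean())


def _count_pairs_le(sa: np.ndarray, sb: np.ndarray, t: float) -> int:
    """Number of ordered pairs with sb_i - sa_j <= t (sorted inputs)."""
    return int(sa.size * sb.size - np.searchsorted(sa, sb - t, side="left").sum())


def _kth_pair_diff(
    sa: np.ndarray, sb: np.ndarray, k: int, lo: float, hi: float, tol: float
) -> float:
    """k-th smallest (0-based) value of {sb_i - sa_j} for sorted inputs.

    Bisection on the value axis; each step counts pairs below the pivot with
    a vectorised binary search, so the cost is O(iters * n log n) instead of
    materialising all n_a*n_b differences.  The order statistic is located
    to within ``tol`` (the counting itself is exact).
    """
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mid <= lo or mid >= hi:  # interval exhausted at double precision
            break
        if _count_pairs_le(sa, sb, mid) >= k + 1:
            hi = mid
        else:
            lo = mid
    return hi


def _pairs_median(la: np.ndarray, lb: np.ndarray, tol_rel: float = 1e-11) -> float:
    """Median of log2(b_i/a_j) over all ordered cross pairs.

    Below the enumeration cap this is a plain median of the outer
    differences; above it, a value-space selection on the sorted vectors
    locates the central order statistics of the full Cartesian product to
    within ``tol_rel`` relative, without forming the pairs.
    """
    n_pairs = la.size * lb.size
    if n_pairs <= PAIR_BRUTE_LIMIT:
        return float(np.median(np.subtract.outer(lb, la)))
    sa = np.sort(la)
    sb = np.sort(lb)
    lo = float(sb[0] - sa[-1])
    hi = float(sb[-1] - sa[0])
    tol = tol_rel * max(1.0, abs(lo), abs(hi))
    k_lo = (n_pairs - 1) // 2
    k_hi = n_pairs // 2
    lo_stat = _kth_pair_diff(sa, sb, k_lo, lo, hi, tol)
    if k_hi == k_lo:
        return lo_stat
    # The next order statistic sits at or just above the k_lo-th; with
    # ~n^2 pairs the two central ones are almost always within tol of each
    # other, so probe a short window before falling back to a full search.
    near = lo_stat + 4.0 * tol
    if _count_pairs_le(sa, sb, near) >= k_hi + 1:
        hi_stat = _kth_pair_diff(sa, sb, k_hi, lo_stat, near, tol)
    else:
        hi_stat = _kth_pair_diff(sa, sb, k_hi, near, hi, tol)
    return 0.5 * (lo_stat + hi_stat)


def log_ratio(
    sample: GroupedSample,
    method: FCMethod | str,
    *,
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | None = None,
) -> float:
    """Log2 treatment/reference ratio of group expected values.

    ``bootstrap_reps`` and ``seed`` are consulted only by the *_BOOTSTRAP
    variants, which resample ``a`` and ``b`` independently with replacement
    to their original sizes, recompute the pairwise aggregate per replicate,
    and average the replicate aggregates.

    Raises
    ------
    DomainError
        If any measurement is non-positive (names the offending variable).
    InputError
        If either group is empty or contains non-finite values.
    """
    method = FCMethod(method)
    sample.check()
    a = _require_positive(sample.a, "a", sample.variable_id)
    b = _require_positive(sample.b, "b", sample.variable_id)

    if method is FCMethod.LOG_OF_MEANS:
        return float(np.log2(b.mean()) - np.log2(a.mean()))
    if method is FCMethod.LOG_OF_MEDIANS:
        return float(np.log2(np.median(b)) - np.log2(np.median(a)))

    la = np.log2(a)
    lb = np.log2(b)
    if method is FCMethod.MEAN_OF_LOGS:
        return float(lb.mean() - la.mean())
    if method is FCMethod.MEDIAN_OF_LOGS:
        return float(np.median(lb) - np.median(la))
    if method is FCMethod.PAIRS_MEAN:
        return _pairs_mean(la, lb)
    if method is FCMethod.PAIRS_MEDIAN:
        return _pairs_median(la, lb)

    # bootstrap variants
    if bootstrap_reps < 1:
        raise InputError("bootstrap_reps must be a positive integer")
    rng = np.random.default_rng(seed)
    if method is FCMethod.PAIRS_MEAN_BOOTSTRAP:
        agg = _pairs_mean
    else:
        # Replicate aggregates are averaged, so a selection tolerance far
        # below the resampling noise is sufficient inside the loop.
        def agg(x, y):
            return _pairs_median(x, y, tol_rel=1e-7)

    total = 0.0
    for _ in range(bootstrap_reps):
        la_star = la[rng.integers(0, la.size, la.size)]
        lb_star = lb[rng.integers(0, lb.size, lb.size)]
        total += agg(la_star, lb_star)
    return total / bootstrap_reps


def fc_from_log_ratio(lr: float) -> float:
    """Signed fold change from a log2 ratio.

    2**lr for lr >= 0, else -2**(-lr), so |fc| >= 1 always and fc = 1 exactly
    when lr = 0.  The compact form 2**|lr| * sign(lr) agrees everywhere except
    lr = 0, where the branch form's value of 1 (no change) is used.
    """
    lr = float(lr)
    if not math.isfinite(lr):
        raise InputError(f"log ratio must be finite, got {lr!r}")
    if lr >= 0:
        return 2.0**lr
    return -(2.0**-lr)


def signed_fold(ratio: float) -> float:
    """Map a ratio (or an already-signed fold value) to the signed fold scale.

    Positive inputs are ratios: r >= 1 maps to r, r < 1 maps to -1/r (so 1/3
    becomes -3).  Inputs <= -1 are taken as already being signed folds.  The
    interval (-1, 0] is not part of the scale and is rejected.
    """
    r = float(ratio)
    if not math.isfinite(r):
        raise InputError(f"fold-change value must be finite, got {r!r}")
    if r > 0:
        return r if r >= 1.0 else -1.0 / r
    if r <= -1.0:
        return r
    raise DomainError(
        f"{r!r} is not a valid fold change: expected a positive ratio or a "
        "signed fold with magnitude >= 1"
    )


def error_fc(fc_calculated: float, fc_true: float) -> FCError:
    """Signed difference between calculated and true FC on the fold scale.

    Both arguments may be given as positive ratios (e.g. 0.5) or as signed
    folds (e.g. -2); they are mapped to the signed scale before subtracting,
    so error_fc(0.5, 2) = (-2) - (+2) = -4.  The metric is zero iff the two
    agree and antisymmetric under swapping the arguments.
    """
    calc = signed_fold(fc_calculated)
    true = signed_fold(fc_true)
    return FCError(error=calc - true, fc_calculated=calc, fc_true=true)


def fc_all_methods(
    sample: GroupedSample,
    methods: Sequence[FCMethod | str] | None = None,
    *,
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | None = None,
) -> list[FCResult]:
    """Apply every enabled estimator to one sample.

    Deterministic for a fixed ``seed`` (each bootstrap method gets its own
    child seed so enabling/disabling one method does not shift another's
    stream).  A failing method aborts the call with an error annotated with
    every affected method, since all estimators share the same domain.
    """
    methods = [FCMethod(m) for m in (methods or list(dict.fromkeys(FCMethod)))]
    try:
        sample.check()
        _require_positive(sample.a, "a", sample.variable_id)
        _require_positive(sample.b, "b", sample.variable_id)
    except (InputError, DomainError) as exc:
        names = ", ".join(m.name for m in methods)
        raise type(exc)(f"all methods failed ({names}): {exc}") from exc

    seed_seq = np.random.SeedSequence(seed)
    child = iter(seed_seq.generate_state(len(methods)))
    results = []
    for m in methods:
        m_seed = int(next(child)) & 0x7FFFFFFF
        try:
            lr = log_ratio(sample, m, bootstrap_reps=bootstrap_reps, seed=m_seed)
        except FoldbenchError as exc:
            raise type(exc)(f"method {m.name} failed: {exc}") from exc
        results.append(
            FCResult(
                method=m,
                log_ratio=lr,
                fc=fc_from_log_ratio(lr),
                variable_id=sample.variable_id,
            )
        )
    return results
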