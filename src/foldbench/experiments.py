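"""The four reproducible estimator stress tests.

1. ``run_distribution_stress`` — recovery of known fold changes across the
   five distribution families (plus the two asymmetric cross-family rows),
   at large and small n, with an optional re-log variant in which already
   generated data are log2-transformed again before estimation.
2. ``run_variance_sweep`` — log-normal data over a grid of true fold
   changes and treatment/reference spread ratios; the arithmetic-mean
   estimator's error follows the closed form (s_b^2 - s_a^2) / (2 ln 2) in
   log2 units while the median/geometric-mean estimators stay near zero.
3. ``run_significance_panel`` — d-variable panels relating |log2 FC| to
   -log10 p (volcano coordinates) for every estimator x test combination,
   plus detection of crossover variables whose regulation direction flips
   between the arithmetic-mean and geometric-mean estimators.
4. ``run_permutation_stress`` — estimator and test concordance on a matrix
   whose entries have been globally shuffled, producing grossly skewed
   per-variable distributions.

Every stochastic cell records the generating parameters and seed, so any
cell is independently recomputable; cell values are means over ``reps``
seeded replicates.
"""

from __future__ import annotations

import json
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import foldbench

from .core import (
    BOOTSTRAP_METHODS,
    DEFAULT_BOOTSTRAP_REPS,
    FCMethod,
    FoldbenchError,
    GroupedSample,
    error_fc,
    fc_from_log_ratio,
    log_ratio,
)
from .simulate import (
    DEFAULT_FC_GRID,
    DEFAULT_S_A_LEVELS,
    DEFAULT_S_RATIO_GRID,
    Family,
    PanelSpec,
    SimSpec,
    child_seeds,
    generate,
    generate_panel,
    permute_matrix,
)
from .stats import GroupTest, compare_groups

__all__ = [
    "ExperimentReport",
    "run_distribution_stress",
    "run_variance_sweep",
    "run_significance_panel",
    "run_permutation_stress",
    "STRESS_FAMILIES",
    "NON_BOOTSTRAP_METHODS",
    "ROBUST_METHODS",
    "lognormal_mean_bias_bits",
]

#: Row order of the distribution stress test.
STRESS_FAMILIES: tuple[Family, ...] = (
    Family.IDENTITY,
    Family.UNIFORM,
    Family.NORMAL,
    Family.LOGNORMAL,
    Family.MIXED_NORMAL_LOGNORMAL,
    Family.MIXED_LOGNORMAL_NORMAL,
    Family.MIXED,
)

NON_BOOTSTRAP_METHODS: tuple[FCMethod, ...] = tuple(
    m for m in FCMethod if m not in BOOTSTRAP_METHODS
)

#: The estimators that stay accurate under unequal log-normal variances.
ROBUST_METHODS: tuple[FCMethod, ...] = (
    FCMethod.LOG_OF_MEDIANS,
    FCMethod.MEAN_OF_LOGS,
    FCMethod.MEDIAN_OF_LOGS,
    FCMethod.PAIRS_MEDIAN,
)


def lognormal_mean_bias_bits(s_a: float, s_b: float) -> float:
    """Closed-form log2 bias of the arithmetic-mean estimator on log-normal data.

    E[mean(b)] / E[mean(a)] = fc * exp((s_b**2 - s_a**2) / 2), so the
    log-of-means estimate converges to log2(fc) + (s_b**2 - s_a**2)/(2 ln 2).
    """
    return (s_b**2 - s_a**2) / (2.0 * math.log(2.0))


@dataclass
class ExperimentReport:
    """Tidy result container shared by all four experiments.

    ``cells`` holds one row per replicate x condition x method (each carrying
    the generating parameters and seed); ``summary`` aggregates cells;
    ``tables`` holds experiment-specific side tables (trend fits, correlation
    matrices, crossover lists, exclusions); ``manifest`` records parameters,
    seeds, and software versions.
    """

    experiment_id: str
    cells: pd.DataFrame
    summary: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path, *, plots: bool = False) -> list[Path]:
        """Write TSV tables and a JSON manifest (and optional plots) to outdir."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in (
            ("cells", self.cells),
            ("summary", self.summary),
            *self.tables.items(),
        ):
            path = outdir / f"{self.experiment_id}_{name}.tsv"
            frame.to_csv(path, sep="\t", index=not isinstance(frame.index, pd.RangeIndex))
            written.append(path)
        manifest_path = outdir / f"{self.experiment_id}_manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2, default=str))
        written.append(manifest_path)
        if plots:
            from . import plots as _plots

            written.extend(_plots.plot_report(self, outdir))
        return written


def _versions() -> dict[str, str]:
    return {
        "python": sys.version.split()[0],
        "foldbench": foldbench.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": __import__("scipy").__version__,
    }


def _stress_spreads(
    family: Family, s_normal: float, s_lognormal: float
) -> tuple[float, float]:
    """Per-family (s_a, s_b) used by the distribution stress test."""
    if family in (Family.IDENTITY, Family.UNIFORM):
        return 0.0, 0.0
    if family is Family.NORMAL:
        return s_normal, s_normal
    if family is Family.MIXED_NORMAL_LOGNORMAL:
        return s_normal, s_lognormal
    if family is Family.MIXED_LOGNORMAL_NORMAL:
        return s_lognormal, s_normal
    return s_lognormal, s_lognormal  # LOGNORMAL and MIXED


def _method_rows(
    sample: GroupedSample,
    methods: Sequence[FCMethod],
    *,
    bootstrap_reps: int,
    seed: int,
    with_error: bool = True,
) -> list[dict]:
    """One row per method on one sample, converting failures into records."""
    rows = []
    for idx, m in enumerate(methods):
        row: dict = {"method": m.name}
        try:
            lr = log_ratio(
                sample,
                m,
                bootstrap_reps=bootstrap_reps,
                seed=(seed + idx) & 0x7FFFFFFF,
            )
            row.update(
                log_ratio=lr, fc=fc_from_log_ratio(lr), failed=False, failure=""
            )
            if with_error and sample.fc_true is not None:
                row["error_fc"] = error_fc(row["fc"], sample.fc_true).error
        except FoldbenchError as exc:
            row.update(
                log_ratio=np.nan,
                fc=np.nan,
                failed=True,
                failure=f"{type(exc).__name__}: {exc}",
            )
            if with_error:
                row["error_fc"] = np.nan
        rows.append(row)
    return rows


def _safe_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho that returns (nan, nan) for degenerate (constant) input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def run_distribution_stress(
    n_levels: Sequence[int] = (10, 10_000),
    fc_grid: Sequence[float] = (1.0 / 3.0, 0.5, 1.0, 2.0, 3.0),
    methods: Sequence[FCMethod | str] | None = None,
    *,
    reps: int = 25,
    m_a: float = 100.0,
    s_normal: float = 10.0,
    s_lognormal: float = 1.0,
    relog: bool = True,
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
    families: Sequence[Family] = STRESS_FAMILIES,
    seed: int = 0,
) -> ExperimentReport:
    """Fold-change recovery across distribution families and sample sizes.

    For every family x fc x n cell, ``reps`` samples are generated and every
    estimator's signed recovery error (``ErrorFC``) is recorded.  When
    ``relog`` is set the same samples are additionally log2-transformed
    before estimation; on that variant only the *ranking* of estimates is
    meaningful (the numbers no longer quantify times-expression), so the
    summary table reports rank preservation instead of errors.
    """
    methods = [FCMethod(m) for m in (methods or list(FCMethod))]
    combos = [
        (fam, int(n), float(fc), r)
        for fam in families
        for n in n_levels
        for fc in fc_grid
        for r in range(reps)
    ]
    seeds = child_seeds(seed, 2 * len(combos))
    rows = []
    for i, (fam, n, fc, rep) in enumerate(combos):
        s_a, s_b = _stress_spreads(fam, s_normal, s_lognormal)
        spec = SimSpec(
            family=fam, m_a=m_a, fc_true=fc, s_a=s_a, s_b=s_b,
            n_a=n, n_b=n, seed=int(seeds[2 * i]),
        )
        sample = generate(spec)
        base = {
            "family": fam.value, "n": n, "fc_true": fc, "replicate": rep,
            "m_a": m_a, "s_a": s_a, "s_b": s_b, "seed": spec.seed,
        }
        method_seed = int(seeds[2 * i + 1])
        for row in _method_rows(
            sample, methods, bootstrap_reps=bootstrap_reps, seed=method_seed
        ):
            rows.append({**base, "transform": "raw", **row})
        if relog:
            if sample.contains_nonpositive:
                for m in methods:
                    rows.append(
                        {
                            **base, "transform": "relog", "method": m.name,
                            "log_ratio": np.nan, "fc": np.nan, "error_fc": np.nan,
                            "failed": True,
                            "failure": "DomainError: non-positive values cannot "
                            "be log-transformed",
                        }
                    )
            else:
                logged = GroupedSample(
                    a=np.log2(sample.a), b=np.log2(sample.b),
                    variable_id=sample.variable_id, validate=False,
                )
                for row in _method_rows(
                    logged, methods, bootstrap_reps=bootstrap_reps,
                    seed=method_seed, with_error=False,
                ):
                    rows.append(
                        {**base, "transform": "relog", "error_fc": np.nan, **row}
                    )

    cells = pd.DataFrame(rows)
    summary = (
        cells.groupby(["family", "n", "fc_true", "transform", "method"], sort=False)
        .agg(
            mean_error=("error_fc", "mean"),
            mean_abs_error=("error_fc", lambda e: np.abs(e).mean()),
            mean_log_ratio=("log_ratio", "mean"),
            n_failed=("failed", "sum"),
            n_reps=("failed", "size"),
        )
        .reset_index()
    )

    tables: dict[str, pd.DataFrame] = {}
    if relog:
        # Rank preservation: correlate the per-fc mean estimates raw vs relog.
        piv = summary.pivot_table(
            index=["family", "n", "method", "fc_true"],
            columns="transform",
            values="mean_log_ratio",
        ).reset_index()
        rank_rows = []
        for (fam, n, method), grp in piv.groupby(["family", "n", "method"]):
            if "relog" not in grp or "raw" not in grp:
                continue
            rho, _ = _safe_spearman(grp["raw"].to_numpy(), grp["relog"].to_numpy())
            rank_rows.append(
                {"family": fam, "n": n, "method": method,
                 "rank_spearman_raw_vs_relog": rho, "n_fc_points": len(grp)}
            )
        tables["relog_rank_preservation"] = pd.DataFrame(rank_rows)

    manifest = {
        "experiment": "distribution_stress",
        "families": [f.value for f in families],
        "n_levels": list(n_levels), "fc_grid": list(fc_grid),
        "methods": [m.name for m in methods], "reps": reps, "m_a": m_a,
        "s_normal": s_normal, "s_lognormal": s_lognormal, "relog": relog,
        "bootstrap_reps": bootstrap_reps, "seed": seed, "versions": _versions(),
    }
    return ExperimentReport(
        "distribution_stress", cells, summary, tables, manifest
    )


def run_variance_sweep(
    fc_grid: Sequence[float] | None = None,
    s_ratio_grid: Sequence[float] = DEFAULT_S_RATIO_GRID,
    s_a_levels: Sequence[float] = DEFAULT_S_A_LEVELS,
    *,
    n: int = 10_000,
    reps: int = 25,
    methods: Sequence[FCMethod | str] | None = None,
    m_a: float = 100.0,
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
) -> ExperimentReport:
    """Log-normal variance-ratio sweep (accuracy vs fc and s_b/s_a).

    Defaults reproduce the benchmark grid: fc on 20 evenly spaced points in
    [0.1, 6], s_b/s_a in {0.1, 0.5, 1, 2, 4, 8}, s_a in {0.1, 1}.  Each cell
    is replicated ``reps`` times.  The ``trends`` table fits an ordinary
    least-squares line of ErrorFC against fc_true within each
    (method, s_a, s_ratio) panel; the ``predicted_bias_bits`` column carries
    the closed-form arithmetic-mean bias for comparison.
    """
    fc_grid = DEFAULT_FC_GRID if fc_grid is None else tuple(float(f) for f in fc_grid)
    methods = [FCMethod(m) for m in (methods or NON_BOOTSTRAP_METHODS)]
    combos = [
        (float(s_a), float(ratio), float(fc), r)
        for s_a in s_a_levels
        for ratio in s_ratio_grid
        for fc in fc_grid
        for r in range(reps)
    ]
    seeds = child_seeds(seed, 2 * len(combos))
    rows = []
    for i, (s_a, ratio, fc, rep) in enumerate(combos):
        s_b = ratio * s_a
        spec = SimSpec(
            family=Family.LOGNORMAL, m_a=m_a, fc_true=fc,
            s_a=s_a, s_b=s_b, n_a=n, n_b=n, seed=int(seeds[2 * i]),
        )
        sample = generate(spec)
        base = {
            "s_a": s_a, "s_ratio": ratio, "s_b": s_b, "fc_true": fc,
            "replicate": rep, "n": n, "m_a": m_a, "seed": spec.seed,
            "predicted_bias_bits": lognormal_mean_bias_bits(s_a, s_b),
        }
        for row in _method_rows(
            sample, methods, bootstrap_reps=bootstrap_reps, seed=int(seeds[2 * i + 1])
        ):
            rows.append({**base, **row})

    cells = pd.DataFrame(rows)
    summary = (
        cells.groupby(["s_a", "s_ratio", "fc_true", "method"], sort=False)
        .agg(
            mean_error=("error_fc", "mean"),
            mean_abs_error=("error_fc", lambda e: np.abs(e).mean()),
            mean_log_ratio=("log_ratio", "mean"),
            predicted_bias_bits=("predicted_bias_bits", "first"),
            n_failed=("failed", "sum"),
            n_reps=("failed", "size"),
        )
        .reset_index()
    )

    trend_rows = []
    for (method, s_a, ratio), grp in cells.groupby(["method", "s_a", "s_ratio"]):
        ok = grp[~grp["failed"]]
        if ok["fc_true"].nunique() < 2:
            continue
        fit = sps.linregress(ok["fc_true"], ok["error_fc"])
        trend_rows.append(
            {
                "method": method, "s_a": s_a, "s_ratio": ratio,
                "slope": fit.slope, "intercept": fit.intercept,
                "rvalue": fit.rvalue, "n": len(ok),
            }
        )
    tables = {"trends": pd.DataFrame(trend_rows)}

    manifest = {
        "experiment": "variance_sweep",
        "fc_grid": list(fc_grid), "s_ratio_grid": list(s_ratio_grid),
        "s_a_levels": list(s_a_levels), "n": n, "reps": reps,
        "methods": [m.name for m in methods], "m_a": m_a,
        "bootstrap_reps": bootstrap_reps, "seed": seed, "versions": _versions(),
    }
    return ExperimentReport("variance_sweep", cells, summary, tables, manifest)


def run_significance_panel(
    d: int = 99,
    families: Sequence[Family] = (Family.NORMAL, Family.LOGNORMAL),
    methods: Sequence[FCMethod | str] | None = None,
    tests: Sequence[GroupTest | str] = (GroupTest.WILCOXON_MWU, GroupTest.T_TEST),
    *,
    n_a: int = 50,
    n_b: int = 50,
    ratio_range: tuple[float, float] = (1.0 / 3.0, 3.0),
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
    crossover_min_bits: float = 0.1,
    seed: int = 0,
) -> ExperimentReport:
    """Effect-size/significance concordance on d-variable panels.

    For each family a panel of ``d`` variables is generated with randomly
    drawn locations, spreads, and true ratios; every estimator is paired
    with the Wilcoxon and t tests and summarised by the Spearman correlation
    of |log2 FC| with -log10 p (and with |log2 fc_true|).  Variables whose
    regulation direction flips between LOG_OF_MEANS and MEAN_OF_LOGS (both
    |log2 FC| above ``crossover_min_bits``) are listed as crossovers.
    Variables containing non-positive draws cannot enter any log-ratio
    estimator and are excluded (reported in the ``excluded`` table).
    """
    methods = [FCMethod(m) for m in (methods or list(FCMethod))]
    tests = [GroupTest(t) for t in tests]
    family_seeds = child_seeds(seed, 2 * len(list(families)))

    rows = []
    excluded_rows = []
    for fi, family in enumerate(families):
        panel = generate_panel(
            PanelSpec(
                d=d, family=Family(family), ratio_range=ratio_range,
                n_a=n_a, n_b=n_b, seed=int(family_seeds[2 * fi]),
            )
        )
        method_seeds = child_seeds(int(family_seeds[2 * fi + 1]), panel.d)
        for vi, (sample, vspec) in enumerate(zip(panel.samples, panel.specs)):
            if sample.contains_nonpositive:
                excluded_rows.append(
                    {
                        "family": Family(family).value,
                        "variable_id": sample.variable_id,
                        "reason": "contains non-positive values",
                    }
                )
                continue
            test_results = [compare_groups(sample, t) for t in tests]
            fc_rows = _method_rows(
                sample, methods, bootstrap_reps=bootstrap_reps,
                seed=int(method_seeds[vi]), with_error=False,
            )
            for row in fc_rows:
                for tr in test_results:
                    rows.append(
                        {
                            "family": Family(family).value,
                            "variable_id": sample.variable_id,
                            "fc_true": sample.fc_true,
                            "m_a": vspec.m_a, "s_a": vspec.s_a, "s_b": vspec.s_b,
                            "seed": vspec.seed,
                            "method": row["method"],
                            "log_ratio": row["log_ratio"], "fc": row["fc"],
                            "failed": row["failed"],
                            "test": tr.test.name,
                            "p_value": tr.p_value,
                            "neg_log10_p": tr.neg_log10_p,
                        }
                    )

    cells = pd.DataFrame(rows)
    corr_rows = []
    if not cells.empty:
        for (family, method, test), grp in cells.groupby(
            ["family", "method", "test"], sort=False
        ):
            ok = grp[~grp["failed"]]
            abs_lr = np.abs(ok["log_ratio"].to_numpy())
            rho_p, pval_p = _safe_spearman(abs_lr, ok["neg_log10_p"].to_numpy())
            rho_t, pval_t = _safe_spearman(
                abs_lr, np.abs(np.log2(ok["fc_true"].to_numpy()))
            )
            corr_rows.append(
                {
                    "family": family, "method": method, "test": test,
                    "rho_significance": rho_p, "p_rho_significance": pval_p,
                    "rho_true_fc": rho_t, "p_rho_true_fc": pval_t,
                    "n_variables": len(ok),
                }
            )
    summary = pd.DataFrame(corr_rows)

    crossover_rows = []
    if not cells.empty and {FCMethod.LOG_OF_MEANS, FCMethod.MEAN_OF_LOGS} <= set(
        methods
    ):
        one_test = cells[cells["test"] == tests[0].name]
        piv = one_test.pivot_table(
            index=["family", "variable_id", "fc_true"],
            columns="method",
            values="log_ratio",
        ).reset_index()
        lom, mol = FCMethod.LOG_OF_MEANS.name, FCMethod.MEAN_OF_LOGS.name
        if lom in piv and mol in piv:
            flip = (
                (np.sign(piv[lom]) != np.sign(piv[mol]))
                & (piv[lom].abs() > crossover_min_bits)
                & (piv[mol].abs() > crossover_min_bits)
            )
            for _, r in piv[flip].iterrows():
                crossover_rows.append(
                    {
                        "family": r["family"], "variable_id": r["variable_id"],
                        "fc_true": r["fc_true"],
                        "log_ratio_log_of_means": r[lom],
                        "log_ratio_mean_of_logs": r[mol],
                    }
                )
    tables = {
        "crossovers": pd.DataFrame(
            crossover_rows,
            columns=[
                "family", "variable_id", "fc_true",
                "log_ratio_log_of_means", "log_ratio_mean_of_logs",
            ],
        ),
        "excluded": pd.DataFrame(
            excluded_rows, columns=["family", "variable_id", "reason"]
        ),
    }

    manifest = {
        "experiment": "significance_panel",
        "d": d, "families": [Family(f).value for f in families],
        "methods": [m.name for m in methods], "tests": [t.name for t in tests],
        "n_a": n_a, "n_b": n_b, "ratio_range": list(ratio_range),
        "bootstrap_reps": bootstrap_reps,
        "crossover_min_bits": crossover_min_bits, "seed": seed,
        "versions": _versions(),
    }
    return ExperimentReport("significance_panel", cells, summary, tables, manifest)


def run_permutation_stress(
    matrix: pd.DataFrame,
    labels: pd.Series,
    *,
    permute: bool = True,
    methods: Sequence[FCMethod | str] | None = None,
    tests: Sequence[GroupTest | str] = (GroupTest.WILCOXON_MWU, GroupTest.T_TEST),
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
) -> ExperimentReport:
    """Estimator/test concordance on a globally permuted expression matrix.

    All matrix entries are shuffled across both axes (seeded), so every
    variable's "groups" are random draws from the heavily mixed pooled
    distribution.  Reports the pooled skewness/kurtosis, the method x method
    Spearman correlation of |log2 FC| across variables, and each method's
    correlation with the significance of both tests.  ``permute=False``
    analyses the matrix as given (useful as the unpermuted baseline).
    """
    from .io import samples_from_matrix  # local import to avoid a cycle

    methods = [FCMethod(m) for m in (methods or list(FCMethod))]
    tests = [GroupTest(t) for t in tests]
    analysed = permute_matrix(matrix, seed) if permute else matrix
    samples = samples_from_matrix(analysed, labels)
    method_seeds = child_seeds(seed + 1, len(samples))

    rows = []
    excluded_rows = []
    for vi, sample in enumerate(samples):
        if sample.contains_nonpositive:
            excluded_rows.append(
                {"variable_id": sample.variable_id,
                 "reason": "contains non-positive values"}
            )
            continue
        test_results = [compare_groups(sample, t) for t in tests]
        for row in _method_rows(
            sample, methods, bootstrap_reps=bootstrap_reps,
            seed=int(method_seeds[vi]), with_error=False,
        ):
            for tr in test_results:
                rows.append(
                    {
                        "variable_id": sample.variable_id,
                        "method": row["method"],
                        "log_ratio": row["log_ratio"], "fc": row["fc"],
                        "failed": row["failed"],
                        "test": tr.test.name, "p_value": tr.p_value,
                        "neg_log10_p": tr.neg_log10_p,
                    }
                )
    cells = pd.DataFrame(rows)

    pooled = analysed.to_numpy().ravel()
    moments = pd.DataFrame(
        [
            {
                "n_values": pooled.size,
                "skewness": float(sps.skew(pooled)),
                "excess_kurtosis": float(sps.kurtosis(pooled)),
                "permuted": permute,
            }
        ]
    )

    method_corr = pd.DataFrame()
    vs_test_rows = []
    if not cells.empty:
        abs_lr = (
            cells[cells["test"] == tests[0].name]
            .pivot_table(index="variable_id", columns="method", values="log_ratio")
            .abs()
        )
        method_corr = abs_lr.corr(method="spearman")
        for test in tests:
            sub = cells[cells["test"] == test.name]
            sig = sub.pivot_table(
                index="variable_id", columns="method", values="neg_log10_p"
            )
            for m in abs_lr.columns:
                rho, p = _safe_spearman(
                    abs_lr[m].to_numpy(), sig[m].reindex(abs_lr.index).to_numpy()
                )
                vs_test_rows.append(
                    {"method": m, "test": test.name, "rho": rho, "p_value": p,
                     "n_variables": int(abs_lr[m].notna().sum())}
                )
    summary = pd.DataFrame(vs_test_rows)

    tables = {
        "pooled_moments": moments,
        "method_correlations": method_corr,
        "excluded": pd.DataFrame(excluded_rows, columns=["variable_id", "reason"]),
    }
    manifest = {
        "experiment": "permutation_stress",
        "shape": list(matrix.shape), "permute": permute,
        "methods": [m.name for m in methods], "tests": [t.name for t in tests],
        "bootstrap_reps": bootstrap_reps, "seed": seed, "versions": _versions(),
    }
    return ExperimentReport("permutation_stress", cells, summary, tables, manifest)
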