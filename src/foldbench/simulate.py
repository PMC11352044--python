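"""Synthetic two-group data with known true fold changes.

Generators for the benchmark conditions: a single variable drawn from one of
five distribution families (identity, uniform, normal, log-normal, and the
mixed variants), a variance-ratio sweep over log-normal data, and
matrix-shaped panels of many variables with per-variable parameters drawn
from predefined ranges.

The log-normal family is parameterised on the natural-log scale:
``a ~ LogNormal(ln m_a, s_a)`` and ``b ~ LogNormal(ln fc + ln m_a, s_b)``.
A consequence worth keeping in mind is that ``fc_true`` is then the ratio of
the groups' *medians* (equivalently geometric means), not of their
arithmetic means — the arithmetic mean of a log-normal exceeds its median by
``exp(s**2 / 2)``, which is exactly what makes the estimator comparison
non-trivial when ``s_a != s_b``.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .core import GroupedSample, InputError

__all__ = [
    "Family",
    "SimSpec",
    "PanelSpec",
    "VariablePanel",
    "generate",
    "generate_sweep",
    "generate_panel",
    "permute_matrix",
    "DEFAULT_FC_GRID",
    "DEFAULT_S_RATIO_GRID",
    "DEFAULT_S_A_LEVELS",
]


class Family(str, enum.Enum):
    IDENTITY = "identity"
    UNIFORM = "uniform"
    NORMAL = "normal"
    LOGNORMAL = "lognormal"
    MIXED_NORMAL_LOGNORMAL = "mixed_normal_lognormal"  # a normal, b log-normal
    MIXED_LOGNORMAL_NORMAL = "mixed_lognormal_normal"  # a log-normal, b normal
    MIXED = "mixed"  # per-element random mixture of the four base families


#: The four base families a MIXED group draws its elements from.
_BASE_FAMILIES = (Family.IDENTITY, Family.UNIFORM, Family.NORMAL, Family.LOGNORMAL)

#: Variance-ratio sweep defaults: 20 evenly spaced fold changes spanning
#: [0.1, 6], treatment/reference spread ratios, and reference spread levels.
DEFAULT_FC_GRID: tuple[float, ...] = tuple(np.linspace(0.1, 6.0, 20))
DEFAULT_S_RATIO_GRID: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 4.0, 8.0)
DEFAULT_S_A_LEVELS: tuple[float, ...] = (0.1, 1.0)


@dataclass(frozen=True)
class SimSpec:
    """Parameters for one generated variable.

    ``s_a``/``s_b`` are standard deviations in measurement units for the
    normal family and on the natural-log scale for the log-normal family;
    identity and uniform ignore them.
    """

    family: Family
    m_a: float = 100.0
    fc_true: float = 1.0
    s_a: float = 0.0
    s_b: float = 0.0
    n_a: int = 10
    n_b: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if not (self.fc_true > 0 and math.isfinite(self.fc_true)):
            raise InputError(f"fc_true must be a positive real, got {self.fc_true}")
        if self.m_a <= 0:
            raise InputError(f"m_a must be positive, got {self.m_a}")
        if self.n_a < 1 or self.n_b < 1:
            raise InputError("group sizes n_a and n_b must be >= 1")
        if self.s_a < 0 or self.s_b < 0:
            raise InputError("spread parameters must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["family"] = self.family.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimSpec":
        return cls(**d)


def _draw_group(
    rng: np.random.Generator,
    family: Family,
    n: int,
    m: float,
    s: float,
) -> np.ndarray:
    """Draw one group with location m (family-specific meaning) and spread s."""
    if family is Family.IDENTITY:
        return np.full(n, m, dtype=float)
    if family is Family.UNIFORM:
        return rng.uniform(0.0, 1.0, n) * m
    if family is Family.NORMAL:
        return rng.normal(m, s, n)
    if family is Family.LOGNORMAL:
        return rng.lognormal(math.log(m), s, n)
    if family is Family.MIXED:
        fams = rng.integers(0, len(_BASE_FAMILIES), n)
        out = np.empty(n, dtype=float)
        for idx, fam in enumerate(_BASE_FAMILIES):
            mask = fams == idx
            out[mask] = _draw_group(rng, fam, int(mask.sum()), m, s)
        return out
    raise InputError(f"family {family} has no single-group draw")


def generate(spec: SimSpec) -> GroupedSample:
    """Generate one variable's reference/treatment sample.

    Bit-identical for identical specs (including seed).  Reference values are
    drawn before treatment values from a single seeded stream.  Non-positive
    draws (possible for the normal family) are *not* truncated; the returned
    sample simply reports ``contains_nonpositive`` and downstream log-domain
    methods will reject it.
    """
    rng = np.random.default_rng(spec.seed)
    fam = spec.family
    m_b = spec.fc_true * spec.m_a

    if fam is Family.MIXED_NORMAL_LOGNORMAL:
        a = _draw_group(rng, Family.NORMAL, spec.n_a, spec.m_a, spec.s_a)
        b = _draw_group(rng, Family.LOGNORMAL, spec.n_b, m_b, spec.s_b)
    elif fam is Family.MIXED_LOGNORMAL_NORMAL:
        a = _draw_group(rng, Family.LOGNORMAL, spec.n_a, spec.m_a, spec.s_a)
        b = _draw_group(rng, Family.NORMAL, spec.n_b, m_b, spec.s_b)
    else:
        a = _draw_group(rng, fam, spec.n_a, spec.m_a, spec.s_a)
        b = _draw_group(rng, fam, spec.n_b, m_b, spec.s_b)

    return GroupedSample(
        a=a, b=b, variable_id=f"{fam.value}", fc_true=spec.fc_true, validate=False
    )


def child_seeds(seed: int | None, n: int) -> np.ndarray:
    """n reproducible child seeds (< 2**31) derived from one parent seed."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def generate_sweep(
    fc_grid: Sequence[float] | None = None,
    s_ratio_grid: Sequence[float] = DEFAULT_S_RATIO_GRID,
    s_a_levels: Sequence[float] = DEFAULT_S_A_LEVELS,
    n: int = 10_000,
    seed: int | None = 0,
    *,
    m_a: float = 100.0,
) -> Iterator[tuple[SimSpec, GroupedSample]]:
    """Log-normal variance-ratio sweep: one sample per (s_a, ratio, fc) cell.

    Each cell draws ``a ~ LogNormal(ln m_a, s_a)`` and
    ``b ~ LogNormal(ln fc + ln m_a, ratio * s_a)``; the whole sweep is
    reproducible from ``seed``.
    """
    fc_grid = DEFAULT_FC_GRID if fc_grid is None else tuple(float(f) for f in fc_grid)
    if not (len(fc_grid) and len(s_ratio_grid) and len(s_a_levels)):
        raise InputError("sweep grids must be non-empty")
    if any(fc <= 0 for fc in fc_grid):
        raise InputError("fc grid values must be positive")
    n_cells = len(s_a_levels) * len(s_ratio_grid) * len(fc_grid)
    seeds = iter(child_seeds(seed, n_cells))
    for s_a in s_a_levels:
        for ratio in s_ratio_grid:
            for fc in fc_grid:
                spec = SimSpec(
                    family=Family.LOGNORMAL,
                    m_a=m_a,
                    fc_true=float(fc),
                    s_a=float(s_a),
                    s_b=float(ratio) * float(s_a),
                    n_a=n,
                    n_b=n,
                    seed=int(next(seeds)),
                )
                yield spec, generate(spec)


@dataclass(frozen=True)
class PanelSpec:
    """A d-variable panel with per-variable parameters drawn from ranges.

    ``family`` fixes the distribution of every variable; ``None`` picks
    normal or log-normal per variable at random (the mixed multi-omics
    shape).  ``ratio_range`` bounds the true fold changes; draws are
    log-uniform so up- and down-regulation are symmetric in fold units.
    Location/spread ranges follow the two families' conventions: log-normal
    m ~ U(30, 40) with s ~ U(1, 5) on the log scale, normal m ~ U(500, 600)
    with s ~ U(20, 200) in measurement units.
    """

    d: int = 99
    family: Family | None = Family.LOGNORMAL
    ratio_range: tuple[float, float] = (1.0 / 3.0, 3.0)
    lognormal_m_range: tuple[float, float] = (30.0, 40.0)
    lognormal_s_range: tuple[float, float] = (1.0, 5.0)
    normal_m_range: tuple[float, float] = (500.0, 600.0)
    normal_s_range: tuple[float, float] = (20.0, 200.0)
    n_a: int = 50
    n_b: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise InputError("panel must contain at least one variable")
        if self.n_a < 1 or self.n_b < 1:
            raise InputError("group sizes must be >= 1")
        lo, hi = self.ratio_range
        if not (0 < lo <= hi):
            raise InputError(f"invalid ratio_range {self.ratio_range}")
        if self.family is not None:
            fam = Family(self.family)
            if fam not in (Family.NORMAL, Family.LOGNORMAL):
                raise InputError(
                    "panel variables must be normal, log-normal, or a mix of the two"
                )
            object.__setattr__(self, "family", fam)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["family"] = None if self.family is None else self.family.value
        return d


@dataclass
class VariablePanel:
    """d generated variables sharing group sizes, with known fc_true each."""

    samples: list[GroupedSample]
    specs: list[SimSpec]
    n_a: int
    n_b: int
    panel_spec: PanelSpec | None = None

    @property
    def d(self) -> int:
        return len(self.samples)

    @property
    def variable_ids(self) -> list[str]:
        return [s.variable_id for s in self.samples]

    @property
    def fc_true(self) -> np.ndarray:
        return np.array([s.fc_true for s in self.samples], dtype=float)

    def to_matrix(self) -> tuple[pd.DataFrame, pd.Series]:
        """Variables x samples matrix plus a sample -> group label series."""
        sample_ids = [f"ref_{i + 1:03d}" for i in range(self.n_a)] + [
            f"trt_{i + 1:03d}" for i in range(self.n_b)
        ]
        rows = [np.concatenate([s.a, s.b]) for s in self.samples]
        matrix = pd.DataFrame(rows, index=self.variable_ids, columns=sample_ids)
        matrix.index.name = "variable_id"
        labels = pd.Series(
            ["reference"] * self.n_a + ["treatment"] * self.n_b,
            index=sample_ids,
            name="group",
        )
        labels.index.name = "sample_id"
        return matrix, labels

    def specs_json(self) -> str:
        payload = {
            "panel_spec": None if self.panel_spec is None else self.panel_spec.to_dict(),
            "variables": [
                {"variable_id": s.variable_id, "fc_true": s.fc_true, **spec.to_dict()}
                for s, spec in zip(self.samples, self.specs)
            ],
        }
        return json.dumps(payload, indent=2)


def generate_panel(spec: PanelSpec) -> VariablePanel:
    """Draw a panel of d variables; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    var_seeds = child_seeds(spec.seed + 1, spec.d)
    lo, hi = spec.ratio_range
    samples: list[GroupedSample] = []
    specs: list[SimSpec] = []
    for i in range(spec.d):
        fam = spec.family
        if fam is None:
            fam = Family.NORMAL if rng.integers(0, 2) == 0 else Family.LOGNORMAL
        if fam is Family.LOGNORMAL:
            m = rng.uniform(*spec.lognormal_m_range)
            s_a = rng.uniform(*spec.lognormal_s_range)
            s_b = rng.uniform(*spec.lognormal_s_range)
        else:
            m = rng.uniform(*spec.normal_m_range)
            s_a = rng.uniform(*spec.normal_s_range)
            s_b = rng.uniform(*spec.normal_s_range)
        fc = float(2.0 ** rng.uniform(math.log2(lo), math.log2(hi)))
        var_spec = SimSpec(
            family=fam,
            m_a=float(m),
            fc_true=fc,
            s_a=float(s_a),
            s_b=float(s_b),
            n_a=spec.n_a,
            n_b=spec.n_b,
            seed=int(var_seeds[i]),
        )
        sample = generate(var_spec)
        sample.variable_id = f"v{i + 1:03d}_{fam.value}"
        samples.append(sample)
        specs.append(var_spec)
    return VariablePanel(
        samples=samples, specs=specs, n_a=spec.n_a, n_b=spec.n_b, panel_spec=spec
    )


def permute_matrix(
    matrix: pd.DataFrame | np.ndarray, seed: int | None = 0
) -> pd.DataFrame | np.ndarray:
    """Globally shuffle every entry of a rectangular matrix (seeded).

    The flattened values are permuted and reshaped, destroying all
    variable/sample structure while preserving the multiset of values, the
    matrix shape, and hence the pooled distribution's moments exactly.
    """
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if values.size == 0:
        raise InputError("cannot permute an empty matrix")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(values.ravel()).reshape(values.shape)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(shuffled, index=matrix.index, columns=matrix.columns)
    return shuffled
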