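"""Matrix/label file I/O and run configuration.

Expression matrices are plain delimited text with variables as rows: the
first column holds variable ids, the header row holds sample ids.  Group
membership comes from a separate two-column table mapping every sample id to
``reference`` or ``treatment``.  Missing values are not supported — a fold
change is undefined under missingness, so non-numeric cells are a hard
error rather than being imputed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .core import (
    DEFAULT_BOOTSTRAP_REPS,
    FCMethod,
    GroupedSample,
    InputError,
    fc_all_methods,
)
from .simulate import VariablePanel

__all__ = [
    "read_matrix",
    "read_labels",
    "samples_from_matrix",
    "write_panel",
    "fc_table",
    "RunConfig",
]

GROUP_NAMES = ("reference", "treatment")


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample_id -> group table (TSV/CSV, with header)."""
    labels = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if labels.shape[1] < 2:
        raise InputError(
            f"label file {path} must have two columns: sample_id and group"
        )
    labels = labels.iloc[:, :2]
    labels.columns = ["sample_id", "group"]
    if labels["sample_id"].duplicated().any():
        dupes = labels.loc[labels["sample_id"].duplicated(), "sample_id"].tolist()
        raise InputError(f"duplicate sample ids in label file: {dupes}")
    series = labels.set_index("sample_id")["group"].str.strip().str.lower()
    bad = sorted(set(series) - set(GROUP_NAMES))
    if bad:
        raise InputError(
            f"unknown group labels {bad}; expected one of {list(GROUP_NAMES)}"
        )
    return series


def read_matrix(
    path: str | Path, labels_path: str | Path
) -> tuple[pd.DataFrame, pd.Series]:
    """Read and validate a variables x samples matrix with its group labels.

    Raises :class:`InputError` for non-numeric cells, duplicated ids, samples
    missing from the label table, or labels covering fewer than two groups.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if raw.index.duplicated().any():
        raise InputError(
            f"duplicate variable ids: {raw.index[raw.index.duplicated()].tolist()}"
        )
    if raw.columns.duplicated().any():
        raise InputError(
            f"duplicate sample ids: {raw.columns[raw.columns.duplicated()].tolist()}"
        )
    try:
        matrix = raw.astype(float)
    except (TypeError, ValueError) as exc:
        bad_cols = [
            c for c in raw.columns
            if pd.to_numeric(raw[c], errors="coerce").isna().any()
        ]
        raise InputError(
            f"non-numeric cells in matrix columns {bad_cols}"
        ) from exc
    if matrix.isna().any().any():
        raise InputError("matrix contains missing values, which are not supported")

    labels = read_labels(labels_path)
    missing = [s for s in matrix.columns if s not in labels.index]
    if missing:
        raise InputError(f"samples missing from label file: {missing}")
    labels = labels.loc[matrix.columns]
    present = set(labels)
    if len(present) < 2:
        raise InputError(
            f"label file assigns all samples to one group ({sorted(present)}); "
            "need both reference and treatment"
        )
    return matrix, labels


def samples_from_matrix(
    matrix: pd.DataFrame, labels: pd.Series
) -> list[GroupedSample]:
    """Split each matrix row into a reference/treatment GroupedSample."""
    ref_cols = labels.index[labels == "reference"]
    trt_cols = labels.index[labels == "treatment"]
    if len(ref_cols) == 0 or len(trt_cols) == 0:
        raise InputError("both reference and treatment samples are required")
    return [
        GroupedSample(
            a=matrix.loc[vid, ref_cols].to_numpy(dtype=float),
            b=matrix.loc[vid, trt_cols].to_numpy(dtype=float),
            variable_id=str(vid),
        )
        for vid in matrix.index
    ]


def write_panel(panel: VariablePanel, outdir: str | Path, prefix: str = "panel") -> dict:
    """Serialise a panel: matrix TSV, label TSV, and a sidecar spec JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, labels = panel.to_matrix()
    paths = {
        "matrix": outdir / f"{prefix}_matrix.tsv",
        "labels": outdir / f"{prefix}_labels.tsv",
        "specs": outdir / f"{prefix}_specs.json",
    }
    matrix.to_csv(paths["matrix"], sep="\t")
    labels.to_frame().to_csv(paths["labels"], sep="\t")
    paths["specs"].write_text(panel.specs_json())
    return paths


def fc_table(
    matrix: pd.DataFrame,
    labels: pd.Series,
    methods: Sequence[FCMethod | str] | None = None,
    *,
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | None = 0,
) -> pd.DataFrame:
    """All-methods fold-change table for a matrix: one row per variable x method."""
    rows = []
    for sample in samples_from_matrix(matrix, labels):
        for res in fc_all_methods(
            sample, methods, bootstrap_reps=bootstrap_reps, seed=seed
        ):
            rows.append(
                {
                    "variable_id": res.variable_id,
                    "method": res.method.name,
                    "log_ratio": res.log_ratio,
                    "fc": res.fc,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Serialisable description of one experiment run.

    Round-trips exactly through JSON or YAML: ``RunConfig.load(path)`` of a
    saved config compares equal to the original.
    """

    experiment: str = "fc"
    seed: int = 0
    out: str = "results"
    methods: list[str] = field(default_factory=lambda: [m.name for m in FCMethod])
    tests: list[str] = field(default_factory=lambda: ["WILCOXON_MWU", "T_TEST"])
    plot: bool = False
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yaml", ".yml")
            else json.loads(text)
        )
        return cls.from_dict(data)
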