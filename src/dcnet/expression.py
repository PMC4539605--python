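"""Expression-matrix container and TSV I/O.

The central data structure is :class:`ExpressionMatrix`: a genes x samples
table of log-intensities with a condition label and a time (minutes) attached
to every sample column.  A matrix may hold one condition or several; all
per-condition operations group columns by the condition label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["ExpressionMatrix", "ProbeAnnotation", "read_expression_tsv"]


@dataclass
class ExpressionMatrix:
    """Genes x samples log-intensity matrix with sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probe/gene id, columns by sample id.  Missing
        measurements are NaN.
    condition : array-like of str
        Condition label per column.
    time : array-like of float
        Sampling time in minutes per column; strictly increasing within
        each condition.
    """

    values: pd.DataFrame
    condition: np.ndarray
    time: np.ndarray

    def __post_init__(self) -> None:
        self.condition = np.asarray(self.condition, dtype=object)
        self.time = np.asarray(self.time, dtype=float)
        n = self.values.shape[1]
        if len(self.condition) != n or len(self.time) != n:
            raise ValueError(
                "column count must equal len(condition) and len(time)"
            )
        if self.values.index.has_duplicates:
            raise ValueError("row ids must be unique")
        for cond in self.conditions:
            t = self.time[self.condition == cond]
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"times within condition {cond!r} must be strictly increasing"
                )

    # -- basic views ----------------------------------------------------
    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.condition:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_condition(self, cond: str) -> "ExpressionMatrix":
        """Return the single-condition sub-matrix for ``cond``."""
        mask = self.condition == cond
        if not mask.any():
            raise KeyError(f"no samples with condition {cond!r}")
        return ExpressionMatrix(
            self.values.loc[:, mask], self.condition[mask], self.time[mask]
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """New matrix with the same sample metadata but different values."""
        if values.shape[1] != self.n_samples:
            raise ValueError("sample metadata does not match new values")
        return ExpressionMatrix(values, self.condition.copy(), self.time.copy())

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the matrix as TSV (NaN as empty field); optionally write the
        sample sidecar YAML mapping sample id -> {condition, time_minutes}."""
        self.values.to_csv(path, sep="\t", na_rep="", index_label="id")
        if sidecar is not None:
            meta = {
                str(s): {"condition": str(c), "time_minutes": float(t)}
                for s, c, t in zip(self.values.columns, self.condition, self.time)
            }
            Path(sidecar).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_expression_tsv(path: str | Path, sidecar: str | Path) -> ExpressionMatrix:
    """Read an expression TSV plus its sample sidecar.

    The TSV's first column is the probe/gene id; the header row holds sample
    ids.  Missing values are empty fields or ``NA``.  The sidecar is a YAML
    mapping ``sample_id -> {condition, time_minutes}``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    meta = yaml.safe_load(Path(sidecar).read_text())
    cond, time = [], []
    for s in df.columns:
        if s not in meta:
            raise KeyError(f"sample {s!r} missing from sidecar {sidecar}")
        cond.append(str(meta[s]["condition"]))
        time.append(float(meta[s]["time_minutes"]))
    # order columns by (condition first-appearance, time) so the
    # strictly-increasing-time invariant holds for well-formed inputs
    order = sorted(
        range(len(df.columns)), key=lambda i: (cond[i], time[i])
    )
    df = df.iloc[:, order]
    return ExpressionMatrix(
        df, [cond[i] for i in order], [time[i] for i in order]
    )


@dataclass
class ProbeAnnotation:
    """Many-probes-to-one-gene mapping; unmapped probes are non-annotated."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe, gene in self.mapping.items():
            if not gene:
                raise ValueError(f"empty gene id for probe {probe!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeAnnotation":
        df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"],
                         dtype=str, comment="#")
        df = df.dropna()
        return cls(dict(zip(df["probe"], df["gene"])))

    def gene_of(self, probe: str) -> str | None:
        return self.mapping.get(probe)

    def __len__(self) -> int:
        return len(self.mapping)
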