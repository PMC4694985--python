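"""Expression matrices: reading, probe collapsing, quantile normalization.

Matrices are genes × samples tables of strictly positive linear-scale
intensities (microarray-style).  Probe-level input is collapsed to gene
level by averaging probes that map to the same gene symbol.  Case samples
are quantile-normalized jointly with each control set so that the
case-to-normal ratio downstream is free of per-sample scale effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "ControlSet",
    "read_expression",
    "read_probe_map",
    "write_expression",
    "quantile_normalize",
    "quantile_normalize_frame",
    "join_case_control",
]

log = logging.getLogger(__name__)

#: Floor on linear intensities keeping log-ratios finite.
INTENSITY_FLOOR = 1e-6


@dataclass
class ExpressionMatrix:
    """Genes × samples grid of positive linear intensities.

    ``data`` is a DataFrame indexed by upper-case gene symbol with sample
    ids as columns; ``sample_labels`` maps each sample id to its role,
    ``"case"`` or ``"control"``.
    """

    data: pd.DataFrame
    sample_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols after collapsing: {dupes[:5]}")
        if not self.sample_labels:
            self.sample_labels = {s: "case" for s in self.data.columns}
        unknown = set(self.sample_labels.values()) - {"case", "control"}
        if unknown:
            raise ValueError(f"unknown sample roles: {sorted(unknown)}")
        if (self.data.to_numpy() <= 0).any():
            raise ValueError("expression values must be positive; clamp to a floor first")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_role(self, role: str) -> "ExpressionMatrix":
        cols = [s for s in self.samples if self.sample_labels.get(s) == role]
        return ExpressionMatrix(
            self.data[cols].copy(), {s: role for s in cols}
        )


@dataclass
class ControlSet:
    """A normal-tissue reference panel used for CNR normalization."""

    control_id: str
    matrix: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError(
                f"control set {self.control_id!r} needs >=2 samples for a mean "
                f"and dispersion, got {self.n_samples}"
            )
        self.matrix.sample_labels = {s: "control" for s in self.matrix.samples}

    @property
    def n_samples(self) -> int:
        return len(self.matrix.samples)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``probe<TAB>gene_symbol`` → probe-to-symbol map."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"probe map line {lineno}: expected 2 fields")
            mapping[fields[0]] = fields[1].upper()
    return mapping


def read_expression(
    path: str | Path,
    probe_map: str | Path | Mapping[str, str] | None = None,
    floor: float = INTENSITY_FLOOR,
    role: str = "case",
) -> ExpressionMatrix:
    """Read a tab-delimited matrix (first column probe/gene id, header of
    sample ids), optionally collapse probes to genes, clamp to a floor.

    Probes absent from ``probe_map`` are dropped (count logged); multiple
    probes for one gene are collapsed by their arithmetic mean.  Values at
    or below ``floor`` are clamped to ``floor`` so later log-ratios stay
    finite.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df[df.isna().any(axis=1)].index[:3].tolist()
        raise ValueError(f"ragged or missing values in rows {bad} of {path}")
    df.index = df.index.astype(str)
    if probe_map is not None:
        mapping = (
            dict(probe_map)
            if isinstance(probe_map, Mapping)
            else read_probe_map(probe_map)
        )
        mapped = df.index.map(mapping.get)
        n_unmapped = int(mapped.isna().sum())
        if n_unmapped == len(df):
            raise ValueError("no probe mapped to a gene symbol")
        if n_unmapped:
            log.info("dropping %d unmapped probes of %d", n_unmapped, len(df))
        df = df[~mapped.isna()]
        df.index = mapped[~mapped.isna()]
        df = df.groupby(level=0, sort=True).mean()
    else:
        df.index = df.index.str.upper()
        if df.index.has_duplicates:
            df = df.groupby(level=0, sort=True).mean()
    df = df.clip(lower=floor)
    return ExpressionMatrix(df, {s: role for s in df.columns})


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the columns of a genes × samples DataFrame.

    Every output column carries the identical empirical distribution: the
    vector of row-wise means of the per-column sorted values.  Tied values
    within a column receive the mean of the reference values at their tied
    ranks.
    """
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    X = df.to_numpy(dtype=float)
    n = X.shape[0]
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        col = np.empty(n)
        col[order] = reference
        # average the reference over groups of tied input values
        ranks = rankdata(X[:, j], method="dense")
        sums = np.bincount(ranks, weights=col)
        counts = np.bincount(ranks)
        with np.errstate(invalid="ignore"):
            means = sums / np.maximum(counts, 1)
        out[:, j] = means[ranks]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize an :class:`ExpressionMatrix` (labels preserved)."""
    return ExpressionMatrix(
        quantile_normalize_frame(matrix.data), dict(matrix.sample_labels)
    )


def join_case_control(
    cases: ExpressionMatrix, control: ControlSet
) -> ExpressionMatrix:
    """Inner-join cases with a control set on gene symbol.

    Unmatched genes are dropped with a logged count; an empty intersection
    is an error.  Sample labels record which columns are cases and which
    are controls.
    """
    shared = cases.data.index.intersection(control.matrix.data.index)
    if len(shared) == 0:
        raise ValueError(
            f"no shared genes between cases and control set {control.control_id!r}"
        )
    n_dropped = (len(cases.data) - len(shared)) + (len(control.matrix.data) - len(shared))
    if n_dropped:
        log.info(
            "gene-symbol join with %s: %d genes shared, %d dropped",
            control.control_id, len(shared), n_dropped,
        )
    joint = pd.concat(
        [cases.data.loc[shared], control.matrix.data.loc[shared]], axis=1
    )
    labels = {s: "case" for s in cases.samples}
    labels.update({s: "control" for s in control.matrix.samples})
    return ExpressionMatrix(joint, labels)
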