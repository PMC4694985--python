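"""Pearson correlation screen of pathway activation against drug IC50.

For every pathway, PAS values across cell lines are correlated with the
corresponding IC50 values (Pearson product-moment r with the two-sided
t-transform p-value, df = n - 2).  Pathways with p below the significance
threshold are kept, with the sign of r recorded: a positive sign means a
more active pathway goes with a higher IC50 (a less effective drug), a
negative sign means activation accompanies drug sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pas import PASProfile

__all__ = [
    "CorrelationRecord",
    "correlate_pas_ic50",
    "screen_pathways",
    "records_to_frame",
    "write_records",
    "read_records",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationRecord:
    """Pearson association of one pathway with one drug's IC50."""

    pathway_id: str
    drug: str
    control_id: str
    dataset_id: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("Pearson record needs n >= 3 cell lines")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("|r| must be <= 1")

    @property
    def sign(self) -> str:
        return "+" if self.r > 0 else "-"


def correlate_pas_ic50(
    pas_by_line: Sequence[float], ic50_by_line: Sequence[float]
) -> tuple[float, float, int]:
    """Pearson r, two-sided p and n for aligned PAS/IC50 vectors.

    Pairs with a missing (NaN) IC50 — censored measurements — are dropped
    pairwise.  Fewer than 3 complete pairs is an error; zero variance in
    either vector leaves r undefined and is also an error (callers skip
    such pathways).
    """
    pas = np.asarray(pas_by_line, dtype=float)
    ic50 = np.asarray(ic50_by_line, dtype=float)
    if pas.shape != ic50.shape:
        raise ValueError("PAS and IC50 vectors must be aligned")
    keep = ~(np.isnan(pas) | np.isnan(ic50))
    pas, ic50 = pas[keep], ic50[keep]
    n = int(pas.size)
    if n < 3:
        raise ValueError(f"need >=3 complete (PAS, IC50) pairs, got {n}")
    if np.ptp(pas) == 0 or np.ptp(ic50) == 0:
        raise ValueError("zero variance: Pearson r undefined")
    r, p = stats.pearsonr(pas, ic50)
    return float(r), float(p), n


def screen_pathways(
    pas_profile: PASProfile,
    ic50_by_line: pd.Series,
    drug: str,
    dataset_id: str,
    alpha: float = 0.05,
    log10_ic50: bool = False,
    bh_correct: bool = False,
) -> list[CorrelationRecord]:
    """Correlate every pathway of a PAS profile against one drug's IC50s.

    Parameters
    ----------
    pas_profile
        Pathways × cell-lines PAS matrix (one control set).
    ic50_by_line
        IC50 per cell line, indexed by cell-line id; censored values as NaN.
    alpha
        Raw-p significance threshold (records with p >= alpha discarded).
    log10_ic50
        Correlate against log10(IC50) instead of the raw scale.
    bh_correct
        Apply Benjamini–Hochberg correction across the profile's pathways
        before thresholding.

    Pathways with constant PAS (or too few complete pairs) are skipped with
    a log message.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    shared = [s for s in pas_profile.samples if s in ic50_by_line.index]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} cell lines shared between PAS profile and "
            f"IC50 table for drug {drug!r}"
        )
    ic50 = ic50_by_line.loc[shared].to_numpy(dtype=float)
    if log10_ic50:
        with np.errstate(invalid="ignore"):
            ic50 = np.log10(ic50)
    tested: list[tuple[str, float, float, int]] = []
    for pathway_id, row in pas_profile.data[shared].iterrows():
        try:
            r, p, n = correlate_pas_ic50(row.to_numpy(), ic50)
        except ValueError as exc:
            log.debug("skipping %s for %s: %s", pathway_id, drug, exc)
            continue
        tested.append((pathway_id, r, p, n))
    if bh_correct and tested:
        from statsmodels.stats.multitest import multipletests

        padj = multipletests([t[2] for t in tested], method="fdr_bh")[1]
        tested = [(pid, r, float(pa), n) for (pid, r, _, n), pa in zip(tested, padj)]
    return [
        CorrelationRecord(pid, drug, pas_profile.control_id, dataset_id, r, p, n)
        for pid, r, p, n in tested
        if p < alpha
    ]


def records_to_frame(records: Iterable[CorrelationRecord]) -> pd.DataFrame:
    rows = [
        {
            "pathway_id": rec.pathway_id,
            "drug": rec.drug,
            "dataset_id": rec.dataset_id,
            "control_id": rec.control_id,
            "n": rec.n,
            "r": rec.r,
            "p": rec.p,
            "sign": rec.sign,
        }
        for rec in records
    ]
    return pd.DataFrame(
        rows,
        columns=["pathway_id", "drug", "dataset_id", "control_id", "n", "r", "p", "sign"],
    )


def write_records(records: Iterable[CorrelationRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_records(path: str | Path) -> list[CorrelationRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CorrelationRecord(
            row.pathway_id, row.drug, str(row.control_id), str(row.dataset_id),
            float(row.r), float(row.p), int(row.n),
        )
        for row in df.itertuples()
    ]
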