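"""Cross-dataset consensus of drug-sensitivity-linked pathways.

Because pathway scores are normalized against several alternative control
panels, a pathway's association with a drug is first aggregated *within* a
dataset: the support is the number of control sets under which the pathway
passed the significance screen, split by the sign of the correlation.
Pathways supported (with a consistent sign) in two independent datasets —
e.g. an in-house cell-line panel and a public drug-sensitivity screen —
form the consensus; pathways whose sign flips between control sets are set
aside as discordant diagnostics rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .correlation import CorrelationRecord

__all__ = [
    "PathwaySupport",
    "ConsensusRecord",
    "aggregate_over_controls",
    "intersect_datasets",
    "supports_to_frame",
    "consensus_to_frame",
]


@dataclass(frozen=True)
class PathwaySupport:
    """Within-dataset tally of control sets supporting one pathway × drug."""

    pathway_id: str
    drug: str
    dataset_id: str
    n_positive: int
    n_negative: int
    total_controls: int

    @property
    def support(self) -> int:
        return self.n_positive + self.n_negative

    @property
    def sign(self) -> str:
        """'+', '-', or 'discordant' when both signs reached significance."""
        if self.n_positive and self.n_negative:
            return "discordant"
        return "+" if self.n_positive else "-"


@dataclass(frozen=True)
class ConsensusRecord:
    """A pathway significant, with one sign, in every dataset."""

    pathway_id: str
    drug: str
    sign: str
    support: dict[str, int]
    total_controls: dict[str, int]

    def __post_init__(self) -> None:
        for ds, count in self.support.items():
            if count < 1:
                raise ValueError(f"consensus requires support >= 1 in dataset {ds!r}")
            if count > self.total_controls.get(ds, 0):
                raise ValueError("support cannot exceed the number of control sets")


def aggregate_over_controls(
    records: Iterable[CorrelationRecord],
    dataset_id: str,
    total_controls: int | None = None,
) -> list[PathwaySupport]:
    """Tally, per pathway × drug, the control sets significant by sign.

    ``records`` must come from one dataset (checked); ``total_controls``
    defaults to the number of distinct control ids seen in the records.
    Pathways significant under zero control sets are simply absent.
    """
    records = list(records)
    foreign = {r.dataset_id for r in records} - {dataset_id}
    if foreign:
        raise ValueError(f"records from other datasets present: {sorted(foreign)}")
    if total_controls is None:
        total_controls = len({r.control_id for r in records})
    tallies: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        pos, neg = tallies.setdefault((rec.pathway_id, rec.drug), [0, 0])
        if rec.sign == "+":
            tallies[(rec.pathway_id, rec.drug)][0] = pos + 1
        else:
            tallies[(rec.pathway_id, rec.drug)][1] = neg + 1
    return [
        PathwaySupport(pid, drug, dataset_id, pos, neg, total_controls)
        for (pid, drug), (pos, neg) in sorted(tallies.items())
    ]


def intersect_datasets(
    agg_a: Sequence[PathwaySupport],
    agg_b: Sequence[PathwaySupport],
    require_sign_match: bool = True,
    min_support: int = 1,
) -> tuple[list[ConsensusRecord], list[PathwaySupport]]:
    """Intersect two datasets' aggregated significant pathways per drug.

    Returns ``(consensus, discordant)``: pathways supported by at least
    ``min_support`` control sets in *both* datasets with (by default) the
    same sign, and the diagnostics list of entries excluded for sign
    conflicts — either within a dataset (mixed signs across control sets)
    or between the two datasets.

    The operation is symmetric in its two arguments up to which dataset id
    labels which support count.
    """
    by_key_a = {(s.pathway_id, s.drug): s for s in agg_a}
    by_key_b = {(s.pathway_id, s.drug): s for s in agg_b}
    consensus: list[ConsensusRecord] = []
    discordant: list[PathwaySupport] = []
    for key in sorted(set(by_key_a) & set(by_key_b)):
        a, b = by_key_a[key], by_key_b[key]
        if a.support < min_support or b.support < min_support:
            continue
        if a.sign == "discordant" or b.sign == "discordant":
            discordant.extend(s for s in (a, b) if s.sign == "discordant")
            continue
        if require_sign_match and a.sign != b.sign:
            discordant.extend((a, b))
            continue
        sign = a.sign if a.sign == b.sign else f"{a.dataset_id}:{a.sign}/{b.dataset_id}:{b.sign}"
        consensus.append(
            ConsensusRecord(
                pathway_id=a.pathway_id,
                drug=a.drug,
                sign=sign,
                support={a.dataset_id: a.support, b.dataset_id: b.support},
                total_controls={
                    a.dataset_id: a.total_controls,
                    b.dataset_id: b.total_controls,
                },
            )
        )
    return consensus, discordant


def supports_to_frame(supports: Iterable[PathwaySupport]) -> pd.DataFrame:
    rows = [
        {
            "pathway_id": s.pathway_id,
            "drug": s.drug,
            "dataset_id": s.dataset_id,
            "n_positive": s.n_positive,
            "n_negative": s.n_negative,
            "support": s.support,
            "total_controls": s.total_controls,
            "sign": s.sign,
        }
        for s in supports
    ]
    return pd.DataFrame(
        rows,
        columns=["pathway_id", "drug", "dataset_id", "n_positive", "n_negative",
                 "support", "total_controls", "sign"],
    )


def consensus_to_frame(records: Iterable[ConsensusRecord]) -> pd.DataFrame:
    """Tabulate consensus records, one support column per dataset."""
    records = list(records)
    datasets = sorted({ds for rec in records for ds in rec.support})
    rows = []
    for rec in records:
        row = {"drug": rec.drug, "pathway_id": rec.pathway_id, "sign": rec.sign}
        for ds in datasets:
            row[f"support_{ds}"] = rec.support.get(ds, 0)
            row[f"total_{ds}"] = rec.total_controls.get(ds, 0)
        rows.append(row)
    cols = ["drug", "pathway_id", "sign"]
    for ds in datasets:
        cols += [f"support_{ds}", f"total_{ds}"]
    return pd.DataFrame(rows, columns=cols)
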