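"""Model/Results objects tying pathway activation to drug sensitivity.

:class:`PathwayDrugSensitivityModel` is built from per-dataset PAS profiles
(one per normalization control set) and IC50 tables; ``fit()`` runs the
Pearson screen for every (pathway, drug, control set), aggregates support
within each dataset, intersects across datasets, and returns a
:class:`PathwayDrugSensitivityResults` carrying the significant records,
per-dataset support tallies, the consensus list and a printable summary
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import (
    ConsensusRecord,
    PathwaySupport,
    aggregate_over_controls,
    consensus_to_frame,
    intersect_datasets,
    supports_to_frame,
)
from .correlation import CorrelationRecord, records_to_frame, screen_pathways
from .pas import PASProfile

__all__ = ["PathwayDrugSensitivityModel", "PathwayDrugSensitivityResults"]


class PathwayDrugSensitivityModel:
    """Correlation screen of PAS against IC50 across control sets/datasets.

    Parameters
    ----------
    pas_profiles
        ``{dataset_id: [PASProfile, ...]}`` — one profile per control set;
        profile columns are cell-line ids.
    ic50_tables
        ``{dataset_id: DataFrame}`` with columns drug, cell_line, ic50_uM
        and optionally censored (censored IC50s are excluded pairwise).
    drugs
        Restrict the screen to these drugs (default: all drugs present).
    """

    def __init__(
        self,
        pas_profiles: Mapping[str, Sequence[PASProfile]],
        ic50_tables: Mapping[str, pd.DataFrame],
        drugs: Sequence[str] | None = None,
    ) -> None:
        if set(pas_profiles) != set(ic50_tables):
            raise ValueError("pas_profiles and ic50_tables must share dataset ids")
        if not pas_profiles:
            raise ValueError("need at least one dataset")
        self.pas_profiles = {k: list(v) for k, v in pas_profiles.items()}
        self.ic50_tables = {k: v.copy() for k, v in ic50_tables.items()}
        all_drugs = sorted(
            {d for tbl in self.ic50_tables.values() for d in tbl["drug"].unique()}
        )
        self.drugs = list(drugs) if drugs is not None else all_drugs

    @classmethod
    def from_dataframes(
        cls,
        pas_frames: Mapping[str, Mapping[str, pd.DataFrame]],
        ic50_tables: Mapping[str, pd.DataFrame],
        **kwargs,
    ) -> "PathwayDrugSensitivityModel":
        """Build from raw pathways × cell-line DataFrames.

        ``pas_frames`` maps dataset id → {control_id: DataFrame}.
        """
        profiles = {
            ds: [PASProfile(cid, frame) for cid, frame in by_ctrl.items()]
            for ds, by_ctrl in pas_frames.items()
        }
        return cls(profiles, ic50_tables, **kwargs)

    def _ic50_series(self, dataset_id: str, drug: str) -> pd.Series:
        tbl = self.ic50_tables[dataset_id]
        sub = tbl[tbl["drug"] == drug]
        ic50 = sub.set_index("cell_line")["ic50_uM"].astype(float)
        if "censored" in sub.columns:
            ic50 = ic50.mask(sub.set_index("cell_line")["censored"].astype(bool))
        return ic50

    def fit(
        self,
        alpha: float = 0.05,
        log10_ic50: bool = False,
        bh_correct: bool = False,
        require_sign_match: bool = True,
        min_support: int = 1,
    ) -> "PathwayDrugSensitivityResults":
        """Run the screen and the cross-dataset consensus.

        ``alpha`` is the per-correlation significance threshold (raw p by
        default; ``bh_correct`` switches to Benjamini–Hochberg-adjusted p);
        ``min_support`` is the number of control sets a pathway must pass
        under within each dataset to count as dataset-significant.
        """
        records: list[CorrelationRecord] = []
        supports: dict[str, list[PathwaySupport]] = {}
        for ds_id, profiles in self.pas_profiles.items():
            ds_records: list[CorrelationRecord] = []
            for drug in self.drugs:
                ic50 = self._ic50_series(ds_id, drug)
                if ic50.empty:
                    continue
                for profile in profiles:
                    ds_records.extend(
                        screen_pathways(
                            profile, ic50, drug, ds_id,
                            alpha=alpha, log10_ic50=log10_ic50,
                            bh_correct=bh_correct,
                        )
                    )
            records.extend(ds_records)
            supports[ds_id] = aggregate_over_controls(
                ds_records, ds_id, total_controls=len(profiles)
            )
        consensus: list[ConsensusRecord] = []
        discordant: list[PathwaySupport] = []
        ds_ids = list(self.pas_profiles)
        if len(ds_ids) >= 2:
            consensus, discordant = intersect_datasets(
                supports[ds_ids[0]], supports[ds_ids[1]],
                require_sign_match=require_sign_match, min_support=min_support,
            )
            for extra in ds_ids[2:]:
                keep_keys = {(s.pathway_id, s.drug): s for s in supports[extra]
                             if s.support >= min_support and s.sign != "discordant"}
                merged: list[ConsensusRecord] = []
                for rec in consensus:
                    s = keep_keys.get((rec.pathway_id, rec.drug))
                    if s is None or (require_sign_match and s.sign != rec.sign):
                        continue
                    rec.support[extra] = s.support
                    rec.total_controls[extra] = s.total_controls
                    merged.append(rec)
                consensus = merged
        else:
            # single dataset: its supported pathways stand alone
            only = ds_ids[0]
            consensus = [
                ConsensusRecord(
                    s.pathway_id, s.drug, s.sign,
                    {only: s.support}, {only: s.total_controls},
                )
                for s in supports[only]
                if s.support >= min_support and s.sign != "discordant"
            ]
        return PathwayDrugSensitivityResults(
            model=self,
            params={
                "alpha": alpha, "log10_ic50": log10_ic50,
                "bh_correct": bh_correct,
                "require_sign_match": require_sign_match,
                "min_support": min_support,
            },
            records=records,
            supports=supports,
            consensus=consensus,
            discordant=discordant,
        )


@dataclass
class PathwayDrugSensitivityResults:
    """Fitted screen: significant records, support tallies, consensus."""

    model: PathwayDrugSensitivityModel
    params: dict
    records: list[CorrelationRecord]
    supports: dict[str, list[PathwaySupport]]
    consensus: list[ConsensusRecord]
    discordant: list[PathwaySupport] = field(default_factory=list)

    @property
    def records_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    @property
    def consensus_frame(self) -> pd.DataFrame:
        return consensus_to_frame(self.consensus)

    def supports_frame(self, dataset_id: str) -> pd.DataFrame:
        return supports_to_frame(self.supports[dataset_id])

    def consensus_pathways(self, drug: str | None = None) -> list[str]:
        return sorted(
            rec.pathway_id for rec in self.consensus
            if drug is None or rec.drug == drug
        )

    def summary(self) -> str:
        """Printable overview: parameters, per-dataset tallies, consensus."""
        lines = ["Pathway / drug-sensitivity correlation screen", "=" * 46]
        lines.append(
            "alpha={alpha:g}  log10_ic50={log10_ic50}  bh={bh_correct}  "
            "sign_match={require_sign_match}  min_support={min_support}".format(
                **self.params
            )
        )
        for ds_id, sups in self.supports.items():
            n_ctrl = len(self.model.pas_profiles[ds_id])
            lines.append(
                f"dataset {ds_id}: {len(sups)} pathway×drug pairs significant "
                f"under >=1 of {n_ctrl} control sets"
            )
        lines.append(f"consensus records: {len(self.consensus)}  "
                     f"(sign-discordant set aside: {len(self.discordant)})")
        if self.consensus:
            lines.append("")
            lines.append(self.consensus_frame.to_string(index=False))
        return "\n".join(lines)

    def plot_pathway(self, pathway_id: str, drug: str, dataset_id: str,
                     control_index: int = 0, ax=None):
        """Scatter PAS against IC50 for one pathway/drug/dataset."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        profile = self.model.pas_profiles[dataset_id][control_index]
        ic50 = self.model._ic50_series(dataset_id, drug)
        shared = [s for s in profile.samples if s in ic50.index]
        x = profile.data.loc[pathway_id, shared].to_numpy(dtype=float)
        y = ic50.loc[shared].to_numpy(dtype=float)
        ax.scatter(x, y)
        ax.set_xlabel(f"PAS ({pathway_id}, {profile.control_id})")
        ax.set_ylabel(f"IC50 of {drug} (uM)")
        return ax
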