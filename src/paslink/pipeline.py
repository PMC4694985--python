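"""End-to-end pipeline: normalize → PAS → IC50 → correlate → consensus.

Configuration is a YAML file listing the pathway database, one or more
datasets (case matrix, named control-set matrices, and either plate-level
dose–response data or a pre-computed IC50 table) and the analysis
parameters.  Every stage writes its intermediates so any stage can be
re-run from the saved files, and the whole run is deterministic for a
fixed config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .consensus import consensus_to_frame, supports_to_frame
from .correlation import write_records
from .expression import ControlSet, read_expression
from .model import PathwayDrugSensitivityModel, PathwayDrugSensitivityResults
from .pas import PASParams, compute_pas_profile, write_pas_profile
from .pathway_db import read_pathway_db
from .viability import (
    experiments_to_ic50_table,
    read_ic50_table,
    read_plate_csv,
    write_ic50_table,
)

__all__ = ["DatasetConfig", "PipelineConfig", "run_pipeline", "analyze_bundle"]

log = logging.getLogger(__name__)


@dataclass
class DatasetConfig:
    dataset_id: str
    cases: Path
    controls: dict[str, Path]
    plates: Path | None = None
    ic50: Path | None = None
    probe_map: Path | None = None

    def __post_init__(self) -> None:
        if (self.plates is None) == (self.ic50 is None):
            raise ValueError(
                f"dataset {self.dataset_id!r}: provide exactly one of "
                "'plates' (dose-response CSV) or 'ic50' (pre-computed table)"
            )
        if not self.controls:
            raise ValueError(f"dataset {self.dataset_id!r}: needs >=1 control set")


@dataclass
class PipelineConfig:
    """Validated run configuration.

    Thresholds must satisfy 0 < low_thresh < 1 < high_thresh and both
    significance levels lie in (0, 1).
    """

    pathway_db: Path
    datasets: list[DatasetConfig]
    outdir: Path = Path("paslink_out")
    alpha_gene: float = 0.05
    low_thresh: float = 0.66
    high_thresh: float = 1.5
    alpha_corr: float = 0.05
    btif_polarity: str = "perturbed"
    ic50_log_transform: bool = False
    bh_correct: bool = False
    min_support: int = 1
    require_sign_match: bool = True
    quantile: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.low_thresh < 1.0 < self.high_thresh):
            raise ValueError("need 0 < low_thresh < 1 < high_thresh")
        for name in ("alpha_gene", "alpha_corr"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if not self.datasets:
            raise ValueError("config lists no datasets")

    @property
    def pas_params(self) -> PASParams:
        return PASParams(
            alpha_gene=self.alpha_gene,
            low_thresh=self.low_thresh,
            high_thresh=self.high_thresh,
            btif_polarity=self.btif_polarity,
            quantile=self.quantile,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; relative paths resolve against the file."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        base = path.parent

        def _p(value: str | None) -> Path | None:
            return None if value is None else base / value

        datasets = [
            DatasetConfig(
                dataset_id=d["dataset_id"],
                cases=_p(d["cases"]),
                controls={cid: _p(p) for cid, p in d["controls"].items()},
                plates=_p(d.get("plates")),
                ic50=_p(d.get("ic50")),
                probe_map=_p(d.get("probe_map")),
            )
            for d in raw.get("datasets", [])
        ]
        params = dict(raw.get("params", {}))
        params.update(overrides)
        return cls(
            pathway_db=_p(raw["pathway_db"]),
            datasets=datasets,
            seed=int(raw.get("seed", 0)),
            **params,
        )


def _load_ic50(ds: DatasetConfig, outdir: Path) -> pd.DataFrame:
    if ds.ic50 is not None:
        return read_ic50_table(ds.ic50)
    experiments = read_plate_csv(ds.plates)
    table = experiments_to_ic50_table(experiments)
    write_ic50_table(table, outdir / f"ic50_{ds.dataset_id}.csv")
    return table


def run_pipeline(config: PipelineConfig) -> PathwayDrugSensitivityResults:
    """Execute all stages, writing intermediates and final tables.

    Outputs under ``config.outdir``: per-control-set PAS profiles
    (``pas_<dataset>_<control>.tsv`` + sidecars), fitted IC50 tables,
    significant correlation records, per-dataset support tallies, the
    consensus table and the sign-discordance diagnostics.  Any stage
    failure raises with the stage named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("parameters: %s", {k: v for k, v in asdict(config).items()
                               if not isinstance(v, (list, Path))})

    try:
        db = read_pathway_db(config.pathway_db)
    except Exception as exc:
        raise RuntimeError(f"stage pathway_db failed: {exc}") from exc

    pas_profiles: dict[str, list] = {}
    ic50_tables: dict[str, pd.DataFrame] = {}
    for ds in config.datasets:
        try:
            cases = read_expression(ds.cases, probe_map=ds.probe_map, role="case")
            profiles = []
            for cid, cpath in ds.controls.items():
                ctrl = ControlSet(cid, read_expression(cpath, role="control"))
                profile = compute_pas_profile(cases, ctrl, db, config.pas_params)
                write_pas_profile(profile, outdir / f"pas_{ds.dataset_id}_{cid}.tsv")
                profiles.append(profile)
            pas_profiles[ds.dataset_id] = profiles
        except Exception as exc:
            raise RuntimeError(
                f"stage pas ({ds.dataset_id}) failed: {exc}"
            ) from exc
        try:
            ic50_tables[ds.dataset_id] = _load_ic50(ds, outdir)
        except Exception as exc:
            raise RuntimeError(
                f"stage ic50 ({ds.dataset_id}) failed: {exc}"
            ) from exc

    try:
        model = PathwayDrugSensitivityModel(pas_profiles, ic50_tables)
        results = model.fit(
            alpha=config.alpha_corr,
            log10_ic50=config.ic50_log_transform,
            bh_correct=config.bh_correct,
            require_sign_match=config.require_sign_match,
            min_support=config.min_support,
        )
    except Exception as exc:
        raise RuntimeError(f"stage correlate/consensus failed: {exc}") from exc

    write_records(results.records, outdir / "correlations.tsv")
    for ds_id in pas_profiles:
        supports_to_frame(results.supports[ds_id]).to_csv(
            outdir / f"support_{ds_id}.tsv", sep="\t", index=False
        )
    results.consensus_frame.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    supports_to_frame(results.discordant).to_csv(
        outdir / "discordant.tsv", sep="\t", index=False
    )
    log.info("consensus: %d records", len(results.consensus))
    return results


def analyze_bundle(bundle, params: PASParams | None = None, alpha: float = 0.05,
                   log10_ic50: bool = False, min_support: int = 1,
                   require_sign_match: bool = True) -> PathwayDrugSensitivityResults:
    """In-memory pipeline over a synthetic bundle (no file round-trip).

    Same stages as :func:`run_pipeline`; used for simulation studies where
    writing intermediates per seed would dominate the runtime.
    """
    params = params or PASParams()
    pas_profiles = {}
    ic50_tables = {}
    for ds in bundle.datasets:
        pas_profiles[ds.dataset_id] = [
            compute_pas_profile(ds.cases, ctrl, bundle.db, params)
            for ctrl in ds.controls
        ]
        ic50_tables[ds.dataset_id] = experiments_to_ic50_table(ds.experiments)
    model = PathwayDrugSensitivityModel(pas_profiles, ic50_tables)
    return model.fit(alpha=alpha, log10_ic50=log10_ic50,
                     min_support=min_support,
                     require_sign_match=require_sign_match)
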