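"""Ground-truth data generator for the whole pipeline.

The generator emulates the statistical shape of a pathway/drug-sensitivity
study at desk scale: log-normally distributed linear-scale expression
intensities; pathways with mixed activator/repressor membership; case cell
lines that perturb the member genes of *planted* pathways in proportion to
a latent per-line activation level; MTT-style dose–response plates
simulated from a four-parameter logistic with Gaussian optical-density
noise; and IC50 values tied linearly (on the log scale) to the latent
activation so that PAS and IC50 correlate at a configured strength.

Two independent "datasets" — different cell lines, control panels of
different sizes, independent noise — exercise the cross-dataset consensus
step.  Every generator is a pure function of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import ControlSet, ExpressionMatrix, write_expression
from .pathway_db import ARR_VALUES, GeneRole, PathwayDefinition, write_pathway_db
from .viability import (
    DEFAULT_DOSES_UM,
    DoseResponseExperiment,
    write_plate_csv,
)

__all__ = [
    "PlantedPathway",
    "SyntheticScenario",
    "SyntheticDataset",
    "LinkedBundle",
    "gen_pathway_db",
    "gen_expression",
    "gen_dose_response",
    "gen_linked_dataset",
    "write_bundle",
]


@dataclass(frozen=True)
class PlantedPathway:
    """A pathway carrying a planted effect and a planted PAS↔IC50 link.

    ``effect`` is the fold-shift applied to a member gene with ARR = +1 in
    a cell line with latent activation 1 (gene g shifts by
    ``effect ** (arr_g * activation_s)``); ``target_r`` is the planted
    correlation between the latent activation and log10(IC50) — positive
    means activation goes with resistance, negative with sensitivity.
    """

    pathway_id: str
    effect: float = 4.0
    target_r: float = 0.95

    def __post_init__(self) -> None:
        if self.effect <= 0:
            raise ValueError("effect must be a positive fold-change")
        if not -1.0 <= self.target_r <= 1.0:
            raise ValueError("|target_r| must be <= 1")


@dataclass(frozen=True)
class SyntheticScenario:
    """Study-shaped defaults for the generator.

    The sizes mirror the shape of a two-dataset cell-line study at desk
    scale: 50 pathways, 11 case cell lines per dataset, 11 control panels
    of 4–33 samples for the first dataset and 3 panels of 2–10 samples for
    the second, the standard 8-point μM dose ladder in quadruplicate, and
    5 %-of-control Gaussian OD noise on the plates.
    """

    seed: int = 0
    n_pathways: int = 50
    genes_per_pathway: tuple[int, int] = (5, 15)
    n_background_genes: int = 400
    metabolic_fraction: float = 0.4
    #: sampling weights over the ARR alphabet (-1, -0.5, 0, +0.5, +1)
    arr_weights: tuple[float, ...] = (0.15, 0.10, 0.05, 0.10, 0.60)
    n_cell_lines: int = 11
    #: (number of control sets, (min, max) samples per set) per dataset
    control_layout: tuple[tuple[int, tuple[int, int]], ...] = (
        (11, (4, 33)),
        (3, (2, 10)),
    )
    dataset_ids: tuple[str, ...] = ("experimental", "screen")
    #: log10-intensity baseline range and within-gene noise sd (log10)
    log_mean_range: tuple[float, float] = (1.5, 3.5)
    log_noise_sd: float = 0.05
    #: per-control-set systematic baseline jitter (log10), tissue-to-tissue
    control_shift_sd: float = 0.02
    planted: tuple[PlantedPathway, ...] = (PlantedPathway("PW_0001"),)
    drug: str = "drugX"
    doses_uM: tuple[float, ...] = DEFAULT_DOSES_UM
    n_replicates: int = 4
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    od_blank: float = 0.08
    od_control: float = 1.0
    od_noise_frac: float = 0.05
    #: log10 IC50 link: log10(ic50) = center + slope * latent mixture
    ic50_log_center: float = 0.796  # log10(6.25 uM), middle of the ladder
    # slope keeping true IC50s inside the ladder (~1.6-25 uM across +-3 sd,
    # a ~16-fold spread between the most and least sensitive lines)
    ic50_log_slope: float = 0.2

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


@dataclass
class SyntheticDataset:
    """One dataset's worth of pipeline inputs plus its ground truth."""

    dataset_id: str
    cases: ExpressionMatrix
    controls: list[ControlSet]
    experiments: list[DoseResponseExperiment]
    true_ic50: pd.Series
    latent_activation: pd.DataFrame  # planted pathways × cell lines


@dataclass
class LinkedBundle:
    """Everything the end-to-end pipeline needs, with planted truth."""

    scenario: SyntheticScenario
    db: list[PathwayDefinition]
    datasets: list[SyntheticDataset]

    @property
    def planted_ids(self) -> list[str]:
        return [p.pathway_id for p in self.scenario.planted]


def gen_pathway_db(scenario: SyntheticScenario) -> list[PathwayDefinition]:
    """Generate the pathway database; deterministic given the seed.

    Pathways get disjoint member-gene sets (G0001, G0002, ...) so a planted
    perturbation cannot leak into unrelated pathways; kinds are a
    signaling/metabolic mixture; ARR roles are drawn from the configured
    weights over the discrete alphabet.
    """
    rng = scenario.rng(1)
    lo, hi = scenario.genes_per_pathway
    weights = np.asarray(scenario.arr_weights, dtype=float)
    weights = weights / weights.sum()
    db: list[PathwayDefinition] = []
    gene_counter = 0
    for k in range(scenario.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        kind = "metabolic" if rng.random() < scenario.metabolic_fraction else "signaling"
        members = []
        for _ in range(size):
            gene_counter += 1
            arr = float(rng.choice(ARR_VALUES, p=weights))
            members.append(GeneRole(f"G{gene_counter:05d}", arr))
        db.append(PathwayDefinition(f"PW_{k + 1:04d}", kind, members))
    return db


def _gene_universe(scenario: SyntheticScenario, db: Sequence[PathwayDefinition]) -> list[str]:
    genes = [m.gene_symbol for pw in db for m in pw.members]
    n_member = len(genes)
    genes += [f"B{j + 1:05d}" for j in range(scenario.n_background_genes)]
    assert len(set(genes)) == n_member + scenario.n_background_genes
    return genes


def gen_expression(
    scenario: SyntheticScenario,
    db: Sequence[PathwayDefinition],
    dataset_index: int = 0,
    latent: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, list[ControlSet], pd.DataFrame]:
    """Case matrix, control sets and latent activations for one dataset.

    Control intensities are log-normal around per-gene baselines (each
    control set additionally jittered by a small systematic tissue shift).
    Case cell lines copy the baselines and multiply each gene g of a
    planted pathway by ``effect ** (arr_g * a_s)``, where a_s ~ N(0, 1) is
    the line's latent activation of that pathway — so activator genes rise
    and repressor genes fall in activated lines, at magnitudes that clear
    the fold-change and tolerance thresholds for |a_s| of order one.
    """
    rng = scenario.rng(2, dataset_index)
    genes = _gene_universe(scenario, db)
    n_genes = len(genes)
    log_mu = rng.uniform(*scenario.log_mean_range, size=n_genes)
    ds_id = scenario.dataset_ids[dataset_index]
    lines = [f"{ds_id}_CL{j + 1:02d}" for j in range(scenario.n_cell_lines)]

    planted_ids = [p.pathway_id for p in scenario.planted]
    if latent is None:
        latent = pd.DataFrame(
            rng.standard_normal((len(planted_ids), len(lines))),
            index=planted_ids, columns=lines,
        )

    log_case = (
        log_mu[:, None]
        + rng.normal(0.0, scenario.log_noise_sd, size=(n_genes, len(lines)))
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    by_id = {pw.pathway_id: pw for pw in db}
    for planted in scenario.planted:
        pw = by_id[planted.pathway_id]
        shift = np.log10(planted.effect)
        acts = latent.loc[planted.pathway_id].to_numpy()
        for member in pw.members:
            i = gene_pos[member.gene_symbol]
            log_case[i] += member.arr * acts * shift
    cases = ExpressionMatrix(
        pd.DataFrame(10.0 ** log_case, index=genes, columns=lines),
        {s: "case" for s in lines},
    )

    n_sets, (smin, smax) = scenario.control_layout[dataset_index]
    controls: list[ControlSet] = []
    for c in range(n_sets):
        crng = scenario.rng(3, dataset_index, c)
        n_samp = int(crng.integers(smin, smax + 1))
        tissue_shift = crng.normal(0.0, scenario.control_shift_sd, size=n_genes)
        log_ctrl = (
            log_mu[:, None]
            + tissue_shift[:, None]
            + crng.normal(0.0, scenario.log_noise_sd, size=(n_genes, n_samp))
        )
        cid = f"{ds_id}_ctrl{c + 1:02d}"
        samples = [f"{cid}_s{j + 1:02d}" for j in range(n_samp)]
        controls.append(
            ControlSet(
                cid,
                ExpressionMatrix(
                    pd.DataFrame(10.0 ** log_ctrl, index=genes, columns=samples),
                    {s: "control" for s in samples},
                ),
            )
        )
    return cases, controls, latent


def true_ic50s(
    scenario: SyntheticScenario,
    latent: pd.DataFrame,
    dataset_index: int = 0,
) -> pd.Series:
    """Ground-truth IC50 per cell line, linearly linked to latent activation.

    log10(IC50_s) = center + slope * (r * z_a + sqrt(1 - r^2) * z_e), where
    z_a is the first planted pathway's latent activation standardized
    across the panel and z_e is standardized noise orthogonalized against
    it — so the *sample* correlation between activation and log10(IC50) is
    exactly the planted ``target_r``.  With no planted pathway the mixture
    is pure noise.
    """
    rng = scenario.rng(4, dataset_index)
    lines = list(latent.columns)
    eps = rng.standard_normal(len(lines))
    if scenario.planted and len(lines) >= 3:
        planted = scenario.planted[0]
        a = latent.loc[planted.pathway_id].to_numpy()
        z_a = (a - a.mean()) / a.std(ddof=0)
        e = eps - eps.mean()
        e -= z_a * (e @ z_a) / (z_a @ z_a)
        z_e = e / e.std(ddof=0) if e.std(ddof=0) > 0 else e
        r = planted.target_r
        mix = r * z_a + np.sqrt(max(0.0, 1.0 - r * r)) * z_e
    else:
        mix = eps
    log_ic50 = scenario.ic50_log_center + scenario.ic50_log_slope * mix
    return pd.Series(10.0 ** log_ic50, index=lines, name="ic50_uM")


def gen_dose_response(
    scenario: SyntheticScenario,
    ic50_by_line: pd.Series,
    dataset_index: int = 0,
    od_noise_frac: float | None = None,
) -> list[DoseResponseExperiment]:
    """Simulated MTT plates: 4PL forward model plus Gaussian OD noise.

    Treated, untreated-control and blank wells are produced for each cell
    line on the scenario's dose ladder with the configured replicate count;
    OD noise is Gaussian with sd ``od_noise_frac`` of the control OD
    (blanks get a tenth of that).
    """
    noise = scenario.od_noise_frac if od_noise_frac is None else od_noise_frac
    doses = np.asarray(scenario.doses_uM, dtype=float)
    nonzero = doses[doses > 0]
    experiments = []
    for j, (line, ic50) in enumerate(ic50_by_line.items()):
        rng = scenario.rng(5, dataset_index, j)
        with np.errstate(divide="ignore"):
            v = scenario.bottom + (scenario.top - scenario.bottom) / (
                1.0 + (nonzero / ic50) ** scenario.hill
            )
        signal = scenario.od_control - scenario.od_blank
        od_true = scenario.od_blank + signal * v / 100.0
        sd = noise * scenario.od_control
        od_treated = od_true[None, :] + rng.normal(
            0.0, sd, size=(scenario.n_replicates, len(nonzero))
        )
        od_untreated = scenario.od_control + rng.normal(0.0, sd, size=scenario.n_replicates)
        od_blank = scenario.od_blank + rng.normal(0.0, sd / 10.0, size=scenario.n_replicates)
        experiments.append(
            DoseResponseExperiment(
                drug=scenario.drug,
                cell_line=str(line),
                concentrations=nonzero,
                od_treated=np.maximum(od_treated, 1e-4),
                od_untreated=np.maximum(od_untreated, 1e-4),
                od_blank=np.maximum(od_blank, 1e-4),
            )
        )
    return experiments


def gen_linked_dataset(scenario: SyntheticScenario) -> LinkedBundle:
    """Full two-dataset pipeline input bundle with planted ground truth.

    Each dataset gets its own cell lines, latent activations, control
    panels and plate noise; the pathway database is shared.  The planted
    pathway should therefore pass the per-dataset screens independently
    and survive the consensus intersection.
    """
    db = gen_pathway_db(scenario)
    planted_missing = {p.pathway_id for p in scenario.planted} - {
        pw.pathway_id for pw in db
    }
    if planted_missing:
        raise ValueError(f"planted pathways not in generated db: {sorted(planted_missing)}")
    datasets = []
    for d, ds_id in enumerate(scenario.dataset_ids):
        cases, controls, latent = gen_expression(scenario, db, dataset_index=d)
        ic50 = true_ic50s(scenario, latent, dataset_index=d)
        experiments = gen_dose_response(scenario, ic50, dataset_index=d)
        datasets.append(
            SyntheticDataset(ds_id, cases, controls, experiments, ic50, latent)
        )
    return LinkedBundle(scenario, db, datasets)


def write_bundle(bundle: LinkedBundle, outdir: str | Path) -> Path:
    """Write a bundle as pipeline input files plus a ready-to-run config.

    Layout: ``pathways.tsv``, per-dataset expression/control TSVs and plate
    CSVs, ground-truth ``truth_<dataset>.csv``, and ``config.yaml``
    consumable by the pipeline runner.  Deterministic byte-for-byte given
    the scenario.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pathway_db(bundle.db, outdir / "pathways.tsv")
    config: dict = {
        "pathway_db": "pathways.tsv",
        "seed": bundle.scenario.seed,
        "datasets": [],
        "params": {},
    }
    for ds in bundle.datasets:
        ds_dir = outdir / ds.dataset_id
        ds_dir.mkdir(exist_ok=True)
        write_expression(ds.cases, ds_dir / "cases.tsv")
        control_entries = {}
        for ctrl in ds.controls:
            fname = f"{ctrl.control_id}.tsv"
            write_expression(ctrl.matrix, ds_dir / fname)
            control_entries[ctrl.control_id] = f"{ds.dataset_id}/{fname}"
        write_plate_csv(ds.experiments, ds_dir / "plates.csv")
        truth = pd.DataFrame(
            {
                "cell_line": ds.true_ic50.index,
                "true_ic50_uM": ds.true_ic50.to_numpy(),
            }
        )
        truth.to_csv(ds_dir / "truth_ic50.csv", index=False, float_format="%.8g")
        config["datasets"].append(
            {
                "dataset_id": ds.dataset_id,
                "cases": f"{ds.dataset_id}/cases.tsv",
                "controls": control_entries,
                "plates": f"{ds.dataset_id}/plates.csv",
            }
        )
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return outdir / "config.yaml"
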