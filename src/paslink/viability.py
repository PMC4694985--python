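"""Cell-viability plates and four-parameter-logistic IC50 estimation.

Percent viability of a treated well is

    (OD_treated - OD_blank) / (mean OD_control - OD_blank) * 100 %

with blanks from no-cell wells and controls from untreated wells.  Mean
viability per concentration is then fitted with the four-parameter logistic
(4PL)

    v(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill),

least squares on log10 dose with a deterministic multi-start grid; the
zero-dose anchor normalizes viability but is excluded from the logistic
fit.  IC50 estimates beyond the top of the dose ladder, or curves that
never cross 50 % in range, are reported censored (``> max dose``) instead
of extrapolated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_DOSES_UM",
    "DoseResponseExperiment",
    "IC50Result",
    "DoseResponseModel",
    "compute_viability",
    "fit_dose_response",
    "read_plate_csv",
    "write_plate_csv",
    "read_ic50_table",
    "write_ic50_table",
    "experiments_to_ic50_table",
]

#: Standard 8-point dose ladder in μM, including the untreated anchor.
DEFAULT_DOSES_UM: tuple[float, ...] = (0.0, 0.8, 1.56, 3.1, 6.25, 12.5, 25.0, 50.0)


def compute_viability(
    od_treated_well: float, od_blank_mean: float, od_control_mean: float
) -> float:
    """Percent viability of a single treated well (raw, not clipped)."""
    if od_control_mean <= od_blank_mean:
        raise ValueError(
            "assay failure: control OD must exceed blank OD "
            f"(control {od_control_mean}, blank {od_blank_mean})"
        )
    return (od_treated_well - od_blank_mean) / (od_control_mean - od_blank_mean) * 100.0


@dataclass
class DoseResponseExperiment:
    """One drug × cell line plate: dose ladder, replicate ODs, references.

    ``od_treated`` is replicates × concentrations; ``od_untreated`` holds
    untreated (100 %) control wells and ``od_blank`` no-cell wells.
    """

    drug: str
    cell_line: str
    concentrations: np.ndarray
    od_treated: np.ndarray
    od_untreated: np.ndarray
    od_blank: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.od_treated = np.atleast_2d(np.asarray(self.od_treated, dtype=float))
        self.od_untreated = np.asarray(self.od_untreated, dtype=float)
        self.od_blank = np.asarray(self.od_blank, dtype=float)
        if (self.concentrations < 0).any():
            raise ValueError("concentrations must be non-negative")
        nonzero = self.concentrations[self.concentrations > 0]
        if len(np.unique(nonzero)) < 3:
            raise ValueError("need >=3 distinct nonzero concentrations for fitting")
        if not np.all(np.diff(nonzero) > 0):
            raise ValueError("nonzero concentrations must be strictly increasing")
        if self.od_treated.shape[1] != len(self.concentrations):
            raise ValueError(
                "od_treated must have one column per concentration "
                f"({self.od_treated.shape[1]} vs {len(self.concentrations)})"
            )

    @property
    def n_replicates(self) -> int:
        return self.od_treated.shape[0]

    @property
    def max_dose(self) -> float:
        return float(self.concentrations.max())

    def viability(self) -> np.ndarray:
        """Replicates × concentrations matrix of percent viability."""
        blank = float(self.od_blank.mean())
        control = float(self.od_untreated.mean())
        return np.vectorize(lambda od: compute_viability(od, blank, control))(
            self.od_treated
        )

    def mean_viability(self) -> tuple[np.ndarray, np.ndarray]:
        """(nonzero doses, mean viability per dose) for fitting."""
        v = self.viability().mean(axis=0)
        mask = self.concentrations > 0
        return self.concentrations[mask], v[mask]


@dataclass
class IC50Result:
    """Fitted 4PL parameters and the IC50 estimate for one plate.

    ``ic50`` is the fitted inflection dose (relative IC50);
    ``ic50_absolute`` is the dose at which the curve crosses 50 %
    viability, or None when it never does.  ``censored`` means the drug did
    not reach half-inhibition within the ladder; report such values as
    ``> max_dose`` rather than as numbers.
    """

    drug: str
    cell_line: str
    ic50: float
    censored: bool
    hill_slope: float
    top: float
    bottom: float
    rss: float
    converged: bool
    max_dose: float
    ic50_absolute: float | None = None
    n_doses: int = 0

    def predict(self, conc: Sequence[float]) -> np.ndarray:
        """4PL viability at the given concentrations."""
        c = np.asarray(conc, dtype=float)
        return _four_pl(c, self.top, self.bottom, np.log10(self.ic50), self.hill_slope)

    def summary(self) -> str:
        ic50_str = f"> {self.max_dose:g}" if self.censored else f"{self.ic50:.4g}"
        lines = [
            f"Dose-response fit: {self.drug} on {self.cell_line}",
            f"  IC50 (uM)      {ic50_str}",
            f"  hill slope     {self.hill_slope:.3f}",
            f"  top / bottom   {self.top:.1f} % / {self.bottom:.1f} %",
            f"  RSS            {self.rss:.4g}",
            f"  converged      {self.converged}",
        ]
        return "\n".join(lines)


def _four_pl(c: np.ndarray, top: float, bottom: float, log_ic50: float, hill: float):
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (
            1.0 + 10.0 ** (hill * (np.log10(c) - log_ic50))
        )


class DoseResponseModel:
    """Least-squares 4PL model of one dose–response plate.

    Parameters are fitted to the mean viability at each nonzero dose.  A
    fixed multi-start grid (hill in {0.5, 1, 2} × IC50 at each interior
    dose) makes the fit deterministic; the best residual sum of squares
    wins.
    """

    _HILL_STARTS = (0.5, 1.0, 2.0)

    def __init__(self, experiment: DoseResponseExperiment):
        self.experiment = experiment
        self.doses, self.response = experiment.mean_viability()

    def fit(self) -> IC50Result:
        exp = self.experiment
        x = np.log10(self.doses)
        y = self.response
        lo = np.array([0.0, -50.0, x.min() - 1.0, 0.05])
        hi = np.array([200.0, 90.0, x.max() + 1.0, 10.0])

        def resid(theta: np.ndarray) -> np.ndarray:
            top, bottom, log_ic50, hill = theta
            return _four_pl(self.doses, top, bottom, log_ic50, hill) - y

        best = None
        top0 = float(np.clip(y.max(), 50.0, 200.0))
        bottom0 = float(np.clip(y.min(), -50.0, 90.0))
        for hill0 in self._HILL_STARTS:
            for log_ic50_0 in x[1:-1] if len(x) > 2 else x:
                theta0 = np.clip([top0, bottom0, log_ic50_0, hill0], lo, hi)
                sol = least_squares(
                    resid, theta0, bounds=(lo, hi), max_nfev=400, method="trf"
                )
                if best is None or sol.cost < best.cost:
                    best = sol
        assert best is not None
        top, bottom, log_ic50, hill = best.x
        ic50 = float(10.0 ** log_ic50)
        rss = float(2.0 * best.cost)
        ic50_abs = self._absolute_ic50(top, bottom, ic50, hill)
        crosses_in_range = (
            ic50_abs is not None and ic50_abs <= exp.max_dose
        )
        censored = ic50 > exp.max_dose or not crosses_in_range
        return IC50Result(
            drug=exp.drug,
            cell_line=exp.cell_line,
            ic50=ic50,
            censored=censored,
            hill_slope=float(hill),
            top=float(top),
            bottom=float(bottom),
            rss=rss,
            converged=bool(best.success),
            max_dose=exp.max_dose,
            ic50_absolute=ic50_abs,
            n_doses=len(self.doses),
        )

    @staticmethod
    def _absolute_ic50(
        top: float, bottom: float, ic50: float, hill: float
    ) -> float | None:
        # dose where the fitted curve crosses 50 % viability
        if not (bottom < 50.0 < top):
            return None
        return float(ic50 * ((top - 50.0) / (50.0 - bottom)) ** (1.0 / hill))

    def plot(self, result: IC50Result | None = None, ax=None):
        """Scatter the replicate viabilities with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        result = result or self.fit()
        exp = self.experiment
        v = exp.viability()
        mask = exp.concentrations > 0
        for rep in v:
            ax.semilogx(exp.concentrations[mask], rep[mask], "o", alpha=0.4, color="C0")
        grid = np.geomspace(self.doses.min() / 3, self.doses.max() * 3, 200)
        ax.semilogx(grid, result.predict(grid), "-", color="C1")
        ax.set_xlabel("concentration (uM)")
        ax.set_ylabel("viability (%)")
        ax.set_title(f"{exp.drug} / {exp.cell_line}")
        return ax


def fit_dose_response(experiment: DoseResponseExperiment) -> IC50Result:
    """Fit one plate; convenience wrapper over :class:`DoseResponseModel`."""
    return DoseResponseModel(experiment).fit()


# ---------------------------------------------------------------------------
# plate and IC50-table I/O

_PLATE_COLUMNS = ["drug", "cell_line", "concentration_uM", "replicate", "od", "well_type"]


def read_plate_csv(path: str | Path) -> list[DoseResponseExperiment]:
    """Read plate-level ODs (long CSV) into one experiment per drug × line.

    Expected columns: drug, cell_line, concentration_uM, replicate, od,
    well_type in {treated, control, blank}.
    """
    df = pd.read_csv(path)
    missing = set(_PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    experiments = []
    for (drug, line), grp in df.groupby(["drug", "cell_line"], sort=True):
        treated = grp[grp.well_type == "treated"]
        pivot = treated.pivot_table(
            index="replicate", columns="concentration_uM", values="od"
        ).sort_index(axis=1)
        experiments.append(
            DoseResponseExperiment(
                drug=str(drug),
                cell_line=str(line),
                concentrations=pivot.columns.to_numpy(dtype=float),
                od_treated=pivot.to_numpy(),
                od_untreated=grp.loc[grp.well_type == "control", "od"].to_numpy(),
                od_blank=grp.loc[grp.well_type == "blank", "od"].to_numpy(),
            )
        )
    return experiments


def write_plate_csv(
    experiments: Iterable[DoseResponseExperiment], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PLATE_COLUMNS)
        for exp in experiments:
            for rep in range(exp.n_replicates):
                for j, conc in enumerate(exp.concentrations):
                    writer.writerow(
                        [exp.drug, exp.cell_line, f"{conc:.17g}", rep + 1,
                         f"{exp.od_treated[rep, j]:.17g}", "treated"]
                    )
            for od in exp.od_untreated:
                writer.writerow([exp.drug, exp.cell_line, 0, "", f"{od:.17g}", "control"])
            for od in exp.od_blank:
                writer.writerow([exp.drug, exp.cell_line, 0, "", f"{od:.17g}", "blank"])


def experiments_to_ic50_table(
    experiments: Iterable[DoseResponseExperiment],
) -> pd.DataFrame:
    """Fit every plate; tabulate drug, cell_line, ic50_uM, censored, fit stats.

    ``ic50_uM`` is the absolute IC50 (dose at the 50 % viability crossing)
    when the fitted curve crosses 50 %, falling back to the inflection
    parameter otherwise: when the lower plateau is poorly determined the
    inflection trades off against it, while the crossing dose stays
    pinned by the data.  The inflection is kept in ``ic50_rel_uM``.
    """
    rows = []
    for exp in experiments:
        res = fit_dose_response(exp)
        rows.append(
            {
                "drug": res.drug,
                "cell_line": res.cell_line,
                "ic50_uM": res.ic50_absolute if res.ic50_absolute is not None else res.ic50,
                "ic50_rel_uM": res.ic50,
                "censored": res.censored,
                "hill": res.hill_slope,
                "top": res.top,
                "bottom": res.bottom,
                "rss": res.rss,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


def read_ic50_table(path: str | Path, unit: str = "uM") -> pd.DataFrame:
    """Read a pre-computed IC50 table (columns drug, cell_line, ic50...).

    Values are stored as provided; ``unit`` is recorded in a ``unit``
    column and never converted — external releases differ in scale (some
    publish natural-log μM) and guessing would corrupt correlations.
    """
    df = pd.read_csv(path)
    required = {"drug", "cell_line"}
    if not required <= set(df.columns):
        raise ValueError(f"IC50 table needs columns {sorted(required)}")
    ic50_col = next(
        (c for c in ("ic50_uM", "ic50") if c in df.columns), None
    )
    if ic50_col is None:
        raise ValueError("IC50 table needs an 'ic50' or 'ic50_uM' column")
    df = df.rename(columns={ic50_col: "ic50_uM"})
    if "censored" not in df.columns:
        df["censored"] = False
    df["unit"] = unit
    return df


def write_ic50_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.6g")
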