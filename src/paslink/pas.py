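"""Pathway Activation Strength (PAS) scoring.

For each case sample, every gene is compared against a panel of normal
controls.  The case-to-normal ratio (CNR) is the case intensity divided by
the control mean; the beyond-tolerance-interval flag (BTIF) marks a gene as
significantly perturbed when its value falls outside a tolerance interval
around the control distribution (two-sided p below ``alpha_gene``) *and*
its CNR leaves the [low_thresh, high_thresh] band.  The PAS of a pathway p
in sample s is the signed sum over member genes n

    PAS_p(s) = sum_n ARR_np * BTIF_n(s) * log10(CNR_n(s)),

so activated activators and repressed repressors push PAS up, and vice
versa.  Genes that are essentially normal contribute nothing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import (
    ControlSet,
    ExpressionMatrix,
    join_case_control,
    quantile_normalize_frame,
)
from .pathway_db import PathwayDefinition

__all__ = [
    "PASParams",
    "GeneStat",
    "PASProfile",
    "compute_cnr",
    "compute_btif",
    "compute_pas",
    "compute_pas_profile",
    "write_pas_profile",
    "read_pas_profile",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PASParams:
    """Tunable parameters of the PAS computation.

    alpha_gene
        Two-sided significance level of the per-gene tolerance-interval
        test (default 0.05).
    low_thresh, high_thresh
        CNR band considered essentially normal; a flag additionally
        requires CNR < low or CNR > high (defaults 0.66 and 1.5).
    btif_polarity
        ``"perturbed"`` (default): BTIF = 1 for significantly perturbed
        genes, which is the reading under which perturbed genes drive the
        score.  ``"literal"`` inverts the flag so unperturbed genes
        contribute instead.
    quantile
        Quantile-normalize cases jointly with the control set before
        computing CNR (default True).
    log_before_quantile
        Quantile-normalize on the log10 scale instead of the linear scale.
    normalize_by_size
        Divide each pathway's PAS by its member count (default off: the
        score is a plain sum).
    min_gene_coverage
        Minimum fraction of database genes that must be present in the
        expression matrix; below it the profile computation refuses to run.
    """

    alpha_gene: float = 0.05
    low_thresh: float = 0.66
    high_thresh: float = 1.5
    btif_polarity: str = "perturbed"
    quantile: bool = True
    log_before_quantile: bool = False
    normalize_by_size: bool = False
    min_gene_coverage: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_gene <= 1.0):
            raise ValueError("alpha_gene must be in (0, 1]")
        if not (0.0 < self.low_thresh < 1.0 < self.high_thresh):
            raise ValueError("thresholds must satisfy 0 < low < 1 < high")
        if self.btif_polarity not in ("perturbed", "literal"):
            raise ValueError("btif_polarity must be 'perturbed' or 'literal'")


@dataclass(frozen=True)
class GeneStat:
    """Per-gene statistics feeding the PAS sum."""

    gene_symbol: str
    cnr: float
    btif: int
    p_gene: float = 1.0

    def __post_init__(self) -> None:
        if self.cnr <= 0:
            raise ValueError("CNR must be positive")
        if self.btif not in (0, 1):
            raise ValueError("BTIF must be 0 or 1")


@dataclass
class PASProfile:
    """Pathways × case-samples PAS matrix from one control set."""

    control_id: str
    data: pd.DataFrame
    params: PASParams = field(default_factory=PASParams)
    coverage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("PAS values must be finite")

    @property
    def pathways(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def compute_cnr(case_value: float, control_values: Sequence[float]) -> float:
    """Case-to-normal ratio: case intensity over the control mean."""
    ctrl = np.asarray(control_values, dtype=float)
    if ctrl.size < 2:
        raise ValueError("need >=2 control values")
    if case_value <= 0 or (ctrl <= 0).any():
        raise ValueError("expression values must be positive")
    return float(case_value / ctrl.mean())


def _tolerance_p(case_value: float, mean: float, sd: float, n: int) -> float:
    # single-observation tolerance check: t-distributed z-score of the case
    # value against the control distribution, df = n - 1
    if sd == 0:
        return 1.0
    z = (case_value - mean) / (sd * np.sqrt(1.0 + 1.0 / n))
    return float(2.0 * stats.t.sf(abs(z), df=n - 1))


def compute_btif(
    case_value: float,
    control_values: Sequence[float],
    alpha_gene: float = 0.05,
    low_thresh: float = 0.66,
    high_thresh: float = 1.5,
) -> tuple[int, float]:
    """Beyond-tolerance-interval flag and its p-value for one gene.

    Returns ``(btif, p_gene)`` where btif = 1 iff the case value is outside
    the control tolerance interval (p_gene < alpha_gene) and the CNR is
    outside [low_thresh, high_thresh].  A zero-variance control panel makes
    the statistical criterion undecidable; p_gene is then 1 (no flag) and a
    warning is emitted.
    """
    ctrl = np.asarray(control_values, dtype=float)
    cnr = compute_cnr(case_value, ctrl)
    sd = float(ctrl.std(ddof=1))
    if sd == 0:
        warnings.warn(
            "zero-variance control vector: tolerance test undecidable, p set to 1",
            stacklevel=2,
        )
    p_gene = _tolerance_p(case_value, float(ctrl.mean()), sd, ctrl.size)
    outside_band = cnr < low_thresh or cnr > high_thresh
    btif = int(p_gene < alpha_gene and outside_band)
    return btif, p_gene


def compute_pas(
    pathway: PathwayDefinition,
    gene_stats: Mapping[str, GeneStat],
) -> float:
    """PAS of one pathway from per-gene statistics.

    Member genes absent from ``gene_stats`` contribute 0 (they carry no
    evidence either way); a pathway with no member present yields 0 with a
    coverage warning.
    """
    total = 0.0
    n_present = 0
    for member in pathway.members:
        stat = gene_stats.get(member.gene_symbol)
        if stat is None:
            continue
        n_present += 1
        total += member.arr * stat.btif * np.log10(stat.cnr)
    if n_present == 0:
        warnings.warn(
            f"pathway {pathway.pathway_id!r}: no member gene present, PAS = 0",
            stacklevel=2,
        )
    return float(total)


def _gene_level_stats(
    joint: ExpressionMatrix, params: PASParams
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """CNR, BTIF and p matrices (genes × case samples) from a joint matrix."""
    df = joint.data
    if params.quantile:
        if params.log_before_quantile:
            df = 10.0 ** quantile_normalize_frame(np.log10(df))
        else:
            df = quantile_normalize_frame(df)
    case_cols = [s for s in df.columns if joint.sample_labels[s] == "case"]
    ctrl_cols = [s for s in df.columns if joint.sample_labels[s] == "control"]
    if len(ctrl_cols) < 2:
        raise ValueError("need >=2 control samples")
    case = df[case_cols].to_numpy()
    ctrl = df[ctrl_cols].to_numpy()
    n = ctrl.shape[1]
    mean = ctrl.mean(axis=1, keepdims=True)
    sd = ctrl.std(axis=1, ddof=1, keepdims=True)
    cnr = case / mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (case - mean) / (sd * np.sqrt(1.0 + 1.0 / n))
    p = 2.0 * stats.t.sf(np.abs(z), df=n - 1)
    p = np.where(sd == 0, 1.0, p)
    outside = (cnr < params.low_thresh) | (cnr > params.high_thresh)
    btif = (p < params.alpha_gene) & outside
    if params.btif_polarity == "literal":
        btif = ~btif
    idx, cols = df.index, pd.Index(case_cols)
    return (
        pd.DataFrame(cnr, index=idx, columns=cols),
        pd.DataFrame(btif.astype(float), index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
    )


def compute_pas_profile(
    cases: ExpressionMatrix,
    control: ControlSet,
    db: Sequence[PathwayDefinition],
    params: PASParams | None = None,
) -> PASProfile:
    """Full pathways × case-samples PAS grid against one control set.

    Cases are inner-joined with the control set on gene symbol and, by
    default, quantile-normalized jointly, then per-gene CNR/BTIF statistics
    are combined into the signed PAS sum for every pathway.  Deterministic
    given its inputs.
    """
    params = params or PASParams()
    joint = join_case_control(cases, control)
    db_genes = {m.gene_symbol for pw in db for m in pw.members}
    present = db_genes & set(joint.data.index)
    coverage_all = len(present) / len(db_genes) if db_genes else 0.0
    if coverage_all < params.min_gene_coverage:
        raise ValueError(
            f"gene coverage {coverage_all:.3f} below required "
            f"{params.min_gene_coverage:.3f}: {len(present)} of {len(db_genes)} "
            f"database genes present in the matrix"
        )
    cnr, btif, _ = _gene_level_stats(joint, params)
    log_cnr = np.log10(cnr.to_numpy())
    contrib = btif.to_numpy() * log_cnr
    gene_index = {g: i for i, g in enumerate(cnr.index)}

    pas = np.zeros((len(db), len(cnr.columns)))
    coverage: dict[str, float] = {}
    for k, pw in enumerate(db):
        rows = [(gene_index[m.gene_symbol], m.arr) for m in pw.members
                if m.gene_symbol in gene_index]
        coverage[pw.pathway_id] = len(rows) / len(pw.members)
        if not rows:
            log.warning("pathway %s: no member gene in matrix", pw.pathway_id)
            continue
        ix = np.fromiter((r[0] for r in rows), dtype=int)
        arr = np.fromiter((r[1] for r in rows), dtype=float)
        pas[k] = arr @ contrib[ix]
        if params.normalize_by_size:
            pas[k] /= len(pw.members)
    data = pd.DataFrame(
        pas, index=[pw.pathway_id for pw in db], columns=cnr.columns
    )
    return PASProfile(control.control_id, data, params, coverage)


def write_pas_profile(profile: PASProfile, path: str | Path) -> None:
    """Write a PAS profile as TSV plus a ``.meta`` key-value sidecar."""
    path = Path(path)
    profile.data.to_csv(path, sep="\t", index_label="pathway", float_format="%.10g")
    meta_lines = [f"control_id\t{profile.control_id}"]
    for key, value in asdict(profile.params).items():
        meta_lines.append(f"{key}\t{value}")
    path.with_suffix(path.suffix + ".meta").write_text(
        "\n".join(meta_lines) + "\n", encoding="utf-8"
    )


def read_pas_profile(path: str | Path) -> PASProfile:
    path = Path(path)
    data = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = path.with_suffix(path.suffix + ".meta")
    control_id = "unknown"
    kwargs: dict[str, object] = {}
    if meta_path.exists():
        bools = {"True": True, "False": False}
        for line in meta_path.read_text(encoding="utf-8").splitlines():
            key, _, value = line.partition("\t")
            if key == "control_id":
                control_id = value
            elif key in ("btif_polarity",):
                kwargs[key] = value
            elif value in bools:
                kwargs[key] = bools[value]
            elif key:
                kwargs[key] = float(value)
    return PASProfile(control_id, data, PASParams(**kwargs))
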