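"""Region-level orchestration and cross-region summaries.

`run_region_analysis` runs the full per-region pipeline: for every species
and both dynamics it classifies per-block outcomes under the configured
breeding-confidence rule, fits the logistic and segmented models on the
configured covariate scale (block cover or block-plus-neighbours cover),
compares them by ΔAIC with the validity screen, and assembles a results
table with the standard column order (species, dynamic, selected model,
AICs, Δi, breakpoint %, SE, AUC).  Species whose response is degenerate
(persistent everywhere, say) are reported with the reason rather than
dropped.

`cross_region_summary` computes, per dynamic, the mean and standard error
of threshold estimates across species that support a threshold in *both*
regions — the headline cross-region comparison.  The SE convention is the
sample (n−1) standard deviation divided by √n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .atlas import (
    AtlasBlock,
    DetectionRecord,
    apply_confidence_filter,
    classify_outcomes,
    deduplicate_records,
)
from .errors import AtlasThreshError, UndefinedCorrelationError, ValidationError
from .segmented import SegmentedFit, fit_logistic, fit_segmented_grid
from .selection import ValidityConfig, compare_models

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "RegionReport",
    "run_region_analysis",
    "cross_region_summary",
    "cover_scale_correlation",
]

REPORT_COLUMNS = [
    "species", "dynamic", "selected", "aic_threshold", "aic_nonthreshold",
    "delta_i", "psi", "psi_se", "auc", "flags",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Scenario configuration for one region analysis."""

    confidence_mode: str = "any_evidence"          # or "confirmed_only"
    covariate_scale: str = "block"                 # or "neighborhood"
    validity: ValidityConfig = field(default_factory=ValidityConfig)

    def __post_init__(self) -> None:
        if self.confidence_mode not in ("any_evidence", "confirmed_only"):
            raise ValidationError(f"unknown confidence mode {self.confidence_mode!r}")
        if self.covariate_scale not in ("block", "neighborhood"):
            raise ValidationError(f"unknown covariate scale {self.covariate_scale!r}")
        if self.validity.delta_aic_cutoff <= 0:
            raise ValidationError("delta_aic_cutoff must be positive")


@dataclass
class RegionReport:
    """Per-species comparison rows plus per-dynamic selection counts."""

    table: pd.DataFrame
    n_threshold_selected: dict[str, int]
    config: AnalysisConfig

    def __post_init__(self) -> None:
        for dyn, count in self.n_threshold_selected.items():
            sel = int(((self.table["dynamic"] == dyn)
                       & (self.table["selected"] == "threshold")).sum())
            assert sel == count, "report counts inconsistent with rows"


def _analyse_one(x: np.ndarray, y: np.ndarray, species: str, dynamic: str,
                 config: AnalysisConfig) -> dict:
    row = {c: np.nan for c in REPORT_COLUMNS}
    row.update(species=species, dynamic=dynamic)
    if len(y) == 0 or y.min() == y.max():
        reason = "no_outcomes" if len(y) == 0 else "degenerate_response"
        row.update(selected="none", flags=reason)
        logger.info("species=%s dynamic=%s: %s, no model fitted", species, dynamic, reason)
        return row
    log_fit = fit_logistic(x, y)
    try:
        seg = fit_segmented_grid(x, y)
    except AtlasThreshError:
        seg = None
    comp = compare_models(log_fit, seg, x=x, y=y, config=config.validity,
                          species=species, dynamic=dynamic)
    psi = seg.psi if isinstance(seg, SegmentedFit) and seg.converged else np.nan
    psi_se = seg.psi_se if isinstance(seg, SegmentedFit) and seg.converged else np.nan
    row.update(
        selected=comp.selected,
        aic_threshold=comp.aic_threshold, aic_nonthreshold=comp.aic_nonthreshold,
        delta_i=comp.delta_i, psi=psi, psi_se=psi_se,
        auc=comp.auc if comp.auc is not None else np.nan,
        flags=";".join(sorted(comp.validity_flags)),
    )
    logger.info(
        "species=%s dynamic=%s selected=%s aic_thr=%.2f aic_non=%.2f psi=%.2f flags=%s",
        species, dynamic, comp.selected, comp.aic_threshold,
        comp.aic_nonthreshold, psi, row["flags"],
    )
    return row


def run_region_analysis(
    blocks: list[AtlasBlock],
    detections: list[DetectionRecord],
    config: AnalysisConfig = AnalysisConfig(),
) -> RegionReport:
    """Fit and compare both models for every species × dynamic in a region."""
    records = deduplicate_records(detections)
    presence = apply_confidence_filter(records, config.confidence_mode)
    species_list = sorted({r.species for r in records})
    rows = []
    for sp in species_list:
        outcomes = classify_outcomes(presence, sp, blocks,
                                     covariate=config.covariate_scale)
        x = np.array([o.covariate_x for o in outcomes], dtype=float)
        for dynamic in ("persistence", "extinction"):
            y = np.array(
                [o.persisted if dynamic == "persistence" else o.extinct
                 for o in outcomes],
                dtype=float,
            )
            rows.append(_analyse_one(x, y, sp, dynamic, config))
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    counts = {
        dyn: int(((table["dynamic"] == dyn) & (table["selected"] == "threshold")).sum())
        for dyn in ("persistence", "extinction")
    }
    return RegionReport(table=table, n_threshold_selected=counts, config=config)


def cross_region_summary(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    name_a: str = "region_a",
    name_b: str = "region_b",
) -> pd.DataFrame:
    """Mean ± SE of thresholds over species supported in both regions.

    Inputs are per-region tables with columns species, dynamic, psi (rows
    for species that support a threshold in that region).  Output has one
    row per (dynamic, region): n, mean threshold, SE of the mean (sample
    n−1 convention; NaN at n = 1).
    """
    for t in (table_a, table_b):
        missing = {"species", "dynamic", "psi"} - set(t.columns)
        if missing:
            raise ValidationError(f"threshold table missing columns {sorted(missing)}")
    out = []
    for dyn in sorted(set(table_a["dynamic"]) | set(table_b["dynamic"])):
        a = table_a[table_a["dynamic"] == dyn]
        b = table_b[table_b["dynamic"] == dyn]
        shared = sorted(set(a["species"]) & set(b["species"]))
        if not shared:
            continue
        for name, t in ((name_a, a), (name_b, b)):
            vals = t.set_index("species").loc[shared, "psi"].to_numpy(dtype=float)
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            out.append({"dynamic": dyn, "region": name, "n": len(vals),
                        "mean_psi": mean, "se": se})
    return pd.DataFrame(out, columns=["dynamic", "region", "n", "mean_psi", "se"])


def cover_scale_correlation(blocks: list[AtlasBlock]) -> tuple[float, float]:
    """Spearman rank correlation of block vs neighbourhood forest cover.

    Returns (rho, p-value).  The neighbourhood covariate is the mean over
    the focal block plus its eight neighbours, as used in the
    landscape-scale models.
    """
    pairs = [
        (b.forest_pct, b.neighborhood_forest_pct)
        for b in blocks
        if b.neighborhood_forest_pct is not None
    ]
    if len(pairs) < 3:
        raise ValidationError("need at least 3 blocks with both covariates")
    x, w = map(np.asarray, zip(*pairs))
    if np.ptp(x) == 0 or np.ptp(w) == 0:
        raise UndefinedCorrelationError("constant covariate; correlation undefined")
    rho, p = spearmanr(x, w)
    return float(rho), float(p)
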