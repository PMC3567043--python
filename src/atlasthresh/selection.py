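"""Threshold vs non-threshold model comparison: ΔAIC, AUC, validity screen.

Model choice follows the information-theoretic rule used throughout the
habitat-threshold literature: the threshold (segmented) model is selected
only when the non-threshold alternative has Δi = AIC difference > 2;
otherwise parsimony prefers the ordinary logistic model (fewer parameters),
including at a tie.

A converged segmented fit is additionally screened before it may be
selected, operationalising the usual manual rejections: a breakpoint
standard error so large the estimate is meaningless, a breakpoint sitting
at the edge of the observed cover range, or a slope change too small to
constitute a threshold (the automated stand-in for visual inspection of
loess plots).

Goodness of fit is the rank-based (Mann–Whitney) AUC of the selected
model's fitted values against the observed outcomes, computed on the
training data (no held-out set — the standard practice for these atlas
analyses, and a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import NoModelError, UndefinedAUCError
from .segmented import LogisticFit, SegmentedFailure, SegmentedFit

__all__ = ["ValidityConfig", "ModelComparison", "auc", "validity_screen", "compare_models"]

#: Flags that disqualify a segmented fit from being selected.
REJECTION_FLAGS = frozenset(
    {"se_too_large", "psi_out_of_range", "no_convergence",
     "degenerate_response", "shape_implausible"}
)


@dataclass(frozen=True)
class ValidityConfig:
    """Screening thresholds for a candidate threshold model.

    max_psi_se : breakpoint SE above which the estimate is deemed
        uninformative (% cover).
    edge_margin : breakpoints within this distance of the data extremes are
        rejected (% cover).
    min_slope_change : minimum |slope change| (logit per % cover) for the
        kink to count as a threshold at all.
    delta_aic_cutoff : Δi needed for the threshold model to beat parsimony.
    """

    max_psi_se: float = 25.0
    edge_margin: float = 2.0
    min_slope_change: float = 1e-3
    delta_aic_cutoff: float = 2.0


@dataclass
class ModelComparison:
    """Outcome of one threshold vs non-threshold comparison."""

    species: str
    dynamic: str
    aic_threshold: float
    aic_nonthreshold: float
    delta_i: float
    selected: str  # {"threshold", "nonthreshold", "none"}
    auc: float | None
    validity_flags: frozenset[str] = field(default_factory=frozenset)


def auc(fitted, y) -> float:
    """Rank-based (Mann–Whitney) AUC of scores against binary outcomes.

    Equals the probability that a random positive outscores a random
    negative, with ties counted half.

    Raises
    ------
    UndefinedAUCError
        If only one outcome class is present.
    """
    fitted = np.asarray(fitted, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("AUC undefined: only one outcome class present")
    ranks = rankdata(fitted)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def validity_screen(
    seg: SegmentedFit, x=None, config: ValidityConfig = ValidityConfig()
) -> frozenset[str]:
    """Flags describing why a segmented fit should not be trusted.

    An empty set means the fit passes.  The range check needs the covariate
    values and is skipped when ``x`` is None.
    """
    flags: set[str] = set()
    if not seg.converged:
        flags.add("no_convergence")
        return frozenset(flags)
    if not np.isfinite(seg.psi_se) or seg.psi_se > config.max_psi_se:
        flags.add("se_too_large")
    if x is not None:
        x = np.asarray(x, dtype=float)
        if (seg.psi < x.min() + config.edge_margin
                or seg.psi > x.max() - config.edge_margin):
            flags.add("psi_out_of_range")
    if abs(seg.slope_change) < config.min_slope_change:
        flags.add("shape_implausible")
    return frozenset(flags)


def compare_models(
    log_fit: LogisticFit | None,
    seg_result: SegmentedFit | SegmentedFailure | None,
    x=None,
    y=None,
    config: ValidityConfig = ValidityConfig(),
    species: str = "",
    dynamic: str = "",
) -> ModelComparison:
    """Select between a logistic and a segmented fit by ΔAIC with screening.

    The threshold model is selected iff it converged, passes the validity
    screen, and the non-threshold model's AIC exceeds the threshold model's
    by more than the cutoff (default 2).  Otherwise the non-threshold model
    is selected; if only a (failing) segmented candidate exists the
    comparison yields ``selected="none"``.

    ``delta_i`` is the ΔAIC carried by whichever model was not selected
    (the absolute AIC difference).  AUC is computed from the selected
    model's fitted values when ``y`` is given.
    """
    if log_fit is None and (seg_result is None or isinstance(seg_result, SegmentedFailure)):
        raise NoModelError("neither model fit is available")

    seg_fit = seg_result if isinstance(seg_result, SegmentedFit) else None
    if seg_fit is not None:
        flags = validity_screen(seg_fit, x=x, config=config)
    elif isinstance(seg_result, SegmentedFailure):
        flags = frozenset({"no_convergence"})
    else:
        flags = frozenset({"no_convergence"})

    aic_thr = seg_fit.aic if seg_fit is not None and np.isfinite(seg_fit.aic) else np.nan
    aic_non = log_fit.aic if log_fit is not None else np.nan
    delta = abs(aic_non - aic_thr) if np.isfinite(aic_thr) and np.isfinite(aic_non) else np.nan

    seg_ok = seg_fit is not None and seg_fit.converged and not (flags & REJECTION_FLAGS)
    if seg_ok and np.isfinite(aic_non) and aic_non - aic_thr > config.delta_aic_cutoff:
        selected = "threshold"
        fitted = seg_fit.fitted
    elif log_fit is not None:
        selected = "nonthreshold"
        fitted = log_fit.fitted
    else:
        selected = "none"
        fitted = None

    auc_val = None
    if y is not None and fitted is not None and len(fitted):
        auc_val = auc(fitted, y)

    return ModelComparison(
        species=species, dynamic=dynamic,
        aic_threshold=float(aic_thr), aic_nonthreshold=float(aic_non),
        delta_i=float(delta), selected=selected, auc=auc_val,
        validity_flags=flags,
    )
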