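"""Well-level QC, detection-rate expression filtering and media-control exclusion.

Three assay-screening stages precede normalization:

1. **Well QC** — wells with Cq > 34, CqConf < 0.8 or AmpScore < 1 are
   censored to missing (the inequalities are strict, so a well at exactly
   the threshold is retained).
2. **Media-control exclusion** — assays that are only detected in cell-free
   media controls, or whose mean Cq separates from the vehicle control by
   less than 3.3 cycles (a 10-fold abundance ratio under perfect doubling),
   are treated as serum-derived background and removed.
3. **Expression filter** — assays must be detected in at least 80% of the
   vehicle-control and treated samples (``BOTH_GROUPS``) or of either group
   (``EITHER_GROUP``); both readings are supported because published
   analyses differ on the conjunction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import UndefinedRateError
from .io import CqMatrix, quality_grids

DETECTION_MODES = ("BOTH_GROUPS", "EITHER_GROUP")


@dataclass
class QcThresholds:
    """Screening thresholds; defaults are the standard array-card QC gates.

    cq_max : retain wells with Cq <= cq_max (cycles).
    cq_conf_min : retain wells with CqConf >= cq_conf_min.
    amp_score_min : retain wells with AmpScore >= amp_score_min.
    detection_rate_min : minimum per-group detection proportion.
    detection_mode : "BOTH_GROUPS" (conjunction) or "EITHER_GROUP".
    mc_delta_min : minimum |mean Cq(MC) - mean Cq(VC)| separation (cycles);
        3.3 cycles corresponds to a 10-fold abundance difference.
    mc_presence_min : MC detection rate at which the separation rule applies.
    """

    cq_max: float = 34.0
    cq_conf_min: float = 0.8
    amp_score_min: float = 1.0
    detection_rate_min: float = 0.80
    detection_mode: str = "BOTH_GROUPS"
    mc_delta_min: float = 3.3
    mc_presence_min: float = 0.50

    def __post_init__(self) -> None:
        for name in ("cq_max", "cq_conf_min", "amp_score_min", "mc_delta_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.detection_rate_min <= 1:
            raise ValueError("detection_rate_min must lie in (0, 1]")
        if self.detection_mode not in DETECTION_MODES:
            raise ValueError(f"detection_mode must be one of {DETECTION_MODES}")


@dataclass
class FilterReport:
    """Per-assay filter diagnostics plus per-stage survivor counts."""

    frame: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)


def apply_well_qc(
    matrix: CqMatrix, wells: pd.DataFrame, thresholds: QcThresholds | None = None
) -> CqMatrix:
    """Censor wells failing the Cq / CqConf / AmpScore rules to missing.

    Each censored cell records exactly one reason — the first failing rule in
    the order the rules are listed (cq_max, then missing quality scores,
    then cq_conf, then amp_score).
    """
    thresholds = thresholds or QcThresholds()
    amp, conf = quality_grids(wells, matrix)
    out = matrix.copy()
    observed = out.values.notna()

    fail_cq = observed & (out.values > thresholds.cq_max)
    no_score = observed & ~fail_cq & (amp.isna() | conf.isna())
    fail_conf = observed & ~fail_cq & ~no_score & (conf < thresholds.cq_conf_min)
    fail_amp = (
        observed & ~fail_cq & ~no_score & ~fail_conf & (amp < thresholds.amp_score_min)
    )
    for mask, reason in (
        (fail_cq, "cq_max"),
        (no_score, "no_quality_score"),
        (fail_conf, "cq_conf"),
        (fail_amp, "amp_score"),
    ):
        out.values[mask] = np.nan
        out.provenance[mask] = f"filtered:{reason}"
    return out


def group_samples(annotations: pd.DataFrame, group: str) -> list[str]:
    return sorted(annotations.loc[annotations["group"] == group, "sample_id"])


def detection_rates(
    matrix: CqMatrix, annotations: pd.DataFrame, groups=("VEHICLE_CONTROL", "TREATED", "MEDIA_CONTROL")
) -> pd.DataFrame:
    """Per-assay detection proportion within each sample group.

    A rate is the number of observed (non-missing, post-QC) cells divided by
    the group size. Requesting a rate for an empty group is an error.
    """
    rates = {}
    for grp in groups:
        members = group_samples(annotations, grp)
        if not members:
            raise UndefinedRateError(f"group {grp} has no samples; rate undefined")
        rates[grp] = matrix.values[members].notna().sum(axis=1) / len(members)
    return pd.DataFrame(rates)


def expression_filter(
    rates: pd.DataFrame, thresholds: QcThresholds | None = None
) -> tuple[list[str], FilterReport]:
    """Keep assays detected in >= detection_rate_min of the relevant groups.

    BOTH_GROUPS requires the vehicle-control and treated rates to each reach
    the threshold; EITHER_GROUP requires only the better of the two. The
    comparison is >=, so a rate of exactly 0.80 passes.
    """
    thresholds = thresholds or QcThresholds()
    r_vc = rates["VEHICLE_CONTROL"]
    r_trt = rates["TREATED"]
    if thresholds.detection_mode == "BOTH_GROUPS":
        ok = (r_vc >= thresholds.detection_rate_min) & (
            r_trt >= thresholds.detection_rate_min
        )
    else:
        ok = np.maximum(r_vc, r_trt) >= thresholds.detection_rate_min
    frame = pd.DataFrame(
        {
            "rate_VC": r_vc,
            "rate_TRT": r_trt,
            "pass_expression": ok,
            "reason": np.where(ok, "", "detection_rate"),
        }
    )
    passing = sorted(frame.index[ok])
    report = FilterReport(frame, {"expression_filter": len(passing)})
    return passing, report


def media_control_filter(
    matrix: CqMatrix,
    annotations: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> tuple[list[str], FilterReport]:
    """Exclude assays attributable to the cell-free media background.

    An assay is excluded when (a) it is detected in at least one media
    control but in no vehicle-control or treated sample, or (b) it is
    detected in at least ``mc_presence_min`` of the media controls and its
    mean Cq is separated from the vehicle-control mean by less than
    ``mc_delta_min`` cycles (direction-agnostic). Assays never detected in
    the media control are untouched by this rule. When rule (b) applies but
    the vehicle-control arm has no observed value at all, the 10-fold
    separation cannot be demonstrated and the assay is excluded
    conservatively.
    """
    thresholds = thresholds or QcThresholds()
    mc = group_samples(annotations, "MEDIA_CONTROL")
    vc = group_samples(annotations, "VEHICLE_CONTROL")
    trt = group_samples(annotations, "TREATED")
    if not mc or not vc:
        raise UndefinedRateError("media-control filtering needs MC and VC samples")

    vals = matrix.values
    mc_n = vals[mc].notna().sum(axis=1)
    mc_rate = mc_n / len(mc)
    cell_n = vals[vc + trt].notna().sum(axis=1)
    mean_mc = vals[mc].mean(axis=1)
    mean_vc = vals[vc].mean(axis=1)
    delta = (mean_mc - mean_vc).abs()

    only_mc = (mc_n > 0) & (cell_n == 0)
    rule_b_scope = (mc_rate >= thresholds.mc_presence_min) & ~only_mc
    too_close = rule_b_scope & delta.notna() & (delta < thresholds.mc_delta_min)
    vc_silent = rule_b_scope & mean_vc.isna()
    excluded_mask = only_mc | too_close | vc_silent

    reason = pd.Series("", index=vals.index)
    reason[vc_silent] = "mc_delta_undefined"
    reason[too_close] = "mc_delta"
    reason[only_mc] = "mc_only"
    frame = pd.DataFrame(
        {
            "rate_MC": mc_rate,
            "mean_MC": mean_mc,
            "mean_VC": mean_vc,
            "abs_delta_mc_vc": delta,
            "pass_media_control": ~excluded_mask,
            "reason": reason,
        }
    )
    excluded = sorted(frame.index[excluded_mask])
    report = FilterReport(frame, {"media_control_filter": int((~excluded_mask).sum())})
    return excluded, report


def fold_to_cycles(fold: float) -> float:
    """Cycles of Cq separation equivalent to a fold-change under perfect doubling."""
    return math.log2(fold)
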