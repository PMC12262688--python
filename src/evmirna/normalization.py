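"""Endogenous-normalizer selection and global-mean ΔCq computation.

Array cards carry no spike-in controls usable for cell-free EV samples, so
background normalization is *global-mean*: a panel of endogenous assays is
selected post-QC and the mean of their Cq values within each sample serves
as that sample's normalizer. An assay qualifies for the panel iff

1. it is undetected, or detected in fewer than 50%, of the media controls;
2. it is observed (post-QC) in **every** vehicle-control and treated sample;
3. when its media-control detection rate is in (0, 0.5), its media-control
   mean Cq differs from the vehicle-control mean by more than 3.3 cycles
   (a 10-fold abundance separation).

ΔCq(assay, sample) = Cq(assay, sample) − mean normalizer Cq(sample). A
group-median alignment mode is provided for sensitivity analysis: each
group's median normalizer score, rather than each sample's mean, is
subtracted; per-run drift is then *not* removed, which is why it is never
the default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import InternalConsistencyError, NormalizationError
from .filtering import QcThresholds, group_samples
from .io import CqMatrix

log = logging.getLogger(__name__)

NORMALIZATION_MODES = ("PER_SAMPLE_MEAN", "MEDIAN_BY_GROUP")


@dataclass
class NormalizerSet:
    """Qualified endogenous normalizer assays and their per-sample mean Cq."""

    assay_ids: list[str]
    per_sample_mean: pd.Series
    mode: str = "PER_SAMPLE_MEAN"
    report: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class DeltaCqMatrix:
    """Background-normalized abundances (cycles); missing where Cq is missing."""

    values: pd.DataFrame
    normalizers: NormalizerSet


def select_normalizers(
    matrix: CqMatrix,
    annotations: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> NormalizerSet:
    """Apply the three normalizer criteria to a post-QC matrix.

    Returns the qualifying assay panel (pooled across both cards) together
    with an eligibility report. Without media-control samples criterion 1
    degenerates to criterion 2 alone, with a warning. Zero qualifying assays
    is an error: normalization cannot proceed and thresholds need review.
    """
    thresholds = thresholds or QcThresholds()
    vc = group_samples(annotations, "VEHICLE_CONTROL")
    trt = group_samples(annotations, "TREATED")
    mc = group_samples(annotations, "MEDIA_CONTROL")
    vals = matrix.values

    fully_observed = vals[vc + trt].notna().all(axis=1)
    if mc:
        mc_rate = vals[mc].notna().sum(axis=1) / len(mc)
        delta = (vals[mc].mean(axis=1) - vals[vc].mean(axis=1)).abs()
        crit1 = mc_rate < 0.50
        # criterion 3 binds only for assays partially detected in media
        needs3 = (mc_rate > 0) & (mc_rate < 0.50)
        crit3 = ~needs3 | (delta > thresholds.mc_delta_min)
    else:
        warnings.warn(
            "no media-control samples: normalizer criterion 1 degenerates to "
            "full observation in VC/treated samples",
            stacklevel=2,
        )
        mc_rate = pd.Series(0.0, index=vals.index)
        delta = pd.Series(float("nan"), index=vals.index)
        crit1 = pd.Series(True, index=vals.index)
        crit3 = pd.Series(True, index=vals.index)

    qualified = crit1 & fully_observed & crit3
    report = pd.DataFrame(
        {
            "rate_MC": mc_rate,
            "fully_observed": fully_observed,
            "abs_delta_mc_vc": delta,
            "qualified": qualified,
        }
    )
    assay_ids = sorted(report.index[qualified])
    if not assay_ids:
        raise NormalizationError(
            "no assay satisfies the normalizer criteria; review QC thresholds "
            "and media-control separation settings"
        )
    if len(assay_ids) == 1:
        log.warning("single-assay normalizer panel: %s", assay_ids[0])
    means = normalizer_means(matrix, assay_ids, annotations)
    return NormalizerSet(assay_ids, means, "PER_SAMPLE_MEAN", report)


def normalizer_means(
    matrix: CqMatrix, assay_ids, annotations: pd.DataFrame
) -> pd.Series:
    """Arithmetic mean normalizer Cq per vehicle-control/treated sample."""
    assay_ids = list(assay_ids)
    if not assay_ids:
        raise NormalizationError("empty normalizer set")
    samples = group_samples(annotations, "VEHICLE_CONTROL") + group_samples(
        annotations, "TREATED"
    )
    block = matrix.values.loc[assay_ids, samples]
    if block.isna().any().any():
        bad = block.columns[block.isna().any()].tolist()
        raise InternalConsistencyError(
            f"normalizer assay missing in sample(s) {bad}; selection invariant violated"
        )
    return block.mean(axis=0)


def delta_cq(matrix: CqMatrix, means: pd.Series, normalizers=None) -> DeltaCqMatrix:
    """ΔCq(a, s) = Cq(a, s) − per-sample normalizer mean; missing propagates."""
    values = matrix.values[means.index].sub(means, axis=1)
    ns = (
        normalizers
        if isinstance(normalizers, NormalizerSet)
        else NormalizerSet(list(normalizers or []), means)
    )
    return DeltaCqMatrix(values, ns)


def align_median_by_group(
    matrix: CqMatrix, annotations: pd.DataFrame, normalizers: NormalizerSet
) -> DeltaCqMatrix:
    """Sensitivity-mode ΔCq: subtract each group's median normalizer score.

    Every Cq value in a group is shifted by the group's median of the
    per-sample normalizer means, so a constant shift of one group's Cq
    values is absorbed entirely by the median. Per-sample (per-run) drift is
    not removed in this mode.
    """
    means = normalizers.per_sample_mean
    group_of = annotations.set_index("sample_id")["group"]
    medians = means.groupby(means.index.map(group_of)).median()
    offsets = means.index.map(group_of).map(medians)
    offsets = pd.Series(list(offsets), index=means.index, dtype=float)
    values = matrix.values[means.index].sub(offsets, axis=1)
    ns = NormalizerSet(
        normalizers.assay_ids, normalizers.per_sample_mean, "MEDIAN_BY_GROUP",
        normalizers.report,
    )
    return DeltaCqMatrix(values, ns)
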