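"""Paired treatment-effect estimation and rank-based testing per assay.

The design is matched pairs: each treated sample is paired with the vehicle
control from the same experimental run, and missing values (QC-censored
wells) leave some pairs incomplete. The primary effect estimator is the
matched-pairs mean of within-pair ΔCq differences (equivalently, the
treatment coefficient of a within-pairs regression restricted to complete
pairs); the primary test is the Skillings-Mack rank test, a generalization
of the Friedman test to block designs with missing cells, which uses every
pair with at least one complete block while the estimator uses only
complete pairs.

Scale conventions: ΔΔCq is in PCR cycles; log2 fold change = −ΔΔCq; fold
change = 2^−ΔΔCq, so FC > 1 means the miRNA is more abundant after
treatment.

Sensitivity alternatives (group-means estimator; sign-flip permutation,
rank-sum and Welch tests) probe how much the conclusions depend on the
choice of estimator and null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exceptions import ContractError, UndefinedTestError
from .normalization import DeltaCqMatrix

#: |log2 FC| >= 0.585 is a 1.5-fold change; the p < 0.2 screen deliberately
#: favors discovery power over false-positive control.
P_DISCOVERY = 0.2
LOG2FC_MIN = 0.585
P_REPORT = 0.05

ESTIMATORS = ("MATCHED_PAIRS", "GROUP_MEANS")
DEFAULT_TESTS = ("skillings_mack", "sign_flip", "welch")


@dataclass
class PairedSeries:
    """One assay's ΔCq values arranged by replicate pair.

    ``pairs`` holds (pair_id, ΔCq treated, ΔCq vehicle-control); NaN marks a
    censored value. Pairs with both arms missing carry no information and
    are dropped at construction.
    """

    assay_id: str
    pairs: list[tuple[int, float, float]]

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.pairs]
        if len(ids) != len(set(ids)):
            raise ContractError(f"{self.assay_id}: duplicate pair ids")
        self.pairs = [
            p for p in self.pairs if not (np.isnan(p[1]) and np.isnan(p[2]))
        ]

    @property
    def complete_diffs(self) -> np.ndarray:
        """Within-pair differences ΔCq(treated) − ΔCq(VC), complete pairs only."""
        return np.array(
            [t - v for _, t, v in self.pairs if not np.isnan(t) and not np.isnan(v)]
        )

    def arm(self, which: str) -> np.ndarray:
        idx = 1 if which == "TREATED" else 2
        vals = np.array([p[idx] for p in self.pairs], dtype=float)
        return vals[~np.isnan(vals)]

    def block_matrix(self) -> np.ndarray:
        """Pairs x 2 array (columns: vehicle control, treated) with NaN holes."""
        return np.array([[v, t] for _, t, v in self.pairs], dtype=float).reshape(-1, 2)


@dataclass
class EffectResult:
    """Per-assay effect estimate with its test p-values."""

    assay_id: str
    ddcq: float
    log2fc: float
    fc: float
    sd_log2fc: float
    n_pairs_complete: int
    p_sm: float = np.nan
    p_alt: dict = field(default_factory=dict)
    estimator: str = "MATCHED_PAIRS"
    reason: str = ""


@dataclass
class SMTestResult:
    statistic: float
    df: int
    p: float
    method: str
    n_blocks_used: int


@dataclass
class SelectionSets:
    """Screening hierarchy: discovery (p<0.2), enrichment (|FC|>=1.5), significant (p<0.05)."""

    table: pd.DataFrame
    discovery: list[str]
    enrichment: list[str]
    significant: list[str]


def paired_series(delta: DeltaCqMatrix, annotations: pd.DataFrame) -> list[PairedSeries]:
    """Arrange a ΔCq matrix into one PairedSeries per assay using pair_id."""
    paired = annotations[annotations["pair_id"].notna()]
    trt = paired[paired["group"] == "TREATED"].set_index("pair_id")["sample_id"]
    vc = paired[paired["group"] == "VEHICLE_CONTROL"].set_index("pair_id")["sample_id"]
    pair_ids = sorted(set(trt.index) & set(vc.index))
    vals = delta.values
    out = []
    for assay in vals.index:
        row = vals.loc[assay]
        pairs = [
            (int(pid), float(row.get(trt[pid], np.nan)), float(row.get(vc[pid], np.nan)))
            for pid in pair_ids
        ]
        out.append(PairedSeries(assay, pairs))
    return out


def fold_change(ddcq: float) -> tuple[float, float]:
    """(fold change, log2 fold change) from a ΔΔCq in cycles: FC = 2^−ΔΔCq."""
    return 2.0 ** (-ddcq), -ddcq


def matched_pairs_effect(series: PairedSeries) -> EffectResult:
    """ΔΔCq as the mean of complete-pair ΔCq differences.

    Identical to the treatment coefficient of a regression of ΔCq on a
    treatment indicator with pair fixed effects, restricted to complete
    pairs. ``sd_log2fc`` is the n−1 sample standard deviation of per-pair
    log2 fold changes (−diffs). Incomplete pairs are excluded here but still
    contribute to the rank test.
    """
    d = series.complete_diffs
    if d.size == 0:
        return EffectResult(
            series.assay_id, np.nan, np.nan, np.nan, np.nan, 0,
            estimator="MATCHED_PAIRS", reason="no_complete_pairs",
        )
    ddcq = float(d.mean())
    fc, log2fc = fold_change(ddcq)
    sd = float(np.std(-d, ddof=1)) if d.size > 1 else np.nan
    return EffectResult(series.assay_id, ddcq, log2fc, fc, sd, int(d.size))


def group_means_effect(series: PairedSeries) -> EffectResult:
    """ΔΔCq as difference of arm means, ignoring pairing (sensitivity mode)."""
    trt, vc = series.arm("TREATED"), series.arm("VEHICLE_CONTROL")
    n_complete = series.complete_diffs.size
    if trt.size == 0 or vc.size == 0:
        return EffectResult(
            series.assay_id, np.nan, np.nan, np.nan, np.nan, n_complete,
            estimator="GROUP_MEANS", reason="empty_arm",
        )
    ddcq = float(trt.mean() - vc.mean())
    fc, log2fc = fold_change(ddcq)
    # dispersion on the log2 FC scale: pooled SD of arm-centered -ΔCq values
    pooled = np.concatenate([trt - trt.mean(), vc - vc.mean()])
    sd = float(np.sqrt((pooled**2).sum() / (pooled.size - 2))) if pooled.size > 2 else np.nan
    return EffectResult(
        series.assay_id, ddcq, log2fc, fc, sd, n_complete, estimator="GROUP_MEANS"
    )


def skillings_mack(
    data,
    method: str = "ASYMPTOTIC_CHI2",
    n_sim: int = 10000,
    seed: int | None = None,
) -> SMTestResult:
    """Skillings-Mack rank test for block designs with missing cells.

    ``data`` is a blocks x treatments array with NaN for unobserved cells.
    Within each block the observed values receive mid-ranks; each treatment's
    centered rank is weighted by sqrt(12/(k_i+1)) where k_i is the number of
    observed treatments in block i, and unobserved treatments contribute the
    centered value 0. The statistic is A' Σ⁻ A with Σ built from the
    pairwise block-concurrence counts and a generalized inverse; its null is
    chi-square with df = rank(Σ). Blocks with fewer than two observations
    carry no ranking information and are ignored. With complete blocks the
    statistic reduces to Friedman's.

    ``method`` "MONTE_CARLO" replaces the asymptotic tail with within-block
    permutation of the observed values (add-one estimator), keeping the same
    statistic; the asymptotic default gives the closed-form two-treatment
    p-values (e.g. 0.0143 for six unanimous pairs).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ContractError("data must be a 2-D blocks x treatments array")
    mask = ~np.isnan(x)
    k = mask.sum(axis=1)
    use = k >= 2
    if use.sum() < 2:
        raise UndefinedTestError(
            "Skillings-Mack requires at least two blocks with two or more observations"
        )
    xb, maskb, kb = x[use], mask[use], k[use]
    n_t = x.shape[1]

    def statistic(blocks: np.ndarray) -> tuple[float, np.ndarray]:
        a = np.zeros(n_t)
        for i in range(blocks.shape[0]):
            obs = maskb[i]
            ki = kb[i]
            ranks = stats.rankdata(blocks[i, obs])
            a[obs] += np.sqrt(12.0 / (ki + 1)) * (ranks - (ki + 1) / 2.0)
        return a

    a = statistic(xb)
    sigma = np.zeros((n_t, n_t))
    for j in range(n_t):
        sigma[j, j] = ((kb - 1) * maskb[:, j]).sum()
        for jp in range(j + 1, n_t):
            lam = (maskb[:, j] & maskb[:, jp]).sum()
            sigma[j, jp] = sigma[jp, j] = -lam
    sigma_pinv = linalg.pinvh(sigma)
    sm = float(a @ sigma_pinv @ a)
    sm = max(sm, 0.0)
    df = int(np.linalg.matrix_rank(sigma))
    if method.upper() in ("ASYMPTOTIC_CHI2", "ASYMPTOTIC"):
        p = float(stats.chi2.sf(sm, df))
        return SMTestResult(sm, df, p, "ASYMPTOTIC_CHI2", int(use.sum()))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sim):
        perm = xb.copy()
        for i in range(perm.shape[0]):
            obs = np.where(maskb[i])[0]
            perm[i, obs] = perm[i, rng.permutation(obs)]
        ap = statistic(perm)
        if float(ap @ sigma_pinv @ ap) >= sm - 1e-12:
            count += 1
    p = (count + 1) / (n_sim + 1)
    return SMTestResult(sm, df, p, "MONTE_CARLO", int(use.sum()))


def skillings_mack_test(series: PairedSeries, **kwargs) -> SMTestResult:
    """Skillings-Mack test on one assay's pairs (blocks) x {VC, treated}."""
    return skillings_mack(series.block_matrix(), **kwargs)


def sign_flip_permutation_test(
    series: PairedSeries,
    n_perm: int = 10000,
    seed: int | None = None,
    exact: bool | None = None,
) -> float:
    """Two-sided paired sign-flip test on the mean complete-pair difference.

    Exact enumeration of all 2^n sign patterns when that is at most 4096
    patterns; otherwise ``n_perm`` Monte-Carlo sign draws with the add-one
    estimator. ``exact`` overrides the automatic choice. The identity flip
    is always part of the null set, so p > 0.
    """
    d = series.complete_diffs
    if d.size == 0:
        raise UndefinedTestError(f"{series.assay_id}: no complete pairs")
    obs = abs(d.mean())
    n = d.size
    if exact is None:
        exact = 2**n <= 4096
    if exact:
        signs = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)]
        )
        means = np.abs(signs @ d) / n
        return float((means >= obs - 1e-12).mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = np.abs(signs @ d) / n
    return float(((means >= obs - 1e-12).sum() + 1) / (n_perm + 1))


def rank_sum_test(series: PairedSeries) -> float:
    """Two-sided Wilcoxon-Mann-Whitney on the pooled ΔCq values by arm.

    Pairing is ignored (sensitivity mode). Mid-ranks handle ties; the null
    is exact for combined n <= 12 without ties, otherwise a normal
    approximation with continuity correction.
    """
    trt, vc = series.arm("TREATED"), series.arm("VEHICLE_CONTROL")
    if trt.size < 2 or vc.size < 2:
        raise UndefinedTestError(f"{series.assay_id}: arm with fewer than two values")
    has_ties = len(np.unique(np.concatenate([trt, vc]))) < trt.size + vc.size
    method = "exact" if (trt.size + vc.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        trt, vc, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def welch_test(series: PairedSeries) -> float:
    """Two-sided Welch unequal-variance t-test on the arm ΔCq values."""
    trt, vc = series.arm("TREATED"), series.arm("VEHICLE_CONTROL")
    if trt.size < 2 or vc.size < 2:
        raise UndefinedTestError(f"{series.assay_id}: arm with fewer than two values")
    if trt.var(ddof=1) == 0 and vc.var(ddof=1) == 0:
        if trt.mean() == vc.mean():
            return 1.0
        warnings.warn(
            f"{series.assay_id}: zero variance in both arms with unequal means; "
            "Welch p degenerates to 0",
            stacklevel=2,
        )
        return 0.0
    res = stats.ttest_ind(trt, vc, equal_var=False)
    return float(res.pvalue)


TEST_FUNCS = _TEST_FUNCS = {
    "skillings_mack": lambda s, n_perm, seed: skillings_mack_test(s).p,
    "sign_flip": lambda s, n_perm, seed: sign_flip_permutation_test(s, n_perm, seed),
    "welch": lambda s, n_perm, seed: welch_test(s),
    "rank_sum": lambda s, n_perm, seed: rank_sum_test(s),
}
_EST_FUNCS = {"MATCHED_PAIRS": matched_pairs_effect, "GROUP_MEANS": group_means_effect}


def sensitivity_grid(
    series: PairedSeries,
    estimators=ESTIMATORS,
    tests=DEFAULT_TESTS,
    extra_tests=("rank_sum",),
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Estimator x test grid of (effect, p) combinations for one assay.

    The default grid is the two effect estimators crossed with the
    Skillings-Mack, sign-flip permutation and Welch tests (six cells), with
    the rank-sum p as an additional column. Cells whose test is undefined on
    the data are reported as NaN.
    """
    estimators, tests = list(estimators), list(tests)
    if not estimators or not tests:
        raise ContractError("sensitivity grid needs at least one estimator and one test")
    rows = []
    for est in estimators:
        eff = _EST_FUNCS[est](series)
        row = {"estimator": est, "ddcq": eff.ddcq, "log2fc": eff.log2fc}
        for t in list(tests) + [x for x in extra_tests if x not in tests]:
            try:
                row[f"p_{t}"] = _TEST_FUNCS[t](series, n_perm, seed)
            except UndefinedTestError:
                row[f"p_{t}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def zscore_log2fc(values) -> np.ndarray:
    """Z-transform a log2 fold-change vector with the n−1 sample SD.

    Missing entries are excluded from the mean/SD and propagate as NaN. A
    zero-SD vector returns all zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ContractError("z-scoring needs at least two finite values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        warnings.warn("constant log2fc vector; z-scores set to 0", stacklevel=2)
        out = np.where(finite, 0.0, np.nan)
        return out
    return (x - mu) / sd


def results_frame(results: list[EffectResult]) -> pd.DataFrame:
    """Flatten EffectResults (alt-test p-values become p_<test> columns)."""
    rows = []
    for r in results:
        row = {
            "assay_id": r.assay_id,
            "ddcq": r.ddcq,
            "log2fc": r.log2fc,
            "fc": r.fc,
            "sd_log2fc": r.sd_log2fc,
            "n_pairs_complete": r.n_pairs_complete,
            "p_sm": r.p_sm,
        }
        row.update({f"p_{k}": v for k, v in r.p_alt.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def rank_and_select(
    results,
    p_discovery: float = P_DISCOVERY,
    log2fc_min: float = LOG2FC_MIN,
    p_report: float = P_REPORT,
) -> SelectionSets:
    """Rank by |ΔΔCq| (descending, ties by assay id) and apply the screens.

    discovery: p_sm < p_discovery (strict); enrichment: |log2fc| >= log2fc_min
    (non-strict, so a 1.5-fold change exactly is included); significant:
    p_sm < p_report. Significant is a subset of discovery by construction.
    """
    frame = results if isinstance(results, pd.DataFrame) else results_frame(results)
    frame = frame.copy()
    frame["abs_ddcq"] = frame["ddcq"].abs()
    frame = frame.sort_values(
        ["abs_ddcq", "assay_id"], ascending=[False, True], kind="mergesort"
    ).drop(columns="abs_ddcq")
    frame["discovery"] = frame["p_sm"] < p_discovery
    frame["enrichment"] = frame["log2fc"].abs() >= log2fc_min
    frame["significant"] = frame["p_sm"] < p_report
    return SelectionSets(
        frame.reset_index(drop=True),
        sorted(frame.loc[frame["discovery"], "assay_id"]),
        sorted(frame.loc[frame["enrichment"], "assay_id"]),
        sorted(frame.loc[frame["significant"], "assay_id"]),
    )


def cross_receptor_sets(sets: dict[str, list]) -> tuple[pd.DataFrame, dict]:
    """Membership table and region counts across per-receptor assay sets.

    Returns a boolean membership DataFrame (assay x receptor) and a dict
    mapping each non-empty receptor combination (sorted tuple) to the number
    of assays belonging to exactly that combination — the regions of the
    Venn partition.
    """
    if len(sets) < 2:
        raise ContractError("cross-receptor comparison needs at least two sets")
    receptors = sorted(sets)
    assays = sorted(set().union(*[set(v) for v in sets.values()]))
    member = pd.DataFrame(
        {r: [a in set(sets[r]) for a in assays] for r in receptors}, index=assays
    )
    regions: dict[tuple, int] = {}
    for _, row in member.iterrows():
        combo = tuple(r for r in receptors if row[r])
        regions[combo] = regions.get(combo, 0) + 1
    return member, regions
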