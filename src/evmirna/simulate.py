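"""Synthetic paired qPCR-array data with ground truth for recovery testing.

The generator emulates a two-card miRNA array experiment on extracellular
vesicles: ~754 assays split over cards A and B, six treated/vehicle-control
replicate pairs and a handful of cell-free media controls. The generative
model on the Cq (log2 abundance) scale is

    Cq(a, s) = baseline(a) + shift(s) + δ(a)·1[s treated] + ε,

with ε ~ Normal(0, residual_sd), per-sample run shifts Normal(0,
sample_shift_sd), and δ(a) = −injected log2 fold change (a positive fold
change lowers Cq). Assay classes:

* **affected** — nonzero injected effect, |log2fc| drawn from
  ``effect_log2fc_range`` with random sign;
* **serum_only** — detected only in media controls (serum-derived
  background that the media-control filter must remove), with optional
  leakage into cell samples;
* **normalizer_like** — zero effect, reduced residual noise, baselines at
  least five cycles below the detection limit so they stay fully observed;
* **null** — everything else.

Wells whose latent Cq exceeds the detection limit are censored to
"Undetermined". Stochastic dropout and AmpScore/CqConf quality failures are
drawn only within the *weak stratum* — wells whose latent Cq lies within
four cycles of the detection limit — mirroring the empirical behavior of
amplification-quality flags, which fire on late, low-abundance curves
rather than uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ContractError

#: width of the late-amplification stratum subject to dropout/quality failures
WEAK_WINDOW_CYCLES = 4.0


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the emulated experiment: 754 assays over two cards, six
    replicate pairs, seven media controls, Cq baselines spanning 20-33
    cycles, 0.25-cycle run shifts, 0.3-cycle residual noise, 5% affected
    assays with |log2fc| between 0.585 (1.5-fold) and 2, 10% serum-only
    background assays, 5% normalizer-like assays, and censoring at 34
    cycles.
    """

    n_assays: int = 754
    n_pairs: int = 6
    n_media_controls: int = 7
    baseline_cq_range: tuple[float, float] = (20.0, 33.0)
    sample_shift_sd: float = 0.25
    residual_sd: float = 0.3
    frac_affected: float = 0.05
    effect_log2fc_range: tuple[float, float] = (0.585, 2.0)
    frac_serum_assays: float = 0.10
    frac_normalizer_like: float = 0.05
    serum_leakage_rate: float = 0.0
    detection_limit: float = 34.0
    dropout_rate: float = 0.02
    ampscore_fail_rate: float = 0.01
    cqconf_fail_rate: float = 0.01
    receptor: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_affected", "frac_serum_assays", "frac_normalizer_like",
            "dropout_rate", "ampscore_fail_rate", "cqconf_fail_rate",
            "serum_leakage_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ContractError(f"{name} must lie in [0, 1]")
        if self.frac_affected + self.frac_serum_assays + self.frac_normalizer_like > 1:
            raise ContractError("class fractions sum to more than 1")
        for name in ("baseline_cq_range", "effect_log2fc_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ContractError(f"{name} must be an ordered interval")
        if self.n_pairs < 2:
            raise ContractError("n_pairs must be at least 2")
        if self.n_assays < 1:
            raise ContractError("n_assays must be positive")


@dataclass
class SimulationTruth:
    """Ground truth: per-assay class and injected effect, per-sample shifts."""

    assays: pd.DataFrame  # assay_id, class, injected_log2fc, baseline_cq, card
    sample_shifts: pd.Series
    config: SimulationConfig = field(repr=False)


def _sample_ids(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for p in range(1, config.n_pairs + 1):
        rows.append(("TRT%02d" % p, config.receptor, "TREATED", p, "B1"))
        rows.append(("VC%02d" % p, config.receptor, "VEHICLE_CONTROL", p, "B1"))
    for j in range(1, config.n_media_controls + 1):
        rows.append(("MC%02d" % j, config.receptor, "MEDIA_CONTROL", None, "B1"))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "receptor", "group", "pair_id", "batch"]
    )
    frame["pair_id"] = frame["pair_id"].astype("Int64")
    return frame


def simulate_experiment(
    config: SimulationConfig | None = None, **overrides
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate (wells, sample sheet, truth) for one synthetic experiment.

    All randomness flows from ``config.seed`` through one generator, so the
    same configuration reproduces the same tables byte for byte. Keyword
    overrides are applied on top of ``config`` (or the defaults).
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(config.seed)
    n = config.n_assays

    assay_ids = np.array([f"hsa-miR-sim{i:04d}" for i in range(1, n + 1)])
    cards = np.where(np.arange(n) < (n + 1) // 2, "A", "B")

    n_aff = round(config.frac_affected * n)
    n_serum = round(config.frac_serum_assays * n)
    n_norm = round(config.frac_normalizer_like * n)
    classes = np.array(
        ["affected"] * n_aff + ["serum_only"] * n_serum
        + ["normalizer_like"] * n_norm + ["null"] * (n - n_aff - n_serum - n_norm)
    )
    rng.shuffle(classes)

    lo, hi = config.baseline_cq_range
    baseline = rng.uniform(lo, hi, size=n)
    is_norm = classes == "normalizer_like"
    norm_hi = min(hi, config.detection_limit - 5.0)
    baseline[is_norm] = rng.uniform(lo, max(norm_hi, lo), size=is_norm.sum())

    lfc = np.zeros(n)
    aff = classes == "affected"
    elo, ehi = config.effect_log2fc_range
    lfc[aff] = rng.uniform(elo, ehi, size=aff.sum()) * rng.choice([-1, 1], size=aff.sum())

    annotations = _sample_ids(config)
    samples = annotations["sample_id"].to_numpy()
    is_mc = (annotations["group"] == "MEDIA_CONTROL").to_numpy()
    is_trt = (annotations["group"] == "TREATED").to_numpy()
    shifts = rng.normal(0.0, config.sample_shift_sd, size=len(samples))

    res_sd = np.full(n, config.residual_sd)
    res_sd[is_norm] = config.residual_sd / 3.0

    # latent Cq for every (assay, sample) well on the cards
    latent = (
        baseline[:, None]
        + shifts[None, :]
        + np.where(is_trt[None, :], -lfc[:, None], 0.0)
        + rng.normal(0.0, 1.0, size=(n, len(samples))) * res_sd[:, None]
    )

    # presence: serum assays amplify in media controls (plus optional leakage
    # into cell samples); cellular assays amplify in cell samples only
    serum = (classes == "serum_only")[:, None]
    present = np.where(serum, is_mc[None, :], ~is_mc[None, :])
    if config.serum_leakage_rate > 0:
        leak = rng.random(size=latent.shape) < config.serum_leakage_rate
        present |= serum & ~is_mc[None, :] & leak

    cq = np.where(present, latent, np.nan)
    censored = present & (latent > config.detection_limit)
    cq[censored] = np.nan

    weak = present & (latent > config.detection_limit - WEAK_WINDOW_CYCLES)
    dropout = weak & (rng.random(size=latent.shape) < config.dropout_rate)
    cq[dropout] = np.nan

    detected = present & ~censored & ~dropout
    amp = np.where(detected, rng.uniform(1.05, 1.60, size=latent.shape), np.nan)
    conf = np.where(detected, rng.uniform(0.85, 1.00, size=latent.shape), np.nan)
    amp_fail = detected & weak & (rng.random(size=latent.shape) < config.ampscore_fail_rate)
    conf_fail = detected & weak & (rng.random(size=latent.shape) < config.cqconf_fail_rate)
    amp[amp_fail] = rng.uniform(0.30, 0.99, size=int(amp_fail.sum()))
    conf[conf_fail] = rng.uniform(0.30, 0.79, size=int(conf_fail.sum()))

    a_idx, s_idx = np.nonzero(present)
    wells = pd.DataFrame(
        {
            "sample_id": samples[s_idx],
            "card": cards[a_idx],
            "well": [f"{cards[i]}{i + 1:03d}" for i in a_idx],
            "assay_id": assay_ids[a_idx],
            "cq": np.round(cq[a_idx, s_idx], 4),
            "amp_score": np.round(amp[a_idx, s_idx], 3),
            "cq_conf": np.round(conf[a_idx, s_idx], 3),
        }
    )
    wells = wells.sort_values(["sample_id", "card", "assay_id"], kind="mergesort")
    wells = wells.reset_index(drop=True)

    truth = SimulationTruth(
        pd.DataFrame(
            {
                "assay_id": assay_ids,
                "class": classes,
                "injected_log2fc": lfc,
                "baseline_cq": baseline,
                "card": cards,
            }
        ),
        pd.Series(shifts, index=samples, name="shift"),
        config,
    )
    return wells, annotations, truth


def truth_report(
    truth: SimulationTruth, results: pd.DataFrame, selection=None
) -> dict:
    """Recovery metrics of estimated effects and selections against the truth.

    Per truth class, the bias and RMSE of the estimated log2 fold changes
    over assays present in ``results``; plus sensitivity/specificity of the
    discovery and enrichment selections against the affected class.
    """
    t = truth.assays.set_index("assay_id")
    r = results.set_index("assay_id") if "assay_id" in results.columns else results
    common = t.index.intersection(r.index)
    if len(common) == 0:
        raise ContractError("truth and results cover disjoint assay universes")
    err = r.loc[common, "log2fc"] - t.loc[common, "injected_log2fc"]
    per_class = {}
    for cls, grp in err.groupby(t.loc[common, "class"]):
        grp = grp.dropna()
        per_class[cls] = {
            "n": int(len(grp)),
            "bias": float(grp.mean()) if len(grp) else float("nan"),
            "rmse": float(np.sqrt((grp**2).mean())) if len(grp) else float("nan"),
        }
    out = {"per_class": per_class, "n_assays_scored": int(len(common))}
    if selection is not None:
        affected = set(t.index[t["class"] == "affected"]) & set(common)
        unaffected = set(common) - affected
        for name, sel in (
            ("discovery", set(selection.discovery)),
            ("enrichment", set(selection.enrichment)),
            ("significant", set(selection.significant)),
        ):
            tp = len(sel & affected)
            fp = len(sel & unaffected)
            out[name] = {
                "sensitivity": tp / len(affected) if affected else float("nan"),
                "specificity": 1 - fp / len(unaffected) if unaffected else float("nan"),
                "n_selected": len(sel & set(common)),
            }
    return out
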