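"""Synthetic methylome cohorts with known clonal structure.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be exercised end-to-end without array data:

* a bimodal normal-breast baseline — each CpG probe belongs to a fixed
  low-methylation component (beta near 0.1, unmethylated CpG-island-like)
  or a high-methylation component (beta near 0.9), the component being a
  property of the probe shared by all samples;
* tumors as sparse persistent perturbations of that baseline — a random
  fraction of probes per tumor is shifted away from its component
  (hypermethylation of low probes, hypomethylation of high probes),
  echoing CpG-island hypermethylation and global hypomethylation;
* matched PT/recurrence pairs that are either clonal (the recurrence is
  the primary's tumor profile plus a small independent per-probe drift of
  mean ``divergence``, optionally plus a progression signature at ``k``
  designated probes) or independent (a fresh tumor on the same baseline);
* optional per-sample copy-number breakpoint sets in which clonal pairs
  share a configurable fraction of breakpoints, a deliberately simplified
  surrogate for breakpoint-based partial-identity scoring;
* exponential survival times with a configurable hazard ratio between the
  true-recurrence and new-primary truth groups, under independent uniform
  censoring.

Default rates are chosen so that, at the array's 27,573 complete probes,
simulated methylation-similarity scores land in the mid 10^-4 range
(clonal pairs near 10 x 10^-4, unrelated pairs near 5 x 10^-4), matching
the magnitude the score takes on real profiles.  Everything is
deterministic for a fixed config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleAnnotation, RECURRENCE_ROLE

__all__ = [
    "CohortConfig",
    "CohortData",
    "probe_baseline",
    "generate_normal_profile",
    "generate_tumor_profile",
    "generate_matched_pair",
    "generate_cohort",
    "generate_survival_records",
    "pis_surrogate",
    "study_configs",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one simulated matched-pair cohort.

    divergence is the expected per-probe |delta beta| between clonal
    siblings; tumor_alteration_rate the fraction of probes perturbed in a
    tumor; shift_low/shift_high bound the uniform perturbation magnitude.
    progression_probes/progression_effect add a shared signed PT->recurrence
    shift at that many designated probes (the progression signature of an
    axillary-metastasis-like cohort; zero elsewhere).
    """

    n_probes: int = 27_578
    n_pairs: int = 17
    n_normals: int = 0
    cohort: str = "PT/LR"
    clonal_fraction: float = 0.5
    divergence: float = 0.035
    tumor_alteration_rate: float = 0.10
    shift_low: float = 0.2
    shift_high: float = 0.4
    noise_sd: float = 0.015
    low_fraction: float = 0.5
    low_center: float = 0.1
    high_center: float = 0.9
    progression_probes: int = 0
    progression_effect: float = 0.0
    n_missing_probes: int = 5
    # simplified copy-number surrogate
    n_breakpoint_loci: int = 0
    breakpoints_per_tumor: int = 20
    breakpoint_share: float = 0.8
    # survival
    baseline_hazard: float = 0.08  # events per year in the NP group
    hazard_ratio: float = 1.0  # TR hazard / NP hazard
    followup_years: float = 12.0  # uniform censoring horizon
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("clonal_fraction", "tumor_alteration_rate", "low_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if not 0 <= self.shift_low <= self.shift_high:
            raise ValueError("need 0 <= shift_low <= shift_high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


class CohortData(NamedTuple):
    beta: BetaMatrix
    annotation: SampleAnnotation
    truth: pd.DataFrame  # pair_id, clonal, label
    breakpoints: dict[str, frozenset[int]] | None
    survival: pd.DataFrame  # pair_id, time_years, event, group


def _component_rng(cfg: CohortConfig) -> np.random.Generator:
    # probe components are a property of the cohort, not of any sample draw
    return np.random.default_rng((cfg.seed, 0xC0))


def probe_baseline(cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe component flags (True = low) and baseline means, fixed by seed."""
    rng = _component_rng(cfg)
    low = rng.random(cfg.n_probes) < cfg.low_fraction
    jitter = rng.uniform(0.0, 0.05, size=cfg.n_probes)
    means = np.where(low, cfg.low_center + jitter, cfg.high_center - jitter)
    return low, means


def generate_normal_profile(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """One normal-tissue beta vector: baseline means plus per-sample noise."""
    _, means = probe_baseline(cfg)
    return np.clip(means + rng.normal(0.0, cfg.noise_sd, size=cfg.n_probes), 0.0, 1.0)


def generate_tumor_profile(
    baseline: np.ndarray, cfg: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Perturb a baseline: a random fraction of probes gets a persistent shift.

    Low-methylation probes shift up (hypermethylation) and high ones down
    (hypomethylation), magnitude Uniform(shift_low, shift_high), clipped to
    [0, 1].  No measurement noise is added here, so the expected Manhattan
    distance to the baseline is n_probes * rate * E|shift| as long as
    clipping does not bind.
    """
    altered = rng.random(baseline.size) < cfg.tumor_alteration_rate
    magnitude = rng.uniform(cfg.shift_low, cfg.shift_high, size=baseline.size)
    direction = np.where(baseline < 0.5, 1.0, -1.0)
    tumor = baseline + np.where(altered, direction * magnitude, 0.0)
    return np.clip(tumor, 0.0, 1.0)


def _progression_signature(cfg: CohortConfig) -> np.ndarray:
    """Fixed signed PT->recurrence effect at the first k probes (0 elsewhere)."""
    effect = np.zeros(cfg.n_probes)
    k = cfg.progression_probes
    if k > 0 and cfg.progression_effect != 0.0:
        signs = np.where(_component_rng(cfg).random(k) < 0.5, -1.0, 1.0)
        effect[:k] = signs * cfg.progression_effect
    return effect


def generate_matched_pair(
    cfg: CohortConfig, rng: np.random.Generator, clonal: bool
) -> tuple[np.ndarray, np.ndarray, str]:
    """One matched (PT, recurrence) pair of noiseless tumor profiles.

    Clonal: recurrence = PT plus independent per-probe drift with
    E|delta beta| = divergence, plus the cohort's progression signature.
    Non-clonal: an independent tumor grown on the same baseline.  Returns
    the truth label TR (clonal) or NP alongside the two vectors.
    """
    _, means = probe_baseline(cfg)
    pt = generate_tumor_profile(means, cfg, rng)
    if clonal:
        # half-normal |drift| has mean sigma*sqrt(2/pi); invert for target d
        sigma = cfg.divergence / np.sqrt(2.0 / np.pi)
        drift = rng.normal(0.0, sigma, size=cfg.n_probes) if sigma > 0 else 0.0
        rec = np.clip(pt + drift + _progression_signature(cfg), 0.0, 1.0)
        label = "TR"
    else:
        rec = generate_tumor_profile(means, cfg, rng)
        label = "NP"
    return pt, rec, label


def _noisy(x: np.ndarray, cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_sd == 0:
        return x.copy()
    return np.clip(x + rng.normal(0.0, cfg.noise_sd, size=x.size), 0.0, 1.0)


def _breakpoint_universe(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    # popularity weights: some breakpoints are recurrent in the population
    w = rng.pareto(2.0, size=cfg.n_breakpoint_loci) + 1.0
    return w / w.sum()


def _draw_breakpoints(
    weights: np.ndarray, cfg: CohortConfig, rng: np.random.Generator
) -> frozenset[int]:
    k = min(cfg.breakpoints_per_tumor, weights.size)
    return frozenset(rng.choice(weights.size, size=k, replace=False, p=weights))


def generate_cohort(cfg: CohortConfig) -> CohortData:
    """Simulate a full cohort: beta matrix, annotation, truth, survival.

    Exactly round(clonal_fraction * n_pairs) pairs are clonal (the first
    ones, before sample-id assignment).  n_missing_probes probes get one
    missing cell each, injected in distinct samples cyclically.  Output is
    bit-identical for identical configs.
    """
    rng = np.random.default_rng((cfg.seed, 0xDA7A))
    rec_role = RECURRENCE_ROLE[cfg.cohort]
    n_clonal = int(round(cfg.clonal_fraction * cfg.n_pairs))

    columns: dict[str, np.ndarray] = {}
    ann_rows = []
    truth_rows = []
    breakpoints: dict[str, frozenset[int]] = {}
    bp_weights = None
    if cfg.n_breakpoint_loci > 0:
        bp_weights = _breakpoint_universe(cfg, rng)

    for i in range(cfg.n_pairs):
        clonal = i < n_clonal
        pair_id = f"P{i + 1:02d}"
        pt_id, rec_id = f"{pair_id}_PT", f"{pair_id}_{rec_role}"
        pt, rec, label = generate_matched_pair(cfg, rng, clonal)
        columns[pt_id] = _noisy(pt, cfg, rng)
        columns[rec_id] = _noisy(rec, cfg, rng)
        ann_rows.append((pt_id, pair_id, "PT", cfg.cohort))
        ann_rows.append((rec_id, pair_id, rec_role, cfg.cohort))
        truth_rows.append((pair_id, clonal, label))
        if bp_weights is not None:
            bp_pt = _draw_breakpoints(bp_weights, cfg, rng)
            if clonal:
                keep = int(round(cfg.breakpoint_share * len(bp_pt)))
                kept = rng.choice(sorted(bp_pt), size=keep, replace=False)
                extra = _draw_breakpoints(bp_weights, cfg, rng)
                bp_rec = frozenset(kept) | frozenset(
                    sorted(extra)[: len(bp_pt) - keep]
                )
            else:
                bp_rec = _draw_breakpoints(bp_weights, cfg, rng)
            breakpoints[pt_id] = bp_pt
            breakpoints[rec_id] = bp_rec

    for j in range(cfg.n_normals):
        sid = f"N{j + 1:02d}"
        columns[sid] = generate_normal_profile(cfg, rng)
        ann_rows.append((sid, sid, "NORMAL", "NORMAL"))

    probe_ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    values = pd.DataFrame(columns, index=probe_ids)

    sample_ids = list(values.columns)
    n_miss = min(cfg.n_missing_probes, cfg.n_probes)
    if n_miss > 0:
        miss_probes = rng.choice(cfg.n_probes, size=n_miss, replace=False)
        for k, p in enumerate(sorted(miss_probes)):
            values.iloc[p, k % len(sample_ids)] = np.nan

    beta = BetaMatrix(values)
    annotation = SampleAnnotation(
        pd.DataFrame(ann_rows, columns=["sample_id", "pair_id", "role", "cohort"])
    )
    truth = pd.DataFrame(truth_rows, columns=["pair_id", "clonal", "label"])

    # survival: exponential with configured TR/NP hazard ratio, uniform censoring
    surv_rows = []
    for pair_id, _, label in truth_rows:
        hazard = cfg.baseline_hazard * (cfg.hazard_ratio if label == "TR" else 1.0)
        t_event = rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
        t_cens = rng.uniform(0.0, cfg.followup_years)
        surv_rows.append(
            (pair_id, float(min(t_event, t_cens)), int(t_event <= t_cens), label)
        )
    survival = pd.DataFrame(
        surv_rows, columns=["pair_id", "time_years", "event", "group"]
    )

    return CohortData(beta, annotation, truth, breakpoints or None, survival)


def generate_survival_records(
    n_per_group: int,
    hazard_ratio: float,
    rng: np.random.Generator,
    baseline_hazard: float = 0.08,
    followup_years: float = 12.0,
) -> pd.DataFrame:
    """Two-group exponential survival sample for calibration experiments."""
    rows = []
    for group, hz in (("NP", baseline_hazard), ("TR", baseline_hazard * hazard_ratio)):
        t_event = rng.exponential(1.0 / hz, size=n_per_group)
        t_cens = rng.uniform(0.0, followup_years, size=n_per_group)
        for te, tc in zip(t_event, t_cens):
            rows.append((group, float(min(te, tc)), int(te <= tc)))
    return pd.DataFrame(rows, columns=["group", "time_years", "event"])


def pis_surrogate(
    bp_a: frozenset[int], bp_b: frozenset[int], weights: np.ndarray | None = None
) -> float:
    """Breakpoint-sharing similarity in [0, 1] (simplified partial identity).

    Shared breakpoints are up-weighted when rare in the population
    (weight 1/frequency); the score is the weighted shared mass over the
    weighted union.  This is a synthetic stand-in used only to give
    simulated cohorts a copy-number-like second score; it is not the
    published breakpoint-frequency algorithm.
    """
    if not bp_a and not bp_b:
        return 0.0
    if weights is None:
        inv = {b: 1.0 for b in bp_a | bp_b}
    else:
        inv = {b: 1.0 / weights[b] for b in bp_a | bp_b}
    shared = sum(inv[b] for b in bp_a & bp_b)
    union = sum(inv[b] for b in bp_a | bp_b)
    return shared / union


def study_configs(
    n_probes: int = 27_578, seed: int = 0, n_normals: int = 22
) -> dict[str, CohortConfig]:
    """Cohort configs mirroring the study design.

    PT/AM: 20 pairs, essentially all clonal, with a 50-probe progression
    signature.  PT/LR: 17 pairs, roughly half clonal.  PT/CL: 11 pairs,
    all independent (contralateral tumors behave as new primaries).  The
    22 normal breast tissues ride along with the PT/LR cohort.
    """
    base = CohortConfig(n_probes=n_probes, seed=seed)
    return {
        "PT/AM": replace(
            base,
            cohort="PT/AM",
            n_pairs=20,
            clonal_fraction=1.0,
            progression_probes=50,
            progression_effect=0.12,
            hazard_ratio=1.0,
            seed=seed,
        ),
        "PT/LR": replace(
            base,
            cohort="PT/LR",
            n_pairs=17,
            clonal_fraction=0.5,
            n_normals=n_normals,
            n_breakpoint_loci=200,
            seed=seed + 1,
        ),
        "PT/CL": replace(
            base, cohort="PT/CL", n_pairs=11, clonal_fraction=0.0, seed=seed + 2
        ),
    }
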