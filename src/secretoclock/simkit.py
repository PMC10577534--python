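"""Synthetic plasma-proteome cohorts with recorded ground truth.

Emulates the statistical structure the analysis pipeline assumes:

* an aptamer panel with a fraction of unannotated probes and a few
  human/mouse ortholog duplicate pairs;
* a cross-sectional healthy reference cohort (default 81 mice, 1-30 months)
  in which a fraction of proteins follow linear or gently nonlinear age
  trajectories on the log2 RFU scale;
* two progeroid case/control studies (default 10 mice per group, 5 male /
  5 female) in which progeroid samples receive (i) genotype effects that are
  predominantly negative, with the second model's effects attenuated by a
  fixed factor relative to the first, (ii) age-trajectory evaluation at a
  shifted age (chronological age + Delta), which makes the clock's age-gap
  estimand equal Delta by construction, and (iii) sex-dependent genotype
  effects on a handful of proteins; every sample carries its cohort's batch
  offset.

All randomness flows from one integer seed. Aptamer-level truth (baselines,
slopes, effects, batch offsets) is drawn from a child stream derived from the
seed alone, so the reference and case/control generators agree on the
underlying biology whenever they share a config and panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel_io import AptamerPanel, ProteomeMatrix, SampleMetadata

LMNA_MODEL = "LmnaG609G"
ZMP_MODEL = "Zmpste24KO"


class SimulationError(ValueError):
    pass


@dataclass
class AgingConfig:
    """Reference-cohort parameters (cross-sectional healthy mice)."""

    n_samples: int = 81
    age_min: float = 1.0           # months
    age_max: float = 30.0          # months
    frac_age_associated: float = 0.15
    slope_sd: float = 0.05         # log2 RFU per month
    nonlinear_fraction: float = 0.2


@dataclass
class CaseControlConfig:
    """Progeroid case/control study parameters (two models, two cohorts)."""

    n_per_group: int = 10
    sex_balance: bool = True       # 5/5 male-female within each group
    frac_de: float = 0.25
    frac_down_among_de: float = 0.85
    effect_sd: float = 0.8         # log2 RFU
    n_interaction_proteins: int = 5
    interaction_effect: float = 1.5  # log2 RFU, random sign per protein
    batch_shift_sd: float = 0.2    # log2 RFU per cohort per aptamer
    attenuation: float = 0.47      # Zmpste24 effect / Lmna effect
    age_acceleration_lmna: float = 10.0  # months
    age_acceleration_zmp: float = 7.0    # months
    age_lmna: float = 4.75         # sampling age, months
    age_zmp: float = 6.5


@dataclass
class SimulationConfig:
    seed: int = 0
    n_aptamers: int = 600
    frac_unmapped: float = 0.05
    n_ortholog_pairs: int = 3
    baseline_mean: float = 10.0    # log2 RFU
    baseline_sd: float = 1.5
    noise_sd: float = 0.3          # log2 RFU
    noise_mode: str = "constant"   # or "mean_dependent"
    aging: AgingConfig = field(default_factory=AgingConfig)
    case_control: CaseControlConfig = field(default_factory=CaseControlConfig)

    def __post_init__(self) -> None:
        cc = self.case_control
        for name, frac in (
            ("frac_unmapped", self.frac_unmapped),
            ("frac_age_associated", self.aging.frac_age_associated),
            ("nonlinear_fraction", self.aging.nonlinear_fraction),
            ("frac_de", cc.frac_de),
            ("frac_down_among_de", cc.frac_down_among_de),
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {frac}")
        for name, sd in (
            ("noise_sd", self.noise_sd),
            ("slope_sd", self.aging.slope_sd),
            ("effect_sd", cc.effect_sd),
            ("batch_shift_sd", cc.batch_shift_sd),
        ):
            if sd < 0:
                raise SimulationError(f"{name} must be >= 0, got {sd}")
        if cc.n_per_group < 6:
            raise SimulationError(
                "n_per_group must be >= 6 to permit >=3 train / >=3 inference splits"
            )
        if self.noise_mode not in ("constant", "mean_dependent"):
            raise SimulationError(f"unknown noise_mode {self.noise_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "aging" in d and isinstance(d["aging"], dict):
            d["aging"] = AgingConfig(**d["aging"])
        if "case_control" in d and isinstance(d["case_control"], dict):
            d["case_control"] = CaseControlConfig(**d["case_control"])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth of injected effects, one record per simulated aptamer."""

    per_aptamer: pd.DataFrame
    # columns: aptamer_id, baseline, age_slope, traj_class, amplitude,
    #          effect_lmna, effect_zmp, is_interaction, interaction_effect
    batch_offsets: pd.DataFrame     # cohorts x aptamers, log2 RFU
    delta: dict[str, float]         # injected age acceleration per model, months

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_aptamer": self.per_aptamer.to_dict(orient="list"),
            "batch_offsets": {
                "index": list(self.batch_offsets.index),
                "columns": list(self.batch_offsets.columns),
                "values": self.batch_offsets.to_numpy().tolist(),
            },
            "delta": self.delta,
        }
        Path(path).write_text(json.dumps(payload) + "\n")


# ---------------------------------------------------------------------------
# Seed routing: independent child streams for panel, truth and each cohort.
# ---------------------------------------------------------------------------

def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


_PANEL_STREAM, _TRUTH_STREAM, _AGING_STREAM, _PROGERIA_STREAM = range(4)


def simulate_panel(config: SimulationConfig) -> AptamerPanel:
    """Simulate an aptamer annotation table.

    ``round(n_aptamers * frac_unmapped)`` aptamers have no gene symbol and
    ``n_ortholog_pairs`` gene symbols are measured by one human-target and one
    mouse-target aptamer each; all other aptamers map to unique symbols.
    """
    n = config.n_aptamers
    n_unmapped = round(n * config.frac_unmapped)
    n_pair_aptamers = 2 * config.n_ortholog_pairs
    if n < n_pair_aptamers:
        raise SimulationError("n_aptamers < 2 * n_ortholog_pairs")
    if n_unmapped + n_pair_aptamers > n:
        raise SimulationError("frac_unmapped and n_ortholog_pairs exceed panel size")
    rng = _child_rng(config.seed, _PANEL_STREAM)

    records = []
    serials = rng.choice(np.arange(10000, 99999), size=n, replace=False)
    k = 0
    for i in range(config.n_ortholog_pairs):
        sym = f"DUP{i + 1:03d}"
        for species in ("human", "mouse"):
            records.append((f"seq.{serials[k]}.{k % 100}", sym, f"P{serials[k]:05d}", species))
            k += 1
    for _ in range(n_unmapped):
        records.append((f"seq.{serials[k]}.{k % 100}", "", "", "unknown"))
        k += 1
    g = 0
    while k < n:
        g += 1
        species = "human" if rng.random() < 0.9 else "mouse"
        records.append((f"seq.{serials[k]}.{k % 100}", f"GENE{g:05d}", f"Q{serials[k]:05d}", species))
        k += 1
    df = pd.DataFrame(records, columns=["aptamer_id", "gene_symbol", "uniprot_id", "species_target"])
    return AptamerPanel(df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True))


def _draw_truth(panel: AptamerPanel, config: SimulationConfig) -> SimulationTruth:
    """Aptamer-level ground truth, identical across cohort generators."""
    rng = _child_rng(config.seed, _TRUTH_STREAM)
    ids = panel.aptamer_ids
    p = len(ids)
    ag, cc = config.aging, config.case_control

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    n_assoc = round(p * ag.frac_age_associated)
    assoc_idx = rng.choice(p, size=n_assoc, replace=False)
    slope = np.zeros(p)
    slope[assoc_idx] = rng.normal(0.0, ag.slope_sd, size=n_assoc)
    traj = np.array(["flat"] * p, dtype=object)
    n_nonlin = round(n_assoc * ag.nonlinear_fraction)
    nonlin_idx = rng.choice(assoc_idx, size=n_nonlin, replace=False) if n_assoc else []
    traj[assoc_idx] = "linear"
    traj[nonlin_idx] = "nonlinear"
    amplitude = np.zeros(p)
    # bend amplitude comparable to a quarter of the linear span over the age range
    amplitude[nonlin_idx] = rng.normal(
        0.0, ag.slope_sd * (ag.age_max - ag.age_min) / 4.0, size=len(nonlin_idx)
    )

    n_de = round(p * cc.frac_de)
    de_idx = rng.choice(p, size=n_de, replace=False)
    effect_lmna = np.zeros(p)
    magnitude = np.abs(rng.normal(0.0, cc.effect_sd, size=n_de))
    sign = np.where(rng.random(n_de) < cc.frac_down_among_de, -1.0, 1.0)
    effect_lmna[de_idx] = sign * magnitude
    effect_zmp = cc.attenuation * effect_lmna

    is_inter = np.zeros(p, dtype=bool)
    inter_effect = np.zeros(p)
    n_inter = min(cc.n_interaction_proteins, p)
    inter_idx = rng.choice(p, size=n_inter, replace=False)
    is_inter[inter_idx] = True
    inter_effect[inter_idx] = rng.choice([-1.0, 1.0], size=n_inter) * cc.interaction_effect

    offsets = pd.DataFrame(
        rng.normal(0.0, cc.batch_shift_sd, size=(2, p)),
        index=["cohortA", "cohortB"],
        columns=ids,
    )
    per_apt = pd.DataFrame(
        {
            "aptamer_id": ids,
            "baseline": baseline,
            "age_slope": slope,
            "traj_class": traj,
            "amplitude": amplitude,
            "effect_lmna": effect_lmna,
            "effect_zmp": effect_zmp,
            "is_interaction": is_inter,
            "interaction_effect": inter_effect,
        }
    )
    return SimulationTruth(
        per_aptamer=per_apt,
        batch_offsets=offsets,
        delta={LMNA_MODEL: cc.age_acceleration_lmna, ZMP_MODEL: cc.age_acceleration_zmp},
    )


def _trajectory(truth: SimulationTruth, ages: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Noise-free expected log2 RFU, samples x aptamers, at the given ages."""
    ag = config.aging
    t = truth.per_aptamer
    base = t["baseline"].to_numpy()
    slope = t["age_slope"].to_numpy()
    amp = t["amplitude"].to_numpy()
    span = max(ag.age_max - ag.age_min, 1e-12)
    phase = np.sin(np.pi * (ages[:, None] - ag.age_min) / span)
    return base[None, :] + np.outer(ages, slope) + phase * amp[None, :]


def _noise_sd_per_aptamer(truth: SimulationTruth, config: SimulationConfig) -> np.ndarray:
    """Per-aptamer noise sd; in mean-dependent mode variance doubles from the
    lowest-baseline aptamer to the highest."""
    p = len(truth.per_aptamer)
    if config.noise_mode == "constant":
        return np.full(p, config.noise_sd)
    b = truth.per_aptamer["baseline"].to_numpy()
    span = b.max() - b.min()
    rel = (b - b.min()) / span if span > 0 else np.zeros(p)
    return config.noise_sd * np.sqrt(1.0 + rel)


def simulate_aging_cohort(
    panel: AptamerPanel, config: SimulationConfig
) -> tuple[ProteomeMatrix, SampleMetadata, SimulationTruth]:
    """Cross-sectional healthy reference cohort (ages uniform on [min, max])."""
    truth = _draw_truth(panel, config)
    rng = _child_rng(config.seed, _AGING_STREAM)
    ag = config.aging
    n = ag.n_samples
    ages = rng.uniform(ag.age_min, ag.age_max, size=n)
    sexes = np.array(["male", "female"])[np.arange(n) % 2]
    rng.shuffle(sexes)
    sample_ids = [f"ref{i + 1:03d}" for i in range(n)]
    mean = _trajectory(truth, ages, config)
    sd = _noise_sd_per_aptamer(truth, config)
    values = mean + rng.standard_normal(mean.shape) * sd[None, :]
    matrix = ProteomeMatrix(pd.DataFrame(values, index=sample_ids, columns=panel.aptamer_ids))
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "genotype": "wildtype",
                "model": "reference",
                "sex": sexes,
                "cohort": "reference",
                "age_months": ages,
            }
        )
    )
    return matrix, meta, truth


def simulate_progeria_cohorts(
    panel: AptamerPanel, config: SimulationConfig
) -> tuple[ProteomeMatrix, SampleMetadata, SimulationTruth]:
    """Two case/control studies: wildtype + progeroid groups for each model.

    Progeroid samples get their model's genotype effect, age-trajectory
    evaluation at ``age + Delta_model``, and (for interaction proteins) a
    sex-dependent genotype effect added for females. Each sample carries its
    cohort's per-aptamer batch offset. Samples are assigned to the two
    cohorts in a balanced way within each group so batch is not confounded
    with genotype or model.
    """
    truth = _draw_truth(panel, config)
    rng = _child_rng(config.seed, _PROGERIA_STREAM)
    cc = config.case_control
    n = cc.n_per_group
    t = truth.per_aptamer
    effect = {LMNA_MODEL: t["effect_lmna"].to_numpy(), ZMP_MODEL: t["effect_zmp"].to_numpy()}
    inter = np.where(t["is_interaction"].to_numpy(), t["interaction_effect"].to_numpy(), 0.0)
    sd = _noise_sd_per_aptamer(truth, config)

    rows, blocks = [], []
    idx = 0
    for model, group_age in ((LMNA_MODEL, cc.age_lmna), (ZMP_MODEL, cc.age_zmp)):
        for genotype in ("wildtype", "progeroid"):
            if cc.sex_balance:
                sexes = ["male"] * (n // 2) + ["female"] * (n - n // 2)
            else:
                sexes = list(rng.choice(["male", "female"], size=n))
            cohorts = np.array(["cohortA", "cohortB"])[np.arange(n) % 2]
            rng.shuffle(cohorts)
            for j in range(n):
                idx += 1
                sid = f"s{idx:03d}"
                delta = truth.delta[model] if genotype == "progeroid" else 0.0
                eff_age = group_age + delta
                mean = _trajectory(truth, np.array([eff_age]), config)[0]
                if genotype == "progeroid":
                    mean = mean + effect[model]
                    if sexes[j] == "female":
                        mean = mean + inter
                mean = mean + truth.batch_offsets.loc[cohorts[j]].to_numpy()
                blocks.append(mean + rng.standard_normal(mean.shape) * sd)
                rows.append(
                    {
                        "sample_id": sid,
                        "genotype": genotype,
                        "model": model,
                        "sex": sexes[j],
                        "cohort": cohorts[j],
                        "age_months": group_age,
                    }
                )
    sample_ids = [r["sample_id"] for r in rows]
    matrix = ProteomeMatrix(
        pd.DataFrame(np.vstack(blocks), index=sample_ids, columns=panel.aptamer_ids)
    )
    meta = SampleMetadata(pd.DataFrame(rows))
    return matrix, meta, truth
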