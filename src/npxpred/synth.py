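"""Synthetic NPX cohort generation with known ground truth.

Cohorts are generated at the NPX level: protein z-scores are drawn
multivariate normal with block-correlation structure (plus an optional
bimodal latent factor for endotype tests), the binary response follows
a logistic model in the standardised features, and each protein is
mapped onto an arbitrary NPX scale with a per-protein limit of
detection set at a lower quantile so that below-LoD masking produces
the configured missingness.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ingest import ClinicalTable, NpxDataset

__all__ = ["SynthConfig", "GroundTruth", "generate_cohort", "make_paper_like_cohort"]

DEFAULT_PANELS = ("CVD_II", "CVD_III", "IMMUNE", "INFLAM")


@dataclass
class SynthConfig:
    n_patients: int = 89
    n_proteins: int = 352
    n_informative: int = 17
    effect_size: float = 1.5  # |log-odds per SD|; signs randomised
    effect_sizes: np.ndarray | None = None  # explicit signed overrides
    n_blocks: int = 8
    block_size: int = 6
    rho: float = 0.5  # within-block correlation
    below_lod_rate: float = 0.015
    qc_flag_rate: float = 0.005
    prevalence: float = 60 / 89
    exact_prevalence: bool = False  # force round(prevalence * n) responders
    male_prevalence: float = 1 - 68 / 89
    gender_effect: float = -1.0  # log-odds for male (responders skew female)
    das_mean: float = 5.4
    das_sd: float = 1.3
    das_effect: float = 0.6  # log-odds per SD of baseline DAS
    endotype_strength: float = 0.0
    endotype_fraction: float = 0.15  # fraction of proteins carrying the factor
    panels: tuple = DEFAULT_PANELS
    t_noise_df: float | None = None  # heavy-tailed noise stress test
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("below_lod_rate", "qc_flag_rate", "prevalence", "male_prevalence", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_informative > self.n_proteins:
            raise ValueError("n_informative exceeds n_proteins")
        if self.das_sd <= 0:
            raise ValueError("das_sd must be > 0")
        if self.below_lod_rate >= 0.5:
            raise ValueError("below_lod_rate would hollow out the matrix")


@dataclass
class GroundTruth:
    informative: dict  # protein id -> true log-odds coefficient per SD
    intercept: float
    gender_effect: float
    das_effect: float
    endotype_proteins: list
    endotype_strength: float
    endotype_group: np.ndarray  # +1/-1 latent factor per patient
    response_probability: np.ndarray

    def to_json(self, path) -> None:
        d = asdict(self)
        d["endotype_group"] = self.endotype_group.tolist()
        d["response_probability"] = self.response_probability.tolist()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2)


def _protein_z(
    cfg: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list, np.ndarray]:
    """Standard-normal protein matrix with correlated blocks and the
    optional latent endotype factor; returns (z, endotype protein idx)."""
    n, p = cfg.n_patients, cfg.n_proteins
    if cfg.t_noise_df:
        eps = rng.standard_t(cfg.t_noise_df, size=(n, p))
        eps /= np.sqrt(cfg.t_noise_df / (cfg.t_noise_df - 2))
    else:
        eps = rng.standard_normal((n, p))
    z = eps.copy()
    in_block_total = min(cfg.n_blocks * cfg.block_size, p)
    for b in range(cfg.n_blocks):
        lo = b * cfg.block_size
        hi = min(lo + cfg.block_size, in_block_total)
        if lo >= hi:
            break
        f = rng.standard_normal(n)
        z[:, lo:hi] = np.sqrt(cfg.rho) * f[:, None] + np.sqrt(1 - cfg.rho) * eps[:, lo:hi]
    endo_idx: list = []
    group = np.ones(n)
    if cfg.endotype_strength > 0:
        n_endo = max(2, int(round(cfg.endotype_fraction * p)))
        endo_idx = list(range(p - n_endo, p))  # keep clear of correlated blocks
        group = rng.choice([-1.0, 1.0], size=n)
        z[:, endo_idx] += cfg.endotype_strength * group[:, None]
    return z, endo_idx, group


def generate_cohort(
    cfg: SynthConfig,
) -> tuple[NpxDataset, ClinicalTable, GroundTruth]:
    """Draw one synthetic cohort; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_patients, cfg.n_proteins
    z, endo_idx, endo_group = _protein_z(cfg, rng)

    # clinical covariates
    gender = (rng.random(n) < cfg.male_prevalence).astype(int)  # male = 1
    a, b = (0 - cfg.das_mean) / cfg.das_sd, (10 - cfg.das_mean) / cfg.das_sd
    das = stats.truncnorm.rvs(
        a, b, loc=cfg.das_mean, scale=cfg.das_sd, size=n, random_state=rng
    )
    das_z = (das - cfg.das_mean) / cfg.das_sd

    # informative proteins and the response model
    info_idx = rng.choice(p, size=cfg.n_informative, replace=False)
    if cfg.effect_sizes is not None:
        betas = np.asarray(cfg.effect_sizes, dtype=float)
        if betas.shape != (cfg.n_informative,):
            raise ValueError("effect_sizes must have length n_informative")
    else:
        betas = cfg.effect_size * rng.choice([-1.0, 1.0], size=cfg.n_informative)
    eta_x = z[:, info_idx] @ betas + cfg.gender_effect * gender + cfg.das_effect * das_z

    def _excess(b0):
        return np.mean(1 / (1 + np.exp(-(b0 + eta_x)))) - cfg.prevalence

    intercept = float(optimize.brentq(_excess, -30, 30))
    prob = 1 / (1 + np.exp(-(intercept + eta_x)))
    if cfg.exact_prevalence:
        n_resp = int(round(cfg.prevalence * n))
        chosen = rng.choice(n, size=n_resp, replace=False, p=prob / prob.sum())
        response = np.zeros(n, dtype=int)
        response[chosen] = 1
    else:
        response = (rng.random(n) < prob).astype(int)

    # NPX scale, LoD and QC
    mu_p = rng.uniform(1.0, 10.0, size=p)
    sd_p = rng.uniform(0.4, 1.5, size=p)
    npx = z * sd_p + mu_p
    if cfg.below_lod_rate > 0:
        lod = np.quantile(npx, cfg.below_lod_rate, axis=0)
    else:
        lod = npx.min(axis=0) - 1.0
    panels = [cfg.panels[int(j * len(cfg.panels) / p)] for j in range(p)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    protein_ids = [f"P{j + 1:04d}:{panels[j]}" for j in range(p)]
    qc = pd.DataFrame(
        rng.random((n, len(cfg.panels))) < cfg.qc_flag_rate,
        index=sample_ids,
        columns=list(cfg.panels),
    )
    ds = NpxDataset(
        sample_ids=sample_ids,
        protein_ids=protein_ids,
        values=npx,
        lod=lod,
        panels=panels,
        qc_flag=qc,
    )

    delta = np.where(
        response == 1, rng.normal(-3.0, 1.1, size=n), rng.normal(-0.2, 1.1, size=n)
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "patient_id": sample_ids,
                "gender": gender,
                "age": np.clip(rng.normal(60.8, 11.3, size=n), 20, 95).round(1),
                "disease_duration": np.clip(
                    rng.normal(9.5, 9.0, size=n), 0, 50
                ).round(1),
                "baseline_das": das.round(2),
                "delta_das": delta.round(2),
                "response": response,
            }
        )
    )
    truth = GroundTruth(
        informative={protein_ids[j]: float(b) for j, b in zip(info_idx, betas)},
        intercept=intercept,
        gender_effect=cfg.gender_effect,
        das_effect=cfg.das_effect,
        endotype_proteins=[protein_ids[j] for j in endo_idx],
        endotype_strength=cfg.endotype_strength,
        endotype_group=endo_group,
        response_probability=prob,
    )
    return ds, clinical, truth


def make_paper_like_cohort(
    seed: int = 0,
) -> tuple[NpxDataset, ClinicalTable, GroundTruth]:
    """Preset cohort: 89 patients, 352 proteins on 4 panels of 88,
    exactly 60 responders, 17 informative proteins with published-scale
    coefficient magnitudes, < 2% below-LoD missingness."""
    rng = np.random.default_rng(seed)
    magnitudes = rng.uniform(0.25, 3.0, size=17)
    signs = rng.choice([-1.0, 1.0], size=17)
    cfg = SynthConfig(
        n_patients=89,
        n_proteins=352,
        n_informative=17,
        effect_sizes=magnitudes * signs,
        n_blocks=10,
        block_size=8,
        rho=0.5,
        below_lod_rate=0.01,
        qc_flag_rate=0.005,
        prevalence=60 / 89,
        exact_prevalence=True,
        seed=seed,
    )
    return generate_cohort(cfg)
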