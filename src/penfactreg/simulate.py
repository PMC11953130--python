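"""Synthetic multi-environment trials with envirotype structure.

The generator emulates the structure of balanced MET datasets used for
GoEn prediction: environments belong to a small number of discrete
environmental scenarios (envirotypes, e.g. well-watered vs water-deficit);
EC values are Gaussian around envirotype-specific means; each genotype has a
main effect and a sparse vector of true sensitivities (only ``n_active`` of
the ``n_c`` ECs carry signal); and i.i.d. Gaussian noise is added per
environment with variance calibrated so that the expected within-environment
heritability hits a target (around 0.5 for a medium-heritability trait).

Both the training and the test environments draw their envirotypes from the
same frequency table, so every scenario present in the test set is also
observed in training — the regime in which transfer of reaction-norm
parameters to new environments can work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    AlignedDataset,
    ECTable,
    MarkerMatrix,
    PhenotypeTable,
    align_and_validate,
)
from .exceptions import ValidationError

__all__ = ["Envirotype", "SimConfig", "SimTruth", "simulate_met", "calibrate_noise"]


@dataclass
class Envirotype:
    """One environmental scenario: EC means/sds and its frequency of occurrence."""

    label: str
    mean: np.ndarray
    sd: np.ndarray
    frequency: float


@dataclass
class SimConfig:
    """Configuration of a simulated MET.

    Defaults describe a mid-sized balanced trial series: 50 genotypes, 60
    training and 20 test environments, 20 candidate ECs of which 3 carry true
    genotype-specific sensitivity, environment main effects clearly larger
    than genotype main effects (sd 2.0 vs 1.0 on the trait scale), slope sd
    0.5 per active EC, and within-environment heritability 0.5.

    The default EC mode is genotype_specific (each genotype sees a slightly
    different covariate value per environment, a proxy for phenology-adapted
    covariates).  Besides realism, this keeps the unpenalized model
    identifiable: with ECs strictly constant within environment, the
    genotype-summed sensitivity columns are absorbed by the environment main
    effects and the lambda = 0 design is rank deficient.
    """

    n_g: int = 50
    n_e_train: int = 60
    n_e_test: int = 20
    n_c: int = 20
    n_active: int = 3
    envirotypes: list[Envirotype] | None = None
    n_envirotypes: int = 4
    envirotype_mean_sd: float = 1.0  # spread of envirotype EC means
    within_envirotype_sd: float = 0.5  # EC spread around the envirotype mean
    sensitivity_scale: float = 0.5
    sd_g: float = 1.0
    sd_e: float = 2.0
    mu: float = 10.0
    h2: float = 0.5
    mode: str = "genotype_specific"
    genotype_jitter_sd: float = 0.1  # genotype-specific EC jitter (phenology proxy)
    n_markers: int | None = None
    n_causal: int | None = None
    marker_determined: bool = False  # g and B built from causal marker effects
    ec_correlation: np.ndarray | None = None  # optional EC correlation within envirotype
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.h2 <= 1:
            raise ValidationError("h2 must be in (0, 1]")
        if self.n_active > self.n_c:
            raise ValidationError("n_active cannot exceed n_c")
        if self.mode not in ("env_level", "genotype_specific"):
            raise ValidationError(f"unknown EC mode {self.mode!r}")
        if self.marker_determined and not self.n_markers:
            raise ValidationError("marker_determined requires n_markers")
        if self.envirotypes is not None:
            total = sum(et.frequency for et in self.envirotypes)
            if not np.isclose(total, 1.0):
                raise ValidationError("envirotype frequencies must sum to 1")


@dataclass
class SimTruth:
    """Ground-truth parameters of a simulated MET, for recovery tests."""

    mu: float
    g: pd.Series  # per genotype
    e: pd.Series  # per environment, train AND test
    B: pd.DataFrame  # genotypes x ECs, inactive columns exactly 0
    active_ecs: list[str]
    sigma2: pd.Series  # per-environment error variance
    genetic_values: pd.DataFrame  # genotypes x environments, noise-free Y
    envirotype_of: dict[str, str]


def calibrate_noise(genetic_values: pd.DataFrame, h2: float) -> pd.Series:
    """Per-environment error variance hitting a target within-env heritability.

    sigma2_j = Var_genotypes(genetic values in env j) * (1 - h2) / h2, so the
    expected heritability Var_g / (Var_g + sigma2_j) equals ``h2``.
    """
    if not 0 < h2 <= 1:
        raise ValidationError("h2 must be in (0, 1]")
    if genetic_values.shape[0] < 2:
        raise ValidationError("need at least 2 genotypes per environment")
    var_g = genetic_values.var(axis=0, ddof=1)
    if h2 < 1 and (var_g <= 0).any():
        bad = var_g.index[var_g <= 0].tolist()
        raise ValidationError(f"zero genetic variance in environment(s) {bad[:5]}")
    return var_g * (1.0 - h2) / h2


def _default_envirotypes(cfg: SimConfig, rng: np.random.Generator) -> list[Envirotype]:
    ets = []
    for k in range(cfg.n_envirotypes):
        ets.append(
            Envirotype(
                label=f"ET{k + 1}",
                mean=rng.normal(0.0, cfg.envirotype_mean_sd, cfg.n_c),
                sd=np.full(cfg.n_c, cfg.within_envirotype_sd),
                frequency=1.0 / cfg.n_envirotypes,
            )
        )
    return ets


def _assign_envirotypes(n: int, ets: list[Envirotype], rng: np.random.Generator) -> list[int]:
    """Largest-remainder proportional allocation, then shuffled.

    Guarantees the envirotype composition follows the configured frequencies
    in both the training and the test block, so every test scenario is also
    represented in training.
    """
    freqs = np.array([et.frequency for et in ets])
    counts = np.floor(freqs * n).astype(int)
    rem = freqs * n - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(len(ets)), counts)
    return list(rng.permutation(labels))


def simulate_met(cfg: SimConfig):
    """Generate (AlignedDataset, MarkerMatrix | None, SimTruth).

    Output is bit-reproducible for a fixed ``cfg.seed``.  Test environments
    receive true main effects and observed (noisy) phenotypes too — used for
    evaluation only, never shown to the fitting routines, which see only the
    train/test split labels on the aligned dataset.
    """
    rng = np.random.default_rng(cfg.seed)
    genotypes = [f"g{i + 1:03d}" for i in range(cfg.n_g)]
    train_envs = [f"e{j + 1:03d}" for j in range(cfg.n_e_train)]
    test_envs = [f"t{j + 1:03d}" for j in range(cfg.n_e_test)]
    all_envs = train_envs + test_envs

    ets = cfg.envirotypes or _default_envirotypes(cfg, rng)
    et_idx = _assign_envirotypes(cfg.n_e_train, ets, rng) + _assign_envirotypes(
        cfg.n_e_test, ets, rng
    )
    envirotype_of = {env: ets[k].label for env, k in zip(all_envs, et_idx)}

    chol = None
    if cfg.ec_correlation is not None:
        chol = np.linalg.cholesky(np.asarray(cfg.ec_correlation))
    env_ecs = np.empty((len(all_envs), cfg.n_c))
    for row, k in enumerate(et_idx):
        z = rng.standard_normal(cfg.n_c)
        if chol is not None:
            z = chol @ z
        env_ecs[row] = ets[k].mean + ets[k].sd * z

    # genotype parameters
    markers = None
    if cfg.n_markers:
        maf = rng.uniform(0.1, 0.5, cfg.n_markers)
        M = rng.binomial(2, maf, size=(cfg.n_g, cfg.n_markers)).astype(float)
        markers = MarkerMatrix(
            values=pd.DataFrame(
                M, index=pd.Index(genotypes, name="genotype"),
                columns=[f"m{k + 1:04d}" for k in range(cfg.n_markers)],
            )
        )
    active = sorted(rng.choice(cfg.n_c, size=cfg.n_active, replace=False).tolist())
    B = np.zeros((cfg.n_g, cfg.n_c))
    if cfg.marker_determined:
        n_causal = cfg.n_causal or max(1, cfg.n_markers // 10)
        causal = rng.choice(cfg.n_markers, size=n_causal, replace=False)
        Mc = markers.values.to_numpy()[:, causal]
        Mc = Mc - Mc.mean(axis=0)

        def _marker_trait(scale: float, size: int) -> np.ndarray:
            eff = rng.normal(0.0, 1.0, (n_causal, size))
            raw = Mc @ eff
            sd = raw.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            return raw / sd * scale

        g = _marker_trait(cfg.sd_g, 1).ravel()
        if cfg.n_active:
            B[:, active] = _marker_trait(cfg.sensitivity_scale, cfg.n_active)
    else:
        g = rng.normal(0.0, cfg.sd_g, cfg.n_g)
        if cfg.n_active:
            B[:, active] = rng.normal(0.0, cfg.sensitivity_scale, (cfg.n_g, cfg.n_active))
    e = rng.normal(0.0, cfg.sd_e, len(all_envs))

    ec_names = [f"ec{t + 1:02d}" for t in range(cfg.n_c)]
    if cfg.mode == "env_level":
        V = np.broadcast_to(env_ecs[None, :, :], (cfg.n_g, len(all_envs), cfg.n_c))
        ec_values = pd.DataFrame(env_ecs, index=pd.Index(all_envs, name="env"), columns=ec_names)
        ecs = ECTable(ec_names=ec_names, values=ec_values, mode="env_level")
    else:
        V = env_ecs[None, :, :] + rng.normal(
            0.0, cfg.genotype_jitter_sd, (cfg.n_g, len(all_envs), cfg.n_c)
        )
        idx = pd.MultiIndex.from_product([all_envs, genotypes], names=["env", "genotype"])
        flat = V.transpose(1, 0, 2).reshape(-1, cfg.n_c)  # env-major to match the index
        ecs = ECTable(ec_names=ec_names, values=pd.DataFrame(flat, index=idx, columns=ec_names), mode="genotype_specific")

    gxe = np.einsum("gjc,gc->gj", V, B)
    genetic = cfg.mu + g[:, None] + e[None, :] + gxe
    genetic_df = pd.DataFrame(genetic, index=pd.Index(genotypes, name="genotype"), columns=all_envs)

    if cfg.h2 == 1.0:
        sigma2 = pd.Series(0.0, index=all_envs)
        Y = genetic.copy()
    else:
        sigma2 = calibrate_noise(genetic_df, cfg.h2)
        noise = rng.standard_normal(genetic.shape) * np.sqrt(sigma2.to_numpy())[None, :]
        Y = genetic + noise

    records = pd.DataFrame(
        {
            "genotype": np.repeat(genotypes, len(all_envs)),
            "env": np.tile(all_envs, cfg.n_g),
            "y": Y.ravel(),
        }
    )
    pheno = PhenotypeTable.from_frame(records)
    data = align_and_validate(pheno, ecs, test_envs=test_envs)

    truth = SimTruth(
        mu=cfg.mu,
        g=pd.Series(g, index=genotypes),
        e=pd.Series(e, index=all_envs),
        B=pd.DataFrame(B, index=pd.Index(genotypes, name="genotype"), columns=ec_names),
        active_ecs=[ec_names[t] for t in active],
        sigma2=pd.Series(sigma2, index=all_envs),
        genetic_values=genetic_df,
        envirotype_of=envirotype_of,
    )
    return data, markers, truth


def write_simulation(data: AlignedDataset, markers, truth: SimTruth, directory) -> None:
    """Write the standard CSVs (phenotypes, ECs, split, truth, markers)."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    data.phenotypes.df.to_csv(d / "phenotypes.csv", index=False)
    data.ecs.values.to_csv(d / "ecs.csv")
    pd.Series(data.split, name="split").rename_axis("env").to_csv(d / "split.csv")
    truth.B.to_csv(d / "true_sensitivities.csv")
    truth.genetic_values.to_csv(d / "genetic_values.csv")
    if markers is not None:
        markers.values.to_csv(d / "markers.csv")
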