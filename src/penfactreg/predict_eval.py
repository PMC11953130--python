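"""Environment-centred prediction for new environments and per-environment accuracy.

For a new (test) environment the environment main effect is unknown, so
predictions are environment-centred:

    y_hat[i, j] = mu + g_i + sum_t v[i, j, t] * beta[i, t]

Within-environment Pearson correlation between y_hat and observations is
unaffected by the missing constant, which is why the per-environment r and
its unweighted average over environments (APCOR_Env) are the accuracy
criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ECTable, PhenotypeTable
from .exceptions import GoEnViolationError, ValidationError

__all__ = [
    "PredictionTable",
    "AccuracyReport",
    "predict_goen",
    "pearson_per_env",
    "apcor_env",
    "accuracy_report",
]


@dataclass
class PredictionTable:
    """Rows of (genotype, env, y_hat[, y_obs]); ``centred`` flags that the
    environment main effect is excluded from y_hat."""

    df: pd.DataFrame
    centred: bool = True

    def with_observed(self, pheno: PhenotypeTable) -> "PredictionTable":
        """Attach observed values by (genotype, env); unobserved cells get NaN."""
        obs = pheno.df.rename(columns={"y": "y_obs"})
        df = self.df.drop(columns=["y_obs"], errors="ignore").merge(
            obs, on=["genotype", "env"], how="left"
        )
        return PredictionTable(df=df, centred=self.centred)


@dataclass
class AccuracyReport:
    """Per-environment Pearson r and their unweighted mean (APCOR_Env)."""

    per_env: dict[str, float | None]
    apcor_env: float
    n_envs_used: int
    n_envs_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "env": list(self.per_env),
                "r": [np.nan if v is None else v for v in self.per_env.values()],
            }
        )


def predict_goen(
    fit,
    ecs: ECTable,
    genotypes,
    envs,
    observed: PhenotypeTable | None = None,
) -> PredictionTable:
    """Predict environment-centred performance for trained genotypes.

    ``fit`` provides mu, g and the sensitivities B on the original EC scale,
    so raw EC values are used directly; this is arithmetically identical to
    combining training-standardized ECs with design-scale slopes.  Genotypes
    absent from training have no reaction-norm parameters and are rejected.
    """
    genotypes = [str(g) for g in genotypes]
    envs = [str(e) for e in envs]
    known = set(fit.genotypes)
    unknown = [g for g in genotypes if g not in known]
    if unknown:
        raise GoEnViolationError(
            f"genotype(s) {unknown[:5]} not in training set; use the two-stage "
            "marker model (baselines.predict_gnen) for new genotypes"
        )
    keys = pd.DataFrame(
        [(g, e) for g in genotypes for e in envs], columns=["genotype", "env"]
    )
    V = ecs.frame_for(keys)  # raw EC values
    B = fit.B.loc[keys["genotype"]].to_numpy()
    g_eff = keys["genotype"].map(fit.g).to_numpy(dtype=float)
    y_hat = fit.mu + g_eff + (V * B).sum(axis=1)
    if not np.isfinite(y_hat).all():
        raise ValidationError("non-finite predictions; check EC values and fit")
    df = keys.assign(y_hat=y_hat)
    preds = PredictionTable(df=df, centred=True)
    if observed is not None:
        preds = preds.with_observed(observed)
    return preds


def pearson_per_env(preds: PredictionTable, min_n: int = 3) -> dict[str, float | None]:
    """Sample Pearson r between y_hat and y_obs within each environment.

    Environments with fewer than ``min_n`` observed rows, or with zero
    variance in either vector, get the undefined marker ``None`` (never NaN).
    """
    df = preds.df
    if "y_obs" not in df.columns:
        raise ValidationError("prediction table has no observed values; attach them first")
    out: dict[str, float | None] = {}
    for env, grp in df.groupby("env", sort=False):
        grp = grp.dropna(subset=["y_obs"])
        if len(grp) < min_n:
            out[str(env)] = None
            continue
        a = grp["y_hat"].to_numpy(dtype=float)
        b = grp["y_obs"].to_numpy(dtype=float)
        if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
            out[str(env)] = None
            continue
        out[str(env)] = float(stats.pearsonr(a, b).statistic)
    return out


def apcor_env(
    per_env: dict[str, float | None],
    weights: dict[str, int] | None = None,
) -> AccuracyReport:
    """Average the defined per-environment correlations.

    Default is the unweighted arithmetic mean over environments with a
    defined r; pass per-environment sample sizes as ``weights`` for the
    size-weighted variant.
    """
    defined = {e: r for e, r in per_env.items() if r is not None}
    if not defined:
        raise ValidationError("no environment has a defined correlation")
    if weights is None:
        mean = float(np.mean(list(defined.values())))
    else:
        w = np.array([weights[e] for e in defined], dtype=float)
        mean = float(np.average(list(defined.values()), weights=w))
    return AccuracyReport(
        per_env=dict(per_env),
        apcor_env=mean,
        n_envs_used=len(defined),
        n_envs_excluded=len(per_env) - len(defined),
    )


def accuracy_report(
    preds: PredictionTable,
    min_n: int = 3,
    weighted: bool = False,
) -> AccuracyReport:
    """Per-environment correlations plus APCOR_Env in one call."""
    per_env = pearson_per_env(preds, min_n=min_n)
    weights = None
    if weighted:
        counts = preds.df.dropna(subset=["y_obs"]).groupby("env").size()
        weights = {str(e): int(n) for e, n in counts.items()}
    return apcor_env(per_env, weights=weights)
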