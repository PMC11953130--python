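"""Baselines around the penalized fit: additive model, unpenalized "Full"
factorial regression, and the optional two-stage marker ridge for new
genotypes (GnEn).

The additive model

    Y[i, j] = mu + g_i + e_j + eps[i, j]

is the large-lambda limit of the penalized fit (all sensitivities shrunk to
zero).  The "Full" model is the factorial regression at lambda = 0, which
overfits once the number of ECs approaches the number of environments.

The two-stage strategy regresses the per-genotype intercepts (g) and slopes
(B) from a stage-1 fit on centred marker dosages with independent
per-response ridge; predicted intercepts and slopes for unseen genotypes are
then combined with EC values exactly as in GoEn prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge, RidgeCV

from .data_model import AlignedDataset, ECTable, MarkerMatrix
from .design import build_design
from .engine import FRFit, PenaltySpec, _coef_to_fit, _main_effect_residuals, _ols_dense
from .exceptions import (
    DegenerateDesignError,
    RankDeficiencyError,
    UnsupportedModeError,
    ValidationError,
)
from .predict_eval import PredictionTable

__all__ = [
    "AdditiveFit",
    "Stage2Fit",
    "fit_additive",
    "fit_full",
    "stage2_marker_ridge",
    "predict_gnen",
]


@dataclass
class AdditiveFit:
    """Main-effects-only least-squares fit (reference levels at zero)."""

    mu: float
    g: dict[str, float]
    e: dict[str, float]
    sigma2_hat: float

    def as_frfit(self, ec_names) -> FRFit:
        """View as an FRFit with B identically zero (for shared prediction code)."""
        genotypes = list(self.g)
        B = pd.DataFrame(
            np.zeros((len(genotypes), len(ec_names))),
            index=pd.Index(genotypes, name="genotype"),
            columns=list(ec_names),
        )
        return FRFit(
            mu=self.mu,
            g=dict(self.g),
            e=dict(self.e),
            B=B,
            penalty=PenaltySpec(kind="lasso"),
            lambda_selected=np.inf,
            sigma2_hat=self.sigma2_hat,
            cv_trace=None,
            genotypes=genotypes,
            environments=list(self.e),
            ec_names=list(ec_names),
            standardize=False,
            ec_standardization=None,
        )


@dataclass
class Stage2Fit:
    """Per-response ridge of stage-1 genotype parameters on centred markers.

    Responses are the genotype intercept g and each sensitivity column of B
    (1 + n_c responses); ``coef`` is markers x responses, ``intercept`` the
    per-response offset, and ``alphas`` the ridge strength per response.
    """

    coef: pd.DataFrame
    intercept: pd.Series
    marker_means: pd.Series
    ec_names: list[str]
    mu: float
    alphas: pd.Series

    def predict_params(self, markers: MarkerMatrix) -> pd.DataFrame:
        """Predicted (g, B columns) for the genotypes in ``markers``."""
        M = markers.values.loc[:, self.marker_means.index].to_numpy(dtype=float)
        Mc = M - self.marker_means.to_numpy()[None, :]
        out = Mc @ self.coef.to_numpy() + self.intercept.to_numpy()[None, :]
        return pd.DataFrame(out, index=markers.values.index.astype(str), columns=self.coef.columns)


def fit_additive(data: AlignedDataset) -> AdditiveFit:
    """Least-squares fit of the additive (main-effects-only) model.

    On balanced data the estimates are the classical two-way ANOVA contrasts:
    g_i and e_j are row/column mean differences from the reference levels.
    """
    design = build_design(data, standardize=False)
    p0 = design.n_unpenalized
    r0, theta_U = _main_effect_residuals(design.X, design.y, p0)
    n_g, n_e = len(design.genotypes), len(design.environments)
    mu = float(theta_U[0])
    g = {design.genotypes[0]: 0.0}
    g.update({gid: float(v) for gid, v in zip(design.genotypes[1:], theta_U[1:n_g])})
    e = {design.environments[0]: 0.0}
    e.update({eid: float(v) for eid, v in zip(design.environments[1:], theta_U[n_g:])})
    dof = max(1, design.N - p0)
    return AdditiveFit(mu=mu, g=g, e=e, sigma2_hat=float(r0 @ r0) / dof)


def fit_full(data: AlignedDataset, standardize: bool = True) -> FRFit:
    """Unpenalized ("Full") factorial regression: lambda = 0 least squares.

    Requires a full-rank design, i.e. clearly more training environments than
    ECs per genotype; otherwise a rank error advises penalization.
    """
    design = build_design(data, standardize=standardize)
    try:
        theta = _ols_dense(design.X, design.y)
    except RankDeficiencyError as exc:
        raise RankDeficiencyError(
            f"{exc} (the Full model needs n_e well above n_c; "
            "use a penalized fit instead)"
        ) from None
    mu, g, e, B = _coef_to_fit(design, theta)
    resid = design.y - design.X @ theta
    dof = max(1, design.N - design.p)
    return FRFit(
        mu=mu,
        g=g,
        e=e,
        B=B,
        penalty=PenaltySpec(kind="ridge"),
        lambda_selected=0.0,
        sigma2_hat=float(resid @ resid) / dof,
        cv_trace=None,
        genotypes=design.genotypes,
        environments=design.environments,
        ec_names=design.ec_names,
        standardize=standardize,
        ec_standardization=None
        if design.ecs.standardization is None
        else design.ecs.standardization.copy(),
        coef_design_scale=theta,
    )


def stage2_marker_ridge(fit: FRFit, markers: MarkerMatrix, shrinkage="cv") -> Stage2Fit:
    """Regress stage-1 genotype intercepts and slopes on centred markers.

    Each of the 1 + n_c responses gets an independent univariate ridge.
    ``shrinkage`` is a fixed ridge strength or "cv", which selects it per
    response by generalized (leave-one-out) cross-validation.
    """
    missing = [g for g in fit.genotypes if g not in set(markers.genotypes)]
    if missing:
        raise ValidationError(f"genotypes without marker rows: {missing[:10]}")
    M = markers.values.loc[fit.genotypes].to_numpy(dtype=float)
    marker_means = pd.Series(M.mean(axis=0), index=markers.marker_names)
    Mc = M - marker_means.to_numpy()[None, :]
    responses = pd.DataFrame({"g": [fit.g[gid] for gid in fit.genotypes]}, index=fit.genotypes)
    responses = pd.concat([responses, fit.B.loc[fit.genotypes]], axis=1)
    Y = responses.to_numpy(dtype=float)
    if shrinkage == "cv":
        model = RidgeCV(alphas=np.logspace(-3, 5, 30), alpha_per_target=True)
        model.fit(Mc, Y)
        alphas = np.atleast_1d(model.alpha_)
        if alphas.size == 1:
            alphas = np.repeat(alphas, Y.shape[1])
    else:
        model = Ridge(alpha=float(shrinkage))
        model.fit(Mc, Y)
        alphas = np.repeat(float(shrinkage), Y.shape[1])
    coef = pd.DataFrame(model.coef_.T, index=markers.marker_names, columns=responses.columns)
    intercept = pd.Series(np.atleast_1d(model.intercept_), index=responses.columns)
    return Stage2Fit(
        coef=coef,
        intercept=intercept,
        marker_means=marker_means,
        ec_names=list(fit.ec_names),
        mu=fit.mu,
        alphas=pd.Series(alphas, index=responses.columns),
    )


def predict_gnen(
    stage2: Stage2Fit,
    markers_new: MarkerMatrix,
    ecs: ECTable,
    envs,
) -> PredictionTable:
    """Predict new genotypes in new environments from markers and ECs.

    Genotype-specific ECs require phenology data that does not exist for
    unobserved genotypes, so only environment-level ECs are supported.
    """
    if ecs.mode != "env_level":
        raise UnsupportedModeError(
            "GnEn prediction requires env_level ECs; genotype-specific EC values "
            "are not available for new genotypes"
        )
    envs = [str(e) for e in envs]
    params = stage2.predict_params(markers_new)
    genotypes = [str(g) for g in params.index]
    keys = pd.DataFrame([(g, e) for g in genotypes for e in envs], columns=["genotype", "env"])
    V = ecs.frame_for(keys)
    B = params.loc[keys["genotype"], stage2.ec_names].to_numpy(dtype=float)
    g_eff = params.loc[keys["genotype"], "g"].to_numpy(dtype=float)
    y_hat = stage2.mu + g_eff + (V * B).sum(axis=1)
    return PredictionTable(df=keys.assign(y_hat=y_hat), centred=True)
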