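"""Sparse design matrix for factorial regression with linear reaction norms.

The model is

    Y[i, j] = mu + g_i + e_j + sum_t v[i, j, t] * beta[i, t] + eps[i, j]

with genotype main effects ``g``, environment main effects ``e`` and
genotype-specific sensitivities (slopes) ``beta`` on the ``n_c`` environmental
covariates.  Identifiability uses treatment (reference-level) coding: the
first genotype and first environment carry no dummy column, i.e. g_1 = e_1 = 0.

Column layout (p = n_g + n_e - 1 + n_g * n_c):

    [intercept | geno_main(2..n_g) | env_main(2..n_e) | sensitivity(i, t)
     ordered genotype-major]

Main-effect columns carry penalty factor 0 (never shrunk); sensitivity
columns carry factor 1, or a genotype-specific positive weight.  Each row has
at most 3 + n_c structural nonzeros, so the matrix is stored sparse (CSC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import AlignedDataset, ECTable
from .exceptions import DegenerateDesignError, GoEnViolationError, ValidationError

__all__ = ["ColumnMeta", "FRDesign", "build_design", "design_for_prediction"]


@dataclass(frozen=True)
class ColumnMeta:
    """Role of one design column: intercept, main effect, or sensitivity."""

    role: str  # "intercept" | "geno_main" | "env_main" | "sensitivity"
    genotype: str | None = None
    env: str | None = None
    ec: str | None = None


@dataclass
class FRDesign:
    """Sparse factorial-regression design over the training rows."""

    X: sp.csc_matrix
    columns: list[ColumnMeta]
    penalty_factor: np.ndarray
    row_keys: list[tuple[str, str]]  # (genotype, env) per row
    y: np.ndarray
    genotypes: list[str]
    environments: list[str]
    ec_names: list[str]
    standardize: bool
    ecs: ECTable  # carries the training standardization statistics

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_unpenalized(self) -> int:
        return len(self.genotypes) + len(self.environments) - 1

    def unpenalized_matrix(self) -> sp.csc_matrix:
        """Intercept + main-effect columns (the additive-model design)."""
        return self.X[:, : self.n_unpenalized].tocsc()

    def penalized_matrix(self) -> sp.csc_matrix:
        return self.X[:, self.n_unpenalized :].tocsc()

    def dump(self, mtx_path, meta_path) -> None:
        """Debug dump: MatrixMarket matrix + column-metadata CSV."""
        from scipy.io import mmwrite

        mmwrite(str(mtx_path), self.X)
        pd.DataFrame([c.__dict__ for c in self.columns]).to_csv(meta_path, index=False)


def _column_meta(genotypes, environments, ec_names) -> list[ColumnMeta]:
    cols = [ColumnMeta("intercept")]
    cols += [ColumnMeta("geno_main", genotype=g) for g in genotypes[1:]]
    cols += [ColumnMeta("env_main", env=e) for e in environments[1:]]
    for g in genotypes:
        cols += [ColumnMeta("sensitivity", genotype=g, ec=t) for t in ec_names]
    return cols


def _rows_to_coo(gi, ej, V, n_g, n_e, n_c):
    """COO triplets for rows with genotype index gi, env index ej, EC rows V."""
    N = len(gi)
    rows = [np.arange(N)]
    cols = [np.zeros(N, dtype=np.int64)]
    data = [np.ones(N)]
    # genotype dummies (skip reference level 0)
    m = gi > 0
    rows.append(np.arange(N)[m])
    cols.append(gi[m])  # column 1 + (gi - 1)
    data.append(np.ones(m.sum()))
    if ej is not None:
        m = ej > 0
        rows.append(np.arange(N)[m])
        cols.append(n_g + ej[m] - 1)
        data.append(np.ones(m.sum()))
    off = n_g + n_e - 1
    sens_cols = off + gi[:, None] * n_c + np.arange(n_c)[None, :]
    rows.append(np.repeat(np.arange(N), n_c))
    cols.append(sens_cols.ravel())
    data.append(V.ravel())
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(data)


def build_design(
    data: AlignedDataset,
    standardize: bool = True,
    genotype_weights: dict[str, float] | None = None,
) -> FRDesign:
    """Build the sparse design and penalty-factor vector over training rows.

    ECs are centred and scaled with the training statistics stored on the
    aligned dataset when ``standardize`` is on (the default); sensitivity
    column (i, t) then holds the standardized EC value of cell (i, j).  The
    response ``y`` is the raw training trait value.

    ``genotype_weights`` optionally sets a positive penalty-factor multiplier
    per genotype on its sensitivity columns (genotype-specific penalties).
    """
    recs = data.train_records
    genotypes = data.phenotypes.genotypes
    environments = data.train_envs
    ec_names = data.ecs.ec_names
    n_g, n_e, n_c = len(genotypes), len(environments), len(ec_names)
    if n_g < 2 or n_e < 2:
        raise DegenerateDesignError(
            f"need at least 2 genotypes and 2 environments (got {n_g} x {n_e})"
        )
    ecs = data.ecs.copy()
    if standardize:
        if ecs.standardization is None:
            raise ValidationError("dataset has no stored EC standardization statistics")
        sd = ecs.standardization["sd"]
        zero = sd.index[~(sd > 0)].tolist()
        if zero:
            raise DegenerateDesignError(
                f"EC(s) with zero training sd cannot be standardized: {zero}"
            )
    else:
        ecs.standardization = None

    g_index = {g: i for i, g in enumerate(genotypes)}
    e_index = {e: j for j, e in enumerate(environments)}
    gi = recs["genotype"].map(g_index).to_numpy(dtype=np.int64)
    ej = recs["env"].map(e_index).to_numpy(dtype=np.int64)
    V = ecs.transform(ecs.frame_for(recs))

    r, c, d = _rows_to_coo(gi, ej, V, n_g, n_e, n_c)
    p = n_g + n_e - 1 + n_g * n_c
    X = sp.coo_matrix((d, (r, c)), shape=(len(recs), p)).tocsc()

    pf = np.zeros(p)
    off = n_g + n_e - 1
    weights = np.ones(n_g)
    if genotype_weights:
        for g, w in genotype_weights.items():
            if w <= 0:
                raise ValidationError(f"genotype penalty weight must be positive: {g}={w}")
            weights[g_index[g]] = w
    pf[off:] = np.repeat(weights, n_c)

    return FRDesign(
        X=X,
        columns=_column_meta(genotypes, environments, ec_names),
        penalty_factor=pf,
        row_keys=list(zip(recs["genotype"], recs["env"])),
        y=recs["y"].to_numpy(dtype=float),
        genotypes=genotypes,
        environments=environments,
        ec_names=ec_names,
        standardize=standardize,
        ecs=ecs,
    )


def design_for_prediction(
    design: FRDesign,
    ecs: ECTable,
    genotypes,
    envs,
) -> tuple[sp.csc_matrix, list[tuple[str, str]]]:
    """Design rows for new environments, with env main-effect columns zeroed.

    Environment main effects are not estimable for environments absent from
    training, so all env_main columns are structurally zero; within-environment
    (rank-based) accuracy is unaffected by the missing constant.  Columns match
    ``design.columns`` exactly, so the training coefficient vector applies
    directly.  ECs are transformed with the training standardization carried
    by ``ecs`` (or raw when the design was built unstandardized).

    Returns the matrix and its (genotype, env) row keys, genotype-major.
    """
    genotypes = [str(g) for g in genotypes]
    envs = [str(e) for e in envs]
    unknown = [g for g in genotypes if g not in set(design.genotypes)]
    if unknown:
        raise GoEnViolationError(
            f"genotype(s) {unknown[:5]} not in training set; reaction-norm parameters "
            "are genotype-specific — use the two-stage marker model for new genotypes"
        )
    n_g, n_e, n_c = len(design.genotypes), len(design.environments), len(design.ec_names)
    g_index = {g: i for i, g in enumerate(design.genotypes)}
    keys = [(g, e) for g in genotypes for e in envs]
    gi = np.array([g_index[g] for g, _ in keys], dtype=np.int64)
    key_df = pd.DataFrame(keys, columns=["genotype", "env"])
    raw = ecs.frame_for(key_df)
    V = design.ecs.transform(raw) if design.standardize else np.asarray(raw, dtype=float)
    r, c, d = _rows_to_coo(gi, None, V, n_g, n_e, n_c)
    X = sp.coo_matrix((d, (r, c)), shape=(len(keys), design.p)).tocsc()
    return X, keys
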