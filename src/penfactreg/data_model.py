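"""Domain types and table I/O for multi-environment trial (MET) data.

The package works on genotype-by-environment means: a long-format phenotype
table ``Y[i, j]`` (one value per genotype ``i`` and environment ``j``), an
environmental-covariate (EC) table holding ``n_c`` covariate values either per
environment or per genotype-environment cell, and an optional genotype-by-
marker dosage matrix for the two-stage marker extension.

All tables are plain CSV (header row, UTF-8, "." decimal).  Genotype and
environment identifiers are opaque strings; their ordering is first-appearance
order in the phenotype table and stays fixed thereafter — it determines the
design-matrix column order and the reference levels used for identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "PhenotypeTable",
    "ECTable",
    "MarkerMatrix",
    "AlignedDataset",
    "read_phenotypes",
    "read_ecs",
    "read_markers",
    "align_and_validate",
    "write_predictions",
]


def _unique_in_order(values) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass
class PhenotypeTable:
    """Observed trait values keyed by genotype and environment.

    ``df`` has columns ``genotype``, ``env``, ``y`` with one row per observed
    (genotype, environment) cell.  ``genotypes`` and ``environments`` are the
    ordered unique identifier lists (first-appearance order).
    """

    df: pd.DataFrame
    genotypes: list[str]
    environments: list[str]

    @property
    def n_g(self) -> int:
        return len(self.genotypes)

    @property
    def n_e(self) -> int:
        return len(self.environments)

    @property
    def N(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records) -> "PhenotypeTable":
        """Build from an iterable of (genotype_id, env_id, y) triples."""
        df = pd.DataFrame(records, columns=["genotype", "env", "y"])
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeTable":
        df = df.loc[:, ["genotype", "env", "y"]].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["env"] = df["env"].astype(str)
        df["y"] = pd.to_numeric(df["y"], errors="raise")
        if not np.isfinite(df["y"].to_numpy()).all():
            bad = df.loc[~np.isfinite(df["y"]), ["genotype", "env"]]
            raise ValidationError(f"non-finite trait values at cells: {bad.values.tolist()[:5]}")
        dup = df.duplicated(subset=["genotype", "env"])
        if dup.any():
            keys = df.loc[dup, ["genotype", "env"]].values.tolist()
            raise ValidationError(f"duplicate (genotype, env) cells: {keys[:10]}")
        return cls(
            df=df.reset_index(drop=True),
            genotypes=_unique_in_order(df["genotype"]),
            environments=_unique_in_order(df["env"]),
        )

    def subset_envs(self, envs) -> pd.DataFrame:
        return self.df[self.df["env"].isin(set(envs))]


@dataclass
class ECTable:
    """Environmental covariate values, environment-level or genotype-specific.

    ``values`` is indexed by ``env`` (mode ``env_level``) or by
    ``(env, genotype)`` (mode ``genotype_specific``), with one numeric column
    per EC.  ``standardization`` holds per-EC training (mean, sd) once
    computed by :func:`align_and_validate`; test-environment ECs are always
    transformed with these stored training statistics.
    """

    ec_names: list[str]
    values: pd.DataFrame
    mode: str  # "env_level" | "genotype_specific"
    standardization: pd.DataFrame | None = None  # index ec_names, columns mean/sd

    @property
    def n_c(self) -> int:
        return len(self.ec_names)

    def copy(self) -> "ECTable":
        return ECTable(
            ec_names=list(self.ec_names),
            values=self.values.copy(),
            mode=self.mode,
            standardization=None if self.standardization is None else self.standardization.copy(),
        )

    def has_env(self, env: str) -> bool:
        if self.mode == "env_level":
            return env in self.values.index
        return env in self.values.index.get_level_values("env")

    def vector(self, env: str, genotype: str | None = None) -> np.ndarray:
        """Raw EC vector for an environment (and genotype, if genotype-specific)."""
        if self.mode == "env_level":
            key = env
        else:
            if genotype is None:
                raise ValidationError("genotype required for genotype_specific EC lookup")
            key = (env, genotype)
        try:
            return self.values.loc[key].to_numpy(dtype=float)
        except KeyError:
            raise ValidationError(f"no EC values for {key!r}") from None

    def frame_for(self, keys: pd.DataFrame) -> np.ndarray:
        """Raw EC matrix (rows aligned with ``keys`` rows of genotype/env)."""
        if self.mode == "env_level":
            idx = keys["env"]
        else:
            idx = pd.MultiIndex.from_arrays([keys["env"], keys["genotype"]], names=["env", "genotype"])
        try:
            return self.values.loc[idx].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValidationError(f"missing EC values: {exc}") from None

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Apply stored training standardization (identity if absent)."""
        if self.standardization is None:
            return np.asarray(raw, dtype=float)
        mean = self.standardization["mean"].to_numpy()
        sd = self.standardization["sd"].to_numpy()
        return (np.asarray(raw, dtype=float) - mean) / sd


@dataclass
class MarkerMatrix:
    """Genotype-by-marker allele dosages with column-mean imputation."""

    values: pd.DataFrame  # index genotype ids, columns marker names

    @property
    def genotypes(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def marker_names(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMatrix":
        if df.index.has_duplicates:
            raise ValidationError("duplicate genotype rows in marker matrix")
        if df.shape[1] < 1:
            raise SchemaError("marker matrix needs at least one marker column")
        df = df.astype(float)
        # column-mean imputation of missing dosages
        if df.isna().any().any():
            df = df.fillna(df.mean(axis=0))
        if df.isna().any().any():
            raise ValidationError("marker columns with all values missing cannot be imputed")
        return cls(values=df)


@dataclass
class AlignedDataset:
    """Phenotypes and ECs aligned on a train/test environment split.

    Training EC standardization statistics are stored on ``ecs`` (a private
    copy); they depend only on training records, never on test environments.
    """

    phenotypes: PhenotypeTable
    ecs: ECTable
    split: dict[str, str]  # env_id -> "train" | "test"

    @property
    def train_envs(self) -> list[str]:
        return [e for e in self.phenotypes.environments if self.split.get(e) == "train"]

    @property
    def test_envs(self) -> list[str]:
        return [e for e in self.phenotypes.environments if self.split.get(e) == "test"]

    @property
    def train_records(self) -> pd.DataFrame:
        return self.phenotypes.df[self.phenotypes.df["env"].map(self.split) == "train"]

    @property
    def test_records(self) -> pd.DataFrame:
        return self.phenotypes.df[self.phenotypes.df["env"].map(self.split) == "test"]


def read_phenotypes(path, column_map: dict[str, str] | None = None) -> PhenotypeTable:
    """Read a long-format phenotype CSV (genotype, env, y).

    ``column_map`` maps the canonical names {"genotype", "env", "y"} to the
    file's column names when they differ.
    """
    df = pd.read_csv(path, dtype=str)
    colmap = {"genotype": "genotype", "env": "env", "y": "y"}
    if column_map:
        colmap.update(column_map)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"phenotype file {path} is missing columns {missing}; found {list(df.columns)}")
    out = pd.DataFrame(
        {
            "genotype": df[colmap["genotype"]],
            "env": df[colmap["env"]],
        }
    )
    try:
        out["y"] = pd.to_numeric(df[colmap["y"]], errors="raise")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"non-numeric trait values in {path}: {exc}") from None
    return PhenotypeTable.from_frame(out)


def read_ecs(path, mode: str = "env_level") -> ECTable:
    """Read a wide EC CSV keyed by env (or env+genotype), one column per EC."""
    if mode not in ("env_level", "genotype_specific"):
        raise ValidationError(f"unknown EC mode {mode!r}")
    df = pd.read_csv(path)
    if "env" not in df.columns:
        raise SchemaError(f"EC file {path} must have an 'env' column")
    keys = ["env"]
    if mode == "genotype_specific":
        if "genotype" not in df.columns:
            raise SchemaError("genotype_specific EC file must have a 'genotype' column")
        keys = ["env", "genotype"]
    elif "genotype" in df.columns:
        raise SchemaError("env_level EC file must not have a 'genotype' column")
    ec_names = [c for c in df.columns if c not in keys]
    if not ec_names:
        raise SchemaError(f"EC file {path} has no covariate columns")
    for k in keys:
        df[k] = df[k].astype(str)
    if df.duplicated(subset=keys).any():
        raise ValidationError(f"duplicate EC rows for keys {keys} in {path}")
    values = df.set_index(keys)[ec_names].astype(float)
    return ECTable(ec_names=ec_names, values=values, mode=mode)


def read_markers(path) -> MarkerMatrix:
    """Read a genotype-by-marker dosage CSV (first column = genotype id)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return MarkerMatrix.from_frame(df)


def _training_ec_cells(pheno: PhenotypeTable, ecs: ECTable, train_envs: list[str]) -> pd.DataFrame:
    """EC rows over which training standardization statistics are computed.

    env_level mode: one row per training environment.  genotype_specific
    mode: one row per observed training (genotype, environment) record.
    """
    if ecs.mode == "env_level":
        return ecs.values.loc[[e for e in train_envs]]
    recs = pheno.df[pheno.df["env"].isin(set(train_envs))]
    idx = pd.MultiIndex.from_arrays([recs["env"], recs["genotype"]], names=["env", "genotype"])
    return ecs.values.loc[idx]


def align_and_validate(
    pheno: PhenotypeTable,
    ecs: ECTable,
    test_envs=(),
) -> AlignedDataset:
    """Align phenotypes with ECs and label a train/test environment split.

    Training environments are the phenotype environments not in ``test_envs``.
    EC standardization statistics (per-EC mean and sample sd, ddof=1) are
    computed on training records only and stored on a copy of ``ecs``; the
    inputs are not mutated, so the operation is idempotent.
    """
    test_envs = {str(e) for e in test_envs}
    env_set = set(pheno.environments)
    train_envs = [e for e in pheno.environments if e not in test_envs]
    if not train_envs:
        raise ValidationError("training environment set is empty")
    for e in sorted(test_envs):
        if not ecs.has_env(e):
            raise ValidationError(f"test environment {e!r} has no EC values")
    ecs = ecs.copy()
    # every phenotype record needs EC values
    if ecs.mode == "env_level":
        no_ec = [e for e in pheno.environments if not ecs.has_env(e)]
        if no_ec:
            raise ValidationError(f"environments without EC values: {no_ec[:10]}")
    else:
        have = set(ecs.values.index)
        missing = [
            (e, g)
            for g, e in zip(pheno.df["genotype"], pheno.df["env"])
            if (e, g) not in have
        ]
        if missing:
            raise ValidationError(f"(env, genotype) cells without EC values: {missing[:10]}")
    split = {e: ("test" if e in test_envs else "train") for e in env_set | test_envs}
    cells = _training_ec_cells(pheno, ecs, train_envs)
    mean = cells.mean(axis=0)
    sd = cells.std(axis=0, ddof=1)
    ecs.standardization = pd.DataFrame({"mean": mean, "sd": sd}).loc[ecs.ec_names]
    return AlignedDataset(phenotypes=pheno, ecs=ecs, split=split)


def write_predictions(preds, path) -> None:
    """Write a prediction table as CSV (genotype, env, y_hat[, y_obs])."""
    df = preds.df if hasattr(preds, "df") else preds
    cols = ["genotype", "env", "y_hat"]
    if "y_obs" in df.columns:
        cols.append("y_obs")
    df.loc[:, cols].to_csv(path, index=False)
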