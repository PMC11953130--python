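import numpy as np
import pandas as pd
import pytest

from penfactreg.data_model import ECTable, PhenotypeTable, align_and_validate


def make_dataset(Y, ecs_by_env=None, test_envs=(), genotypes=None, envs=None, mode="env_level"):
    """Build an AlignedDataset from a full genotype-by-environment matrix.

    ``Y``: 2-d array (genotypes x environments), NaN for unobserved cells.
    ``ecs_by_env``: environments x n_c array of EC values (env-level), or a
    dict {(env, genotype): vector} for genotype-specific mode.
    """
    Y = np.asarray(Y, dtype=float)
    n_g, n_e = Y.shape
    genotypes = genotypes or [f"g{i+1}" for i in range(n_g)]
    envs = envs or [f"e{j+1}" for j in range(n_e)]
    recs = [
        (genotypes[i], envs[j], Y[i, j])
        for i in range(n_g)
        for j in range(n_e)
        if np.isfinite(Y[i, j])
    ]
    pheno = PhenotypeTable.from_records(recs)
    if mode == "env_level":
        E = np.asarray(ecs_by_env, dtype=float)
        ec_names = [f"ec{t+1}" for t in range(E.shape[1])]
        values = pd.DataFrame(E, index=pd.Index(envs, name="env"), columns=ec_names)
    else:
        ec_names = [f"ec{t+1}" for t in range(len(next(iter(ecs_by_env.values()))))]
        idx = pd.MultiIndex.from_tuples(list(ecs_by_env), names=["env", "genotype"])
        values = pd.DataFrame(
            np.array([ecs_by_env[k] for k in ecs_by_env], dtype=float),
            index=idx,
            columns=ec_names,
        )
    ecs = ECTable(ec_names=ec_names, values=values, mode=mode)
    return align_and_validate(pheno, ecs, test_envs=test_envs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim():
    """Small simulated MET shared across tests (genotype-specific ECs)."""
    from penfactreg.simulate import SimConfig, simulate_met

    cfg = SimConfig(n_g=15, n_e_train=25, n_e_test=6, n_c=4, n_active=2, seed=42)
    return simulate_met(cfg)
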