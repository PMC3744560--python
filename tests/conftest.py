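import numpy as np
import pandas as pd
import pytest

from pathdyn import synthetic
from pathdyn.normalization import (
    compute_residuals,
    identify_background_cohort,
    identify_equally_expressed_cohort,
    normalize_arrays,
)
from pathdyn.selection import build_reference_group, select_above_background


@pytest.fixture(scope="session")
def default_sim():
    """Reference simulation (planted clusters, chains, group edges), seed 1."""
    cfg = synthetic.default_config(seed=1)
    ds, truth = synthetic.generate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Everything through normalization/selection on the reference simulation."""
    cfg, ds, truth = default_sim
    bg = identify_background_cohort(ds)
    cohort = identify_equally_expressed_cohort(ds, bg)
    nm = normalize_arrays(ds, cohort)
    rm = compute_residuals(nm)
    above, N, by_group = select_above_background(nm, bg, per_group=True)
    ref = build_reference_group(rm, above)
    return {
        "cfg": cfg,
        "ds": ds,
        "truth": truth,
        "bg": bg,
        "cohort": cohort,
        "nm": nm,
        "rm": rm,
        "above": above,
        "N": N,
        "by_group": by_group,
        "ref": ref,
    }


@pytest.fixture
def null_residuals():
    """Factory for i.i.d.-normal residual-style matrices (genes x arrays)."""

    def make(n_genes=500, n_arrays=8, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.standard_normal((n_genes, n_arrays)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"a{j}" for j in range(n_arrays)],
        )

    return make
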