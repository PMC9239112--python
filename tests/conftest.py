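import numpy as np
import pandas as pd
import pytest

from communitylens import Condition
from communitylens.count_data import CountMatrix
from communitylens.diffexpr import DETable
from communitylens.simulate import SimConfig, simulate_community


def small_config(n_genes: int = 400, **overrides) -> SimConfig:
    """A scaled-down community design with full-design per-gene coverage."""
    defaults = dict(
        genome_sizes={"B": n_genes, "F": n_genes, "P": n_genes},
        depth_scale=n_genes / 5700.0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_community(small_config(), seed=101)


def toy_count_matrix(species="F", conditions=None, replicates=2, n_genes=50,
                     mean=100.0, phi=0.1, seed=0):
    """NB count matrix with flat means over the given conditions."""
    conditions = conditions or [Condition({species})]
    rng = np.random.default_rng(seed)
    meta, cols = {}, {}
    size = 1.0 / phi if phi > 0 else None
    for cond in conditions:
        for r in range(1, replicates + 1):
            sid = f"{cond.name}_r{r}"
            meta[sid] = (cond, r)
            if size is None:
                cols[sid] = rng.poisson(mean, n_genes)
            else:
                cols[sid] = rng.negative_binomial(size, size / (size + mean), n_genes)
    genes = [f"{species}_{i:04d}" for i in range(n_genes)]
    return CountMatrix(species=species,
                       counts=pd.DataFrame(cols, index=pd.Index(genes, name="gene_id")),
                       sample_meta=meta)


def make_de_table(log2fc, fdr, label="toy", genes=None, pvalue=None):
    """Hand-built DETable for classification/attribution fixtures."""
    log2fc = np.asarray(log2fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    genes = genes or [f"g{i:04d}" for i in range(len(log2fc))]
    table = pd.DataFrame({
        "log2FC": log2fc,
        "pvalue": fdr if pvalue is None else pvalue,
        "fdr": fdr,
        "mean_cpm_baseline": np.full(len(log2fc), 100.0),
        "mean_cpm_treatment": np.full(len(log2fc), 100.0) * 2.0 ** log2fc,
    }, index=pd.Index(genes, name="gene_id"))
    return DETable(comparison=label, table=table)
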