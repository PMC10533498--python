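import numpy as np
import pandas as pd
import pytest

import fatescreen as fs


@pytest.fixture
def toy_ranked():
    """10 genes with statistics 5..1, -1..-5 (already in rank order)."""
    genes = [f"g{i:02d}" for i in range(1, 11)]
    stats = [5, 4, 3, 2, 1, -1, -2, -3, -4, -5]
    return fs.RankedGeneList.from_stats(genes, stats)


@pytest.fixture
def toy_expr():
    """4 genes x (2 initial + 2 target) samples."""
    values = pd.DataFrame(
        {
            "i1": [3.0, 4.0, 2.0, 7.0],
            "i2": [3.0, 6.0, 2.0, 7.0],
            "t1": [5.0, 4.0, 1.0, 7.0],
            "t2": [5.0, 2.0, 1.0, 7.0],
        },
        index=["ga", "gb", "gc", "gd"],
    )
    cond = pd.Series(
        ["initial", "initial", "target", "target"], index=["i1", "i2", "t1", "t2"]
    )
    return fs.ExpressionMatrix(values=values, sample_condition=cond)


@pytest.fixture
def tiny_profile():
    genes = [f"g{i:02d}" for i in range(1, 11)]
    rng = np.random.default_rng(7)
    return fs.PerturbationProfile(
        molecule="molA",
        cell_line="CL1",
        dose="10uM",
        stats=pd.Series(rng.normal(size=10), index=genes),
    )


@pytest.fixture(scope="session")
def small_screen():
    """A small but complete synthetic screen shared across tests."""
    spec = fs.SyntheticSpec(seed=11, n_genes=300, n_molecules=60, n_planted=3,
                            n_de=60, n_replicates=2, n_cell_lines=2)
    expr, truth = fs.generate_transition(spec)
    ranked = fs.compute_fold_change(expr)
    sig = fs.extract_signature(ranked, n_sig=60)
    lib, targets = fs.generate_library(spec, truth)
    agg = fs.aggregate_replicates(lib)
    result = fs.score_library(sig, agg)
    return dict(spec=spec, expr=expr, truth=truth, ranked=ranked, sig=sig,
                lib=lib, agg=agg, targets=targets, result=result)
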