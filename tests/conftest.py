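import numpy as np
import pytest

from epilayers import (
    SimConfig,
    build_cross_correlation,
    cluster_cross_correlation,
    compute_signature,
    fit_layers,
    identify_tme_modules,
    knn_normalize,
    simulate_cohort,
)
from epilayers.annotation import bin_time_of_replication
from epilayers.core import Parameters


def run_tme_chain(meth, expr, metadata, group, params=None):
    """Cross-correlation -> module identification -> signatures -> K-nn
    normalization for one sample group; the shared front half of the
    pipeline used by many tests."""
    params = params or Parameters()
    prom = meth.subset_class("promoter")
    C = build_cross_correlation(expr, prom, params, metadata, group)
    cluster_cross_correlation(C, params=params)
    modules = identify_tme_modules(C)
    imm_sig = compute_signature(expr, modules.immune_genes)
    caf_sig = compute_signature(expr, modules.caf_genes)
    samples = list(metadata.samples_in_group(group))
    sub = meth.subset_samples(samples)
    norm = knn_normalize(sub, imm_sig[samples], caf_sig[samples],
                         params=params, group=group)
    return {
        "C": C, "modules": modules,
        "immune_sig": imm_sig, "caf_sig": caf_sig,
        "meth_group": sub, "norm": norm, "samples": samples,
    }


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def cohort():
    """The default study-condition cohort: 500 tumors, fixed seed."""
    return simulate_cohort(SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def chain(cohort, params):
    meth, expr, metadata, truth = cohort
    return run_tme_chain(meth, expr, metadata, "ER+", params)


@pytest.fixture(scope="session")
def layer_model(cohort, chain, params):
    meth, expr, metadata, truth = cohort
    normals = list(metadata.samples_in_group("normal"))
    tor_bin = bin_time_of_replication(meth.loci["tor_value"], "two", params)
    return fit_layers(
        chain["norm"],
        raw_normals=meth.values[normals],
        tor_bin=tor_bin,
        params=params,
        seed=1,
    )


def pearson(x, y):
    return float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1])
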