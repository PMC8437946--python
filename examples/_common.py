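"""Shared helper for the example scripts: the TME front half of the
pipeline (module discovery, signatures, K-nn normalization) on ER+."""

from epilayers import (
    build_cross_correlation,
    cluster_cross_correlation,
    compute_signature,
    identify_tme_modules,
    knn_normalize,
)


def tme_chain(meth, expr, metadata, params, group="ER+"):
    C = build_cross_correlation(expr, meth.subset_class("promoter"), params,
                                metadata, group)
    cluster_cross_correlation(C, params=params)
    modules = identify_tme_modules(C)
    imm = compute_signature(expr, modules.immune_genes)
    caf = compute_signature(expr, modules.caf_genes)
    samples = list(metadata.samples_in_group(group))
    norm = knn_normalize(meth.subset_samples(samples), imm[samples],
                         caf[samples], params=params, group=group)
    return norm, samples
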