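import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import run_tme_chain
from epilayers import SimConfig, fit_layers, project_scores, simulate_cohort
from epilayers.annotation import bin_time_of_replication
from epilayers.core import Parameters
from epilayers.layers import annotate_layers


def _planted_signature_norm(meth, expr, metadata, truth, params):
    """K-nn normalize ER+ tumors using signatures from the planted TME
    gene sets (skips module discovery, which needs a full-size matrix)."""
    from epilayers import compute_signature, knn_normalize

    er = list(metadata.samples_in_group("ER+"))
    imm = compute_signature(expr, truth.immune_genes)
    caf = compute_signature(expr, truth.caf_genes)
    return knn_normalize(meth.subset_samples(er), imm[er], caf[er],
                         params=params, group="ER+")


class TestFitLayers:
    def test_planted_layer_recovery(self, cohort, layer_model):
        _, _, _, truth = cohort
        for layer in ("clock", "mg", "ml"):
            planted = truth.locus_layer.index[truth.locus_layer == layer]
            assigned = layer_model.locus_layer.reindex(planted)
            assert (assigned == layer).mean() >= 0.90

    def test_scores_track_latents(self, cohort, chain, layer_model):
        _, _, metadata, truth = cohort
        er = metadata.samples_in_group("ER+")
        for layer, latent in (("clock", truth.clock), ("mg", truth.mg),
                              ("ml", truth.ml)):
            r = np.corrcoef(layer_model.scores[layer], latent[er])[0, 1]
            assert r >= 0.9

    def test_layer_sets_disjoint_and_scores_are_means(self, chain, layer_model):
        counts = layer_model.locus_layer.value_counts()
        assert counts.sum() == len(layer_model.locus_layer)
        ids = layer_model.layer_loci("mg")
        manual = chain["norm"].values.loc[ids].mean(axis=0)
        assert np.allclose(layer_model.scores["mg"], manual)

    def test_determinism(self, cohort, chain, params):
        meth, _, metadata, _ = cohort
        normals = list(metadata.samples_in_group("normal"))
        m1 = fit_layers(chain["norm"], raw_normals=meth.values[normals],
                        params=params, seed=11)
        m2 = fit_layers(chain["norm"], raw_normals=meth.values[normals],
                        params=params, seed=11)
        assert m1.locus_layer.equals(m2.locus_layer)
        assert np.allclose(m1.scores, m2.scores)

    def test_blockwise_correlation_independent_of_block_size(
            self, cohort, chain, params):
        meth, _, metadata, _ = cohort
        normals = list(metadata.samples_in_group("normal"))
        m1 = fit_layers(chain["norm"], raw_normals=meth.values[normals],
                        params=params, seed=11, block=97)
        m2 = fit_layers(chain["norm"], raw_normals=meth.values[normals],
                        params=params, seed=11, block=4096)
        assert m1.locus_layer.equals(m2.locus_layer)

    def test_subsampling_stability(self, cohort, chain, params, layer_model):
        # two disjoint halves of the eligible loci give near-identical scores
        meth, _, metadata, _ = cohort
        normals = list(metadata.samples_in_group("normal"))
        eligible = layer_model.locus_layer.index
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(eligible))
        halves = [eligible[np.sort(perm[: len(perm) // 2])],
                  eligible[np.sort(perm[len(perm) // 2:])]]
        models = [
            fit_layers(chain["norm"], raw_normals=meth.values[normals],
                       params=params, seed=1, loci=h)
            for h in halves
        ]
        for layer in ("clock", "mg", "ml"):
            r = np.corrcoef(models[0].scores[layer], models[1].scores[layer])[0, 1]
            assert r > 0.95

    def test_null_cohort_specificity(self, params):
        # no planted latents: at the default cohort size the |r| > 0.25
        # partner filter leaves nothing to cluster, so layer fitting
        # refuses rather than inventing layers from noise
        cfg = SimConfig(n_tumors=500, n_normals=40, n_promoters=400,
                        n_fragments=400, n_enhancers=80, latent_dist="zero",
                        n_cis_pairs=0, n_distal_pairs=0, n_trans_genes=0,
                        n_neutral_genes=60, rng_seed=9)
        meth, expr, metadata, truth = simulate_cohort(cfg)
        norm = _planted_signature_norm(meth, expr, metadata, truth, params)
        normals = list(metadata.samples_in_group("normal"))
        frags = meth.loci.index[meth.loci["locus_class"] == "fragment"]
        with pytest.raises(ValueError, match="correlation filter"):
            fit_layers(norm, raw_normals=meth.values[normals],
                       params=params, seed=2, loci=frags)
        # even when clustering is forced, no score separates the (random)
        # simulated grade groups
        model = fit_layers(norm, raw_normals=meth.values[normals],
                           params=params.override(corr_floor=0.0),
                           seed=2, loci=frags)
        er = metadata.samples_in_group("ER+")
        grade = metadata.table.loc[er, "grade"]
        for layer in ("clock", "mg", "ml"):
            groups = [model.scores.loc[er, layer][grade == g]
                      for g in sorted(grade.dropna().unique())]
            p = stats.kruskal(*groups).pvalue
            assert p > 0.01

    def test_single_planted_layer_leaves_noise_clusters(self, params):
        cfg = SimConfig(n_tumors=200, n_normals=40, n_promoters=250,
                        n_fragments=400, n_enhancers=50, n_cis_pairs=0,
                        n_distal_pairs=0, n_trans_genes=0, n_neutral_genes=50,
                        layer_fraction=0.0, rng_seed=4)
        # plant only the clock by re-enabling a clock-sized layer fraction
        meth, expr, metadata, truth = simulate_cohort(
            cfg.override(layer_fraction=0.05, mg_amplitude=(0.0, 0.0),
                         ml_amplitude=(0.0, 0.0)))
        norm = _planted_signature_norm(meth, expr, metadata, truth, params)
        normals = list(metadata.samples_in_group("normal"))
        loose = params.override(corr_floor=0.0)
        model = fit_layers(norm, raw_normals=meth.values[normals],
                           params=loose, seed=2)
        # three clusters exist; the non-clock ones are weakly self-correlated
        from epilayers._stats import blockwise_self_pearson
        assert model.locus_layer.nunique() == 3
        clock_planted = truth.locus_layer.index[truth.locus_layer == "clock"]
        best = max(
            ("clock", "mg", "ml"),
            key=lambda l: model.layer_loci(l).intersection(clock_planted).size,
        )
        for layer in ("clock", "mg", "ml"):
            if layer == best:
                continue
            ids = model.layer_loci(layer)
            if len(ids) < 3:
                continue
            corr = blockwise_self_pearson(norm.values.loc[ids].to_numpy().T)
            off = corr[~np.eye(len(ids), dtype=bool)]
            assert np.nanmean(np.abs(off)) < 0.1

    def test_too_few_eligible_loci_rejected(self, params):
        vals = pd.DataFrame(np.random.default_rng(0).normal(0, .01, (4, 60)),
                            index=list("abcd"),
                            columns=[f"s{i}" for i in range(60)])
        from epilayers.knn_norm import NormalizedMethylMatrix
        norm = NormalizedMethylMatrix(vals, pd.DataFrame(), k=5)
        with pytest.raises(ValueError, match="correlation filter"):
            fit_layers(norm, params=params.override(corr_floor=0.99), seed=0)


class TestProjection:
    def test_projection_onto_training_group_is_identity(self, chain, layer_model):
        proj = project_scores(layer_model, chain["norm"])
        assert np.allclose(proj.to_numpy(), layer_model.scores.to_numpy())

    def test_missing_layer_loci_gives_missing_score(self, chain, layer_model):
        keep = layer_model.layer_loci("clock").union(layer_model.layer_loci("ml"))
        sub = chain["norm"].values.loc[keep]
        proj = project_scores(layer_model, sub)
        assert proj["mg"].isna().all()
        assert proj["clock"].notna().all()

    def test_projection_recovers_shared_latents_in_other_group(self, params):
        cfg = SimConfig(n_tumors=400, n_normals=60, er_neg_fraction=0.5,
                        rng_seed=6)
        meth, expr, metadata, truth = simulate_cohort(cfg)
        chain_pos = run_tme_chain(meth, expr, metadata, "ER+", params)
        normals = list(metadata.samples_in_group("normal"))
        model = fit_layers(chain_pos["norm"],
                           raw_normals=meth.values[normals],
                           params=params, seed=3)
        chain_neg = run_tme_chain(meth, expr, metadata, "ER-", params)
        proj = project_scores(model, chain_neg["norm"])
        neg = metadata.samples_in_group("ER-")
        for layer, latent in (("clock", truth.clock), ("mg", truth.mg),
                              ("ml", truth.ml)):
            r = np.corrcoef(proj.loc[neg, layer], latent[neg])[0, 1]
            assert r >= 0.85


class TestAnnotation:
    def test_clock_layer_is_late_replication_enriched(self, cohort, layer_model,
                                                      params):
        meth, _, _, _ = cohort
        meta = meth.loci.copy()
        meta["tor_bin"] = bin_time_of_replication(meta["tor_value"], "two", params)
        report = annotate_layers(layer_model, meta, params=params)
        tor = report["tor"].set_index("layer")
        assert tor.loc["clock", "ks_p"] < 0.01
        assert tor.loc["clock", "mean"] < tor.loc["clock", "background_mean"]
        bins = report["tor_bins"].set_index("layer")
        assert bins.loc["clock", "frac_late"] > bins.loc["clock", "background_frac_late"]

    def test_enhancer_linkage_fractions(self, cohort, chain, layer_model, params):
        meth, _, metadata, truth = cohort
        normals = list(metadata.samples_in_group("normal"))
        report = annotate_layers(layer_model, meth.loci, chain["norm"],
                                 meth.values[normals], params=params)
        enh = report["enhancer_linkage"]
        assert set(enh["layer"]) == {"clock", "mg", "ml"}
        assert enh["frac_linked"].between(0, 1).all()
        # MG enhancers live at low normal methylation and link to the MG score
        low_mg = enh.query("normal_meth_bin == 'low' and layer == 'mg'")
        low_clock = enh.query("normal_meth_bin == 'low' and layer == 'clock'")
        assert low_mg["frac_linked"].iloc[0] > low_clock["frac_linked"].iloc[0]

    def test_missing_annotation_sections_skipped(self, layer_model):
        meta = pd.DataFrame(index=layer_model.locus_layer.index)
        report = annotate_layers(layer_model, meta)
        assert report == {}
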