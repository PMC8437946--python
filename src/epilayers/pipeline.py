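"""End-to-end orchestration: run the deconvolution stages in order on a
directory of input tables (or a freshly simulated cohort), writing one
set of deterministic TSV outputs per stage.

Stage order: simulate -> crosscor -> normalize -> layers -> cis ->
epipoly -> integrate.  Each stage consumes the previous stage's in-memory
results when available, falling back to the TSVs in the output directory,
and fails with a clear message naming the missing upstream stage
otherwise.  All outputs carry a header with the tool version, the config
hash and the seed; reruns under the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotation, cis, crosscor, epipoly, io, knn_norm, layers
from .core import ExprMatrix, MethylMatrix, Parameters, SampleMetadata
from .integration import associate_scores, dosage_compensation
from .simulate import SimConfig, simulate_cohort, simulate_pattern_cohort

log = logging.getLogger("epilayers")

STAGES = ("simulate", "crosscor", "normalize", "layers", "cis", "epipoly", "integrate")
_DEPS = {
    "crosscor": ("simulate",),
    "normalize": ("crosscor",),
    "layers": ("normalize",),
    "cis": ("crosscor",),
    "epipoly": ("simulate",),
    "integrate": ("layers",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One YAML-serializable description of a pipeline run."""

    out_dir: str = "epilayers_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    groups: tuple[str, ...] = ("ER+", "normal")
    fit_group: str = "ER+"
    params: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    # real-data mode inputs (unused when "simulate" is enabled)
    meth_path: Optional[str] = None
    expr_path: Optional[str] = None
    samples_path: Optional[str] = None
    patterns_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        cfg.groups = tuple(cfg.groups)
        return cfg

    def config_hash(self) -> str:
        """Hash of everything that affects results (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = Parameters().override(**config.params, rng_seed=config.seed)
    header = [
        f"epilayers v{__version__}",
        f"seed={config.seed}",
        f"config={config.config_hash()}",
    ]
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    state: dict = {}
    summary: dict[str, dict] = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        _check_deps(stage, config, state, out)
        log.info("stage %s", stage)
        runner = globals()[f"_stage_{stage}"]
        info = runner(config, params, header, out, state)
        summary[stage] = info or {}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out


def _check_deps(stage: str, config: RunConfig, state: dict, out: Path) -> None:
    for dep in _DEPS.get(stage, ()):
        if dep in state:
            continue
        if dep in config.stages and STAGES.index(dep) < STAGES.index(stage):
            continue
        # fall back to files the dependency would have produced
        marker = {
            "simulate": out / "meth.tsv",
            "crosscor": out / "signatures_ER+.tsv",
            "normalize": out / "normalized_ER+.tsv",
            "layers": out / "signature_table.tsv",
        }.get(dep)
        if dep == "simulate" and config.meth_path:
            continue
        if marker is not None and marker.exists():
            continue
        raise PipelineError(
            f"stage '{stage}' requires outputs of disabled stage '{dep}'"
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, params, header, out, state):
    sim_cfg = SimConfig(**{**config.sim, "rng_seed": config.seed})
    meth, expr, metadata, truth = simulate_cohort(sim_cfg)
    state.update(meth=meth, expr=expr, metadata=metadata, truth=truth)
    io.write_methyl_matrix(meth, out / "meth.tsv", header)
    io.write_expr_matrix(expr, out / "expr.tsv", header)
    io.write_sample_metadata(metadata, out / "samples.tsv", header)
    if metadata.mutations is not None:
        io.write_frame(metadata.mutations, out / "mutations.tsv", header,
                       index_label="feature")
    io.write_frame(
        truth.locus_layer.to_frame("layer"), out / "truth_loci.tsv", header,
        index_label="locus_id",
    )
    truth_samples = pd.DataFrame(
        {"f_imm": truth.f_imm, "f_caf": truth.f_caf, "clock": truth.clock,
         "mg": truth.mg, "ml": truth.ml}
    )
    io.write_frame(truth_samples, out / "truth_samples.tsv", header,
                   index_label="sample")
    counts, labels, _ = simulate_pattern_cohort(
        n_background=150, n_concentrated=30, depth=60, seed=config.seed
    )
    io.write_pattern_table(
        counts.assign(label=labels).reset_index(names="fragment_id"),
        out / "patterns.tsv", header,
    )
    return {"n_loci": len(meth.values), "n_genes": len(expr.values),
            "n_samples": len(meth.samples)}


def _load_inputs(config, out, state):
    if "meth" in state:
        return
    if config.meth_path:
        meth_p, expr_p, samp_p = config.meth_path, config.expr_path, config.samples_path
    else:
        meth_p, expr_p, samp_p = out / "meth.tsv", out / "expr.tsv", out / "samples.tsv"
    state["meth"] = io.read_methyl_matrix(meth_p)
    state["expr"] = io.read_expr_matrix(expr_p)
    mut = out / "mutations.tsv"
    state["metadata"] = io.read_sample_metadata(
        samp_p, mutation_path=mut if mut.exists() else None
    )


def _stage_crosscor(config, params, header, out, state):
    _load_inputs(config, out, state)
    meth, expr, metadata = state["meth"], state["expr"], state["metadata"]
    prom = meth.subset_class("promoter")
    info = {}
    for group in config.groups:
        n = len(metadata.samples_in_group(group))
        if n < params.min_corr_samples:
            log.warning("group %s has %d samples; skipped", group, n)
            continue
        C = crosscor.build_cross_correlation(expr, prom, params, metadata, group)
        crosscor.cluster_cross_correlation(C, params=params)
        modules = crosscor.identify_tme_modules(C)
        imm_sig = crosscor.compute_signature(expr, modules.immune_genes)
        caf_sig = crosscor.compute_signature(expr, modules.caf_genes)
        gsamples = metadata.samples_in_group(group)
        sigs = pd.DataFrame(
            {"immune_expr": imm_sig[gsamples], "caf_expr": caf_sig[gsamples]}
        )
        state.setdefault("modules", {})[group] = modules
        state.setdefault("signatures", {})[group] = sigs
        tag = group.replace("+", "+").replace("/", "_")
        io.write_frame(C.r, out / f"crosscor_{tag}.tsv", header, index_label="gene")
        io.write_frame(
            pd.DataFrame({"cluster": C.row_clusters}),
            out / f"gene_clusters_{tag}.tsv", header, index_label="gene",
        )
        io.write_frame(sigs, out / f"signatures_{tag}.tsv", header,
                       index_label="sample")
        io.write_frame(
            pd.DataFrame(
                {"gene": modules.immune_genes + modules.caf_genes,
                 "module": ["immune"] * len(modules.immune_genes)
                 + ["caf"] * len(modules.caf_genes)}
            ),
            out / f"tme_modules_{tag}.tsv", header,
        )
        info[group] = {"matrix_shape": list(C.r.shape),
                       "immune_genes": len(modules.immune_genes),
                       "caf_genes": len(modules.caf_genes)}
    if not state.get("signatures"):
        raise PipelineError("crosscor produced no group signatures")
    return info


def _stage_normalize(config, params, header, out, state):
    _load_inputs(config, out, state)
    meth, metadata = state["meth"], state["metadata"]
    info = {}
    for group, sigs in state.get("signatures", {}).items():
        gsamples = list(sigs.index)
        sub = meth.subset_samples(gsamples)
        norm = knn_norm.knn_normalize(
            sub, sigs["immune_expr"], sigs["caf_expr"],
            params=params, group=group,
        )
        state.setdefault("normalized", {})[group] = norm
        tag = group
        io.write_frame(norm.values, out / f"normalized_{tag}.tsv", header,
                       index_label="locus_id")
        io.write_frame(norm.neighbors, out / f"neighbors_{tag}.tsv", header,
                       index_label="sample")
        prom = meth.subset_class("promoter").subset_samples(gsamples)
        tme_scores = pd.DataFrame({
            "immune_meth": knn_norm.tme_methylation_score(
                prom, sigs["immune_expr"], params),
            "caf_meth": knn_norm.tme_methylation_score(
                prom, sigs["caf_expr"], params),
        })
        state.setdefault("tme_scores", {})[group] = tme_scores
        io.write_frame(tme_scores, out / f"tme_scores_{tag}.tsv", header,
                       index_label="sample")
        info[group] = {"k": norm.k}
    return info


def _stage_layers(config, params, header, out, state):
    _load_inputs(config, out, state)
    meth, metadata = state["meth"], state["metadata"]
    fit_group = config.fit_group
    norm = state.get("normalized", {}).get(fit_group)
    if norm is None:
        raise PipelineError(f"stage 'layers' requires normalized matrix for {fit_group}")
    normal_ids = metadata.samples_in_group("normal")
    raw_normals = meth.values[list(normal_ids)] if len(normal_ids) else None
    tor_bin = None
    if "tor_value" in meth.loci.columns:
        tor_bin = annotation.bin_time_of_replication(
            meth.loci["tor_value"], "two", params)
    model = layers.fit_layers(
        norm, raw_normals=raw_normals, tor_bin=tor_bin, params=params,
        seed=config.seed,
    )
    state["layer_model"] = model

    tables = {}
    for group, n in state.get("normalized", {}).items():
        tables[group] = layers.project_scores(model, n)
    sig_rows = []
    for group, scores in tables.items():
        t = scores.copy()
        tme = state.get("tme_scores", {}).get(group)
        if tme is not None:
            t = t.join(tme)
        t["group"] = group
        sig_rows.append(t)
    signature_table = pd.concat(sig_rows).rename(
        columns={"clock": "Clock", "mg": "MG", "ml": "ML",
                 "immune_meth": "Immune", "caf_meth": "CAF"}
    )
    state["signature_table"] = signature_table
    io.write_frame(signature_table, out / "signature_table.tsv", header,
                   index_label="sample")
    io.write_frame(
        pd.DataFrame({"layer": model.locus_layer, "layer_corr": model.locus_corr}),
        out / "layer_loci.tsv", header, index_label="locus_id",
    )
    meta = meth.loci.copy()
    if tor_bin is not None:
        meta["tor_bin"] = tor_bin
    report = layers.annotate_layers(model, meta, norm, raw_normals, params)
    for name, df in report.items():
        io.write_frame(df, out / f"layer_annotation_{name}.tsv", header)
    return {"loci_per_layer": model.locus_layer.value_counts().to_dict()}


def _stage_cis(config, params, header, out, state):
    _load_inputs(config, out, state)
    meth, expr, metadata = state["meth"], state["expr"], state["metadata"]
    group = config.fit_group
    gsamples = list(metadata.samples_in_group(group))
    normal_ids = list(metadata.samples_in_group("normal"))
    prom = meth.subset_class("promoter")
    pairing = match_promoters(expr, prom, normal_ids)
    exclude: list[str] = []
    modules = state.get("modules", {}).get(group)
    if modules is not None:
        exclude = modules.immune_genes + modules.caf_genes

    expr_sq = expr.values.loc[pairing.index, gsamples]
    meth_sq = prom.values.loc[pairing.to_numpy(), gsamples]
    meth_sq.index = pairing.index
    result = cis.promoter_cis_screen(expr_sq, meth_sq, params, exclude_genes=exclude)
    state["cis_promoters"] = result
    io.write_frame(result.table, out / "cis_promoters.tsv", header)
    io.write_frame(result.fdr_curve, out / "cis_fdr_curve.tsv", header)

    nonprom = meth.subset_class("fragment")
    locus_coords = nonprom.loci[["chrom", "start", "end"]]
    gene_coords = expr.genes[["chrom", "tss"]]
    distal = cis.distal_cis_screen(
        expr.values[gsamples], gene_coords, nonprom.values[gsamples],
        locus_coords, params, n_shuffles=5, seed=config.seed,
    )
    state["cis_distal"] = distal
    io.write_frame(distal.table, out / "distal_pairs.tsv", header)
    bed = locus_coords.loc[distal.table.loc[distal.table["paired"], "locus"]]
    io.write_bed(bed.assign(name=bed.index), out / "distal_paired.bed")
    return {"n_cis_genes_fdr05": len(result.genes_at_fdr(0.05)),
            "n_distal_paired": distal.n_paired,
            "distal_fdr": distal.fdr}


def _stage_epipoly(config, params, header, out, state):
    src = config.patterns_path or out / "patterns.tsv"
    if not Path(src).exists():
        raise PipelineError("stage 'epipoly' requires a pattern table "
                            "(simulate stage or patterns_path)")
    patterns = io.read_pattern_table(src)
    patterns = patterns.set_index("fragment_id")
    table = epipoly.epipolymorphism_table(
        patterns, depth=params.epipoly_depth, seed=config.seed, params=params
    )
    if "label" in patterns.columns:
        table["label"] = patterns["label"]
    state["epipoly"] = table
    io.write_frame(table, out / "epipoly.tsv", header, index_label="fragment_id")
    return {"n_fragments": len(table),
            "n_uncovered": int(table["epipolymorphism"].isna().sum())}


def _stage_integrate(config, params, header, out, state):
    if "signature_table" not in state:
        raise PipelineError("stage 'integrate' requires the layer signature table")
    metadata = state["metadata"]
    scores = state["signature_table"].drop(columns=["group"])
    features = pd.DataFrame(index=metadata.table.index)
    if metadata.mutations is not None:
        features = features.join(metadata.mutations.T)
    if "cin" in metadata.table.columns:
        features["cin"] = metadata.table["cin"]
    tumors = metadata.table.index[metadata.table["group"] != "normal"]
    assoc = associate_scores(
        scores.loc[scores.index.intersection(tumors)],
        features.loc[features.index.intersection(tumors)], params,
    )
    io.write_frame(assoc, out / "score_associations.tsv", header)
    info = {"n_associations": len(assoc)}
    if metadata.cn_states is not None:
        prom = state["meth"].subset_class("promoter")
        dosage = dosage_compensation(
            prom.values, state["expr"].values, metadata.cn_states, params
        )
        io.write_frame(dosage.table, out / "dosage_compensation.tsv", header)
        info["n_compensated"] = len(dosage.compensated_genes())
    return info


def match_promoters(
    expr: ExprMatrix,
    promoters: MethylMatrix,
    normal_samples: list[str],
) -> pd.Series:
    """Map each gene to its resolved promoter locus.

    Candidate promoters are promoter-class loci overlapping the gene's
    promoter window; ambiguity resolves to the candidate with minimal
    mean methylation in normal samples.  Genes without a resolvable
    candidate are dropped.
    """
    import pyranges as pr

    genes = expr.genes.dropna(subset=["chrom", "tss"])
    windows = []
    for g, row in genes.iterrows():
        loc = annotation.make_promoter_window(
            row["chrom"], int(row["tss"]), row.get("strand", "+")
        )
        windows.append((row["chrom"], loc.start, loc.end, g))
    win_df = pd.DataFrame(windows, columns=["Chromosome", "Start", "End", "gene"])
    loci = promoters.loci
    loc_df = pd.DataFrame({
        "Chromosome": loci["chrom"], "Start": loci["start"], "End": loci["end"],
        "locus_id": loci.index,
    })
    hits = pr.PyRanges(win_df).join(pr.PyRanges(loc_df)).df
    if hits.empty:
        return pd.Series(dtype=object)
    normals = (
        promoters.values[normal_samples]
        if normal_samples
        else promoters.values
    )
    mapping = {}
    for g, sub in hits.groupby("gene"):
        cand = list(sub["locus_id"])
        chosen = annotation.resolve_promoter(cand, normals, loci)
        if chosen is not None:
            mapping[g] = chosen
    return pd.Series(mapping, name="promoter").sort_index()
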