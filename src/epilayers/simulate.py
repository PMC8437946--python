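"""Synthetic bulk-methylome cohorts with known ground truth.

The generator emulates the statistical structure the deconvolution
pipeline assumes: beta-like per-locus methylation mixed across tumor,
immune and fibroblast compartments; a replication-time-graded methylation
loss latent (clock); CpG-island gain (MG) and loss (ML) latents; planted
promoter-gene cis couples; and binomially sampled read-level epialleles.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ExprMatrix, MethylMatrix, SampleMetadata

IMMUNE_ANCHORS = ["CD3D", "CD3E", "CD8A", "CTLA4", "PDCD1"]
CAF_ANCHORS = ["CAV1", "FAP", "VIM"]

_CHROMS = [f"chr{i}" for i in range(1, 6)]
_CHROM_LEN = 100_000_000


@dataclass
class SimConfig:
    """Cohort generator settings.

    Defaults describe the study conditions the recovery tests assume:
    500 tumors plus adjacent normals, ~5% of loci per global methylation
    layer, 50 planted cis promoter-gene couples, and Beta-distributed
    immune/CAF contamination fractions.
    """

    n_tumors: int = 500
    n_normals: int = 60
    er_neg_fraction: float = 0.0
    n_promoters: int = 1200
    n_fragments: int = 1600
    n_enhancers: int = 240
    # contamination: f = scale * (lo + (hi - lo) * Beta(a, b)); flat Beta(1, 1)
    # over a bounded range keeps the signature-space density smooth, which the
    # K-nn neighborhood averaging relies on
    f_imm_params: tuple[float, float] = (1.0, 1.0)
    f_caf_params: tuple[float, float] = (1.0, 1.0)
    f_bounds: tuple[float, float] = (0.05, 0.35)
    normal_contamination_scale: float = 1.0
    contamination_scale: float = 1.0
    # immune/CAF methylation differential at TME marker loci (bulk sorted
    # profiles show moderate, locus-dependent cell-type differences)
    tme_delta: tuple[float, float] = (0.20, 0.40)
    # latent model: "uniform", "beta:a,b" or "zero"
    latent_dist: str = "uniform"
    layer_fraction: float = 0.05
    tme_fraction: float = 0.05
    clock_loading: tuple[float, float] = (0.10, 0.50)  # min..max loss vs lateness
    mg_amplitude: tuple[float, float] = (0.30, 0.60)
    ml_amplitude: tuple[float, float] = (0.25, 0.40)
    n_cis_pairs: int = 50
    rho_cis: float = 0.6
    n_distal_pairs: int = 30
    rho_distal: float = 0.5
    n_immune_genes: int = 40
    n_caf_genes: int = 40
    n_trans_genes: int = 150  # genes tracking MG/ML latents in trans
    n_neutral_genes: int = 400
    noise_meth: float = 0.03
    noise_expr: float = 1.0
    pattern_depth_mean: float = 60.0
    rng_seed: int = 0

    def override(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted latents and labels; consumed only by recovery tests."""

    f_imm: pd.Series
    f_caf: pd.Series
    clock: pd.Series
    mg: pd.Series
    ml: pd.Series
    locus_layer: pd.Series  # {clock, mg, ml, tme_immune, tme_caf, neutral}
    cis_pairs: pd.DataFrame  # gene, locus, rho
    distal_pairs: pd.DataFrame  # gene, locus, rho, distance
    immune_genes: list[str] = field(default_factory=list)
    caf_genes: list[str] = field(default_factory=list)


def _draw_latent(rng: np.random.Generator, dist: str, n: int) -> np.ndarray:
    if dist == "zero":
        return np.zeros(n)
    if dist == "uniform":
        return rng.uniform(0.0, 1.0, n)
    if dist.startswith("beta:"):
        a, b = (float(x) for x in dist.split(":", 1)[1].split(","))
        return rng.beta(a, b, n)
    raise ValueError(f"unknown latent distribution {dist!r}")


def _beta_mixture(rng: np.random.Generator, n: int, weights: Sequence[float]) -> np.ndarray:
    """Bimodal methylome shape: hypo / hemi / hyper Beta components."""
    comp = rng.choice(3, size=n, p=np.asarray(weights) / np.sum(weights))
    out = np.empty(n)
    out[comp == 0] = rng.beta(2, 30, (comp == 0).sum())
    out[comp == 1] = rng.beta(10, 10, (comp == 1).sum())
    out[comp == 2] = rng.beta(20, 5, (comp == 2).sum())
    return out


def simulate_cohort(config: SimConfig | None = None):
    """Generate a full synthetic cohort.

    Returns ``(MethylMatrix, ExprMatrix, SampleMetadata, GroundTruth)``.
    Observed methylation is the compartment mixture
    ``(1-f_imm-f_caf) * tumor + f_imm * immune + f_caf * caf`` plus
    Gaussian noise, clipped to [0, 1].
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    needed = cfg.n_immune_genes + cfg.n_caf_genes + cfg.n_cis_pairs
    if cfg.n_promoters < needed:
        raise ValueError(
            f"n_promoters={cfg.n_promoters} cannot host the {needed} "
            "immune/CAF/cis gene promoters"
        )

    # ---- samples --------------------------------------------------------
    tumor_ids = [f"T{i:04d}" for i in range(cfg.n_tumors)]
    normal_ids = [f"N{i:04d}" for i in range(cfg.n_normals)]
    samples = tumor_ids + normal_ids
    n_er_neg = int(round(cfg.er_neg_fraction * cfg.n_tumors))
    groups = (["ER-"] * n_er_neg + ["ER+"] * (cfg.n_tumors - n_er_neg)) + (
        ["normal"] * cfg.n_normals
    )

    flo, fhi = cfg.f_bounds
    f_imm = (flo + (fhi - flo) * rng.beta(*cfg.f_imm_params, len(samples))) * cfg.contamination_scale
    f_caf = (flo + (fhi - flo) * rng.beta(*cfg.f_caf_params, len(samples))) * cfg.contamination_scale
    f_imm[len(tumor_ids):] *= cfg.normal_contamination_scale
    f_caf[len(tumor_ids):] *= cfg.normal_contamination_scale
    total = f_imm + f_caf
    over = total > 0.9
    f_imm[over] *= 0.9 / total[over]
    f_caf[over] *= 0.9 / total[over]

    is_tumor = np.array([g != "normal" for g in groups])
    clock = np.where(is_tumor, _draw_latent(rng, cfg.latent_dist, len(samples)), 0.0)
    mg = np.where(is_tumor, _draw_latent(rng, cfg.latent_dist, len(samples)), 0.0)
    ml = np.where(is_tumor, _draw_latent(rng, cfg.latent_dist, len(samples)), 0.0)

    # ---- genes ----------------------------------------------------------
    immune_genes = (IMMUNE_ANCHORS + [f"IMM{i:03d}" for i in range(cfg.n_immune_genes)])[
        : cfg.n_immune_genes
    ]
    caf_genes = (CAF_ANCHORS + [f"CAF{i:03d}" for i in range(cfg.n_caf_genes)])[
        : cfg.n_caf_genes
    ]
    cis_genes = [f"CIS{i:03d}" for i in range(cfg.n_cis_pairs)]
    distal_genes = [f"DST{i:03d}" for i in range(cfg.n_distal_pairs)]
    trans_genes = [f"TRS{i:03d}" for i in range(cfg.n_trans_genes)]
    neutral_genes = [f"GEN{i:04d}" for i in range(cfg.n_neutral_genes)]
    genes = (immune_genes + caf_genes + cis_genes + distal_genes
             + trans_genes + neutral_genes)

    gene_chrom = rng.choice(_CHROMS, len(genes))
    gene_tss = rng.integers(1_000_000, _CHROM_LEN - 1_000_000, len(genes))
    gene_strand = rng.choice(["+", "-"], len(genes))
    gene_meta = pd.DataFrame(
        {"chrom": gene_chrom, "tss": gene_tss, "strand": gene_strand}, index=genes
    )

    # ---- loci -----------------------------------------------------------
    n_loci = cfg.n_promoters + cfg.n_fragments + cfg.n_enhancers
    locus_class = np.array(
        ["promoter"] * cfg.n_promoters
        + ["fragment"] * cfg.n_fragments
        + ["enhancer"] * cfg.n_enhancers
    )
    locus_ids = (
        [f"P{i:05d}" for i in range(cfg.n_promoters)]
        + [f"F{i:05d}" for i in range(cfg.n_fragments)]
        + [f"E{i:05d}" for i in range(cfg.n_enhancers)]
    )
    chrom = rng.choice(_CHROMS, n_loci)
    start = rng.integers(10_000, _CHROM_LEN - 10_000, n_loci)
    width = np.where(locus_class == "promoter", 550,
                     np.where(locus_class == "enhancer", 200,
                              rng.integers(80, 400, n_loci)))
    # genes' own promoters sit at their TSS (one resolved promoter per gene)
    gene_promoter = {g: f"P{i:05d}" for i, g in enumerate(genes) if i < cfg.n_promoters}
    for i, g in enumerate(genes):
        if i >= cfg.n_promoters:
            break
        chrom[i] = gene_meta.at[g, "chrom"]
        tss = gene_meta.at[g, "tss"]
        start[i] = tss - 500 if gene_meta.at[g, "strand"] == "+" else tss - 50
    end = start + width

    cpg_content = np.where(
        locus_class == "fragment",
        rng.uniform(0.01, 0.06, n_loci),
        rng.uniform(0.06, 0.15, n_loci),
    )
    tor_value = rng.uniform(0.0, 100.0, n_loci)  # high = early replication

    # ---- layer / TME labels --------------------------------------------
    layer = np.array(["neutral"] * n_loci, dtype=object)
    n_per_layer = int(round(cfg.layer_fraction * n_loci))
    frag_idx = np.where(locus_class == "fragment")[0]
    prom_idx = np.arange(cfg.n_promoters)
    enh_idx = np.where(locus_class == "enhancer")[0]

    # immune / CAF methylation loci: the promoters of the TME genes plus extras
    n_tme = max(int(round(cfg.tme_fraction * cfg.n_promoters)), 1)
    imm_prom = [gene_promoter[g] for g in immune_genes if g in gene_promoter]
    caf_prom = [gene_promoter[g] for g in caf_genes if g in gene_promoter]
    id_to_idx = {lid: i for i, lid in enumerate(locus_ids)}
    imm_idx = [id_to_idx[l] for l in imm_prom]
    caf_idx = [id_to_idx[l] for l in caf_prom]
    taken = set(imm_idx) | set(caf_idx) | {
        id_to_idx[gene_promoter[g]] for g in cis_genes if g in gene_promoter
    }
    free_prom = np.array([i for i in prom_idx if i not in taken], dtype=np.int64)
    rng.shuffle(free_prom)
    extra = max(n_tme - len(imm_idx), 0)
    imm_idx += list(free_prom[:extra])
    caf_idx += list(free_prom[extra : extra + max(n_tme - len(caf_idx), 0)])
    free_prom = free_prom[extra + max(n_tme - len(caf_idx), 0):]
    layer[imm_idx] = "tme_immune"
    layer[caf_idx] = "tme_caf"

    # clock loci: fragments, sampled with probability graded by lateness
    lateness = 1.0 - tor_value / 100.0
    w = lateness[frag_idx] ** 2 + 0.05
    clock_idx = rng.choice(frag_idx, size=min(n_per_layer, len(frag_idx)),
                           replace=False, p=w / w.sum())
    layer[clock_idx] = "clock"

    def _free(pool: np.ndarray) -> np.ndarray:
        pool = np.asarray(pool, dtype=np.int64)
        if pool.size == 0:
            return pool
        return pool[np.array([layer[i] == "neutral" for i in pool], dtype=bool)]

    mg_pool = np.concatenate([_free(free_prom), _free(enh_idx)])
    mg_idx = rng.choice(mg_pool, size=min(n_per_layer, len(mg_pool)), replace=False)
    layer[mg_idx] = "mg"
    ml_pool = np.concatenate([_free(frag_idx), _free(free_prom)])
    ml_idx = rng.choice(ml_pool, size=min(n_per_layer, len(ml_pool)), replace=False)
    layer[ml_idx] = "ml"

    # ---- compartment profiles ------------------------------------------
    base = np.empty(n_loci)
    for cls, wts in (("promoter", (0.75, 0.15, 0.10)),
                     ("fragment", (0.10, 0.15, 0.75)),
                     ("enhancer", (0.40, 0.40, 0.20))):
        m = locus_class == cls
        base[m] = _beta_mixture(rng, m.sum(), wts)
    base[clock_idx] = rng.uniform(0.60, 0.92, len(clock_idx))
    base[mg_idx] = rng.uniform(0.02, 0.08, len(mg_idx))
    base[ml_idx] = rng.uniform(0.40, 0.70, len(ml_idx))
    base[imm_idx] = rng.uniform(0.50, 0.90, len(imm_idx))
    base[caf_idx] = rng.uniform(0.50, 0.90, len(caf_idx))

    immune_profile = base.copy()
    caf_profile = base.copy()
    immune_profile[imm_idx] = base[imm_idx] - rng.uniform(*cfg.tme_delta, len(imm_idx))
    caf_profile[caf_idx] = base[caf_idx] - rng.uniform(*cfg.tme_delta, len(caf_idx))

    # ---- tumor-intrinsic per-sample methylation -------------------------
    n_s = len(samples)
    tumor_prof = np.tile(base[:, None], (1, n_s))
    lo, hi = cfg.clock_loading
    clock_load = lo + (hi - lo) * lateness[clock_idx]
    tumor_prof[clock_idx] = base[clock_idx, None] - np.outer(clock_load, clock)
    mg_amp = rng.uniform(*cfg.mg_amplitude, len(mg_idx))
    tumor_prof[mg_idx] = base[mg_idx, None] + np.outer(mg_amp, mg)
    ml_amp = rng.uniform(*cfg.ml_amplitude, len(ml_idx))
    tumor_prof[ml_idx] = base[ml_idx, None] - np.outer(ml_amp, ml)

    cis_locus_idx = np.array([id_to_idx[gene_promoter[g]] for g in cis_genes], dtype=int)
    if len(cis_locus_idx):
        mean_cis = rng.uniform(0.20, 0.50, len(cis_locus_idx))
        conc = 8.0
        a = mean_cis * conc
        b = (1 - mean_cis) * conc
        tumor_prof[cis_locus_idx] = rng.beta(a[:, None], b[:, None], (len(cis_locus_idx), n_s))

    # planted distal elements: fragments near their gene's TSS
    distal_rows = []
    if cfg.n_distal_pairs:
        cand = _free(frag_idx)
        pick = rng.choice(cand, size=min(cfg.n_distal_pairs, len(cand)), replace=False)
        for g, li in zip(distal_genes, pick):
            offset = int(rng.integers(5_000, 300_000)) * (1 if rng.random() < 0.5 else -1)
            chrom[li] = gene_meta.at[g, "chrom"]
            start[li] = np.clip(gene_meta.at[g, "tss"] + offset, 1000, _CHROM_LEN - 1000)
            end[li] = start[li] + width[li]
            mean_d = rng.uniform(0.25, 0.55)
            tumor_prof[li] = rng.beta(mean_d * 8, (1 - mean_d) * 8, n_s)
            distal_rows.append((g, locus_ids[li], cfg.rho_distal,
                                abs(offset)))
    distal_pairs = pd.DataFrame(distal_rows, columns=["gene", "locus", "rho", "distance"])

    # ---- mixing, noise, clipping ---------------------------------------
    purity = 1.0 - f_imm - f_caf
    observed = (
        tumor_prof * purity[None, :]
        + immune_profile[:, None] * f_imm[None, :]
        + caf_profile[:, None] * f_caf[None, :]
    )
    if cfg.noise_meth > 0:
        # read-sampling-like noise: variance shrinks toward the [0, 1] bounds
        sd = cfg.noise_meth * (2.0 * np.sqrt(np.clip(observed * (1 - observed), 0, None)) + 0.1)
        observed = observed + rng.normal(0.0, 1.0, observed.shape) * sd
    np.clip(observed, 0.0, 1.0, out=observed)

    meth_values = pd.DataFrame(observed, index=locus_ids, columns=samples)
    loci_meta = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": ".",
            "locus_class": locus_class,
            "cpg_content": cpg_content,
            "tor_value": tor_value,
        },
        index=locus_ids,
    )
    meth = MethylMatrix(meth_values, loci_meta)

    # ---- expression -----------------------------------------------------
    expr = np.empty((len(genes), n_s))
    gi = {g: i for i, g in enumerate(genes)}
    noise = cfg.noise_expr
    # marker-gene expression is dominated by the cell fraction itself, so
    # within-module residual noise is small relative to the shared factor
    for g in immune_genes:
        expr[gi[g]] = 7.0 + 3.0 * f_imm + rng.normal(0, 0.1, n_s)
    for g in caf_genes:
        expr[gi[g]] = 7.0 + 3.0 * f_caf + rng.normal(0, 0.1, n_s)
    for g in neutral_genes:
        expr[gi[g]] = rng.normal(8.0, noise, n_s)
    # trans-coupled genes: expression tracks the instability latents, the
    # way large co-expression programs track the MG/ML layers
    for j, g in enumerate(trans_genes):
        latent = mg if j % 5 < 3 else ml
        expr[gi[g]] = 8.0 + 1.5 * latent + rng.normal(0, 0.8, n_s)

    def _couple(target: np.ndarray, rho: float) -> np.ndarray:
        z = (target - target.mean()) / max(target.std(), 1e-12)
        eps = rng.normal(0, 1, n_s)
        return 8.0 + noise * (-rho * z + np.sqrt(max(1 - rho**2, 0.0)) * eps)

    cis_rows = []
    for g, li in zip(cis_genes, cis_locus_idx):
        expr[gi[g]] = _couple(observed[li], cfg.rho_cis)
        cis_rows.append((g, locus_ids[li], cfg.rho_cis))
    for g, lid in zip(distal_pairs["gene"], distal_pairs["locus"]):
        expr[gi[g]] = _couple(observed[id_to_idx[lid]], cfg.rho_distal)
    cis_pairs = pd.DataFrame(cis_rows, columns=["gene", "locus", "rho"])

    expr_values = pd.DataFrame(expr, index=genes, columns=samples)
    expr_mat = ExprMatrix(expr_values, gene_meta)

    # ---- metadata -------------------------------------------------------
    grade_latent = 0.5 * (mg + ml) + rng.normal(0, 0.2, n_s)
    grade = np.clip(np.digitize(grade_latent, [0.3, 0.7]) + 1, 1, 3)
    cin = np.clip(0.15 + 0.5 * mg + rng.normal(0, 0.08, n_s), 0.0, 1.0)
    cin[~is_tumor] = np.clip(rng.normal(0.02, 0.01, (~is_tumor).sum()), 0, 1)
    table = pd.DataFrame(
        {"group": groups, "grade": grade, "cin": cin}, index=samples
    )
    table.loc[~is_tumor, "grade"] = np.nan
    mut = pd.DataFrame(
        {
            "TP53like": (rng.random(n_s) < np.clip(0.1 + 0.5 * ml, 0, 1)).astype(int),
            **{
                f"NULLMUT{j}": (rng.random(n_s) < 0.2).astype(int)
                for j in range(5)
            },
        },
        index=samples,
    ).T
    mut.loc[:, ~is_tumor] = 0
    metadata = SampleMetadata(table, mutations=mut)

    truth = GroundTruth(
        f_imm=pd.Series(f_imm, index=samples),
        f_caf=pd.Series(f_caf, index=samples),
        clock=pd.Series(clock, index=samples),
        mg=pd.Series(mg, index=samples),
        ml=pd.Series(ml, index=samples),
        locus_layer=pd.Series(layer, index=locus_ids),
        cis_pairs=cis_pairs,
        distal_pairs=distal_pairs,
        immune_genes=list(immune_genes),
        caf_genes=list(caf_genes),
    )
    return meth, expr_mat, metadata, truth


# ---------------------------------------------------------------------------
# focused generators for individual stages
# ---------------------------------------------------------------------------

def simulate_cis_matrices(
    n_genes: int,
    n_planted: int,
    rho: float,
    n_samples: int,
    seed: int,
    meth_sd: float = 0.12,
):
    """Square gene/promoter matrices for the cis screen.

    Promoter methylation is independent noise per gene; the first
    ``n_planted`` genes' expression is coupled to their own promoter at
    correlation ``-rho``.  Returns (expr_df, meth_df, planted gene ids).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    meth = np.clip(
        rng.uniform(0.2, 0.6, (n_genes, 1)) + rng.normal(0, meth_sd, (n_genes, n_samples)),
        0, 1,
    )
    expr = rng.normal(8.0, 1.0, (n_genes, n_samples))
    for i in range(n_planted):
        z = (meth[i] - meth[i].mean()) / max(meth[i].std(), 1e-12)
        expr[i] = 8.0 - rho * z + np.sqrt(max(1 - rho**2, 0)) * rng.normal(0, 1, n_samples)
    cols = [f"S{i:04d}" for i in range(n_samples)]
    return (
        pd.DataFrame(expr, index=genes, columns=cols),
        pd.DataFrame(meth, index=genes, columns=cols),
        genes[:n_planted],
    )


def simulate_distal_geometry(
    n_loci: int,
    n_genes: int,
    n_samples: int,
    seed: int,
    n_coupled: int = 0,
    rho: float = 0.5,
    chrom_length: int = _CHROM_LEN,
):
    """Non-promoter loci and gene expression with genomic coordinates.

    With ``n_coupled`` = 0 the two matrices are independent (a global
    null for the distal pairing screen).  Coupled loci are placed within
    200 kb of their partner gene's TSS.  ``chrom_length`` controls the
    chance-pairing rate (window size / genome size) and hence how many
    pairing events a null run produces.
    """
    rng = np.random.default_rng(seed)
    loci = [f"L{i:05d}" for i in range(n_loci)]
    genes = [f"G{i:05d}" for i in range(n_genes)]
    cols = [f"S{i:04d}" for i in range(n_samples)]
    locus_chrom = rng.choice(_CHROMS, n_loci)
    locus_start = rng.integers(10_000, chrom_length - 10_000, n_loci)
    gene_chrom = rng.choice(_CHROMS, n_genes)
    gene_tss = rng.integers(10_000, chrom_length - 10_000, n_genes)
    meth = np.clip(
        rng.uniform(0.2, 0.7, (n_loci, 1)) + rng.normal(0, 0.12, (n_loci, n_samples)),
        0, 1,
    )
    expr = rng.normal(8.0, 1.0, (n_genes, n_samples))
    for j in range(n_coupled):
        locus_chrom[j] = gene_chrom[j]
        locus_start[j] = np.clip(
            gene_tss[j] + int(rng.integers(-200_000, 200_000)), 1000,
            chrom_length - 1000,
        )
        z = (meth[j] - meth[j].mean()) / max(meth[j].std(), 1e-12)
        expr[j] = 8.0 - rho * z + np.sqrt(max(1 - rho**2, 0)) * rng.normal(0, 1, n_samples)
    locus_coords = pd.DataFrame(
        {"chrom": locus_chrom, "start": locus_start, "end": locus_start + 200},
        index=loci,
    )
    gene_coords = pd.DataFrame({"chrom": gene_chrom, "tss": gene_tss}, index=genes)
    return (
        pd.DataFrame(expr, index=genes, columns=cols),
        gene_coords,
        pd.DataFrame(meth, index=loci, columns=cols),
        locus_coords,
    )


def simulate_dosage_cohort(
    n_genes: int = 200,
    n_samples: int = 300,
    frac_compensated: float = 0.5,
    seed: int = 0,
):
    """Genes under copy-number change, half methylation-compensated.

    Compensated genes shift promoter methylation with copy number while
    expression stays flat; pure-dosage genes scale expression with copy
    number while methylation stays flat.  Returns
    (meth_df, expr_df, cn_df, truth labels).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    cols = [f"S{i:04d}" for i in range(n_samples)]
    n_comp = int(round(frac_compensated * n_genes))
    labels = pd.Series(
        ["compensated"] * n_comp + ["dosage"] * (n_genes - n_comp), index=genes
    )
    cn = rng.choice([1, 2, 3, 4], size=(n_genes, n_samples), p=[0.1, 0.6, 0.2, 0.1])
    meth = np.clip(rng.normal(0.3, 0.05, (n_genes, n_samples)), 0, 1)
    expr = rng.normal(8.0, 0.5, (n_genes, n_samples))
    comp = labels.to_numpy() == "compensated"
    meth[comp] = np.clip(meth[comp] + 0.2 * (cn[comp] - 2) / 1.0, 0, 1)
    expr[~comp] = expr[~comp] + 1.5 * np.log2(cn[~comp] / 2.0)
    return (
        pd.DataFrame(meth, index=genes, columns=cols),
        pd.DataFrame(expr, index=genes, columns=cols),
        pd.DataFrame(cn, index=genes, columns=cols),
        labels,
    )


# ---------------------------------------------------------------------------
# read-level epiallele simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    """Raw per-read CpG calls for one restriction fragment."""

    fragment_id: str
    reads: pd.DataFrame  # read_id, pos, call
    positions: list[int]
    flagged: bool  # True when the fragment has <5 CpGs
    true_distribution: dict


def simulate_read_patterns(
    fragment_id: str,
    positions: Sequence[int],
    depth: int,
    epiallele_distribution: dict,
    rng: np.random.Generator,
    per_cpg_dropout: float = 0.0,
) -> SimulatedReads:
    """Draw reads for a fragment from a 5-mer epiallele distribution.

    Patterns are tuples/strings of 0/1 over the first five positions;
    additional CpGs on the fragment get independent Bernoulli calls at the
    distribution's mean methylation.  ``per_cpg_dropout`` removes each
    call with a per-CpG jittered probability so that the most-covered-CpG
    selection downstream is exercised.  Fragments with <5 CpGs are
    emitted but flagged.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    positions = sorted(int(p) for p in positions)
    flagged = len(positions) < 5
    pats = list(epiallele_distribution)
    probs = np.array([epiallele_distribution[p] for p in pats], dtype=float)
    probs = probs / probs.sum()
    pat_arrays = [np.array([int(c) for c in ("".join(map(str, p)) if not isinstance(p, str) else p)])
                  for p in pats]
    k = min(5, len(positions))
    mean_meth = float(np.mean([a[:k].mean() for a in pat_arrays])) if k else 0.0

    drop = rng.uniform(0.0, 2 * per_cpg_dropout, len(positions)) if per_cpg_dropout else None
    rows = []
    choice = rng.choice(len(pats), size=depth, p=probs)
    for r in range(depth):
        calls = pat_arrays[choice[r]]
        for j, pos in enumerate(positions):
            if j < k:
                call = int(calls[j]) if j < len(calls) else 0
            else:
                call = int(rng.random() < mean_meth)
            if drop is not None and rng.random() < drop[j]:
                continue
            rows.append((f"{fragment_id}.r{r}", pos, call))
    reads = pd.DataFrame(rows, columns=["read_id", "pos", "call"])
    return SimulatedReads(fragment_id, reads, positions, flagged, dict(epiallele_distribution))


def simulate_pattern_cohort(
    n_background: int,
    n_concentrated: int,
    depth: int,
    seed: int,
    ncpg: int = 5,
):
    """Per-fragment epiallele count tables with matched mean methylation.

    Background fragments draw patterns from an independent-CpG model (high
    epiallele diversity); "concentrated" fragments (emulating convergent
    cis-regulated loci) place most mass on one or two epialleles.  Returns
    (counts DataFrame indexed by fragment with 2**ncpg pattern columns,
    labels Series, mean methylation Series).
    """
    rng = np.random.default_rng(seed)
    npat = 2 ** ncpg
    bits = np.array([[(i >> (ncpg - 1 - j)) & 1 for j in range(ncpg)] for i in range(npat)])
    rows, labels, means = [], [], []
    ids = [f"BG{i:04d}" for i in range(n_background)] + [
        f"CC{i:04d}" for i in range(n_concentrated)
    ]
    for i, fid in enumerate(ids):
        m = rng.uniform(0.05, 0.6)
        if i < n_background:
            p_cpg = np.clip(rng.normal(m, 0.05, ncpg), 0.01, 0.99)
            probs = np.prod(np.where(bits == 1, p_cpg, 1 - p_cpg), axis=1)
            labels.append("background")
        else:
            k = int(round(m * ncpg))
            main = int("".join(["1"] * k + ["0"] * (ncpg - k)), 2)
            probs = np.full(npat, 0.02 / (npat - 1))
            probs[main] = 0.98
            labels.append("concentrated")
        probs = probs / probs.sum()
        counts = rng.multinomial(depth, probs)
        rows.append(counts)
        means.append(float((counts @ bits.sum(axis=1)) / (depth * ncpg)))
    counts_df = pd.DataFrame(
        rows, index=ids, columns=[f"m{i:0{ncpg}b}" for i in range(npat)]
    )
    return counts_df, pd.Series(labels, index=ids), pd.Series(means, index=ids)
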