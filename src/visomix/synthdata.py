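"""Multi-cohort multi-omics simulator with planted ground truth.

The generator emulates the structure of a multi-cohort blood methylation +
expression study: several cohorts with shifted phenotype distributions, beta
values in [0, 1] driven by per-CpG baselines, log-normal expression levels
that pass a counts-per-million inclusion filter by construction, a small set
of causal genes whose latent per-sample signal enters both omics (or only
one, to probe omic-specific information), and a binary "sex" covariate that
shifts a designated gene block. Gene TSS positions and CpG positions are laid
out so that nearest-TSS annotation recovers the intended CpG->gene map
exactly, which makes every mask-building step testable against the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annot_masks import AnnotationSet, CpGSite, GeneRegion, PathwayHierarchy
from .dataset import OmicsDataset

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "simulate_classification",
    "simulate_hierarchy",
]

_GENE_SPACING = 100_000  # bp between consecutive TSSs
_CPG_SPAN = 20_000       # CpGs fall within +-span of their gene's TSS


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a four-cohort study of 250 samples each over 500 genes
    with on average five CpGs per gene and five causal genes. Effect sizes
    are per-omic coefficients on the standardized gene-level signals;
    ``omic_specificity`` is the fraction of causal genes whose effect lives
    in a single omic (alternating methylation-only / expression-only).
    ``cohort_shift`` adds a per-cohort offset to the phenotype, emulating
    cohorts with different outcome distributions.
    """

    n_cohorts: int = 4
    samples_per_cohort: int = 250
    n_genes: int = 500
    cpgs_per_gene_mean: float = 5.0
    n_causal_genes: int = 5
    me_beta: float = 1.0
    ge_beta: float = 1.0
    omic_specificity: float = 0.0
    cohort_shift: float = 0.5
    n_sex_genes: int = 0
    sex_effect: float = 1.5
    sex_block_overlap_causal: bool = False
    noise_sd: float = 0.5
    me_loading: float = 1.2
    ge_loading: float = 0.8
    me_view_noise: float = 0.3
    ge_view_noise: float = 0.4
    phenotype_offset: float = 50.0
    phenotype_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cohorts, self.samples_per_cohort, self.n_genes) < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.n_causal_genes <= self.n_genes):
            raise ValueError("n_causal_genes must lie in [0, n_genes]")
        if not (0.0 <= self.omic_specificity <= 1.0):
            raise ValueError("omic_specificity must lie in [0, 1]")
        if self.n_sex_genes > self.n_genes:
            raise ValueError("n_sex_genes cannot exceed n_genes")
        if self.cpgs_per_gene_mean <= 0 or self.noise_sd < 0:
            raise ValueError("invalid dispersion/noise settings")


@dataclass
class GroundTruth:
    """What the generator planted, for comparing against model output."""

    causal_genes: dict[str, tuple[float, float]]  # gene -> (me_coef, ge_coef)
    sex_genes: list[str]
    cpg_gene_map: dict[str, str]
    true_score: pd.Series
    formula: str
    extras: dict = field(default_factory=dict)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _layout(cfg: SimulationConfig, rng) -> tuple[list[GeneRegion], list[CpGSite], dict[str, str]]:
    """TSS grid plus CpGs scattered close enough that nearest-TSS is exact."""
    genes, cpgs, cmap = [], [], {}
    n_per_chrom = 250
    for j in range(cfg.n_genes):
        chrom = f"chr{j // n_per_chrom + 1}"
        tss = (j % n_per_chrom) * _GENE_SPACING + _GENE_SPACING  # keep >= 1
        genes.append(GeneRegion(f"G{j:04d}", chrom, tss, "+"))
    counts = np.maximum(1, rng.poisson(cfg.cpgs_per_gene_mean, size=cfg.n_genes))
    k = 0
    for g, c in zip(genes, counts):
        offsets = rng.integers(-_CPG_SPAN, _CPG_SPAN + 1, size=c)
        for off in offsets:
            pos = int(max(1, g.tss + off))
            cid = f"cg{k:06d}"
            cpgs.append(CpGSite(cid, g.chrom, pos))
            cmap[cid] = g.gene_id
            k += 1
    return genes, cpgs, cmap


def _build(cfg: SimulationConfig, rng):
    """Shared machinery: matrices, latent score, annotations."""
    genes, cpgs, cmap = _layout(cfg, rng)
    gene_ids = [g.gene_id for g in genes]
    n = cfg.n_cohorts * cfg.samples_per_cohort
    samples = [f"S{i:05d}" for i in range(n)]
    cohorts = np.repeat([f"cohort{c+1}" for c in range(cfg.n_cohorts)], cfg.samples_per_cohort)
    sex = rng.integers(0, 2, size=n)

    causal_ids = sorted(rng.choice(cfg.n_genes, size=cfg.n_causal_genes, replace=False))
    causal = [gene_ids[i] for i in causal_ids]
    n_specific = int(round(cfg.omic_specificity * cfg.n_causal_genes))
    coefs: dict[str, tuple[float, float]] = {}
    for k, g in enumerate(causal):
        if k < n_specific:
            # alternate methylation-only / expression-only signal
            coefs[g] = (cfg.me_beta, 0.0) if k % 2 == 0 else (0.0, cfg.ge_beta)
        else:
            coefs[g] = (cfg.me_beta, cfg.ge_beta)
    if cfg.sex_block_overlap_causal and cfg.n_sex_genes:
        # group effect sits on the predictive genes (plus random extras), so
        # the trained network's gene activations carry the group structure
        extra = max(0, cfg.n_sex_genes - len(causal))
        others = [i for i in range(cfg.n_genes) if i not in causal_ids]
        picked = list(rng.choice(others, size=extra, replace=False)) if extra else []
        sex_genes = sorted(set(causal) | {gene_ids[i] for i in picked})
    else:
        sex_gene_ids = sorted(rng.choice(cfg.n_genes, size=cfg.n_sex_genes, replace=False))
        sex_genes = [gene_ids[i] for i in sex_gene_ids]

    # latent per-sample factor for every causal gene drives both omics
    factors = {g: rng.standard_normal(n) for g in causal}

    # methylation: logit-scale baseline per CpG + factor loading + noise
    cpg_ids = [c.cpg_id for c in cpgs]
    base = rng.uniform(-1.5, 1.5, size=len(cpgs))
    logit = base[None, :] + cfg.me_view_noise * rng.standard_normal((n, len(cpgs)))
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    gene_of = np.array([gene_pos[cmap[c]] for c in cpg_ids])
    for g, (me_c, _) in coefs.items():
        if me_c != 0.0:
            sel = gene_of == gene_pos[g]
            logit[:, sel] += cfg.me_loading * factors[g][:, None]
    for g in sex_genes:
        sel = gene_of == gene_pos[g]
        logit[:, sel] += cfg.sex_effect * (sex[:, None] - 0.5)
    me = _sigmoid(logit)

    # expression: log-normal levels, mean CPM comfortably above the >=1 filter
    log_base = rng.uniform(2.0, 6.0, size=cfg.n_genes)
    log_expr = log_base[None, :] + cfg.ge_view_noise * rng.standard_normal((n, cfg.n_genes))
    for g, (_, ge_c) in coefs.items():
        if ge_c != 0.0:
            log_expr[:, gene_pos[g]] += cfg.ge_loading * factors[g]
    for g in sex_genes:
        log_expr[:, gene_pos[g]] += cfg.sex_effect * 0.5 * (sex - 0.5)
    ge = np.exp(log_expr)

    # phenotype score built from the observable gene-level summaries
    def _z(v):
        return (v - v.mean()) / max(v.std(), 1e-12)

    score = np.zeros(n)
    for g, (me_c, ge_c) in coefs.items():
        cols = gene_of == gene_pos[g]
        if me_c != 0.0:
            score += me_c * _z(me[:, cols].mean(axis=1))
        if ge_c != 0.0:
            score += ge_c * _z(np.log(ge[:, gene_pos[g]]))
    shift = cfg.cohort_shift * np.repeat(np.arange(cfg.n_cohorts), cfg.samples_per_cohort)
    shift = shift - shift.mean()

    me_df = pd.DataFrame(me, index=samples, columns=cpg_ids)
    ge_df = pd.DataFrame(ge, index=samples, columns=gene_ids)
    cov = pd.DataFrame({"sex": sex}, index=samples)
    cohort = pd.Series(cohorts, index=samples, name="cohort")
    annot = AnnotationSet(cpgs=cpgs, genes=genes)
    return me_df, ge_df, cov, cohort, annot, cmap, coefs, sex_genes, score, shift, rng


_FORMULA = (
    "y = offset + scale * ( sum_causal [ me_coef * z(mean beta of gene CpGs) + ge_coef * z(log expr) ]"
    " + cohort_shift + sex_effect + noise )"
)


def simulate(config: SimulationConfig) -> tuple[OmicsDataset, AnnotationSet, GroundTruth]:
    """Continuous-phenotype dataset with planted causal genes.

    Same seed gives bit-identical output. The phenotype is a linear
    combination of standardized gene-level methylation means and log
    expression values of the causal genes, plus a per-cohort offset and
    Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    me, ge, cov, cohort, annot, cmap, coefs, sex_genes, score, shift, rng = _build(config, rng)
    noise = config.noise_sd * rng.standard_normal(len(score))
    # affine map to an age-like positive scale (regression networks end in a
    # ReLU output, so the target must live in [0, inf)): the combined signal
    # is standardized, then mapped to mean `phenotype_offset`, sd
    # `phenotype_scale`
    raw = score + shift + noise
    denom = max(raw.std(), 1e-12)
    y_raw = config.phenotype_offset + config.phenotype_scale * (raw - raw.mean()) / denom
    y = pd.Series(y_raw, index=me.index, name="phenotype")
    ds = OmicsDataset(methylation=me, expression=ge, phenotype=y, cohort=cohort, covariates=cov)
    truth = GroundTruth(
        causal_genes=coefs,
        sex_genes=sex_genes,
        cpg_gene_map=cmap,
        true_score=pd.Series(
            config.phenotype_offset
            + config.phenotype_scale * (score + shift - raw.mean()) / denom,
            index=me.index, name="true_score",
        ),
        formula=_FORMULA,
        extras={"noise_sd": config.noise_sd, "task": "regression"},
    )
    return ds, annot, truth


def simulate_classification(
    config: SimulationConfig, prevalence: float = 0.25
) -> tuple[OmicsDataset, AnnotationSet, GroundTruth]:
    """Binary-phenotype dataset via a logistic link with prevalence control.

    The intercept is solved so the expected prevalence matches the target;
    ``truth.extras['bayes_auc']`` holds the AUC of the true latent score
    against the sampled labels — the generator's own performance ceiling.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(config.seed)
    me, ge, cov, cohort, annot, cmap, coefs, sex_genes, score, shift, rng = _build(config, rng)
    s = score + shift
    # bisect the intercept so mean sigmoid(s + b) hits the target prevalence
    lo, hi = -50.0, 50.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _sigmoid(s + mid).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    p = _sigmoid(s + 0.5 * (lo + hi))
    y = pd.Series((rng.uniform(size=len(p)) < p).astype(float), index=me.index, name="phenotype")
    ds = OmicsDataset(methylation=me, expression=ge, phenotype=y, cohort=cohort, covariates=cov)
    from sklearn.metrics import roc_auc_score

    bayes = float(roc_auc_score(y, s)) if 0 < y.sum() < len(y) else float("nan")
    truth = GroundTruth(
        causal_genes=coefs,
        sex_genes=sex_genes,
        cpg_gene_map=cmap,
        true_score=pd.Series(s, index=me.index, name="true_score"),
        formula=_FORMULA + "; binary y ~ Bernoulli(sigmoid(score + intercept))",
        extras={"bayes_auc": bayes, "prevalence": float(y.mean()), "task": "classification"},
    )
    return ds, annot, truth


def simulate_hierarchy(
    genes: list[str],
    n_local: int = 321,
    n_mid: int = 44,
    n_global: int = 6,
    annotated_fraction: float = 0.6,
    seed: int = 0,
) -> PathwayHierarchy:
    """Random three-level pathway forest over the given genes.

    A fraction of genes receives one or two local-pathway memberships; local
    pathways are assigned round-robin to mid-level parents and mids to global
    parents, so every level stays fully reachable. Defaults mirror a
    functional-pathway hierarchy with 321/44/6 nodes.
    """
    rng = np.random.default_rng(seed)
    locals_ = [f"L{i:03d}" for i in range(n_local)]
    mids = [f"M{i:02d}" for i in range(n_mid)]
    globals_ = [f"T{i}" for i in range(n_global)]
    parent = {p: mids[i % n_mid] for i, p in enumerate(locals_)}
    parent |= {m: globals_[i % n_global] for i, m in enumerate(mids)}
    n_annot = int(round(annotated_fraction * len(genes)))
    chosen = rng.choice(len(genes), size=n_annot, replace=False)
    membership: dict[str, set[str]] = {g: set() for g in genes}
    for gi in chosen:
        k = 1 + int(rng.uniform() < 0.3)
        for p in rng.choice(n_local, size=k, replace=False):
            membership[genes[gi]].add(locals_[p])
    # make sure no local pathway is empty so the fixture keeps exact widths
    have = {p for ps in membership.values() for p in ps}
    empty = [p for p in locals_ if p not in have]
    if empty and n_annot:
        anchors = rng.choice(chosen, size=len(empty))
        for p, gi in zip(empty, anchors):
            membership[genes[gi]].add(p)
    return PathwayHierarchy(membership=membership, parent=parent)
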