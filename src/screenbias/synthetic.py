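"""Seeded synthetic CRISPR-Cas9 screen bundles with known ground truth.

The generator emulates the statistical structure of dependency-map screen
data at desk scale:

* a genome of evenly spaced genes on p/q arms with fixed centromeres;
* per-gene fitness effects with a common-essential / non-essential split
  (essential effect -1, everything else 0 unless a selective dependency is
  planted);
* integer absolute copy number with occasional amplified runs (mode 2) and
  a linear-above-diploid CN depletion bias b(CN) = -beta * max(0, CN - 2);
* screen-specific chromosome-arm offsets, drawn with a larger spread in
  TP53-mutant models (arm-scale damage is worse without functional p53);
* unexpressed genes (lognormal TPM with a planted low-expression class)
  that carry no true fitness effect;
* cancer functional events with tissue labels, optionally with planted
  biomarker associations (a gene made selectively essential in the
  event-positive models of one tissue);
* optional negative-binomial read-count emission around a plasmid baseline
  for exercising the preprocessing chain end to end.

The observed gene-level LFC decomposes exactly as

    observed = gene_effect + cn_bias + arm_offset + noise

and every component is stored in :class:`SyntheticTruth`, so corrections and
metrics can be validated against the planted signal. Each component draws
from its own RNG stream spawned from the master seed, so adding a component
never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    CFECatalog,
    CountMatrix,
    GenomeAnnotation,
    GeneSets,
    GuideMap,
    OmicsProfiles,
    ScreenBundle,
    ScreenMatrix,
)

__all__ = [
    "PlantedBiomarker",
    "SimConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "simulate_bundle",
    "truth_reconstruction_check",
    "tiny_config",
]

_STREAMS = (
    "cn", "tpm", "effects", "arm_offsets", "noise",
    "cfe", "oncogenes", "guides", "counts",
)


@dataclass(frozen=True)
class PlantedBiomarker:
    """A gene made selectively essential in event-positive models of a tissue."""

    tissue: str
    cfe: str
    gene: str
    effect: float  # added to the gene's LFC in event-positive models (negative = depleted)


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults describe a typically biased screen.

    ``noise_sd`` is the gene-level residual spread after guide collapse;
    ``cn_bias_slope`` is the depletion added per copy above diploid;
    ``arm_offset_sd_*`` are the spreads of per-(model, arm) offsets for TP53
    wild-type and mutant models (mutant larger).
    """

    n_models: int = 20
    n_chromosomes: int = 5
    genes_per_arm: int = 100
    guides_per_gene: int = 4
    essential_fraction: float = 0.1
    essential_effect: float = -1.0
    noise_sd: float = 0.2
    cn_bias_slope: float = 0.1
    arm_offset_sd_wt: float = 0.1
    arm_offset_sd_mut: float = 0.3
    fraction_unexpressed: float = 0.3
    fraction_variable_expression: float = 0.1
    fraction_tp53_mutant: float = 0.5
    n_nonessential_controls: int = 100
    n_cfes: int = 10
    n_ssd_genes: int = 20
    n_oncogenes: int = 15
    oncogene_mutation_rate: float = 0.15
    oncogene_addiction_effect: float = -1.0
    amplified_run_prob: float = 0.3
    amplified_run_mean_length: int = 15
    tissue_labels: tuple = ("lung", "breast", "colon")
    planted_biomarkers: tuple = ()
    emit_counts: bool = False
    plasmid_mean_reads: float = 500.0
    replicates_per_model: int = 2
    guide_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "essential_fraction",
            "fraction_unexpressed",
            "fraction_variable_expression",
            "fraction_tp53_mutant",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("noise_sd", "arm_offset_sd_wt", "arm_offset_sd_mut", "guide_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.genes_per_arm < 2:
            raise ValueError("need >= 2 genes per arm")

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * 2 * self.genes_per_arm

    def with_(self, **overrides) -> "SimConfig":
        return replace(self, **overrides)


def tiny_config(**overrides) -> SimConfig:
    """A small bundle (4 chromosomes, 200 genes, 12 models) for tests/docs."""
    base = SimConfig(
        n_models=12, n_chromosomes=4, genes_per_arm=25,
        n_nonessential_controls=30, n_cfes=6, n_ssd_genes=10, n_oncogenes=8,
        tissue_labels=("pan",),
    )
    return base.with_(**overrides) if overrides else base


@dataclass
class SyntheticTruth:
    """Ground-truth components of a simulated bundle.

    The observed gene-level LFC equals gene_effects + cn_bias +
    arm_offset_by_gene + noise, entry for entry.
    """

    gene_effects: pd.DataFrame
    cn_bias: pd.DataFrame
    arm_offsets: pd.DataFrame  # (chromosome, arm) x models
    arm_offset_by_gene: pd.DataFrame
    noise: pd.DataFrame
    essential: list[str]
    nonessential: list[str]
    unexpressed: pd.DataFrame  # boolean genes x models
    planted: tuple = ()


@dataclass
class SyntheticBundle(ScreenBundle):
    truth: SyntheticTruth | None = None
    config: SimConfig | None = None


def _layout(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Evenly spaced gene starts; centromere between the p and q blocks."""
    spacing = 1_000_000
    rows = []
    centromeres = {}
    gene_no = 0
    for c in range(1, config.n_chromosomes + 1):
        chrom = str(c)
        centromeres[chrom] = int((config.genes_per_arm + 0.5) * spacing)
        for i in range(2 * config.genes_per_arm):
            rows.append(
                {
                    "gene": f"GENE{gene_no:05d}",
                    "chromosome": chrom,
                    "start": (i + 1) * spacing,
                }
            )
            gene_no += 1
    genes = pd.DataFrame(rows).set_index("gene")
    return genes, pd.Series(centromeres, name="centromere_bp")


def _simulate_cn(config: SimConfig, genes: pd.DataFrame, models, rng) -> pd.DataFrame:
    cn = np.full((len(genes), len(models)), 2, dtype=int)
    sprinkle = rng.random(cn.shape) < 0.03
    cn[sprinkle] = rng.choice([0, 1, 3], size=int(sprinkle.sum()), p=[0.2, 0.4, 0.4])
    chrom_index = {c: np.nonzero((genes["chromosome"] == c).to_numpy())[0]
                   for c in genes["chromosome"].unique()}
    for j in range(len(models)):
        for idx in chrom_index.values():
            if rng.random() >= config.amplified_run_prob:
                continue
            length = int(rng.poisson(config.amplified_run_mean_length)) + 3
            start = int(rng.integers(0, len(idx)))
            level = int(rng.integers(4, 9))
            cn[idx[start:start + length], j] = level
    return pd.DataFrame(cn, index=genes.index, columns=models)


def _simulate_tpm(
    config: SimConfig, genes: pd.DataFrame, models, rng
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Lognormal TPM with three gene classes: unexpressed, variable, expressed."""
    n = len(genes)
    u = rng.random(n)
    unexpressed_class = u < config.fraction_unexpressed
    variable_class = (~unexpressed_class) & (
        u < config.fraction_unexpressed + config.fraction_variable_expression
    )
    base = np.where(
        unexpressed_class,
        rng.normal(-1.3, 0.4, n),
        np.where(variable_class, rng.normal(0.0, 0.8, n), rng.normal(1.5, 0.6, n)),
    )
    model_sd = np.where(variable_class, 0.6, 0.2)
    log_tpm = base[:, None] + rng.normal(0.0, 1.0, (n, len(models))) * model_sd[:, None]
    tpm = pd.DataFrame(10.0 ** log_tpm, index=genes.index, columns=models)
    return tpm, unexpressed_class, variable_class


def simulate_bundle(config: SimConfig) -> SyntheticBundle:
    """Generate a fully consistent synthetic screen bundle plus ground truth."""
    streams = dict(
        zip(_STREAMS, (np.random.default_rng(s)
                       for s in np.random.SeedSequence(config.seed).spawn(len(_STREAMS))))
    )
    genes, centromeres = _layout(config)
    annotation = GenomeAnnotation(genes, centromeres)
    models = [f"MODEL{i:03d}" for i in range(config.n_models)]
    gene_idx = genes.index

    cn = _simulate_cn(config, genes, models, streams["cn"])
    tpm, unexpr_class, variable_class = _simulate_tpm(
        config, genes, models, streams["tpm"]
    )
    omics = OmicsProfiles(cn, tpm)
    unexpressed = tpm < 1.0

    # --- tissue, TP53, CFEs ------------------------------------------------
    rng_cfe = streams["cfe"]
    tissue = pd.Series(
        [config.tissue_labels[i % len(config.tissue_labels)] for i in range(len(models))],
        index=models,
        name="tissue",
    )
    n_mut = int(round(config.fraction_tp53_mutant * len(models)))
    mut_models = set(np.array(models)[rng_cfe.permutation(len(models))[:n_mut]])
    tp53 = pd.Series(
        ["mutant" if m in mut_models else "wild_type" for m in models],
        index=models,
        name="tp53_status",
    )
    cfe_ids = [f"CFE{i:03d}" for i in range(config.n_cfes)]
    for pb in config.planted_biomarkers:
        if pb.cfe not in cfe_ids:
            cfe_ids.append(pb.cfe)
    events = pd.DataFrame(0, index=cfe_ids, columns=models, dtype=int)
    planted_by_cfe = {pb.cfe: pb for pb in config.planted_biomarkers}
    for cfe_id in cfe_ids:
        prevalence = rng_cfe.uniform(0.25, 0.6)
        events.loc[cfe_id] = (rng_cfe.random(len(models)) < prevalence).astype(int)
        pb = planted_by_cfe.get(cfe_id)
        if pb is not None:
            # balanced event split within the target tissue -> usable groups
            in_tissue = [m for m in models if tissue[m] == pb.tissue]
            perm = rng_cfe.permutation(len(in_tissue))
            half = len(in_tissue) // 2
            for pos, m in enumerate(in_tissue):
                events.loc[cfe_id, m] = int(perm[pos] < half)
    cfe = CFECatalog(events, tissue, tp53)

    # --- true gene effects --------------------------------------------------
    rng_eff = streams["effects"]
    expressed_pool = gene_idx[~unexpr_class & ~variable_class]
    n_essential = int(round(config.essential_fraction * len(gene_idx)))
    essential = list(
        rng_eff.choice(expressed_pool, size=min(n_essential, len(expressed_pool)),
                       replace=False)
    )
    effects = pd.DataFrame(0.0, index=gene_idx, columns=models)
    effects.loc[essential] = config.essential_effect

    rng_onc = streams["oncogenes"]
    variable_pool = [g for g in gene_idx[variable_class] if g not in essential]
    oncogenes = list(
        rng_onc.choice(variable_pool, size=min(config.n_oncogenes, len(variable_pool)),
                       replace=False)
    )
    mutation_calls = pd.DataFrame(
        (rng_onc.random((len(oncogenes), len(models)))
         < config.oncogene_mutation_rate).astype(int),
        index=oncogenes,
        columns=models,
    )
    for g in oncogenes:
        mutated = mutation_calls.loc[g].astype(bool)
        effects.loc[g, mutated[mutated].index] += config.oncogene_addiction_effect

    for pb in config.planted_biomarkers:
        if pb.gene not in effects.index:
            raise ValueError(f"planted biomarker gene {pb.gene!r} not in genome")
        carriers = [
            m for m in models
            if tissue[m] == pb.tissue and events.loc[pb.cfe, m] == 1
        ]
        effects.loc[pb.gene, carriers] += pb.effect

    # --- structural biases and noise ----------------------------------------
    arm_table, _ = annotation.assign_arms(gene_idx)
    arm_key = pd.MultiIndex.from_frame(arm_table[["chromosome", "arm"]])
    arm_levels = arm_key.unique().sort_values()
    rng_arm = streams["arm_offsets"]
    sd_by_model = np.array(
        [
            config.arm_offset_sd_mut if tp53[m] == "mutant" else config.arm_offset_sd_wt
            for m in models
        ]
    )
    raw_offsets = (
        rng_arm.normal(0.0, 1.0, (len(arm_levels), len(models))) * sd_by_model[None, :]
    )
    # Offsets are screen-specific deviations from the arm's consensus level:
    # a component shared by all screens would be real arm biology, not bias,
    # so each arm's offsets are centered to zero median across screens.
    raw_offsets -= np.median(raw_offsets, axis=1, keepdims=True)
    arm_offsets = pd.DataFrame(raw_offsets, index=arm_levels, columns=models)
    arm_offset_by_gene = arm_offsets.loc[arm_key].set_axis(gene_idx, axis=0)

    cn_bias = pd.DataFrame(
        -config.cn_bias_slope * np.maximum(0, cn.to_numpy() - 2),
        index=gene_idx,
        columns=models,
    )
    noise = pd.DataFrame(
        streams["noise"].normal(0.0, config.noise_sd, (len(gene_idx), len(models))),
        index=gene_idx,
        columns=models,
    )
    observed = effects + cn_bias + arm_offset_by_gene + noise
    screen = ScreenMatrix(observed, level="gene", scale_tag="raw", name="uncorrected")

    # --- gene sets -----------------------------------------------------------
    rng_guides = streams["guides"]
    zero_effect_expressed = [
        g for g in expressed_pool if g not in set(essential)
    ]
    pool = list(zero_effect_expressed)
    rng_eff.shuffle(pool)
    nonessential = pool[: config.n_nonessential_controls]
    ssd_extra = [g for g in pool[config.n_nonessential_controls:]
                 if g not in {pb.gene for pb in config.planted_biomarkers}]
    ssd_genes = list({pb.gene for pb in config.planted_biomarkers}) + ssd_extra[
        : config.n_ssd_genes
    ]
    msigdb = {
        "msigdb_essential": frozenset(
            rng_eff.choice(essential, size=max(1, len(essential) // 2), replace=False)
        )
    }
    gene_sets = GeneSets(
        essential=frozenset(essential),
        nonessential=frozenset(nonessential),
        msigdb_sets=msigdb,
        oncogenes=frozenset(oncogenes),
        ssd_genes=frozenset(ssd_genes),
    )

    # --- guide map and optional count emission -------------------------------
    guide_rows = []
    for i, g in enumerate(gene_idx):
        for j in range(config.guides_per_gene):
            guide_rows.append(
                {
                    "guide_id": f"{g}_sg{j}",
                    "gene": g,
                    "chromosome": genes.loc[g, "chromosome"],
                    "position": int(genes.loc[g, "start"]) + j * 10,
                    "qc_flags": frozenset(),
                }
            )
        if i % 50 == 0:  # sprinkle disqualified guides to exercise guide QC
            flag = rng_guides.choice(sorted(
                {"multi_align_multi_gene", "no_alignment", "intergenic_only"}
            ))
            guide_rows.append(
                {
                    "guide_id": f"{g}_sgX",
                    "gene": g,
                    "chromosome": genes.loc[g, "chromosome"],
                    "position": int(genes.loc[g, "start"]) + 990,
                    "qc_flags": frozenset({str(flag)}),
                }
            )
    guidemap = GuideMap(pd.DataFrame(guide_rows).set_index("guide_id"))

    counts = None
    if config.emit_counts:
        counts = _emit_counts(config, guidemap, observed, models, streams["counts"])

    truth = SyntheticTruth(
        gene_effects=effects,
        cn_bias=cn_bias,
        arm_offsets=arm_offsets,
        arm_offset_by_gene=arm_offset_by_gene,
        noise=noise,
        essential=list(essential),
        nonessential=list(nonessential),
        unexpressed=unexpressed,
        planted=tuple(config.planted_biomarkers),
    )
    return SyntheticBundle(
        screen=screen,
        guidemap=guidemap,
        omics=omics,
        annotation=annotation,
        gene_sets=gene_sets,
        cfe=cfe,
        counts=counts,
        mutation_calls=mutation_calls,
        truth=truth,
        config=config,
    )


def _emit_counts(
    config: SimConfig,
    guidemap: GuideMap,
    gene_lfc: pd.DataFrame,
    models,
    rng,
) -> CountMatrix:
    """Invert LFCs into negative-binomial read counts around a plasmid baseline."""
    guides = guidemap.guides
    gene_of = guidemap.table["gene"]
    dispersion = 10.0
    mean = config.plasmid_mean_reads

    def nb(mu):
        mu = np.clip(mu, 1e-6, None)
        p = dispersion / (dispersion + mu)
        return rng.negative_binomial(dispersion, p)

    plasmid = nb(np.full(len(guides), mean)).astype(float)
    columns = {"pDNA": plasmid}
    roles = {"pDNA": "plasmid"}
    rep_to_model = {}
    base_lfc = gene_lfc.reindex(gene_of.to_numpy())
    for model in models:
        guide_lfc = (
            base_lfc[model].to_numpy()
            + rng.normal(0.0, config.guide_sd, len(guides))
        )
        mu = plasmid * np.power(2.0, guide_lfc)
        for r in range(config.replicates_per_model):
            name = f"{model}_rep{r}"
            columns[name] = nb(mu).astype(float)
            roles[name] = "replicate"
            rep_to_model[name] = model
    values = pd.DataFrame(columns, index=guides)
    return CountMatrix(values, roles, rep_to_model)


def truth_reconstruction_check(
    bundle: SyntheticBundle, truth: SyntheticTruth | None = None, tol: float = 1e-10
) -> bool:
    """True iff observed LFC minus stored components equals the stored noise."""
    truth = truth if truth is not None else bundle.truth
    if bundle.screen.level != "gene":
        raise ValueError("reconstruction check requires a gene-level bundle")
    expected = (
        truth.gene_effects + truth.cn_bias + truth.arm_offset_by_gene + truth.noise
    )
    try:
        diff = (bundle.screen.values - expected).abs().to_numpy()
    except ValueError:
        return False
    return bool(np.isfinite(diff).all() and diff.max() <= tol)
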