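"""Screen-quality and data-distortion metrics.

A gene-level depletion profile is treated as a rank-based classifier of
essential genes (most depleted = most essential). This module measures how
well a screen separates common-essential from non-essential controls
(AUROC, AUPRC, NNMD, recall at fixed FDR), whether oncogene addictions stay
detectable (pooled ROC of mutated vs wild-type-unexpressed oncogenes), and
whether biomarker associations survive correction (t-test scan with
Benjamini-Hochberg control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import precision_recall_curve, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .datamodel import CFECatalog, GeneSets, OmicsProfiles, ScreenMatrix

__all__ = [
    "screen_roc",
    "nnmd",
    "recall_at_fdr",
    "FDRRecallResult",
    "oncogene_addiction_auroc",
    "biomarker_scan",
    "BiomarkerScanResult",
    "bh_adjust",
]


def screen_roc(screen_lfc: pd.Series, gene_sets: GeneSets) -> tuple[float, float]:
    """AUROC and AUPRC of one screen as a classifier of essential genes.

    Genes are ranked by LFC ascending; essential controls are the positive
    class, non-essential controls the negative class.
    """
    lfc = screen_lfc.dropna()
    ess = sorted(gene_sets.essential & set(lfc.index))
    ness = sorted(gene_sets.nonessential & set(lfc.index))
    if not ess or not ness:
        raise ValueError("a control set is empty after intersection with the screen")
    labels = np.r_[np.ones(len(ess)), np.zeros(len(ness))]
    scores = -lfc.loc[ess + ness].to_numpy()  # more depleted = higher score
    auroc = float(roc_auc_score(labels, scores))
    precision, recall, _ = precision_recall_curve(labels, scores)
    auprc = float(_auc(recall, precision))
    return auroc, auprc


def _mad(x: np.ndarray, scaled: bool) -> float:
    return float(stats.median_abs_deviation(x, scale="normal" if scaled else 1.0))


def nnmd(essential_lfc, nonessential_lfc, scaled_mad: bool = False) -> float:
    """Null-normalized median difference between control LFC distributions.

    NNMD = (median(essential) - median(non-essential)) / MAD(non-essential).
    More negative means better separation. The default denominator is the
    unscaled MAD; ``scaled_mad`` applies the 1.4826 normal-consistency
    factor.
    """
    e = np.asarray(essential_lfc, dtype=float)
    n = np.asarray(nonessential_lfc, dtype=float)
    if e.size == 0 or n.size == 0:
        raise ValueError("both control sets must be non-empty")
    mad = _mad(n, scaled_mad)
    if mad == 0:
        raise ValueError("MAD of non-essential controls is zero; NNMD undefined")
    return float((np.median(e) - np.median(n)) / mad)


@dataclass
class FDRRecallResult:
    """Recall of gene sets at the deepest LFC threshold with PPV >= target."""

    k_star: int | None
    lfc_star: float
    recalls: dict[str, float]
    ppv_threshold: float
    flagged: bool = False


def recall_at_fdr(
    screen_lfc: pd.Series,
    gene_sets: GeneSets,
    target_sets: dict[str, frozenset] | None = None,
    ppv_threshold: float = 0.95,
) -> FDRRecallResult:
    """Recall of target gene sets at a fixed 5%-FDR-style LFC threshold.

    Essential (E) and non-essential (N) controls are ranked by LFC
    ascending. PPV_k = |top-k ∩ E| / k over the ranked controls; k* is the
    deepest rank with PPV_k >= ``ppv_threshold`` and LFC* the control LFC at
    that rank. For every target set G, the recall is the fraction of G
    (restricted to screened genes) with LFC <= LFC*.
    """
    lfc = screen_lfc.dropna()
    ess = gene_sets.essential & set(lfc.index)
    ness = gene_sets.nonessential & set(lfc.index)
    if not ess or not ness:
        raise ValueError("a control set is empty after intersection with the screen")
    if target_sets is None:
        target_sets = {}
    targets = {"essential": frozenset(ess), "nonessential": frozenset(ness)}
    targets.update(target_sets)

    controls = sorted(ess | ness, key=lambda g: (lfc[g], g))
    is_ess = np.array([g in ess for g in controls])
    ppv = np.cumsum(is_ess) / np.arange(1, len(controls) + 1)
    hits = np.nonzero(ppv >= ppv_threshold)[0]
    if hits.size == 0:
        return FDRRecallResult(
            k_star=None,
            lfc_star=float("-inf"),
            recalls={name: 0.0 for name in targets},
            ppv_threshold=ppv_threshold,
            flagged=True,
        )
    k_star = int(hits[-1]) + 1  # 1-based rank
    lfc_star = float(lfc[controls[k_star - 1]])
    recalls = {}
    for name, genes in targets.items():
        screened = [g for g in genes if g in lfc.index]
        if not screened:
            recalls[name] = 0.0
            continue
        recalls[name] = float(np.mean(lfc.loc[screened] <= lfc_star))
    return FDRRecallResult(k_star, lfc_star, recalls, ppv_threshold)


def oncogene_addiction_auroc(
    scaled: ScreenMatrix,
    omics: OmicsProfiles,
    oncogenes,
    mutation_calls: pd.DataFrame,
    tpm_threshold: float = 1.0,
) -> float:
    """Pooled ROC of oncogene addiction across screens.

    Per (oncogene, model): mutated oncogenes are positives, wild-type and
    unexpressed (TPM < threshold) oncogenes are negatives; oncogenes lacking
    at least one positive and one negative are dropped. Instances are pooled
    across screens into one list ranked by scaled LFC.
    """
    if scaled.scale_tag != "scaled":
        raise ValueError("oncogene addiction ROC requires a scaled matrix")
    genes = sorted(
        set(oncogenes)
        & set(scaled.values.index)
        & set(mutation_calls.index)
        & set(omics.tpm.index)
    )
    models = scaled.values.columns.intersection(mutation_calls.columns).intersection(
        omics.tpm.columns
    )
    pos_scores: list[np.ndarray] = []
    neg_scores: list[np.ndarray] = []
    for gene in genes:
        mutated = mutation_calls.loc[gene, models].astype(bool)
        unexpressed = omics.tpm.loc[gene, models] < tpm_threshold
        pos = models[mutated.to_numpy()]
        neg = models[(~mutated & unexpressed).to_numpy()]
        if len(pos) == 0 or len(neg) == 0:
            continue
        pos_scores.append(scaled.values.loc[gene, pos].to_numpy(dtype=float))
        neg_scores.append(scaled.values.loc[gene, neg].to_numpy(dtype=float))
    if not pos_scores or not neg_scores:
        raise ValueError("empty positive or negative oncogene-addiction pool")
    pos_all = np.concatenate(pos_scores)
    neg_all = np.concatenate(neg_scores)
    labels = np.r_[np.ones(pos_all.size), np.zeros(neg_all.size)]
    return float(roc_auc_score(labels, -np.r_[pos_all, neg_all]))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (joint over the whole scan)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class BiomarkerScanResult:
    """All tests performed in a biomarker scan plus the significant hits."""

    tests: pd.DataFrame
    fdr_level: float
    n_tests: int = 0

    @property
    def hits(self) -> pd.DataFrame:
        if self.tests.empty:
            return self.tests
        return self.tests[self.tests["fdr"] < self.fdr_level]


def biomarker_scan(
    lfc: ScreenMatrix,
    cfe: CFECatalog,
    ssd_genes,
    min_group: int = 3,
    fdr_level: float = 0.05,
    equal_var: bool = True,
) -> BiomarkerScanResult:
    """Differential-essentiality scan of SSD genes against CFE status.

    For every (tissue, CFE, SSD gene) with at least ``min_group`` models in
    both the event-positive and event-negative subpopulation, a two-sided
    t-test (pooled variance by default; Welch with ``equal_var=False``)
    compares the gene's LFCs across the two groups. P-values are BH-adjusted
    jointly across all tests performed.
    """
    genes = sorted(set(ssd_genes) & set(lfc.values.index))
    models = lfc.values.columns.intersection(cfe.events.columns)
    rows: list[dict] = []
    tissues = cfe.tissue.loc[models]
    for tissue in sorted(tissues.unique()):
        t_models = models[(tissues == tissue).to_numpy()]
        if len(t_models) < 2 * min_group:
            continue
        events = cfe.events[t_models]
        for cfe_id, status in events.iterrows():
            grp1 = t_models[(status == 1).to_numpy()]
            grp0 = t_models[(status == 0).to_numpy()]
            if len(grp1) < min_group or len(grp0) < min_group:
                continue
            x1 = lfc.values.loc[genes, grp1].to_numpy(dtype=float)
            x0 = lfc.values.loc[genes, grp0].to_numpy(dtype=float)
            t, p = stats.ttest_ind(x1, x0, axis=1, equal_var=equal_var)
            for g, ti, pi in zip(genes, t, p):
                rows.append(
                    {
                        "tissue": tissue,
                        "cfe": cfe_id,
                        "gene": g,
                        "t": float(ti),
                        "p": float(pi),
                        "n_with_event": len(grp1),
                        "n_without_event": len(grp0),
                    }
                )
    if not rows:
        warnings.warn("no testable (tissue, CFE, SSD) triple", stacklevel=2)
        empty = pd.DataFrame(
            columns=["tissue", "cfe", "gene", "t", "p",
                     "n_with_event", "n_without_event", "fdr"]
        )
        return BiomarkerScanResult(empty, fdr_level, 0)
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return BiomarkerScanResult(table, fdr_level, len(table))
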