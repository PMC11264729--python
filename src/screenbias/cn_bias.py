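"""Copy-number bias quantification.

Two complementary metrics:

* **AURC** — area under the recall-vs-rank curve of *amplified unexpressed*
  genes (top 1% copy number, TPM < 1 in the screened model), using the
  remaining unexpressed genes as outgroup. Because unexpressed genes carry
  no fitness signal, a bias-free screen ranks them randomly and AURC is
  about 0.5; CN bias pushes amplified ones towards the depleted end and
  AURC towards 1.

* **ARD** — the mean over integer copy-number bins of |bin median LFC / bin
  standard deviation|. A method that centers LFC distributions at 0 across
  CN levels scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import OmicsProfiles, ScreenMatrix

__all__ = [
    "amplified_unexpressed_positives",
    "aurc",
    "CNBinSummary",
    "cn_bin_summary",
    "ard_from_bins",
    "ard",
    "dataset_ard",
    "per_screen_aurc",
]


def amplified_unexpressed_positives(
    omics: OmicsProfiles,
    model: str,
    top_fraction: float = 0.01,
    tpm_threshold: float = 1.0,
) -> tuple[set, set]:
    """Split a model's unexpressed genes into amplified positives and outgroup.

    The CN threshold is the (1 - top_fraction) quantile of copy number over
    *all* genes in the model; positives are the unexpressed genes at or
    above it, the outgroup the unexpressed genes below it.
    """
    genes = omics.cn.index.intersection(omics.tpm.index)
    cn = omics.cn.loc[genes, model].dropna()
    tpm = omics.tpm.loc[cn.index, model]
    unexpressed = cn.index[tpm < tpm_threshold]
    if len(unexpressed) == 0:
        raise ValueError(f"model {model!r} has no unexpressed gene")
    threshold = float(np.quantile(cn.to_numpy(), 1 - top_fraction))
    amp = cn.loc[unexpressed] >= threshold
    positives = set(unexpressed[amp])
    outgroup = set(unexpressed[~amp])
    return positives, outgroup


def aurc(screen_lfc: pd.Series, positives: set, outgroup: set) -> float:
    """Area under the recall-vs-rank curve of the positive set.

    Genes in positives | outgroup are ranked by LFC ascending (ties broken
    by gene id for determinism); recall(k) is the fraction of positives
    within the top k; the curve is integrated by the trapezoidal rule over
    the rank index and normalized by K - 1 so that a random ranking scores
    about 0.5.
    """
    positives = set(positives)
    outgroup = set(outgroup)
    if positives & outgroup:
        raise ValueError("positives and outgroup must be disjoint")
    if not positives or not outgroup:
        raise ValueError("positives and outgroup must both be non-empty")
    genes = [g for g in positives | outgroup if g in screen_lfc.index]
    if len(genes) < 2:
        raise ValueError("AURC undefined for fewer than 2 ranked genes")
    ranked = sorted(genes, key=lambda g: (screen_lfc[g], g))
    hits = np.array([g in positives for g in ranked], dtype=float)
    n_pos = hits.sum()
    if n_pos == 0:
        raise ValueError("no positive gene present in the screen")
    recall = np.cumsum(hits) / n_pos
    return float(np.trapezoid(recall) / (len(ranked) - 1))


@dataclass
class CNBinSummary:
    """Per-integer-CN bin statistics of an LFC distribution.

    ``table`` is indexed by the integer CN value with columns ``n``,
    ``median`` and ``sd`` (ddof=1; NaN for singleton bins). ``retained``
    flags the bins entering the ARD (n >= min_bin_size and sd > 0).
    """

    table: pd.DataFrame
    min_bin_size: int

    @property
    def retained(self) -> pd.DataFrame:
        t = self.table
        return t[(t["n"] >= self.min_bin_size) & (t["sd"] > 0)]


def cn_bin_summary(
    lfc: pd.Series, cn: pd.Series, min_bin_size: int = 5
) -> CNBinSummary:
    common = lfc.index.intersection(cn.index)
    df = pd.DataFrame(
        {"lfc": lfc.loc[common], "cn": cn.loc[common].round().astype(int)}
    ).dropna()
    grouped = df.groupby("cn")["lfc"]
    table = pd.DataFrame(
        {"n": grouped.size(), "median": grouped.median(), "sd": grouped.std(ddof=1)}
    )
    table.index.name = "cn"
    return CNBinSummary(table, min_bin_size)


def ard_from_bins(bins) -> float:
    """ARD of explicit (median, sd) bins: mean of |median / sd|."""
    ratios = [abs(med / sd) for med, sd in bins]
    if not ratios:
        raise ValueError("ARD undefined without bins")
    return float(np.mean(ratios))


def ard(
    lfc: pd.Series,
    cn: pd.Series,
    min_bin_size: int = 5,
    raw: bool = False,
) -> tuple[float, CNBinSummary]:
    """Average residual difference across integer CN bins.

    Default: mean of |bin median / bin sd| over bins with at least
    ``min_bin_size`` members and positive sd (sparse high-CN bins are
    inevitable and excluded). ``raw`` instead divides the sum over all
    defined bins by C, the maximum CN value observed.
    """
    summary = cn_bin_summary(lfc, cn, min_bin_size)
    retained = summary.retained
    if retained.empty:
        raise ValueError("all CN bins degenerate; ARD undefined")
    if raw:
        t = summary.table.dropna(subset=["sd"])
        t = t[t["sd"] > 0]
        c = int(summary.table.index.max())
        value = float((t["median"].abs() / t["sd"]).sum() / max(c, 1))
    else:
        value = ard_from_bins(zip(retained["median"], retained["sd"]))
    return value, summary


def dataset_ard(
    screen: ScreenMatrix,
    omics: OmicsProfiles,
    tpm_threshold: float = 1.0,
    min_bin_size: int = 5,
    raw: bool = False,
) -> tuple[float, CNBinSummary]:
    """ARD over unexpressed (gene, model) observations pooled across models.

    For every model, the LFCs of its unexpressed genes (TPM < threshold) are
    pooled together with their absolute CN values, then binned by CN.
    """
    lfc_parts: list[np.ndarray] = []
    cn_parts: list[np.ndarray] = []
    genes = screen.values.index.intersection(omics.cn.index).intersection(
        omics.tpm.index
    )
    models = [m for m in screen.values.columns
              if m in omics.cn.columns and m in omics.tpm.columns]
    for model in models:
        unexpr = genes[omics.tpm.loc[genes, model] < tpm_threshold]
        lfc_parts.append(screen.values.loc[unexpr, model].to_numpy(dtype=float))
        cn_parts.append(omics.cn.loc[unexpr, model].to_numpy(dtype=float))
    pooled_lfc = pd.Series(np.concatenate(lfc_parts))
    pooled_cn = pd.Series(np.concatenate(cn_parts))
    return ard(pooled_lfc, pooled_cn, min_bin_size=min_bin_size, raw=raw)


def per_screen_aurc(
    screen: ScreenMatrix,
    omics: OmicsProfiles,
    top_fraction: float = 0.01,
    tpm_threshold: float = 1.0,
) -> pd.Series:
    """Amplified-unexpressed AURC for every screen in the matrix."""
    out = {}
    for model in screen.values.columns:
        if model not in omics.cn.columns or model not in omics.tpm.columns:
            continue
        positives, outgroup = amplified_unexpressed_positives(
            omics, model, top_fraction, tpm_threshold
        )
        if not positives or not outgroup:
            continue
        out[model] = aurc(screen.values[model], positives, outgroup)
    return pd.Series(out, name="aurc")
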