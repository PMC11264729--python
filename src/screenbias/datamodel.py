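"""Shared domain types for pooled CRISPR-Cas9 screen analysis.

All tabular containers are thin dataclasses around :class:`pandas.DataFrame`
with the axis conventions used throughout the package:

* guide- and gene-level matrices are *rows = guides/genes, columns = samples
  or models*;
* gene identity is the bare HGNC-style symbol (DepMap-style ``"SYMBOL
  (ENTREZ)"`` headers are stripped on load);
* genomic coordinates are 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GuideMap",
    "CountMatrix",
    "ScreenMatrix",
    "GenomeAnnotation",
    "OmicsProfiles",
    "GeneSets",
    "CFECatalog",
    "ScreenBundle",
    "DISQUALIFYING_GUIDE_FLAGS",
]

#: Guide-level QC flags that disqualify a guide from analysis: ambiguous or
#: missing library alignment, purely intergenic targeting, or being the only
#: passing guide for its gene (a single guide cannot be error-checked).
DISQUALIFYING_GUIDE_FLAGS = frozenset(
    {
        "multi_align_same_gene",
        "multi_align_multi_gene",
        "no_alignment",
        "intergenic_only",
        "sole_passing_guide",
    }
)


class FormatError(ValueError):
    """An input file does not conform to the expected tabular layout."""

    def __init__(self, path, message):
        self.path = str(path)
        super().__init__(f"{path}: {message}")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()[:10]
        raise ValueError(f"duplicate {what} identifiers: {dupes}")


@dataclass
class GuideMap:
    """Map from sgRNA to target gene with genomic position and QC flags.

    ``table`` is indexed by guide id and carries columns ``gene``,
    ``chromosome``, ``position`` (1-based bp) and ``qc_flags`` (a frozenset
    per guide, possibly empty).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "chromosome", "position", "qc_flags"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"guide map missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "guide")
        pos = self.table["position"]
        if (pos.dropna() < 1).any():
            raise ValueError("guide positions must be >= 1 (1-based)")

    @property
    def guides(self) -> pd.Index:
        return self.table.index

    def genes(self) -> pd.Index:
        return pd.Index(self.table["gene"].unique())

    def guides_for(self, gene: str) -> list[str]:
        return self.table.index[self.table["gene"] == gene].tolist()


@dataclass
class CountMatrix:
    """Raw sgRNA read counts (guides x samples) with sample role metadata.

    ``sample_roles`` maps every column of ``values`` to ``"plasmid"`` or
    ``"replicate"``; ``replicate_to_model`` maps each replicate column to the
    screened model. Missing counts are imputed to 0 on construction.
    """

    values: pd.DataFrame
    sample_roles: dict[str, str]
    replicate_to_model: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "guide")
        _check_unique(self.values.columns, "sample")
        self.values = self.values.fillna(0)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("read counts must be nonnegative")
        unknown = set(self.values.columns) - set(self.sample_roles)
        if unknown:
            raise ValueError(f"samples without a role: {sorted(unknown)[:10]}")
        if not self.plasmid_samples:
            raise ValueError("count matrix must contain >= 1 plasmid sample")
        for rep in self.replicate_samples:
            if rep not in self.replicate_to_model:
                raise ValueError(f"replicate {rep!r} has no model assignment")

    @property
    def plasmid_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_roles[s] == "plasmid"]

    @property
    def replicate_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_roles[s] == "replicate"]

    @property
    def models(self) -> list[str]:
        seen: dict[str, None] = {}
        for rep in self.replicate_samples:
            seen.setdefault(self.replicate_to_model[rep], None)
        return list(seen)

    def replicates_of(self, model: str) -> list[str]:
        return [
            s
            for s in self.replicate_samples
            if self.replicate_to_model[s] == model
        ]


@dataclass
class ScreenMatrix:
    """Genes (or guides) x models matrix of depletion LFCs / gene effects.

    ``level`` records whether rows are guides or genes; ``scale_tag``
    tracks provenance (``raw`` LFC, ``corrected`` output of a bias
    correction, ``scaled`` after essential/non-essential calibration).
    ``name`` optionally labels the correction method that produced it.
    """

    values: pd.DataFrame
    level: str = "gene"
    scale_tag: str = "raw"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.level not in {"guide", "gene"}:
            raise ValueError(f"level must be 'guide' or 'gene', got {self.level!r}")
        if self.scale_tag not in {"raw", "corrected", "scaled"}:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        _check_unique(self.values.index, self.level)
        _check_unique(self.values.columns, "model")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def models(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame, **overrides) -> "ScreenMatrix":
        kwargs = dict(level=self.level, scale_tag=self.scale_tag, name=self.name)
        kwargs.update(overrides)
        return ScreenMatrix(values, **kwargs)


@dataclass
class GenomeAnnotation:
    """Gene coordinates plus per-chromosome centromere positions.

    ``genes`` is indexed by gene symbol with columns ``chromosome`` and
    ``start`` (1-based bp). Arm membership is derived from the gene start:
    start < centromere means the p arm, otherwise q.
    """

    genes: pd.DataFrame
    centromeres: pd.Series

    def __post_init__(self) -> None:
        required = {"chromosome", "start"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        _check_unique(self.genes.index, "gene")

    def assign_arms(self, genes) -> tuple[pd.DataFrame, list[str]]:
        """Assign each gene to a (chromosome, arm) or report it unmapped.

        Returns a frame indexed by the mapped genes with columns
        ``chromosome`` and ``arm`` ('p'/'q'), and the list of unmapped genes
        (no coordinates, or chromosome absent from the centromere table).
        """
        genes = pd.Index(genes)
        known = genes.intersection(self.genes.index)
        sub = self.genes.loc[known]
        on_known_chrom = sub["chromosome"].isin(self.centromeres.index)
        mapped = sub[on_known_chrom].copy()
        unmapped = genes.difference(mapped.index).tolist()
        if unmapped:
            warnings.warn(
                f"{len(unmapped)} gene(s) without arm assignment; "
                "they are excluded from arm-level operations",
                stacklevel=2,
            )
        cent = self.centromeres.loc[mapped["chromosome"]].to_numpy()
        mapped["arm"] = np.where(mapped["start"].to_numpy() < cent, "p", "q")
        return mapped[["chromosome", "arm"]], unmapped

    def genome_order(self, genes) -> pd.Index:
        """Order genes along the genome: by chromosome, then start position."""
        genes = pd.Index(genes).intersection(self.genes.index)
        sub = self.genes.loc[genes]
        key = sub["chromosome"].map(_chromosome_sort_key)
        order = np.lexsort((sub["start"].to_numpy(), key.to_numpy()))
        return sub.index[order]


def _chromosome_sort_key(chrom: str) -> int:
    c = str(chrom).removeprefix("chr")
    if c.isdigit():
        return int(c)
    return {"X": 23, "Y": 24, "MT": 25, "M": 25}.get(c, 26)


@dataclass
class OmicsProfiles:
    """Per-model absolute copy number (integer) and expression (linear TPM)."""

    cn: pd.DataFrame
    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.cn.index, "gene")
        _check_unique(self.tpm.index, "gene")
        if (self.cn.to_numpy() < 0).any():
            raise ValueError("copy number values must be nonnegative")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be nonnegative")

    def unexpressed(self, model: str, tpm_threshold: float = 1.0) -> pd.Index:
        """Genes with TPM strictly below the threshold in ``model``."""
        col = self.tpm[model]
        return col.index[col < tpm_threshold]


@dataclass
class GeneSets:
    """Labelled control gene sets driving the quality metrics."""

    essential: frozenset
    nonessential: frozenset
    msigdb_sets: dict[str, frozenset] = field(default_factory=dict)
    oncogenes: frozenset = frozenset()
    ssd_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.essential = frozenset(self.essential)
        self.nonessential = frozenset(self.nonessential)
        self.oncogenes = frozenset(self.oncogenes)
        self.ssd_genes = frozenset(self.ssd_genes)
        self.msigdb_sets = {k: frozenset(v) for k, v in self.msigdb_sets.items()}
        overlap = self.essential & self.nonessential
        if overlap:
            raise ValueError(
                f"essential and non-essential sets overlap: {sorted(overlap)[:10]}"
            )


@dataclass
class CFECatalog:
    """Binary cancer functional events per model, with tissue and TP53 status.

    ``events`` is CFE x model in {0, 1}; ``tissue`` maps model -> tissue
    label; ``tp53_status`` maps model -> 'wild_type' | 'mutant'.
    """

    events: pd.DataFrame
    tissue: pd.Series
    tp53_status: pd.Series

    def __post_init__(self) -> None:
        vals = self.events.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("CFE events must be binary")
        missing = set(self.events.columns) - set(self.tissue.index)
        if missing:
            raise ValueError(f"models without tissue label: {sorted(missing)[:10]}")
        bad = set(self.tp53_status.unique()) - {"wild_type", "mutant"}
        if bad:
            raise ValueError(f"invalid TP53 status values: {sorted(bad)}")

    def models_by_tp53(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {"wild_type": [], "mutant": []}
        for model in self.events.columns:
            status = self.tp53_status.get(model)
            if status in out:
                out[status].append(model)
        return out


@dataclass
class ScreenBundle:
    """Everything one screen dataset needs for the full evaluation suite."""

    screen: ScreenMatrix
    guidemap: GuideMap | None
    omics: OmicsProfiles
    annotation: GenomeAnnotation
    gene_sets: GeneSets
    cfe: CFECatalog | None = None
    counts: CountMatrix | None = None
    mutation_calls: pd.DataFrame | None = None
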