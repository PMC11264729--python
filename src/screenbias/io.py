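"""Readers and writers for the DepMap-style CSV dialect.

Matrix files have the gene (or guide) identifier in the first column and one
column per model/sample. Gene headers in the ``"SYMBOL (ENTREZ)"`` dialect
are normalized to bare symbols on load. Gene sets are one symbol per line.
"""

from __future__ import annotations

import json
import re
from importlib import resources
from pathlib import Path

import pandas as pd

from .datamodel import (
    CFECatalog,
    CountMatrix,
    FormatError,
    GenomeAnnotation,
    GeneSets,
    GuideMap,
    OmicsProfiles,
    ScreenMatrix,
)

__all__ = [
    "normalize_gene_id",
    "read_matrix",
    "write_matrix",
    "read_screen_matrix",
    "write_screen_matrix",
    "read_guide_map",
    "write_guide_map",
    "read_annotation",
    "load_centromeres",
    "read_gene_set",
    "write_gene_set",
    "read_cfe_catalog",
    "write_cfe_catalog",
    "read_counts",
    "write_counts",
    "load_screen_bundle",
    "intersect_bundle_axes",
]

_ENTREZ_SUFFIX = re.compile(r"\s*\(\d+\)\s*$")


def normalize_gene_id(gene: str) -> str:
    """Strip a DepMap-style Entrez suffix: ``"A1BG (1)"`` -> ``"A1BG"``."""
    return _ENTREZ_SUFFIX.sub("", str(gene).strip())


def read_matrix(path, normalize_genes: bool = True) -> pd.DataFrame:
    """Read an id-keyed numeric CSV matrix (first column = row identifier)."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.index.isna().any():
        raise FormatError(path, "missing row identifiers")
    if normalize_genes:
        df.index = pd.Index([normalize_gene_id(g) for g in df.index], name=df.index.name)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:10]
        raise FormatError(path, f"duplicate row identifiers: {dupes}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label=df.index.name or "gene")


def read_screen_matrix(path, level: str = "gene", scale_tag: str = "raw",
                       name: str | None = None) -> ScreenMatrix:
    return ScreenMatrix(read_matrix(path, normalize_genes=level == "gene"),
                        level=level, scale_tag=scale_tag, name=name)


def write_screen_matrix(sm: ScreenMatrix, path) -> None:
    write_matrix(sm.values, path)


def read_guide_map(path) -> GuideMap:
    df = pd.read_csv(path)
    required = ["guide_id", "gene", "chromosome", "position", "qc_flags"]
    for col in required:
        if col not in df.columns:
            raise FormatError(path, f"guide map missing column {col!r}")
    df["gene"] = df["gene"].map(normalize_gene_id)
    df["chromosome"] = df["chromosome"].astype(str)
    df["qc_flags"] = [
        frozenset(str(f).split(";")) - {"", "nan"} if pd.notna(f) else frozenset()
        for f in df["qc_flags"]
    ]
    return GuideMap(df.set_index("guide_id"))


def write_guide_map(gm: GuideMap, path) -> None:
    df = gm.table.copy()
    df["qc_flags"] = [";".join(sorted(f)) for f in df["qc_flags"]]
    df.to_csv(path, index_label="guide_id")


def load_centromeres(path=None) -> pd.Series:
    """Load a centromere table (chromosome -> bp).

    Without ``path``, a packaged table of approximate GRCh38 centromere
    midpoints is used; pass a two-column CSV (``chromosome,centromere_bp``)
    to override with coordinates matching the annotation's genome build.
    """
    if path is None:
        ref = resources.files("screenbias.data") / "centromeres_grch38.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    for col in ("chromosome", "centromere_bp"):
        if col not in df.columns:
            raise FormatError(path or "packaged centromere table",
                              f"missing column {col!r}")
    s = df.set_index(df["chromosome"].astype(str))["centromere_bp"]
    s.index.name = "chromosome"
    return s


def read_annotation(path, centromeres_path=None) -> GenomeAnnotation:
    """Read gene coordinates (columns gene, chromosome, start) + centromeres."""
    df = pd.read_csv(path)
    for col in ("gene", "chromosome", "start"):
        if col not in df.columns:
            raise FormatError(path, f"annotation missing column {col!r}")
    df["gene"] = df["gene"].map(normalize_gene_id)
    df["chromosome"] = df["chromosome"].astype(str)
    genes = df.set_index("gene")[["chromosome", "start"]]
    if genes.index.has_duplicates:
        raise FormatError(path, "duplicate gene identifiers in annotation")
    return GenomeAnnotation(genes, load_centromeres(centromeres_path))


def write_annotation(annotation: GenomeAnnotation, path, centromeres_path=None) -> None:
    annotation.genes.to_csv(path, index_label="gene")
    if centromeres_path is not None:
        annotation.centromeres.to_csv(centromeres_path, index_label="chromosome")


def read_gene_set(path) -> frozenset:
    lines = Path(path).read_text().splitlines()
    return frozenset(normalize_gene_id(x) for x in lines if x.strip())


def write_gene_set(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_cfe_catalog(events_path, models_path) -> CFECatalog:
    """Read a binary CFE x model matrix and a model metadata table.

    ``models_path`` must have columns model, tissue, tp53_status.
    """
    events = pd.read_csv(events_path, index_col=0)
    meta = pd.read_csv(models_path)
    for col in ("model", "tissue", "tp53_status"):
        if col not in meta.columns:
            raise FormatError(models_path, f"missing column {col!r}")
    meta = meta.set_index("model")
    return CFECatalog(events, meta["tissue"], meta["tp53_status"])


def write_cfe_catalog(cfe: CFECatalog, events_path, models_path) -> None:
    cfe.events.to_csv(events_path, index_label="cfe")
    meta = pd.DataFrame({"tissue": cfe.tissue, "tp53_status": cfe.tp53_status})
    meta.to_csv(models_path, index_label="model")


def read_counts(counts_path, samples_path=None) -> CountMatrix:
    """Read raw guide counts plus the sample role/model sidecar table.

    ``samples_path`` defaults to ``<counts stem>_samples.csv`` next to the
    counts file; it must carry columns sample, role, model (model may be
    empty for plasmid samples).
    """
    if samples_path is None:
        p = Path(counts_path)
        samples_path = p.with_name(p.stem + "_samples.csv")
    values = pd.read_csv(counts_path, index_col=0)
    meta = pd.read_csv(samples_path)
    for col in ("sample", "role"):
        if col not in meta.columns:
            raise FormatError(samples_path, f"missing column {col!r}")
    roles = dict(zip(meta["sample"], meta["role"]))
    rep_to_model = {
        s: m
        for s, m, r in zip(meta["sample"], meta.get("model", ""), meta["role"])
        if r == "replicate" and pd.notna(m)
    }
    return CountMatrix(values, roles, rep_to_model)


def write_counts(counts: CountMatrix, counts_path, samples_path=None) -> None:
    if samples_path is None:
        p = Path(counts_path)
        samples_path = p.with_name(p.stem + "_samples.csv")
    counts.values.to_csv(counts_path, index_label="guide_id")
    rows = [
        {
            "sample": s,
            "role": counts.sample_roles[s],
            "model": counts.replicate_to_model.get(s, ""),
        }
        for s in counts.values.columns
    ]
    pd.DataFrame(rows).to_csv(samples_path, index=False)


def intersect_bundle_axes(
    counts: CountMatrix,
    guidemap: GuideMap,
    omics: OmicsProfiles,
) -> tuple[CountMatrix, GuideMap, OmicsProfiles]:
    """Restrict all inputs to models and genes present in CRISPR, CN and TPM.

    Mirrors cohort construction in dependency-map analyses: a model enters
    the benchmark only with screen, copy-number and expression data; a gene
    only if screened (via its guides) and profiled in both omics layers.
    """
    models = [
        m
        for m in counts.models
        if m in omics.cn.columns and m in omics.tpm.columns
    ]
    genes = (
        pd.Index(guidemap.table["gene"].unique())
        .intersection(omics.cn.index)
        .intersection(omics.tpm.index)
    )
    gm = GuideMap(guidemap.table[guidemap.table["gene"].isin(genes)])
    keep_samples = [
        s
        for s in counts.values.columns
        if counts.sample_roles[s] == "plasmid"
        or counts.replicate_to_model.get(s) in set(models)
    ]
    cm = CountMatrix(
        counts.values.loc[counts.values.index.intersection(gm.guides), keep_samples],
        {s: counts.sample_roles[s] for s in keep_samples},
        {s: m for s, m in counts.replicate_to_model.items() if s in keep_samples},
    )
    om = OmicsProfiles(
        omics.cn.loc[genes, models].copy(), omics.tpm.loc[genes, models].copy()
    )
    return cm, gm, om


def load_screen_bundle(
    counts_path,
    guidemap_path,
    cn_path,
    tpm_path,
    annotation_path,
    samples_path=None,
    centromeres_path=None,
) -> tuple[CountMatrix, GuideMap, OmicsProfiles, GenomeAnnotation]:
    """Load and axis-align a full screen bundle from CSV files.

    Models and genes are restricted to those present in all of the CRISPR
    counts, copy-number and expression inputs; gene identifiers are
    normalized to bare symbols.
    """
    counts = read_counts(counts_path, samples_path)
    guidemap = read_guide_map(guidemap_path)
    omics = OmicsProfiles(read_matrix(cn_path), read_matrix(tpm_path))
    annotation = read_annotation(annotation_path, centromeres_path)
    counts, guidemap, omics = intersect_bundle_axes(counts, guidemap, omics)
    return counts, guidemap, omics, annotation


def write_json_summary(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")


# --- bundle directory layout -------------------------------------------------
# screen.csv, guidemap.csv, cn.csv, tpm.csv, annotation.csv, centromeres.csv,
# gene set text files, cfe_events.csv + cfe_models.csv, mutation_calls.csv and
# optionally counts.csv + counts_samples.csv.


def write_bundle(bundle, outdir) -> None:
    """Serialize a :class:`~screenbias.datamodel.ScreenBundle` to a directory."""
    from .datamodel import ScreenBundle  # local import avoids cycle at module load

    assert isinstance(bundle, ScreenBundle)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_screen_matrix(bundle.screen, out / "screen.csv")
    if bundle.guidemap is not None:
        write_guide_map(bundle.guidemap, out / "guidemap.csv")
    write_matrix(bundle.omics.cn, out / "cn.csv")
    write_matrix(bundle.omics.tpm, out / "tpm.csv")
    write_annotation(bundle.annotation, out / "annotation.csv", out / "centromeres.csv")
    gs = bundle.gene_sets
    write_gene_set(gs.essential, out / "essential.txt")
    write_gene_set(gs.nonessential, out / "nonessential.txt")
    if gs.oncogenes:
        write_gene_set(gs.oncogenes, out / "oncogenes.txt")
    if gs.ssd_genes:
        write_gene_set(gs.ssd_genes, out / "ssd_genes.txt")
    for name, genes in gs.msigdb_sets.items():
        write_gene_set(genes, out / f"set_{name}.txt")
    if bundle.cfe is not None:
        write_cfe_catalog(bundle.cfe, out / "cfe_events.csv", out / "cfe_models.csv")
    if bundle.mutation_calls is not None:
        write_matrix(bundle.mutation_calls, out / "mutation_calls.csv")
    if bundle.counts is not None:
        write_counts(bundle.counts, out / "counts.csv", out / "counts_samples.csv")


def read_bundle(indir):
    """Load a bundle directory written by :func:`write_bundle`."""
    from .datamodel import ScreenBundle

    d = Path(indir)
    screen = read_screen_matrix(d / "screen.csv")
    guidemap = read_guide_map(d / "guidemap.csv") if (d / "guidemap.csv").exists() else None
    omics = OmicsProfiles(read_matrix(d / "cn.csv"), read_matrix(d / "tpm.csv"))
    annotation = read_annotation(d / "annotation.csv", d / "centromeres.csv")
    msigdb = {
        p.stem.removeprefix("set_"): read_gene_set(p) for p in sorted(d.glob("set_*.txt"))
    }
    gene_sets = GeneSets(
        essential=read_gene_set(d / "essential.txt"),
        nonessential=read_gene_set(d / "nonessential.txt"),
        msigdb_sets=msigdb,
        oncogenes=read_gene_set(d / "oncogenes.txt") if (d / "oncogenes.txt").exists() else frozenset(),
        ssd_genes=read_gene_set(d / "ssd_genes.txt") if (d / "ssd_genes.txt").exists() else frozenset(),
    )
    cfe = None
    if (d / "cfe_events.csv").exists():
        cfe = read_cfe_catalog(d / "cfe_events.csv", d / "cfe_models.csv")
    mutation_calls = (
        read_matrix(d / "mutation_calls.csv") if (d / "mutation_calls.csv").exists() else None
    )
    counts = (
        read_counts(d / "counts.csv", d / "counts_samples.csv")
        if (d / "counts.csv").exists()
        else None
    )
    return ScreenBundle(
        screen=screen,
        guidemap=guidemap,
        omics=omics,
        annotation=annotation,
        gene_sets=gene_sets,
        cfe=cfe,
        counts=counts,
        mutation_calls=mutation_calls,
    )
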