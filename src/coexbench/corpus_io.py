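"""Reading, converting, and quality-filtering RNA-seq count corpora.

A *corpus* is a named collection of datasets, each a non-negative
gene-by-sample count matrix with optional per-sample metadata (average
read length, paired-end status) and a tissue label.  Counts matrices are
plain :class:`pandas.DataFrame` objects with gene IDs as the row index
and sample IDs as columns; this module validates their invariants and
implements the preprocessing filters applied before network
construction:

* conversion of base-pair-per-gene counts to read counts,
* summation of transcript-level counts to gene-level counts,
* removal of low-coverage samples (too many zero-count genes),
* removal of datasets that drop below a minimum sample count,
* corpus-wide removal of genes never expressed above a CPM floor,
* restriction to long-RNA biotypes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "Corpus",
    "validate_counts",
    "bp_counts_to_gene_counts",
    "sum_transcripts_to_genes",
    "filter_low_coverage_samples",
    "filter_min_samples",
    "filter_low_expression_genes",
    "filter_gene_types",
    "preprocess_corpus",
    "strip_gene_versions",
    "read_counts",
    "write_counts",
    "read_sample_meta",
    "read_gene_lengths",
    "read_gene_types",
    "read_tx2gene",
    "load_corpus",
    "save_corpus",
]

#: Long-RNA biotypes retained by default for coexpression analysis.
DEFAULT_KEEP_BIOTYPES = frozenset({"protein_coding", "lncRNA", "antisense"})


def validate_counts(counts: pd.DataFrame, *, name: str = "counts") -> pd.DataFrame:
    """Check counts-matrix invariants: unique IDs, no negative entries."""
    if not counts.index.is_unique:
        dups = counts.index[counts.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{name}: duplicate gene IDs, e.g. {dups}")
    if not counts.columns.is_unique:
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{name}: duplicate sample IDs, e.g. {dups}")
    values = counts.to_numpy()
    if values.size and np.nanmin(values) < 0:
        raise ValueError(f"{name}: negative entries are not valid counts")
    return counts


@dataclass
class Dataset:
    """One expression dataset: a counts matrix plus sample metadata."""

    dataset_id: str
    counts: pd.DataFrame
    tissue: str = "unknown"
    #: per-sample metadata indexed by sample ID with columns
    #: ``avg_read_length`` (bases) and ``paired_end`` (bool); optional.
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        validate_counts(self.counts, name=self.dataset_id)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


@dataclass
class Corpus:
    """A collection of datasets sharing (after filtering) one gene universe."""

    datasets: dict[str, Dataset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, ds in self.datasets.items():
            if key != ds.dataset_id:
                raise ValueError(f"corpus key {key!r} != dataset ID {ds.dataset_id!r}")

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets.values())

    def subset_genes(self, genes: Iterable[str]) -> "Corpus":
        """Restrict every dataset to ``genes`` (order preserved per dataset)."""
        genes = set(genes)
        out = {}
        for ds in self:
            keep = ds.counts.index[ds.counts.index.isin(genes)]
            out[ds.dataset_id] = replace(ds, counts=ds.counts.loc[keep])
        return Corpus(out)


# ---------------------------------------------------------------------------
# Count conversion
# ---------------------------------------------------------------------------

def bp_counts_to_gene_counts(
    bp_counts: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Convert base-pair-per-gene counts to read counts.

    Each sample's column is divided by that sample's average read length;
    paired-end samples are further divided by two, since two mates of one
    fragment contribute base pairs.  Fractional counts are kept as reals.

    Parameters
    ----------
    bp_counts
        Base pairs mapped per gene (rows) and sample (columns).
    meta
        Per-sample table indexed by sample ID with columns
        ``avg_read_length`` (> 0) and ``paired_end`` (bool).
    """
    validate_counts(bp_counts, name="bp_counts")
    missing = [s for s in bp_counts.columns if s not in meta.index]
    if missing:
        raise KeyError(f"no sample metadata for: {missing}")
    rl = meta.loc[bp_counts.columns, "avg_read_length"].astype(float)
    if (rl <= 0).any():
        bad = rl.index[rl <= 0].tolist()
        raise ValueError(f"non-positive average read length for samples: {bad}")
    paired = meta.loc[bp_counts.columns, "paired_end"].astype(bool)
    divisor = rl * np.where(paired, 2.0, 1.0)
    return bp_counts.div(divisor, axis=1)


def sum_transcripts_to_genes(
    transcript_counts: pd.DataFrame, tx2gene: Mapping[str, str]
) -> pd.DataFrame:
    """Aggregate transcript-level counts to gene-level counts by summation.

    Transcripts missing from ``tx2gene`` are dropped (a warning reports how
    many).  Gene order follows first appearance among mapped transcripts.
    """
    if not tx2gene:
        raise ValueError("empty transcript-to-gene mapping")
    validate_counts(transcript_counts, name="transcript_counts")
    mapped = transcript_counts.index.isin(tx2gene.keys())
    n_dropped = int((~mapped).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} transcripts without a gene mapping were dropped",
            stacklevel=2,
        )
    sub = transcript_counts.loc[mapped]
    genes = pd.Index([tx2gene[t] for t in sub.index], name="gene")
    out = sub.groupby(genes, sort=False).sum()
    return out


def strip_gene_versions(counts: pd.DataFrame) -> pd.DataFrame:
    """Strip Ensembl-style version suffixes (``ENSG...123.4`` -> ``ENSG...123``).

    Logs how many IDs were rewritten.  Raises if stripping creates duplicates.
    """
    stripped = counts.index.str.replace(r"\.\d+$", "", regex=True)
    n_changed = int((stripped != counts.index).sum())
    if n_changed:
        logger.info("stripped version suffix from %d gene IDs", n_changed)
    out = counts.copy()
    out.index = stripped
    return validate_counts(out, name="counts (version-stripped)")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_low_coverage_samples(
    counts: pd.DataFrame, zero_fraction_threshold: float = 0.5
) -> pd.DataFrame:
    """Drop samples with zero counts in at least ``zero_fraction_threshold``
    of genes (inclusive bound: "at least half" removes a sample at exactly
    one half)."""
    if not 0 < zero_fraction_threshold <= 1:
        raise ValueError("zero_fraction_threshold must be in (0, 1]")
    validate_counts(counts)
    zero_frac = (counts == 0).mean(axis=0)
    keep = zero_frac < zero_fraction_threshold
    if not keep.any():
        warnings.warn("all samples removed by the low-coverage filter", stacklevel=2)
    return counts.loc[:, keep]


def filter_min_samples(corpus: Corpus, min_samples: int = 5) -> Corpus:
    """Drop datasets with fewer than ``min_samples`` samples (inclusive keep)."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    kept = {k: ds for k, ds in corpus.datasets.items() if ds.n_samples >= min_samples}
    return Corpus(kept)


def filter_low_expression_genes(
    corpus: Corpus, cpm_threshold: float = 1.0, sample_fraction: float = 0.2
) -> list[str]:
    """Return genes expressed at >= ``cpm_threshold`` CPM in at least
    ``sample_fraction`` of samples of at least one dataset.

    The rule is corpus-wide: passing in a single dataset keeps the gene in
    every dataset.  Both thresholds are inclusive.  The returned list keeps
    the gene order of the first dataset in which each gene appears.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    keep: set[str] = set()
    order: list[str] = []
    seen: set[str] = set()
    for ds in corpus:
        for g in ds.counts.index:
            if g not in seen:
                seen.add(g)
                order.append(g)
        lib = ds.counts.sum(axis=0)
        if (lib <= 0).any():
            bad = lib.index[lib <= 0].tolist()
            raise ValueError(
                f"dataset {ds.dataset_id}: zero library size for samples {bad}"
            )
        cpm = ds.counts.div(lib, axis=1) * 1e6
        frac = (cpm >= cpm_threshold).mean(axis=1)
        keep.update(frac.index[frac >= sample_fraction])
    if not keep:
        warnings.warn("no genes pass the low-expression filter", stacklevel=2)
    return [g for g in order if g in keep]


def filter_gene_types(
    counts: pd.DataFrame,
    types: Mapping[str, str],
    keep: frozenset[str] | set[str] = DEFAULT_KEEP_BIOTYPES,
) -> pd.DataFrame:
    """Keep only genes whose biotype is in ``keep``.

    Genes absent from the biotype table are dropped (conservative) with a
    warning reporting the count.
    """
    if not keep:
        raise ValueError("keep must be a non-empty set of biotypes")
    validate_counts(counts)
    known = counts.index.to_series().map(lambda g: types.get(g))
    n_unknown = int(known.isna().sum())
    if n_unknown:
        warnings.warn(
            f"{n_unknown} genes missing from the biotype table were dropped",
            stacklevel=2,
        )
    mask = known.isin(keep).to_numpy()
    return counts.loc[mask]


def preprocess_corpus(
    corpus: Corpus,
    *,
    gene_types: Mapping[str, str] | None = None,
    keep_biotypes: frozenset[str] | set[str] = DEFAULT_KEEP_BIOTYPES,
    zero_fraction_threshold: float = 0.5,
    min_samples: int = 5,
    cpm_threshold: float = 1.0,
    sample_fraction: float = 0.2,
    strict_sample_qc: bool = False,
) -> Corpus:
    """Run the full preprocessing chain in order: biotype filter (optional),
    low-coverage sample filter, dataset-size filter, corpus-wide gene filter.

    With ``strict_sample_qc=True`` a dataset is discarded outright if *any*
    of its samples fails the coverage filter; the default keeps the dataset
    (minus failing samples) as long as it still has ``min_samples`` samples.
    """
    stage1: dict[str, Dataset] = {}
    for ds in corpus:
        counts = ds.counts
        if gene_types is not None:
            counts = filter_gene_types(counts, gene_types, keep_biotypes)
        filtered = filter_low_coverage_samples(counts, zero_fraction_threshold)
        if strict_sample_qc and filtered.shape[1] != counts.shape[1]:
            logger.info("dropping dataset %s: failed strict sample QC", ds.dataset_id)
            continue
        if filtered.shape[1] == 0:
            continue
        stage1[ds.dataset_id] = replace(ds, counts=filtered)
    out = filter_min_samples(Corpus(stage1), min_samples)
    if len(out) == 0:
        warnings.warn("no datasets survive preprocessing", stacklevel=2)
        return out
    genes = filter_low_expression_genes(out, cpm_threshold, sample_fraction)
    return out.subset_genes(genes)


# ---------------------------------------------------------------------------
# File I/O — tab-delimited text formats
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited counts matrix (first column gene IDs, header row
    sample IDs; transparently gunzipped by extension)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_counts(df, name=str(path))


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read sample metadata: columns sample_id, avg_read_length, paired_end."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    df = df.set_index("sample_id")
    df["avg_read_length"] = df["avg_read_length"].astype(float)
    df["paired_end"] = (
        df["paired_end"].astype(str).str.lower().map({"true": True, "false": False})
    )
    if df["paired_end"].isna().any():
        raise ValueError(f"{path}: paired_end must be true/false")
    return df


def _read_two_column(path: str | Path, value_name: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name=value_name)
    return s[~s.index.duplicated()]


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a gene -> length (bases) table; lengths must be >= 1."""
    s = _read_two_column(path, "length").astype(int)
    if (s < 1).any():
        raise ValueError(f"{path}: gene lengths must be >= 1")
    return s


def read_gene_types(path: str | Path) -> dict[str, str]:
    return _read_two_column(path, "biotype").to_dict()


def read_tx2gene(path: str | Path) -> dict[str, str]:
    return _read_two_column(path, "gene").to_dict()


def load_corpus(manifest_path: str | Path) -> Corpus:
    """Load a corpus from a YAML/JSON manifest.

    The manifest lists datasets as ``{id, tissue, counts, meta?}`` with file
    paths relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    manifest = (
        json.loads(text) if manifest_path.suffix == ".json" else yaml.safe_load(text)
    )
    base = manifest_path.parent
    datasets = {}
    for entry in manifest["datasets"]:
        meta = None
        if entry.get("meta"):
            meta = read_sample_meta(base / entry["meta"])
        ds = Dataset(
            dataset_id=str(entry["id"]),
            counts=read_counts(base / entry["counts"]),
            tissue=str(entry.get("tissue", "unknown")),
            meta=meta,
        )
        datasets[ds.dataset_id] = ds
    return Corpus(datasets)


def save_corpus(corpus: Corpus, directory: str | Path) -> Path:
    """Write a corpus as one counts TSV per dataset plus a YAML manifest.

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for ds in corpus:
        counts_file = f"{ds.dataset_id}.counts.tsv"
        write_counts(ds.counts, directory / counts_file)
        entry = {"id": ds.dataset_id, "tissue": ds.tissue, "counts": counts_file}
        if ds.meta is not None:
            meta_file = f"{ds.dataset_id}.meta.tsv"
            ds.meta.to_csv(directory / meta_file, sep="\t", index_label="sample_id")
            entry["meta"] = meta_file
        entries.append(entry)
    manifest = directory / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"datasets": entries}, sort_keys=False))
    return manifest
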