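"""Functional gold standards from Gene Ontology annotations.

A gold standard is a disjoint pair of gene-pair sets: *positives* are gene
pairs co-annotated to at least one "specific" GO Biological Process term
under experimental or curator evidence; *negatives* are the remaining
pairs among positive-bearing genes, after screening out (a) pairs whose
genes sit in two different specific terms with significantly overlapping
gene sets (hypergeometric upper tail, raw p < 0.05) and (b) pairs
co-annotated to a curated "general" term — both screens remove pairs whose
functional relatedness is ambiguous rather than absent.  The *prior* is
the fraction of positives among labeled pairs, which is also the auPRC of
a random ranking.

Tissue-aware standards restrict a naive standard by tissue expression:
positives survive only if both genes are expressed in the tissue;
negatives survive if both genes are in the tissue, or one is in the tissue
and the other is expressed in some other considered tissue.

Annotations based on expression evidence (IEP) are always discarded to
avoid circularity when scoring coexpression networks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "EXPERIMENTAL_EVIDENCE",
    "AnnotationSet",
    "GoldStandard",
    "gene_pair",
    "load_gaf",
    "hypergeom_overlap_p",
    "build_naive_standard",
    "build_tissue_standard",
    "read_term_list",
    "read_tissue_gene_sets",
    "read_standard",
    "write_standard",
]

#: Experimental + curated GO evidence codes accepted by default.
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "TAS", "IC"})

Pair = tuple[str, str]


def gene_pair(a: str, b: str) -> Pair:
    """Canonical unordered gene pair (sorted tuple); self-pairs are invalid."""
    if a == b:
        raise ValueError(f"self-pair for gene {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class AnnotationSet:
    """Gene-term annotations plus the term -> gene-set index."""

    records: list[tuple[str, str, str]]  # (gene, term, evidence)
    term_to_genes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.term_to_genes:
            for gene, term, _ in self.records:
                self.term_to_genes.setdefault(term, set()).add(gene)

    @property
    def genes(self) -> set[str]:
        return {g for g, _, _ in self.records}


@dataclass(frozen=True)
class GoldStandard:
    """Disjoint positive/negative unordered gene-pair sets."""

    positives: frozenset[Pair]
    negatives: frozenset[Pair]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")
        for a, b in list(self.positives)[:1] + list(self.negatives)[:1]:
            if a == b:
                raise ValueError("self-pairs are not allowed")

    @property
    def prior(self) -> float:
        total = len(self.positives) + len(self.negatives)
        if total == 0:
            raise ValueError("empty gold standard has no prior")
        return len(self.positives) / total

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.positives | self.negatives:
            out.add(a)
            out.add(b)
        return out


# ---------------------------------------------------------------------------
# GAF parsing
# ---------------------------------------------------------------------------

def load_gaf(
    path: str | Path,
    allowed_evidence: frozenset[str] | set[str] = EXPERIMENTAL_EVIDENCE,
    excluded_evidence: frozenset[str] | set[str] = frozenset({"IEP"}),
    aspect: str = "P",
) -> AnnotationSet:
    """Parse a GAF 2.x file into an annotation set.

    Keeps only annotations of the requested aspect (default Biological
    Process) whose evidence code is in ``allowed_evidence`` and not in
    ``excluded_evidence``; drops NOT-qualified annotations.  Malformed
    lines are skipped with a logged line number; more than 10% malformed
    data lines is a hard error.
    """
    records: list[tuple[str, str, str]] = []
    n_data = n_malformed = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            n_data += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 15 or not fields[1] or not fields[4]:
                n_malformed += 1
                logger.warning("skipping malformed GAF line %d", lineno)
                continue
            qualifier, go_id, evidence, gaf_aspect = (
                fields[3], fields[4], fields[6], fields[8],
            )
            if "NOT" in qualifier.split("|"):
                continue
            if gaf_aspect != aspect:
                continue
            if evidence in excluded_evidence or evidence not in allowed_evidence:
                continue
            records.append((fields[1], go_id, evidence))
    if n_data and n_malformed / n_data > 0.10:
        raise ValueError(
            f"{path}: {n_malformed}/{n_data} malformed GAF lines (> 10%)"
        )
    return AnnotationSet(records)


# ---------------------------------------------------------------------------
# Standard construction
# ---------------------------------------------------------------------------

def hypergeom_overlap_p(
    n_overlap: int, size_a: int, size_b: int, universe: int
) -> float:
    """Upper-tail P(X >= n_overlap) for the overlap of two gene sets drawn
    from a universe of ``universe`` genes."""
    if not (0 <= n_overlap <= min(size_a, size_b) <= universe):
        raise ValueError(
            f"inconsistent counts: overlap={n_overlap}, sizes=({size_a}, {size_b}), "
            f"universe={universe}"
        )
    return float(hypergeom.sf(n_overlap - 1, universe, size_a, size_b))


def build_naive_standard(
    ann: AnnotationSet,
    specific_terms: Iterable[str],
    general_terms: Iterable[str] = (),
    overlap_alpha: float = 0.05,
) -> GoldStandard:
    """Tissue-naive gold standard from co-annotation to specific terms.

    Positives: all unordered pairs co-annotated to at least one specific
    term.  Candidate negatives: remaining pairs among genes that carry at
    least one positive edge.  Candidates are left unlabeled (excluded from
    negatives) when the two genes are annotated to two different specific
    terms whose gene sets overlap significantly (raw hypergeometric
    p < ``overlap_alpha``; universe = all annotated genes), or when the
    pair is co-annotated to any general term.
    """
    specific_terms = set(specific_terms)
    general_terms = set(general_terms)
    if specific_terms & general_terms:
        raise ValueError("specific and general term lists must be disjoint")

    spec_genes = {
        t: set(ann.term_to_genes.get(t, ())) for t in sorted(specific_terms)
    }
    positives: set[Pair] = set()
    for genes in spec_genes.values():
        for a, b in combinations(sorted(genes), 2):
            positives.add(gene_pair(a, b))
    if not positives:
        raise ValueError("no positive pairs: no specific term has >= 2 genes")

    universe = len(ann.genes)
    # which pairs of distinct specific terms have significantly similar gene sets
    similar: set[frozenset[str]] = set()
    terms = sorted(t for t, g in spec_genes.items() if g)
    for t1, t2 in combinations(terms, 2):
        g1, g2 = spec_genes[t1], spec_genes[t2]
        p = hypergeom_overlap_p(len(g1 & g2), len(g1), len(g2), universe)
        if p < overlap_alpha:
            similar.add(frozenset((t1, t2)))

    gene_to_spec: dict[str, set[str]] = {}
    for t, genes in spec_genes.items():
        for g in genes:
            gene_to_spec.setdefault(g, set()).add(t)

    gen_genes = {t: set(ann.term_to_genes.get(t, ())) for t in general_terms}

    pos_genes = sorted({g for p in positives for g in p})
    negatives: set[Pair] = set()
    for a, b in combinations(pos_genes, 2):
        pair = gene_pair(a, b)
        if pair in positives:
            continue
        if any(
            t1 != t2 and frozenset((t1, t2)) in similar
            for t1 in gene_to_spec.get(a, ())
            for t2 in gene_to_spec.get(b, ())
        ):
            continue
        if any(a in genes and b in genes for genes in gen_genes.values()):
            continue
        negatives.add(pair)
    if not negatives:
        raise ValueError("no negative pairs survive the exclusion screens")
    return GoldStandard(frozenset(positives), frozenset(negatives))


def build_tissue_standard(
    naive: GoldStandard,
    tissues: Mapping[str, set[str]],
    tissue: str,
    min_positives: int = 50,
) -> GoldStandard | None:
    """Restrict a naive standard to one tissue's expressed genes.

    Positives are kept iff both genes are expressed in the tissue.
    Negatives are kept iff both genes are in the tissue, or one gene is in
    the tissue and the other is expressed in some *other* considered
    tissue.  Returns ``None`` (rejection, not an error) if fewer than
    ``min_positives`` positives survive.
    """
    if tissue not in tissues:
        raise KeyError(f"tissue {tissue!r} not in the tissue gene-set table")
    in_tissue = set(tissues[tissue])
    other = set()
    for name, genes in tissues.items():
        if name != tissue:
            other |= set(genes)

    positives = frozenset(
        p for p in naive.positives if p[0] in in_tissue and p[1] in in_tissue
    )
    if len(positives) < min_positives:
        warnings.warn(
            f"tissue {tissue!r}: only {len(positives)} positives "
            f"(minimum {min_positives}); standard rejected",
            stacklevel=2,
        )
        return None

    def keep_negative(pair: Pair) -> bool:
        a_in, b_in = pair[0] in in_tissue, pair[1] in in_tissue
        if a_in and b_in:
            return True
        if a_in and pair[1] in other:
            return True
        if b_in and pair[0] in other:
            return True
        return False

    negatives = frozenset(p for p in naive.negatives if keep_negative(p))
    return GoldStandard(positives, negatives)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_term_list(path: str | Path) -> set[str]:
    """One term ID per line; blank lines and ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_tissue_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (tissue, gene) -> tissue -> gene-set mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out: dict[str, set[str]] = {}
    for tissue, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(tissue, set()).add(gene)
    return out


def write_standard(std: GoldStandard, path: str | Path) -> None:
    """Three-column TSV: gene_a, gene_b (ordered), label in {1, 0}."""
    rows = [(a, b, 1) for a, b in sorted(std.positives)] + [
        (a, b, 0) for a, b in sorted(std.negatives)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_standard(path: str | Path) -> GoldStandard:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    pos, neg = set(), set()
    for a, b, label in zip(df["gene_a"], df["gene_b"], df["label"].astype(int)):
        (pos if label == 1 else neg).add(gene_pair(a, b))
    return GoldStandard(frozenset(pos), frozenset(neg))
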