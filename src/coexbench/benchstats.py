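"""Workflow enumeration, execution, and benchmark comparison statistics.

A *workflow* is a triple (within-sample normalization, between-sample
normalization, network transformation).  Within-sample normalization
rescales counts away from the raw scale, so it cannot be followed by the
count-based factor methods: if ``within != none`` then ``between`` must be
``none`` or ``qnt``.  Under that constraint there are 36 workflows.

Workflows are compared per dataset on log2(auPRC/prior) with one-sided
paired Wilcoxon signed-rank tests over all ordered workflow pairs,
Benjamini-Hochberg corrected, significant at FDR <= 0.01 by default.
Method impact aggregates those comparisons into the proportion of
significant wins attributable to including one method, with fairness
exclusions so that each method group is judged on comparable workflows.

Experimental-factor utilities (sample similarity, read-count diversity,
equal-size binning) and the fixed-size resampling design support the
analysis of how dataset properties affect workflow accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, wilcoxon
from statsmodels.stats.multitest import multipletests

from . import normalization as norm
from .corpus_io import Corpus
from .netbuild import CoexpressionNetwork, clr_transform, correlation_network, wto_transform

__all__ = [
    "WITHIN_METHODS",
    "BETWEEN_METHODS",
    "TRANSFORM_METHODS",
    "WorkflowSpec",
    "enumerate_workflows",
    "run_workflow",
    "ComparisonResult",
    "pairwise_compare",
    "method_impact",
    "sample_similarity",
    "read_count_diversity",
    "bin_datasets",
    "ResampleSpec",
    "resample_design",
]

WITHIN_METHODS = ("none", "cpm", "rpkm", "tpm")
BETWEEN_METHODS = ("none", "qnt", "tmm", "uq", "ctf", "cuf")
TRANSFORM_METHODS = ("none", "clr", "wto")

#: Between-sample methods that operate on raw counts via scale factors.
_COUNT_BASED_BETWEEN = ("tmm", "uq", "ctf", "cuf")


@dataclass(frozen=True)
class WorkflowSpec:
    """One (within, between, transform) method triple."""

    within: str = "none"
    between: str = "none"
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.within not in WITHIN_METHODS:
            raise ValueError(f"unknown within-sample method {self.within!r}")
        if self.between not in BETWEEN_METHODS:
            raise ValueError(f"unknown between-sample method {self.between!r}")
        if self.transform not in TRANSFORM_METHODS:
            raise ValueError(f"unknown network transformation {self.transform!r}")
        if self.within != "none" and self.between in _COUNT_BASED_BETWEEN:
            raise ValueError(
                f"{self.between.upper()} requires raw counts and cannot follow "
                f"{self.within.upper()} normalization"
            )

    @property
    def name(self) -> str:
        """Conventional workflow name, e.g. ``Counts``, ``CTF_CLR``, ``TPM``."""
        parts = [m.upper() for m in (self.within, self.between, self.transform)
                 if m != "none"]
        return "_".join(parts) if parts else "Counts"

    @property
    def methods(self) -> frozenset[str]:
        return frozenset(m for m in (self.within, self.between, self.transform)
                         if m != "none")


def enumerate_workflows(exclude_methods: Iterable[str] = ()) -> list[WorkflowSpec]:
    """All valid workflow triples in canonical order, skipping any that
    contains an excluded method (method names case-insensitive)."""
    exclude = {m.lower() for m in exclude_methods}
    known = set(WITHIN_METHODS + BETWEEN_METHODS + TRANSFORM_METHODS) - {"none"}
    unknown = exclude - known
    if unknown:
        raise ValueError(f"unknown methods in exclusion set: {sorted(unknown)}")
    out = []
    for within in WITHIN_METHODS:
        for between in BETWEEN_METHODS:
            if within != "none" and between in _COUNT_BASED_BETWEEN:
                continue
            for transform in TRANSFORM_METHODS:
                spec = WorkflowSpec(within, between, transform)
                if spec.methods & exclude:
                    continue
                out.append(spec)
    return out


def run_workflow(
    counts: pd.DataFrame,
    lengths: Mapping[str, int] | pd.Series | None,
    spec: WorkflowSpec,
    corr: str = "pearson",
    wto_variant: str = "sign",
) -> CoexpressionNetwork:
    """Execute one workflow: within-sample norm -> between-sample norm ->
    asinh -> correlation -> network transformation.

    ``lengths`` is only required for TPM/RPKM.  Stage failures are
    re-raised with the stage name attached.
    """
    stage = "within-sample normalization"
    try:
        if spec.within == "none":
            x: pd.DataFrame | norm.ExpressionMatrix = counts
        elif spec.within == "cpm":
            x = norm.cpm(counts)
        elif spec.within == "rpkm":
            if lengths is None:
                raise ValueError("RPKM requires gene lengths")
            x = norm.rpkm(counts, lengths)
        else:
            if lengths is None:
                raise ValueError("TPM requires gene lengths")
            x = norm.tpm(counts, lengths)

        stage = "between-sample normalization"
        if spec.between == "qnt":
            x = norm.quantile_normalize(x)
        elif spec.between == "tmm":
            x = norm.apply_effective_library_size(x, norm.tmm_factors(counts), "tmm")
        elif spec.between == "uq":
            x = norm.apply_effective_library_size(x, norm.uq_factors(counts), "uq")
        elif spec.between == "ctf":
            x = norm.apply_count_adjustment(x, norm.tmm_factors(counts), "ctf")
        elif spec.between == "cuf":
            x = norm.apply_count_adjustment(x, norm.uq_factors(counts), "cuf")

        stage = "asinh transformation"
        x = norm.asinh_transform(x)

        stage = "network construction"
        net = correlation_network(x, method=corr)

        stage = "network transformation"
        if spec.transform == "clr":
            net = clr_transform(net)
        elif spec.transform == "wto":
            net = wto_transform(net, variant=wto_variant)
    except Exception as exc:
        raise type(exc)(f"workflow {spec.name} failed at {stage}: {exc}") from exc
    return net


# ---------------------------------------------------------------------------
# Workflow comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Pairwise workflow comparison over a score table.

    ``table`` has one row per ordered workflow pair with columns
    workflow_a, workflow_b, n_shared, win_proportion, p_value, p_adjusted,
    significant; ``outperform_counts`` counts, per workflow, how many other
    workflows it significantly outperforms.
    """

    table: pd.DataFrame
    outperform_counts: pd.Series
    alpha: float


def _signed_rank_p(diff: np.ndarray, exact_max_n: int = 25) -> float:
    """One-sided (greater) paired Wilcoxon signed-rank p-value.

    Zero differences are discarded; an all-zero vector gives p = 1.  The
    exact null is used up to ``exact_max_n`` non-zero tie-free differences,
    the normal approximation with continuity correction otherwise.
    """
    nz = diff[diff != 0]
    if nz.size == 0:
        return 1.0
    if nz.size <= exact_max_n:
        from scipy.stats import rankdata

        # enumeration of the 2^n sign assignments, run as a DP over the
        # (tie-averaged) ranks doubled to integers
        ranks2 = np.rint(2 * rankdata(np.abs(nz))).astype(int)
        w_obs2 = int(ranks2[nz > 0].sum())
        ways = {0: 1}
        for r in ranks2:
            nxt: dict[int, int] = {}
            for s, c in ways.items():
                nxt[s] = nxt.get(s, 0) + c
                nxt[s + r] = nxt.get(s + r, 0) + c
            ways = nxt
        tail = sum(c for s, c in ways.items() if s >= w_obs2)
        return tail / 2 ** nz.size
    res = wilcoxon(nz, alternative="greater", method="approx", correction=True)
    return float(res.pvalue)


def pairwise_compare(
    scores: pd.DataFrame, alpha: float = 0.01, exact_max_n: int = 25
) -> ComparisonResult:
    """Compare every ordered workflow pair on per-dataset scores.

    ``scores`` is a dataset-by-workflow table of log2(auPRC/prior) values;
    NaN marks a dataset not scored under a workflow, and each pair is
    compared only on its shared datasets.  Win proportion gives ties half
    credit.  Benjamini-Hochberg correction runs across all ordered pairs of
    this table (one evaluation setting).
    """
    workflows = list(scores.columns)
    if len(workflows) < 2:
        raise ValueError("need at least two workflows to compare")
    rows = []
    for a, b in permutations(workflows, 2):
        shared = scores[[a, b]].dropna()
        if len(shared) < 2:
            raise ValueError(f"fewer than 2 shared datasets for {a} vs {b}")
        sa, sb = shared[a].to_numpy(), shared[b].to_numpy()
        wins = float(np.mean(sa > sb) + 0.5 * np.mean(sa == sb))
        rows.append(
            {
                "workflow_a": a,
                "workflow_b": b,
                "n_shared": len(shared),
                "win_proportion": wins,
                "p_value": _signed_rank_p(sa - sb, exact_max_n),
            }
        )
    table = pd.DataFrame(rows)
    _, adj, _, _ = multipletests(table["p_value"], method="fdr_bh")
    table["p_adjusted"] = adj
    table["significant"] = table["p_adjusted"] <= alpha
    counts = (
        table[table["significant"]].groupby("workflow_a").size()
        .reindex(workflows, fill_value=0)
    )
    counts.name = "n_significantly_outperformed"
    return ComparisonResult(table=table, outperform_counts=counts, alpha=alpha)


def _method_group(method: str) -> str:
    if method in ("cpm", "rpkm", "tpm", "no-within"):
        return "within"
    if method in ("qnt", "tmm", "uq", "ctf", "cuf", "no-between"):
        return "between"
    if method in ("clr", "wto", "no-transform"):
        return "transform"
    raise ValueError(f"unknown method {method!r}")


def _includes(spec: WorkflowSpec, method: str) -> bool:
    if method == "no-within":
        return spec.within == "none"
    if method == "no-between":
        return spec.between == "none"
    if method == "no-transform":
        return spec.transform == "none"
    return method in spec.methods


def _eligible(spec: WorkflowSpec, group: str) -> bool:
    # Fairness exclusions: between-sample methods are judged only on
    # workflows without within-sample normalization (CPM/TPM/RPKM cannot be
    # paired with the count-based factors), and within-sample methods only
    # on workflows without count-based between-sample normalization.
    if group == "between":
        return spec.within == "none"
    if group == "within":
        return spec.between not in _COUNT_BASED_BETWEEN
    return True


def method_impact(
    comparisons: ComparisonResult,
    workflows: Mapping[str, WorkflowSpec],
    methods: Sequence[str] = (
        "cpm", "rpkm", "tpm", "no-within",
        "qnt", "tmm", "uq", "ctf", "cuf", "no-between",
        "clr", "wto", "no-transform",
    ),
) -> pd.Series:
    """Proportion of eligible (with-method vs. without-method) comparisons
    that are significant wins, per method.  Methods with no eligible
    comparison are reported as NaN."""
    table = comparisons.table
    out = {}
    for m in methods:
        group = _method_group(m)
        n = wins = 0
        for row in table.itertuples(index=False):
            sa = workflows[row.workflow_a]
            sb = workflows[row.workflow_b]
            if not (_eligible(sa, group) and _eligible(sb, group)):
                continue
            if _includes(sa, m) and not _includes(sb, m):
                n += 1
                if row.significant:
                    wins += 1
        out[m] = wins / n if n else np.nan
        if n == 0:
            warnings.warn(f"no eligible comparisons for method {m!r}", stacklevel=2)
    return pd.Series(out, name="impact_proportion")


# ---------------------------------------------------------------------------
# Experimental factors
# ---------------------------------------------------------------------------

def sample_similarity(counts: pd.DataFrame, variable_fraction: float = 0.5) -> float:
    """Median Spearman correlation between all sample pairs, using the most
    variable ``variable_fraction`` of genes (by count variance)."""
    if counts.shape[1] < 2:
        raise ValueError("sample similarity needs >= 2 samples")
    var = counts.var(axis=1, ddof=1)
    k = int(np.ceil(counts.shape[0] * variable_fraction))
    if k < 2:
        raise ValueError("fewer than 2 genes after variable-gene selection")
    # deterministic selection: by variance descending, gene ID as tie-break
    order = sorted(zip(-var.to_numpy(), counts.index.astype(str)))[:k]
    top = counts.loc[[g for _, g in order]]
    if counts.shape[1] == 2:
        rho = spearmanr(top.iloc[:, 0], top.iloc[:, 1]).statistic
        return float(rho)
    rho = spearmanr(top.to_numpy()).statistic  # samples are columns -> variables
    iu = np.triu_indices(counts.shape[1], k=1)
    return float(np.median(rho[iu]))


def read_count_diversity(counts: pd.DataFrame) -> float:
    """Sample standard deviation (n-1 denominator) of per-sample count sums."""
    if counts.shape[1] < 2:
        raise ValueError("read-count diversity needs >= 2 samples")
    return float(counts.sum(axis=0).std(ddof=1))


def bin_datasets(values: Mapping[str, float], n_bins: int = 5) -> list[list[str]]:
    """Sort datasets by value (ties broken by ID) and split into ``n_bins``
    contiguous groups whose sizes differ by at most one; the remainder goes
    to the lowest-value bins first."""
    items = sorted(values.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    if n < n_bins:
        raise ValueError(f"need >= {n_bins} datasets, got {n}")
    base, rem = divmod(n, n_bins)
    bins, start = [], 0
    for i in range(n_bins):
        size = base + (1 if i < rem else 0)
        bins.append([k for k, _ in items[start:start + size]])
        start += size
    return bins


# ---------------------------------------------------------------------------
# Resampling design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResampleSpec:
    """One resampled dataset: a fixed-size sample subset of a source."""

    source: str
    size: int
    replicate: int
    sample_ids: tuple[str, ...]


DEFAULT_RESAMPLE_SIZES = (5, 6, 7, 9, 11, 13, 16, 25, 40)


def resample_design(
    corpus: Corpus,
    sizes: Sequence[int] = DEFAULT_RESAMPLE_SIZES,
    replicates: int = 10,
    min_source: int = 70,
    seed: int = 0,
) -> list[ResampleSpec]:
    """Draw ``replicates`` without-replacement sample subsets of each size
    from every source dataset with at least ``min_source`` samples.

    Reproducible: each (source, size, replicate) cell gets its own
    generator substream derived from ``seed``, so the design is stable
    under parallel or partial execution.
    """
    specs = []
    sources = sorted(
        (ds for ds in corpus if ds.n_samples >= min_source),
        key=lambda ds: ds.dataset_id,
    )
    for src_idx, ds in enumerate(sources):
        samples = np.asarray(ds.counts.columns, dtype=object)
        for size in sizes:
            if size > samples.size:
                warnings.warn(
                    f"{ds.dataset_id}: requested size {size} exceeds "
                    f"{samples.size} samples; skipped",
                    stacklevel=2,
                )
                continue
            for rep in range(replicates):
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, src_idx, size, rep])
                )
                chosen = rng.choice(samples, size=size, replace=False)
                specs.append(
                    ResampleSpec(
                        source=ds.dataset_id,
                        size=size,
                        replicate=rep,
                        sample_ids=tuple(chosen),
                    )
                )
    return specs
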