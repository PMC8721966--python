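"""Within- and between-sample normalization of RNA-seq counts.

Within-sample methods (CPM, TPM, RPKM) rescale genes inside one sample so
they can be compared to each other.  Between-sample methods make the same
gene comparable across samples: quantile normalization (QNT) forces every
sample onto the common average distribution, while TMM and UQ estimate one
positive scale factor per sample — TMM from doubly trimmed, inverse-variance
weighted log-fold-changes against a reference sample, UQ from the 75th
percentile of counts.  The factors are geometric-mean centered so they
multiply to one, and can be applied in two ways:

* as *effective library sizes* (``apply_effective_library_size``), i.e. a
  CPM computed with ``library_size * factor`` — the classic TMM/UQ usage;
* as a *direct divisor of counts* (``apply_count_adjustment``) with no
  library-size correction — the CTF/CUF counts-adjustment variants, which
  differ from TMM/UQ output only by a per-sample multiplier ``1e6 / N_k``.

Every matrix is finally passed through the hyperbolic arcsine
(``asinh_transform``), a variance-stabilizing log-like transform that needs
no pseudocount.

Matrices carry a ``units`` provenance chain so that incompatible
compositions (e.g. TMM after TPM) are rejected rather than silently
computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus_io import validate_counts

__all__ = [
    "ExpressionMatrix",
    "cpm",
    "rpkm",
    "tpm",
    "quantile_normalize",
    "tmm_factors",
    "uq_factors",
    "center_factors",
    "apply_effective_library_size",
    "apply_count_adjustment",
    "asinh_transform",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A gene-by-sample matrix of reals tagged with its normalization chain.

    ``units`` records provenance innermost-first, e.g. ``("tpm", "qnt",
    "asinh")`` for asinh(QNT(TPM(counts))).  Raw counts have ``("counts",)``.
    """

    frame: pd.DataFrame
    units: tuple[str, ...]

    @property
    def unit_label(self) -> str:
        label = "counts" if self.units[0] == "counts" else f"{self.units[0]}(counts)"
        for u in self.units[1:]:
            label = f"{u}({label})"
        return label


def _as_frame(x: pd.DataFrame | ExpressionMatrix) -> pd.DataFrame:
    return x.frame if isinstance(x, ExpressionMatrix) else x


def _require_counts(x: pd.DataFrame | ExpressionMatrix, op: str) -> pd.DataFrame:
    if isinstance(x, ExpressionMatrix):
        if x.units != ("counts",):
            raise ValueError(
                f"{op} operates on raw counts, got units {x.unit_label!r}"
            )
        return x.frame
    return validate_counts(x)


def _library_sizes(counts: pd.DataFrame, op: str) -> pd.Series:
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"{op}: zero library size for samples {bad}")
    return lib


def _lengths_kb(counts: pd.DataFrame, lengths: Mapping[str, int] | pd.Series) -> np.ndarray:
    lengths = pd.Series(lengths)
    missing = [g for g in counts.index if g not in lengths.index]
    if missing:
        raise KeyError(f"missing gene lengths for: {missing[:10]}" +
                       (f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""))
    return lengths.loc[counts.index].to_numpy(float) / 1e3


# ---------------------------------------------------------------------------
# Within-sample normalization
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame | ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: each column scaled to sum to 1e6."""
    frame = _require_counts(counts, "cpm")
    lib = _library_sizes(frame, "cpm")
    return ExpressionMatrix(frame.div(lib, axis=1) * 1e6, ("cpm",))


def rpkm(
    counts: pd.DataFrame | ExpressionMatrix, lengths: Mapping[str, int] | pd.Series
) -> ExpressionMatrix:
    """Reads per kilobase per million: library-size correction first, then
    gene-length correction.  Column sums are not fixed (unlike TPM)."""
    frame = _require_counts(counts, "rpkm")
    lib = _library_sizes(frame, "rpkm")
    kb = _lengths_kb(frame, lengths)
    out = frame.div(lib / 1e6, axis=1).div(kb, axis=0)
    return ExpressionMatrix(out, ("rpkm",))


def tpm(
    counts: pd.DataFrame | ExpressionMatrix, lengths: Mapping[str, int] | pd.Series
) -> ExpressionMatrix:
    """Transcripts per million: gene-length correction first, then each
    column of length-corrected rates scaled to sum to 1e6."""
    frame = _require_counts(counts, "tpm")
    kb = _lengths_kb(frame, lengths)
    rates = frame.div(kb, axis=0)
    total = rates.sum(axis=0)
    if (total <= 0).any():
        bad = total.index[total <= 0].tolist()
        raise ValueError(f"tpm: all-zero sample columns {bad}")
    return ExpressionMatrix(rates.div(total, axis=1) * 1e6, ("tpm",))


# ---------------------------------------------------------------------------
# Between-sample normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame | ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization: every sample is forced onto the cross-sample
    mean distribution (identical sorted columns afterwards).

    Each value is replaced by the mean, across samples, of the values at its
    rank; tied values within a sample receive the mean of the rank-means
    they jointly occupy.
    """
    frame = _as_frame(matrix)
    if frame.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    A = frame.to_numpy(float)
    order = np.argsort(A, axis=0, kind="stable")
    sorted_a = np.take_along_axis(A, order, axis=0)
    ref = sorted_a.mean(axis=1)
    out = np.empty_like(A)
    rows = np.arange(A.shape[0])
    for j in range(A.shape[1]):
        col = np.empty(A.shape[0])
        col[order[:, j]] = ref
        # average over tie groups of the input column
        _, inv, cnt = np.unique(A[:, j], return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=col)
        out[rows, j] = (sums / cnt)[inv]
    units = matrix.units if isinstance(matrix, ExpressionMatrix) else ("counts",)
    return ExpressionMatrix(
        pd.DataFrame(out, index=frame.index, columns=frame.columns),
        units + ("qnt",),
    )


def center_factors(raw: pd.Series) -> pd.Series:
    """Divide factors by their geometric mean so they multiply to one."""
    raw = pd.Series(raw, dtype=float)
    if (raw <= 0).any() or not np.isfinite(raw).all():
        raise ValueError("scale factors must be positive and finite")
    centered = raw / np.exp(np.log(raw).mean())
    return centered


def tmm_factors(
    counts: pd.DataFrame | ExpressionMatrix,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, geometric-mean centered.

    The reference sample is the one whose 75th percentile of
    count/library-size is closest to the mean of that statistic.  For each
    other sample, genes with positive counts in both it and the reference
    contribute a log-fold-change M and an average log-intensity A; the top
    and bottom ``logratio_trim`` fraction by M *and* the top and bottom
    ``abs_trim`` fraction by A are discarded (rank thresholds, ties at the
    boundary kept), and the factor is two to the inverse-variance weighted
    mean of the surviving M values.
    """
    frame = _require_counts(counts, "tmm_factors")
    if frame.shape[1] < 2:
        raise ValueError("tmm_factors needs >= 2 samples")
    y = frame.to_numpy(float)
    lib = _library_sizes(frame, "tmm_factors").to_numpy()
    f75 = np.quantile(y / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(frame.shape[1])
    for k in range(frame.shape[1]):
        if k == ref:
            continue
        factors[k] = _tmm_pair_factor(
            y[:, k], y[:, ref], lib[k], lib[ref], logratio_trim, abs_trim
        )
    return center_factors(pd.Series(factors, index=frame.columns, name="tmm_factor"))


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        warnings.warn("TMM: no genes with positive counts in both samples; factor 1",
                      stacklevel=3)
        return 1.0
    o, r = obs[both], ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    from scipy.stats import rankdata

    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        warnings.warn("TMM: trimming removed all genes; factor 1", stacklevel=3)
        return 1.0
    # precision weights: inverse of the delta-method variance of M
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def uq_factors(
    counts: pd.DataFrame | ExpressionMatrix, quantile: float = 0.75
) -> pd.Series:
    """Upper-quartile scale factors, geometric-mean centered.

    Genes with zero counts in every sample are removed first; each sample's
    factor is its 75th-percentile count (linear interpolation between order
    statistics) divided by its library size.
    """
    frame = _require_counts(counts, "uq_factors")
    if frame.shape[1] < 2:
        raise ValueError("uq_factors needs >= 2 samples")
    lib = _library_sizes(frame, "uq_factors").to_numpy()
    y = frame.to_numpy(float)
    y = y[y.sum(axis=1) > 0]
    if y.size == 0:
        raise ValueError("uq_factors: no non-zero genes")
    q = np.quantile(y, quantile, axis=0)
    if (q <= 0).any():
        bad = frame.columns[np.asarray(q) <= 0].tolist()
        raise ValueError(
            f"uq_factors: upper quantile is zero for samples {bad} (degenerate library)"
        )
    return center_factors(pd.Series(q / lib, index=frame.columns, name="uq_factor"))


def _aligned_factors(frame: pd.DataFrame, factors: pd.Series) -> np.ndarray:
    missing = [s for s in frame.columns if s not in factors.index]
    if missing:
        raise KeyError(f"no scale factor for samples: {missing}")
    return factors.loc[frame.columns].to_numpy(float)


def apply_effective_library_size(
    counts: pd.DataFrame | ExpressionMatrix,
    factors: pd.Series,
    label: str = "effective-cpm",
) -> ExpressionMatrix:
    """CPM computed with effective library sizes ``N_k * factor_k`` —
    the TMM/UQ workflow output."""
    frame = _require_counts(counts, "apply_effective_library_size")
    lib = _library_sizes(frame, "apply_effective_library_size").to_numpy()
    f = _aligned_factors(frame, factors)
    out = frame.div(lib * f, axis=1) * 1e6
    return ExpressionMatrix(out, (label,))


def apply_count_adjustment(
    counts: pd.DataFrame | ExpressionMatrix,
    factors: pd.Series,
    label: str = "count-adjusted",
) -> ExpressionMatrix:
    """Divide each sample's counts by its scale factor, with no library-size
    correction — the CTF/CUF workflow output."""
    frame = _require_counts(counts, "apply_count_adjustment")
    f = _aligned_factors(frame, factors)
    return ExpressionMatrix(frame.div(f, axis=1), (label,))


# ---------------------------------------------------------------------------
# Data transformation
# ---------------------------------------------------------------------------

def asinh_transform(matrix: pd.DataFrame | ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise hyperbolic arcsine, ln(x + sqrt(x^2 + 1)).

    Strictly increasing, defined on all reals, and applied in every
    workflow — including the plain-counts one — as the final
    variance-stabilizing step before correlation.
    """
    frame = _as_frame(matrix)
    units = matrix.units if isinstance(matrix, ExpressionMatrix) else ("counts",)
    return ExpressionMatrix(np.arcsinh(frame), units + ("asinh",))
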