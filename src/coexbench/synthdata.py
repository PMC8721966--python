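"""Synthetic RNA-seq count corpora with planted coexpression modules.

The generator emulates the statistical structure the benchmark assumes:
negative-binomial read counts with log-normal library-size variation,
log-normal baseline gene abundances, and functionally coherent gene
modules.  Each module m has a latent per-sample activity a_mj ~ N(0, 1);
a member gene's expected count is

    mu_gj = depth * s_j * b_g * exp(beta * a_mj - beta^2 / 2),

where s_j is the sample's library factor, b_g the gene's relative
baseline abundance, and beta the module effect size (background genes
have beta = 0).  Counts are drawn negative-binomially with dispersion phi
(variance mu + phi * mu^2).  Within-module gene pairs are therefore
correlated, and the planted truth yields a gold standard directly:
within-module pairs positive, cross-module pairs negative, background
genes unlabeled.

A corpus shares one gene universe and module assignment across datasets;
tissues are emulated by assigning each tissue a subset of modules (plus
the background) as its expressed gene set, which exercises the
tissue-aware evaluation path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .corpus_io import Corpus, Dataset
from .goldstd import GoldStandard, gene_pair

__all__ = ["SynthConfig", "SynthTruth", "SynthCorpus", "generate_dataset", "generate_corpus"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic dataset.

    Defaults describe a small but realistic bulk RNA-seq experiment:
    a few hundred long-RNA genes at ~1000x mean gene coverage, library
    sizes varying ~40% (log-normal sigma 0.35), module effect beta = 1.0,
    and negative-binomial dispersion 0.2 (a typical bulk-tissue scale).
    """

    n_genes: int = 300
    n_modules: int = 6
    module_size: int = 10
    n_samples: int = 50
    mean_depth: float = 3e5
    lib_sigma: float = 0.35
    baseline_sigma: float = 1.2
    beta: float = 1.0
    dispersion: float = 0.2
    gene_length_range: tuple[int, int] = (200, 10_000)
    read_length: float = 100.0
    paired_end: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules do not fit in the gene universe")
        for name in ("n_genes", "n_modules", "module_size", "n_samples",
                     "mean_depth", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0 or self.lib_sigma < 0 or self.baseline_sigma < 0:
            raise ValueError("spread parameters must be non-negative")
        lo, hi = self.gene_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid gene length range")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass(frozen=True)
class SynthTruth:
    """Planted module assignment and the implied gold standard."""

    modules: tuple[tuple[str, ...], ...]
    background: tuple[str, ...]

    @property
    def module_of(self) -> dict[str, int]:
        return {g: m for m, genes in enumerate(self.modules) for g in genes}

    def standard(self) -> GoldStandard:
        """Within-module pairs positive; cross-module pairs negative;
        background genes unlabeled."""
        positives = set()
        for genes in self.modules:
            positives.update(gene_pair(a, b) for a, b in combinations(genes, 2))
        negatives = set()
        for m1, m2 in combinations(range(len(self.modules)), 2):
            for a in self.modules[m1]:
                for b in self.modules[m2]:
                    negatives.add(gene_pair(a, b))
        return GoldStandard(frozenset(positives), frozenset(negatives))


@dataclass
class SynthCorpus:
    """A synthetic corpus bundle: datasets, shared truth and gold standard,
    gene lengths, and the tissue -> expressed-gene-set emulation."""

    corpus: Corpus
    truth: SynthTruth
    standard: GoldStandard
    gene_lengths: pd.Series
    tissue_gene_sets: dict[str, set[str]] = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{str(i).zfill(width)}" for i in range(1, n + 1)]


def _planted_truth(cfg: SynthConfig) -> SynthTruth:
    genes = _gene_ids(cfg.n_genes)
    modules = tuple(
        tuple(genes[m * cfg.module_size:(m + 1) * cfg.module_size])
        for m in range(cfg.n_modules)
    )
    background = tuple(genes[cfg.n_modules * cfg.module_size:])
    return SynthTruth(modules, background)


def generate_dataset(
    cfg: SynthConfig, dataset_id: str = "synth", tissue: str = "unknown"
) -> tuple[Dataset, SynthTruth]:
    """Generate one dataset (counts + per-sample metadata) and its truth.

    Deterministic: the same config (including seed) reproduces the counts
    bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = _planted_truth(cfg)
    genes = _gene_ids(cfg.n_genes)
    samples = [f"{dataset_id}.S{i + 1}" for i in range(cfg.n_samples)]

    baseline = rng.lognormal(mean=0.0, sigma=cfg.baseline_sigma, size=cfg.n_genes)
    baseline /= baseline.sum()
    # mean-one library factors
    lib = rng.lognormal(mean=-cfg.lib_sigma ** 2 / 2, sigma=cfg.lib_sigma,
                        size=cfg.n_samples)
    activity = rng.standard_normal((cfg.n_modules, cfg.n_samples))

    log_effect = np.zeros((cfg.n_genes, cfg.n_samples))
    module_of = truth.module_of
    for i, g in enumerate(genes):
        m = module_of.get(g)
        if m is not None:
            log_effect[i] = cfg.beta * activity[m] - cfg.beta ** 2 / 2
    mu = cfg.mean_depth * lib[None, :] * baseline[:, None] * np.exp(log_effect)

    if cfg.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    frame = pd.DataFrame(counts, index=genes, columns=samples)
    meta = pd.DataFrame(
        {
            "avg_read_length": cfg.read_length,
            "paired_end": cfg.paired_end,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return Dataset(dataset_id, frame, tissue=tissue, meta=meta), truth


def generate_corpus(
    cfg: SynthConfig,
    n_datasets: int,
    n_tissues: int = 3,
    seed: int | None = None,
) -> SynthCorpus:
    """Generate a corpus of datasets sharing one gene universe and module
    truth; tissue labels are assigned round-robin and each tissue's
    expressed gene set is the union of a round-robin subset of modules
    plus the background genes."""
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    master = cfg.seed if seed is None else seed
    truth = _planted_truth(cfg)
    genes = _gene_ids(cfg.n_genes)

    length_rng = np.random.default_rng(np.random.SeedSequence([master, 10_000]))
    lo, hi = cfg.gene_length_range
    lengths = pd.Series(
        length_rng.integers(lo, hi + 1, size=cfg.n_genes), index=genes, name="length"
    )

    tissue_names = [f"tissue{i + 1}" for i in range(n_tissues)]
    tissue_modules: dict[str, list[int]] = {t: [] for t in tissue_names}
    for m in range(cfg.n_modules):
        tissue_modules[tissue_names[m % n_tissues]].append(m)
    tissue_sets = {
        t: {g for m in mods for g in truth.modules[m]} | set(truth.background)
        for t, mods in tissue_modules.items()
    }

    datasets = {}
    for i in range(n_datasets):
        child_seed = int(
            np.random.SeedSequence([master, i]).generate_state(1)[0] % (2 ** 31)
        )
        ds_cfg = replace(cfg, seed=child_seed)
        ds_id = f"synth{i + 1:03d}"
        ds, _ = generate_dataset(ds_cfg, dataset_id=ds_id,
                                 tissue=tissue_names[i % n_tissues])
        datasets[ds_id] = ds
    return SynthCorpus(
        corpus=Corpus(datasets),
        truth=truth,
        standard=truth.standard(),
        gene_lengths=lengths,
        tissue_gene_sets=tissue_sets,
    )
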