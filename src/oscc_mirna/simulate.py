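"""Synthetic two-class miRNA expression data with known ground truth.

Emulates the two study designs the pipeline targets: a small-RNA-seq cohort
(read counts; defaults: 20 tumor vs 7 normal brush samples) and an RT-qPCR
panel cohort (Ct values; 372-assay panels are typical, we default to 400
miRNAs).  Counts follow a gamma-Poisson (negative binomial) model with
log-normal baseline means spanning several orders of magnitude, independent
Bernoulli dropout (zero inflation), and a modest library-size spread.  Ct
values are Gaussian noise around the true log2 abundance with censoring at a
detection ceiling.  Differential miRNAs are planted at configurable fold
changes with direction randomized 50/50; red-blood-cell contamination
markers (miR-451a / miR-144) are spiked up in tumor samples only, emulating
the blood contamination of tumor biopsies, and are never part of the
differential ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import PLATFORM_COUNTS, PLATFORM_CT, RBC_MARKERS, ExpressionMatrix

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-class expression simulator.

    Defaults mirror the miRNAseq brush-biopsy cohort: 20 tumor and 7 normal
    samples over 400 miRNAs, 15 differential miRNAs planted at 4-fold change,
    moderate overdispersion, 10% structural dropout, a 4× RBC-marker spike in
    tumor samples, and a qPCR detection ceiling of 40 cycles.
    """

    n_tumor: int = 20
    n_normal: int = 7
    n_mirna: int = 400
    n_de: int = 15
    fold_changes: tuple[float, ...] = (4.0,)
    #: biological CV 0.4 (the standard rule of thumb for human bulk samples)
    dispersion: float = 0.16
    zero_inflation: float = 0.1
    rbc_spike: float = 4.0
    ct_ceiling: float = 40.0
    seed: int = 0
    #: max/min spread of per-sample library sizes (counts platform only)
    library_size_spread: float = 3.0
    #: minimal baseline mean count for a miRNA to carry a planted effect —
    #: a diagnostic signature is by construction quantifiable, so effects
    #: are planted on miRNAs above the shot-noise floor
    min_planted_mean: float = 50.0

    def __post_init__(self) -> None:
        if self.n_tumor < 1:
            raise ConfigurationError("n_tumor must be ≥ 1")
        if self.n_normal < 1:
            raise ConfigurationError("n_normal must be ≥ 1")
        if self.n_mirna < 1:
            raise ConfigurationError("n_mirna must be ≥ 1")
        if not 0 <= self.n_de <= self.n_mirna:
            raise ConfigurationError("n_de must satisfy 0 ≤ n_de ≤ n_mirna")
        if self.n_de and not self.fold_changes:
            raise ConfigurationError("fold_changes must be non-empty when n_de > 0")
        if any(f < 1 for f in self.fold_changes):
            raise ConfigurationError("fold_changes must all be ≥ 1 (linear scale)")
        if not 0 <= self.zero_inflation <= 1:
            raise ConfigurationError("zero_inflation must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be ≥ 0")
        if self.rbc_spike < 1:
            raise ConfigurationError("rbc_spike must be ≥ 1")
        if self.ct_ceiling <= 0:
            raise ConfigurationError("ct_ceiling must be > 0")
        if self.library_size_spread < 1:
            raise ConfigurationError("library_size_spread must be ≥ 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: differential miRNAs with their true (signed) folds.

    ``de_mirnas`` maps miRNA id → true tumor/normal linear fold change
    (values < 1 mean down in tumor).  ``contamination_markers`` are the RBC
    miRNAs, which are never members of ``de_mirnas``.  ``planted_pathway``
    is filled in by :func:`simulate_annotation`.
    """

    de_mirnas: dict[str, float]
    contamination_markers: tuple[str, ...] = RBC_MARKERS
    planted_pathway: str | None = None


def _mirna_ids(n: int) -> list[str]:
    """Identifier universe: the three real RBC marker names plus synthetic ids."""
    ids = [f"mir-{i:04d}" for i in range(n - len(RBC_MARKERS))]
    return ids + list(RBC_MARKERS)


def _plant_effects(config: SimulationConfig, rng: np.random.Generator,
                   ids: list[str], abundance: np.ndarray,
                   min_abundance: float) -> dict[str, float]:
    """Pick n_de quantifiable non-marker miRNAs and assign signed fold changes.

    Eligible miRNAs have baseline abundance ≥ ``min_abundance``; if fewer
    than ``n_de`` qualify, the most abundant non-markers fill in.
    """
    non_marker = [(m, a) for m, a in zip(ids, abundance) if m not in RBC_MARKERS]
    candidates = [m for m, a in non_marker if a >= min_abundance]
    if len(candidates) < config.n_de:
        candidates = [m for m, _ in sorted(non_marker, key=lambda x: -x[1])[: config.n_de]]
    chosen = rng.choice(len(candidates), size=config.n_de, replace=False)
    folds = {}
    for j, idx in enumerate(sorted(chosen)):
        f = config.fold_changes[j % len(config.fold_changes)]
        up = rng.random() < 0.5
        folds[candidates[idx]] = f if up else 1.0 / f
    return folds


def simulate_counts(
    config: SimulationConfig, cohort_seed: int | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a small-RNA-seq count matrix with planted differential miRNAs.

    Per-miRNA baseline means are log-normal over several orders of magnitude;
    counts are gamma-Poisson with the configured dispersion; dropout zeroes
    each observation independently with probability ``zero_inflation``; RBC
    markers are multiplied by ``rbc_spike`` in tumor samples only.

    ``cohort_seed`` draws an independent cohort from the *same* population
    (identical baselines and planted effects, new sampling noise) — the
    external-validation scenario.
    """
    rng = np.random.default_rng(config.seed)
    ids = _mirna_ids(config.n_mirna)
    n_samples = config.n_tumor + config.n_normal
    samples = [f"T{i + 1:02d}" for i in range(config.n_tumor)] + [
        f"N{i + 1:02d}" for i in range(config.n_normal)
    ]
    is_tumor = np.array([1] * config.n_tumor + [0] * config.n_normal, dtype=bool)

    # baselines span roughly 4 orders of magnitude, as small-RNA-seq does
    base = rng.lognormal(mean=np.log(200.0), sigma=2.0, size=config.n_mirna)
    folds = _plant_effects(config, rng, ids, base, config.min_planted_mean)

    mean = np.tile(base[:, None], (1, n_samples))
    for mirna, f in folds.items():
        mean[ids.index(mirna), is_tumor] *= f
    for marker in RBC_MARKERS:
        mean[ids.index(marker), is_tumor] *= config.rbc_spike

    if cohort_seed is not None:
        rng = np.random.default_rng(cohort_seed)  # fresh sampling noise

    # 3x default max/min library-size spread, log-uniform
    spread = config.library_size_spread
    lib = np.exp(rng.uniform(0.0, np.log(spread), size=n_samples))
    lib /= np.exp(np.mean(np.log(lib)))
    mean = mean * lib[None, :]

    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mean / shape)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(float)
    if config.zero_inflation > 0:
        counts[rng.random(counts.shape) < config.zero_inflation] = 0.0

    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=ids, columns=samples),
        platform=PLATFORM_COUNTS,
        labels={s: (TUMOR if t else NORMAL) for s, t in zip(samples, is_tumor)},
    )
    return matrix, GroundTruth(de_mirnas=folds)


#: Ct value of a single abundance unit; Ct = CT_ANCHOR − log2(abundance).
CT_ANCHOR = 36.0
#: technical noise of a qPCR reaction, in cycles
CT_NOISE_SD = 0.5


def simulate_ct(
    config: SimulationConfig, cohort_seed: int | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate an RT-qPCR Ct matrix (lower Ct = more abundant).

    A planted linear fold change f appears as a tumor−normal Ct difference of
    −log2(f).  Reactions whose Ct would exceed ``ct_ceiling`` are recorded as
    undetected (missing).  ``cohort_seed`` resamples an independent cohort
    from the same population, as in :func:`simulate_counts`.
    """
    rng = np.random.default_rng(config.seed)
    ids = _mirna_ids(config.n_mirna)
    n_samples = config.n_tumor + config.n_normal
    samples = [f"T{i + 1:02d}" for i in range(config.n_tumor)] + [
        f"N{i + 1:02d}" for i in range(config.n_normal)
    ]
    is_tumor = np.array([1] * config.n_tumor + [0] * config.n_normal, dtype=bool)

    # true log2 abundance; Ct ≈ N(28, 3) so a ceiling of 40 censors the tail
    log2_abund = rng.normal(loc=8.0, scale=3.0, size=config.n_mirna)
    # eligible miRNAs sit ≥4 cycles clear of the detection ceiling
    min_abund = CT_ANCHOR - config.ct_ceiling + 4.0
    folds = _plant_effects(config, rng, ids, log2_abund, min_abund)

    abund = np.tile(log2_abund[:, None], (1, n_samples))
    for mirna, f in folds.items():
        abund[ids.index(mirna), is_tumor] += np.log2(f)
    for marker in RBC_MARKERS:
        abund[ids.index(marker), is_tumor] += np.log2(config.rbc_spike)

    if cohort_seed is not None:
        rng = np.random.default_rng(cohort_seed)

    ct = CT_ANCHOR - abund + rng.normal(0.0, CT_NOISE_SD, size=abund.shape)
    ct[ct > config.ct_ceiling] = np.nan
    # structural dropout: reaction failure independent of abundance
    if config.zero_inflation > 0:
        ct[rng.random(ct.shape) < config.zero_inflation] = np.nan

    matrix = ExpressionMatrix(
        values=pd.DataFrame(ct, index=ids, columns=samples),
        platform=PLATFORM_CT,
        labels={s: (TUMOR if t else NORMAL) for s, t in zip(samples, is_tumor)},
    )
    return matrix, GroundTruth(de_mirnas=folds)


@dataclass(frozen=True)
class AnnotationConfig:
    """Parameters of the synthetic target-map / pathway generator.

    A pool of "promiscuous" genes is targeted by every miRNA with high
    probability, emulating the carcinogenesis-heavy bias of curated target
    databases; pathways drawn from that pool light up for *any* miRNA set
    and are what the negative-control filter must remove.  The planted
    pathway's genes are spread across the differential miRNAs so that only
    the full signature, not a stray member, covers the pathway.
    """

    n_genes: int = 2000
    n_pathways: int = 20
    pathway_size: int = 50
    targets_per_mirna: int = 100
    n_promiscuous: int = 3
    promiscuous_pool_size: int = 150
    promiscuous_target_prob: float = 0.5
    planted_enrichment: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.planted_enrichment <= 1:
            raise ConfigurationError("planted_enrichment must lie in [0, 1]")
        if self.pathway_size > self.n_genes:
            raise ConfigurationError("pathway_size must be ≤ n_genes")
        if self.n_promiscuous >= self.n_pathways:
            raise ConfigurationError("n_promiscuous must be < n_pathways")
        if self.promiscuous_pool_size > self.n_genes:
            raise ConfigurationError("promiscuous_pool_size must be ≤ n_genes")


def simulate_annotation(
    config: SimulationConfig,
    truth: GroundTruth,
    annotation: AnnotationConfig | None = None,
) -> tuple[dict[str, set[str]], dict[str, tuple[str, set[str]]], GroundTruth]:
    """Generate a miRNA→target map and GMT-style pathway sets to match a simulation.

    Returns ``(target_map, pathways, truth)`` where ``truth`` is updated with
    the planted pathway id.  With ``planted_enrichment = 1`` every gene of the
    planted pathway is targeted by some differential miRNA (split roughly
    evenly among them); with 0 the planted pathway is indistinguishable from
    the uniform background.
    """
    ann = annotation or AnnotationConfig()
    rng = np.random.default_rng(config.seed + 10_000_019)
    ids = _mirna_ids(config.n_mirna)
    genes = np.array([f"GENE{i:05d}" for i in range(ann.n_genes)])

    pool = rng.choice(ann.n_genes, size=ann.promiscuous_pool_size, replace=False)

    pathways: dict[str, tuple[str, set[str]]] = {}
    for p in range(ann.n_promiscuous):
        members = rng.choice(pool, size=min(ann.pathway_size, len(pool)), replace=False)
        pathways[f"PW{p:03d}"] = ("promiscuous pathway", set(genes[members]))
    # the planted pathway is drawn like any background pathway, so with
    # enrichment off it is exchangeable with the rest
    planted_id = f"PW{ann.n_promiscuous:03d}"
    planted_members = rng.choice(ann.n_genes, size=ann.pathway_size, replace=False)
    planted_genes = set(genes[planted_members])
    pathways[planted_id] = ("planted pathway", planted_genes)
    for p in range(ann.n_promiscuous + 1, ann.n_pathways):
        members = rng.choice(ann.n_genes, size=ann.pathway_size, replace=False)
        pathways[f"PW{p:03d}"] = ("background pathway", set(genes[members]))

    target_map: dict[str, set[str]] = {}
    for mirna in ids:
        hit = rng.random(len(pool)) < ann.promiscuous_target_prob
        targets = set(genes[pool[hit]])
        extra = rng.choice(ann.n_genes, size=ann.targets_per_mirna, replace=False)
        targets |= set(genes[extra])
        target_map[mirna] = targets

    de = sorted(truth.de_mirnas)
    if de and ann.planted_enrichment > 0:
        n_assign = int(round(ann.planted_enrichment * len(planted_genes)))
        assigned = rng.choice(sorted(planted_genes), size=n_assign, replace=False)
        for j, gene in enumerate(assigned):
            # spread pathway genes across the signature: no single miRNA
            # covers enough of the pathway to reach significance alone
            target_map[de[j % len(de)]].add(gene)

    truth = replace(truth, planted_pathway=planted_id)
    return target_map, pathways, truth


__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "AnnotationConfig",
    "simulate_counts",
    "simulate_ct",
    "simulate_annotation",
    "TUMOR",
    "NORMAL",
]
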