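"""Synthetic RPKM-like datasets with planted mRNA-lncRNA-miRNA triplets.

The generator emulates the regime the pipeline targets: positive
RPKM-scale abundances with a tunable fraction of exact zeros, background
genes that are mutually independent, and planted triplets whose three
members share a latent factor.  On the log scale a planted member is

    latent_loading * z_t + Gaussian(0, noise_sd)

with z_t standard normal per sample and shared within the triplet, so any
two members correlate at loading^2 / (loading^2 + noise_sd^2) and each
pairwise regression attains a high adjusted R^2.  Background genes are
independent standard normals.  Log values are mapped to the RPKM-like
scale as ``rpkm_scale * 2**logexpr``, and exact zeros are planted only in
background entries by default so that recovery tests isolate the network
stage from the imputation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .expression import ExpressionMatrix
from .triplets import Triplet


@dataclass
class SimConfig:
    """Study-design knobs of the generator.

    Defaults are a desk-scale version of a tumor multi-omics cohort:
    300 patients, 50 mRNAs / 50 lncRNAs / 20 miRNAs, five planted
    triplets at unit latent loading with noise_sd 0.1 (pairwise log-scale
    correlation ~0.99), and 2% exact zeros among background entries.
    """

    n_samples: int = 300
    n_mrna: int = 50
    n_lncrna: int = 50
    n_mirna: int = 20
    n_planted_triplets: int = 5
    latent_loading: float = 1.0
    noise_sd: float = 0.1
    zero_fraction: float = 0.02
    rpkm_scale: float = 10.0
    seed: int = 0
    zeros_in_planted: bool = False

    def __post_init__(self):
        if min(self.n_samples, self.n_mrna, self.n_lncrna, self.n_mirna) < 1:
            raise ValidationError("all dimensions must be positive")
        if self.n_planted_triplets < 0:
            raise ValidationError("n_planted_triplets must be >= 0")
        if self.n_planted_triplets > min(self.n_mrna, self.n_lncrna,
                                         self.n_mirna):
            raise ValidationError(
                "n_planted_triplets exceeds the smallest gene-class size")
        if not 0.0 <= self.zero_fraction < 1.0:
            raise ValidationError("zero_fraction must be in [0, 1)")
        if self.noise_sd < 0 or self.rpkm_scale <= 0:
            raise ValidationError("noise_sd >= 0 and rpkm_scale > 0 required")


@dataclass
class GroundTruth:
    """What was planted: triplets, their pairwise edges, latent factors."""

    triplets: list = field(default_factory=list)
    edges: set = field(default_factory=set)
    latent_factors: pd.DataFrame | None = None
    planted_genes: set = field(default_factory=set)

    def __post_init__(self):
        expected = set()
        for t in self.triplets:
            expected |= {frozenset((t.mrna, t.lncrna)),
                         frozenset((t.mrna, t.mirna)),
                         frozenset((t.lncrna, t.mirna))}
        if self.edges != expected:
            raise ValidationError(
                "edges must be exactly the pairwise closures of the triplets")


def _gene_names(n_mrna: int, n_lncrna: int, n_mirna: int):
    mrna = [f"GENE{i:04d}" for i in range(n_mrna)]
    lnc = [f"LINC{i:04d}" for i in range(n_lncrna)]
    mir = [f"hsa-mir-{i + 1:03d}" for i in range(n_mirna)]
    return mrna, lnc, mir


def generate_dataset(config: SimConfig):
    """Draw one dataset; returns (mrna, lncrna, mirna, truth).

    Deterministic per ``config.seed``.  The planted triplet t uses the
    t-th gene of each class; remaining genes are background.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{j:04d}" for j in range(n)]
    mrna_ids, lnc_ids, mir_ids = _gene_names(
        config.n_mrna, config.n_lncrna, config.n_mirna)

    blocks = {}
    for ids in (mrna_ids, lnc_ids, mir_ids):
        blocks[id(ids)] = rng.standard_normal((len(ids), n))

    npl = config.n_planted_triplets
    z = rng.standard_normal((npl, n)) if npl else np.empty((0, n))
    triplets = []
    planted_genes = set()
    for t in range(npl):
        trip = Triplet(mrna_ids[t], lnc_ids[t], mir_ids[t])
        triplets.append(trip)
        planted_genes |= set(trip)
        for ids in (mrna_ids, lnc_ids, mir_ids):
            noise = rng.normal(0.0, config.noise_sd, size=n)
            blocks[id(ids)][t] = config.latent_loading * z[t] + noise

    matrices = []
    for ids, typ in ((mrna_ids, "mRNA"), (lnc_ids, "lncRNA"),
                     (mir_ids, "miRNA")):
        logexpr = blocks[id(ids)]
        rpkm = config.rpkm_scale * np.power(2.0, logexpr)
        if config.zero_fraction > 0:
            mask = rng.random(rpkm.shape) < config.zero_fraction
            if not config.zeros_in_planted:
                bg = np.array([g not in planted_genes for g in ids])
                mask &= bg[:, None]
            rpkm = np.where(mask, 0.0, rpkm)
        df = pd.DataFrame(rpkm, index=pd.Index(ids, name="gene_id"),
                          columns=samples)
        matrices.append(
            ExpressionMatrix(df, pd.Series(typ, index=df.index, dtype=object)))

    edges = set()
    for trip in triplets:
        edges |= {frozenset((trip.mrna, trip.lncrna)),
                  frozenset((trip.mrna, trip.mirna)),
                  frozenset((trip.lncrna, trip.mirna))}
    latent = pd.DataFrame(
        z, index=[f"triplet_{t}" for t in range(npl)], columns=samples)
    truth = GroundTruth(triplets=triplets, edges=edges,
                        latent_factors=latent, planted_genes=planted_genes)
    return matrices[0], matrices[1], matrices[2], truth


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float
    f1: float
    degenerate: bool  # both found and truth empty: metrics defined as 0


def recovery_metrics(found, truth: GroundTruth) -> RecoveryMetrics:
    """Set-based precision/recall/F1 of found vs planted triplets."""
    found_set = {Triplet(*t) for t in found}
    true_set = {Triplet(*t) for t in truth.triplets}
    if not found_set and not true_set:
        return RecoveryMetrics(0.0, 0.0, 0.0, degenerate=True)
    tp = len(found_set & true_set)
    precision = tp / len(found_set) if found_set else 0.0
    recall = tp / len(true_set) if true_set else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return RecoveryMetrics(precision, recall, f1, degenerate=False)
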