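"""Synthetic reciprocal-cross study generator.

Emulates the data the analysis consumes so every stage is testable without
downloads: a gene registry with known imprinted clusters (each with an ICR)
and novel candidates placed to realise known class labels; replicate-level
allele-specific read counts under a binomial model with additive parental
and strain effects; and pyrosequencing measurements with primer
amplification bias and Gaussian noise.

Count model: in each replicate the paternal read count is
Binomial(depth, p) with p = clip(theta_p + s * theta_s, 0.02, 0.98), where
theta_p is the true paternal fraction, theta_s the Cast-allele shift in
probability units, and s = +1 in BxC (the paternal allele is Cast) and -1 in
CxB. Effects are additive on the probability scale, so the reciprocal-mean
estimator of theta_p is exactly unbiased whenever the clip is inactive.

Pyro model: the raw percentage is the amplification distortion (odds
multiplication by the assay's gDNA odds, the exact inverse of the
correction) of the per-cross true percentage plus Gaussian noise, clipped to
[0, 100]; correcting then averaging recovers truth in expectation.

Generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import GeneRecord, ICRRecord, KnownRegistry
from .validation import distort_amplification

CLIP = (0.02, 0.98)


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the source-study designs: six biological replicates per
    reciprocal cross, ~1e4 informative reads per gene per replicate, four
    pyrosequencing replicates per cross with ~1.5-point assay noise and a
    modest (55%) primer amplification bias.
    """

    n_genes: int = 100
    n_known_clusters: int = 3
    genes_per_cluster: int = 4
    parental_effect: float = 0.5  # theta_p: true paternal fraction
    strain_effect: float = 0.0  # theta_s: Cast-allele probability shift
    depth: int = 10_000
    n_replicates: int = 6  # per cross
    pyro_noise_sd: float = 1.5  # percentage points
    gdna_bias: float = 55.0  # assay gDNA paternal percent (50 = unbiased)
    pyro_replicates: int = 4  # per cross
    chrom_length: int = 60_000_000
    gene_length: int = 2_000

    def __post_init__(self):
        if not 0.0 <= self.parental_effect <= 1.0:
            raise ValueError("parental_effect must be a fraction in [0,1]")
        if self.depth <= 0 or self.n_replicates <= 0:
            raise ValueError("depth and n_replicates must be positive")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_registry(
    config: SimulationConfig, seed
) -> tuple[KnownRegistry, list[GeneRecord], dict[str, str]]:
    """Generate a known registry plus novel candidates with ground-truth
    class labels.

    Each chromosome holds one known cluster (genes 50 kb apart, a maternal-
    or paternally methylated ICR at its centre) with two class-3 candidates
    within 1 Mb, one class-2 pair 400 kb apart but >2 Mb from the cluster,
    and one class-1 singleton >2 Mb from everything else. Spacing is
    constructed, not sampled, so the truth labels are exact; the seed only
    jitters gene starts within their slots.
    """
    rng = _rng(seed)
    L = config.gene_length
    if config.chrom_length < 20_000_000:
        raise ValueError("chromosome too short for the requested spacing")
    knowns: list[GeneRecord] = []
    candidates: list[GeneRecord] = []
    truth: dict[str, str] = {}
    status: dict[str, str] = {}
    cluster_of: dict[str, str] = {}
    icrs: dict[str, ICRRecord] = {}
    for c in range(config.n_known_clusters):
        chrom = f"chr{c + 1}"
        cluster_id = f"cluster{c + 1}"
        base = 5_000_000 + int(rng.integers(0, 100_000))
        for g in range(config.genes_per_cluster):
            start = base + g * 50_000
            rec = GeneRecord(f"known_{c}_{g}", chrom, start, start + L,
                             strand="+" if g % 2 == 0 else "-")
            knowns.append(rec)
            status[rec.gene_id] = "known"
            cluster_of[rec.gene_id] = cluster_id
            truth[rec.gene_id] = "known"
        span_end = base + config.genes_per_cluster * 50_000
        icrs[cluster_id] = ICRRecord(
            f"icr_{cluster_id}", chrom, base + 10_000, base + 12_000,
            methylated_parent="maternal" if c % 2 == 0 else "paternal",
            cluster_id=cluster_id,
        )
        # two class-3 candidates: one 0.3-0.8 Mb left of the cluster, one right
        for side, off in (("l", -int(rng.integers(300_000, 800_000)) - L),
                          ("r", int(rng.integers(300_000, 800_000)))):
            start = base + off if side == "l" else span_end + off
            rec = GeneRecord(f"class3_{c}_{side}", chrom, start, start + L, strand="+")
            candidates.append(rec)
            truth[rec.gene_id] = "class3"
            cluster_of[rec.gene_id] = cluster_id
        # class-2 pair: 400 kb apart, >2 Mb from anything known
        pair_base = span_end + 4_000_000 + int(rng.integers(0, 100_000))
        for i in range(2):
            start = pair_base + i * 400_000
            rec = GeneRecord(f"class2_{c}_{i}", chrom, start, start + L, strand="-")
            candidates.append(rec)
            truth[rec.gene_id] = "class2"
        # class-1 singleton: >2 Mb beyond the pair
        start = pair_base + 400_000 + 3_000_000 + int(rng.integers(0, 100_000))
        rec = GeneRecord(f"class1_{c}", chrom, start, start + L, strand="+")
        candidates.append(rec)
        truth[rec.gene_id] = "class1"
    for rec in candidates:
        status[rec.gene_id] = "novel"
    registry = KnownRegistry(
        genes=knowns + candidates, status=status, cluster_of=cluster_of, icrs=icrs
    )
    return registry, candidates, truth


def simulate_counts(
    config: SimulationConfig,
    seed,
    gene_effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Replicate-level allele-specific count table for the two crosses.

    ``gene_effects`` may supply per-gene columns ``gene_id``,
    ``parental_effect``, ``strain_effect`` (and optionally ``length``);
    otherwise ``config.n_genes`` genes share the config's effects. Returns
    the long-format table the decomposition consumes, deterministic for a
    fixed seed.
    """
    rng = _rng(seed)
    if gene_effects is None:
        gene_effects = pd.DataFrame(
            {
                "gene_id": [f"g{i:04d}" for i in range(config.n_genes)],
                "parental_effect": config.parental_effect,
                "strain_effect": config.strain_effect,
            }
        )
    if "length" not in gene_effects.columns:
        gene_effects = gene_effects.assign(length=config.gene_length)
    rows = []
    for rec in gene_effects.itertuples(index=False):
        for cross, s in (("BxC", 1.0), ("CxB", -1.0)):
            p = float(np.clip(rec.parental_effect + s * rec.strain_effect, *CLIP))
            pat = rng.binomial(config.depth, p, size=config.n_replicates)
            for rep, k in enumerate(pat, start=1):
                rows.append(
                    {
                        "gene_id": rec.gene_id,
                        "replicate": f"{cross}_r{rep}",
                        "cross": cross,
                        "maternal_reads": int(config.depth - k),
                        "paternal_reads": int(k),
                        "length": int(rec.length),
                    }
                )
    return pd.DataFrame(rows)


def simulate_pyro(
    config: SimulationConfig,
    seed,
    gene_truth: pd.DataFrame | None = None,
    tissues: tuple[str, ...] = ("brain", "liver", "placenta"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pyrosequencing measurement table plus the per-gene truth used.

    ``gene_truth`` may supply ``gene_id``, ``parental_effect``,
    ``strain_effect``, ``rel_expression``; otherwise config-level effects are
    used for ``config.n_genes`` genes with rel_expression 1.0. Raw
    percentages are the amplification-distorted per-cross truths plus
    Gaussian noise, clipped to [0, 100]; the matched gDNA percentage is the
    assay-level ``config.gdna_bias``.
    """
    rng = _rng(seed)
    if gene_truth is None:
        gene_truth = pd.DataFrame(
            {
                "gene_id": [f"g{i:04d}" for i in range(config.n_genes)],
                "parental_effect": config.parental_effect,
                "strain_effect": config.strain_effect,
                "rel_expression": 1.0,
            }
        )
    rows = []
    for rec in gene_truth.itertuples(index=False):
        for tissue in tissues:
            for cross, s in (("BxC", 1.0), ("CxB", -1.0)):
                true_frac = float(np.clip(rec.parental_effect + s * rec.strain_effect, *CLIP))
                distorted = distort_amplification(100.0 * true_frac, config.gdna_bias)
                noise = rng.normal(0.0, config.pyro_noise_sd, size=config.pyro_replicates)
                raw = np.clip(distorted + noise, 0.0, 100.0)
                for rep, val in enumerate(raw, start=1):
                    rows.append(
                        {
                            "gene_id": rec.gene_id,
                            "tissue": tissue,
                            "cross": cross,
                            "replicate": rep,
                            "paternal_pct_raw": float(val),
                            "gdna_paternal_pct": config.gdna_bias,
                            "rel_expression": float(rec.rel_expression),
                            "is_placenta": tissue == "placenta",
                        }
                    )
    return pd.DataFrame(rows), gene_truth
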