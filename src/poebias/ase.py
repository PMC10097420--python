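"""Parental/strain decomposition of allele-specific read counts.

Input is a long-format replicate-level table of maternal/paternal read counts
per gene in the two reciprocal crosses (BxC: B6 dam x Cast sire; CxB the
reverse). Replicates are pooled by summing counts within each cross, the
per-cross paternal percentage is computed, and the pair is rotated into a
parental-origin score (mean over crosses, strain effects cancel) and a strain
score (mean Cast-allele share, parental effects cancel).

A label-flipping permutation test screens for parental effects at the
replicate level. It is a deliberately simple stand-in significance screen;
it does not reimplement any published ASE caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias import paternal_percent_from_reads, reciprocal_mean_paternal, strain_percent
from .errors import UndefinedBiasError

CROSSES = ("BxC", "CxB")

COUNT_COLUMNS = ["gene_id", "replicate", "cross", "maternal_reads", "paternal_reads", "length"]


@dataclass
class AseResult:
    """Per-gene decomposition of allelic expression."""

    gene_id: str
    parental_pct: float  # mean paternal % over crosses
    strain_pct: float  # mean Cast-allele % over crosses
    mean_tpm: float
    n_replicates: dict[str, int]
    permutation_p: float | None = None


def tpm(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Transcripts-per-million from per-gene read counts and lengths in bp.

    Length-normalised rates are rescaled to sum to 1e6. An all-zero count
    vector yields all-zero TPM with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        warnings.warn("all-zero counts: TPM undefined, returning zeros")
        return np.zeros_like(rates)
    return 1e6 * rates / total


def _validate_table(table: pd.DataFrame) -> None:
    missing = set(COUNT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    bad = set(table["cross"].unique()) - set(CROSSES)
    if bad:
        raise ValueError(f"unknown cross labels {sorted(bad)}; expected {CROSSES}")
    if (table[["maternal_reads", "paternal_reads"]] < 0).any().any():
        raise ValueError("negative read counts")


def gene_ase(gene_table: pd.DataFrame, mean_tpm: float = float("nan")) -> AseResult:
    """Decompose one gene's replicate-level counts into parental and strain
    percentages.

    Counts are pooled (summed) across replicates within each cross before the
    per-cross paternal percentage is computed. A cross with zero total reads
    raises :class:`UndefinedBiasError`. ``mean_tpm`` is threaded through from
    the table-level computation (TPM needs the whole library).
    """
    _validate_table(gene_table)
    gids = gene_table["gene_id"].unique()
    if len(gids) != 1:
        raise ValueError(f"gene_ase expects a single gene, got {list(gids)}")
    per_cross = {}
    n_reps = {}
    for cross in CROSSES:
        sub = gene_table[gene_table["cross"] == cross]
        if sub.empty:
            raise UndefinedBiasError(f"{gids[0]}: no replicates in cross {cross}")
        pat = int(sub["paternal_reads"].sum())
        tot = pat + int(sub["maternal_reads"].sum())
        if tot == 0:
            raise UndefinedBiasError(f"{gids[0]}: zero reads in cross {cross}")
        per_cross[cross] = paternal_percent_from_reads(pat, tot)
        n_reps[cross] = len(sub)
    return AseResult(
        gene_id=str(gids[0]),
        parental_pct=reciprocal_mean_paternal(per_cross["BxC"], per_cross["CxB"]),
        strain_pct=strain_percent(per_cross["BxC"], per_cross["CxB"]),
        mean_tpm=mean_tpm,
        n_replicates=n_reps,
    )


def low_count_filter(gene_table: pd.DataFrame, min_reads_per_cross: int = 20) -> bool:
    """Keep (True) iff the pooled total in *each* cross reaches the threshold.

    Below ~20 reads a single read moves the allelic fraction by >= 5 points,
    the failure mode behind spurious weak-bias calls in lowly expressed genes.
    """
    if min_reads_per_cross < 1:
        raise ValueError("min_reads_per_cross must be >= 1")
    for cross in CROSSES:
        sub = gene_table[gene_table["cross"] == cross]
        total = int(sub["maternal_reads"].sum() + sub["paternal_reads"].sum())
        if total < min_reads_per_cross:
            return False
    return True


def permutation_parent_test(
    gene_table: pd.DataFrame,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for a parental-origin effect.

    The statistic is |parental% - 50| computed from replicate-level paternal
    fractions (per-cross replicate mean, then cross mean). The null flips the
    maternal/paternal labels of whole replicates independently (fraction f ->
    1-f), preserving the cross structure. p = (1 + #{perm >= obs}) / (1 +
    n_perm); deterministic for a fixed seed.
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value granularity")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fracs = []
    slices = []
    offset = 0
    for cross in CROSSES:
        sub = gene_table[gene_table["cross"] == cross]
        if len(sub) < 2:
            raise ValueError(f"permutation test needs >=2 replicates per cross ({cross})")
        tot = (sub["maternal_reads"] + sub["paternal_reads"]).to_numpy(float)
        if np.any(tot == 0):
            raise UndefinedBiasError("replicate with zero reads")
        fracs.append(sub["paternal_reads"].to_numpy(float) / tot)
        slices.append(slice(offset, offset + len(sub)))
        offset += len(sub)
    f = np.concatenate(fracs)

    def stat(mat: np.ndarray) -> np.ndarray:
        parental = sum(mat[..., s].mean(axis=-1) for s in slices) / len(slices)
        return np.abs(parental - 0.5)

    observed = float(stat(f[None, :])[0])
    flips = rng.random((n_perm, f.size)) < 0.5
    permuted = np.where(flips, 1.0 - f, f)
    exceed = int(np.sum(stat(permuted) >= observed - 1e-12))
    return (1 + exceed) / (1 + n_perm)


def decompose_table(
    table: pd.DataFrame,
    min_reads_per_cross: int = 20,
    n_perm: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full per-gene decomposition over a replicate-level count table.

    Returns one row per retained gene with parental_pct, strain_pct, mean_tpm
    (mean over replicate libraries of the gene's TPM from summed maternal+
    paternal counts) and, when ``n_perm`` is set, a permutation p-value. Genes
    failing the low-count filter are dropped (column ``kept`` in the attrs).
    """
    _validate_table(table)
    rng = np.random.default_rng(seed)
    # per-replicate TPM over the whole library (both genomes' counts summed)
    table = table.copy()
    table["total"] = table["maternal_reads"] + table["paternal_reads"]
    tpm_per_gene: dict[str, list[float]] = {g: [] for g in table["gene_id"].unique()}
    for (_, _), lib in table.groupby(["cross", "replicate"], sort=True):
        vals = tpm(lib["total"].to_numpy(), lib["length"].to_numpy())
        for g, v in zip(lib["gene_id"], vals):
            tpm_per_gene[g].append(float(v))
    rows = []
    dropped = []
    for gid, sub in table.groupby("gene_id", sort=True):
        if not low_count_filter(sub, min_reads_per_cross):
            dropped.append(gid)
            continue
        res = gene_ase(sub, mean_tpm=float(np.mean(tpm_per_gene[gid])))
        if n_perm is not None:
            res.permutation_p = permutation_parent_test(sub, n_perm=n_perm, seed=rng)
        rows.append(
            {
                "gene_id": res.gene_id,
                "parental_pct": res.parental_pct,
                "strain_pct": res.strain_pct,
                "mean_tpm": res.mean_tpm,
                "n_reps_BxC": res.n_replicates["BxC"],
                "n_reps_CxB": res.n_replicates["CxB"],
                "permutation_p": res.permutation_p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["dropped_low_count"] = dropped
    return out
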