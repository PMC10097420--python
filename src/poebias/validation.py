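"""Pyrosequencing validation calling.

Allele-specific pyrosequencing quantifies the paternal share of transcripts
at a strain-distinguishing SNP. Each assay is corrected for primer
amplification bias against genomic DNA (true 50:50), replicates are averaged
within each reciprocal cross and the two crosses averaged (cancelling strain
effects), and each tissue mean is called against the biallelic window:
above 55% paternally biased, below 45% maternally biased, inside [45, 55]
biallelic. Genes expressed below 0.05x the housekeeping gene Tbp are not
callable (Low expression); genes whose only out-of-window tissue is the
placenta are called Placental.

The amplification correction divides the measured allelic odds by the odds
observed on gDNA. It is the unique correction that is the identity for an
unbiased assay and maps the gDNA measurement itself to exactly 50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .bias import reciprocal_mean_paternal, strain_percent

BIALLELIC_LOW = 45.0
BIALLELIC_HIGH = 55.0
EXPRESSION_GATE = 0.05  # relative to Tbp, strict "lower than"
STRAIN_WINDOW = (45.0, 55.0)

PYRO_COLUMNS = [
    "gene_id", "tissue", "cross", "replicate",
    "paternal_pct_raw", "gdna_paternal_pct", "rel_expression", "is_placenta",
]

CATEGORIES = (
    "Paternal", "Maternal", "Biallelic",
    "Placental_paternal", "Placental_maternal", "Low_expression",
)


@dataclass
class ValidationCall:
    """Categorical validation outcome for one gene."""

    gene_id: str
    category: str
    tissue_means: dict[str, float] = field(default_factory=dict)
    tissue_calls: dict[str, str] = field(default_factory=dict)
    strain_flag: bool = False
    conflict: bool = False


def _odds(pct: float) -> float:
    return pct / (100.0 - pct)


def _clamp(pct: float, label: str) -> float:
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"{label} out of [0,100]: {pct}")
    if pct < 1.0 or pct > 99.0:
        warnings.warn(f"{label}={pct} clamped to [1,99] before odds correction")
        return min(max(pct, 1.0), 99.0)
    return pct


def correct_amplification(paternal_pct_raw: float, gdna_paternal_pct: float) -> float:
    """Correct a raw paternal percentage for assay amplification bias.

    corrected odds = raw odds / gDNA odds; the gDNA sample measured against
    itself corrects to exactly 50, and an unbiased assay (gDNA = 50) leaves
    the measurement unchanged. Values at the 0/100 boundaries are clamped to
    [1, 99] with a warning before forming odds.
    """
    raw = _clamp(paternal_pct_raw, "paternal_pct_raw")
    gdna = _clamp(gdna_paternal_pct, "gdna_paternal_pct")
    o = _odds(raw) / _odds(gdna)
    return 100.0 * o / (1.0 + o)


def distort_amplification(true_pct: float, gdna_paternal_pct: float) -> float:
    """Inverse of :func:`correct_amplification`: what an assay with the given
    gDNA bias would report for a sample whose true paternal share is
    ``true_pct``. Used by the synthetic generator so correction recovers
    truth exactly at zero noise."""
    t = _clamp(true_pct, "true_pct")
    gdna = _clamp(gdna_paternal_pct, "gdna_paternal_pct")
    o = _odds(t) * _odds(gdna)
    return 100.0 * o / (1.0 + o)


def expression_gate(rel_expression: float) -> bool:
    """True (pass) unless expression is strictly below 0.05x Tbp."""
    if rel_expression < 0:
        raise ValueError("relative expression must be nonnegative")
    return rel_expression >= EXPRESSION_GATE


def tissue_mean(measurements: pd.DataFrame) -> float | None:
    """Corrected reciprocal-mean paternal percent for one gene x tissue.

    Expects columns ``cross``, ``paternal_pct_raw``, ``gdna_paternal_pct``.
    Replicates are corrected individually, averaged within each cross, and
    the two cross means averaged. Returns None (a missing tissue value,
    excluded from calling) when either cross is absent.
    """
    per_cross = {}
    for cross, sub in measurements.groupby("cross"):
        corrected = [
            correct_amplification(r, g)
            for r, g in zip(sub["paternal_pct_raw"], sub["gdna_paternal_pct"])
        ]
        per_cross[str(cross)] = float(np.mean(corrected))
    if set(per_cross) != {"BxC", "CxB"}:
        return None
    return reciprocal_mean_paternal(per_cross["BxC"], per_cross["CxB"])


def call_tissue(mean_pct: float) -> str:
    """Direction call for one tissue mean against the biallelic window."""
    if mean_pct > BIALLELIC_HIGH:
        return "paternal"
    if mean_pct < BIALLELIC_LOW:
        return "maternal"
    return "biallelic"


def call_gene(
    gene_id: str,
    tissue_means: Mapping[str, float],
    placenta_tissues: Iterable[str] = ("placenta",),
) -> ValidationCall:
    """Combine per-tissue corrected means into a gene-level validation call.

    Precedence: Low_expression (no callable tissue at all) > Placental_*
    (the only out-of-window tissues are placental) > directional (>=1
    out-of-window somatic tissue) > Biallelic. Somatic tissues called in
    both directions are resolved by majority with a conflict warning; the
    rule is a documented fallback for a case the validation data never
    exercises.
    """
    placenta = set(placenta_tissues)
    means = {t: float(v) for t, v in tissue_means.items() if v is not None and not np.isnan(v)}
    if not means:
        return ValidationCall(gene_id, "Low_expression")
    calls = {t: call_tissue(v) for t, v in means.items()}
    out = {t: c for t, c in calls.items() if c != "biallelic"}
    if not out:
        return ValidationCall(gene_id, "Biallelic", means, calls)
    somatic = {t: c for t, c in out.items() if t not in placenta}
    if not somatic:
        directions = set(out.values())
        conflict = len(directions) > 1
        direction = _majority(gene_id, out, means) if conflict else directions.pop()
        return ValidationCall(gene_id, f"Placental_{direction}", means, calls, conflict=conflict)
    directions = set(somatic.values())
    conflict = len(directions) > 1
    if conflict:
        direction = _majority(gene_id, somatic, means)
    else:
        direction = directions.pop()
    return ValidationCall(gene_id, direction.capitalize(), means, calls, conflict=conflict)


def _majority(gene_id: str, out_calls: dict[str, str], means: dict[str, float]) -> str:
    warnings.warn(f"{gene_id}: tissues called in both directions; using majority")
    n_pat = sum(1 for c in out_calls.values() if c == "paternal")
    n_mat = sum(1 for c in out_calls.values() if c == "maternal")
    if n_pat != n_mat:
        return "paternal" if n_pat > n_mat else "maternal"
    dev = float(np.mean([means[t] - 50.0 for t in out_calls]))
    return "paternal" if dev >= 0 else "maternal"


def strain_flag(strain_percents: Iterable[float]) -> bool:
    """True iff the strain score falls strictly outside 45:55 in more than
    one tissue."""
    lo, hi = STRAIN_WINDOW
    n_out = sum(1 for v in strain_percents if v < lo or v > hi)
    return n_out >= 2


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Full validation pipeline over a replicate-level measurement table.

    Input columns: ``gene_id tissue cross replicate paternal_pct_raw
    gdna_paternal_pct rel_expression is_placenta``. Per gene x tissue the
    expression gate is applied to the mean relative expression; gated-out or
    single-cross tissues contribute no mean. Returns one row per gene with
    the category, the strain-bias flag (computed from per-tissue strain
    scores on corrected per-cross means), and per-tissue means as columns.
    """
    missing = set(PYRO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")
    rows = []
    for gid, gsub in df.groupby("gene_id", sort=True):
        means: dict[str, float] = {}
        strains: list[float] = []
        placenta_tissues = set(gsub.loc[gsub["is_placenta"].astype(bool), "tissue"])
        for tis, tsub in gsub.groupby("tissue"):
            if not expression_gate(float(tsub["rel_expression"].mean())):
                continue
            m = tissue_mean(tsub)
            if m is None:
                continue
            means[str(tis)] = m
            per_cross = {
                str(c): float(
                    np.mean(
                        [
                            correct_amplification(r, g)
                            for r, g in zip(s["paternal_pct_raw"], s["gdna_paternal_pct"])
                        ]
                    )
                )
                for c, s in tsub.groupby("cross")
            }
            strains.append(strain_percent(per_cross["BxC"], per_cross["CxB"]))
        call = call_gene(str(gid), means, placenta_tissues)
        call.strain_flag = strain_flag(strains)
        row = {
            "gene_id": call.gene_id,
            "category": call.category,
            "strain_flag": call.strain_flag,
            "conflict": call.conflict,
        }
        row.update({f"mean_{t}": v for t, v in call.tissue_means.items()})
        rows.append(row)
    return pd.DataFrame(rows)
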