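"""Percent allelic-bias metrics for reciprocal-cross expression data.

Conventions used throughout:

* Percentages are "percent of transcripts from the paternal allele" unless a
  function says otherwise; the maternal percentage is always the complement
  to 100.
* BxC denotes the C57BL/6 dam x CastEiJ sire cross (paternal allele is Cast);
  CxB is the reciprocal. Averaging the paternal percentage over the two
  crosses cancels any expression difference that tracks the strain of the
  allele rather than its parental origin.
* A symmetrised bias lives in [50, 100]: it is the percentage from whichever
  allele is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import MissingCrossError, UndefinedBiasError

BIN_LABELS = ("50-60", "60-70", "70-80", "80-90", "90-100")
CANONICAL_THRESHOLD = 70.0  # strict: canonical iff bias > 70


@dataclass(frozen=True)
class BiasValue:
    """The maximum symmetric bias of a gene and the parent it favours."""

    percent_preferred: float  # in [50, 100]
    preferred_parent: str  # "maternal" | "paternal" | "both" | "none"
    tissue: str = ""
    study: str = ""

    def __post_init__(self):
        if not 50.0 <= self.percent_preferred <= 100.0:
            raise ValueError(f"percent_preferred out of [50,100]: {self.percent_preferred}")
        if self.preferred_parent == "none" and self.percent_preferred != 50.0:
            raise ValueError("preferred_parent='none' requires percent 50")


def paternal_percent_from_reads(paternal_reads: int, total_reads: int) -> float:
    """Percent paternal expression from pooled reciprocal-cross read counts.

    Raises :class:`UndefinedBiasError` when there are no informative reads:
    such a gene must be filtered, never silently reported as 50:50.
    """
    if paternal_reads < 0 or total_reads < 0:
        raise ValueError("read counts must be nonnegative")
    if total_reads == 0:
        raise UndefinedBiasError("zero informative reads: allelic bias undefined")
    if paternal_reads > total_reads:
        raise ValueError("paternal_reads exceeds total_reads")
    return 100.0 * paternal_reads / total_reads


def maternal_percent_from_fold_change(fc: float) -> float:
    """Percent maternal expression from a maternal/paternal fold change.

    Maps fc through fc/(1+fc): 0 -> 0, 1 -> 50, and approaches 100 as the
    fold change grows. Strictly increasing, hence invertible on (0, 100).
    """
    if fc < 0:
        raise ValueError(f"fold change must be nonnegative, got {fc}")
    return 100.0 * fc / (1.0 + fc)


def fold_change_from_maternal_percent(pct: float) -> float:
    """Inverse of :func:`maternal_percent_from_fold_change` on (0, 100)."""
    if not 0 < pct < 100:
        raise ValueError("percent must lie strictly inside (0, 100)")
    return pct / (100.0 - pct)


def _check_pct(value: float, name: str) -> None:
    if value is None:
        raise MissingCrossError(f"{name} missing: both reciprocal crosses required")
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} out of [0,100]: {value}")


def reciprocal_mean_paternal(paternal_pct_bc: float, paternal_pct_cb: float) -> float:
    """Parental-origin score: mean paternal percent over the two reciprocal
    crosses. A pure strain effect enters the two crosses with opposite sign
    and cancels exactly."""
    _check_pct(paternal_pct_bc, "paternal_pct_bc")
    _check_pct(paternal_pct_cb, "paternal_pct_cb")
    return (paternal_pct_bc + paternal_pct_cb) / 2.0


def strain_percent(paternal_pct_bc: float, paternal_pct_cb: float) -> float:
    """Strain score: mean percent of the Cast allele over the two crosses.

    In BxC the paternal allele is Cast; in CxB it is the maternal allele, so
    the Cast share there is the complement. 50 under no strain effect; a pure
    parent-of-origin effect cancels exactly.
    """
    _check_pct(paternal_pct_bc, "paternal_pct_bc")
    _check_pct(paternal_pct_cb, "paternal_pct_cb")
    return (paternal_pct_bc + (100.0 - paternal_pct_cb)) / 2.0


def percents_from_scores(parental_pct: float, strain_pct: float) -> tuple[float, float]:
    """Invert (parental, strain) scores back to per-cross paternal percents.

    The forward map is an invertible linear transform; this reconstruction is
    exact: bc = parental + strain - 50, cb = parental - strain + 50.
    """
    return parental_pct + strain_pct - 50.0, parental_pct - strain_pct + 50.0


def symmetrise(paternal_pct: float) -> tuple[float, str]:
    """Fold a paternal percent onto [50, 100] and name the preferred parent."""
    if not 0.0 <= paternal_pct <= 100.0:
        raise ValueError(f"percent out of [0,100]: {paternal_pct}")
    if paternal_pct > 50.0:
        return paternal_pct, "paternal"
    if paternal_pct < 50.0:
        return 100.0 - paternal_pct, "maternal"
    return 50.0, "none"


def max_bias(paternal_percents: list[float], tissue: str = "", study: str = "") -> BiasValue:
    """Maximum symmetric bias across tissues and the parent it favours.

    Each per-tissue paternal percent is symmetrised to [50, 100]; the maximum
    is reported. If tissues achieving the maximum favour different parents the
    gene is labelled parent="both" (tissue-dependent direction).
    """
    if not paternal_percents:
        raise ValueError("max_bias of an empty list")
    folded = [symmetrise(v) for v in paternal_percents]
    best = max(v for v, _ in folded)
    parents = {p for v, p in folded if v == best and p != "none"}
    if not parents:
        parent = "none"
    elif len(parents) == 1:
        parent = parents.pop()
    else:
        parent = "both"
    return BiasValue(best, parent, tissue=tissue, study=study)


def assign_bin(bias: float) -> str:
    """Assign a symmetric bias in [50, 100] to one of the five 10-point bins.

    Bins are left-closed right-open ([50,60), ..., [80,90)) with the top bin
    closed at 100, so the labels partition [50, 100] exactly.
    """
    if not 50.0 <= bias <= 100.0:
        raise ValueError(f"bias out of [50,100]: {bias}")
    if bias == 100.0:
        return BIN_LABELS[-1]
    return BIN_LABELS[int((bias - 50.0) // 10.0)]


def canonical_flag(bias: float) -> str:
    """'canonical' iff the bias exceeds the 70:30 threshold (strict), else
    'weak'."""
    if not 50.0 <= bias <= 100.0:
        raise ValueError(f"bias out of [50,100]: {bias}")
    return "canonical" if bias > CANONICAL_THRESHOLD else "weak"
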