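"""Co-mutation enrichment statistics.

Per tumor type and composite gene, samples are split into a composite group
(samples carrying a composite mutation in that gene) and a non-composite
group; each candidate co-gene is tested with a two-sided Fisher's exact test
on the 2×2 presence table, selecting co-genes at raw P < 0.05.  A per-stratum
background mutation rate (median per-gene mutation frequency) scaled by 1.04
gives a frequency threshold that normalizes for tumor-type mutation burden.

The module also quantifies the *complementary relationship* — the Pearson
correlation between each co-gene's event frequency in the composite versus
non-composite context — and collapses single-nucleotide substitutions into
the six pyrimidine/adenine-reference classes to form mutation spectra.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .composite_caller import extract_driver_events
from .io_formats import Cohort, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "CoMutationResult",
    "ComplementaryFit",
    "SubstitutionSpectrum",
    "BackgroundRate",
    "EmptyStratumError",
    "ZeroVarianceError",
    "SUBSTITUTION_CLASSES",
    "COMUTATION_RESULT_COLUMNS",
    "fisher_exact",
    "compute_background_rate",
    "test_comutations",
    "complementary_relationship",
    "substitution_spectrum",
]

#: The six collapsed single-nucleotide substitution classes (purine-reference
#: changes are complemented into these).
SUBSTITUTION_CLASSES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

COMUTATION_RESULT_COLUMNS = [
    "tumor_type",
    "composite_gene",
    "co_gene",
    "a",
    "b",
    "c",
    "d",
    "p_value",
    "odds_ratio",
    "freq_composite",
    "freq_noncomposite",
    "passes_background_threshold",
    "significant",
]


class EmptyStratumError(ValidationError):
    """A (tumor type, composite gene) stratum has no composite samples."""


class ZeroVarianceError(ValidationError):
    """A frequency vector is constant; a correlation fit is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 table: co-gene event presence × composite status.

    ``a``/``b``: composite samples with / without the co-gene event;
    ``c``/``d``: non-composite samples with / without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n_composite(self) -> int:
        return self.a + self.b

    @property
    def n_noncomposite(self) -> int:
        return self.c + self.d


@dataclass
class BackgroundRate:
    """Per-stratum background mutation rate and the 1.04× co-mutation
    frequency threshold derived from it."""

    tumor_type: str
    per_gene_frequency: pd.Series
    background_rate: float
    multiplier: float = 1.04

    @property
    def threshold(self) -> float:
        return self.multiplier * self.background_rate


@dataclass
class ComplementaryFit:
    """Pearson fit of composite-context vs non-composite-context co-gene
    frequencies."""

    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    n_pairs: int


@dataclass
class SubstitutionSpectrum:
    """Fractions of single-nucleotide changes over the six collapsed classes."""

    fractions: dict[str, float] = field(default_factory=dict)
    n_snv: int = 0
    n_skipped: int = 0


def fisher_exact(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2×2 table.

    Returns ``(p_value, odds_ratio)``.  The p-value sums hypergeometric
    probabilities of all tables with the observed margins no more probable
    than the observed one.  The odds ratio is the unconditional cross-product
    ratio a·d / b·c, reported as ``inf`` when b·c = 0 with a·d > 0 and ``nan``
    when both products vanish.  A table with an empty composite or
    non-composite margin is rejected; an all-zero presence (or absence)
    column carries no information and yields P = 1.
    """
    t = table
    if t.n_composite == 0 or t.n_noncomposite == 0:
        raise ValidationError("fisher_exact requires both group margins > 0")
    if (t.a + t.c == 0) or (t.b + t.d == 0):
        logger.info("fisher_exact: degenerate column margin, P defined as 1.0")
        p = 1.0
    else:
        _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
        p = float(min(1.0, p))
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    return p, odds


def _mutation_presence(cohort: Cohort, stratum_samples: pd.Index) -> pd.DataFrame:
    """Sample × gene boolean matrix: any mutation record present."""
    mut = cohort.mutations
    mut = mut[mut["sample_id"].isin(stratum_samples)]
    mat = (pd.crosstab(mut["sample_id"], mut["gene"]) > 0).reindex(
        index=stratum_samples,
        columns=sorted(cohort.annotations["symbol"]),
        fill_value=False,
    )
    return mat.astype(bool)


def compute_background_rate(
    cohort: Cohort,
    tumor_type: str,
    statistic: str = "median",
    multiplier: float = 1.04,
) -> BackgroundRate:
    """Background mutation rate of a tumor-type stratum.

    The per-gene frequency is the fraction of the stratum's samples with any
    mutation in that gene; the background rate is by default the median of
    these frequencies over all annotated genes (robust to hypermutated
    outlier genes; ``statistic="mean"`` is available).  The co-mutation
    frequency threshold is ``multiplier``× the background rate, with the
    multiplier fixed at 1.04 by default.
    """
    stratum = cohort.samples_of_type(tumor_type)
    if len(stratum) == 0:
        raise EmptyStratumError(f"tumor type {tumor_type!r} has no samples")
    freq = _mutation_presence(cohort, stratum).mean(axis=0)
    if statistic == "median":
        rate = float(freq.median())
    elif statistic == "mean":
        rate = float(freq.mean())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return BackgroundRate(
        tumor_type=tumor_type,
        per_gene_frequency=freq,
        background_rate=rate,
        multiplier=multiplier,
    )


def test_comutations(
    cohort: Cohort,
    calls: pd.DataFrame,
    composite_gene: str,
    tumor_type: str,
    events: pd.DataFrame | None = None,
    alpha: float = 0.05,
    background_statistic: str = "median",
    background_multiplier: float = 1.04,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Fisher enrichment of co-gene driver events in composite vs
    non-composite samples of one (tumor type, composite gene) stratum.

    Candidate co-genes are genes (other than the composite gene) with a
    driver-level event in at least one composite sample of the stratum.  One
    row per candidate, with the 2×2 counts, two-sided Fisher P, cross-product
    odds ratio, the two group frequencies, a flag for exceeding the
    1.04×background frequency threshold, and the raw-P significance flag.
    With ``bh_correct=True`` an additional ``q_value`` column is added and
    ``significant`` switches to the Benjamini–Hochberg criterion.
    """
    stratum = cohort.samples_of_type(tumor_type)
    if len(stratum) == 0:
        raise EmptyStratumError(f"tumor type {tumor_type!r} has no samples")
    in_stratum = calls["sample_id"].isin(stratum)
    composite_samples = pd.Index(
        sorted(calls.loc[in_stratum & (calls["gene"] == composite_gene), "sample_id"])
    )
    if len(composite_samples) == 0:
        raise EmptyStratumError(
            f"no composite samples for gene {composite_gene!r} in "
            f"tumor type {tumor_type!r}"
        )
    noncomposite_samples = stratum.difference(composite_samples)

    if events is None:
        events = extract_driver_events(cohort)
    ev = events[events["sample_id"].isin(stratum)]
    presence = set(zip(ev["sample_id"], ev["gene"]))
    candidates = sorted(
        set(ev.loc[ev["sample_id"].isin(composite_samples), "gene"])
        - {composite_gene}
    )

    background = compute_background_rate(
        cohort,
        tumor_type,
        statistic=background_statistic,
        multiplier=background_multiplier,
    )

    rows = []
    for co_gene in candidates:
        a = sum((s, co_gene) in presence for s in composite_samples)
        c = sum((s, co_gene) in presence for s in noncomposite_samples)
        table = ContingencyTable(
            a=a,
            b=len(composite_samples) - a,
            c=c,
            d=len(noncomposite_samples) - c,
        )
        p, odds = fisher_exact(table)
        freq_comp = table.a / table.n_composite
        freq_non = (
            table.c / table.n_noncomposite if table.n_noncomposite else float("nan")
        )
        passes = bool(
            background.per_gene_frequency.get(co_gene, 0.0) >= background.threshold
        )
        rows.append(
            (
                tumor_type,
                composite_gene,
                co_gene,
                table.a,
                table.b,
                table.c,
                table.d,
                p,
                odds,
                freq_comp,
                freq_non,
                passes,
                p < alpha,
            )
        )
    out = pd.DataFrame(rows, columns=COMUTATION_RESULT_COLUMNS)
    if bh_correct and len(out):
        order = np.argsort(out["p_value"].to_numpy(), kind="stable")
        m = len(out)
        q = np.empty(m)
        ranked = out["p_value"].to_numpy()[order] * m / np.arange(1, m + 1)
        q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        out["q_value"] = np.minimum(q, 1.0)
        out["significant"] = out["q_value"] < alpha
    return out


def complementary_relationship(results: pd.DataFrame) -> ComplementaryFit:
    """Pearson correlation between co-gene frequencies in the non-composite
    and composite contexts, with the least-squares slope.

    ``results`` must carry ``freq_composite`` and ``freq_noncomposite``
    columns (e.g. the output of :func:`test_comutations`, possibly pooled
    over strata).  Requires ≥3 complete pairs and non-constant vectors.
    """
    pairs = results[["freq_noncomposite", "freq_composite"]].dropna()
    if len(pairs) < 3:
        raise ValidationError(
            f"complementary fit needs >=3 frequency pairs, got {len(pairs)}"
        )
    x = pairs["freq_noncomposite"].to_numpy(float)
    y = pairs["freq_composite"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("a frequency vector has zero variance")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return ComplementaryFit(
        pearson_r=float(r),
        p_value=float(p),
        slope=float(slope),
        intercept=float(intercept),
        n_pairs=int(len(pairs)),
    )


def substitution_spectrum(mutations: pd.DataFrame) -> SubstitutionSpectrum:
    """Collapse single-nucleotide substitutions into the six classes.

    Purine-reference changes are strand-complemented (G>A counts as C>T,
    T>G as A>C) so every substitution falls into one of
    :data:`SUBSTITUTION_CLASSES`.  Non-SNV records (multi-base or non-ACGT
    alleles) are skipped with a count.  Fractions sum to 1 whenever at least
    one SNV exists.
    """
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    n_skipped = 0
    for ref, alt in zip(mutations["ref_allele"], mutations["alt_allele"]):
        ref, alt = str(ref).upper(), str(alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
            n_skipped += 1
            continue
        if ref in ("G", "T"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    n_snv = sum(counts.values())
    fractions = (
        {cls: counts[cls] / n_snv for cls in SUBSTITUTION_CLASSES} if n_snv else {}
    )
    return SubstitutionSpectrum(fractions=fractions, n_snv=n_snv, n_skipped=n_skipped)
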