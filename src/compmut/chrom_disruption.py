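"""Chromosomal-location structure of co-mutations ("chromosysmos").

Co-mutations cluster on the chromosome that carries the composite-mutated
gene.  This module measures that enrichment as the fraction of co-mutation
events located on the composite gene's chromosome, builds per-chromosome
event histograms, and tests the enrichment against a randomization null in
which each true composite gene is replaced by a sham driver gene drawn
uniformly from a candidate pool.

It also provides the genome-normalized inter-gene distance used as the
continuous predictor feature: genes are mapped to a concatenated-genome
coordinate (cumulative chromosome offset + gene midpoint) and distances are
scaled by the total genome distance (3×10⁹ bp by default) and clamped to
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composite_caller import EventPartition, HOTSPOT_MUTATION
from .io_formats import GenomeLayout, ValidationError

__all__ = [
    "SameChromStat",
    "SameChromReport",
    "concatenated_coordinate",
    "normalized_distance",
    "same_chromosome_fraction",
    "per_chromosome_share",
    "randomization_test",
]


@dataclass
class SameChromReport:
    """Observed same-chromosome co-mutation fractions.

    ``pooled_fraction`` counts every (composite call, co-mutation event)
    comparison once; ``per_gene`` gives the fraction per composite gene;
    ``histogram`` counts co-mutation events per chromosome, split into
    mutation vs CNV events.
    """

    pooled_fraction: float
    per_gene: dict[str, float]
    mean_per_gene_fraction: float
    n_comparisons: int
    histogram: pd.DataFrame  # chromosome, comutation_count, cnv_count, is_composite_chromosome


@dataclass
class SameChromStat:
    """Randomization test of same-chromosome co-mutation enrichment."""

    observed_fraction: float
    null_fractions: np.ndarray
    empirical_p: float
    n_iterations: int
    seed: int


def concatenated_coordinate(
    gene: str, annotations: pd.DataFrame, layout: GenomeLayout
) -> float:
    """Concatenated-genome coordinate of a gene: chromosome offset + midpoint."""
    ann = annotations.loc[annotations["symbol"] == gene]
    if len(ann) == 0:
        raise ValidationError(f"gene {gene!r} is not annotated")
    row = ann.iloc[0]
    chrom = row["chromosome"]
    if chrom not in layout:
        raise ValidationError(f"chromosome {chrom!r} of gene {gene!r} not in layout")
    midpoint = (int(row["start"]) + int(row["end"])) / 2.0
    return layout.offsets[chrom] + midpoint


def normalized_distance(
    gene_a: str, gene_b: str, annotations: pd.DataFrame, layout: GenomeLayout
) -> float:
    """Genome-normalized distance between two genes, clamped to [0, 1].

    Distance is |concatenated coordinate difference| / ``layout.normalizer``.
    Identical genes have distance 0; the measure is symmetric.
    """
    ca = concatenated_coordinate(gene_a, annotations, layout)
    cb = concatenated_coordinate(gene_b, annotations, layout)
    return min(1.0, abs(ca - cb) / layout.normalizer)


def _comparisons(
    calls: pd.DataFrame, partition: EventPartition, gene_chrom: pd.Series
) -> pd.DataFrame:
    """One row per (composite call, co-mutation event of the same sample).

    Samples with several composite genes contribute their co-mutation events
    once per composite gene, mirroring the per-composite-gene analyses.
    """
    comut = partition.comutation_events()
    if len(comut) == 0 or len(calls) == 0:
        return pd.DataFrame(
            columns=["sample_id", "composite_gene", "gene", "kind", "chromosome"]
        )
    merged = calls[["sample_id", "gene"]].rename(columns={"gene": "composite_gene"})
    out = merged.merge(comut, on="sample_id", how="inner")
    missing = sorted(set(out["gene"]) - set(gene_chrom.index)) + sorted(
        set(out["composite_gene"]) - set(gene_chrom.index)
    )
    if missing:
        raise ValidationError(f"unannotated gene(s) in events: {missing[:10]}")
    out["chromosome"] = out["gene"].map(gene_chrom)
    return out


def same_chromosome_fraction(
    calls: pd.DataFrame,
    partition: EventPartition,
    annotations: pd.DataFrame,
    layout: GenomeLayout | None = None,
) -> SameChromReport:
    """Fraction of co-mutation events on the composite gene's chromosome.

    Returns pooled (event-weighted) and per-composite-gene fractions plus a
    per-chromosome histogram of co-mutation events, split into mutation and
    CNV events and flagging chromosomes that carry a composite gene.
    """
    gene_chrom = annotations.set_index("symbol")["chromosome"]
    comp = _comparisons(calls, partition, gene_chrom)
    if len(comp) == 0:
        raise ValidationError("no (composite call, co-mutation event) comparisons")

    comp_chrom = comp["composite_gene"].map(gene_chrom)
    same = (comp["chromosome"] == comp_chrom).to_numpy()
    pooled = float(same.mean())
    per_gene = (
        pd.Series(same, index=comp["composite_gene"].to_numpy())
        .groupby(level=0)
        .mean()
        .to_dict()
    )

    comut = partition.comutation_events().copy()
    comut["chromosome"] = comut["gene"].map(gene_chrom)
    is_mut = comut["kind"] == HOTSPOT_MUTATION
    chrom_index = (
        list(layout.names) if layout is not None else sorted(gene_chrom.unique())
    )
    hist = pd.DataFrame(
        {
            "chromosome": chrom_index,
            "comutation_count": [
                int((is_mut & (comut["chromosome"] == c)).sum()) for c in chrom_index
            ],
            "cnv_count": [
                int((~is_mut & (comut["chromosome"] == c)).sum()) for c in chrom_index
            ],
        }
    )
    composite_chroms = set(gene_chrom.reindex(calls["gene"].unique()).dropna())
    hist["is_composite_chromosome"] = hist["chromosome"].isin(composite_chroms)

    return SameChromReport(
        pooled_fraction=pooled,
        per_gene={k: float(v) for k, v in sorted(per_gene.items())},
        mean_per_gene_fraction=float(np.mean(list(per_gene.values()))),
        n_comparisons=int(len(comp)),
        histogram=hist,
    )


def per_chromosome_share(histogram: pd.DataFrame) -> pd.Series:
    """Per-chromosome share of all events in a histogram (sums to 1).

    The mean share over the 24 nuclear chromosomes is 1/24 ≈ 4.2% regardless
    of the event distribution — the per-chromosome expectancy against which
    same-chromosome enrichment is judged.
    """
    totals = histogram["comutation_count"] + histogram["cnv_count"]
    grand = totals.sum()
    if grand == 0:
        raise ValidationError("histogram has no events")
    return pd.Series(
        (totals / grand).to_numpy(), index=histogram["chromosome"].to_numpy()
    )


def randomization_test(
    calls: pd.DataFrame,
    partition: EventPartition,
    annotations: pd.DataFrame,
    candidate_genes: list[str],
    n_iterations: int = 1000,
    seed: int = 0,
) -> SameChromStat:
    """Randomization null for same-chromosome co-mutation enrichment.

    Each iteration replaces every distinct true composite gene with a sham
    gene drawn uniformly without replacement from ``candidate_genes`` and
    recomputes the pooled same-chromosome fraction with the co-mutation
    events held fixed.  The empirical p-value uses the plus-one estimator
    (1 + #{null ≥ observed}) / (1 + n), so it is never zero.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    gene_chrom = annotations.set_index("symbol")["chromosome"]
    comp = _comparisons(calls, partition, gene_chrom)
    if len(comp) == 0:
        raise ValidationError("no (composite call, co-mutation event) comparisons")

    composite_genes = sorted(comp["composite_gene"].unique())
    candidates = sorted(set(candidate_genes))
    missing = sorted(set(candidates) - set(gene_chrom.index))
    if missing:
        raise ValidationError(f"unannotated candidate gene(s): {missing[:10]}")
    if len(candidates) < len(composite_genes):
        raise ValidationError(
            f"{len(candidates)} candidate genes < {len(composite_genes)} "
            "composite genes"
        )

    chrom_codes = {c: i for i, c in enumerate(sorted(gene_chrom.unique()))}
    event_chrom = comp["chromosome"].map(chrom_codes).to_numpy()
    gene_idx = {g: i for i, g in enumerate(composite_genes)}
    event_gene = comp["composite_gene"].map(gene_idx).to_numpy()

    # counts[g, c]: events compared against composite gene g lying on chromosome c
    counts = np.zeros((len(composite_genes), len(chrom_codes)), dtype=np.int64)
    np.add.at(counts, (event_gene, event_chrom), 1)
    total = counts.sum()

    obs_chrom = np.array(
        [chrom_codes[gene_chrom[g]] for g in composite_genes], dtype=np.int64
    )
    observed = counts[np.arange(len(composite_genes)), obs_chrom].sum() / total

    cand_chroms = np.array(
        [chrom_codes[gene_chrom[g]] for g in candidates], dtype=np.int64
    )
    rng = np.random.default_rng(seed)
    null = np.empty(n_iterations)
    k = len(composite_genes)
    for i in range(n_iterations):
        sham = rng.choice(len(candidates), size=k, replace=False)
        null[i] = counts[np.arange(k), cand_chroms[sham]].sum() / total

    p = (1 + int((null >= observed).sum())) / (1 + n_iterations)
    return SameChromStat(
        observed_fraction=float(observed),
        null_fractions=null,
        empirical_p=float(p),
        n_iterations=n_iterations,
        seed=seed,
    )
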