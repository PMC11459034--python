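"""Driver-event extraction and composite-mutation calling.

A *driver-level event* is either a hotspot mutation (a protein change present
in the cohort's hotspot catalog) or a high-level copy-number call (deep
deletion −2 or high-level amplification +2).  A gene in a sample carries a
*composite mutation* when it accumulates at least two independent driver-level
events if it is an oncogene, or at least three if it is a tumor suppressor —
the footprint of repeated independent genetic hits on the same gene.

Within a composite-bearing sample, the remaining driver-level events in other
genes are its *co-mutations*; mutations below the driver level (non-hotspot
protein changes, |CNV| < 2) are *background*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Cohort, ONCOGENE, TUMOR_SUPPRESSOR, ValidationError

__all__ = [
    "HOTSPOT_MUTATION",
    "DEEP_DELETION",
    "HIGH_AMPLIFICATION",
    "COMPOSITE_THRESHOLDS",
    "EVENT_COLUMNS",
    "CALL_COLUMNS",
    "EventPartition",
    "PrevalenceReport",
    "extract_driver_events",
    "call_composites",
    "partition_events",
    "composite_prevalence",
]

HOTSPOT_MUTATION = "hotspot_mutation"
DEEP_DELETION = "deep_deletion"
HIGH_AMPLIFICATION = "high_amplification"

#: Minimum number of independent driver-level events per gene for a composite
#: call: two for an oncogene, three for a tumor suppressor.
COMPOSITE_THRESHOLDS: dict[str, int] = {ONCOGENE: 2, TUMOR_SUPPRESSOR: 3}

EVENT_COLUMNS = ["sample_id", "gene", "kind", "detail"]
CALL_COLUMNS = ["sample_id", "gene", "role", "n_events", "events"]


@dataclass
class EventPartition:
    """Per-sample partition of a composite-bearing sample's record classes.

    ``events`` covers all driver-level events of composite-bearing samples
    with ``event_class`` ∈ {"composite", "comutation"}; ``background`` holds
    the same samples' non-driver mutation records and sub-threshold CNV calls.
    The classes are disjoint by construction.
    """

    events: pd.DataFrame  # EVENT_COLUMNS + ["event_class"]
    background_mutations: pd.DataFrame
    background_cnvs: pd.DataFrame

    def comutation_events(self) -> pd.DataFrame:
        return self.events[self.events["event_class"] == "comutation"]

    def composite_events(self) -> pd.DataFrame:
        return self.events[self.events["event_class"] == "composite"]


@dataclass
class PrevalenceReport:
    """Composite-mutation prevalence, overall and per gene × tumor type."""

    overall: float
    n_composite_samples: int
    n_samples: int
    by_gene_tumor_type: pd.DataFrame  # genes × tumor types, composite case counts
    by_tumor_type: pd.Series  # per tumor type, fraction of samples affected


def extract_driver_events(cohort: Cohort) -> pd.DataFrame:
    """Return one row per driver-level event: hotspot mutations and ±2 CNVs.

    Mutations whose protein change is absent from the hotspot catalog yield no
    event; CNV calls in {−1, 0, 1} yield no event.  Events are distinct
    ``(sample_id, gene, kind, detail)`` tuples, sorted for determinism.
    """
    if len(cohort.hotspots) == 0:
        raise ValidationError("hotspot catalog is empty; cannot extract driver events")

    frames: list[pd.DataFrame] = []
    mut = cohort.mutations
    if len(mut):
        is_hotspot = [
            (g, p) in cohort.hotspots
            for g, p in zip(mut["gene"], mut["protein_change"])
        ]
        hs = mut.loc[is_hotspot, ["sample_id", "gene", "protein_change"]].copy()
        hs["kind"] = HOTSPOT_MUTATION
        hs = hs.rename(columns={"protein_change": "detail"})
        frames.append(hs[EVENT_COLUMNS])

    cnv = cohort.cnvs
    if len(cnv):
        driver_cnv = cnv[cnv["call"].abs() == 2].copy()
        driver_cnv["kind"] = np.where(
            driver_cnv["call"] == -2, DEEP_DELETION, HIGH_AMPLIFICATION
        )
        driver_cnv["detail"] = driver_cnv["call"].astype(str)
        frames.append(driver_cnv[EVENT_COLUMNS])

    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    events = pd.concat(frames, ignore_index=True)
    events = events.drop_duplicates().sort_values(EVENT_COLUMNS, kind="stable")
    return events.reset_index(drop=True)


def call_composites(events: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Call composite mutations from driver-level events.

    A call is emitted for each ``(sample, gene)`` whose distinct driver-event
    count meets the gene role's threshold (oncogene ≥ 2, tumor suppressor
    ≥ 3).  Output is sorted by (sample_id, gene); ``events`` serializes the
    contributing events as ``kind:detail`` joined with ``;``.
    """
    if len(events) == 0:
        return pd.DataFrame(columns=CALL_COLUMNS)
    role_of = annotations.set_index("symbol")["role"]
    unknown = sorted(set(events["gene"]) - set(role_of.index))
    if unknown:
        raise ValidationError(f"driver events in genes without a role: {unknown[:10]}")

    ev = events.sort_values(EVENT_COLUMNS, kind="stable")
    grouped = ev.groupby(["sample_id", "gene"], sort=True)
    rows = []
    for (sample_id, gene), grp in grouped:
        role = role_of[gene]
        n = len(grp)
        if n >= COMPOSITE_THRESHOLDS[role]:
            serialized = ";".join(
                f"{k}:{d}" for k, d in zip(grp["kind"], grp["detail"])
            )
            rows.append((sample_id, gene, role, n, serialized))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def partition_events(
    cohort: Cohort, calls: pd.DataFrame, events: pd.DataFrame | None = None
) -> EventPartition:
    """Partition composite-bearing samples' records into the three classes.

    Only samples with at least one composite call appear (co-mutations are
    defined only in the presence of a composite mutation).  For those samples,
    driver-level events in composite genes are ``composite``; driver-level
    events in any other gene are ``comutation``; everything else (non-hotspot
    mutations, CNV calls with |call| < 2) is background.
    """
    if events is None:
        events = extract_driver_events(cohort)
    if len(calls) == 0:
        empty = pd.DataFrame(columns=EVENT_COLUMNS + ["event_class"])
        return EventPartition(
            events=empty,
            background_mutations=cohort.mutations.iloc[0:0],
            background_cnvs=cohort.cnvs.iloc[0:0],
        )

    bearing = set(calls["sample_id"])
    composite_pairs = set(zip(calls["sample_id"], calls["gene"]))

    ev = events[events["sample_id"].isin(bearing)].copy()
    in_composite_gene = [
        (s, g) in composite_pairs for s, g in zip(ev["sample_id"], ev["gene"])
    ]
    ev["event_class"] = np.where(in_composite_gene, "composite", "comutation")

    mut = cohort.mutations
    mut = mut[mut["sample_id"].isin(bearing)]
    is_hotspot = [
        (g, p) in cohort.hotspots for g, p in zip(mut["gene"], mut["protein_change"])
    ]
    background_mut = mut.loc[[not h for h in is_hotspot]].reset_index(drop=True)

    cnv = cohort.cnvs
    background_cnv = cnv[
        cnv["sample_id"].isin(bearing) & (cnv["call"].abs() < 2)
    ].reset_index(drop=True)

    return EventPartition(
        events=ev.reset_index(drop=True),
        background_mutations=background_mut,
        background_cnvs=background_cnv,
    )


def composite_prevalence(calls: pd.DataFrame, cohort: Cohort) -> PrevalenceReport:
    """Fraction of samples carrying ≥1 composite call, with a gene × tumor
    type case-count matrix."""
    n_samples = len(cohort.samples)
    if n_samples == 0:
        raise ValidationError("empty cohort")
    tt = cohort.tumor_type_of()
    tumor_types = sorted(tt.unique())

    if len(calls) == 0:
        matrix = pd.DataFrame(index=pd.Index([], name="gene"), columns=tumor_types)
        by_tt = pd.Series(0.0, index=tumor_types)
        return PrevalenceReport(0.0, 0, n_samples, matrix.fillna(0), by_tt)

    carriers = calls["sample_id"].unique()
    with_tt = calls.assign(tumor_type=calls["sample_id"].map(tt))
    matrix = (
        with_tt.groupby(["gene", "tumor_type"])["sample_id"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=tumor_types, fill_value=0)
        .sort_index()
    )
    per_tt_carriers = (
        pd.Series(list(tt[carriers]), index=carriers).value_counts()
        if len(carriers)
        else pd.Series(dtype=int)
    )
    totals = tt.value_counts()
    by_tt = (per_tt_carriers.reindex(tumor_types, fill_value=0) / totals).fillna(0.0)
    return PrevalenceReport(
        overall=len(carriers) / n_samples,
        n_composite_samples=int(len(carriers)),
        n_samples=int(n_samples),
        by_gene_tumor_type=matrix,
        by_tumor_type=by_tt,
    )
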