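"""Synthetic tumor cohorts with planted composite-mutation structure.

The generator emulates the statistical structure the analyses assume:

- tumor-type strata with their own background mutation rates;
- composite-mutation carriers at a configurable prevalence (default 5%),
  each given the role-appropriate driver-event set (exactly 2 for an
  oncogene, 3 for a tumor suppressor; one event may be a ±2 CNV);
- *association channel*: designated co-genes whose driver-event odds are
  multiplied by a planted odds ratio in carriers;
- *location channel*: additional co-mutation events in carriers whose gene
  is drawn on the carrier's composite-gene chromosome with probability
  ``same_chrom_prob`` (default 0.35), else uniformly elsewhere;
- driver-event noise at a low uniform rate, sub-driver CNV noise (±1), and
  non-hotspot background mutations with a C>T-heavy substitution spectrum.

Every run returns the emitted :class:`~compmut.io_formats.Cohort` together
with a :class:`GroundTruth` that records what was planted, closing the loop
for parameter-recovery tests (prevalence, odds ratios, same-chromosome
fraction, predictability).

The default gene panel places three synthetic driver genes on each of the 24
nuclear chromosomes (GRCh38-proportional lengths) plus five well-known driver
genes at their approximate GRCh38 loci, so concatenated-genome distances and
per-chromosome expectancies are exercised realistically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    Cohort,
    GenomeLayout,
    HotspotCatalog,
    NUCLEAR_CHROMOSOMES,
    ONCOGENE,
    TUMOR_SUPPRESSOR,
    ValidationError,
    load_cohort,
    write_cnv_matrix,
    write_gene_annotations,
    write_genome_layout,
    write_hotspots,
    write_maf,
    write_sample_table,
)

__all__ = [
    "GRCH38_CHROMOSOME_LENGTHS",
    "TumorTypeSpec",
    "SimConfig",
    "GroundTruth",
    "default_layout",
    "build_panel",
    "generate_cohort",
    "generate_null_cohort",
    "write_fixture_bundle",
    "load_fixture_bundle",
]

#: GRCh38 primary-assembly chromosome lengths (bp).
GRCH38_CHROMOSOME_LENGTHS: dict[str, int] = {
    "1": 248_956_422,
    "2": 242_193_529,
    "3": 198_295_559,
    "4": 190_214_555,
    "5": 181_538_259,
    "6": 170_805_979,
    "7": 159_345_973,
    "8": 145_138_636,
    "9": 138_394_717,
    "10": 133_797_422,
    "11": 135_086_622,
    "12": 133_275_309,
    "13": 114_364_328,
    "14": 107_043_718,
    "15": 101_991_189,
    "16": 90_338_345,
    "17": 83_257_441,
    "18": 80_373_285,
    "19": 58_617_616,
    "20": 64_444_167,
    "21": 46_709_983,
    "22": 50_818_468,
    "X": 156_040_895,
    "Y": 57_227_415,
}

# approximate GRCh38 loci of the named driver genes in the demo panel
_NAMED_GENES: list[tuple[str, str, str, int, int, tuple[str, ...]]] = [
    ("BRAF", ONCOGENE, "7", 140_719_327, 140_924_929, ("V600E", "V600M", "K601E")),
    ("EGFR", ONCOGENE, "7", 55_019_017, 55_211_628, ("T790M", "L858R", "G719A")),
    ("KRAS", ONCOGENE, "12", 25_205_246, 25_250_929, ("G12D", "G12V", "G13D")),
    ("PIK3CA", ONCOGENE, "3", 179_148_114, 179_240_093, ("E545K", "H1047R", "E542K")),
    ("TP53", TUMOR_SUPPRESSOR, "17", 7_668_402, 7_687_550, ("R175H", "R248Q", "R273H")),
]

_PYRIMIDINE_CLASSES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class TumorTypeSpec:
    """One tumor-type stratum: size and per-gene background mutation
    probability per sample."""

    name: str
    n_samples: int
    background_mutation_rate: float

    def __post_init__(self) -> None:
        if self.n_samples < 0 or not 0 <= self.background_mutation_rate <= 1:
            raise ValidationError(f"invalid tumor type spec {self.name!r}")


def _default_tumor_types() -> tuple[TumorTypeSpec, ...]:
    return (
        TumorTypeSpec("lung", 600, 0.015),
        TumorTypeSpec("skin", 500, 0.020),
        TumorTypeSpec("breast", 500, 0.010),
        TumorTypeSpec("bowel", 400, 0.015),
    )


def _default_comut_effects() -> dict[str, float]:
    # six co-genes with a planted odds ratio of 8 for driver events in carriers
    return {g: 8.0 for g in ("G1_1", "G3_2", "G7_1", "G9_1", "G12_1", "G17_1")}


def _default_substitution_weights() -> dict[str, float]:
    # C>T-dominated spectrum, as in most solid-tumor cohorts
    return {
        "C>T": 0.45,
        "C>A": 0.12,
        "C>G": 0.08,
        "A>G": 0.15,
        "A>T": 0.10,
        "A>C": 0.10,
    }


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults are the emulated study conditions.

    ``composite_prevalence`` defaults to 0.05 (≈5% of patients carry a
    composite mutation) and ``same_chrom_prob`` to 0.35 (≈35% of planted
    co-mutations placed on the composite gene's chromosome).  ``comut_effects``
    maps co-genes to the planted odds ratio of their driver event in carriers
    versus non-carriers (baseline probability ``comut_base_prob``).
    ``comut_rate`` is the Poisson mean of location-channel co-mutation events
    per carrier.  ``cnv_driver_prob`` is the chance a planted driver event
    materializes as a ±2 CNV rather than a hotspot mutation.
    """

    seed: int = 0
    tumor_types: tuple[TumorTypeSpec, ...] = field(
        default_factory=_default_tumor_types
    )
    genes_per_chromosome: int = 3
    composite_genes: tuple[str, ...] = ("BRAF", "EGFR", "KRAS", "PIK3CA")
    composite_prevalence: float = 0.05
    comut_effects: dict[str, float] = field(default_factory=_default_comut_effects)
    comut_base_prob: float = 0.10
    comut_rate: float = 4.0
    same_chrom_prob: float = 0.35
    cnv_driver_prob: float = 0.25
    driver_noise_prob: float = 0.02
    cnv_noise_prob: float = 0.02
    substitution_weights: dict[str, float] = field(
        default_factory=_default_substitution_weights
    )
    normalizer: float = 3_000_000_000.0

    def __post_init__(self) -> None:
        for name, p in (
            ("composite_prevalence", self.composite_prevalence),
            ("comut_base_prob", self.comut_base_prob),
            ("same_chrom_prob", self.same_chrom_prob),
            ("cnv_driver_prob", self.cnv_driver_prob),
            ("driver_noise_prob", self.driver_noise_prob),
            ("cnv_noise_prob", self.cnv_noise_prob),
        ):
            if not 0 <= p <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if any(odds <= 0 for odds in self.comut_effects.values()):
            raise ValidationError("planted odds ratios must be positive")
        if self.genes_per_chromosome < 1:
            raise ValidationError("need at least one gene per chromosome")
        bad = set(self.substitution_weights) - set(_PYRIMIDINE_CLASSES)
        if bad:
            raise ValidationError(f"unknown substitution class(es): {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return sum(t.n_samples for t in self.tumor_types)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tumor_types"] = [dataclasses.asdict(t) for t in self.tumor_types]
        return d


@dataclass
class GroundTruth:
    """What the generator planted, record-consistent with the cohort."""

    carriers: pd.DataFrame  # sample_id, gene, role, n_events
    prevalence_planted: float
    same_chrom_prob: float | None  # None for the uniform (null) placement
    comut_effects: dict[str, float]
    n_driver_events: int
    n_location_events: int
    n_location_same_chrom: int
    comutation_counts: pd.Series  # planted co-mutation events per carrier sample
    is_null: bool

    def to_dict(self) -> dict:
        return {
            "carriers": self.carriers.to_dict(orient="list"),
            "prevalence_planted": self.prevalence_planted,
            "same_chrom_prob": self.same_chrom_prob,
            "comut_effects": dict(sorted(self.comut_effects.items())),
            "n_driver_events": self.n_driver_events,
            "n_location_events": self.n_location_events,
            "n_location_same_chrom": self.n_location_same_chrom,
            "comutation_counts": {
                k: int(v) for k, v in sorted(self.comutation_counts.items())
            },
            "is_null": self.is_null,
            "n_samples": int(len(self.comutation_counts)),
        }


def default_layout(normalizer: float = 3_000_000_000.0) -> GenomeLayout:
    """24 nuclear chromosomes with GRCh38 lengths, 3×10⁹ distance normalizer."""
    return GenomeLayout(
        tuple((c, GRCH38_CHROMOSOME_LENGTHS[c]) for c in NUCLEAR_CHROMOSOMES),
        normalizer=normalizer,
    )


def build_panel(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GenomeLayout]:
    """Deterministic gene panel: annotations, hotspot table, genome layout.

    Three (configurable) synthetic genes per chromosome named ``G<chrom>_<k>``
    with three hotspot protein changes each, plus the five named driver genes.
    Roughly two-thirds of synthetic genes are oncogenes.
    """
    layout = default_layout(config.normalizer)
    rows = []
    hotspot_rows = []
    for name, role, chrom, start, end, hotspots in _NAMED_GENES:
        rows.append((name, role, chrom, start, end))
        hotspot_rows += [(name, h) for h in hotspots]
    for ci, chrom in enumerate(NUCLEAR_CHROMOSOMES):
        length = GRCH38_CHROMOSOME_LENGTHS[chrom]
        for k in range(config.genes_per_chromosome):
            symbol = f"G{chrom}_{k + 1}"
            start = int(length * (k + 0.5) / (config.genes_per_chromosome + 1))
            end = start + 100_000
            role = TUMOR_SUPPRESSOR if (ci + k) % 3 == 0 else ONCOGENE
            rows.append((symbol, role, chrom, start, end))
            hotspot_rows += [(symbol, f"A{100 + j}T") for j in range(3)]
    annotations = pd.DataFrame(
        rows, columns=["symbol", "role", "chromosome", "start", "end"]
    )
    hotspot_table = pd.DataFrame(hotspot_rows, columns=["gene", "protein_change"])
    missing = set(config.composite_genes) - set(annotations["symbol"])
    if missing:
        raise ValidationError(f"composite gene(s) not in panel: {sorted(missing)}")
    missing = set(config.comut_effects) - set(annotations["symbol"])
    if missing:
        raise ValidationError(
            f"planted-effect gene(s) not in panel: {sorted(missing)}"
        )
    return annotations, hotspot_table, layout


def _draw_substitution(rng: np.random.Generator, weights: dict[str, float]) -> tuple[str, str]:
    classes = sorted(weights)
    w = np.array([weights[c] for c in classes], float)
    cls = classes[rng.choice(len(classes), p=w / w.sum())]
    ref, alt = cls.split(">")
    if rng.random() < 0.5:  # emit the purine-strand representation half the time
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def generate_cohort(
    config: SimConfig, null: bool = False
) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and its planted ground truth.

    With ``null=True`` all planted odds ratios are forced to 1 and
    location-channel genes are drawn uniformly over the eligible driver genes
    regardless of chromosome (the uniform-gene null).  Fully reproducible from
    ``config.seed``.
    """
    annotations, hotspot_table, layout = build_panel(config)
    hotspots = HotspotCatalog.from_pairs(
        zip(hotspot_table["gene"], hotspot_table["protein_change"])
    )
    genes = list(annotations["symbol"])
    gene_index = {g: i for i, g in enumerate(genes)}
    gene_role = dict(zip(annotations["symbol"], annotations["role"]))
    gene_chrom = dict(zip(annotations["symbol"], annotations["chromosome"]))
    gene_span = {
        g: (int(s), int(e))
        for g, s, e in zip(
            annotations["symbol"], annotations["start"], annotations["end"]
        )
    }
    gene_hotspots = {
        g: list(grp["protein_change"])
        for g, grp in hotspot_table.groupby("gene", sort=True)
    }

    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    if n == 0:
        raise ValidationError("config defines no samples")
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    tumor_type = np.concatenate(
        [np.full(t.n_samples, t.name, dtype=object) for t in config.tumor_types]
    )
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "tumor_type": tumor_type, "source": "tissue"}
    )

    # --- composite carriers -------------------------------------------------
    carrier = rng.random(n) < config.composite_prevalence
    comp_choice = rng.integers(0, len(config.composite_genes), size=n)
    carrier_gene = np.where(
        carrier, np.array(config.composite_genes, object)[comp_choice], None
    )
    if config.composite_prevalence > 0 and not carrier.any():
        import warnings

        warnings.warn("no composite carriers drawn; cohort may be too small")

    # --- non-composite driver-event presence (association + noise) ----------
    effects = {g: (1.0 if null else odds) for g, odds in config.comut_effects.items()}
    presence = np.zeros((n, len(genes)), dtype=bool)
    for g in sorted(effects):
        p0 = config.comut_base_prob
        odds = effects[g]
        p1 = odds * p0 / (1 - p0 + odds * p0)
        p = np.where(carrier, p1, p0)
        presence[:, gene_index[g]] = rng.random(n) < p
    noise_cols = [gene_index[g] for g in genes if g not in effects]
    if config.driver_noise_prob > 0 and noise_cols:
        noise = rng.random((n, len(noise_cols))) < config.driver_noise_prob
        presence[:, noise_cols] |= noise

    # --- location channel ----------------------------------------------------
    # Every sample draws the same Poisson co-mutation budget, so presence is
    # label-independent under the null; carrier status only biases *placement*
    # (probability same_chrom_prob on the carrier's composite chromosome).
    eligible = [
        g
        for g in genes
        if g not in config.composite_genes and g not in effects
    ]
    by_chrom: dict[str, list[str]] = {}
    for g in eligible:
        by_chrom.setdefault(gene_chrom[g], []).append(g)
    all_pool = np.array(sorted(eligible), dtype=object)
    n_location = 0
    n_location_same = 0
    carrier_idx = np.flatnonzero(carrier)
    budgets = rng.poisson(config.comut_rate, size=n)
    for i in range(n):
        k = int(budgets[i])
        if k == 0:
            continue
        directed = carrier[i] and not null
        if directed:
            own_chrom = gene_chrom[carrier_gene[i]]
            same_pool = by_chrom.get(own_chrom, [])
            other_pool = [
                g for c, gs in sorted(by_chrom.items()) if c != own_chrom for g in gs
            ]
            n_same = min(int(rng.binomial(k, config.same_chrom_prob)), len(same_pool))
            n_other = min(k - n_same, len(other_pool))
            chosen = list(
                np.array(same_pool, object)[
                    rng.choice(len(same_pool), size=n_same, replace=False)
                ]
            ) + list(
                np.array(other_pool, object)[
                    rng.choice(len(other_pool), size=n_other, replace=False)
                ]
            )
        else:
            chosen = list(
                all_pool[rng.choice(len(all_pool), size=min(k, len(all_pool)), replace=False)]
            )
        for g in chosen:
            j = gene_index[g]
            if not presence[i, j]:
                presence[i, j] = True
                if carrier[i]:
                    n_location += 1
                    if gene_chrom[g] == gene_chrom[carrier_gene[i]]:
                        n_location_same += 1

    # a carrier's own composite gene is populated by the composite channel only
    for i in carrier_idx:
        presence[i, gene_index[carrier_gene[i]]] = False

    # --- materialize events --------------------------------------------------
    mut_rows: list[tuple] = []
    cnv_calls = np.zeros((n, len(genes)), dtype=np.int8)

    def add_hotspot(i: int, g: str, protein_change: str) -> None:
        start, end = gene_span[g]
        offset = gene_hotspots[g].index(protein_change)
        pos = min(start + 1000 * (offset + 1), end)
        ref, alt = _draw_substitution(rng, config.substitution_weights)
        mut_rows.append(
            (sample_ids[i], g, protein_change, gene_chrom[g], pos, ref, alt)
        )

    carrier_records: list[tuple] = []
    n_composite_events = 0
    for i in carrier_idx:
        g = carrier_gene[i]
        role = gene_role[g]
        n_events = 2 if role == ONCOGENE else 3
        hs = list(gene_hotspots[g])
        use_cnv = rng.random() < config.cnv_driver_prob
        n_hot = n_events - int(use_cnv)
        chosen_hs = list(
            np.array(hs, object)[rng.choice(len(hs), size=n_hot, replace=False)]
        )
        for pc in chosen_hs:
            add_hotspot(i, g, pc)
        if use_cnv:
            cnv_calls[i, gene_index[g]] = 2 if role == ONCOGENE else -2
        carrier_records.append((sample_ids[i], g, role, n_events))
        n_composite_events += n_events

    n_presence_events = 0
    for i, j in zip(*np.nonzero(presence)):
        g = genes[j]
        n_presence_events += 1
        if rng.random() < config.cnv_driver_prob:
            cnv_calls[i, j] = 2 if gene_role[g] == ONCOGENE else -2
        else:
            pc = gene_hotspots[g][rng.integers(0, len(gene_hotspots[g]))]
            add_hotspot(i, g, pc)

    # --- sub-driver CNV noise (±1) and background mutations ------------------
    if config.cnv_noise_prob > 0:
        noise_mask = (rng.random((n, len(genes))) < config.cnv_noise_prob) & (
            cnv_calls == 0
        )
        signs = rng.choice(np.array([-1, 1], dtype=np.int8), size=noise_mask.sum())
        cnv_calls[noise_mask] = signs

    bg_rate = np.concatenate(
        [
            np.full(t.n_samples, t.background_mutation_rate)
            for t in config.tumor_types
        ]
    )
    bg = rng.random((n, len(genes))) < bg_rate[:, None]
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for i, j in zip(*np.nonzero(bg)):
        g = genes[j]
        start, end = gene_span[g]
        pos = int(rng.integers(start, end + 1))
        # protein positions >= 2000 never collide with catalog hotspots
        pc = f"{aa[rng.integers(0, 20)]}{2000 + int(rng.integers(0, 999))}{aa[rng.integers(0, 20)]}"
        ref, alt = _draw_substitution(rng, config.substitution_weights)
        mut_rows.append((sample_ids[i], g, pc, gene_chrom[g], pos, ref, alt))

    mutations = pd.DataFrame(
        mut_rows,
        columns=[
            "sample_id",
            "gene",
            "protein_change",
            "chromosome",
            "position",
            "ref_allele",
            "alt_allele",
        ],
    )
    cnvs = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, len(genes)),
            "gene": np.tile(genes, n),
            "call": cnv_calls.ravel().astype(int),
        }
    )

    cohort = load_cohort(
        maf=mutations.sort_values(
            ["sample_id", "gene", "protein_change"], kind="stable"
        ).reset_index(drop=True),
        cnv=cnvs.sort_values(["sample_id", "gene"], kind="stable").reset_index(
            drop=True
        ),
        annotations=annotations.sort_values("symbol", kind="stable").reset_index(
            drop=True
        ),
        hotspots=hotspots,
        samples=samples.sort_values("sample_id", kind="stable").reset_index(drop=True),
        layout=layout,
    )

    comut_counts = pd.Series(
        presence.sum(axis=1), index=pd.Index(sample_ids, name="sample_id")
    )
    truth = GroundTruth(
        carriers=pd.DataFrame(
            carrier_records, columns=["sample_id", "gene", "role", "n_events"]
        ).sort_values("sample_id", kind="stable").reset_index(drop=True),
        prevalence_planted=config.composite_prevalence,
        same_chrom_prob=None if null else config.same_chrom_prob,
        comut_effects=effects,
        n_driver_events=n_composite_events + n_presence_events,
        n_location_events=n_location,
        n_location_same_chrom=n_location_same,
        comutation_counts=comut_counts,
        is_null=null,
    )
    return cohort, truth


def generate_null_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Cohort with no planted association (all odds ratios 1) and uniform
    co-mutation gene placement; for type-I-error and null-AUC properties."""
    return generate_cohort(config, null=True)


def write_fixture_bundle(
    cohort: Cohort, truth: GroundTruth, directory: str | Path
) -> dict[str, Path]:
    """Write a cohort + truth bundle as plain TSV/JSON, readable by the
    io layer; byte-identical across runs for a fixed config and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "maf": directory / "mutations.maf.tsv",
        "cnv": directory / "cnv_matrix.tsv",
        "annotations": directory / "annotations.tsv",
        "hotspots": directory / "hotspots.tsv",
        "samples": directory / "samples.tsv",
        "layout": directory / "layout.tsv",
        "truth": directory / "truth.json",
    }
    write_maf(cohort.mutations, paths["maf"])
    write_cnv_matrix(cohort.cnvs, paths["cnv"])
    write_gene_annotations(cohort.annotations, paths["annotations"])
    write_hotspots(cohort.hotspots, paths["hotspots"])
    write_sample_table(cohort.samples, paths["samples"])
    write_genome_layout(cohort.layout, paths["layout"])
    paths["truth"].write_text(
        json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return paths


def load_fixture_bundle(directory: str | Path) -> tuple[Cohort, dict]:
    """Read back a bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    cohort = load_cohort(
        maf=directory / "mutations.maf.tsv",
        cnv=directory / "cnv_matrix.tsv",
        annotations=directory / "annotations.tsv",
        hotspots=directory / "hotspots.tsv",
        samples=directory / "samples.tsv",
        layout=directory / "layout.tsv",
    )
    truth = json.loads((directory / "truth.json").read_text())
    return cohort, truth
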