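"""Shared fixtures: a tiny hand-built cohort and synthetic-cohort factories."""

from __future__ import annotations

import pandas as pd
import pytest

from compmut.io_formats import GenomeLayout, HotspotCatalog, load_cohort
from compmut.synthetic_data import SimConfig, TumorTypeSpec, default_layout


@pytest.fixture(scope="session")
def toy_layout() -> GenomeLayout:
    """Three 1-Gb chromosomes; total genome = normalizer = 3 Gb."""
    return GenomeLayout(
        (("1", 1_000_000_000), ("2", 1_000_000_000), ("3", 1_000_000_000))
    )


def _demo_frames():
    annotations = pd.DataFrame(
        [
            ("BRAF", "oncogene", "7", 140_719_327, 140_924_929),
            ("EGFR", "oncogene", "7", 55_019_017, 55_211_628),
            ("KRAS", "oncogene", "12", 25_205_246, 25_250_929),
            ("TP53", "tumor_suppressor", "17", 7_668_402, 7_687_550),
            ("PTEN", "tumor_suppressor", "10", 87_863_113, 87_971_930),
        ],
        columns=["symbol", "role", "chromosome", "start", "end"],
    )
    hotspots = HotspotCatalog.from_pairs(
        [
            ("BRAF", "V600E"),
            ("BRAF", "V600M"),
            ("EGFR", "T790M"),
            ("EGFR", "L858R"),
            ("KRAS", "G12D"),
            ("TP53", "R175H"),
            ("TP53", "R248Q"),
            ("TP53", "R273H"),
            ("PTEN", "R130Q"),
        ]
    )
    samples = pd.DataFrame(
        {
            "sample_id": [
                "TCGA-BF-A3DL-01",
                "LUAD-NYU1142-Tumor",
                "S-LUNG-003",
                "S-SKIN-004",
            ],
            "tumor_type": ["skin", "lung", "lung", "skin"],
            "source": ["tissue"] * 4,
        }
    )
    mutations = pd.DataFrame(
        [
            ("TCGA-BF-A3DL-01", "BRAF", "V600E", "7", 140_753_336, "A", "T"),
            ("TCGA-BF-A3DL-01", "BRAF", "V600M", "7", 140_753_337, "C", "T"),
            ("TCGA-BF-A3DL-01", "KRAS", "G12D", "12", 25_245_350, "C", "T"),
            ("TCGA-BF-A3DL-01", "TP53", "A2000T", "17", 7_675_000, "G", "A"),
            ("LUAD-NYU1142-Tumor", "EGFR", "T790M", "7", 55_181_378, "C", "T"),
            ("LUAD-NYU1142-Tumor", "EGFR", "L858R", "7", 55_191_822, "T", "G"),
            ("LUAD-NYU1142-Tumor", "PTEN", "R130Q", "10", 87_933_147, "G", "A"),
            ("S-LUNG-003", "KRAS", "G12D", "12", 25_245_350, "C", "T"),
        ],
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
        [
            ("TCGA-BF-A3DL-01", "PTEN", -2),
            ("TCGA-BF-A3DL-01", "EGFR", 1),
            ("LUAD-NYU1142-Tumor", "KRAS", 0),
            ("S-SKIN-004", "BRAF", -1),
        ],
        columns=["sample_id", "gene", "call"],
    )
    return mutations, cnvs, annotations, hotspots, samples


@pytest.fixture(scope="session")
def demo_cohort():
    """Four-sample cohort containing the two canonical composite cases:
    BRAF V600E+V600M and EGFR T790M+L858R."""
    mutations, cnvs, annotations, hotspots, samples = _demo_frames()
    return load_cohort(
        maf=mutations,
        cnv=cnvs,
        annotations=annotations,
        hotspots=hotspots,
        samples=samples,
        layout=default_layout(),
    )


def make_signal_config(seed: int, n: int = 1500) -> SimConfig:
    """Single-gene signal cohort: prevalence 5%, six co-genes at odds ratio 8,
    same-chromosome placement probability 0.35."""
    return SimConfig(
        seed=seed,
        tumor_types=(TumorTypeSpec("lung", n, 0.01),),
        composite_genes=("BRAF",),
        composite_prevalence=0.05,
        comut_effects={g: 8.0 for g in ("G1_1", "G3_2", "G7_1", "G9_1", "G12_1", "G17_1")},
        comut_base_prob=0.10,
        comut_rate=4.0,
        same_chrom_prob=0.35,
    )


def make_location_config(
    seed: int,
    same_chrom_prob: float,
    n: int = 4000,
    prevalence: float = 0.35,
    composite_genes: tuple[str, ...] = ("BRAF",),
) -> SimConfig:
    """Location-channel-only cohort for same-chromosome calibration: no
    association effects, no driver noise, so every co-mutation event comes
    from the placement channel.  A dense panel (8 genes per chromosome) keeps
    the same-chromosome pool from saturating at high placement probability."""
    return SimConfig(
        seed=seed,
        tumor_types=(TumorTypeSpec("lung", n, 0.0),),
        genes_per_chromosome=8,
        composite_genes=composite_genes,
        composite_prevalence=prevalence,
        comut_effects={},
        comut_base_prob=0.0,
        comut_rate=4.0,
        same_chrom_prob=same_chrom_prob,
        driver_noise_prob=0.0,
        cnv_noise_prob=0.0,
    )
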