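"""Domain types and tabular I/O for somatic mutation / copy-number cohorts.

The analyses in this package operate on a validated :class:`Cohort` bundle:
per-sample metadata, somatic mutation records (MAF-style), gene-level discrete
copy-number calls (GISTIC-style −2…+2), gene annotations (symbol, driver role,
GRCh38 coordinates), a hotspot catalog of known driver protein changes, and a
:class:`GenomeLayout` giving chromosome lengths and concatenated-genome
offsets.

All tabular inputs are plain TSV.  Coordinates are 1-based inclusive (MAF /
GRCh38 convention).  Only the 24 nuclear chromosomes are accepted;
mitochondrial and alternative contigs are rejected at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "NUCLEAR_CHROMOSOMES",
    "GenomeLayout",
    "HotspotCatalog",
    "Cohort",
    "DEFAULT_MAF_DIALECT",
    "MUTATION_COLUMNS",
    "CNV_COLUMNS",
    "ANNOTATION_COLUMNS",
    "SAMPLE_COLUMNS",
    "ONCOGENE",
    "TUMOR_SUPPRESSOR",
    "read_maf",
    "read_cnv_matrix",
    "read_gene_annotations",
    "read_hotspots",
    "read_sample_table",
    "read_genome_layout",
    "load_cohort",
    "write_maf",
    "write_cnv_matrix",
    "write_gene_annotations",
    "write_hotspots",
    "write_sample_table",
    "write_genome_layout",
]


class FormatError(ValueError):
    """A file violates its expected tabular format."""


class ValidationError(ValueError):
    """Cross-table consistency of a cohort is violated."""


#: Karyotype order of the 24 nuclear chromosomes (22 autosomes + X + Y).
NUCLEAR_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

ONCOGENE = "oncogene"
TUMOR_SUPPRESSOR = "tumor_suppressor"
ROLES = frozenset({ONCOGENE, TUMOR_SUPPRESSOR})

MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "protein_change",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
]
CNV_COLUMNS = ["sample_id", "gene", "call"]
ANNOTATION_COLUMNS = ["symbol", "role", "chromosome", "start", "end"]
SAMPLE_COLUMNS = ["sample_id", "tumor_type", "source"]

#: Default column-name mapping for cBioPortal-style MAF exports.
DEFAULT_MAF_DIALECT: dict[str, str] = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "protein_change": "HGVSp_Short",
    "chromosome": "Chromosome",
    "position": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
}

_VALID_CNV_CALLS = frozenset({-2, -1, 0, 1, 2})


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths and concatenated-genome coordinates.

    Chromosomes are concatenated in the given (karyotype) order; a gene's
    concatenated coordinate is its chromosome's cumulative offset plus its
    within-chromosome position.  ``normalizer`` is the genome-distance constant
    used to scale inter-gene distances into [0, 1]; the default of 3×10⁹ bp is
    the conventional total length of the human genome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    normalizer: float = 3_000_000_000.0

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate chromosome names in layout")
        if not names:
            raise ValidationError("layout has no chromosomes")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length")
        if self.normalizer <= 0:
            raise ValidationError("normalizer must be positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def offsets(self) -> dict[str, int]:
        """Start coordinate of each chromosome in the concatenated genome."""
        out: dict[str, int] = {}
        pos = 0
        for name, length in self.chromosomes:
            out[name] = pos
            pos += length
        return out

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self.lengths


@dataclass(frozen=True)
class HotspotCatalog:
    """Catalog of known driver (gene, protein change) pairs.

    Lookups are case-normalized and ignore a leading ``p.`` HGVS prefix.
    """

    entries: frozenset[tuple[str, str]]

    @staticmethod
    def _norm(gene: str, protein_change: str) -> tuple[str, str]:
        pc = str(protein_change).strip()
        if pc.lower().startswith("p."):
            pc = pc[2:]
        return str(gene).strip().upper(), pc.upper()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "HotspotCatalog":
        return cls(frozenset(cls._norm(g, p) for g, p in pairs))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._norm(*pair) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.entries)


@dataclass
class Cohort:
    """Validated bundle of samples, mutations, CNV calls and annotations.

    Invariants established by :func:`load_cohort`:

    - every mutation/CNV ``sample_id`` exists in ``samples``;
    - every gene in ``mutations``/``cnvs`` is annotated (others are dropped
      with a logged count, recorded in ``summary``);
    - no duplicate ``(sample_id, gene, protein_change)`` mutation rows and no
      duplicate ``(sample_id, gene)`` CNV rows;
    - all chromosomes are nuclear and present in ``layout``.
    """

    samples: pd.DataFrame
    mutations: pd.DataFrame
    cnvs: pd.DataFrame
    annotations: pd.DataFrame
    layout: GenomeLayout
    hotspots: HotspotCatalog
    summary: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["sample_id"])

    def tumor_type_of(self) -> pd.Series:
        return self.samples.set_index("sample_id")["tumor_type"]

    def samples_of_type(self, tumor_type: str) -> pd.Index:
        mask = self.samples["tumor_type"] == tumor_type
        return pd.Index(self.samples.loc[mask, "sample_id"])

    def gene_chromosome(self) -> pd.Series:
        return self.annotations.set_index("symbol")["chromosome"]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, comment="#")


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def _strip_protein_prefix(pc: str) -> str:
    pc = str(pc).strip()
    return pc[2:] if pc.lower().startswith("p.") else pc


def _check_chromosomes(chroms: pd.Series, what: str) -> None:
    bad = sorted(set(chroms) - set(NUCLEAR_CHROMOSOMES))
    if bad:
        raise FormatError(
            f"{what}: non-nuclear or unknown chromosome(s) {bad}; "
            f"accepted: 1-22, X, Y"
        )


def read_maf(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a MAF-style TSV of somatic mutation records.

    Parameters
    ----------
    path
        TSV file with one row per mutation call.
    dialect
        Mapping from canonical field names (``sample_id``, ``gene``,
        ``protein_change``, ``chromosome``, ``position``, ``ref_allele``,
        ``alt_allele``) to the file's column names.  Defaults to cBioPortal
        MAF column names (:data:`DEFAULT_MAF_DIALECT`).

    Returns a DataFrame with the canonical columns, duplicate
    ``(sample_id, gene, protein_change)`` rows collapsed (count logged and
    stored in ``df.attrs["n_duplicates_dropped"]``), sorted so that input row
    order does not affect downstream results.
    """
    dialect = dict(dialect or DEFAULT_MAF_DIALECT)
    raw = _read_tsv(path)
    missing = [col for field_, col in dialect.items() if col not in raw.columns]
    if missing:
        raise FormatError(f"MAF {path}: missing required column(s) {missing}")
    df = pd.DataFrame({canon: raw[col] for canon, col in dialect.items()})

    positions = pd.to_numeric(df["position"], errors="coerce")
    bad = positions.isna() | (positions <= 0)
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based incl. header
        raise FormatError(
            f"MAF {path}: unparseable or non-positive position at line {row}"
        )
    df["position"] = positions.astype(int)
    df["protein_change"] = df["protein_change"].map(_strip_protein_prefix)
    df["chromosome"] = df["chromosome"].astype(str).str.removeprefix("chr")
    _check_chromosomes(df["chromosome"], f"MAF {path}")
    for col in ("ref_allele", "alt_allele"):
        df[col] = df[col].astype(str).str.upper()
    same = df["ref_allele"] == df["alt_allele"]
    if same.any():
        row = int(same.idxmax()) + 2
        raise FormatError(f"MAF {path}: ref_allele equals alt_allele at line {row}")

    before = len(df)
    df = df.drop_duplicates(subset=["sample_id", "gene", "protein_change"])
    n_dup = before - len(df)
    if n_dup:
        logger.info("read_maf(%s): collapsed %d duplicate mutation row(s)", path, n_dup)
    df = df.sort_values(["sample_id", "gene", "protein_change"], kind="stable")
    df = df[MUTATION_COLUMNS].reset_index(drop=True)
    df.attrs["n_duplicates_dropped"] = n_dup
    return df


def read_cnv_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene × sample matrix of discrete copy-number calls.

    The first column holds gene symbols; remaining columns are samples.  Cells
    must be integers in {−2, −1, 0, 1, 2}.  Returns a long-form DataFrame with
    columns ``sample_id``, ``gene``, ``call`` (all cells stored, including
    zeros).
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"CNV matrix {path}: needs a gene column plus >=1 sample")
    gene_col = raw.columns[0]
    long = raw.melt(id_vars=[gene_col], var_name="sample_id", value_name="call")
    long = long.rename(columns={gene_col: "gene"})
    calls = pd.to_numeric(long["call"], errors="coerce")
    bad = calls.isna() | (calls != calls.round()) | ~calls.round().isin(_VALID_CNV_CALLS)
    if bad.any():
        i = bad.idxmax()
        raise FormatError(
            f"CNV matrix {path}: invalid call {long.loc[i, 'call']!r} for "
            f"gene {long.loc[i, 'gene']!r}, sample {long.loc[i, 'sample_id']!r}"
        )
    long["call"] = calls.astype(int)
    dup = long.duplicated(subset=["sample_id", "gene"])
    if dup.any():
        i = dup.idxmax()
        raise FormatError(
            f"CNV matrix {path}: duplicate gene row {long.loc[i, 'gene']!r}"
        )
    long = long.sort_values(["sample_id", "gene"], kind="stable")
    return long[CNV_COLUMNS].reset_index(drop=True)


def read_gene_annotations(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV: symbol, role, chromosome, start, end."""
    df = _read_tsv(path)
    _require_columns(df, ANNOTATION_COLUMNS, f"annotations {path}")
    df = df[ANNOTATION_COLUMNS].copy()
    bad_role = ~df["role"].isin(ROLES)
    if bad_role.any():
        raise FormatError(
            f"annotations {path}: role must be one of {sorted(ROLES)}; "
            f"got {sorted(df.loc[bad_role, 'role'].unique())}"
        )
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            raise FormatError(f"annotations {path}: non-positive or missing {col}")
        df[col] = vals.astype(int)
    if (df["start"] > df["end"]).any():
        raise FormatError(f"annotations {path}: start > end")
    df["chromosome"] = df["chromosome"].astype(str).str.removeprefix("chr")
    _check_chromosomes(df["chromosome"], f"annotations {path}")
    if df["symbol"].duplicated().any():
        raise FormatError(f"annotations {path}: duplicate gene symbol(s)")
    return df.sort_values("symbol", kind="stable").reset_index(drop=True)


def read_hotspots(path: str | Path) -> HotspotCatalog:
    """Read a hotspot TSV with columns gene, protein_change."""
    df = _read_tsv(path)
    _require_columns(df, ["gene", "protein_change"], f"hotspots {path}")
    return HotspotCatalog.from_pairs(zip(df["gene"], df["protein_change"]))


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read sample metadata: sample_id, tumor_type, optional source."""
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "tumor_type"], f"samples {path}")
    if "source" not in df.columns:
        df["source"] = "tissue"
    bad = ~df["source"].isin(["tissue", "cell_line"])
    if bad.any():
        raise FormatError(f"samples {path}: source must be tissue or cell_line")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise FormatError(f"samples {path}: duplicate sample_id(s) {dups[:5]}")
    df = df[SAMPLE_COLUMNS].sort_values("sample_id", kind="stable")
    return df.reset_index(drop=True)


def read_genome_layout(
    path: str | Path, normalizer: float = 3_000_000_000.0
) -> GenomeLayout:
    """Read a genome layout TSV with columns chromosome, length."""
    df = _read_tsv(path)
    _require_columns(df, ["chromosome", "length"], f"layout {path}")
    lengths = pd.to_numeric(df["length"], errors="coerce")
    if lengths.isna().any() or (lengths <= 0).any():
        raise FormatError(f"layout {path}: non-positive or missing length")
    chroms = df["chromosome"].astype(str).str.removeprefix("chr")
    return GenomeLayout(
        tuple(zip(chroms, lengths.astype(int))), normalizer=normalizer
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def load_cohort(
    maf: str | Path | pd.DataFrame,
    cnv: str | Path | pd.DataFrame,
    annotations: str | Path | pd.DataFrame,
    hotspots: str | Path | HotspotCatalog,
    samples: str | Path | pd.DataFrame,
    layout: str | Path | GenomeLayout,
) -> Cohort:
    """Assemble and validate a :class:`Cohort` from files or loaded objects.

    Genes absent from the annotation table are dropped from mutations and CNV
    calls with a logged count; mutations or CNVs referencing unknown samples
    raise :class:`ValidationError`.  The returned cohort's ``summary`` records
    sample/gene/record counts and the numbers dropped.
    """
    mutations = maf if isinstance(maf, pd.DataFrame) else read_maf(maf)
    cnvs = cnv if isinstance(cnv, pd.DataFrame) else read_cnv_matrix(cnv)
    ann = (
        annotations
        if isinstance(annotations, pd.DataFrame)
        else read_gene_annotations(annotations)
    )
    hs = hotspots if isinstance(hotspots, HotspotCatalog) else read_hotspots(hotspots)
    smp = samples if isinstance(samples, pd.DataFrame) else read_sample_table(samples)
    lay = layout if isinstance(layout, GenomeLayout) else read_genome_layout(layout)

    if len(smp) == 0:
        raise ValidationError("cohort has no samples")
    _check_chromosomes(ann["chromosome"], "annotations")
    unknown_chrom = sorted(set(ann["chromosome"]) - set(lay.names))
    if unknown_chrom:
        raise ValidationError(f"annotated chromosome(s) not in layout: {unknown_chrom}")

    known_samples = set(smp["sample_id"])
    for name, df in (("mutations", mutations), ("cnvs", cnvs)):
        unknown = sorted(set(df["sample_id"]) - known_samples)
        if unknown:
            raise ValidationError(
                f"{name} reference unknown sample id(s): {unknown[:10]}"
                + (" ..." if len(unknown) > 10 else "")
            )

    known_genes = set(ann["symbol"])
    mut_keep = mutations["gene"].isin(known_genes)
    cnv_keep = cnvs["gene"].isin(known_genes)
    n_drop_mut = int((~mut_keep).sum())
    n_drop_cnv = int((~cnv_keep).sum())
    if n_drop_mut or n_drop_cnv:
        logger.info(
            "load_cohort: dropped %d mutation and %d CNV record(s) in "
            "unannotated genes",
            n_drop_mut,
            n_drop_cnv,
        )
    mutations = (
        mutations.loc[mut_keep]
        .drop_duplicates(subset=["sample_id", "gene", "protein_change"])
        .sort_values(["sample_id", "gene", "protein_change"], kind="stable")
        .reset_index(drop=True)
    )
    cnvs = (
        cnvs.loc[cnv_keep]
        .sort_values(["sample_id", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    if cnvs.duplicated(subset=["sample_id", "gene"]).any():
        raise ValidationError("duplicate (sample, gene) CNV calls")

    # positions must fall inside their chromosome
    if len(mutations):
        lens = mutations["chromosome"].map(lay.lengths)
        if lens.isna().any():
            bad = sorted(mutations.loc[lens.isna(), "chromosome"].unique())
            raise ValidationError(f"mutation chromosome(s) not in layout: {bad}")
        over = mutations["position"] > lens
        if over.any():
            raise ValidationError(
                f"{int(over.sum())} mutation position(s) beyond chromosome length"
            )

    summary = {
        "n_samples": int(len(smp)),
        "n_genes": int(len(ann)),
        "n_mutations": int(len(mutations)),
        "n_cnvs": int(len(cnvs)),
        "n_dropped_unannotated_mutations": n_drop_mut,
        "n_dropped_unannotated_cnvs": n_drop_cnv,
        "n_hotspot_entries": len(hs),
    }
    return Cohort(
        samples=smp,
        mutations=mutations,
        cnvs=cnvs,
        annotations=ann,
        layout=lay,
        hotspots=hs,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# writers (plain TSV, deterministic ordering)
# ---------------------------------------------------------------------------


def write_maf(
    mutations: pd.DataFrame,
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    dialect = dict(dialect or DEFAULT_MAF_DIALECT)
    out = mutations[MUTATION_COLUMNS].rename(columns=dialect)
    out = out.sort_values(
        [dialect["sample_id"], dialect["gene"], dialect["protein_change"]],
        kind="stable",
    )
    out.to_csv(path, sep="\t", index=False)


def write_cnv_matrix(cnvs: pd.DataFrame, path: str | Path) -> None:
    wide = (
        cnvs.pivot(index="gene", columns="sample_id", values="call")
        .fillna(0)
        .astype(int)
        .sort_index()
        .sort_index(axis=1)
    )
    wide.index.name = "gene"
    wide.reset_index().to_csv(path, sep="\t", index=False)


def write_gene_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations[ANNOTATION_COLUMNS].sort_values("symbol", kind="stable").to_csv(
        path, sep="\t", index=False
    )


def write_hotspots(hotspots: HotspotCatalog, path: str | Path) -> None:
    df = pd.DataFrame(sorted(hotspots.entries), columns=["gene", "protein_change"])
    df.to_csv(path, sep="\t", index=False)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SAMPLE_COLUMNS].sort_values("sample_id", kind="stable").to_csv(
        path, sep="\t", index=False
    )


def write_genome_layout(layout: GenomeLayout, path: str | Path) -> None:
    df = pd.DataFrame(layout.chromosomes, columns=["chromosome", "length"])
    df.to_csv(path, sep="\t", index=False)
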