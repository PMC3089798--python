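"""Readers and writers for every external representation the pipeline touches.

All tabular formats are tab-delimited text with a header row.  Promoters are
FASTA with a header dialect ``>species|gene_id|tss_index=<int>`` where
``tss_index`` is the 0-based index of the transcription start site (TSS) base
within the record sequence.  DRE positions are always reported as signed
offsets with TSS = 0 and upstream negative; BED output (only available when
genomic coordinates are attached to hits) is 0-based half-open.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

SPECIES_DEFAULT = ("human", "mouse", "rat")
TREATMENTS = ("vehicle", "TCDD", "CHX", "TCDD+CHX")
DYES = ("Cy3", "Cy5")

#: Orientation precedence within a two-color array: the sample later in this
#: list is the "treated" channel of the pair, the earlier one the control.
TREATMENT_PRECEDENCE = {"vehicle": 0, "CHX": 1, "TCDD": 2, "TCDD+CHX": 3}


class FormatError(ValueError):
    """Raised when an input file violates its declared format contract."""


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "species",
    "treatment",
    "time_hr",
    "dye",
    "replicate",
    "array_id",
]


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet against the two-color pairing invariants.

    Every ``array_id`` must carry exactly two samples with opposite dyes;
    ``sample_id`` must be unique.  Returns the sheet with canonical dtypes.
    """
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    sheet = sheet.copy()
    sheet["time_hr"] = pd.to_numeric(sheet["time_hr"])
    sheet["replicate"] = sheet["replicate"].astype(int)
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate sample ids: {sorted(set(dup))}")
    bad_dye = set(sheet["dye"]) - set(DYES)
    if bad_dye:
        raise FormatError(f"unknown dyes: {sorted(bad_dye)}")
    bad_trt = set(sheet["treatment"]) - set(TREATMENTS)
    if bad_trt:
        raise FormatError(f"unknown treatments: {sorted(bad_trt)}")
    if (sheet["replicate"] < 1).any():
        raise FormatError("replicate numbers must be >= 1")
    for array_id, grp in sheet.groupby("array_id"):
        if len(grp) != 2 or set(grp["dye"]) != set(DYES):
            raise FormatError(
                f"array {array_id!r} must have exactly two samples with "
                f"opposite dyes; got {list(zip(grp['sample_id'], grp['dye']))}"
            )
    return sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "array_id": str})
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Probe x sample matrix of two-channel intensities or log2 ratios.

    ``values`` is indexed by probe id; columns are sample ids for
    ``raw_two_channel`` data (one column per channel) or array ids for
    ``log2_ratio`` data (one column per hybridization, oriented
    treated-over-control).  ``gene_map`` maps probe id -> gene id; several
    probes may map to the same gene.  Missing cells are NaN and stay missing.
    """

    values: pd.DataFrame
    gene_map: pd.Series
    value_kind: str  # "raw_two_channel" | "log2_ratio"

    def __post_init__(self) -> None:
        if self.value_kind not in ("raw_two_channel", "log2_ratio"):
            raise FormatError(f"unknown value_kind {self.value_kind!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()]
            raise FormatError(f"duplicate probe ids: {sorted(set(dups))[:5]}")
        if (self.gene_map.reindex(self.values.index).astype(str) == "").any():
            raise FormatError("empty gene_id for some probes")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    def subset_columns(self, cols: Sequence[str]) -> "ExpressionTable":
        return ExpressionTable(self.values[list(cols)], self.gene_map, self.value_kind)


def read_expression(
    path: str | Path, sample_sheet_path: str | Path
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Read a probe x sample intensity TSV joined against its sample sheet.

    The TSV must have ``probe_id`` and ``gene_id`` columns followed by one
    column per sample.  Samples present in the table but absent from the
    sheet are a hard error naming the sample; sheet samples without a data
    column are reported via the returned sheet's ``in_table`` column.
    """
    sheet = read_sample_sheet(sample_sheet_path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_id"):
        if col not in raw.columns:
            raise FormatError(f"expression table missing {col!r} column")
    sample_cols = [c for c in raw.columns if c not in ("probe_id", "gene_id")]
    unknown = [c for c in sample_cols if c not in set(sheet["sample_id"])]
    if unknown:
        raise FormatError(f"samples not in sample sheet: {unknown}")
    values = raw.set_index("probe_id")[sample_cols]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    nonblank = values.astype(str).apply(lambda c: c.str.strip() != "")
    bad = numeric.isna() & values.notna() & nonblank
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at probe {values.index[r]!r}, "
            f"sample {values.columns[c]!r}: {values.iat[r, c]!r}"
        )
    gene_map = raw.set_index("probe_id")["gene_id"]
    table = ExpressionTable(numeric, gene_map, "raw_two_channel")
    sheet = sheet.copy()
    sheet["in_table"] = sheet["sample_id"].isin(sample_cols)
    return table, sheet


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    out = table.values.copy()
    out.insert(0, "gene_id", table.gene_map.reindex(out.index))
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_log_ratio_table(path: str | Path) -> ExpressionTable:
    """Read a probe x array log2-ratio TSV (as written by the pipeline)."""
    raw = pd.read_csv(path, sep="\t", index_col="probe_id", float_precision="round_trip")
    gene_map = raw["gene_id"]
    values = raw.drop(columns="gene_id").apply(pd.to_numeric)
    return ExpressionTable(values, gene_map, "log2_ratio")


# ---------------------------------------------------------------------------
# Ortholog tables
# ---------------------------------------------------------------------------


def validate_ortholog_table(orth: pd.DataFrame) -> pd.DataFrame:
    """Check HomoloGene-style mapping: (species, gene) unique, groups >= 2 species."""
    need = {"group_id", "species", "gene_id"}
    if not need <= set(orth.columns):
        raise FormatError(f"ortholog table needs columns {sorted(need)}")
    orth = orth.astype({"group_id": str, "species": str, "gene_id": str})
    dup = orth.duplicated(subset=["species", "gene_id"])
    if dup.any():
        rows = orth[dup][["species", "gene_id"]].iloc[0]
        raise FormatError(
            f"gene mapped to more than one group: {tuple(rows)}"
        )
    sizes = orth.groupby("group_id")["species"].nunique()
    small = sizes[sizes < 2]
    if len(small):
        raise FormatError(f"groups with < 2 species: {list(small.index)[:5]}")
    return orth


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    return validate_ortholog_table(pd.read_csv(path, sep="\t", dtype=str))


def write_ortholog_table(orth: pd.DataFrame, path: str | Path) -> None:
    orth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Promoter FASTA
# ---------------------------------------------------------------------------

VALID_BASES = frozenset("ACGTN")


@dataclass
class PromoterRecord:
    """A promoter sequence anchored at its TSS.

    ``tss_index`` is the 0-based index of the TSS base; the scan window is
    ``[-upstream_bp, +downstream_bp]`` in TSS-relative coordinates.
    """

    species: str
    gene_id: str
    sequence: str
    tss_index: int
    upstream_bp: int = 10000
    downstream_bp: int = 1000

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not (0 <= self.tss_index < len(self.sequence)):
            raise FormatError(
                f"{self.species}|{self.gene_id}: tss_index {self.tss_index} "
                f"out of bounds for sequence of length {len(self.sequence)}"
            )
        if self.upstream_bp <= 0 or self.downstream_bp <= 0:
            raise FormatError("window bounds must be positive")
        bad = [i for i, b in enumerate(self.sequence) if b not in VALID_BASES]
        if bad:
            raise FormatError(
                f"{self.species}|{self.gene_id}: invalid base "
                f"{self.sequence[bad[0]]!r} at position {bad[0]}"
            )


def read_promoters(
    fasta_path: str | Path, upstream_bp: int = 10000, downstream_bp: int = 1000
) -> list[PromoterRecord]:
    """Parse promoter FASTA with ``>species|gene_id|tss_index=<int>`` headers."""
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3 or not parts[2].startswith("tss_index="):
            raise FormatError(
                f"bad promoter header {rec.id!r}; expected "
                "'species|gene_id|tss_index=<int>'"
            )
        species, gene_id = parts[0], parts[1]
        try:
            tss_index = int(parts[2].split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"non-integer tss_index in {rec.id!r}") from exc
        records.append(
            PromoterRecord(
                species=species,
                gene_id=gene_id,
                sequence=str(rec.seq),
                tss_index=tss_index,
                upstream_bp=upstream_bp,
                downstream_bp=downstream_bp,
            )
        )
    return records


def write_promoters(records: Iterable[PromoterRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.species}|{rec.gene_id}|tss_index={rec.tss_index}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# DRE hit tables
# ---------------------------------------------------------------------------

DRE_TSV_COLUMNS = ["species", "gene_id", "core_center", "strand", "seq19", "ms"]


def write_dre_hits(hits, path: str | Path, dialect: str = "tsv") -> None:
    """Write scanned DREs as TSV (TSS-relative) or BED (genomic, 0-based).

    BED output needs hits carrying ``chrom`` and ``genome_start`` (0-based
    start of the 19-mer on the + strand); requesting it without genomic
    coordinates is an error.  The BED score column is ``round(1000 * MS)``.
    """
    hits = list(hits)
    if dialect == "tsv":
        rows = [
            {
                "species": h.species,
                "gene_id": h.gene_id,
                "core_center": h.core_center,
                "strand": h.strand,
                "seq19": h.seq19,
                "ms": "" if h.ms is None else f"{h.ms:.6f}",
            }
            for h in hits
        ]
        pd.DataFrame(rows, columns=DRE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif dialect == "bed":
        lines = []
        for h in hits:
            chrom = getattr(h, "chrom", None)
            start = getattr(h, "genome_start", None)
            if chrom is None or start is None:
                raise FormatError(
                    "BED output requires genomic coordinates (chrom, genome_start)"
                )
            score = 0 if h.ms is None else int(round(1000 * h.ms))
            name = f"{h.species}|{h.gene_id}|DRE"
            lines.append(f"{chrom}\t{start}\t{start + 19}\t{name}\t{score}\t{h.strand}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def read_dre_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "gene_id": str})
    missing = [c for c in DRE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"DRE TSV missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Dendrograms -> Newick
# ---------------------------------------------------------------------------


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a SciPy linkage matrix as Newick with height-derived branch lengths.

    A child's branch length is its parent's merge height minus its own
    (leaves have height 0), so a two-leaf tree merged at height h renders as
    ``(A:h,B:h);``.
    """
    labels = list(labels)
    if len(labels) == 1:
        return f"{labels[0]};"
    linkage = np.asarray(linkage, dtype=float)
    if linkage.ndim != 2 or linkage.shape[1] != 4 or linkage.shape[0] != len(labels) - 1:
        raise FormatError("merge tree is not a binary linkage over the given leaves")
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"


def write_dendrogram(
    linkage: np.ndarray, labels: Sequence[str], path: str | Path
) -> None:
    Path(path).write_text(linkage_to_newick(linkage, labels) + "\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ConfigBundle:
    """Analysis thresholds and scan parameters, one object for the whole run.

    Defaults mirror the study conditions: differential expression requires
    P1(t) > 0.999 and |fold change| > 1.4 (both strict); DRE scanning uses the
    invariant GCGTG core extended to 19 bp, and orthologous-DRE clustering
    cuts the tree at Euclidean distance 3.0.
    """

    p1_min: float = 0.999
    abs_fc_min: float = 1.4
    dre_core: str = "GCGTG"
    flank_bp: int = 7
    distance_threshold: float = 3.0
    ms_min: float = 0.0
    retention_alpha: float = 0.5
    chx_times_hr: tuple[float, ...] = (4.0, 12.0)
    prior_active: float = 0.01
    signal_variance_ratio: float = 64.0
    lowess_frac: float = 0.4
    seed: int = 0
    fixtures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1_min <= 1.0):
            raise FormatError(f"p1_min must be in [0, 1], got {self.p1_min}")
        if self.abs_fc_min < 1.0:
            raise FormatError(f"abs_fc_min must be >= 1, got {self.abs_fc_min}")
        if len(self.dre_core) != 5:
            raise FormatError("DRE core must be 5 bp")
        if not (0.0 <= self.ms_min <= 1.0):
            raise FormatError("ms_min must be in [0, 1]")
        if not (0.0 < self.retention_alpha <= 1.0):
            raise FormatError("retention_alpha must be in (0, 1]")
        if self.distance_threshold < 0:
            raise FormatError("distance_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConfigBundle":
        data = yaml.safe_load(Path(path).read_text()) or {}
        de = data.pop("de_thresholds", {})
        dre = data.pop("dre", {})
        chx = data.pop("chx", {})
        kwargs = dict(data)
        kwargs.update(
            {k: de[k] for k in ("p1_min", "abs_fc_min") if k in de},
        )
        rename = {"core": "dre_core", "distance_threshold": "distance_threshold",
                  "flank_bp": "flank_bp", "ms_min": "ms_min"}
        kwargs.update({rename[k]: v for k, v in dre.items() if k in rename})
        if "retention_alpha" in chx:
            kwargs["retention_alpha"] = chx["retention_alpha"]
        if "times_hr" in chx:
            kwargs["chx_times_hr"] = tuple(chx["times_hr"])
        if "chx_times_hr" in kwargs:
            kwargs["chx_times_hr"] = tuple(kwargs["chx_times_hr"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "de_thresholds": {"p1_min": self.p1_min, "abs_fc_min": self.abs_fc_min},
            "dre": {
                "core": self.dre_core,
                "flank_bp": self.flank_bp,
                "distance_threshold": self.distance_threshold,
                "ms_min": self.ms_min,
            },
            "chx": {
                "retention_alpha": self.retention_alpha,
                "times_hr": list(self.chx_times_hr),
            },
            "prior_active": self.prior_active,
            "signal_variance_ratio": self.signal_variance_ratio,
            "lowess_frac": self.lowess_frac,
            "seed": self.seed,
            "fixtures": self.fixtures,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
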