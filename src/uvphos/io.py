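"""Readers and writers for site tables, gene models, coverage and gene sets.

All genomic coordinates are 0-based half-open internally; conversion from
1-based inclusive conventions (GTF) happens only at the parse boundary.
SILAC ratios are stored in log2 space; a table dialect declares whether
the file on disk holds linear or already-logarithmized ratios.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TableDialect",
    "SilacSiteTable",
    "PulldownTable",
    "GeneModel",
    "CoverageTrack",
    "GeneSetCollection",
    "read_site_table",
    "write_site_table",
    "read_pulldown_table",
    "write_pulldown_table",
    "read_gene_models",
    "write_gene_models_bed",
    "read_coverage",
    "write_coverage_bedgraph",
    "read_gmt",
    "write_gmt",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# SILAC site / pulldown tables
# ---------------------------------------------------------------------------

#: default ratio column pattern: "ratio:<condition>:<replicate>"
RATIO_PATTERN = r"^ratio:(?P<condition>.+):(?P<replicate>\d+)$"

SITE_COLUMNS = {
    "site_id": "site_id",
    "protein_id": "protein_id",
    "gene_name": "gene_name",
    "position": "position",
    "residue": "residue",
    "localization_prob": "localization_prob",
    "sequence_window": "sequence_window",
}


@dataclass
class TableDialect:
    """Column mapping for a site/pulldown TSV.

    ``columns`` maps canonical field names to file column headers;
    ``ratio_pattern`` is a regex with named groups ``condition`` and
    ``replicate`` matched against remaining headers; ``linear_ratios``
    declares that on-disk ratios need a log2 transform on read.
    """

    columns: dict = field(default_factory=lambda: dict(SITE_COLUMNS))
    ratio_pattern: str = RATIO_PATTERN
    linear_ratios: bool = False

    @classmethod
    def from_yaml(cls, path) -> "TableDialect":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(
            columns={**SITE_COLUMNS, **cfg.get("columns", {})},
            ratio_pattern=cfg.get("ratio_pattern", RATIO_PATTERN),
            linear_ratios=bool(cfg.get("linear_ratios", False)),
        )


def _split_ratio_columns(header, dialect: TableDialect):
    pat = re.compile(dialect.ratio_pattern)
    ratio_cols = {}
    for col in header:
        m = pat.match(col)
        if m:
            ratio_cols[col] = (m.group("condition"), int(m.group("replicate")))
    return ratio_cols


@dataclass
class SilacSiteTable:
    """Phosphosite table: metadata frame + (condition, replicate) log2-ratio matrix.

    ``sites`` is indexed by site_id with columns protein_id, gene_name,
    position, residue, localization_prob, sequence_window.  ``ratios``
    shares the index; its columns are a MultiIndex (condition, replicate)
    holding log2 ratios with NaN for missing quantifications.
    """

    sites: pd.DataFrame
    ratios: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not self.sites.index.equals(self.ratios.index):
            raise FormatError("sites and ratios must share the same index")
        windows = self.sites["sequence_window"].astype(str)
        residues = self.sites["residue"].astype(str)
        for sid, win, res in zip(self.sites.index, windows, residues):
            if len(win) % 2 == 0:
                raise FormatError(f"sequence_window {win!r} has even length")
            if win[len(win) // 2] != res:
                raise FormatError(
                    f"window center {win[len(win)//2]!r} != residue {res!r} for site {sid}"
                )
        lp = self.sites["localization_prob"]
        if ((lp < 0) | (lp > 1)).any():
            raise FormatError("localization_prob outside [0, 1]")

    @property
    def conditions(self) -> list:
        return list(self.ratios.columns.get_level_values(0).unique())

    def condition_matrix(self, condition: str) -> pd.DataFrame:
        """site x replicate log2-ratio matrix for one condition."""
        if condition not in self.conditions:
            raise KeyError(f"condition {condition!r} not in table (have {self.conditions})")
        return self.ratios[condition]


@dataclass
class PulldownTable:
    """Protein-level pulldown table; same ratio contract as SilacSiteTable."""

    proteins: pd.DataFrame  # index protein_id; columns gene_name
    ratios: pd.DataFrame  # MultiIndex (contrast, replicate)

    @property
    def conditions(self) -> list:
        return list(self.ratios.columns.get_level_values(0).unique())

    def condition_matrix(self, condition: str) -> pd.DataFrame:
        if condition not in self.conditions:
            raise KeyError(f"condition {condition!r} not in table (have {self.conditions})")
        return self.ratios[condition]


def _read_ratio_table(path, dialect, id_col, meta_fields):
    df = pd.read_csv(path, sep="\t", dtype={dialect.columns.get(id_col, id_col): str})
    cols = dialect.columns
    for canonical in meta_fields:
        if cols[canonical] not in df.columns:
            raise FormatError(f"missing mandatory column {cols[canonical]!r} ({canonical})")
    ratio_cols = _split_ratio_columns(df.columns, dialect)
    meta = df[[cols[c] for c in meta_fields]].copy()
    meta.columns = list(meta_fields)
    meta = meta.set_index(id_col)

    data = {}
    for col, key in ratio_cols.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} non-numeric ratio value(s) in column {col!r} set to missing"
            )
        if dialect.linear_ratios:
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.log2(vals.where(vals > 0))
        data[key] = vals.to_numpy()
    ratios = pd.DataFrame(data, index=meta.index)
    ratios.columns = pd.MultiIndex.from_tuples(ratios.columns, names=["condition", "replicate"])
    ratios = ratios.sort_index(axis=1)
    return meta, ratios


def read_site_table(path, dialect: TableDialect | None = None) -> SilacSiteTable:
    """Read a phosphosite TSV into a SilacSiteTable (ratios in log2)."""
    dialect = dialect or TableDialect()
    meta, ratios = _read_ratio_table(
        path, dialect, "site_id", list(SITE_COLUMNS)
    )
    meta["position"] = meta["position"].astype(int)
    meta["localization_prob"] = meta["localization_prob"].astype(float)
    return SilacSiteTable(sites=meta, ratios=ratios)


def write_site_table(table: SilacSiteTable, path):
    """Write the canonical TSV (log2 ratios, 'ratio:<cond>:<rep>' columns)."""
    out = table.sites.reset_index()
    for (cond, rep) in table.ratios.columns:
        out[f"ratio:{cond}:{rep}"] = table.ratios[(cond, rep)].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pulldown_table(path, dialect: TableDialect | None = None) -> PulldownTable:
    dialect = dialect or TableDialect(
        columns={"protein_id": "protein_id", "gene_name": "gene_name"}
    )
    meta, ratios = _read_ratio_table(path, dialect, "protein_id", ["protein_id", "gene_name"])
    return PulldownTable(proteins=meta, ratios=ratios)


def write_pulldown_table(table: PulldownTable, path):
    out = table.proteins.reset_index()
    for (cond, rep) in table.ratios.columns:
        out[f"ratio:{cond}:{rep}"] = table.ratios[(cond, rep)].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene as an oriented interval.

    ``tss`` is the 0-based coordinate of the first transcribed base; for
    minus-strand genes tss > tes in genomic coordinates and transcription
    runs toward lower coordinates.  ``tes`` is exclusive in transcription
    direction, so length == abs(tes - tss) == BED interval length.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise FormatError(f"unknown strand {self.strand!r} for gene {self.gene_id}")
        if self.length <= 0:
            raise FormatError(f"gene {self.gene_id} has non-positive length")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def start(self) -> int:
        """0-based half-open genomic start."""
        return self.tss if self.strand == "+" else self.tes + 1

    @property
    def end(self) -> int:
        return self.tes if self.strand == "+" else self.tss + 1

    @classmethod
    def from_interval(cls, gene_id, chrom, start, end, strand) -> "GeneModel":
        """Build from a 0-based half-open genomic interval."""
        if strand == "+":
            return cls(gene_id, chrom, strand, tss=start, tes=end)
        return cls(gene_id, chrom, strand, tss=end - 1, tes=start - 1)


def read_gene_models(path, format: str = "bed") -> list[GeneModel]:
    """Read gene models from BED (0-based half-open) or GTF (1-based inclusive).

    Zero-length intervals are skipped with a warning; unknown strand
    characters raise.
    """
    genes = []
    if format == "bed":
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t") if "\t" in line else line.split()
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
                strand = f[5] if len(f) > 5 else "+"
                if start == end:
                    warnings.warn(f"skipping zero-length gene {name}")
                    continue
                genes.append(GeneModel.from_interval(name, chrom, start, end, strand))
    elif format == "gtf":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
                m = re.search(r'gene_id\s+"([^"]+)"', attrs)
                name = m.group(1) if m else f"{chrom}:{start}-{end}"
                # GTF 1-based inclusive -> 0-based half-open
                start0, end0 = start - 1, end
                if start0 == end0:
                    warnings.warn(f"skipping zero-length gene {name}")
                    continue
                genes.append(GeneModel.from_interval(name, chrom, start0, end0, strand))
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    return genes


def write_gene_models_bed(genes, path):
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Dense per-base read coverage per chromosome for one library.

    ``library_mass`` is the total coverage mass (sum over all bases);
    dividing by ``read_length`` gives an approximate mapped-read count.
    RPKM values computed from coverage are independent of read length
    (it cancels between the window and the library normalizer).
    """

    condition: str
    replicate: int
    coverage: dict  # chrom -> np.ndarray (float, >= 0)
    read_length: float = 1.0

    @property
    def library_mass(self) -> float:
        if not hasattr(self, "_mass"):
            self._mass = float(sum(arr.sum() for arr in self.coverage.values()))
        return self._mass

    @property
    def library_size(self) -> float:
        """Approximate mapped read count."""
        return self.library_mass / self.read_length

    def rpkm(self, chrom: str, start: int, end: int) -> float:
        """Mean normalized signal over [start, end): reads per kb per 1e6 reads."""
        arr = self.coverage.get(chrom)
        if arr is None:
            raise KeyError(f"chromosome {chrom!r} not in track")
        start, end = max(start, 0), min(end, len(arr))
        if end <= start:
            return np.nan
        mass = float(arr[start:end].sum())
        total = self.library_mass
        if total == 0:
            return 0.0
        # read_length cancels: (mass/rl) / ((end-start)/1e3 * (total/rl)/1e6)
        return mass * 1e9 / ((end - start) * total)


def read_coverage(path, condition: str, replicate: int, read_length: float = 1.0) -> CoverageTrack:
    """Read a bedGraph into a dense per-base CoverageTrack.

    Intervals must be 0-based half-open and non-overlapping per
    chromosome; negative values are rejected.
    """
    entries = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise FormatError(f"bedGraph line {ln}: expected 4 fields")
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if value < 0:
                raise FormatError(f"bedGraph line {ln}: negative coverage {value}")
            entries.setdefault(chrom, []).append((start, end, value))
    coverage = {}
    for chrom, ivals in entries.items():
        ivals.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise FormatError(f"overlapping bedGraph intervals on {chrom} at {s2}")
        size = ivals[-1][1]
        arr = np.zeros(size)
        for s, e, v in ivals:
            arr[s:e] = v
        coverage[chrom] = arr
    return CoverageTrack(condition=condition, replicate=replicate, coverage=coverage,
                         read_length=read_length)


def write_coverage_bedgraph(track: CoverageTrack, path):
    """Write dense coverage back to bedGraph (run-length collapsed)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.coverage):
            arr = track.coverage[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.6g}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Flat named gene sets; identifiers uppercase-normalized, no empty sets."""

    sets: dict  # name -> (description, frozenset of members)

    def __post_init__(self):
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def members(self, name: str) -> frozenset:
        return self.sets[name][1]

    def items(self):
        for name, (desc, members) in self.sets.items():
            yield name, desc, members


def read_gmt(path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"GMT line {ln}: expected >= 3 tab-separated fields")
            name, desc = f[0], f[1]
            if name in sets:
                raise FormatError(f"GMT line {ln}: duplicate set name {name!r}")
            members = frozenset(m.strip().upper() for m in f[2:] if m.strip())
            if not members:
                raise FormatError(f"GMT line {ln}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path):
    with open(path, "w") as fh:
        for name, desc, members in collection.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
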