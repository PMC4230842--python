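"""Readers/writers for the on-disk formats and the shared coordinate conventions.

Conventions used throughout the package:

* cytosine *sites* are 1-based positions on their strand (as in per-position
  count tables);
* genomic *intervals* (regions, features) are 0-based half-open, BED-style;
* spike-in (unmethylated control) records live on a reserved chromosome
  named ``lambda``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
TISSUES = ("root", "shoot")
TREATMENTS = ("control23", "cold4")
SPIKEIN_CHROM = "lambda"

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "n_total", "n_meth"]


class MethIOError(ValueError):
    """Malformed input file or record."""


@dataclass(frozen=True)
class SampleKey:
    """Factorial identity of one sample.

    ``replicate`` is a positive integer for a biological replicate and 0 for
    the pool obtained by combining replicates.
    """

    species: str
    tissue: str
    treatment: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.replicate < 0:
            raise ValueError("replicate must be >= 0")

    @property
    def combination(self) -> tuple[str, str]:
        """The tissue-treatment combination, one of the four in the design."""
        return (self.tissue, self.treatment)

    def combined(self) -> "SampleKey":
        """Key of the replicate-combined sample."""
        return replace(self, replicate=0)

    def label(self) -> str:
        rep = "combined" if self.replicate == 0 else f"rep{self.replicate}"
        return f"{self.species}_{self.tissue}_{self.treatment}_{rep}"


def _validate_records(df: pd.DataFrame, where: str = "table") -> pd.DataFrame:
    missing = [c for c in CYTOSINE_COLUMNS if c not in df.columns]
    if missing:
        raise MethIOError(f"{where}: missing columns {missing}")
    df = df[CYTOSINE_COLUMNS].copy()
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        i = int(np.flatnonzero(bad_ctx.to_numpy())[0])
        raise MethIOError(f"{where}, row {i + 1}: invalid context {df['context'].iat[i]!r}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        i = int(np.flatnonzero(bad_strand.to_numpy())[0])
        raise MethIOError(f"{where}, row {i + 1}: invalid strand {df['strand'].iat[i]!r}")
    if (df["n_total"] < 0).any() or (df["n_meth"] < 0).any():
        raise MethIOError(f"{where}: negative read counts")
    over = df["n_meth"] > df["n_total"]
    if over.any():
        i = int(np.flatnonzero(over.to_numpy())[0])
        raise MethIOError(
            f"{where}, row {i + 1}: n_meth={df['n_meth'].iat[i]} exceeds "
            f"n_total={df['n_total'].iat[i]}"
        )
    return df


def sort_records(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )


@dataclass
class SampleTable:
    """One sample's per-cytosine counts plus its spike-in control counts."""

    key: SampleKey
    records: pd.DataFrame
    spikein: pd.DataFrame = field(default_factory=lambda: _empty_records())

    def __post_init__(self) -> None:
        self.records = _validate_records(self.records, "records")
        self.spikein = _validate_records(self.spikein, "spikein")
        if not self.records["chrom"].ne(SPIKEIN_CHROM).all():
            raise MethIOError(f"genomic records may not use reserved chrom {SPIKEIN_CHROM!r}")
        srt = sort_records(self.records)
        if not srt[["chrom", "pos", "strand"]].equals(
            self.records[["chrom", "pos", "strand"]]
        ):
            logger.warning("unsorted cytosine records for %s: sorting", self.key.label())
            self.records = srt
        dup = self.records.duplicated(["chrom", "pos", "strand"])
        if dup.any():
            raise MethIOError("duplicate (chrom, pos, strand) in records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def rates(self) -> pd.Series:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.records["n_meth"] / self.records["n_total"]


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "n_total": pd.Series(dtype=np.int64),
            "n_meth": pd.Series(dtype=np.int64),
        }
    )


def empty_records() -> pd.DataFrame:
    """An empty, correctly typed cytosine record table."""
    return _empty_records()


def read_cytosine_table(path: str | Path, sample: SampleKey) -> SampleTable:
    """Read a per-cytosine count TSV into a :class:`SampleTable`.

    Spike-in rows (chromosome ``lambda``) are separated from genomic rows.
    Malformed rows raise :class:`MethIOError` naming the offending line.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "context": str,
                "n_total": np.int64,
                "n_meth": np.int64,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise MethIOError(f"{path}: {exc}") from exc
    df = _validate_records(df, str(path))
    spike = df[df["chrom"] == SPIKEIN_CHROM].reset_index(drop=True)
    genomic = df[df["chrom"] != SPIKEIN_CHROM].reset_index(drop=True)
    return SampleTable(key=sample, records=genomic, spikein=spike)


def write_cytosine_table(table: SampleTable, path: str | Path) -> None:
    out = pd.concat([table.records, table.spikein], ignore_index=True)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

FEATURE_KINDS = (
    "gene",
    "exon",
    "intron",
    "five_prime_UTR",
    "three_prime_UTR",
    "TE",
    "intergenic",
    "upstream1kb",
)

_GFF_TE_TYPES = {
    "TE",
    "transposable_element",
    "transposon",
    "repeat_region",
    "transposable_element_gene",
}


@dataclass(frozen=True)
class GenomicFeature:
    """A genomic interval (0-based half-open) with a feature kind."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start


def read_gff(path: str | Path, upstream: int = 1000) -> list[GenomicFeature]:
    """Read a GFF3 annotation into :class:`GenomicFeature` intervals.

    Besides genes, exons, UTRs and TE/repeat features found in the file,
    introns are derived as the gaps between a gene's exons and an
    ``upstream1kb`` interval is derived as the ``upstream`` bases preceding
    each gene's start codon on the coding strand.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feats: list[GenomicFeature] = []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        g0, g1 = gene.start - 1, gene.end
        feats.append(GenomicFeature(gene.seqid, g0, g1, gene.strand, "gene", gid))
        exons = sorted(
            db.children(gene, featuretype="exon"), key=lambda f: (f.start, f.end)
        )
        for ex in exons:
            if ex.start < gene.start or ex.end > gene.end:
                raise MethIOError(
                    f"exon {ex.id} outside parent gene {gid} "
                    f"([{ex.start},{ex.end}] vs [{gene.start},{gene.end}])"
                )
            feats.append(
                GenomicFeature(ex.seqid, ex.start - 1, ex.end, ex.strand, "exon", gid)
            )
        if not exons:
            logger.warning("gene %s has no exons; no introns derived", gid)
        for left, right in zip(exons, exons[1:]):
            if right.start - 1 > left.end:
                feats.append(
                    GenomicFeature(
                        gene.seqid, left.end, right.start - 1, gene.strand, "intron", gid
                    )
                )
        for utr_type, kind in (
            ("five_prime_UTR", "five_prime_UTR"),
            ("three_prime_UTR", "three_prime_UTR"),
        ):
            for u in db.children(gene, featuretype=utr_type):
                feats.append(
                    GenomicFeature(u.seqid, u.start - 1, u.end, u.strand, kind, gid)
                )
        if gene.strand == "-":
            up = GenomicFeature(gene.seqid, g1, g1 + upstream, "-", "upstream1kb", gid)
            feats.append(up)
        else:
            s = max(0, g0 - upstream)
            if s < g0:
                feats.append(
                    GenomicFeature(gene.seqid, s, g0, "+", "upstream1kb", gid)
                )
    for ftype in _GFF_TE_TYPES:
        try:
            te_iter = db.features_of_type(ftype)
        except Exception:
            continue
        for te in te_iter:
            feats.append(
                GenomicFeature(te.seqid, te.start - 1, te.end, te.strand or "+", "TE")
            )
    return feats


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------


@dataclass
class Region:
    """Half-open genomic interval with an optional methylation rate."""

    chrom: str
    start: int
    end: int
    name: str = "."
    rate: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


def write_regions_bed(regions: Iterable[Region], path: str | Path) -> None:
    """Write regions as BED6; the score column is rate x 1000, rounded."""
    with open(path, "w") as fh:
        for r in regions:
            score = int(round(r.rate * 1000))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


def read_regions_bed(path: str | Path) -> list[Region]:
    out: list[Region] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise MethIOError(f"{path}, line {ln}: expected 6 BED columns")
            out.append(
                Region(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    name=parts[3],
                    rate=int(parts[4]) / 1000.0,
                    strand=parts[5],
                )
            )
    return out


# ---------------------------------------------------------------------------
# maps and matrices
# ---------------------------------------------------------------------------


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    """Read a 1:1:1 ortholog TSV (one gene-id column per species)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 3:
        raise MethIOError(f"{path}: expected 3 gene-id columns, got {df.shape[1]}")
    for col in df.columns:
        if df[col].duplicated().any():
            raise MethIOError(f"{path}: duplicated gene ids in column {col!r}")
    return df


def aligned_site_columns(species: Sequence[str]) -> list[str]:
    cols: list[str] = []
    for sp in species:
        cols += [f"chrom_{sp}", f"pos_{sp}", f"strand_{sp}", f"context_{sp}"]
    return cols


def read_aligned_sites(path: str | Path, species: Sequence[str]) -> pd.DataFrame:
    """Read the three-way aligned-cytosine map (one row per aligned site)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in aligned_site_columns(species) if c not in df.columns]
    if missing:
        raise MethIOError(f"{path}: missing columns {missing}")
    return df


def read_counts_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample integer count matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise MethIOError(f"{path}: negative counts")
    return df


def site_to_interval(pos: int) -> tuple[int, int]:
    """1-based site position -> 0-based half-open single-base interval."""
    return pos - 1, pos


def interval_to_site(start: int, end: int) -> int:
    """Inverse of :func:`site_to_interval` for single-base intervals."""
    if end != start + 1:
        raise ValueError("not a single-base interval")
    return start + 1
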