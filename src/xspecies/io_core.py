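"""Core genomic/expression data types and text-format readers/writers.

All coordinates are 0-based half-open (BED convention) throughout the
package; GTF-style 1-based inclusive coordinates must be converted at the
boundary by the caller. Expression values are stored on a linear scale;
log transforms are applied inside the analyses that need them.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")

ANNOTATION_CATEGORIES = ("coding", "pseudogene", "ncRNA", "other")


class ValidationError(ValueError):
    """An object violates a type invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@functools.total_ordering
@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open coordinates; requires ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    name : str
        Free-text identifier (BED column 4).
    score : float, optional
        BED column 5; ``None`` when absent.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def _key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def __lt__(self, other: "GenomicInterval") -> bool:
        return self._key < other._key

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class CoverageTrack:
    """Dense per-base signal for one species, one array per chromosome.

    ``values`` maps chromosome name to a non-negative float array whose
    length defines the chromosome length.
    """

    species: str
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValidationError(f"track for {chrom} is not 1-D")
            if arr.size and arr.min() < 0:
                raise ValidationError(f"negative coverage on {chrom}")
            clean[chrom] = arr
        self.values = clean

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(a.size) for c, a in self.values.items()}

    def slice(self, interval: GenomicInterval) -> np.ndarray:
        """Per-base values over ``interval``; errors if out of bounds."""
        arr = self.values.get(interval.chrom)
        if arr is None:
            raise KeyError(f"no chromosome {interval.chrom!r} in track")
        if interval.end > arr.size:
            raise ValidationError(
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {arr.size}"
            )
        return arr[interval.start : interval.end]


@dataclass
class ExpressionMatrix:
    """A gene-by-sample expression matrix with per-sample metadata.

    Parameters
    ----------
    species : str
        Species tag for all genes in this matrix.
    values : pandas.DataFrame
        Genes in rows, samples in columns, non-negative linear-scale values.
    sample_meta : pandas.DataFrame
        Indexed by sample id; expected columns include ``stage_index``,
        ``stage_label`` and ``tissue`` where the analysis needs them.
    """

    species: str
    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r} in {self.species}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative expression value")
        if len(self.sample_meta):
            missing = set(self.values.columns) - set(self.sample_meta.index)
            if missing:
                raise ValidationError(
                    f"samples without metadata: {sorted(missing)[:5]}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


class OrthologyMap:
    """A symmetric set of cross-species ortholog gene pairs.

    Supports one-to-one, one-to-many and many-to-many relations; a pair is
    stored once in canonical order and looked up from either side.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, str, str]] = ()) -> None:
        self._pairs: set[tuple[tuple[str, str], tuple[str, str]]] = set()
        for sa, ga, sb, gb in pairs:
            self.add(sa, ga, sb, gb)

    def add(self, species_a: str, gene_a: str, species_b: str, gene_b: str) -> None:
        if species_a == species_b:
            raise ValidationError(
                f"ortholog pair within one species: {species_a}/{gene_a}-{gene_b}"
            )
        a, b = (species_a, gene_a), (species_b, gene_b)
        self._pairs.add((a, b) if a <= b else (b, a))

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair) -> bool:
        sa, ga, sb, gb = pair
        a, b = (sa, ga), (sb, gb)
        return ((a, b) if a <= b else (b, a)) in self._pairs

    def __iter__(self):
        return iter(sorted(self._pairs))

    def pairs_between(self, species_a: str, species_b: str) -> list[tuple[str, str]]:
        """Ortholog pairs as ``(gene_a, gene_b)`` oriented a→b."""
        out = []
        for (s1, g1), (s2, g2) in self._pairs:
            if s1 == species_a and s2 == species_b:
                out.append((g1, g2))
            elif s2 == species_a and s1 == species_b:
                out.append((g2, g1))
        return sorted(out)

    def partners(self, species: str, gene: str) -> list[tuple[str, str]]:
        """All ``(species, gene)`` partners of one gene."""
        out = []
        for (s1, g1), (s2, g2) in self._pairs:
            if (s1, g1) == (species, gene):
                out.append((s2, g2))
            elif (s2, g2) == (species, gene):
                out.append((s1, g1))
        return sorted(out)


@dataclass
class AnnotationSet:
    """Annotated intervals with a category from a fixed vocabulary."""

    intervals: list[GenomicInterval]
    categories: list[str]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.categories):
            raise ValidationError("intervals and categories differ in length")
        for cat in self.categories:
            if cat not in ANNOTATION_CATEGORIES:
                raise ValidationError(f"unknown annotation category {cat!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3–BED6 into a list of :class:`GenomicInterval`.

    Coordinates are kept verbatim (0-based half-open). A missing strand
    column yields ``"."``; a missing score yields ``None``.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 else ""
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write intervals as BED6; round-trips through :func:`read_bed`."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "0" if iv.score is None else repr(iv.score)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def read_bedgraph(path, chrom_lengths: Mapping[str, int], species: str = "") -> CoverageTrack:
    """Read a 4-column bedGraph into a dense :class:`CoverageTrack`.

    Uncovered bases are 0. Overlapping spans are an error, as is a span
    extending past the declared chromosome length.
    """
    values = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
            chrom, start, end, val = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if chrom not in values:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= chrom_lengths[chrom]):
                raise ValidationError(
                    f"{path}:{lineno}: span {start}-{end} outside chromosome "
                    f"of length {chrom_lengths[chrom]}"
                )
            if covered[chrom][start:end].any():
                raise ValidationError(f"{path}:{lineno}: overlapping spans")
            covered[chrom][start:end] = True
            values[chrom][start:end] = val
    return CoverageTrack(species=species, values=values)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write non-zero runs of a track as bedGraph spans."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [arr.size]))
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def read_expression(path, meta_path, species: str | None = None) -> ExpressionMatrix:
    """Read an expression TSV plus its companion sample-metadata TSV.

    The expression file has gene ids in the first column and sample ids in
    the header; the metadata file has columns ``sample``, ``species``,
    ``stage_index``, ``stage_label``, ``tissue``.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample")
    missing = set(values.columns) - set(meta.index)
    if missing:
        raise ValidationError(f"samples missing from metadata: {sorted(missing)}")
    meta = meta.loc[list(values.columns)]
    if species is None:
        tags = meta["species"].unique()
        if len(tags) != 1:
            raise ValidationError(
                f"metadata names multiple species {list(tags)}; pass `species`"
            )
        species = str(tags[0])
    return ExpressionMatrix(species=species, values=values, sample_meta=meta)


def write_expression(expr: ExpressionMatrix, path, meta_path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    expr.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_gtf_tss(path) -> list[GenomicInterval]:
    """Extract one TSS interval per gene from a GTF file.

    GTF coordinates are 1-based inclusive and converted here to the
    package's 0-based half-open convention. For each ``gene`` feature (or
    every feature when no ``gene`` lines exist) a 1-base interval at the
    5' end is returned, strand preserved; the ``gene_id`` attribute
    becomes the interval name.
    """
    out: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "gene":
                continue
            start0, end0 = int(start) - 1, int(end)  # 1-based incl -> 0-based half-open
            name = ""
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    name = item.split(None, 1)[1].strip().strip('"')
                    break
            if name in seen:
                continue
            seen.add(name)
            tss = end0 - 1 if strand == "-" else start0
            out.append(GenomicInterval(chrom, tss, tss + 1, strand, name))
    return out


def read_orthology(path) -> OrthologyMap:
    """Read a TSV of ortholog pairs (species_a, gene_a, species_b, gene_b).

    The symmetric closure is applied and duplicate rows collapse to one
    pair; a pair within a single species is an error.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_a", "gene_a", "species_b", "gene_b"}
    if not required.issubset(table.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    omap = OrthologyMap()
    for row in table.itertuples(index=False):
        omap.add(row.species_a, row.gene_a, row.species_b, row.gene_b)
    return omap


def write_orthology(omap: OrthologyMap, path) -> None:
    rows = [
        {"species_a": s1, "gene_a": g1, "species_b": s2, "gene_b": g2}
        for (s1, g1), (s2, g2) in omap
    ]
    pd.DataFrame(rows, columns=["species_a", "gene_a", "species_b", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )
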