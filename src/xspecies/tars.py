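"""Transcriptionally active region (TAR) discovery and characterization.

A TAR is a contiguous run of covered bases outside annotated genes,
called by minimum-run/maximum-gap segmentation of a coverage track:
bases at or above a signal threshold form runs, runs separated by short
sub-threshold gaps are bridged, and merged regions shorter than the
minimum run length are discarded. The module also restricts TARs to
non-canonical space by subtracting annotations, quantifies TAR
expression across samples, tests interval-set overlap enrichment against
a within-chromosome permutation null, and annotates TARs by correlating
their expression profiles with module profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import (
    AnnotationSet,
    CoverageTrack,
    ExpressionMatrix,
    GenomicInterval,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TarCallParams",
    "EnrichmentResult",
    "call_tars",
    "subtract_annotation",
    "genome_fraction",
    "quantify_tars",
    "overlap_enrichment",
    "correlate_tars_with_modules",
]


@dataclass(frozen=True)
class TarCallParams:
    """Segmentation parameters: signal threshold, minimum region length
    (bases) and maximum bridged sub-threshold gap (bases).

    Defaults (threshold 1 depth unit, min_run 50 bp, max_gap 25 bp) are
    package conventions, exposed so a user can match any external
    segmentation.
    """

    threshold: float = 1.0
    min_run: int = 50
    max_gap: int = 25

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("threshold must be > 0")
        if self.min_run < 1:
            raise ValidationError("min_run must be >= 1")
        if self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0")


def _covered_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as half-open spans."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def segment(
    values: np.ndarray,
    threshold: float,
    min_run: int,
    max_gap: int,
    merge_first: bool = True,
) -> list[tuple[int, int]]:
    """Minimum-run/maximum-gap segmentation of a per-base signal array.

    With ``merge_first`` (default) runs separated by gaps <= ``max_gap``
    are bridged before the ``min_run`` length filter is applied to the
    merged regions; with ``merge_first=False`` runs are length-filtered
    first and the survivors merged.
    """
    runs = _covered_runs(np.asarray(values) >= threshold)
    if not merge_first:
        runs = [(s, e) for s, e in runs if e - s >= min_run]
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    if merge_first:
        merged = [(s, e) for s, e in merged if e - s >= min_run]
    return merged


def call_tars(
    track: CoverageTrack,
    params: TarCallParams,
    merge_first: bool = True,
) -> list[GenomicInterval]:
    """Call TARs on every chromosome of a coverage track.

    Returns sorted, non-overlapping intervals; each interval's score is
    the mean per-base signal over the region. Strand is ignored (tracks
    may be unstranded).
    """
    out: list[GenomicInterval] = []
    for chrom in sorted(track.values):
        arr = track.values[chrom]
        for i, (s, e) in enumerate(
            segment(arr, params.threshold, params.min_run, params.max_gap, merge_first)
        ):
            out.append(
                GenomicInterval(
                    chrom,
                    s,
                    e,
                    name=f"TAR_{chrom}_{i}",
                    score=float(arr[s:e].mean()),
                )
            )
    return out


def _merge_union(intervals: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    """Merged (union) spans per chromosome."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in sorted(intervals):
        spans = per_chrom.setdefault(iv.chrom, [])
        if spans and iv.start <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], iv.end))
        else:
            spans.append((iv.start, iv.end))
    return per_chrom


def subtract_annotation(
    tars: list[GenomicInterval],
    annot: AnnotationSet,
    min_run: int = 1,
) -> list[GenomicInterval]:
    """Base-level set difference of TARs against all annotated intervals.

    Remaining fragments shorter than ``min_run`` are dropped. Names carry
    a fragment suffix when a TAR is split.
    """
    annot_spans = _merge_union(annot.intervals)
    out: list[GenomicInterval] = []
    for iv in sorted(tars):
        pieces = [(iv.start, iv.end)]
        for a_s, a_e in annot_spans.get(iv.chrom, []):
            next_pieces = []
            for s, e in pieces:
                if a_e <= s or a_s >= e:
                    next_pieces.append((s, e))
                    continue
                if s < a_s:
                    next_pieces.append((s, a_s))
                if a_e < e:
                    next_pieces.append((a_e, e))
            pieces = next_pieces
        for j, (s, e) in enumerate(pieces):
            if e - s >= min_run:
                name = iv.name if len(pieces) == 1 else f"{iv.name}.{j}"
                out.append(GenomicInterval(iv.chrom, s, e, iv.strand, name, iv.score))
    return out


def genome_fraction(
    intervals: list[GenomicInterval], chrom_lengths: dict[str, int]
) -> float:
    """Fraction of the genome covered by the union of the intervals."""
    total = sum(chrom_lengths.values())
    if total == 0:
        return 0.0
    covered = 0
    for chrom, spans in _merge_union(intervals).items():
        if chrom not in chrom_lengths:
            raise ValidationError(f"interval on unknown chromosome {chrom!r}")
        if spans and spans[-1][1] > chrom_lengths[chrom]:
            raise ValidationError(f"interval exceeds length of {chrom!r}")
        covered += sum(e - s for s, e in spans)
    return covered / total


def quantify_tars(
    tars: list[GenomicInterval],
    tracks: dict[str, CoverageTrack],
    species: str = "",
) -> ExpressionMatrix:
    """Mean per-base signal of every TAR in every sample track."""
    sample_ids = sorted(tracks)
    data = np.empty((len(tars), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        track = tracks[sid]
        for i, iv in enumerate(tars):
            data[i, j] = float(track.slice(iv).mean())
    values = pd.DataFrame(data, index=[iv.name for iv in tars], columns=sample_ids)
    meta = pd.DataFrame(
        {
            "species": species or (tracks[sample_ids[0]].species if sample_ids else ""),
            "stage_index": np.arange(len(sample_ids)),
            "stage_label": sample_ids,
            "tissue": "",
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionMatrix(species=meta["species"].iloc[0] if sample_ids else species,
                            values=values, sample_meta=meta)


@dataclass
class EnrichmentResult:
    """Permutation overlap-enrichment outcome for two interval sets."""

    observed_overlap: int
    permuted_overlaps: list[int]
    fold: float
    p_value: float


def _overlap_bases(
    spans_a: dict[str, list[tuple[int, int]]],
    spans_b: dict[str, list[tuple[int, int]]],
) -> int:
    total = 0
    for chrom, a_spans in spans_a.items():
        b_spans = b if (b := spans_b.get(chrom)) else []
        i = j = 0
        while i < len(a_spans) and j < len(b_spans):
            s = max(a_spans[i][0], b_spans[j][0])
            e = min(a_spans[i][1], b_spans[j][1])
            if e > s:
                total += e - s
            if a_spans[i][1] < b_spans[j][1]:
                i += 1
            else:
                j += 1
    return total


def _relocate(
    lengths: list[int], chrom_length: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Place intervals of given lengths uniformly without overlap."""
    placed: list[tuple[int, int]] = []
    for length in lengths:
        if length > chrom_length:
            raise ValidationError("interval longer than its chromosome")
        for _ in range(1000):
            s = int(rng.integers(0, chrom_length - length + 1))
            e = s + length
            if all(e <= ps or pe <= s for ps, pe in placed):
                placed.append((s, e))
                break
        else:
            raise ValidationError("could not relocate intervals without overlap")
    return sorted(placed)


def overlap_enrichment(
    set_a: list[GenomicInterval],
    set_b: list[GenomicInterval],
    chrom_lengths: dict[str, int],
    n_perm: int,
    seed: int,
) -> EnrichmentResult:
    """Permutation test of base-level overlap between two interval sets.

    Each permutation relocates every ``set_a`` interval uniformly within
    its own chromosome, preserving lengths and non-overlap; ``set_b`` is
    fixed. The upper-tail p-value uses the add-one rule
    ``p = (1 + #{perm >= obs}) / (n_perm + 1)`` and the fold change adds a
    +1 pseudocount to numerator and mean-permuted denominator.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    spans_b = _merge_union(set_b)
    observed = _overlap_bases(_merge_union(set_a), spans_b)
    lengths_by_chrom: dict[str, list[int]] = {}
    for iv in sorted(set_a):
        if iv.end - iv.start > chrom_lengths[iv.chrom]:
            raise ValidationError("interval longer than its chromosome")
        lengths_by_chrom.setdefault(iv.chrom, []).append(iv.end - iv.start)
    rng = np.random.default_rng(seed)
    permuted = []
    for _ in range(n_perm):
        spans_perm = {
            chrom: _relocate(lengths, chrom_lengths[chrom], rng)
            for chrom, lengths in lengths_by_chrom.items()
        }
        permuted.append(_overlap_bases(spans_perm, spans_b))
    n_ge = sum(1 for v in permuted if v >= observed)
    p = (1 + n_ge) / (n_perm + 1)
    fold = (observed + 1) / (float(np.mean(permuted)) + 1) if permuted else float("nan")
    return EnrichmentResult(
        observed_overlap=observed, permuted_overlaps=permuted, fold=fold, p_value=p
    )


def correlate_tars_with_modules(
    tar_expr: ExpressionMatrix,
    module_profiles: pd.DataFrame,
    r_min: float = 0.7,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Annotate TARs by correlation of their profiles with module profiles.

    ``module_profiles`` holds one row per module, columns matching the TAR
    expression samples. Returns a table (tar, module, r, p, q) of pairs
    with ``|r| >= r_min`` and BH ``q <= fdr``; a TAR may match several
    modules. Zero-variance profiles are skipped and logged.
    """
    if list(tar_expr.samples) != list(module_profiles.columns):
        raise ValidationError("TAR and module profiles have different samples")
    rows = []
    for tar in tar_expr.genes:
        x = tar_expr.values.loc[tar].to_numpy(dtype=float)
        if np.std(x) == 0:
            logger.info("skipping constant TAR profile %s", tar)
            continue
        for module in module_profiles.index:
            y = module_profiles.loc[module].to_numpy(dtype=float)
            if np.std(y) == 0:
                logger.info("skipping constant module profile %s", module)
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"tar": tar, "module": module, "r": r, "p": p})
    table = pd.DataFrame(rows, columns=["tar", "module", "r", "p"])
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table[(table["r"].abs() >= r_min) & (table["q"] <= fdr)]
    else:
        table["q"] = pd.Series(dtype=float)
    return table.reset_index(drop=True)
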