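"""Developmental stage alignment between two species.

Stage-associated genes (highly expressed at one stage but not broadly)
are called per species from stage-collapsed expression; stages are then
aligned by the hypergeometric significance of ortholog-pair overlap
between the two species' stage-associated sets, scanned over every stage
pair. Significant cells cluster into diagonal bands, and ortholog pairs
contributing to two or more bands are the dual-alignment genes (the
embryo↔metamorphosis-type signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix, OrthologyMap, ValidationError

__all__ = [
    "StageSeries",
    "StageAssociation",
    "AlignmentMatrix",
    "AlignmentBand",
    "stage_series_from_expression",
    "stage_associated_genes",
    "align_stages",
    "extract_alignment_bands",
    "dual_alignment_genes",
    "StageAlignmentModel",
    "StageAlignmentResults",
]


@dataclass
class StageSeries:
    """Ordered developmental stages with stage-collapsed expression.

    ``expr`` is a gene × stage DataFrame whose columns follow
    ``stage_labels`` order (stage indices 0..n-1).
    """

    species: str
    stage_labels: list[str]
    expr: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.stage_labels) < 3:
            raise ValidationError("need at least 3 stages")
        if list(self.expr.columns) != list(self.stage_labels):
            raise ValidationError("expr columns must equal stage labels in order")

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)


def stage_series_from_expression(expr: ExpressionMatrix) -> StageSeries:
    """Collapse an ExpressionMatrix to a StageSeries using its metadata.

    Samples sharing a ``stage_index`` are averaged; stages are ordered by
    index.
    """
    meta = expr.sample_meta
    if "stage_index" not in meta.columns:
        raise ValidationError("sample metadata lacks stage_index")
    order = sorted(meta["stage_index"].unique())
    cols = []
    labels = []
    for idx in order:
        samples = meta.index[meta["stage_index"] == idx]
        labels.append(str(meta.loc[samples[0], "stage_label"]))
        cols.append(expr.values[list(samples)].mean(axis=1))
    collapsed = pd.concat(cols, axis=1)
    collapsed.columns = labels
    return StageSeries(species=expr.species, stage_labels=labels, expr=collapsed)


@dataclass
class StageAssociation:
    """Per-stage sets of stage-associated genes, with the parameters used
    and the expressed-gene universe (genes above the floor at any stage)."""

    species: str
    per_stage: dict[int, set[str]]
    expressed_genes: set[str]
    z_min: float
    floor: float
    max_breadth: float

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.per_stage.values():
            out |= s
        return out


def stage_associated_genes(
    series: StageSeries,
    z_min: float = 1.5,
    floor: float = 1.0,
    max_breadth: float = 0.5,
) -> StageAssociation:
    """Call genes highly expressed at particular stages but not broadly.

    Gene g is associated with stage s iff (i) its linear expression at s
    is at least ``floor``, (ii) the z-score of its ``log(expr+1)`` value
    at s across stages is at least ``z_min`` (sample s.d., ddof=1), and
    (iii) the fraction of stages passing (i)–(ii) is at most
    ``max_breadth``. Zero-variance genes are associated with no stage.
    """
    if z_min <= 0:
        raise ValidationError("z_min must be > 0")
    if floor < 0:
        raise ValidationError("floor must be >= 0")
    if not 0 < max_breadth <= 1:
        raise ValidationError("max_breadth must be in (0, 1]")
    values = series.expr.to_numpy(dtype=float)
    logged = np.log(values + 1.0)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (logged - mean) / sd, 0.0)
    passes = (values >= floor) & (z >= z_min)
    breadth_ok = passes.sum(axis=1) / series.n_stages <= max_breadth
    passes &= breadth_ok[:, None]
    genes = np.array(series.expr.index)
    per_stage = {
        s: set(genes[passes[:, s]].tolist()) for s in range(series.n_stages)
    }
    expressed = set(genes[(values >= floor).any(axis=1)].tolist())
    return StageAssociation(
        species=series.species,
        per_stage=per_stage,
        expressed_genes=expressed,
        z_min=z_min,
        floor=floor,
        max_breadth=max_breadth,
    )


@dataclass
class AlignmentMatrix:
    """Stage-pair overlap grid with significance.

    Rows are species-A stages, columns species-B stages; ``overlap`` holds
    ortholog-pair counts, ``neglog10_p`` the -log10 hypergeometric
    upper-tail p per cell and ``q`` BH-adjusted values across all cells.
    ``contributing`` maps each cell to the ortholog pairs counted there.
    """

    species_a: str
    species_b: str
    overlap: np.ndarray
    neglog10_p: np.ndarray
    q: np.ndarray
    background_pairs: int
    contributing: dict[tuple[int, int], set[tuple[str, str]]] = field(
        default_factory=dict
    )

    @property
    def shape(self) -> tuple[int, int]:
        return self.overlap.shape

    def to_frame(self, what: str = "neglog10_p") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, what))


def align_stages(
    assoc_a: StageAssociation,
    assoc_b: StageAssociation,
    orthology: OrthologyMap,
    background_pairs: int | None = None,
) -> AlignmentMatrix:
    """Align two species' stages by ortholog overlap significance.

    A cell (s_a, s_b) counts ortholog pairs (g_a, g_b) with g_a associated
    to s_a and g_b to s_b. Its p-value is the hypergeometric upper tail of
    that count when ``n`` pairs involving s_a-associated A genes are drawn
    from ``background_pairs`` pairs of which ``K`` involve s_b-associated
    B genes. The default background is all ortholog pairs between genes
    expressed above the floor in at least one stage on each side. BH
    correction runs across all cells. Empty associations give p = 1.
    """
    all_pairs = orthology.pairs_between(assoc_a.species, assoc_b.species)
    bg_pairs = [
        (ga, gb)
        for ga, gb in all_pairs
        if ga in assoc_a.expressed_genes and gb in assoc_b.expressed_genes
    ]
    if background_pairs is None:
        background_pairs = len(bg_pairs)
    n_a = len(assoc_a.per_stage)
    n_b = len(assoc_b.per_stage)
    overlap = np.zeros((n_a, n_b), dtype=int)
    pvals = np.ones((n_a, n_b))
    contributing: dict[tuple[int, int], set[tuple[str, str]]] = {}
    # per-stage pair counts
    n_by_a = {
        s: sum(1 for ga, _ in bg_pairs if ga in assoc_a.per_stage[s])
        for s in range(n_a)
    }
    k_by_b = {
        s: sum(1 for _, gb in bg_pairs if gb in assoc_b.per_stage[s])
        for s in range(n_b)
    }
    for s_a in range(n_a):
        set_a = assoc_a.per_stage[s_a]
        for s_b in range(n_b):
            set_b = assoc_b.per_stage[s_b]
            cell_pairs = {
                (ga, gb) for ga, gb in bg_pairs if ga in set_a and gb in set_b
            }
            k = len(cell_pairs)
            overlap[s_a, s_b] = k
            contributing[(s_a, s_b)] = cell_pairs
            n = n_by_a[s_a]
            big_k = k_by_b[s_b]
            if k == 0 or n == 0 or big_k == 0 or background_pairs == 0:
                pvals[s_a, s_b] = 1.0
            else:
                if max(n, big_k) > background_pairs:
                    raise ValidationError(
                        "background_pairs smaller than a marginal count"
                    )
                pvals[s_a, s_b] = float(
                    stats.hypergeom.sf(k - 1, background_pairs, big_k, n)
                )
    q = multipletests(pvals.ravel(), method="fdr_bh")[1].reshape(pvals.shape)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.clip(pvals, 1e-300, 1.0))
    return AlignmentMatrix(
        species_a=assoc_a.species,
        species_b=assoc_b.species,
        overlap=overlap,
        neglog10_p=neglog,
        q=q,
        background_pairs=background_pairs,
        contributing=contributing,
    )


@dataclass
class AlignmentBand:
    """A connected cluster of significant alignment cells."""

    cells: list[tuple[int, int]]
    mean_offset: float


def extract_alignment_bands(
    matrix: AlignmentMatrix, q_max: float = 0.05
) -> list[AlignmentBand]:
    """Group significant cells (q <= q_max) into 8-connected bands.

    Each band reports its mean diagonal offset, computed on a stage grid
    rescaled so the main diagonal of a rectangular matrix has offset 0:
    ``offset = s_b - s_a * (n_b - 1) / (n_a - 1)``. Bands are sorted by
    offset.
    """
    if not 0 < q_max < 1:
        raise ValidationError("q_max must be in (0, 1)")
    sig = matrix.q <= q_max
    if not sig.any():
        return []
    labeled, n_found = ndimage.label(sig, structure=np.ones((3, 3), dtype=int))
    n_a, n_b = matrix.shape
    scale = (n_b - 1) / (n_a - 1) if n_a > 1 else 1.0
    bands = []
    for lab in range(1, n_found + 1):
        cells = [tuple(map(int, c)) for c in np.argwhere(labeled == lab)]
        offsets = [s_b - s_a * scale for s_a, s_b in cells]
        bands.append(AlignmentBand(cells=sorted(cells), mean_offset=float(np.mean(offsets))))
    bands.sort(key=lambda b: b.mean_offset)
    return bands


def dual_alignment_genes(
    matrix: AlignmentMatrix,
    bands: list[AlignmentBand],
) -> set[tuple[str, str]]:
    """Ortholog pairs contributing overlap to cells in >= 2 distinct bands."""
    if len(bands) < 2:
        raise ValidationError("need at least two bands for a dual alignment")
    pair_bands: dict[tuple[str, str], set[int]] = {}
    for bi, band in enumerate(bands):
        for cell in band.cells:
            for pair in matrix.contributing.get(cell, ()):
                pair_bands.setdefault(pair, set()).add(bi)
    return {pair for pair, bs in pair_bands.items() if len(bs) >= 2}


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class StageAlignmentModel:
    """Hypergeometric stage alignment of two developmental time courses."""

    def __init__(
        self,
        series_a: StageSeries,
        series_b: StageSeries,
        orthology: OrthologyMap,
        z_min: float = 1.5,
        floor: float = 1.0,
        max_breadth: float = 0.5,
    ) -> None:
        self.series_a = series_a
        self.series_b = series_b
        self.orthology = orthology
        self.z_min = z_min
        self.floor = floor
        self.max_breadth = max_breadth

    def fit(self, q_max: float = 0.05) -> "StageAlignmentResults":
        assoc_a = stage_associated_genes(
            self.series_a, self.z_min, self.floor, self.max_breadth
        )
        assoc_b = stage_associated_genes(
            self.series_b, self.z_min, self.floor, self.max_breadth
        )
        matrix = align_stages(assoc_a, assoc_b, self.orthology)
        bands = extract_alignment_bands(matrix, q_max=q_max)
        dual = dual_alignment_genes(matrix, bands) if len(bands) >= 2 else set()
        return StageAlignmentResults(
            model=self, assoc_a=assoc_a, assoc_b=assoc_b,
            matrix=matrix, bands=bands, dual_pairs=dual, q_max=q_max,
        )


@dataclass
class StageAlignmentResults:
    """Fitted stage alignment: association calls, grid, bands, dual genes."""

    model: StageAlignmentModel
    assoc_a: StageAssociation
    assoc_b: StageAssociation
    matrix: AlignmentMatrix
    bands: list[AlignmentBand]
    dual_pairs: set[tuple[str, str]]
    q_max: float

    def summary(self) -> str:
        m = self.matrix
        lines = [
            f"Stage alignment {m.species_a} vs {m.species_b}",
            f"  grid: {m.shape[0]} x {m.shape[1]} stages; "
            f"background ortholog pairs: {m.background_pairs}",
            f"  stage-associated genes: {len(self.assoc_a.genes())} "
            f"({m.species_a}), {len(self.assoc_b.genes())} ({m.species_b})",
            f"  significant cells (q <= {self.q_max:g}): "
            f"{int((m.q <= self.q_max).sum())}",
            f"  bands: {len(self.bands)}",
        ]
        for i, band in enumerate(self.bands):
            lines.append(
                f"    band {i}: {len(band.cells)} cells, "
                f"mean offset {band.mean_offset:+.2f}"
            )
        lines.append(f"  dual-alignment ortholog pairs: {len(self.dual_pairs)}")
        return "\n".join(lines)
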