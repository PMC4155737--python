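"""Synthetic benchmark generators with planted ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — transcribed runs over background noise, cross-species
co-expression modules linked by orthology, two-species developmental time
courses with a planted stage correspondence and hourglass-shaped module
divergence, and chromatin signal tensors generated from a known linear
model of log-expression. Every generator is a pure function of its seed
and parameters, and every returned object satisfies the io_core type
invariants.

The distributional choices (log-normal expression, latent-factor modules,
Bernoulli coverage noise) are package conventions chosen for analytic
control of the planted effect sizes, not claims about any particular
experimental data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin import BinScheme, SignalTensor
from .io_core import (
    CoverageTrack,
    ExpressionMatrix,
    GenomicInterval,
    OrthologyMap,
    ValidationError,
)

__all__ = [
    "TarTruth",
    "ModuleTruth",
    "StageTruth",
    "ChromatinTruth",
    "simulate_coverage",
    "simulate_multilayer_expression",
    "simulate_dev_timecourse",
    "simulate_hourglass_profiles",
    "simulate_chromatin",
]


@dataclass
class TarTruth:
    """Planted transcribed runs underlying a simulated coverage track."""

    intervals: list[GenomicInterval]
    depth: float
    background_rate: float


@dataclass
class ModuleTruth:
    """Planted module labels for a multilayer co-expression benchmark.

    ``assignment`` maps ``(species, gene) -> module label``; background
    genes carry the label ``-1``.
    """

    assignment: dict[tuple[str, str], int]
    n_modules: int
    rho: float
    ortholog_consistency: float


@dataclass
class StageTruth:
    """Planted structure of a two-species developmental time course."""

    stage_map: set[tuple[int, int]]
    secondary_map: set[tuple[int, int]]
    associated_genes: dict[str, dict[int, set[str]]]
    dual_pairs: set[tuple[str, str]]
    module_assignment: dict[str, dict[str, int]]
    phylotypic_index: dict[str, int]
    hourglass_amplitude: float


@dataclass
class ChromatinTruth:
    """Generative parameters of a simulated chromatin→expression data set."""

    marks: list[str]
    beta: np.ndarray
    sigma: float
    organism_scales: list[float]
    bin_profile: np.ndarray  # marks × bins, rows sum to 1
    peak_bins: list[int]
    gene_class: dict[str, str] = field(default_factory=dict)  # gene -> coding/ncRNA
    intercepts: list[float] = field(default_factory=list)  # per organism


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def simulate_coverage(
    chrom_length: int,
    n_runs: int,
    run_length_range: tuple[int, int],
    depth: float,
    background_rate: float,
    seed: int,
    chrom: str = "chr1",
    species: str = "syn",
    noise_depth: float = 1.0,
    min_separation: int = 30,
) -> tuple[CoverageTrack, TarTruth]:
    """Plant non-overlapping transcribed runs on a noisy coverage track.

    Runs of length uniform in ``run_length_range`` are placed uniformly at
    random, separated by at least ``min_separation`` bases, and receive a
    constant per-base signal ``depth``. Background noise adds
    ``noise_depth`` to each base independently with probability
    ``background_rate``. Segmentation recovers the planted runs exactly
    (absent noise) whenever its max_gap is smaller than
    ``min_separation``, which the default separation guarantees for the
    default gap of 25 bases.
    """
    lo, hi = run_length_range
    if not (1 <= lo <= hi):
        raise ValidationError("run_length_range must satisfy 1 <= lo <= hi")
    if n_runs * hi >= chrom_length:
        raise ValidationError("planted runs cannot fit in the chromosome")
    rng = np.random.default_rng(seed)
    placed: list[tuple[int, int]] = []
    for _ in range(n_runs):
        length = int(rng.integers(lo, hi + 1))
        sep = min_separation
        for _attempt in range(1000):
            start = int(rng.integers(0, chrom_length - length + 1))
            end = start + length
            if all(end + sep <= s or e + sep <= start for s, e in placed):
                placed.append((start, end))
                break
        else:
            raise ValidationError("could not place runs without overlap")
    placed.sort()
    values = np.zeros(chrom_length)
    if background_rate > 0:
        noise = rng.random(chrom_length) < background_rate
        values[noise] += noise_depth
    intervals = []
    for i, (s, e) in enumerate(placed):
        values[s:e] += depth
        intervals.append(GenomicInterval(chrom, s, e, name=f"run_{i}"))
    track = CoverageTrack(species=species, values={chrom: values})
    return track, TarTruth(intervals=intervals, depth=depth, background_rate=background_rate)


# ---------------------------------------------------------------------------
# multilayer co-expression
# ---------------------------------------------------------------------------

def simulate_multilayer_expression(
    k_species: int,
    genes_per_species: int,
    n_modules: int,
    rho: float,
    ortholog_fraction: float,
    ortholog_consistency: float,
    n_samples: int,
    seed: int,
    background_fraction: float = 0.2,
) -> tuple[dict[str, ExpressionMatrix], OrthologyMap, ModuleTruth]:
    """Generate k species' expression matrices with planted shared modules.

    Within a module, every gene loads on one latent per-sample factor with
    weight ``sqrt(rho)`` so any two module genes have expected Pearson
    correlation ``rho`` on the latent (log) scale; background genes are
    independent noise. Expression is the exponential of the latent value,
    hence strictly positive. Module labels are shared across species, and
    ortholog pairs link same-label genes with probability
    ``ortholog_consistency`` (otherwise two random genes).
    """
    if not 0 <= rho < 1:
        raise ValidationError("rho must be in [0, 1)")
    if n_modules > genes_per_species:
        raise ValidationError("more modules than genes per species")
    for frac in (ortholog_fraction, ortholog_consistency, background_fraction):
        if not 0 <= frac <= 1:
            raise ValidationError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    species = [f"sp{i}" for i in range(k_species)]
    n_background = int(round(background_fraction * genes_per_species))
    n_module_genes = genes_per_species - n_background

    assignment: dict[tuple[str, str], int] = {}
    exprs: dict[str, ExpressionMatrix] = {}
    module_members: dict[str, dict[int, list[str]]] = {}
    for sp in species:
        genes = [f"{sp}_g{i:04d}" for i in range(genes_per_species)]
        labels = np.full(genes_per_species, -1, dtype=int)
        if n_modules > 0 and n_module_genes > 0:
            labels[:n_module_genes] = np.arange(n_module_genes) % n_modules
        factors = rng.standard_normal((n_modules, n_samples))
        noise = rng.standard_normal((genes_per_species, n_samples))
        latent = np.empty((genes_per_species, n_samples))
        for i, lab in enumerate(labels):
            if lab >= 0:
                latent[i] = np.sqrt(rho) * factors[lab] + np.sqrt(1 - rho) * noise[i]
            else:
                latent[i] = noise[i]
        values = pd.DataFrame(
            np.exp(latent),
            index=genes,
            columns=[f"s{j:03d}" for j in range(n_samples)],
        )
        meta = pd.DataFrame(
            {
                "species": sp,
                "stage_index": np.arange(n_samples),
                "stage_label": [f"s{j:03d}" for j in range(n_samples)],
                "tissue": "whole",
            },
            index=pd.Index(values.columns, name="sample"),
        )
        exprs[sp] = ExpressionMatrix(species=sp, values=values, sample_meta=meta)
        members: dict[int, list[str]] = {m: [] for m in range(n_modules)}
        for g, lab in zip(genes, labels):
            assignment[(sp, g)] = int(lab)
            if lab >= 0:
                members[int(lab)].append(g)
        module_members[sp] = members

    omap = OrthologyMap()
    n_pairs = int(round(ortholog_fraction * genes_per_species))
    for ia in range(k_species):
        for ib in range(ia + 1, k_species):
            sa, sb = species[ia], species[ib]
            for _ in range(n_pairs):
                if n_modules > 0 and rng.random() < ortholog_consistency:
                    m = int(rng.integers(n_modules))
                    ga = module_members[sa][m][int(rng.integers(len(module_members[sa][m])))]
                    gb = module_members[sb][m][int(rng.integers(len(module_members[sb][m])))]
                else:
                    ga = exprs[sa].genes[int(rng.integers(genes_per_species))]
                    gb = exprs[sb].genes[int(rng.integers(genes_per_species))]
                omap.add(sa, ga, sb, gb)

    truth = ModuleTruth(
        assignment=assignment,
        n_modules=n_modules,
        rho=rho,
        ortholog_consistency=ortholog_consistency,
    )
    return exprs, omap, truth


# ---------------------------------------------------------------------------
# developmental time courses
# ---------------------------------------------------------------------------

def _primary_stage(s_a: int, n_a: int, n_b: int) -> int:
    if n_a == 1:
        return 0
    return int(round(s_a * (n_b - 1) / (n_a - 1)))


def simulate_dev_timecourse(
    n_stages_a: int,
    n_stages_b: int,
    n_genes: int,
    assoc_per_stage: int,
    dual_band: bool,
    phylotypic_a: int,
    phylotypic_b: int,
    hourglass_amplitude: float,
    noise_sd: float,
    seed: int,
    n_modules: int = 16,
    dual_genes_per_stage: int = 4,
    peak_log_expr: float = 4.0,
    base_log_expr: float = 0.7,
) -> tuple[tuple[ExpressionMatrix, ExpressionMatrix], OrthologyMap, StageTruth]:
    """Two species' stage-collapsed time courses with planted structure.

    Three layers of structure are planted on top of log-scale noise:

    * per stage, ``assoc_per_stage`` stage-associated genes that peak at
      their stage (high ``peak_log_expr`` there, low elsewhere);
    * an orthology map pairing the stage-associated genes of corresponding
      stages along the primary (proportional) stage correspondence, plus —
      when ``dual_band`` — a secondary band at a positive stage offset in
      species B (the embryo↔metamorphosis-type pairing), carried by
      ``dual_genes_per_stage`` B genes per banded stage that are associated
      with *both* of their A-stage partners' B stages;
    * ``n_modules`` gene modules whose per-stage mean trajectories all pass
      through a common value at the species' phylotypic stage and spread
      apart linearly with distance from it, at slope proportional to
      ``hourglass_amplitude`` (the hourglass shape).
    """
    for n_stages, phylo in ((n_stages_a, phylotypic_a), (n_stages_b, phylotypic_b)):
        if not 0 <= phylo < n_stages:
            raise ValidationError("phylotypic index out of stage range")
    if assoc_per_stage * max(n_stages_a, n_stages_b) > n_genes:
        raise ValidationError("not enough genes for the requested associations")
    rng = np.random.default_rng(seed)

    species = ("wrm", "fly")
    n_stages = {"wrm": n_stages_a, "fly": n_stages_b}
    phylotypic = {"wrm": phylotypic_a, "fly": phylotypic_b}

    # planted stage correspondences
    primary = {(s, _primary_stage(s, n_stages_a, n_stages_b)) for s in range(n_stages_a)}
    secondary: set[tuple[int, int]] = set()
    if dual_band:
        offset = max(2, n_stages_b // 3)
        for s_a in range(n_stages_a // 2, n_stages_a):
            s_b = _primary_stage(s_a, n_stages_a, n_stages_b) + offset
            if s_b < n_stages_b:
                secondary.add((s_a, s_b))

    # stage-associated genes: first assoc_per_stage*n_stages genes, in blocks
    assoc: dict[str, dict[int, set[str]]] = {}
    genes: dict[str, list[str]] = {}
    assoc_stages: dict[str, dict[str, set[int]]] = {}
    for sp in species:
        gl = [f"{sp}_g{i:04d}" for i in range(n_genes)]
        genes[sp] = gl
        per_stage: dict[int, set[str]] = {}
        stages_of: dict[str, set[int]] = {}
        for s in range(n_stages[sp]):
            block = gl[s * assoc_per_stage : (s + 1) * assoc_per_stage]
            per_stage[s] = set(block)
            for g in block:
                stages_of.setdefault(g, set()).add(s)
        assoc[sp] = per_stage
        assoc_stages[sp] = stages_of

    # orthology along the bands; dual genes get a second B-stage association
    omap = OrthologyMap()
    dual_pairs: set[tuple[str, str]] = set()
    blocks_a = {s: sorted(assoc["wrm"][s]) for s in range(n_stages_a)}
    blocks_b = {s: sorted(assoc["fly"][s]) for s in range(n_stages_b)}
    for s_a, s_b in sorted(primary):
        for ga, gb in zip(blocks_a[s_a], blocks_b[s_b]):
            omap.add("wrm", ga, "fly", gb)
    for s_a, s_b2 in sorted(secondary):
        s_b1 = _primary_stage(s_a, n_stages_a, n_stages_b)
        n_dual = min(dual_genes_per_stage, assoc_per_stage)
        for k, (ga, gb) in enumerate(zip(blocks_a[s_a], blocks_b[s_b2])):
            omap.add("wrm", ga, "fly", gb)
            if k < n_dual:
                # the primary partner of ga becomes associated with s_b2 too,
                # so the pair (ga, primary partner) hits both bands
                gb1 = blocks_b[s_b1][k]
                assoc["fly"][s_b2].add(gb1)
                assoc_stages["fly"][gb1].add(s_b2)
                dual_pairs.add((ga, gb1))

    # modules over the remaining genes, with hourglass trajectories: a
    # common linear drift plus per-module stage-wise deviations whose
    # s.d. grows with distance from the phylotypic stage, so module
    # trajectories converge there (and still do after median-centering)
    module_assignment: dict[str, dict[str, int]] = {}
    exprs: dict[str, ExpressionMatrix] = {}
    for sp in species:
        ns = n_stages[sp]
        used = assoc_per_stage * ns
        free = genes[sp][used:]
        mod_of: dict[str, int] = {}
        for i, g in enumerate(free):
            mod_of[g] = i % n_modules if n_modules > 0 else -1
        module_assignment[sp] = mod_of

        stages_idx = np.arange(ns)
        common = base_log_expr + stages_idx / max(ns - 1, 1)
        dist = np.abs(stages_idx - phylotypic[sp]) / max(ns - 1, 1)
        module_dev = (
            hourglass_amplitude
            * dist[None, :]
            * rng.standard_normal((max(n_modules, 1), ns))
        )
        log_expr = np.empty((n_genes, ns))
        for i, g in enumerate(genes[sp]):
            if g in assoc_stages[sp]:
                prof = np.full(ns, base_log_expr)
                for s in assoc_stages[sp][g]:
                    prof[s] = peak_log_expr
            else:
                m = mod_of[g]
                prof = common + (module_dev[m] if m >= 0 else 0.0)
            log_expr[i] = prof
        log_expr += noise_sd * rng.standard_normal(log_expr.shape)
        values = pd.DataFrame(
            np.exp(log_expr),
            index=genes[sp],
            columns=[f"{sp}_st{s:02d}" for s in range(ns)],
        )
        meta = pd.DataFrame(
            {
                "species": sp,
                "stage_index": np.arange(ns),
                "stage_label": values.columns,
                "tissue": "whole",
            },
            index=pd.Index(values.columns, name="sample"),
        )
        exprs[sp] = ExpressionMatrix(species=sp, values=values, sample_meta=meta)

    truth = StageTruth(
        stage_map=primary,
        secondary_map=secondary,
        associated_genes=assoc,
        dual_pairs=dual_pairs,
        module_assignment=module_assignment,
        phylotypic_index=phylotypic,
        hourglass_amplitude=hourglass_amplitude,
    )
    return (exprs["wrm"], exprs["fly"]), omap, truth


def simulate_hourglass_profiles(
    n_species: int,
    n_stages: int,
    phylotypic_index: int,
    hourglass_amplitude: float,
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, int]:
    """Per-species stage profiles of one module that converge mid-development.

    Returns an ``n_species × n_stages`` array of log-scale module summary
    values: per-species stage-wise deviations whose s.d. equals
    ``hourglass_amplitude`` times the relative stage distance from the
    phylotypic index (so the profiles converge there), plus baseline
    Gaussian noise. The trajectory component shared by all species is
    constant (zero): any shared trajectory cancels from a cross-species
    dispersion comparison, while a non-constant one would let per-profile
    median-centering anchor every profile at the same stage and
    manufacture spurious convergence there.
    """
    if not 0 <= phylotypic_index < n_stages:
        raise ValidationError("phylotypic index out of stage range")
    rng = np.random.default_rng(seed)
    stages = np.arange(n_stages)
    dist = np.abs(stages - phylotypic_index) / max(n_stages - 1, 1)
    profiles = hourglass_amplitude * dist[None, :] * rng.standard_normal(
        (n_species, n_stages)
    )
    profiles += noise_sd * rng.standard_normal(profiles.shape)
    return profiles, phylotypic_index


# ---------------------------------------------------------------------------
# chromatin
# ---------------------------------------------------------------------------

def simulate_chromatin(
    n_genes: int,
    marks: list[str],
    n_bins: int,
    beta: np.ndarray,
    sigma: float,
    organisms: int,
    organism_scales: list[float],
    seed: int,
    ncrna_fraction: float = 0.2,
    pseudocount: float = 1.0,
    bin_width: int = 100,
) -> tuple[list[SignalTensor], list[ExpressionMatrix], ChromatinTruth]:
    """Simulate gene × mark × bin signal tensors and matched expression.

    Each mark has a spatial profile across bins peaked at a mark-specific
    bin; a gene's per-mark base level is log-normal. Per organism, signals
    are multiplied by that organism's scale, and expression is then the
    planted linear model evaluated on the *stored* (scaled) signal, on the
    same pseudocounted log scale a downstream fit uses:

        log(expr + pc) = sum_m beta_m * log(signal[g, m, peak_bin_m] + pc)
                         + intercept + N(0, sigma)

    with the intercept chosen from the realized signals (and recorded in
    the truth) so expression stays non-negative; a noiseless fit at the
    peak bins therefore recovers ``beta`` exactly. A
    fraction of genes is tagged ``ncRNA`` (same generative process as
    coding genes) for train-on-coding/predict-on-ncRNA experiments.

    Returns per-organism signal tensors (arrays), per-organism single-sample
    expression matrices, and the generative truth.
    """
    beta = np.asarray(beta, dtype=float)
    if len(beta) != len(marks):
        raise ValidationError("beta and marks differ in length")
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if len(organism_scales) != organisms:
        raise ValidationError("need one scale per organism")
    if any(s <= 0 for s in organism_scales):
        raise ValidationError("organism scales must be positive")
    rng = np.random.default_rng(seed)
    n_marks = len(marks)

    # mark spatial profiles: Gaussian bumps at spread-out peak bins
    peak_bins = [int(round((m + 0.5) * n_bins / n_marks - 0.5)) for m in range(n_marks)]
    bins = np.arange(n_bins)
    width = max(n_bins / 10.0, 1.0)
    profile = np.empty((n_marks, n_bins))
    for m in range(n_marks):
        bump = np.exp(-0.5 * ((bins - peak_bins[m]) / width) ** 2)
        profile[m] = bump / bump.sum()

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    n_nc = int(round(ncrna_fraction * n_genes))
    nc_set = set(rng.choice(n_genes, size=n_nc, replace=False).tolist())
    gene_class = {
        g: ("ncRNA" if i in nc_set else "coding") for i, g in enumerate(gene_ids)
    }

    scheme = BinScheme(n_bins=n_bins, bin_width=bin_width)
    tensors: list[SignalTensor] = []
    exprs: list[ExpressionMatrix] = []
    intercepts: list[float] = []
    for org in range(organisms):
        base = np.exp(rng.normal(2.0, 1.0, size=(n_genes, n_marks)))
        rel = profile / profile.max(axis=1, keepdims=True)
        tensor = organism_scales[org] * base[:, :, None] * rel[None, :, :]
        peak_sig = tensor[:, np.arange(n_marks), peak_bins]
        log_x = np.log(peak_sig + pseudocount)
        log_y = log_x @ beta + sigma * rng.standard_normal(n_genes)
        # shift so exp(log_y + intercept) >= pseudocount for every gene,
        # keeping expression non-negative on the linear scale
        neg = np.clip(beta, None, 0.0)
        intercept = float(np.log(pseudocount) - (log_x.max(axis=0) @ neg)
                          + sigma * 6.0)
        values = pd.DataFrame(
            {"expr": np.exp(log_y + intercept) - pseudocount},
            index=pd.Index(gene_ids, name="gene"),
        )
        values[values < 0] = 0.0  # only reachable by >6-sigma noise
        intercepts.append(intercept)
        meta = pd.DataFrame(
            {
                "species": f"org{org}",
                "stage_index": [0],
                "stage_label": ["bulk"],
                "tissue": "whole",
            },
            index=pd.Index(["expr"], name="sample"),
        )
        tensors.append(
            SignalTensor(
                organism=f"org{org}",
                genes=gene_ids,
                marks=list(marks),
                scheme=scheme,
                values=tensor,
            )
        )
        exprs.append(
            ExpressionMatrix(species=f"org{org}", values=values, sample_meta=meta)
        )

    truth = ChromatinTruth(
        marks=list(marks),
        beta=beta,
        sigma=sigma,
        organism_scales=list(organism_scales),
        bin_profile=profile,
        peak_bins=peak_bins,
        gene_class=gene_class,
        intercepts=intercepts,
    )
    return tensors, exprs, truth
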