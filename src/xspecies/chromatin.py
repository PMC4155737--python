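"""Predicting gene expression from chromatin signal around the TSS.

Chromatin signals (histone marks or TF binding) are averaged into fixed
bins around each gene's TSS, oriented so bin 0 is always most upstream.
Per-mark correlation profiles against log expression pick one best bin
per mark; those features enter an ordinary least-squares model of log
expression, evaluated by gene-wise cross-validated Pearson correlation,
with feature importance measured by normalized drop-one loss in R².
A universal variant z-standardizes features and response per organism,
pools the rows, and fits one organism-independent coefficient vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .io_core import CoverageTrack, ExpressionMatrix, GenomicInterval, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BinScheme",
    "SignalTensor",
    "CorrelationProfile",
    "ModelFit",
    "bin_signals",
    "correlation_profile",
    "select_best_bins",
    "fit_organism_model",
    "fit_universal_model",
    "predict_expression",
    "tf_subset_curve",
    "ChromatinExpressionModel",
    "UniversalChromatinModel",
    "ChromatinResults",
]


@dataclass(frozen=True)
class BinScheme:
    """Strand-aware binning geometry around the TSS.

    ``n_bins`` must be odd so one bin straddles the TSS; bins are
    ``bin_width`` bases wide and bin 0 is the most upstream bin on either
    strand. The default (81 bins x 100 bp, about ±4 kb) is a package
    convention.
    """

    n_bins: int = 81
    bin_width: int = 100

    def __post_init__(self) -> None:
        if self.n_bins % 2 == 0 or self.n_bins < 1:
            raise ValidationError("n_bins must be odd and >= 1")
        if self.bin_width < 1:
            raise ValidationError("bin_width must be >= 1")

    @property
    def center(self) -> int:
        return self.n_bins // 2

    def bin_span(self, tss: int, strand: str, i: int) -> tuple[int, int]:
        """Half-open genomic span of bin ``i`` for a TSS at base ``tss``.

        Minus-strand spans are the exact base-level mirror of the
        plus-strand spans around the TSS base, so reversing the genome
        and all strands leaves the binning invariant.
        """
        w, c = self.bin_width, self.center
        if strand == "-":
            start = tss - (i - c) * w - (w - w // 2) + 1
        else:
            start = tss + (i - c) * w - w // 2
        return start, start + w


@dataclass
class SignalTensor:
    """Mean signal per gene × mark × bin for one organism."""

    organism: str
    genes: list[str]
    marks: list[str]
    scheme: BinScheme
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.genes), len(self.marks), self.scheme.n_bins)
        if self.values.shape != expected:
            raise ValidationError(
                f"tensor shape {self.values.shape} != {expected}"
            )
        if self.values.size and self.values.min() < 0:
            raise ValidationError("negative signal in tensor")

    def subset_marks(self, marks: list[str]) -> "SignalTensor":
        idx = [self.marks.index(m) for m in marks]
        return SignalTensor(
            organism=self.organism,
            genes=self.genes,
            marks=list(marks),
            scheme=self.scheme,
            values=self.values[:, idx, :],
        )


def tss_position(interval: GenomicInterval) -> int:
    """TSS base of a gene interval: 5' end respecting strand."""
    return interval.end - 1 if interval.strand == "-" else interval.start


def bin_signals(
    tracks: dict[str, CoverageTrack],
    tss: list[GenomicInterval],
    scheme: BinScheme,
    organism: str = "",
) -> SignalTensor:
    """Average per-mark signal into strand-oriented bins around each TSS.

    ``tracks`` maps mark name to its coverage track. Bins extending past
    a chromosome end are zero-filled (the mean is taken over the full bin
    width) and logged. For minus-strand genes the bin order is mirrored so
    bin 0 is always the most upstream bin.
    """
    if not tracks:
        raise ValidationError("no tracks supplied")
    marks = sorted(tracks)
    genes = [iv.name or f"{iv.chrom}:{iv.start}" for iv in tss]
    values = np.zeros((len(tss), len(marks), scheme.n_bins))
    for mi, mark in enumerate(marks):
        track = tracks[mark]
        for gi, iv in enumerate(tss):
            arr = track.values.get(iv.chrom)
            if arr is None:
                raise ValidationError(f"track {mark!r} lacks chromosome {iv.chrom!r}")
            t = tss_position(iv)
            clipped = False
            for b in range(scheme.n_bins):
                s, e = scheme.bin_span(t, iv.strand, b)
                cs, ce = max(s, 0), min(e, arr.size)
                if cs >= ce:
                    clipped = clipped or (s < 0 or e > arr.size)
                    continue
                if s < 0 or e > arr.size:
                    clipped = True
                values[gi, mi, b] = arr[cs:ce].sum() / scheme.bin_width
            if clipped:
                logger.info("bins clipped at chromosome edge for %s", genes[gi])
    return SignalTensor(organism=organism or next(iter(tracks.values())).species,
                        genes=genes, marks=marks, scheme=scheme, values=values)


@dataclass
class CorrelationProfile:
    """Per-mark, per-bin Pearson correlation with log expression."""

    marks: list[str]
    raw: np.ndarray  # marks × bins
    normalized: np.ndarray  # per-mark division by max |r|, sign preserved
    scheme: BinScheme


def _matched_expression(tensor: SignalTensor, expr: ExpressionMatrix) -> np.ndarray:
    missing = sorted(set(tensor.genes) - set(expr.values.index))
    if missing:
        raise ValidationError(f"expression missing for genes {missing[:3]}")
    sub = expr.values.loc[tensor.genes]
    if sub.shape[1] != 1:
        raise ValidationError("expected a single expression sample per organism")
    return sub.to_numpy(dtype=float).ravel()


def correlation_profile(
    tensor: SignalTensor,
    expr: ExpressionMatrix,
    normalize: bool = True,
    pseudocount: float = 1.0,
) -> CorrelationProfile:
    """Correlate log signal in every (mark, bin) with log expression.

    Constant features get r = 0 (logged). The normalized variant divides
    each mark's bin vector by its maximum |r|, preserving sign.
    """
    y = np.log(_matched_expression(tensor, expr) + pseudocount)
    x = np.log(tensor.values + pseudocount)
    n_marks, n_bins = len(tensor.marks), tensor.scheme.n_bins
    raw = np.zeros((n_marks, n_bins))
    y_sd = y.std()
    for m in range(n_marks):
        for b in range(n_bins):
            v = x[:, m, b]
            # near-constant columns carry only float noise; their sample
            # correlations are spurious and must not win bin selection
            if v.std() <= 1e-10 * max(1.0, abs(v.mean())) or y_sd == 0:
                logger.info("constant feature %s bin %d: r set to 0",
                            tensor.marks[m], b)
                continue
            raw[m, b] = stats.pearsonr(v, y)[0]
    normalized = raw.copy()
    for m in range(n_marks):
        peak = np.abs(raw[m]).max()
        if peak > 0:
            normalized[m] = raw[m] / peak
    return CorrelationProfile(marks=list(tensor.marks), raw=raw,
                              normalized=normalized if normalize else raw.copy(),
                              scheme=tensor.scheme)


def select_best_bins(profile: CorrelationProfile) -> dict[str, int]:
    """Pick per mark the bin with maximum |r|.

    Ties are broken by distance to the TSS-straddling center bin, then in
    favor of the upstream bin.
    """
    c = profile.scheme.center
    best: dict[str, int] = {}
    for m, mark in enumerate(profile.marks):
        absr = np.abs(profile.raw[m])
        peak = absr.max()
        candidates = np.flatnonzero(absr == peak)
        best[mark] = int(min(candidates, key=lambda b: (abs(b - c), b >= c, b)))
    return best


@dataclass
class ModelFit:
    """A fitted (possibly universal) chromatin→expression linear model.

    Coefficients act on log(signal + pseudocount) at each mark's selected
    bin; for universal fits they act on per-organism z-standardized
    features, with the standardization parameters recorded per organism.
    """

    marks: list[str]
    best_bins: dict[str, dict[str, int]]  # organism -> mark -> bin
    coef: np.ndarray
    intercept: float
    importance: np.ndarray
    cv_accuracy: float
    cv_per_fold: list[float]
    universal: bool
    pseudocount: float
    folds: int
    standardization: dict[str, dict[str, np.ndarray | float]] = field(
        default_factory=dict
    )
    cv_per_organism: dict[str, float] = field(default_factory=dict)
    organism: str = ""

    def summary(self) -> str:
        kind = "universal" if self.universal else f"organism ({self.organism})"
        lines = [
            f"Chromatin expression model [{kind}]",
            f"  features ({len(self.marks)} marks, best bin per mark):",
        ]
        for i, mark in enumerate(self.marks):
            bins = {org: bb[mark] for org, bb in self.best_bins.items()}
            binstr = ", ".join(f"{o}:{b}" for o, b in sorted(bins.items()))
            lines.append(
                f"    {mark:<12} coef={self.coef[i]:+.4f} "
                f"importance={self.importance[i]:.3f} bin[{binstr}]"
            )
        lines.append(f"  intercept: {self.intercept:+.4f}")
        lines.append(
            f"  cross-validated Pearson r ({self.folds}-fold): "
            f"{self.cv_accuracy:.4f}"
        )
        for org, r in sorted(self.cv_per_organism.items()):
            lines.append(f"    {org}: r = {r:.4f}")
        return "\n".join(lines)


def _is_constant(a: np.ndarray) -> bool:
    return bool(a.std() <= 1e-12 * max(1.0, float(np.abs(a).max(initial=0.0))))


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if _is_constant(a) or _is_constant(b):
        return 0.0
    return float(stats.pearsonr(a, b)[0])


def _design(tensor: SignalTensor, best: dict[str, int], pc: float) -> np.ndarray:
    cols = [
        np.log(tensor.values[:, tensor.marks.index(m), best[m]] + pc)
        for m in tensor.marks
    ]
    return np.column_stack(cols)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least squares with intercept; returns (coef, intercept, r2)."""
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
    return beta[1:], float(beta[0]), float(r2)


def _check_rank(x: np.ndarray, marks: list[str]) -> None:
    design = np.column_stack([np.ones(len(x)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name features whose column is (nearly) in the span of the others
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [marks[i - 1] for i in range(1, design.shape[1])
               if diag[i] < 1e-10 * max(diag.max(), 1.0)]
        raise ValidationError(f"rank-deficient design; collinear features: {bad}")


def _drop_one_importance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    _, _, r2_full = _ols(x, y)
    losses = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        keep = [k for k in range(x.shape[1]) if k != j]
        if keep:
            _, _, r2_drop = _ols(x[:, keep], y)
        else:
            r2_drop = 0.0
        losses[j] = max(r2_full - r2_drop, 0.0)
    total = losses.sum()
    if total == 0:
        return np.full(x.shape[1], 1.0 / x.shape[1])
    return losses / total


def fit_organism_model(
    tensor: SignalTensor,
    expr: ExpressionMatrix,
    folds: int = 10,
    seed: int = 0,
    pseudocount: float = 1.0,
    best_bins: dict[str, int] | None = None,
) -> ModelFit:
    """OLS of log expression on per-mark best-bin log signals.

    Cross-validated accuracy is the mean held-out Pearson r over seeded
    gene-wise folds; importance is the normalized drop-one loss in R²
    (floored at 0, rescaled to sum to 1).
    """
    if len(tensor.marks) < 1:
        raise ValidationError("need at least one mark")
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if best_bins is None:
        profile = correlation_profile(tensor, expr, pseudocount=pseudocount)
        best_bins = select_best_bins(profile)
    x = _design(tensor, best_bins, pseudocount)
    y = np.log(_matched_expression(tensor, expr) + pseudocount)
    _check_rank(x, tensor.marks)
    coef, intercept, _ = _ols(x, y)
    importance = _drop_one_importance(x, y)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    for train, test in kf.split(x):
        c, b0, _ = _ols(x[train], y[train])
        pred = x[test] @ c + b0
        per_fold.append(_safe_pearson(pred, y[test]))
    return ModelFit(
        marks=list(tensor.marks),
        best_bins={tensor.organism: dict(best_bins)},
        coef=coef,
        intercept=intercept,
        importance=importance,
        cv_accuracy=float(np.mean(per_fold)),
        cv_per_fold=per_fold,
        universal=False,
        pseudocount=pseudocount,
        folds=folds,
        organism=tensor.organism,
    )


def fit_universal_model(
    data: list[tuple[SignalTensor, ExpressionMatrix]],
    folds: int = 10,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> ModelFit:
    """One organism-independent coefficient vector across organisms.

    Each organism's features (its own best bin per mark) and log
    expression are z-standardized per organism; standardized rows are
    pooled and a single OLS fit made. Cross-validation splits each
    organism's genes into seeded folds (so every fold holds out genes
    from every organism) and computes standardization on the training
    portion only. ``cv_per_organism`` reports held-out r per organism and
    ``cv_accuracy`` their mean.
    """
    if not data:
        raise ValidationError("no organisms supplied")
    mark_sets = {tuple(t.marks) for t, _ in data}
    if len(mark_sets) != 1:
        raise ValidationError("organisms have different mark sets")
    marks = list(data[0][0].marks)
    xs, ys, best_bins = {}, {}, {}
    for tensor, expr in data:
        profile = correlation_profile(tensor, expr, pseudocount=pseudocount)
        bb = select_best_bins(profile)
        best_bins[tensor.organism] = bb
        xs[tensor.organism] = _design(tensor, bb, pseudocount)
        ys[tensor.organism] = np.log(_matched_expression(tensor, expr) + pseudocount)

    def standardize(x, y):
        xm, xs_ = x.mean(axis=0), x.std(axis=0)
        ym, ysd = y.mean(), y.std()
        xs_ = np.where(xs_ > 0, xs_, 1.0)
        ysd = ysd if ysd > 0 else 1.0
        return (x - xm) / xs_, (y - ym) / ysd, xm, xs_, ym, ysd

    standardization = {}
    pooled_x, pooled_y = [], []
    for org in sorted(xs):
        zx, zy, xm, xsd, ym, ysd = standardize(xs[org], ys[org])
        standardization[org] = {
            "x_mean": xm, "x_sd": xsd, "y_mean": float(ym), "y_sd": float(ysd)
        }
        pooled_x.append(zx)
        pooled_y.append(zy)
    x_all = np.vstack(pooled_x)
    y_all = np.concatenate(pooled_y)
    _check_rank(x_all, marks)
    coef, intercept, _ = _ols(x_all, y_all)
    importance = _drop_one_importance(x_all, y_all)

    splitters = {
        org: list(KFold(folds, shuffle=True, random_state=seed).split(xs[org]))
        for org in sorted(xs)
    }
    per_fold = []
    per_org_acc = {org: [] for org in xs}
    for f in range(folds):
        train_x, train_y = [], []
        fold_std = {}
        for org in sorted(xs):
            tr, _ = splitters[org][f]
            zx, zy, xm, xsd, ym, ysd = standardize(xs[org][tr], ys[org][tr])
            fold_std[org] = (xm, xsd, ym, ysd)
            train_x.append(zx)
            train_y.append(zy)
        c, b0, _ = _ols(np.vstack(train_x), np.concatenate(train_y))
        fold_rs = []
        for org in sorted(xs):
            _, te = splitters[org][f]
            xm, xsd, ym, ysd = fold_std[org]
            pred = ((xs[org][te] - xm) / xsd) @ c + b0
            truth = (ys[org][te] - ym) / ysd
            r = _safe_pearson(pred, truth)
            per_org_acc[org].append(r)
            fold_rs.append(r)
        per_fold.append(float(np.mean(fold_rs)))
    cv_per_organism = {org: float(np.mean(rs)) for org, rs in per_org_acc.items()}
    return ModelFit(
        marks=marks,
        best_bins=best_bins,
        coef=coef,
        intercept=intercept,
        importance=importance,
        cv_accuracy=float(np.mean(list(cv_per_organism.values()))),
        cv_per_fold=per_fold,
        universal=True,
        pseudocount=pseudocount,
        folds=folds,
        standardization=standardization,
        cv_per_organism=cv_per_organism,
    )


def predict_expression(
    fit: ModelFit,
    tensor: SignalTensor,
    expr: ExpressionMatrix | None = None,
) -> tuple[np.ndarray, float | None]:
    """Predict log expression for a tensor; optionally score against truth.

    Returns predictions on the log(expr + pseudocount) scale and, when
    ``expr`` is given, the Pearson r against the log truth (0 with a
    warning when predictions are constant).
    """
    missing = [m for m in fit.marks if m not in tensor.marks]
    if missing:
        raise ValidationError(f"tensor lacks marks {missing}")
    org = tensor.organism
    if fit.universal:
        if org not in fit.standardization:
            raise ValidationError(
                f"no standardization parameters for organism {org!r}"
            )
        bb = fit.best_bins.get(org)
        if bb is None:
            raise ValidationError(f"no selected bins for organism {org!r}")
        sub = tensor.subset_marks(fit.marks)
        x = _design(sub, bb, fit.pseudocount)
        std = fit.standardization[org]
        zx = (x - std["x_mean"]) / std["x_sd"]
        pred = std["y_mean"] + std["y_sd"] * (zx @ fit.coef + fit.intercept)
    else:
        bb = next(iter(fit.best_bins.values()))
        sub = tensor.subset_marks(fit.marks)
        x = _design(sub, bb, fit.pseudocount)
        pred = x @ fit.coef + fit.intercept
    accuracy = None
    if expr is not None:
        y = np.log(_matched_expression(tensor, expr) + fit.pseudocount)
        if _is_constant(pred):
            warnings.warn("constant predictions; accuracy reported as 0")
            accuracy = 0.0
        else:
            accuracy = _safe_pearson(pred, y)
    return pred, accuracy


def tf_subset_curve(
    tensor: SignalTensor,
    expr: ExpressionMatrix,
    n_range: list[int],
    reps: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated accuracy of models on random TF subsets of size n.

    For each n in ``n_range``, ``reps`` random subsets of the tensor's
    marks are drawn (seeded) and an organism model fitted on each; the
    mean and s.d. of the cross-validated accuracy are reported per n.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if max(n_range) > len(tensor.marks):
        raise ValidationError("subset size exceeds available TFs")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_range:
        accs = []
        for _ in range(reps):
            chosen = sorted(rng.choice(len(tensor.marks), size=n, replace=False))
            sub = tensor.subset_marks([tensor.marks[i] for i in chosen])
            fit = fit_organism_model(sub, expr, folds=folds,
                                     seed=int(rng.integers(2**31)))
            accs.append(fit.cv_accuracy)
        rows.append({"n": n, "mean_accuracy": float(np.mean(accs)),
                     "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class ChromatinExpressionModel:
    """Organism-specific chromatin→expression model (statsmodels-style)."""

    def __init__(self, tensor: SignalTensor, expr: ExpressionMatrix,
                 pseudocount: float = 1.0) -> None:
        self.tensor = tensor
        self.expr = expr
        self.pseudocount = pseudocount

    def fit(self, folds: int = 10, seed: int = 0) -> "ChromatinResults":
        fit = fit_organism_model(self.tensor, self.expr, folds=folds, seed=seed,
                                 pseudocount=self.pseudocount)
        return ChromatinResults(fit=fit)


class UniversalChromatinModel:
    """Universal (organism-independent) chromatin→expression model."""

    def __init__(self, data: list[tuple[SignalTensor, ExpressionMatrix]],
                 pseudocount: float = 1.0) -> None:
        self.data = data
        self.pseudocount = pseudocount

    def fit(self, folds: int = 10, seed: int = 0) -> "ChromatinResults":
        fit = fit_universal_model(self.data, folds=folds, seed=seed,
                                  pseudocount=self.pseudocount)
        return ChromatinResults(fit=fit)


@dataclass
class ChromatinResults:
    """Results wrapper exposing the fitted parameters and summary table."""

    fit: ModelFit

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit.coef, index=self.fit.marks, name="coef")

    @property
    def importance(self) -> pd.Series:
        return pd.Series(self.fit.importance, index=self.fit.marks,
                         name="importance")

    def predict(self, tensor: SignalTensor, expr: ExpressionMatrix | None = None):
        return predict_expression(self.fit, tensor, expr)

    def summary(self) -> str:
        return self.fit.summary()
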