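"""K-fold protocol, P/U/O safety metrics, model comparison, odds ratios.

P/U/O summarize a predictor of safe resection volume from the surgical
safety standpoint:

* **P** — percentage of cases predicted *at or above* the reference
  volume (an over-prediction errs on the safe side; a tie counts as over,
  consistent with the loss's branch convention);
* **U** — mean absolute error among under-predicted cases (mL);
* **O** — mean absolute error among over-predicted cases (mL).

They satisfy the exact decomposition n*MAE = under_count*U + over_count*O.
The protocol is shuffled K-fold cross-validation (default K=5 on a
52-patient cohort, giving fold sizes 11,11,10,10,10), with per-fold P/U/O
averaged across folds; a pooled variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from .baselines import RegressorSpec, make_baseline
from .cohort import DEFAULT_FEATURE_NAMES, PatientRecord, cohort_to_arrays

__all__ = [
    "FoldPlan",
    "PUOMetrics",
    "MetricsReport",
    "ComparisonReport",
    "OddsRatioResult",
    "kfold_split",
    "compute_puo",
    "run_kfold",
    "compare_models",
    "paired_sign_test",
    "odds_ratio_2x2",
]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    n: int
    k: int
    assignment: tuple[int, ...]  # fold index per sample
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignment) == fold)

    def fold_sizes(self) -> list[int]:
        return [int(np.sum(np.asarray(self.assignment) == f)) for f in range(self.k)]


def kfold_split(n: int, k: int, seed: int = 0) -> FoldPlan:
    """Shuffled K-fold partition; sizes differ by at most one."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    assignment = np.empty(n, dtype=int)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)))):
        assignment[test_idx] = fold
    return FoldPlan(n=n, k=k, assignment=tuple(int(a) for a in assignment), seed=seed)


# ---------------------------------------------------------------------------
# P / U / O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PUOMetrics:
    p: float            # percent of over-(safe-)predicted cases
    u: float            # mean |error| among under-predictions, mL
    o: float            # mean |error| among over-predictions, mL
    under_count: int
    over_count: int
    under_empty: bool   # U reported as 0 because no case was under-predicted
    over_empty: bool


def compute_puo(y_pred, y_true) -> PUOMetrics:
    """P/U/O for one prediction vector; tie (pred == true) counts as over."""
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    y_true = np.asarray(y_true, dtype=float).ravel()
    if y_pred.shape != y_true.shape:
        raise ValueError(f"length mismatch: {y_pred.shape} vs {y_true.shape}")
    if y_pred.size == 0:
        raise ValueError("empty prediction vector")
    err = y_pred - y_true
    over = err >= 0
    over_count = int(over.sum())
    under_count = int((~over).sum())
    u = float(np.abs(err[~over]).mean()) if under_count else 0.0
    o = float(np.abs(err[over]).mean()) if over_count else 0.0
    return PUOMetrics(
        p=100.0 * over_count / y_pred.size,
        u=u, o=o,
        under_count=under_count, over_count=over_count,
        under_empty=under_count == 0, over_empty=over_count == 0,
    )


@dataclass(frozen=True)
class MetricsReport:
    model: str
    folds: tuple[PUOMetrics, ...]
    mean_p: float
    mean_u: float
    mean_o: float
    pooled: PUOMetrics | None = None

    @staticmethod
    def from_folds(model: str, folds: list[PUOMetrics], pooled: PUOMetrics | None = None):
        return MetricsReport(
            model=model,
            folds=tuple(folds),
            mean_p=float(np.mean([f.p for f in folds])),
            mean_u=float(np.mean([f.u for f in folds])),
            mean_o=float(np.mean([f.o for f in folds])),
            pooled=pooled,
        )


def _as_xy(cohort, feature_names) -> tuple[np.ndarray, np.ndarray]:
    records = getattr(cohort, "records", cohort)
    if len(records) and isinstance(records[0], PatientRecord):
        return cohort_to_arrays(records, feature_names)
    X, y = cohort  # (features, targets) pair
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


def run_kfold(
    model_spec: RegressorSpec,
    cohort,
    k: int = 5,
    seed: int = 0,
    feature_names=DEFAULT_FEATURE_NAMES,
) -> MetricsReport:
    """Fit on k-1 blocks, score the held-out block, average P/U/O.

    ``cohort`` may be a SyntheticCohort, a list of PatientRecord, or an
    ``(X, y)`` array pair. A fresh model (seeded per fold) is fit each
    iteration; the report also carries the pooled-prediction variant.
    """
    X, y = _as_xy(cohort, feature_names)
    plan = kfold_split(len(y), k, seed)
    folds = []
    pooled_pred = np.empty_like(y)
    for fold in range(k):
        test = plan.fold_indices(fold)
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test] = False
        model = make_baseline(model_spec.with_seed(model_spec.seed * 1000 + fold))
        try:
            model.fit(X[train_mask], y[train_mask])
            pred = np.asarray(model.predict(X[test]), dtype=float)
        except Exception as exc:
            raise RuntimeError(f"model {model_spec.name!r} failed on fold {fold}: {exc}") from exc
        pooled_pred[test] = pred
        folds.append(compute_puo(pred, y[test]))
    return MetricsReport.from_folds(
        model_spec.name, folds, pooled=compute_puo(pooled_pred, y)
    )


# ---------------------------------------------------------------------------
# Multi-model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonReport:
    """Per-model per-seed mean metrics plus one-way ANOVA across models."""

    models: tuple[str, ...]                       # ranked by mean P, descending
    per_seed: dict[str, dict[str, tuple[float, ...]]]
    mean: dict[str, dict[str, float]]
    anova_f: dict[str, float] = field(default_factory=dict)
    anova_p: dict[str, float] = field(default_factory=dict)


def compare_models(
    specs: list[RegressorSpec],
    cohort,
    k: int = 5,
    seeds=(0, 1, 2, 3, 4),
    feature_names=DEFAULT_FEATURE_NAMES,
) -> ComparisonReport:
    """Repeated seeded K-fold runs per model, one-way ANOVA per metric.

    The unit of replication for the ANOVA is the per-seed mean metric
    (each seed reshuffles the folds and reseeds the models).
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 model specs to compare")
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds per model for ANOVA")
    per_seed: dict[str, dict[str, list[float]]] = {}
    labels = []
    for spec in specs:
        label = spec.name
        suffix = 2
        while label in per_seed:  # disambiguate repeated specs
            label = f"{spec.name}#{suffix}"
            suffix += 1
        labels.append(label)
        entry = {"p": [], "u": [], "o": []}
        for seed in seeds:
            rep = run_kfold(spec.with_seed(seed), cohort, k=k, seed=seed,
                            feature_names=feature_names)
            entry["p"].append(rep.mean_p)
            entry["u"].append(rep.mean_u)
            entry["o"].append(rep.mean_o)
        per_seed[label] = entry
    anova_f, anova_p = {}, {}
    for metric in ("p", "u", "o"):
        groups = [per_seed[label][metric] for label in labels]
        f, pval = stats.f_oneway(*groups)
        anova_f[metric], anova_p[metric] = float(f), float(pval)
    mean = {
        name: {m: float(np.mean(vals)) for m, vals in entry.items()}
        for name, entry in per_seed.items()
    }
    ranked = tuple(sorted(mean, key=lambda name: mean[name]["p"], reverse=True))
    frozen = {
        name: {m: tuple(vals) for m, vals in entry.items()}
        for name, entry in per_seed.items()
    }
    return ComparisonReport(models=ranked, per_seed=frozen, mean=mean,
                            anova_f=anova_f, anova_p=anova_p)


def paired_sign_test(a, b, alternative: str = "greater"):
    """Sign test on paired observations; ties are discarded.

    Returns ``(n_positive, n_effective, p_value)`` for H1: median(a-b)
    matches ``alternative``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    nz = diff != 0
    n_eff = int(nz.sum())
    n_pos = int((diff > 0).sum())
    if n_eff == 0:
        return 0, 0, 1.0
    res = stats.binomtest(n_pos, n_eff, 0.5, alternative=alternative)
    return n_pos, n_eff, float(res.pvalue)


# ---------------------------------------------------------------------------
# 2x2 odds ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float


def odds_ratio_2x2(
    a: float, b: float, c: float, d: float,
    *, haldane: bool = False, reciprocal: bool = False,
) -> OddsRatioResult:
    """Cross-product odds ratio with a 95% Wald (log) confidence interval.

    The table is ``[[a, b], [c, d]]``; ``haldane`` adds 0.5 to every cell
    (required when any cell is zero), ``reciprocal`` flips the exposure
    orientation, returning 1/OR with the CI inverted accordingly.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    if haldane:
        cells = cells + 0.5
    if np.any(cells == 0):
        raise ValueError("zero cell; pass haldane=True for the 0.5 correction")
    a_, b_, c_, d_ = cells
    log_or = np.log(a_ * d_ / (b_ * c_))
    se = np.sqrt((1 / cells).sum())
    z = stats.norm.ppf(0.975)
    lo, hi = np.exp(log_or - z * se), np.exp(log_or + z * se)
    if reciprocal:
        log_or, lo, hi = -log_or, 1 / hi, 1 / lo
    return OddsRatioResult(float(np.exp(log_or)), float(lo), float(hi))
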