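"""Scoring, permutation calibration and ranking of pathways.

Each pathway is scored by its most class-discriminative wavelet feature
(the maximum absolute Welch t statistic over all features).  Because a
maximum over many correlated features has no tractable closed-form null,
the score's null distribution is obtained by shuffling the condition
labels (without replacement, class sizes preserved) and fitting a Gumbel
extreme-value distribution to the permuted scores; the pathway p-value is
the fitted upper-tail probability of the observed score.  P-values are
corrected for multiple testing across pathways (Bonferroni by default),
and each pathway additionally reports how many of its reactions are
individually up-/down-regulated (rank-sum tests, per-pathway Bonferroni).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, lay_out_grids, reaction_expression, z_transform
from .preprocess import PreprocessedPathway
from .wavelets import feature_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "STATISTIC_CAP",
    "FeatureScore",
    "GumbelNull",
    "PathwayResult",
    "AnalysisResult",
    "feature_statistic",
    "pathway_score",
    "permutation_null",
    "gumbel_pvalue",
    "adjust_pvalues",
    "count_up_down",
    "run_analysis",
    "filter_results",
]

# stand-in for an infinite t statistic when both groups have zero variance
# but different means; keeps the Gumbel fit finite
STATISTIC_CAP = 1e6

_CORRECTION_ALIASES = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "bh": "fdr_bh",
    "benjamini-hochberg": "fdr_bh",
    "fdr_bh": "fdr_bh",
}


@dataclass(frozen=True)
class FeatureScore:
    """Class-separation strength of one feature.

    ``statistic`` is |Welch t| (non-negative); ``sign`` is the sign of
    mean(class A) - mean(class B).
    """

    index: int
    statistic: float
    sign: int


@dataclass
class GumbelNull:
    """Gumbel fit to permuted pathway scores.

    loc/scale are the location (mu) and scale (beta > 0) of the fitted
    extreme-value distribution; the raw permuted scores are retained.
    """

    loc: float
    scale: float
    n_permutations: int
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("Gumbel scale must be > 0")
        if self.n_permutations < 100:
            raise ValueError("at least 100 permutations are required")


@dataclass
class PathwayResult:
    """Final per-pathway outcome: score, calibrated significance, counts."""

    pathway_id: str
    title: str
    score: float
    best_feature: FeatureScore
    best_key: tuple  # (shift, level, sec_row, sec_col, kind)
    p_value: float
    p_adjusted: float
    n_up: int
    n_nochange: int
    n_down: int
    n_measured: int
    direction_calls: dict[str, str] = field(default_factory=dict)


@dataclass
class AnalysisResult:
    """All pathway results plus the filtered/ranked selection."""

    results: list[PathwayResult]
    filtered: list[PathwayResult]
    params: dict


def _welch(sum_a, sumsq_a, n_a, sum_t, sumsq_t, n):
    """Vectorized |Welch t| and sign from per-group sums and sums of squares.

    Group B statistics are derived from the totals, so one matrix product
    per permutation batch suffices.
    """
    n_b = n - n_a
    sum_b = sum_t - sum_a
    sumsq_b = sumsq_t - sumsq_a
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    var_a = np.clip((sumsq_a - n_a * mean_a**2) / (n_a - 1), 0.0, None)
    var_b = np.clip((sumsq_b - n_b * mean_b**2) / (n_b - 1), 0.0, None)
    diff = mean_a - mean_b
    se = np.sqrt(var_a / n_a + var_b / n_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.abs(diff) / se
    scale = np.maximum(np.abs(mean_a) + np.abs(mean_b), 1.0)
    zero_diff = np.abs(diff) <= 1e-12 * scale
    t = np.where(se == 0, np.where(zero_diff, 0.0, STATISTIC_CAP), t)
    t = np.minimum(t, STATISTIC_CAP)
    return t, np.sign(diff)


def _stat_matrix(F: np.ndarray, A: np.ndarray):
    """|Welch t| for each permutation (rows of A) and feature (cols of F).

    F: (n_samples, n_features); A: (n_perm, n_samples) 0/1 class-A
    indicators with constant row sums.
    """
    n = F.shape[0]
    n_a = float(A[0].sum())
    Af = A.astype(float)
    sum_t = F.sum(axis=0)
    sumsq_t = (F**2).sum(axis=0)
    sum_a = Af @ F
    sumsq_a = Af @ (F**2)
    return _welch(sum_a, sumsq_a, n_a, sum_t, sumsq_t, n)


def feature_statistic(values_a: np.ndarray, values_b: np.ndarray) -> FeatureScore:
    """|Welch t| separation of one feature between the two classes.

    Zero when both groups are constant and equal; capped at
    ``STATISTIC_CAP`` when they are constant but different.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each class needs at least 2 samples")
    F = np.concatenate([a, b])[:, None]
    A = np.concatenate([np.ones(a.size), np.zeros(b.size)])[None, :]
    t, sign = _stat_matrix(F, A)
    return FeatureScore(index=0, statistic=float(t[0, 0]), sign=int(sign[0, 0]))


def pathway_score(F: np.ndarray, labels: np.ndarray) -> tuple[float, FeatureScore]:
    """Max |Welch t| over all features; ties go to the canonical order.

    ``labels`` is the boolean class-A indicator over samples (rows of F).
    """
    labels = np.asarray(labels, dtype=bool)
    if F.shape[1] == 0:
        return 0.0, FeatureScore(index=0, statistic=0.0, sign=0)
    t, sign = _stat_matrix(F, labels[None, :].astype(float))
    best = int(np.argmax(t[0]))
    return float(t[0, best]), FeatureScore(index=best, statistic=float(t[0, best]),
                                           sign=int(sign[0, best]))


def _permutation_matrix(labels: np.ndarray, n_perm: int, rng: np.random.Generator,
                        pairs: np.ndarray | None = None) -> np.ndarray:
    """n_perm shuffled class-A indicator rows (class sizes preserved).

    For paired designs, labels are swapped within pairs (each pair's two
    samples trade labels with probability 1/2), which respects the
    exchangeability structure of matched samples.
    """
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    if pairs is None:
        out = np.empty((n_perm, n), dtype=float)
        for i in range(n_perm):
            out[i] = rng.permutation(labels)
        return out
    pair_ids = pd.unique(pairs)
    members = {p: np.flatnonzero(pairs == p) for p in pair_ids}
    for p, idx in members.items():
        if idx.size != 2 or labels[idx].sum() != 1:
            raise ValueError(f"pair {p!r} must contain one sample of each class")
    out = np.tile(labels.astype(float), (n_perm, 1))
    flips = rng.integers(0, 2, size=(n_perm, len(pair_ids))).astype(bool)
    for j, p in enumerate(pair_ids):
        idx = members[p]
        rowsel = flips[:, j]
        out[np.ix_(rowsel, idx)] = 1.0 - out[np.ix_(rowsel, idx)]
    return out


def permutation_null(
    F: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    pairs: np.ndarray | None = None,
) -> GumbelNull:
    """Gumbel null of the pathway score under label shuffling.

    The score is recomputed for ``n_perm`` label permutations and a Gumbel
    distribution is fitted to the permuted scores by maximum likelihood
    (method-of-moments fallback).  Deterministic for a given seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=bool)
    A = _permutation_matrix(labels, n_perm, rng, pairs=pairs)
    t, _ = _stat_matrix(F, A)
    scores = t.max(axis=1) if t.shape[1] else np.zeros(n_perm)
    if np.ptp(scores) == 0:
        raise ValueError(
            "degenerate permutation null (all permuted scores equal); "
            "use more permutations or check the input features"
        )
    loc, scale = _fit_gumbel(scores)
    return GumbelNull(loc=float(loc), scale=float(scale), n_permutations=n_perm,
                      scores=scores)


def _fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    try:
        loc, scale = sps.gumbel_r.fit(scores)
        if not (np.isfinite(loc) and np.isfinite(scale) and scale > 0):
            raise ValueError
        return loc, scale
    except Exception:  # moments fallback: beta = sd*sqrt(6)/pi, mu = mean - gamma*beta
        scale = scores.std(ddof=1) * np.sqrt(6) / np.pi
        loc = scores.mean() - np.euler_gamma * scale
        return loc, scale


def gumbel_pvalue(score: float, null: GumbelNull) -> float:
    """Upper-tail Gumbel probability of the observed score.

    p = 1 - exp(-exp(-(score - mu)/beta)), clamped to
    [smallest positive float, 1].
    """
    if null.scale <= 0:
        raise ValueError("Gumbel scale must be > 0")
    p = float(sps.gumbel_r.sf(score, loc=null.loc, scale=null.scale))
    return min(max(p, np.finfo(float).tiny), 1.0)


def adjust_pvalues(p: list[float] | np.ndarray, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment (bonferroni, holm, or BH), order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = _CORRECTION_ALIASES.get(method.lower())
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, method=key)[1]


def count_up_down(
    reaction_expr: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    pairs: np.ndarray | None = None,
) -> tuple[int, int, int, dict[str, str]]:
    """Per-reaction up/no-change/down calls within one pathway.

    Two-sided Wilcoxon rank-sum per measured reaction (signed-rank within
    pairs for matched designs), Bonferroni-corrected within the pathway;
    a reaction is "up" when significant with mean(A) > mean(B).  Returns
    (n_up, n_nochange, n_down, calls) with counts summing to the number
    of measured reactions.
    """
    labels = np.asarray(labels, dtype=bool)
    arr = reaction_expr.to_numpy(dtype=float)
    measured = ~np.isnan(arr).any(axis=1)
    m = int(measured.sum())
    calls: dict[str, str] = {}
    n_up = n_down = 0
    for i in np.flatnonzero(measured):
        a, b = arr[i, labels], arr[i, ~labels]
        if pairs is not None:
            order_a = np.argsort(pairs[labels], kind="stable")
            order_b = np.argsort(pairs[~labels], kind="stable")
            diffs = a[order_a] - b[order_b]
            if np.allclose(diffs, 0):
                p = 1.0
            else:
                p = float(sps.wilcoxon(diffs, zero_method="wilcox").pvalue)
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        p_adj = min(p * m, 1.0)
        call = "nochange"
        if p_adj < alpha:
            if a.mean() > b.mean():
                call, n_up = "up", n_up + 1
            elif a.mean() < b.mean():
                call, n_down = "down", n_down + 1
        calls[str(reaction_expr.index[i])] = call
    return n_up, m - n_up - n_down, n_down, calls


def _child_seed(master_seed: int, pathway_id: str) -> np.random.Generator:
    """Per-pathway generator independent of pathway iteration order."""
    tag = zlib.crc32(pathway_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


def filter_results(
    results: list[PathwayResult], p_threshold: float = 0.05, min_dysregulated: int = 0
) -> list[PathwayResult]:
    """Keep pathways below the adjusted-p threshold with enough up- or
    downregulated reactions; ordering is preserved."""
    return [
        r
        for r in results
        if r.p_adjusted < p_threshold
        and (r.n_up >= min_dysregulated or r.n_down >= min_dysregulated)
    ]


def run_analysis(
    pathways: list[PreprocessedPathway],
    expr: ExpressionMatrix,
    n_perm: int = 1000,
    correction: str = "bonferroni",
    p_threshold: float = 0.05,
    min_dysregulated: int = 0,
    alpha_updown: float = 0.05,
    seed: int = 0,
    paired: bool = False,
) -> AnalysisResult:
    """Full two-class analysis over a preprocessed pathway collection.

    Per pathway: map expression to reactions, z-transform, lay grids out,
    extract Haar features, score, calibrate by permutation, and count
    up/down reactions.  Pathways with fewer than two measured reactions
    are skipped with a warning.  Results are sorted by adjusted p
    ascending (ties: score descending, then pathway id); the filtered
    list applies ``p_threshold`` and ``min_dysregulated``.
    """
    class_a, class_b = expr.validate_two_classes()
    labels = expr.label_vector()
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    pairs = None
    if paired:
        if expr.pairs is None:
            raise ValueError("paired=True requires ExpressionMatrix.pairs")
        pairs = np.array([expr.pairs[s] for s in expr.samples])

    rows = []
    for pw in pathways:
        net = pw.network
        rexpr, measured = reaction_expression(net, expr)
        if int(measured.sum()) < 2:
            logger.warning("skipping pathway %s: fewer than 2 measured reactions",
                           net.pathway_id)
            continue
        z = z_transform(rexpr)
        grids = lay_out_grids(net, pw.embedding, z)
        index, F = feature_matrix(grids)
        score, best = pathway_score(F, labels)
        rng = _child_seed(seed, net.pathway_id)
        null = permutation_null(F, labels, n_perm=n_perm, seed=rng, pairs=pairs)
        p = gumbel_pvalue(score, null)
        n_up, n_nc, n_down, calls = count_up_down(rexpr, labels, alpha=alpha_updown,
                                                  pairs=pairs)
        rows.append(
            PathwayResult(
                pathway_id=net.pathway_id,
                title=pw.title,
                score=score,
                best_feature=best,
                best_key=index[best.index] if index else ("none", 0, 0, 0, "mean_of_means"),
                p_value=p,
                p_adjusted=np.nan,
                n_up=n_up,
                n_nochange=n_nc,
                n_down=n_down,
                n_measured=int(measured.sum()),
                direction_calls=calls,
            )
        )

    adj = adjust_pvalues([r.p_value for r in rows], method=correction)
    for r, pa in zip(rows, adj):
        r.p_adjusted = float(max(pa, r.p_value))
    rows.sort(key=lambda r: (r.p_adjusted, -r.score, r.pathway_id))
    filtered = filter_results(rows, p_threshold=p_threshold,
                              min_dysregulated=min_dysregulated)
    params = {
        "n_perm": n_perm, "correction": correction, "p_threshold": p_threshold,
        "min_dysregulated": min_dysregulated, "alpha_updown": alpha_updown,
        "seed": seed, "paired": paired, "class_a": class_a, "class_b": class_b,
    }
    return AnalysisResult(results=rows, filtered=filtered, params=params)
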