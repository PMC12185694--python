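"""The study's statistical toolkit.

Group differences use a normality-gated two-sample test: Shapiro-Wilk
on each group, pooled-variance t-test when both pass (p >= 0.05),
Wilcoxon rank-sum otherwise.  One-tailed directions must be supplied
explicitly by the caller — they encode a pre-stated hypothesis and are
never inferred from the data.  Correlations are Pearson or Spearman;
partial correlation is the Pearson correlation of residuals after
regressing both variables on the covariates, with n - k - 2 degrees of
freedom.  Multiple comparisons use the Holm-Bonferroni step-down
adjustment.  Voxel-wise group maps are compared with pooled t-tests
thresholded at the voxel level and corrected by cluster extent, with
the extent threshold taken from a group-label permutation null (a
self-contained replacement for Gaussian-random-field Monte Carlo
cluster simulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .core import InvalidConfigError, NeurofluidError

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "ModelFit",
    "VoxelStatMap",
    "auto_compare",
    "correlate",
    "partial_correlation",
    "holm_bonferroni",
    "joint_linear_models",
    "voxelwise_test",
]

_SHAPIRO_GATE = 0.05


@dataclass(frozen=True)
class GroupComparison:
    test_name: str  # "t" or "rank-sum"
    statistic: float
    p: float
    tails: int
    n_per_group: tuple[int, int]
    normality_p: tuple[float, float]


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman" | "partial-pearson"
    estimate: float
    p: float
    tails: int
    n: int
    covariates: int = 0


@dataclass(frozen=True)
class ModelFit:
    predictors: tuple[str, ...]
    r2: float
    coefficients: dict
    partial_r2: dict  # unique contribution: R2_full - R2_without


@dataclass(frozen=True)
class VoxelStatMap:
    tmap: np.ndarray
    voxel_p: float
    labels: np.ndarray
    extent_threshold: int
    surviving: tuple[tuple[int, int], ...]  # (label, size)

    @property
    def surviving_mask(self) -> np.ndarray:
        out = np.zeros(self.labels.shape, dtype=bool)
        for lab, _ in self.surviving:
            out |= self.labels == lab
        return out


def _alternative(tails: int, direction: str | None) -> str:
    if tails == 2:
        return "two-sided"
    if tails == 1:
        if direction not in ("greater", "less"):
            raise InvalidConfigError(
                "one-tailed tests need an explicit direction ('greater' or 'less')"
            )
        return direction
    raise InvalidConfigError("tails must be 1 or 2")


def auto_compare(
    a,
    b,
    tails: int = 2,
    direction: str | None = None,
    welch: bool = False,
) -> GroupComparison:
    """Normality-gated two-sample comparison.

    Shapiro-Wilk on each group; if both p >= 0.05 a two-sample t-test
    (pooled variance by default, Welch behind the flag), otherwise the
    Wilcoxon rank-sum test.  ``direction`` states the pre-existing
    hypothesis ('greater' means a > b) for one-tailed tests.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InvalidConfigError("each group needs n >= 3")
    alt = _alternative(tails, direction)
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    if sw_a >= _SHAPIRO_GATE and sw_b >= _SHAPIRO_GATE:
        res = stats.ttest_ind(a, b, equal_var=not welch, alternative=alt)
        name = "t"
    else:
        res = stats.ranksums(a, b, alternative=alt)
        name = "rank-sum"
    return GroupComparison(
        test_name=name,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        tails=tails,
        n_per_group=(a.size, b.size),
        normality_p=(float(sw_a), float(sw_b)),
    )


def correlate(
    x,
    y,
    method: str = "pearson",
    tails: int = 2,
    direction: str | None = None,
) -> CorrelationResult:
    """Pearson or Spearman correlation with one- or two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise InvalidConfigError("need equal-length samples with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise NeurofluidError("constant input; correlation undefined")
    alt = _alternative(tails, direction)
    if method == "pearson":
        res = stats.pearsonr(x, y, alternative=alt)
    elif method == "spearman":
        res = stats.spearmanr(x, y, alternative=alt)
    else:
        raise InvalidConfigError(f"unknown method {method!r}")
    return CorrelationResult(
        method=method,
        estimate=float(res.statistic),
        p=float(res.pvalue),
        tails=tails,
        n=x.size,
    )


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x,
    y,
    covariates,
    tails: int = 2,
    direction: str | None = None,
) -> CorrelationResult:
    """Pearson correlation of x and y after removing covariates.

    Both variables are regressed (with intercept) on the covariates;
    the residual correlation is tested with n - k - 2 degrees of
    freedom.  Collinear covariates or a variable fully explained by
    them raise an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if z.shape[0] != x.size:
        z = z.T
    n, k = z.shape
    if x.size != y.size or x.size != n:
        raise InvalidConfigError("x, y and covariates must share n")
    if n <= k + 3:
        raise InvalidConfigError("need n > covariate count + 3")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise NeurofluidError("collinear covariates")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    df = n - k - 2
    if rx.std() < 1e-10 * max(x.std(), 1e-12):
        # the predictor is collinear with the covariates: ill-posed
        raise NeurofluidError("x is fully explained by the covariates")
    if ry.std() < 1e-10 * max(y.std(), 1e-12):
        # no outcome variance left to explain: the partial correlation is 0
        return CorrelationResult(
            method="partial-pearson", estimate=0.0, p=1.0, tails=tails,
            n=n, covariates=k,
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    r_ = min(max(r, -0.999999999), 0.999999999)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    alt = _alternative(tails, direction)
    if alt == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif alt == "greater":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    return CorrelationResult(
        method="partial-pearson",
        estimate=r,
        p=float(p),
        tails=tails,
        n=n,
        covariates=k,
    )


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the original order.

    sorted p(i) -> max_{j<=i} ((m - j + 1) * p(j)), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InvalidConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def joint_linear_models(
    outcome,
    predictors: dict,
    sets: list[tuple[str, ...]] | None = None,
) -> list[ModelFit]:
    """OLS models predicting ``outcome`` from named predictor sets.

    ``sets`` defaults to each predictor alone plus all jointly.  Each
    fit reports R-squared, coefficients, and every predictor's unique
    contribution (delta R-squared against the model without it).
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    names = list(predictors)
    cols = {k: np.asarray(v, dtype=float) for k, v in predictors.items()}
    for k, v in cols.items():
        if v.size != y.size:
            raise InvalidConfigError(f"predictor {k!r} length mismatch")
    if sets is None:
        sets = [(nm,) for nm in names]
        if len(names) > 1:
            sets.append(tuple(names))

    def _r2(subset: tuple[str, ...]) -> tuple[float, dict]:
        X = sm.add_constant(np.column_stack([cols[nm] for nm in subset]))
        if y.size <= X.shape[1] + 1:
            raise InvalidConfigError("n must exceed predictors + 2")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise NeurofluidError(f"rank-deficient design for {subset}")
        fit = sm.OLS(y, X).fit()
        coefs = {"const": float(fit.params[0])}
        coefs.update({nm: float(b) for nm, b in zip(subset, fit.params[1:])})
        return float(fit.rsquared), coefs

    out = []
    for subset in sets:
        r2, coefs = _r2(subset)
        partial = {}
        for nm in subset:
            rest = tuple(m for m in subset if m != nm)
            partial[nm] = r2 - (_r2(rest)[0] if rest else 0.0)
        out.append(ModelFit(predictors=tuple(subset), r2=r2,
                            coefficients=coefs, partial_r2=partial))
    return out


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _pooled_tmap(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return t, df


def _max_cluster_size(supra: np.ndarray) -> int:
    labels, nlab = ndimage.label(supra, structure=_CONN26)
    if nlab == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def voxelwise_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    voxel_p: float = 0.05,
    extent: int | None = None,
    n_perm: int = 1000,
    cluster_p: float = 0.05,
    seed: int = 0,
) -> VoxelStatMap:
    """Voxel-wise pooled two-sample t with cluster-extent correction.

    ``maps_a``/``maps_b`` are ``(n_subjects, X, Y, Z)``.  Voxels with
    two-sided p below ``voxel_p`` form 26-connected clusters; clusters
    survive if their size reaches ``extent`` (user-set) or, when
    ``extent`` is None, exceeds the (1 - cluster_p) quantile of the
    maximum cluster size under ``n_perm`` group-label permutations.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.ndim != 4 or b.ndim != 4 or a.shape[1:] != b.shape[1:]:
        raise InvalidConfigError("group maps must be (n, X, Y, Z) on a common grid")
    na, nb = a.shape[0], b.shape[0]
    if na < 3 or nb < 3:
        raise InvalidConfigError("need >= 3 subjects per group")
    t, df = _pooled_tmap(a, b)
    tcrit = stats.t.isf(voxel_p / 2.0, df)
    supra = np.abs(t) > tcrit
    labels, nlab = ndimage.label(supra, structure=_CONN26)
    sizes = np.bincount(labels.ravel())[1:] if nlab else np.array([], dtype=int)

    if extent is None:
        rng = np.random.default_rng(seed)
        both = np.concatenate([a, b], axis=0)
        maxes = np.empty(n_perm, dtype=int)
        idx = np.arange(na + nb)
        for i in range(n_perm):
            perm = rng.permutation(idx)
            tp, _ = _pooled_tmap(both[perm[:na]], both[perm[na:]])
            maxes[i] = _max_cluster_size(np.abs(tp) > tcrit)
        # smallest size s with P(max >= s) <= cluster_p (with +1 correction)
        thr = int(np.quantile(maxes, 1.0 - cluster_p, method="higher"))
        extent_threshold = thr + 1
    else:
        extent_threshold = int(extent)

    surviving = tuple(
        (int(lab + 1), int(sz))
        for lab, sz in enumerate(sizes)
        if sz >= extent_threshold
    )
    return VoxelStatMap(
        tmap=t,
        voxel_p=voxel_p,
        labels=labels,
        extent_threshold=extent_threshold,
        surviving=surviving,
    )
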