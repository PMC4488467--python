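"""Statistical battery for patriline-structured size and shape data.

Covers the full analysis chain applied to the aligned wings: nested ANOVA of
log centroid size with variance components, Procrustes ANOVA of the
measurement-error study, sequential (Type I) MANCOVA with Pillai trace and
its approximate F, two-sample Hotelling T-squared, canonical-variate
leave-one-out reassignment, the common allometric component (pooled
within-group shape-on-size regression) with allometry-corrected residuals,
and angle comparisons of group-difference vectors against a permutation
null.

Degrees-of-freedom conventions
------------------------------
* Nested size ANOVA: sequential decomposition colony -> patriline(colony),
  both mean squares tested against the residual mean square.
* MANCOVA: sequential (Type I) sums of squares and cross-products in the
  order size, colony, patriline(colony), size x colony, size x patriline;
  Pillai trace V with s = min(p, q), m = (|p - q| - 1)/2,
  n' = (nu - p - 1)/2, F = ((2n' + s + 1)/(2m + s + 1)) (V/s)/(1 - V/s) on
  (s(2m + s + 1), s(2n' + s + 1)) df.
* Procrustes ANOVA: per-stratum df are the univariate nested level
  increments times the shape-space dimension 2k - 4 (34 for 19 landmarks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .superimpose import AlignedSample, procrustes_distance

__all__ = [
    "SizeVarianceComponents",
    "HotellingResult",
    "AngleTestResult",
    "CommonAllometry",
    "GroupDistances",
    "size_nested_anova",
    "size_variance_components",
    "procrustes_anova",
    "shape_mancova",
    "hotelling_t2",
    "cva_loo",
    "cva_sweep",
    "common_allometric_component",
    "vector_angle",
    "angle_null_test",
    "welch_t",
    "group_mean_distances",
]


# --------------------------------------------------------------------------
# size: nested ANOVA and variance components
# --------------------------------------------------------------------------

def _as_labels(x) -> np.ndarray:
    return np.asarray(x)


def size_nested_anova(logcs, colony_labels, patriline_labels) -> pd.DataFrame:
    """Two-level nested ANOVA of log centroid size.

    Sequential decomposition: colony, then patriline within colony; both
    effects tested against the residual mean square. Returns a table with
    rows Colony, Patriline, Residuals and columns SS, Df, MS, F, P. A
    zero-residual design yields NaN F (flagged degenerate) rather than an
    error.
    """
    y = np.asarray(logcs, dtype=float)
    colony = _as_labels(colony_labels)
    pat = _as_labels(patriline_labels)
    if y.shape[0] != colony.shape[0] or y.shape[0] != pat.shape[0]:
        raise ValueError("length mismatch between sizes and labels")
    if len(np.unique(colony)) < 2:
        raise ValueError("nested size ANOVA requires >= 2 colonies")

    grand = y.mean()
    cells = [(c, p) for c, p in dict.fromkeys(zip(colony, pat))]
    n_cells = len(cells)
    if n_cells >= y.shape[0]:
        raise ValueError("singleton design: no residual degrees of freedom")

    ss_colony = 0.0
    ss_pat = 0.0
    ss_res = 0.0
    for c in np.unique(colony):
        mask_c = colony == c
        mean_c = y[mask_c].mean()
        ss_colony += mask_c.sum() * (mean_c - grand) ** 2
        for p in np.unique(pat[mask_c]):
            mask_cp = mask_c & (pat == p)
            mean_cp = y[mask_cp].mean()
            ss_pat += mask_cp.sum() * (mean_cp - mean_c) ** 2
            ss_res += ((y[mask_cp] - mean_cp) ** 2).sum()

    df_colony = len(np.unique(colony)) - 1
    df_pat = n_cells - len(np.unique(colony))
    df_res = y.shape[0] - n_cells
    ms_res = ss_res / df_res
    rows = []
    for name, ss, df in (
        ("Colony", ss_colony, df_colony),
        ("Patriline", ss_pat, df_pat),
    ):
        ms = ss / df
        if ms_res > 0:
            f = ms / ms_res
            p = float(stats.f.sf(f, df, df_res))
        else:
            f, p = np.nan, np.nan
        rows.append((name, ss, df, ms, f, p))
    rows.append(("Residuals", ss_res, df_res, ms_res, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["Effect", "SS", "Df", "MS", "F", "P"]).set_index(
        "Effect"
    )


@dataclass
class SizeVarianceComponents:
    """Log-centroid-size variances at the colony/patriline/individual levels."""

    s2_inter_colony: float
    s2_inter_patriline: float
    s2_intra_patriline: float


def size_variance_components(
    logcs, colony_labels, patriline_labels
) -> SizeVarianceComponents:
    """Descriptive variance components of log centroid size.

    ``s2_intra_patriline`` is the pooled within-patriline variance;
    ``s2_inter_patriline`` the pooled (unweighted) variance of patriline
    means about their colony mean-of-means; ``s2_inter_colony`` the variance
    of colony means about the grand mean of colony means. Undefined
    components (fewer than two groups at a level) are NaN.
    """
    y = np.asarray(logcs, dtype=float)
    colony = _as_labels(colony_labels)
    pat = _as_labels(patriline_labels)

    ss_within = 0.0
    n_within = 0
    colony_means = []
    ss_pat = 0.0
    df_pat = 0
    for c in np.unique(colony):
        mask_c = colony == c
        pat_means = []
        for p in np.unique(pat[mask_c]):
            grp = y[mask_c & (pat == p)]
            pat_means.append(grp.mean())
            ss_within += ((grp - grp.mean()) ** 2).sum()
            n_within += grp.size - 1
        pat_means = np.asarray(pat_means)
        colony_means.append(pat_means.mean())
        if pat_means.size >= 2:
            ss_pat += ((pat_means - pat_means.mean()) ** 2).sum()
            df_pat += pat_means.size - 1
    colony_means = np.asarray(colony_means)

    s2_intra = ss_within / n_within if n_within > 0 else np.nan
    s2_pat = ss_pat / df_pat if df_pat > 0 else np.nan
    if colony_means.size >= 2:
        s2_col = ((colony_means - colony_means.mean()) ** 2).sum() / (
            colony_means.size - 1
        )
    else:
        s2_col = np.nan
    return SizeVarianceComponents(float(s2_col), float(s2_pat), float(s2_intra))


# --------------------------------------------------------------------------
# Procrustes ANOVA (measurement error)
# --------------------------------------------------------------------------

def procrustes_anova(
    tangent: np.ndarray,
    specimen_ids,
    mountings,
    digitizations,
    group_labels,
) -> pd.DataFrame:
    """Hierarchical Procrustes ANOVA: patriline > individual > mounting >
    digitization.

    Sums of squares are observation-level squared deviations of each
    stratum's mean tangent vector from its parent-stratum mean, summed over
    all coordinates; per-stratum df are the univariate nested level
    increments times the shape dimension ``2k - 4``. Requires a balanced
    replicate design.
    """
    x = np.asarray(tangent, dtype=float)
    spec = _as_labels(specimen_ids)
    mount = _as_labels(mountings)
    digit = _as_labels(digitizations)
    group = _as_labels(group_labels)
    n = x.shape[0]
    if not (len(spec) == len(mount) == len(digit) == len(group) == n):
        raise ValueError("length mismatch between tangent rows and identifiers")

    mount_key = np.array([f"{s}|{m}" for s, m in zip(spec, mount)])
    digit_key = np.array(
        [f"{s}|{m}|{d}" for s, m, d in zip(spec, mount, digit)]
    )
    if len(np.unique(digit_key)) != n:
        raise ValueError("duplicate (specimen, mounting, digitization) records")

    specimens, spec_inv = np.unique(spec, return_inverse=True)
    mounts, mount_inv = np.unique(mount_key, return_inverse=True)
    # balance checks
    per_spec = np.bincount(
        np.unique(np.stack([spec_inv, mount_inv]), axis=1)[0]
    )
    if len(set(per_spec.tolist())) != 1:
        raise ValueError("unbalanced design: unequal mountings per specimen")
    per_mount = np.bincount(mount_inv)
    if len(set(per_mount.tolist())) != 1:
        raise ValueError("unbalanced design: unequal digitizations per mounting")

    dim = x.shape[1] - 4  # shape dimension 2k - 4

    def level_means(inv, n_levels):
        sums = np.zeros((n_levels, x.shape[1]))
        np.add.at(sums, inv, x)
        counts = np.bincount(inv, minlength=n_levels)
        return sums / counts[:, None]

    groups, group_inv = np.unique(group, return_inverse=True)
    grand = x.mean(axis=0)
    g_mean = level_means(group_inv, len(groups))[group_inv]
    s_mean = level_means(spec_inv, len(specimens))[spec_inv]
    m_mean = level_means(mount_inv, len(mounts))[mount_inv]

    ss_group = ((g_mean - grand) ** 2).sum()
    ss_spec = ((s_mean - g_mean) ** 2).sum()
    ss_mount = ((m_mean - s_mean) ** 2).sum()
    ss_digit = ((x - m_mean) ** 2).sum()

    df_group = (len(groups) - 1) * dim
    df_spec = (len(specimens) - len(groups)) * dim
    df_mount = (len(mounts) - len(specimens)) * dim
    df_digit = (n - len(mounts)) * dim

    rows = []
    for name, ss, df in (
        ("Patriline", ss_group, df_group),
        ("Individual", ss_spec, df_spec),
        ("Wing mounting", ss_mount, df_mount),
        ("Landmark digitization", ss_digit, df_digit),
    ):
        rows.append((name, ss, df, ss / df if df > 0 else np.nan))
    return pd.DataFrame(rows, columns=["Effect", "SS", "Df", "MS"]).set_index(
        "Effect"
    )


# --------------------------------------------------------------------------
# MANCOVA (sequential Type I, Pillai trace)
# --------------------------------------------------------------------------

def _dummies(labels) -> np.ndarray:
    values = np.unique(labels)
    return (np.asarray(labels)[:, None] == values[None, :]).astype(float)


def _pillai_f(v: float, p: int, q: int, nu: int):
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nprime = (nu - p - 1) / 2.0
    num_df = s * (2 * m + s + 1)
    den_df = s * (2 * nprime + s + 1)
    if den_df <= 0:
        raise ValueError("insufficient residual df for the Pillai F transform")
    f = ((2 * nprime + s + 1) / (2 * m + s + 1)) * (v / s) / (1 - v / s)
    return f, int(round(num_df)), int(round(den_df))


def shape_mancova(
    scores: np.ndarray, logcs, colony_labels, patriline_labels
) -> pd.DataFrame:
    """Sequential MANCOVA of shape scores on size, colony and patriline.

    Terms enter in the order Size, Colony, Patriline(colony), Size x Colony,
    Size x Patriline; each term's SSCP is taken over the design columns it
    adds beyond the preceding terms (Type I). Pillai trace and its
    approximate F are reported per term; the Residuals row carries the
    residual df. Raises if a term is fully aliased or the residual df cannot
    support the F transform.
    """
    y = np.asarray(scores, dtype=float)
    size = np.asarray(logcs, dtype=float)
    n, p = y.shape
    colony = _as_labels(colony_labels)
    pat = _as_labels(patriline_labels)
    cell = np.array([f"{c}|{q}" for c, q in zip(colony, pat)])

    col_d = _dummies(colony)
    cell_d = _dummies(cell)
    blocks = [
        ("Intercept", np.ones((n, 1))),
        ("Size", size[:, None]),
        ("Colony", col_d),
        ("Patriline", cell_d),
        ("Size:Colony", size[:, None] * col_d),
        ("Size:Patriline", size[:, None] * cell_d),
    ]

    q_basis = np.zeros((n, 0))
    terms = []
    for name, block in blocks:
        # residualize against preceding terms (twice, for numerical hygiene),
        # then detect the added rank from the singular spectrum
        b = block - q_basis @ (q_basis.T @ block)
        b = b - q_basis @ (q_basis.T @ b)
        u, sv, _ = np.linalg.svd(b, full_matrices=False)
        block_scale = np.linalg.norm(block, 2)
        qb = u[:, sv > 1e-8 * max(block_scale, 1.0)]
        df_term = qb.shape[1]
        if name != "Intercept" and df_term == 0:
            raise ValueError(f"term {name} is aliased with preceding terms")
        zy = qb.T @ y
        terms.append((name, df_term, zy.T @ zy))
        q_basis = np.hstack([q_basis, qb])

    rank = q_basis.shape[1]
    nu = n - rank
    qty = q_basis.T @ y
    e = y.T @ y - qty.T @ qty
    if nu <= p:
        raise ValueError(
            f"residual df {nu} too small for {p} response variables"
        )

    rows = []
    for name, df_term, h in terms:
        if name == "Intercept":
            continue
        v = float(np.trace(np.linalg.solve(h + e, h)))
        f, num_df, den_df = _pillai_f(v, p, df_term, nu)
        pval = float(stats.f.sf(f, num_df, den_df))
        rows.append((name, df_term, v, f, num_df, den_df, pval))
    rows.append(("Residuals", nu, np.nan, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["Effect", "Df", "Pillai", "approxF", "numDf", "denDf", "P"]
    ).set_index("Effect")


# --------------------------------------------------------------------------
# Hotelling T2
# --------------------------------------------------------------------------

@dataclass
class HotellingResult:
    t2: float
    f: float
    df_num: int
    df_den: int
    p: float


def hotelling_t2(group1: np.ndarray, group2: np.ndarray) -> HotellingResult:
    """Two-sample Hotelling T-squared with pooled covariance.

    ``F = T2 (n1 + n2 - p - 1) / ((n1 + n2 - 2) p)`` on
    ``(p, n1 + n2 - p - 1)`` df.
    """
    x1 = np.atleast_2d(np.asarray(group1, dtype=float))
    x2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("groups must share the variable count")
    n1, n2, p = x1.shape[0], x2.shape[0], x1.shape[1]
    if n1 + n2 <= p + 1:
        raise ValueError("need n1 + n2 > p + 1 observations")
    d = x1.mean(axis=0) - x2.mean(axis=0)
    s_pooled = (
        (n1 - 1) * np.cov(x1, rowvar=False).reshape(p, p)
        + (n2 - 1) * np.cov(x2, rowvar=False).reshape(p, p)
    ) / (n1 + n2 - 2)
    try:
        factor = cho_factor(s_pooled)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled covariance") from exc
    t2 = float((n1 * n2) / (n1 + n2) * d @ cho_solve(factor, d))
    df_num = p
    df_den = n1 + n2 - p - 1
    f = t2 * df_den / ((n1 + n2 - 2) * p)
    return HotellingResult(t2, float(f), df_num, df_den, float(stats.f.sf(f, df_num, df_den)))


# --------------------------------------------------------------------------
# canonical variates with leave-one-out cross-validation
# --------------------------------------------------------------------------

def _lda_predict(train_x, train_labels, test_x):
    """Assign test rows to the nearest group mean in Mahalanobis metric
    (pooled within-group covariance, equal priors)."""
    groups = np.unique(train_labels)
    means = np.stack([train_x[train_labels == g].mean(axis=0) for g in groups])
    centered = train_x - means[np.searchsorted(groups, train_labels)]
    s = centered.T @ centered / (train_x.shape[0] - len(groups))
    try:
        factor = cho_factor(s)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled within-group covariance; use fewer PCs"
        ) from exc
    diffs = test_x[:, None, :] - means[None, :, :]  # (t, g, p)
    flat = diffs.reshape(-1, diffs.shape[2])
    solved = cho_solve(factor, flat.T).T.reshape(diffs.shape)
    d2 = (diffs * solved).sum(axis=2)
    return groups[np.argmin(d2, axis=1)]


def cva_loo(scores: np.ndarray, labels, n_pcs: int) -> float:
    """Leave-one-out canonical-variate reassignment rate on the first
    ``n_pcs`` score columns (fraction of specimens reassigned to their own
    group)."""
    x = np.asarray(scores, dtype=float)
    y = _as_labels(labels)
    if n_pcs < 1 or n_pcs > x.shape[1]:
        raise ValueError(f"n_pcs must be in [1, {x.shape[1]}]")
    values, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 specimens")
    x = x[:, :n_pcs]
    correct = 0
    for i in range(x.shape[0]):
        mask = np.ones(x.shape[0], dtype=bool)
        mask[i] = False
        pred = _lda_predict(x[mask], y[mask], x[i : i + 1])[0]
        correct += pred == y[i]
    return correct / x.shape[0]


def cva_sweep(scores: np.ndarray, labels, n_pcs_range) -> dict[int, float]:
    """Reassignment rate for every PC count in ``n_pcs_range``."""
    return {int(k): cva_loo(scores, labels, int(k)) for k in n_pcs_range}


# --------------------------------------------------------------------------
# allometry
# --------------------------------------------------------------------------

@dataclass
class CommonAllometry:
    """Pooled within-group regression of shape on log centroid size.

    ``cac`` is the vector of per-coordinate slopes (the common allometric
    component); ``direction`` its unit version; ``se`` the per-coordinate
    standard errors of the slopes; ``corrected`` the allometry-corrected
    data: group-centered shapes minus the size-predicted part, with group
    means re-added for downstream group tests.
    """

    cac: np.ndarray
    direction: np.ndarray
    se: np.ndarray
    corrected: np.ndarray


def common_allometric_component(
    shapes: np.ndarray, logcs, group_labels
) -> CommonAllometry:
    x = np.asarray(shapes, dtype=float)
    size = np.asarray(logcs, dtype=float)
    groups = _as_labels(group_labels)
    values = np.unique(groups)
    if np.unique(size).size < 2:
        raise ValueError("constant size: allometry undefined")

    group_means = np.zeros_like(x)
    size_centered = np.empty_like(size)
    for g in values:
        mask = groups == g
        group_means[mask] = x[mask].mean(axis=0)
        size_centered[mask] = size[mask] - size[mask].mean()
    centered = x - group_means

    sxx = float((size_centered**2).sum())
    cac = centered.T @ size_centered / sxx
    residuals = centered - np.outer(size_centered, cac)
    df = x.shape[0] - len(values) - 1
    sigma2 = (residuals**2).sum(axis=0) / max(df, 1)
    se = np.sqrt(sigma2 / sxx)
    norm = np.linalg.norm(cac)
    direction = cac / norm if norm > 0 else cac
    return CommonAllometry(
        cac=cac,
        direction=direction,
        se=se,
        corrected=residuals + group_means,
    )


# --------------------------------------------------------------------------
# angles between shape-change vectors
# --------------------------------------------------------------------------

def vector_angle(v1, v2) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for a zero vector")
    return float(np.degrees(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0))))


@dataclass
class AngleTestResult:
    theta_degrees: float
    p: float
    n_draws: int


def angle_null_test(
    v1, v2, sample: np.ndarray, n_draws: int = 10000, seed=None
) -> AngleTestResult:
    """Is the angle between two group-difference vectors unusually small?

    The null draws 4 distinct specimens from the sample, forms the two
    difference vectors of the disjoint pairs, and records their angle; the
    one-sided p-value is ``(1 + #{null <= observed}) / (n_draws + 1)``.
    """
    x = np.asarray(sample, dtype=float)
    if x.shape[0] < 4:
        raise ValueError("angle null test needs at least 4 specimens")
    observed = vector_angle(v1, v2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_draws):
        i, j, k, l = rng.choice(x.shape[0], size=4, replace=False)
        a = x[i] - x[j]
        b = x[k] - x[l]
        if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
            count += 1  # degenerate draw counts toward the tail (conservative)
            continue
        if vector_angle(a, b) <= observed:
            count += 1
    return AngleTestResult(observed, (1 + count) / (n_draws + 1), n_draws)


# --------------------------------------------------------------------------
# Welch t
# --------------------------------------------------------------------------

def welch_t(group1, group2):
    """Welch unequal-variance t test with Satterthwaite df.

    Returns ``(t, df, p)``; degenerate inputs (zero variance in both groups
    with equal means) yield NaNs.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return (np.nan, np.nan, np.nan) if a.mean() == b.mean() else (np.inf, np.nan, 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# --------------------------------------------------------------------------
# Procrustes distance summaries
# --------------------------------------------------------------------------

@dataclass
class GroupDistances:
    """Between-patriline and within-patriline Procrustes distance statistics."""

    between_mean: float
    between_sd: float
    within_mean: float
    within_sd: float
    n_pairs: int
    n_specimens: int


def group_mean_distances(
    sample: AlignedSample, patriline_labels, colony_labels
) -> GroupDistances:
    """Mean +/- SD Procrustes distances between patriline mean shapes
    (within-colony pairs, pooled over colonies) and between each specimen and
    its own patriline mean shape.

    Patriline mean shapes are tangent-space means mapped back to landmark
    configurations; patrilines with a single specimen are excluded from the
    within-statistic with a warning.
    """
    pat = _as_labels(patriline_labels)
    colony = _as_labels(colony_labels)
    n = sample.n_configurations
    if len(pat) != n or len(colony) != n:
        raise ValueError("label length mismatch with aligned sample")
    k = sample.consensus.shape[0]
    consensus_flat = sample.consensus.ravel()

    mean_config: dict[tuple, np.ndarray] = {}
    counts: dict[tuple, int] = {}
    for c in np.unique(colony):
        for p in np.unique(pat[colony == c]):
            mask = (colony == c) & (pat == p)
            mean_tan = sample.tangent[mask].mean(axis=0)
            mean_config[(c, p)] = (consensus_flat + mean_tan).reshape(k, 2)
            counts[(c, p)] = int(mask.sum())

    between = []
    for c in np.unique(colony):
        pats = sorted(p for (cc, p) in mean_config if cc == c)
        for i in range(len(pats)):
            for j in range(i + 1, len(pats)):
                between.append(
                    procrustes_distance(
                        mean_config[(c, pats[i])], mean_config[(c, pats[j])]
                    )
                )
    if not between:
        raise ValueError("need >= 2 patrilines in at least one colony")

    singletons = [key for key, cnt in counts.items() if cnt < 2]
    if singletons:
        warnings.warn(
            f"patrilines with a single specimen excluded from the "
            f"within-statistic: {singletons}",
            stacklevel=2,
        )
    within = []
    for i in range(n):
        key = (colony[i], pat[i])
        if counts[key] < 2:
            continue
        within.append(procrustes_distance(sample.aligned[i], mean_config[key]))

    between = np.asarray(between)
    within = np.asarray(within)
    return GroupDistances(
        between_mean=float(between.mean()),
        between_sd=float(between.std(ddof=1)) if between.size > 1 else 0.0,
        within_mean=float(within.mean()),
        within_sd=float(within.std(ddof=1)) if within.size > 1 else 0.0,
        n_pairs=between.size,
        n_specimens=within.size,
    )
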