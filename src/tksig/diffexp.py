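"""Risk-class characterization: moderated t, FDR, centroid score, metagenes.

The two risk classes are characterized by gene-wise differential expression
using the empirical-Bayes moderated t-statistic: the per-gene pooled
two-group variance s2_g (d_g = n1 + n2 - 2 df) is shrunk toward a prior
variance s0^2 with d0 prior degrees of freedom, estimated by moment-matching
the distribution of log s2_g through digamma/trigamma identities.  The
moderated statistic t = logFC / sqrt(s2_post * (1/n1 + 1/n2)) with
s2_post = (d0 s0^2 + d_g s2_g) / (d0 + d_g) is referred to a t distribution
on d0 + d_g degrees of freedom; d0 = inf collapses every variance to s0^2.

Sign convention: logFC = mean(first group) - mean(second group); the
pipeline passes (low-risk, high-risk), so genes over-expressed in low-risk
samples have positive logFC.  The fold-change filter FC > |1.25x| operates
on the linear scale, i.e. |logFC| > log2(1.25), since inputs are log2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

logger = logging.getLogger(__name__)

LOG2_FC_125 = math.log2(1.25)


# ---------------------------------------------------------------------------
# moderated t-test with empirical-Bayes variance shrinkage


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0_sq) from per-gene sample variances.

    Under the hierarchical model s2_g ~ s0^2 * F(d_g, d0), the statistic
    e_g = log s2_g - digamma(d/2) + log(d/2) has mean
    log s0^2 - digamma(d0/2) + log(d0/2) and excess variance trigamma(d0/2)
    beyond trigamma(d/2); equating empirical moments yields the estimates.
    Zero variances are excluded from estimation (shrinkage still rescues
    them at test time).  Returns d0 = inf when no excess variance remains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 10:
        raise ValueError("need >= 10 genes with positive variance to estimate the prior")
    e = np.log(s2[ok]) - digamma(df / 2.0) + np.log(df / 2.0)
    n = len(e)
    mean_e = e.mean()
    var_e = ((e - mean_e) ** 2).sum() / (n - 1) - float(polygamma(1, df / 2.0))
    if var_e <= 0:
        return np.inf, float(np.exp(mean_e))
    d0 = 2.0 * trigamma_inverse(var_e)
    s0_sq = float(np.exp(mean_e + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


@dataclass
class ModeratedTestResult:
    table: pd.DataFrame  # per gene: logFC, s2, t_mod, df_total, p, q
    d0: float
    s0_sq: float
    groups: tuple[str, str]


def moderated_t(
    matrix: pd.DataFrame,
    labels: pd.Series,
    groups: tuple[str, str],
    prior: tuple[float, float] | None = None,
) -> ModeratedTestResult:
    """Empirical-Bayes moderated two-group t-test per gene.

    ``matrix`` is gene × sample (log2 scale); ``labels`` assigns each sample
    to one of ``groups``; logFC = mean(groups[0]) - mean(groups[1]).  The
    variance prior is estimated from the data unless ``prior`` fixes
    (d0, s0_sq) externally; d0 = 0 reduces exactly to the ordinary
    pooled-variance t-test and d0 = inf to equal-variance shrinkage.
    """
    g1, g2 = groups
    labels = labels.loc[matrix.columns]
    m1 = (labels == g1).to_numpy()
    m2 = (labels == g2).to_numpy()
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per class")
    if g1 == g2:
        raise ValueError("identical class labels")
    X = matrix.to_numpy(dtype=float)
    x1, x2 = X[:, m1], X[:, m2]
    logfc = x1.mean(axis=1) - x2.mean(axis=1)
    df = n1 + n2 - 2
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / df

    if prior is not None:
        d0, s0_sq = float(prior[0]), float(prior[1])
    else:
        if matrix.shape[0] < 10:
            raise ValueError("need >= 10 genes to estimate the variance prior")
        d0, s0_sq = estimate_variance_prior(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = logfc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t_mod = np.where(np.isfinite(t_mod), t_mod, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame({
        "logFC": logfc, "s2": s2, "t_mod": t_mod,
        "df_total": df_total, "p": p, "q": bh_fdr(p),
    }, index=matrix.index)
    return ModeratedTestResult(table=table, d0=d0, s0_sq=s0_sq, groups=groups)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DEGeneList:
    up_in_first: list[str]  # over-expressed in groups[0] (positive logFC)
    up_in_second: list[str]
    thresholds: dict


def de_gene_list(
    result: ModeratedTestResult,
    p_max: float = 1e-2,
    q_max: float = 1e-2,
    fc_min: float = 1.25,
) -> DEGeneList:
    """Differential genes at joint p/q/fold-change thresholds, split by sign."""
    log_fc_min = math.log2(fc_min)
    t = result.table
    sig = (t["p"] < p_max) & (t["q"] < q_max) & (t["logFC"].abs() > log_fc_min)
    up_first = list(t.index[sig & (t["logFC"] > 0)])
    up_second = list(t.index[sig & (t["logFC"] < 0)])
    logger.info("DE genes: %d up in %s, %d up in %s",
                len(up_first), result.groups[0], len(up_second), result.groups[1])
    return DEGeneList(
        up_in_first=up_first, up_in_second=up_second,
        thresholds={"p_max": p_max, "q_max": q_max, "fc_min": fc_min},
    )


# ---------------------------------------------------------------------------
# centroid correlation-difference prediction score


@dataclass
class CentroidScore:
    scores: pd.DataFrame  # per sample: r_high, r_low, score, predicted
    centroids: pd.DataFrame  # gene x {high, low} median profiles
    ttest_p: float | None  # Welch t comparing scores between known classes
    ttest_stat: float | None


def centroid_score(
    matrix: pd.DataFrame,
    learning_labels: pd.Series,
    groups: tuple[str, str],
    new_matrix: pd.DataFrame,
    new_labels: pd.Series | None = None,
    method: str = "pearson",
) -> CentroidScore:
    """Correlation-difference prediction score against class median centroids.

    Centroids are the per-gene median profiles of the two learning classes
    over the supplied (DE-restricted) gene rows.  For each new sample,
    score = corr(profile, centroid_first) - corr(profile, centroid_second);
    a positive score predicts membership in the first group.  When known
    labels for the scored samples are given, a two-sample Welch t-test
    comparing the score distributions is reported.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 genes for a meaningful correlation score")
    g_first, g_second = groups
    labels = learning_labels.loc[matrix.columns]
    cent = pd.DataFrame({
        g_first: matrix.loc[:, (labels == g_first).to_numpy()].median(axis=1),
        g_second: matrix.loc[:, (labels == g_second).to_numpy()].median(axis=1),
    })
    new = new_matrix.loc[matrix.index]

    def corr(col: np.ndarray, ref: np.ndarray) -> float:
        sd = col.std()
        if sd == 0 or ref.std() == 0:
            return np.nan
        if method == "spearman":
            return float(stats.spearmanr(col, ref).statistic)
        return float(np.corrcoef(col, ref)[0, 1])

    ref1 = cent[g_first].to_numpy()
    ref2 = cent[g_second].to_numpy()
    rows = []
    for s in new.columns:
        col = new[s].to_numpy(dtype=float)
        r1, r2 = corr(col, ref1), corr(col, ref2)
        score = r1 - r2
        rows.append({"sample_id": s, "r_first": r1, "r_second": r2, "score": score,
                     "predicted": (g_first if score > 0 else g_second)
                     if np.isfinite(score) else np.nan})
    scores = pd.DataFrame(rows).set_index("sample_id")
    flagged = int(scores["score"].isna().sum())
    if flagged:
        logger.warning("%d samples with undefined centroid score flagged", flagged)

    tstat = tp = None
    if new_labels is not None:
        lab = new_labels.loc[scores.index]
        a = scores.loc[(lab == g_first).to_numpy(), "score"].dropna()
        b = scores.loc[(lab == g_second).to_numpy(), "score"].dropna()
        if len(a) >= 2 and len(b) >= 2:
            res = stats.ttest_ind(a, b, equal_var=False)
            tstat, tp = float(res.statistic), float(res.pvalue)
    return CentroidScore(scores=scores, centroids=cent, ttest_p=tp, ttest_stat=tstat)


# ---------------------------------------------------------------------------
# generic gene-set metagene score


def metagene_score(
    matrix: pd.DataFrame,
    gene_set: list[str],
    weights: dict[str, float] | None = None,
    set_name: str = "gene_set",
) -> pd.Series:
    """Mean of (weighted) z-scored member-gene expression per sample.

    Member genes absent from the matrix are dropped with a log entry; an
    empty overlap raises, naming the set.  Weights default to uniform; the
    conventional +1/-1 weights encode up/down set members.
    """
    present = [g for g in gene_set if g in matrix.index]
    dropped = len(gene_set) - len(present)
    if not present:
        raise KeyError(f"no genes of set {set_name!r} present in the matrix")
    if dropped:
        logger.info("set %s: %d of %d member genes absent, dropped",
                    set_name, dropped, len(gene_set))
    sub = matrix.loc[present].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mean) / sd
    w = np.array([1.0 if weights is None else float(weights.get(g, 1.0))
                  for g in present])
    return pd.Series((w[:, None] * z).mean(axis=0), index=matrix.columns,
                     name=set_name)


# ---------------------------------------------------------------------------
# class/clinical association tests (Fisher exact r x c, Welch t)


def _table_logprob(table: np.ndarray, lgamma=math.lgamma) -> float:
    """Log hypergeometric probability of an r x c table given its margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = (sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols)
          - lgamma(n + 1) - sum(lgamma(v + 1) for v in table.ravel()))
    return lp


def _count_tables(rows: tuple[int, ...], cols: tuple[int, ...]) -> int:
    """Number of non-negative integer tables with the given margins (DP)."""

    def rec(r_idx: int, remaining_cols: tuple[int, ...]) -> int:
        if r_idx == len(rows) - 1:
            return 1
        total = 0
        target = rows[r_idx]

        def fill(c_idx: int, left: int, cols_now: list[int]):
            nonlocal total
            if c_idx == len(remaining_cols) - 1:
                if left <= remaining_cols[c_idx]:
                    new_cols = tuple(
                        cols_now[i] - (left if i == c_idx else 0)
                        for i in range(len(cols_now)))
                    total += rec(r_idx + 1, new_cols)
                return
            for v in range(min(left, remaining_cols[c_idx]) + 1):
                cols_now[c_idx] -= v
                fill(c_idx + 1, left - v, cols_now)
                cols_now[c_idx] += v

        fill(0, target, list(remaining_cols))
        return total

    return rec(0, cols)


def fisher_exact_rxc(
    table,
    max_tables: int = 1_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided Fisher's exact test for an r x c contingency table.

    Exact enumeration of all tables with the observed margins when their
    count does not exceed ``max_tables``; otherwise a seeded Monte-Carlo
    estimate drawing tables with fixed margins.  p is the total probability
    of tables no more probable than the observed one (with a 1e-7 relative
    tolerance, matching the usual implementation convention).
    """
    obs = np.asarray(table, dtype=int)
    if obs.min() < 0:
        raise ValueError("counts must be non-negative")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 1.0
    rows = tuple(int(r) for r in obs.sum(axis=1))
    cols = tuple(int(c) for c in obs.sum(axis=0))
    lp_obs = _table_logprob(obs)
    cutoff = lp_obs + 1e-7

    if _count_tables(rows, cols) <= max_tables:
        total = 0.0
        r, c = len(rows), len(cols)
        cells = np.zeros((r, c), dtype=int)

        def enumerate_tables(idx: int, row_left: list[int], col_left: list[int]):
            nonlocal total
            i, j = divmod(idx, c)
            if i == r - 1:
                for jj in range(c):
                    cells[i, jj] = col_left[jj]
                if all(v >= 0 for v in cells[i]) and cells[i].sum() == row_left[i]:
                    lp = _table_logprob(cells)
                    if lp <= cutoff:
                        total += math.exp(lp)
                return
            if j == c - 1:
                v = row_left[i]
                if 0 <= v <= col_left[j]:
                    cells[i, j] = v
                    row_left[i] -= v
                    col_left[j] -= v
                    enumerate_tables((i + 1) * c, row_left, col_left)
                    row_left[i] += v
                    col_left[j] += v
                return
            for v in range(min(row_left[i], col_left[j]) + 1):
                cells[i, j] = v
                row_left[i] -= v
                col_left[j] -= v
                enumerate_tables(idx + 1, row_left, col_left)
                row_left[i] += v
                col_left[j] += v

        enumerate_tables(0, list(rows), list(cols))
        return min(1.0, total)

    rng = np.random.default_rng(seed)
    sampler = stats.random_table(rows, cols)
    draws = sampler.rvs(n_mc, random_state=rng)
    lps = np.array([_table_logprob(np.asarray(t, dtype=int)) for t in draws])
    return float(((lps <= cutoff).sum() + 1) / (n_mc + 1))


def association_tests(
    labels: pd.Series,
    clinical: pd.DataFrame,
    variables: list[str] | None = None,
    max_categories: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Association of a two-class labelling with clinical variables.

    Categorical variables get Fisher's exact test on the class × level
    table; numeric variables get a two-sample Welch t-test.  Output mirrors a
    cohort-description table: one row per variable level with per-class
    counts and column percentages, plus the variable-level p.  Single-level
    variables are skipped with a note.
    """
    clinical = clinical.loc[labels.index]
    classes = sorted(labels.dropna().unique())
    if len(classes) != 2:
        raise ValueError("labels must have exactly two classes")
    if variables is None:
        variables = [c for c in clinical.columns
                     if c not in ("sample_id", "dataset_id")]
    rows = []
    for var in variables:
        col = clinical[var]
        values = col.dropna()
        if values.nunique() < 2:
            rows.append({"variable": var, "level": None, "test": "skipped",
                         "p": np.nan, "note": "single level"})
            continue
        numeric = pd.api.types.is_numeric_dtype(values) and \
            values.nunique() > max_categories
        if numeric:
            a = values[labels.loc[values.index] == classes[0]]
            b = values[labels.loc[values.index] == classes[1]]
            res = stats.ttest_ind(a, b, equal_var=False)
            rows.append({
                "variable": var, "level": "(continuous)", "test": "welch_t",
                "p": float(res.pvalue),
                f"mean_{classes[0]}": float(a.mean()),
                f"mean_{classes[1]}": float(b.mean()),
            })
            continue
        ct = pd.crosstab(values, labels.loc[values.index])
        ct = ct.reindex(columns=classes, fill_value=0)
        p = fisher_exact_rxc(ct.to_numpy(), seed=seed)
        col_totals = ct.sum(axis=0)
        for level, counts in ct.iterrows():
            row = {"variable": var, "level": str(level), "test": "fisher_exact",
                   "p": p}
            for cls in classes:
                row[f"n_{cls}"] = int(counts[cls])
                row[f"pct_{cls}"] = round(100.0 * counts[cls] / max(col_totals[cls], 1))
            rows.append(row)
    return pd.DataFrame(rows)
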