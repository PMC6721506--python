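"""Cross-study harmonization and transcriptional receptor-status calling.

Multi-study expression cohorts cannot be pooled directly: each study carries
platform- and lab-specific location/scale distortions.  The strategy here is
the one used for pooled breast-cancer compendia: within each study, collapse
probes to genes (keeping the most variable probe per gene), standardize every
gene against a reference "anchor" subgroup of luminal-A-like samples
(z = (x - m_anchor) / s_anchor), then pool studies on the common gene space.
Because the anchor subgroup has a comparable expression distribution in every
study, anchoring removes affine batch distortions without using the outcome.

Receptor status (ER, PR, ERBB2) is called per study from the bimodal
distribution of the corresponding transcript (ESR1, PGR, ERBB2): a
two-component Gaussian mixture is fit and samples above the posterior-0.5
crossing point between the component means are called positive.  Molecular
subtype follows from the three calls (ERBB2+ / ER+ERBB2- / triple-negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .genes import RECEPTOR_GENES

logger = logging.getLogger(__name__)

SUBTYPE_TN = "TN"
SUBTYPE_ERBB2 = "ERBB2+"
SUBTYPE_ER = "ER+/ERBB2-"

#: plausibility window for log2-scale expression input
_LOG2_RANGE = (-10.0, 30.0)


class NotBimodalError(ValueError):
    """Raised when a receptor gene's expression shows no usable two-mode structure."""


@dataclass
class ExpressionStudy:
    """One study's probe- or gene-level log2 expression matrix.

    ``matrix`` is probes/genes × samples.  ``probe_map`` maps row identifier
    to gene symbol; ``None`` means rows already are genes.
    """

    matrix: pd.DataFrame
    platform: str  # "microarray" | "rnaseq"
    dataset_id: str
    probe_map: dict[str, str] | None = None
    provenance: dict = field(default_factory=dict)
    standardized: bool = False  # True once z-scored; skips the log2 range check

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            raise ValueError(f"{self.dataset_id}: duplicate sample ids")
        if self.platform not in ("microarray", "rnaseq"):
            raise ValueError(f"{self.dataset_id}: unknown platform {self.platform!r}")
        vals = self.matrix.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if (not self.standardized and finite.size
                and (finite.min() < _LOG2_RANGE[0] or finite.max() > _LOG2_RANGE[1])):
            raise ValueError(
                f"{self.dataset_id}: values outside the plausible log2 range "
                f"{_LOG2_RANGE}; input must be log2-transformed upstream"
            )
        all_missing = ~np.isfinite(vals).any(axis=1)
        if all_missing.any():
            raise ValueError(
                f"{self.dataset_id}: {int(all_missing.sum())} all-missing rows"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class HarmonizedCohort:
    """Pooled z-scored matrix plus clinical annotations and derived calls."""

    matrix: pd.DataFrame  # gene × sample, anchor z-scores
    clinical: pd.DataFrame  # indexed by sample_id
    receptor_calls: pd.DataFrame  # columns ER/PR/ERBB2, values "positive"/"negative"
    subtype: pd.Series  # per sample
    anchor_flag: pd.Series  # per sample bool

    def samples(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class ReceptorThreshold:
    gene: str
    dataset_id: str
    cutpoint: float
    means: tuple[float, float]
    sds: tuple[float, float]
    weight: float  # mixing weight of the lower component
    method: str  # "gmm" | "kde_valley" | "manual"


def collapse_probes(study: ExpressionStudy) -> ExpressionStudy:
    """Collapse a probe-level study to gene level.

    For each gene the probe with the highest sample variance (missing values
    excluded) is retained.  Exact variance ties resolve to the
    lexicographically smallest probe id, with a warning.
    """
    if study.probe_map is None:
        return study
    missing = [p for p in study.matrix.index if p not in study.probe_map]
    if missing:
        raise ValueError(f"{study.dataset_id}: probe_map misses {len(missing)} probes")
    if study.matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to compute probe variances")

    variances = study.matrix.var(axis=1, ddof=1, skipna=True)
    chosen: dict[str, str] = {}
    for probe in sorted(study.matrix.index):
        gene = study.probe_map[probe]
        if gene not in chosen:
            chosen[gene] = probe
            continue
        best = chosen[gene]
        if variances[probe] > variances[best]:
            chosen[gene] = probe
        elif variances[probe] == variances[best]:
            logger.warning(
                "%s: variance tie for gene %s between probes %s and %s; keeping %s",
                study.dataset_id, gene, best, probe, min(best, probe),
            )
            chosen[gene] = min(best, probe)
    genes = sorted(chosen)
    mat = study.matrix.loc[[chosen[g] for g in genes]].copy()
    mat.index = genes
    prov = dict(study.provenance)
    prov["probe_for_gene"] = {g: chosen[g] for g in genes}
    return ExpressionStudy(
        matrix=mat, platform=study.platform, dataset_id=study.dataset_id,
        probe_map=None, provenance=prov,
    )


def zscore_by_anchor(
    study: ExpressionStudy,
    anchor_ids,
    hard_fail: bool = False,
) -> ExpressionStudy:
    """Standardize each gene against the study's anchor samples.

    Output value = (x - m_g) / s_g with m_g, s_g the mean and SD of gene g
    over the study's anchor samples.  Fewer than 3 anchors falls back to
    all-sample moments (or raises when ``hard_fail``); a gene with zero
    anchor SD falls back to its all-sample SD.
    """
    anchors = [s for s in anchor_ids if s in study.matrix.columns]
    if len(anchors) < 3:
        msg = f"{study.dataset_id}: only {len(anchors)} anchor samples"
        if hard_fail:
            raise ValueError(msg)
        logger.warning("%s; falling back to all-sample moments", msg)
        anchors = study.sample_ids

    ref = study.matrix[anchors]
    m = ref.mean(axis=1, skipna=True)
    s = ref.std(axis=1, ddof=1, skipna=True)
    degenerate = ~(s > 0)
    if degenerate.any():
        logger.warning(
            "%s: %d genes with zero anchor SD; using all-sample SD",
            study.dataset_id, int(degenerate.sum()),
        )
        s_all = study.matrix.std(axis=1, ddof=1, skipna=True)
        s = s.where(~degenerate, s_all)
        s = s.where(s > 0, 1.0)  # constant gene everywhere: leave centred only
    z = study.matrix.sub(m, axis=0).div(s, axis=0)
    prov = dict(study.provenance)
    prov["anchor_n"] = len(anchors)
    return replace(study, matrix=z, provenance=prov, standardized=True)


def _gmm_crossing(m1, s1, w1, m2, s2, w2) -> float | None:
    """Point between two component means with equal posterior membership.

    Solves w1 N(x|m1,s1) = w2 N(x|m2,s2); returns the root inside (m1, m2)
    or None if there is none (degenerate geometry).
    """
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)
         + np.log((w1 * s2) / (w2 * s1)))
    lo, hi = min(m1, m2), max(m1, m2)
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            return None
        x = -c / b
        return float(x) if lo < x < hi else None
    disc = b**2 - 4 * a * c
    if disc < 0:
        return None
    roots = [(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)]
    inside = [r for r in roots if lo < r < hi]
    return float(inside[0]) if inside else None


def _kde_valley(values: np.ndarray) -> float:
    """Deepest kernel-density valley between the two largest modes."""
    kde = stats.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    interior = np.arange(1, len(grid) - 1)
    peaks = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if len(peaks) < 2:
        raise NotBimodalError("not bimodal")
    top2 = sorted(peaks[np.argsort(dens[peaks])[-2:]])
    seg = slice(top2[0], top2[1] + 1)
    valley = top2[0] + int(np.argmin(dens[seg]))
    return float(grid[valley])


def call_receptor(
    values: pd.Series,
    method: str = "gmm",
    manual_cutpoint: float | None = None,
    dataset_id: str = "",
    gene: str = "",
) -> tuple[ReceptorThreshold, pd.Series]:
    """Call positive/negative receptor status from one gene's expression.

    Fits a two-component Gaussian mixture; the cutpoint is the posterior-0.5
    crossing between the component means and samples strictly above it are
    positive.  A degenerate mixture (component weight < 0.05 or separation
    |Δmean|/pooled SD < 0.5) falls back to the deepest KDE valley between the
    two largest density modes.  Raises :class:`NotBimodalError` when no
    two-mode structure exists.
    """
    x = values.dropna().astype(float)
    if manual_cutpoint is None and len(x) < 20:
        raise ValueError(f"need >= 20 samples to call receptor status, got {len(x)}")
    if manual_cutpoint is not None:
        thr = ReceptorThreshold(gene, dataset_id, float(manual_cutpoint),
                                (np.nan, np.nan), (np.nan, np.nan), np.nan, "manual")
        calls = _calls_from_cutpoint(values, thr.cutpoint)
        return thr, calls
    if np.ptp(x.to_numpy()) == 0:
        raise NotBimodalError("not bimodal")

    cutpoint = None
    if method == "gmm":
        gm = GaussianMixture(n_components=2, n_init=5, random_state=0)
        gm.fit(x.to_numpy().reshape(-1, 1))
        order = np.argsort(gm.means_.ravel())
        m1, m2 = gm.means_.ravel()[order]
        s1, s2 = np.sqrt(gm.covariances_.ravel()[order])
        w1, w2 = gm.weights_[order]
        pooled = np.sqrt(w1 * s1**2 + w2 * s2**2)
        degenerate = min(w1, w2) < 0.05 or (m2 - m1) / pooled < 0.5
        if not degenerate:
            cutpoint = _gmm_crossing(m1, s1, w1, m2, s2, w2)
        if cutpoint is not None:
            thr = ReceptorThreshold(gene, dataset_id, cutpoint,
                                    (float(m1), float(m2)), (float(s1), float(s2)),
                                    float(w1), "gmm")
            return thr, _calls_from_cutpoint(values, cutpoint)
        logger.warning("%s/%s: degenerate mixture, falling back to KDE valley",
                       dataset_id, gene)
        method = "kde_valley"
    if method == "kde_valley":
        cutpoint = _kde_valley(x.to_numpy())
        thr = ReceptorThreshold(gene, dataset_id, cutpoint,
                                (np.nan, np.nan), (np.nan, np.nan), np.nan, "kde_valley")
        return thr, _calls_from_cutpoint(values, cutpoint)
    raise ValueError(f"unknown receptor-calling method {method!r}")


def _calls_from_cutpoint(values: pd.Series, cutpoint: float) -> pd.Series:
    calls = pd.Series(
        np.where(values > cutpoint, "positive", "negative"), index=values.index
    )
    calls[values.isna()] = np.nan
    return calls


def assign_subtype(receptor_calls: pd.DataFrame) -> pd.Series:
    """Map (ER, PR, ERBB2) calls to molecular subtype.

    ERBB2-positive dominates; otherwise ER or PR positivity gives ER+/ERBB2-;
    all-negative is triple-negative.  Samples with any missing call are
    excluded (NaN) with a log entry.
    """
    for col in ("ER", "PR", "ERBB2"):
        if col not in receptor_calls.columns:
            raise ValueError(f"receptor calls missing column {col}")
    calls = receptor_calls[["ER", "PR", "ERBB2"]]
    ok = calls.notna().all(axis=1)
    if (~ok).any():
        logger.warning("%d samples excluded from subtyping (missing receptor call)",
                       int((~ok).sum()))
    pos = calls == "positive"
    subtype = pd.Series(np.nan, index=calls.index, dtype=object)
    subtype[ok & pos["ERBB2"]] = SUBTYPE_ERBB2
    subtype[ok & ~pos["ERBB2"] & (pos["ER"] | pos["PR"])] = SUBTYPE_ER
    subtype[ok & ~pos["ERBB2"] & ~pos["ER"] & ~pos["PR"]] = SUBTYPE_TN
    return subtype


def harmonize_cohort(
    studies: list[ExpressionStudy],
    clinical: pd.DataFrame,
    anchor_ids=None,
    hard_fail_anchors: bool = False,
) -> tuple[HarmonizedCohort, list[ReceptorThreshold]]:
    """Run the full per-study harmonization and pool the studies.

    Per study: collapse probes, call ER/PR/ERBB2 from raw log2 values,
    z-score against anchors, then pool on the gene intersection.  When
    ``anchor_ids`` is None, anchors fall back to the luminal-A-like heuristic
    (called ER-positive and ERBB2-negative) within each study.
    """
    if not studies:
        raise ValueError("no studies")
    clinical = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical

    gene_studies = [collapse_probes(s) for s in studies]
    thresholds: list[ReceptorThreshold] = []
    call_frames = []
    zed = []
    for study in gene_studies:
        calls = {}
        for label, gene in zip(("ER", "PR", "ERBB2"), RECEPTOR_GENES):
            if gene not in study.matrix.index:
                raise ValueError(f"{study.dataset_id}: receptor gene {gene} absent")
            thr, c = call_receptor(
                study.matrix.loc[gene], dataset_id=study.dataset_id, gene=gene
            )
            thresholds.append(thr)
            calls[label] = c
        calls = pd.DataFrame(calls)
        call_frames.append(calls)

        if anchor_ids is None:
            study_anchors = calls.index[
                (calls["ER"] == "positive") & (calls["ERBB2"] == "negative")
            ]
        else:
            study_anchors = [s for s in anchor_ids if s in study.matrix.columns]
        zed.append(zscore_by_anchor(study, study_anchors, hard_fail=hard_fail_anchors))

    common = sorted(set.intersection(*[set(s.matrix.index) for s in zed]))
    if not common:
        raise ValueError("gene intersection across studies is empty")
    matrix = pd.concat([s.matrix.loc[common] for s in zed], axis=1)
    receptor_calls = pd.concat(call_frames, axis=0)
    receptor_calls = receptor_calls.loc[matrix.columns]
    subtype = assign_subtype(receptor_calls)

    if anchor_ids is None:
        anchor_flag = (receptor_calls["ER"] == "positive") & (
            receptor_calls["ERBB2"] == "negative")
    else:
        anchor_flag = pd.Series(matrix.columns.isin(list(anchor_ids)),
                                index=matrix.columns)
    clin = clinical.loc[[s for s in matrix.columns if s in clinical.index]]
    cohort = HarmonizedCohort(
        matrix=matrix, clinical=clin, receptor_calls=receptor_calls,
        subtype=subtype, anchor_flag=anchor_flag.astype(bool),
    )
    return cohort, thresholds


def select_subgroup(
    cohort: HarmonizedCohort,
    subtype: str,
    require_survival: str = "dfs",
) -> HarmonizedCohort:
    """Restrict the cohort to one subtype with informative survival.

    Retains samples of the requested subtype whose requested endpoint has a
    positive, non-missing time and a non-missing event indicator.
    ``subtype`` may be "TN", "ERBB2+", "ER+/ERBB2-", "non_tn" or "all".
    """
    tcol, ecol = f"{require_survival}_months", f"{require_survival}_event"
    for col in (tcol, ecol):
        if col not in cohort.clinical.columns:
            raise ValueError(f"clinical table lacks {col}")
    if subtype == "all":
        in_subtype = cohort.subtype.notna()
    elif subtype == "non_tn":
        in_subtype = cohort.subtype.notna() & (cohort.subtype != SUBTYPE_TN)
    else:
        in_subtype = cohort.subtype == subtype
    keep = []
    for s in cohort.matrix.columns:
        if not in_subtype.get(s, False) or s not in cohort.clinical.index:
            continue
        t, e = cohort.clinical.loc[s, tcol], cohort.clinical.loc[s, ecol]
        if pd.notna(t) and t > 0 and pd.notna(e):
            keep.append(s)
    if not keep:
        raise ValueError(f"no samples of subtype {subtype!r} with {require_survival} data")
    logger.info("subgroup %s/%s: %d of %d samples retained",
                subtype, require_survival, len(keep), cohort.matrix.shape[1])
    return HarmonizedCohort(
        matrix=cohort.matrix[keep],
        clinical=cohort.clinical.loc[keep],
        receptor_calls=cohort.receptor_calls.loc[keep],
        subtype=cohort.subtype.loc[keep],
        anchor_flag=cohort.anchor_flag.loc[keep],
    )
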