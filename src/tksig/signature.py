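"""Prognostic signature discovery and the two-class risk classifier.

The discovery recipe: split the analysis cohort into a learning set (~2/3,
stratified by platform) and a validation set (~1/3); screen each candidate
gene in the learning set by univariate Cox regression (Wald p <= 0.05);
search the screened genes for the best multivariate combination by AIC
stepwise selection (bidirectional, starting from the full screened model);
build a risk classifier from the final model's linear predictor
(score_i = sum_g beta_g z_gi) dichotomized at the median learning-set score;
and apply the frozen classifier — coefficients and cutoff, no refitting — to
the validation set.  Validation outcomes are never touched before the
classifier is frozen, which is what makes the validation log-rank test an
honest measure of prognostic value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import SurvivalData, CoxFit, Z95, cox_fit, km_fit, logrank_test

logger = logging.getLogger(__name__)

LOW_RISK = "low-risk"
HIGH_RISK = "high-risk"


@dataclass
class CohortSplit:
    learning_ids: list[str]
    validation_ids: list[str]
    seed: int
    fractions: tuple[float, float] = (2 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if set(self.learning_ids) & set(self.validation_ids):
            raise ValueError("learning and validation sets overlap")


@dataclass
class SignatureModel:
    """Ordered gene list, Cox coefficients, and the risk-score cutoff."""

    genes: list[str]
    beta: np.ndarray
    cutoff: float | None = None
    learning_aic: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.genes) != len(self.beta):
            raise ValueError("genes and beta must be aligned")
        if len(self.genes) == 0:
            raise ValueError("signature must contain at least one gene")

    def scores(self, matrix: pd.DataFrame) -> pd.Series:
        """Risk score (Cox linear predictor) per sample of a gene × sample matrix.

        Samples with any signature gene missing get an undefined (NaN) score
        and are excluded by :meth:`classify` with a log entry.
        """
        missing = [g for g in self.genes if g not in matrix.index]
        if missing:
            raise KeyError(f"matrix lacks signature genes: {missing}")
        sub = matrix.loc[self.genes]
        score = pd.Series(self.beta @ sub.to_numpy(dtype=float),
                          index=matrix.columns)
        score[sub.isna().any(axis=0).to_numpy()] = np.nan
        return score

    def classify(self, matrix: pd.DataFrame) -> pd.Series:
        if self.cutoff is None:
            raise ValueError("classifier cutoff not set; call build_classifier first")
        score = self.scores(matrix)
        dropped = int(score.isna().sum())
        if dropped:
            logger.warning("%d samples with undefined risk score excluded", dropped)
        cls = pd.Series(np.where(score > self.cutoff, HIGH_RISK, LOW_RISK),
                        index=score.index, dtype=object)
        cls[score.isna()] = np.nan
        return cls

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "beta": [float(b) for b in self.beta],
            "cutoff": None if self.cutoff is None else float(self.cutoff),
            "meta": {
                "learning_aic": self.learning_aic,
                **self.provenance,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        meta = dict(d.get("meta", {}))
        return cls(
            genes=list(d["genes"]), beta=np.asarray(d["beta"], dtype=float),
            cutoff=d.get("cutoff"), learning_aic=meta.pop("learning_aic", None),
            provenance=meta,
        )


def split_cohort(
    sample_ids,
    platforms: pd.Series,
    fractions: tuple[float, float] = (2 / 3, 1 / 3),
    seed: int = 0,
) -> CohortSplit:
    """Random learning/validation split stratified by platform.

    Within each platform stratum, round(f * n) samples go to learning so that
    both technologies stay balanced between the two sets.  A stratum with
    fewer than 2 samples is assigned wholly to learning with a warning.
    Deterministic given the seed.
    """
    sample_ids = list(sample_ids)
    if len(sample_ids) < 10:
        raise ValueError("need >= 10 samples to split")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    learning, validation = [], []
    for platform in sorted(platforms.loc[sample_ids].unique()):
        members = [s for s in sample_ids if platforms[s] == platform]
        if len(members) < 2:
            logger.warning("stratum %s has %d sample(s); assigned to learning",
                           platform, len(members))
            learning.extend(members)
            continue
        perm = rng.permutation(len(members))
        n_learn = int(round(fractions[0] * len(members)))
        n_learn = min(max(n_learn, 1), len(members) - 1)
        learning.extend(members[i] for i in perm[:n_learn])
        validation.extend(members[i] for i in perm[n_learn:])
    logger.info("split: %d learning / %d validation", len(learning), len(validation))
    return CohortSplit(learning_ids=sorted(learning), validation_ids=sorted(validation),
                       seed=seed, fractions=fractions)


def stepwise_aic(
    data: SurvivalData,
    expression: pd.DataFrame,
    candidates: list[str],
) -> SignatureModel:
    """Bidirectional AIC stepwise search over screened candidate genes.

    Starts from the full candidate model; at each step every single-gene
    deletion and re-addition is evaluated and the move with the largest AIC
    decrease is applied; the search stops when no move decreases the AIC.
    Ties prefer deletion over addition, then lexicographic gene order, so the
    trace is deterministic.  Non-convergent candidate fits are skipped with a
    warning.  Returns the refitted final model with the full move trace.
    """
    if not candidates:
        raise ValueError("no candidate genes")
    candidates = list(candidates)
    X_all = expression.loc[candidates].to_numpy(dtype=float).T  # n x k
    col = {g: i for i, g in enumerate(candidates)}

    def fit_for(genes: tuple[str, ...]) -> CoxFit | None:
        X = X_all[:, [col[g] for g in genes]]
        try:
            fit = cox_fit(data, X, names=list(genes))
        except ValueError as exc:
            logger.warning("stepwise move skipped (%s): %s", genes, exc)
            return None
        if not fit.converged:
            logger.warning("stepwise move skipped: non-convergent fit for %s", genes)
            return None
        return fit

    current = tuple(sorted(candidates))
    current_fit = fit_for(current)
    if current_fit is None:
        raise ValueError("full candidate model did not converge")
    trace = [{"action": "start", "gene": None, "aic": current_fit.aic,
              "genes": list(current)}]
    cache: dict[tuple[str, ...], float] = {current: current_fit.aic}

    while True:
        moves = []  # (aic, move_rank, gene, new_genes); move_rank 0=deletion
        for g in current:
            new = tuple(x for x in current if x != g)
            if not new:
                continue
            moves.append(("del", g, new))
        for g in sorted(set(candidates) - set(current)):
            new = tuple(sorted(current + (g,)))
            moves.append(("add", g, new))
        best = None
        for action, g, new in sorted(moves, key=lambda m: (m[0] != "del", m[1])):
            if new in cache:
                aic = cache[new]
            else:
                fit = fit_for(new)
                if fit is None:
                    cache[new] = np.inf
                    continue
                aic = cache[new] = fit.aic
            if aic < current_fit.aic - 1e-10 and (best is None or aic < best[0] - 1e-10):
                best = (aic, action, g, new)
        if best is None:
            break
        _, action, g, new = best
        current = new
        current_fit = fit_for(current)
        trace.append({"action": action, "gene": g, "aic": current_fit.aic,
                      "genes": list(current)})

    final_fit = current_fit
    return SignatureModel(
        genes=list(current),
        beta=final_fit.beta,
        learning_aic=final_fit.aic,
        provenance={"stepwise_trace": trace, "candidates": candidates},
    )


def build_classifier(
    model: SignatureModel,
    learning_matrix: pd.DataFrame,
) -> SignatureModel:
    """Set the risk-score cutoff at the median learning-set score.

    The median rule splits the learning set in (near-)halves and is applied
    unchanged to any later cohort.  An all-zero coefficient vector has no
    ordering information and raises ("null signature").
    """
    if np.allclose(model.beta, 0.0):
        raise ValueError("null signature")
    scores = model.scores(learning_matrix).dropna()
    if scores.empty:
        raise ValueError("no learning sample has a defined risk score")
    model.cutoff = float(np.median(scores))
    model.provenance.setdefault("cutoff_rule", "median of learning-set scores")
    return model


def evaluate_classifier(
    model: SignatureModel,
    matrix: pd.DataFrame,
    data: SurvivalData,
    horizon_months: float = 60.0,
) -> dict:
    """Evaluate the frozen classifier on one cohort subset.

    Reports per-class Kaplan–Meier summaries (survival at the horizon with
    95% CI, median survival), the two-group log-rank test, and the univariate
    Cox hazard ratio of high- vs low-risk membership.
    """
    classes = model.classify(matrix)
    keep = classes.notna().to_numpy()
    classes = classes[keep]
    sub = SurvivalData(data.time[keep], data.event[keep])
    n_high = int((classes == HIGH_RISK).sum())
    n_low = int((classes == LOW_RISK).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("one risk class is empty; cannot evaluate classifier")

    out = {"n": sub.n, "horizon_months": horizon_months, "classes": {}}
    per_class = {}
    for label in (LOW_RISK, HIGH_RISK):
        mask = (classes == label).to_numpy()
        grp = SurvivalData(sub.time[mask], sub.event[mask])
        km = km_fit(grp)
        lo, hi = km.ci_at(horizon_months)
        out["classes"][label] = {
            "n": grp.n, "n_events": grp.n_events,
            "survival_at_horizon": km.survival_at(horizon_months),
            "ci_at_horizon": [lo, hi],
            "median_months": km.median,
        }
        per_class[label] = grp
    chi2, p = logrank_test(per_class[LOW_RISK], per_class[HIGH_RISK])
    out["logrank_chi2"], out["logrank_p"] = chi2, p

    indicator = (classes == HIGH_RISK).to_numpy(dtype=float)
    fit = cox_fit(sub, indicator[:, None], names=["high_vs_low"])
    out["cox_high_vs_low"] = fit.to_dict()["covariates"][0]
    out["cox_high_vs_low"]["converged"] = fit.converged
    return out
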