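"""Synthetic multi-study expression cohorts with known ground truth.

The generator emulates the statistical structure the discovery pipeline
assumes, with every latent quantity exposed for parameter-recovery tests:

* several datasets ("studies"), each with its own additive/multiplicative
  batch distortion and platform tag (microarray or RNA-seq);
* three receptor genes (ESR1, PGR, ERBB2) whose expression is a two-component
  Gaussian mixture tied to each sample's true receptor class;
* a candidate gene panel (86 tyrosine kinases by default) containing a
  planted prognostic subset: each planted gene has a latent N(0,1) covariate
  that enters both the gene's expression and the relapse hazard with a known
  log-hazard coefficient;
* luminal-A-like "anchor" samples (ER+/PR+/ERBB2-) used downstream as the
  z-scoring reference;
* right-censored disease-free survival from a Weibull proportional-hazards
  model, with independent exponential censoring whose rate is solved to hit a
  target censoring fraction, and overall survival coupled to relapse.

Expression of gene g in sample i of dataset d is
``mu_g + shift_d + scale_d * (signal_gi + eps_gi)``; anchoring on the
luminal-A-like reference therefore removes the batch terms exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io
from .genes import RECEPTOR_GENES, TK_PANEL
from .harmonize import ExpressionStudy

#: default planted prognostic genes: log-hazard per latent unit.
DEFAULT_PLANTED = {
    "ALK": 0.8, "FLT1": 0.8, "EPHA4": 0.8, "ITK": -0.8, "ZAP70": -0.8,
}

#: default receptor mixtures: (negative mean, positive mean, negative SD,
#: positive SD) on the log2 signal scale, relative to the gene's baseline.
DEFAULT_RECEPTOR_MIXTURES = {
    "ESR1": (-1.8, 1.8, 0.55, 0.55),
    "PGR": (-1.6, 1.6, 0.6, 0.6),
    "ERBB2": (-1.5, 2.0, 0.55, 0.65),
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated multi-dataset cohort."""

    n_datasets: int = 4
    samples_per_dataset: int = 410
    n_genes_total: int = 150
    panel_genes: tuple[str, ...] = TK_PANEL
    planted_genes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PLANTED))
    receptor_mixtures: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_RECEPTOR_MIXTURES))
    batch_shift: tuple[float, ...] | None = None  # None: auto linspace(-2, 2)
    batch_scale: tuple[float, ...] | None = None  # None: auto geomspace(0.75, 1.35)
    n_rnaseq_datasets: int = 1
    baseline_hazard: tuple[float, float] = (1.2, 120.0)  # Weibull shape, scale (months)
    censoring_rate: float = 0.4
    anchor_fraction: float = 0.2
    noise_sd: float = 0.3
    er_pos_rate: float = 0.20
    pr_pos_given_er: float = 0.7
    pr_pos_given_not_er: float = 0.1
    erbb2_pos_rate: float = 0.15
    os_death_fraction: float = 0.6  # fraction of relapsers who progress to death
    os_lag_mean_months: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_datasets, self.samples_per_dataset, self.n_genes_total) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if not 0 <= self.anchor_fraction < 1:
            raise ValueError("anchor_fraction must be in [0, 1)")
        panel = set(self.panel_genes)
        if not set(self.planted_genes) <= panel:
            raise ValueError("planted_genes must be a subset of panel_genes")
        if set(RECEPTOR_GENES) & panel:
            raise ValueError("receptor genes cannot be panel genes")
        if self.n_genes_total < len(panel) + len(RECEPTOR_GENES):
            raise ValueError("n_genes_total too small for panel + receptor genes")
        shape, scale = self.baseline_hazard
        if shape <= 0 or scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        for g, (m_neg, m_pos, s_neg, s_pos) in self.receptor_mixtures.items():
            if abs(m_pos - m_neg) < 0.5 * max(s_neg, s_pos):
                raise ValueError(
                    f"receptor mixture for {g} is not separable "
                    f"(|delta mean| < 0.5 * max SD); receptor calling would be undefined"
                )
        if self.batch_scale is not None and min(self.batch_scale) <= 0:
            raise ValueError("batch_scale factors must be > 0")
        for name in ("batch_shift", "batch_scale"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_datasets:
                raise ValueError(f"{name} must have one entry per dataset")

    def shifts(self) -> np.ndarray:
        if self.batch_shift is not None:
            return np.asarray(self.batch_shift, dtype=float)
        if self.n_datasets == 1:
            return np.zeros(1)
        return np.linspace(-2.0, 2.0, self.n_datasets)

    def scales(self) -> np.ndarray:
        if self.batch_scale is not None:
            return np.asarray(self.batch_scale, dtype=float)
        if self.n_datasets == 1:
            return np.ones(1)
        return np.geomspace(0.75, 1.35, self.n_datasets)


@dataclass
class GroundTruth:
    """Truth channel: per-sample classes and times, per-gene effects."""

    samples: pd.DataFrame  # index sample_id: dataset_id, er/pr/erbb2, subtype_true,
    #                        anchor, event_time, censor_time, os_death_time
    genes: pd.DataFrame  # index gene: beta
    batch_free: pd.DataFrame  # gene x sample matrix without batch terms


@dataclass
class SimulatedBundle:
    studies: list[ExpressionStudy]
    clinical: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig

    def __iter__(self):  # allow tuple-style unpacking
        return iter((self.studies, self.clinical, self.truth))


def _censoring_rate_for(event_times: np.ndarray, target: float) -> float:
    """Exponential censoring rate r with mean_i(1 - exp(-r t_i)) = target."""
    if target <= 0:
        return 0.0

    def f(r):
        return np.mean(1.0 - np.exp(-r * event_times)) - target

    hi = 1.0
    while f(hi) < 0:
        hi *= 4.0
        if hi > 1e6:
            break
    return brentq(f, 1e-12, hi)


def simulate_cohort(config: SimulationConfig) -> SimulatedBundle:
    """Generate one multi-study cohort; same seed, same bytes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = list(config.panel_genes)
    receptors = list(RECEPTOR_GENES)
    n_bg = config.n_genes_total - len(panel) - len(receptors)
    background = [f"BG{i:04d}" for i in range(n_bg)]
    genes = panel + receptors + background
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    mu = np.clip(rng.normal(8.0, 1.5, size=n_genes), 4.0, 12.0)
    shifts, scales = config.shifts(), config.scales()
    shape, wscale = config.baseline_hazard
    planted = list(config.planted_genes)
    beta = np.array([config.planted_genes[g] for g in planted])

    studies: list[ExpressionStudy] = []
    sample_rows = []
    clin_rows = []
    batch_free_cols = []
    all_event_times = []

    for d in range(config.n_datasets):
        ds_id = f"D{d + 1:02d}"
        platform = ("rnaseq"
                    if d >= config.n_datasets - config.n_rnaseq_datasets
                    else "microarray")
        m = config.samples_per_dataset
        ids = [f"{ds_id}_S{i + 1:04d}" for i in range(m)]

        anchor = rng.random(m) < config.anchor_fraction
        er = np.where(anchor, True, rng.random(m) < config.er_pos_rate)
        pr_prob = np.where(er, config.pr_pos_given_er, config.pr_pos_given_not_er)
        pr = np.where(anchor, True, rng.random(m) < pr_prob)
        erbb2 = np.where(anchor, False, rng.random(m) < config.erbb2_pos_rate)
        tn = ~er & ~pr & ~erbb2
        subtype_true = np.where(anchor, "anchor", np.where(tn, "TN", "other"))

        # latent prognostic covariates and expression signal
        signal = rng.normal(0.0, 1.0, size=(n_genes, m))
        z_planted = signal[[gene_pos[g] for g in planted], :]
        for g in receptors:
            m_neg, m_pos, s_neg, s_pos = config.receptor_mixtures[g]
            positive = {"ESR1": er, "PGR": pr, "ERBB2": erbb2}[g]
            comp_mean = np.where(positive, m_pos, m_neg)
            comp_sd = np.where(positive, s_pos, s_neg)
            signal[gene_pos[g], :] = comp_mean + comp_sd * rng.normal(size=m)

        eps = rng.normal(0.0, config.noise_sd, size=(n_genes, m))
        clean = mu[:, None] + signal + eps
        values = mu[:, None] + shifts[d] + scales[d] * (signal + eps)
        batch_free_cols.append(pd.DataFrame(clean, index=genes, columns=ids))

        # Weibull proportional-hazards relapse times
        eta = beta @ z_planted if planted else np.zeros(m)
        event_time = wscale * (rng.exponential(size=m) / np.exp(eta)) ** (1.0 / shape)
        all_event_times.append(event_time)

        age = np.round(np.clip(rng.normal(56, 12, size=m), 25, 90), 1)
        grade = rng.choice([1, 2, 3], p=[0.05, 0.20, 0.75], size=m)
        pT = rng.choice(["pT1", "pT2", "pT3"], p=[0.30, 0.55, 0.15], size=m)
        pN = rng.choice(["negative", "positive"], p=[0.6, 0.4], size=m)
        histo = rng.choice(["ductal", "lobular", "other"], p=[0.80, 0.05, 0.15], size=m)

        studies.append(ExpressionStudy(
            matrix=pd.DataFrame(values, index=genes, columns=ids),
            platform=platform, dataset_id=ds_id,
        ))
        sample_rows.append(pd.DataFrame({
            "dataset_id": ds_id, "er": er, "pr": pr, "erbb2": erbb2,
            "subtype_true": subtype_true, "anchor": anchor,
            "event_time": event_time,
        }, index=ids))
        clin_rows.append(pd.DataFrame({
            "sample_id": ids, "dataset_id": ds_id, "platform": platform,
            "age_years": age, "grade": grade, "pT": pT, "pN": pN,
            "histotype": histo,
        }))

    truth_samples = pd.concat(sample_rows)
    clinical = pd.concat(clin_rows, ignore_index=True)
    event_time = truth_samples["event_time"].to_numpy()
    n_total = len(event_time)

    rate = _censoring_rate_for(event_time, config.censoring_rate)
    if rate > 0:
        censor_time = rng.exponential(1.0 / rate, size=n_total)
    else:
        censor_time = np.full(n_total, event_time.max() + 1.0)
    dfs_months = np.minimum(event_time, censor_time)
    dfs_event = (event_time <= censor_time).astype(int)

    # overall survival: a fraction of relapsers die after a positive lag;
    # follow-up for OS ends at the same censoring time.
    dies = (dfs_event == 1) & (rng.random(n_total) < config.os_death_fraction)
    lag = rng.exponential(config.os_lag_mean_months, size=n_total)
    death_time = np.where(dies, event_time + lag, np.inf)
    os_event = (death_time <= censor_time).astype(int)
    os_months = np.where(os_event == 1, death_time, censor_time)

    truth_samples["censor_time"] = censor_time
    truth_samples["os_death_time"] = death_time
    clinical["dfs_months"] = dfs_months
    clinical["dfs_event"] = dfs_event
    clinical["os_months"] = os_months
    clinical["os_event"] = os_event
    clinical = clinical[io.CLINICAL_COLUMNS]

    truth = GroundTruth(
        samples=truth_samples,
        genes=pd.DataFrame(
            {"beta": [config.planted_genes.get(g, 0.0) for g in genes]}, index=genes),
        batch_free=pd.concat(batch_free_cols, axis=1),
    )
    return SimulatedBundle(studies=studies, clinical=clinical, truth=truth, config=config)


def write_fixture(bundle: SimulatedBundle, directory: str | Path, force: bool = False) -> dict:
    """Serialize a simulated bundle to TSV files plus a JSON manifest.

    Writes one expression TSV per study, the clinical table, the per-sample
    and per-gene truth tables, and ``manifest.json`` (file hashes, seed,
    platforms).  Refuses to overwrite an existing manifest unless ``force``.
    The latent batch-free matrix is not serialized; regenerate it from the
    config when needed.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    if any(s.matrix.shape[0] == 0 for s in bundle.studies):
        raise ValueError("no genes")
    directory.mkdir(parents=True, exist_ok=True)

    files: dict[str, str] = {}
    platforms: dict[str, str] = {}
    for study in bundle.studies:
        name = f"expression_{study.dataset_id}.tsv"
        io.write_matrix_tsv(study.matrix, directory / name)
        files[name] = io.sha256_file(directory / name)
        platforms[study.dataset_id] = study.platform
    io.write_clinical_tsv(bundle.clinical, directory / "clinical.tsv")
    files["clinical.tsv"] = io.sha256_file(directory / "clinical.tsv")
    ts = bundle.truth.samples.copy()
    ts.index.name = "sample_id"
    ts.to_csv(directory / "truth_samples.tsv", sep="\t", na_rep="NA")
    files["truth_samples.tsv"] = io.sha256_file(directory / "truth_samples.tsv")
    tg = bundle.truth.genes.copy()
    tg.index.name = "gene_id"
    tg.to_csv(directory / "truth_genes.tsv", sep="\t", na_rep="NA")
    files["truth_genes.tsv"] = io.sha256_file(directory / "truth_genes.tsv")

    manifest = {
        "seed": bundle.config.seed,
        "n_datasets": bundle.config.n_datasets,
        "platforms": platforms,
        "files": files,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                             encoding="utf-8")
    return manifest


def read_fixture(directory: str | Path) -> tuple[list[ExpressionStudy], pd.DataFrame]:
    """Read back the expression studies and clinical table of a fixture."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
    studies = []
    for ds_id, platform in sorted(manifest["platforms"].items()):
        mat = io.read_matrix_tsv(directory / f"expression_{ds_id}.tsv")
        studies.append(ExpressionStudy(matrix=mat, platform=platform, dataset_id=ds_id))
    clinical = io.read_clinical_tsv(directory / "clinical.tsv")
    return studies, clinical
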