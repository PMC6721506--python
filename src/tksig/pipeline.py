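"""End-to-end orchestration of the discovery pipeline.

Stages (mirroring the analysis flow): simulate → preprocess/harmonize →
discover (split, screen, stepwise, classifier, evaluation) → resampling
null → differential expression / centroid score → report.  Each stage reads
and writes plain-text artifacts in a run directory and records hashes in a
run manifest, so identical configs and seeds reproduce identical outputs.

The learning/validation split is frozen by the discover stage (split.json,
hashed into signature.json); the null stage refuses to run against a
signature whose split hash does not match, which prevents accidental
leakage between signature selection and its significance assessment.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .diffexp import association_tests, centroid_score, de_gene_list, moderated_t
from .genes import TK_PANEL
from .harmonize import HarmonizedCohort, harmonize_cohort, select_subgroup
from .resampling import run_resampling_null
from .report import render_report
from .signature import (CohortSplit, SignatureModel, build_classifier,
                        evaluate_classifier, split_cohort, stepwise_aic)
from .simulate import SimulationConfig, read_fixture, simulate_cohort, write_fixture
from .survival import SurvivalData, univariate_screen

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    input_dir: str = "fixtures"
    out_dir: str = "run"
    seed: int = 0
    subgroup: str = "TN"
    endpoint: str = "dfs"
    screen_alpha: float = 0.05
    split_fractions: tuple[float, float] = (2 / 3, 1 / 3)
    split_seed: int | None = None  # default: seed
    resampling_B: int = 10_000
    resampling_k: int | None = None
    resampling_seed: int | None = None
    de_p_max: float = 0.01
    de_q_max: float = 0.01
    de_fc_min: float = 1.25
    anchors_file: str | None = None  # one sample id per line; None: heuristic
    gene_panel_file: str | None = None  # one symbol per line; None: built-in 86
    gmt_file: str | None = None  # gene sets for metagene scoring (diffexp stage)
    simulate: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 <= self.screen_alpha < 1:
            raise ValueError("screen_alpha must be in [0, 1)")
        if not np.isclose(sum(self.split_fractions), 1.0):
            raise ValueError("split_fractions must sum to 1")
        if self.resampling_B < 1:
            raise ValueError("resampling_B must be >= 1")
        if self.endpoint not in ("dfs", "os"):
            raise ValueError("endpoint must be 'dfs' or 'os'")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")
        for name in ("anchors_file", "gene_panel_file", "gmt_file"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def snapshot(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["split_fractions"] = list(self.split_fractions)
        return d


def _panel(config: PipelineConfig) -> list[str]:
    if config.gene_panel_file:
        lines = Path(config.gene_panel_file).read_text(encoding="utf-8").split()
        return [g for g in lines if g]
    return list(TK_PANEL)


def _manifest_update(out_dir: Path, stage: str, files: list[str], config: PipelineConfig):
    path = out_dir / "run_manifest.json"
    manifest = io.read_json(path) if path.exists() else {
        "version": __version__, "config": config.snapshot(), "stages": {}}
    manifest["stages"][stage] = {
        "files": {f: io.sha256_file(out_dir / f) for f in files
                  if (out_dir / f).exists()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    io.write_json(manifest, path)


def _split_hash(split: CohortSplit) -> str:
    payload = "|".join(sorted(split.learning_ids)) + "||" + \
        "|".join(sorted(split.validation_ids))
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# stages


def cmd_simulate(config: PipelineConfig, force: bool = False) -> dict:
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", config.seed)
    sim = SimulationConfig(**sim_kwargs)
    bundle = simulate_cohort(sim)
    manifest = write_fixture(bundle, config.input_dir, force=force)
    anchors = bundle.truth.samples.index[bundle.truth.samples["anchor"]]
    (Path(config.input_dir) / "anchors.txt").write_text(
        "\n".join(anchors) + "\n", encoding="utf-8")
    return manifest


def load_cohort(config: PipelineConfig) -> HarmonizedCohort:
    studies, clinical = read_fixture(config.input_dir)
    anchors = None
    if config.anchors_file:
        anchors = [s for s in
                   Path(config.anchors_file).read_text(encoding="utf-8").split()
                   if s]
    cohort, thresholds = harmonize_cohort(studies, clinical, anchor_ids=anchors)
    return cohort


def cmd_preprocess(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    studies, clinical = read_fixture(config.input_dir)
    anchors = None
    if config.anchors_file:
        anchors = [s for s in
                   Path(config.anchors_file).read_text(encoding="utf-8").split() if s]
    cohort, thresholds = harmonize_cohort(studies, clinical, anchor_ids=anchors)
    io.write_matrix_tsv(cohort.matrix, out / "harmonized_matrix.tsv")
    calls = cohort.receptor_calls.copy()
    calls["subtype"] = cohort.subtype
    calls["anchor"] = cohort.anchor_flag
    calls.index.name = "sample_id"
    calls.to_csv(out / "receptor_calls.tsv", sep="\t", na_rep="NA")
    io.write_json([vars(t) for t in thresholds], out / "receptor_thresholds.json")
    _manifest_update(out, "preprocess",
                     ["harmonized_matrix.tsv", "receptor_calls.tsv",
                      "receptor_thresholds.json"], config)
    return out


def survival_data_for(cohort: HarmonizedCohort, ids: list[str],
                      endpoint: str) -> SurvivalData:
    """Survival container for a set of cohort samples at one endpoint."""
    clin = cohort.clinical.loc[ids]
    return SurvivalData(clin[f"{endpoint}_months"].to_numpy(),
                        clin[f"{endpoint}_event"].to_numpy())


_survival_for = survival_data_for


def discover_signature(
    cohort: HarmonizedCohort,
    panel: list[str],
    split: CohortSplit,
    endpoint: str = "dfs",
    screen_alpha: float = 0.05,
) -> tuple[SignatureModel, pd.DataFrame]:
    """Screen + stepwise + classifier, touching learning outcomes only.

    The returned model is fully frozen (genes, coefficients, cutoff) before
    any validation outcome is read, which the evaluation stage relies on.
    """
    genes = [g for g in panel if g in cohort.matrix.index]
    if not genes:
        raise ValueError("no panel genes present in the harmonized matrix")
    learn_matrix = cohort.matrix.loc[genes, split.learning_ids]
    learn_data = _survival_for(cohort, split.learning_ids, endpoint)
    passing, screen_table = univariate_screen(learn_data, learn_matrix,
                                              alpha=screen_alpha)
    if not passing:
        raise ValueError("no genes passed the univariate screen")
    logger.info("screen: %d of %d genes at p <= %g", len(passing), len(genes),
                screen_alpha)
    model = stepwise_aic(learn_data, learn_matrix, passing)
    build_classifier(model, learn_matrix)
    model.provenance.update({
        "screen_alpha": screen_alpha,
        "n_screened": len(passing),
        "endpoint": endpoint,
        "split_seed": split.seed,
        "split_hash": _split_hash(split),
    })
    return model, screen_table


def _write_km_curves(model: SignatureModel, matrix: pd.DataFrame,
                     data: SurvivalData, path: Path) -> None:
    """Per-class Kaplan–Meier step functions as TSV (time, S, lo, hi, class)."""
    from .survival import km_fit

    classes = model.classify(matrix)
    rows = []
    for label in ("low-risk", "high-risk"):
        mask = (classes == label).to_numpy()
        if not mask.any():
            continue
        km = km_fit(SurvivalData(data.time[mask], data.event[mask]))
        for t, s, lo, hi in zip(km.times, km.survival, km.ci_low, km.ci_high):
            rows.append({"time_months": t, "survival": s,
                         "ci_low": lo, "ci_high": hi, "class": label})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def cmd_discover(config: PipelineConfig) -> Path:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(config)
    target = select_subgroup(cohort, config.subgroup, require_survival=config.endpoint)

    platforms = target.clinical["platform"]
    split = split_cohort(target.matrix.columns, platforms,
                        fractions=config.split_fractions,
                        seed=config.seed if config.split_seed is None
                        else config.split_seed)
    model, screen_table = discover_signature(
        target, _panel(config), split,
        endpoint=config.endpoint, screen_alpha=config.screen_alpha)

    io.write_json(model.to_dict(), out / "signature.json")
    io.write_json({
        "learning_ids": split.learning_ids,
        "validation_ids": split.validation_ids,
        "seed": split.seed,
        "hash": _split_hash(split),
    }, out / "split.json")
    screen_table.reset_index().to_csv(out / "screen_table.tsv", sep="\t",
                                      index=False, na_rep="NA")

    files = ["signature.json", "split.json", "screen_table.tsv"]
    for name, ids in (("learning", split.learning_ids),
                      ("validation", split.validation_ids)):
        data = _survival_for(target, ids, config.endpoint)
        ev = evaluate_classifier(model, target.matrix[ids], data)
        io.write_json(ev, out / f"evaluation_{name}.json")
        _write_km_curves(model, target.matrix[ids], data,
                         out / f"km_{name}.tsv")
        files += [f"evaluation_{name}.json", f"km_{name}.tsv"]

    # the classifier should be specific to the target subgroup: apply it to
    # the complementary (non-target) samples as a negative control
    if config.subgroup == "TN":
        try:
            non_target = select_subgroup(cohort, "non_tn",
                                         require_survival=config.endpoint)
            ev = evaluate_classifier(
                model, non_target.matrix,
                _survival_for(non_target, non_target.samples(), config.endpoint))
            io.write_json(ev, out / "evaluation_non_target.json")
            files.append("evaluation_non_target.json")
        except ValueError as exc:
            logger.info("non-target check skipped: %s", exc)
    _manifest_update(out, "discover", files, config)
    return out


def cmd_null(config: PipelineConfig, signature_path: str | Path | None = None) -> Path:
    config.validate()
    out = Path(config.out_dir)
    signature_path = Path(signature_path or out / "signature.json")
    sig = SignatureModel.from_dict(io.read_json(signature_path))
    split_info = io.read_json(out / "split.json")
    if sig.provenance.get("split_hash") != split_info["hash"]:
        raise ValueError(
            "split hash mismatch between signature and run directory; "
            "refusing to run the resampling null on a different split")

    cohort = load_cohort(config)
    target = select_subgroup(cohort, config.subgroup, require_survival=config.endpoint)
    panel = [g for g in _panel(config) if g in target.matrix.index]
    learn_ids = split_info["learning_ids"]
    valid_ids = split_info["validation_ids"]
    null = run_resampling_null(
        sig.genes, panel,
        target.matrix.loc[panel, learn_ids],
        _survival_for(target, learn_ids, config.endpoint),
        target.matrix.loc[panel, valid_ids],
        _survival_for(target, valid_ids, config.endpoint),
        B=config.resampling_B,
        k=config.resampling_k,
        seed=config.seed if config.resampling_seed is None
        else config.resampling_seed,
    )
    io.write_json(null.to_dict(), out / "null_summary.json")
    pd.DataFrame({"p": null.null_p}).to_csv(out / "null_pvalues.tsv", sep="\t",
                                            index=False)
    _manifest_update(out, "null", ["null_summary.json", "null_pvalues.tsv"], config)
    return out


def cmd_diffexp(config: PipelineConfig) -> Path:
    config.validate()
    out = Path(config.out_dir)
    sig = SignatureModel.from_dict(io.read_json(out / "signature.json"))
    split_info = io.read_json(out / "split.json")
    cohort = load_cohort(config)
    target = select_subgroup(cohort, config.subgroup, require_survival=config.endpoint)

    classes = sig.classify(target.matrix)
    learn_ids = [s for s in split_info["learning_ids"] if pd.notna(classes.get(s))]
    valid_ids = split_info["validation_ids"]

    result = moderated_t(target.matrix[learn_ids], classes,
                         groups=("low-risk", "high-risk"))
    de = de_gene_list(result, p_max=config.de_p_max, q_max=config.de_q_max,
                      fc_min=config.de_fc_min)
    table = result.table.copy()
    table["direction"] = np.where(
        table.index.isin(de.up_in_first), "up_in_low-risk",
        np.where(table.index.isin(de.up_in_second), "up_in_high-risk", ""))
    table.index.name = "gene"
    table.to_csv(out / "de_table.tsv", sep="\t", na_rep="NA")

    summary = {
        "n_up_in_low": len(de.up_in_first),
        "n_up_in_high": len(de.up_in_second),
        "thresholds": de.thresholds,
        "d0": result.d0 if np.isfinite(result.d0) else "inf",
        "s0_sq": result.s0_sq,
        "centroid_ttest_p": None,
    }
    de_genes = de.up_in_first + de.up_in_second
    if len(de_genes) >= 3:
        cs = centroid_score(
            target.matrix.loc[de_genes, learn_ids], classes,
            groups=("high-risk", "low-risk"),
            new_matrix=target.matrix.loc[de_genes, valid_ids],
            new_labels=classes,
        )
        cs.scores.to_csv(out / "centroid_scores.tsv", sep="\t", na_rep="NA")
        summary["centroid_ttest_p"] = cs.ttest_p
    io.write_json(summary, out / "de_summary.json")

    if config.gmt_file:
        from .diffexp import metagene_score

        sets = io.read_gmt(config.gmt_file)
        scores = pd.DataFrame({
            name: metagene_score(target.matrix, genes, set_name=name)
            for name, genes in sets.items()})
        scores.index.name = "sample_id"
        scores.to_csv(out / "metagene_scores.tsv", sep="\t", na_rep="NA")

    assoc = association_tests(classes.dropna(),
                              target.clinical.loc[classes.dropna().index],
                              seed=config.seed)
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False, na_rep="NA")
    _manifest_update(out, "diffexp",
                     ["de_table.tsv", "de_summary.json", "associations.tsv"],
                     config)
    return out


def cmd_report(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    text = render_report(out)
    (out / "report.md").write_text(text, encoding="utf-8")
    _manifest_update(out, "report", ["report.md"], config)
    return out / "report.md"
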