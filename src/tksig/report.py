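"""Human-readable reporting helpers and the run-level markdown report.

Display conventions follow the field's prognostic-study tables: hazard
ratios as "HR (95%CI lo–hi)" with two decimals, cohort-description rows as
"N (pct%)" with whole-number column percentages, and survival probabilities
as whole percentages with their confidence bands.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .survival import Z95


def format_hr(beta: float, se: float) -> str:
    """Format a Cox coefficient as ``HR (lo–hi)`` with two decimals.

    Degenerate (separated) fits print as ``HR (0–Inf)``.
    """
    hr = math.exp(beta)
    if not np.isfinite(se) or se > 50:
        return f"{hr:.2f} (0–Inf)"
    lo = math.exp(beta - Z95 * se)
    hi = math.exp(beta + Z95 * se)
    return f"{hr:.2f} ({lo:.2f}–{hi:.2f})"


def percent(count: int, total: int) -> int:
    """Whole-number percentage as printed in cohort-description tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total)


def count_table(counts: dict[str, int]) -> list[tuple[str, int, int]]:
    """Rows of (level, N, pct) for a categorical cohort-description block."""
    total = sum(counts.values())
    return [(level, n, percent(n, total)) for level, n in counts.items()]


def format_survival_pct(s: float, lo: float, hi: float) -> str:
    return f"{round(100 * s)}% (95%CI {round(100 * lo)}–{round(100 * hi)})"


def _eval_section(title: str, ev: dict) -> list[str]:
    lines = [f"### {title}", ""]
    for label in ("low-risk", "high-risk"):
        c = ev["classes"][label]
        lo, hi = c["ci_at_horizon"]
        med = c["median_months"]
        med_txt = f"{med:.0f}" if np.isfinite(med) else "not reached"
        lines.append(
            f"- {label}: N = {c['n']}, "
            f"{ev['horizon_months'] / 12:.0f}-year survival "
            f"{format_survival_pct(c['survival_at_horizon'], lo, hi)}, "
            f"median {med_txt} months"
        )
    cox = ev["cox_high_vs_low"]
    lines += [
        f"- log-rank p = {ev['logrank_p']:.3g}",
        f"- Cox high- vs low-risk: HR (95%CI) = "
        f"{format_hr(cox['beta'], cox['se'])}, Wald p = {cox['p']:.3g}",
        "",
    ]
    return lines


def render_report(run_dir: str | Path) -> str:
    """Assemble the markdown report from a run directory's stage outputs.

    Partial runs yield partial reports: sections whose inputs are missing
    state so explicitly instead of failing.
    """
    from . import io  # local import to avoid cycle

    run_dir = Path(run_dir)
    lines = ["# Prognostic signature run report", ""]

    sig_path = run_dir / "signature.json"
    if sig_path.exists():
        sig = io.read_json(sig_path)
        lines += [
            "## Signature",
            "",
            f"- genes ({len(sig['genes'])}): {', '.join(sig['genes'])}",
            f"- risk-score cutoff: {sig['cutoff']:.4f}",
            "",
        ]
    else:
        lines += ["## Signature", "", "discovery: not run", ""]

    for name, title in (("evaluation_learning.json", "Learning set"),
                        ("evaluation_validation.json", "Validation set"),
                        ("evaluation_non_target.json", "Non-target subgroup")):
        path = run_dir / name
        lines += ["## " + title, ""]
        if path.exists():
            lines += _eval_section("Classifier performance", io.read_json(path))
        else:
            lines += [f"{title.lower()} evaluation: not run", ""]

    null_path = run_dir / "null_summary.json"
    lines += ["## Resampling null", ""]
    if null_path.exists():
        ns = io.read_json(null_path)
        lines += [
            f"- B = {ns['B']} random {ns['k']}-gene signatures",
            f"- observed validation log-rank p = {ns['observed_p']:.3g}",
            f"- empirical p (strict proportion) = {ns['empirical_p']:.3g}",
            f"- empirical p (smoothed) = {ns['empirical_p_smoothed']:.3g}",
            "",
        ]
    else:
        lines += ["resampling: not run", ""]

    de_path = run_dir / "de_summary.json"
    lines += ["## Differential expression", ""]
    if de_path.exists():
        de = io.read_json(de_path)
        lines += [
            f"- {de['n_up_in_low']} genes over-expressed in low-risk, "
            f"{de['n_up_in_high']} in high-risk "
            f"(p < {de['thresholds']['p_max']}, q < {de['thresholds']['q_max']}, "
            f"FC > |{de['thresholds']['fc_min']}x|)",
        ]
        if de.get("centroid_ttest_p") is not None:
            lines += [f"- centroid-score separation (validation): "
                      f"Welch t p = {de['centroid_ttest_p']:.3g}"]
        lines += [""]
    else:
        lines += ["differential expression: not run", ""]

    assoc_path = run_dir / "associations.tsv"
    lines += ["## Class / clinical associations", ""]
    if assoc_path.exists():
        lines += ["see associations.tsv", ""]
    else:
        lines += ["associations: not run", ""]
    return "\n".join(lines) + "\n"
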