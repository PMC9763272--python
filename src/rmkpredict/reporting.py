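"""Report assembly: JSON-serializable result trees and a markdown rendering.

The JSON report mirrors the structure of the study-style result tables: per
outcome and per set (training/validation for the split-sample procedure, the
pooled out-of-fold set for leave-one-out), the error metrics with their
normalized percentages, the R-squared pair, and the Spearman correlation of
the discrete-corrected predictions with its strength label.  Normalized RMSE
values additionally carry their display rounding (integers for sub-items,
one decimal for the upper-limb total).
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .evaluation import ValidationReport, format_rmse_n
from .regression import (
    LOOCVResult,
    PUBLISHED_LOOCV_MODELS,
    RegressionModel,
    SSVResult,
)
from .scales import get_scale

__all__ = [
    "model_to_dict",
    "report_to_dict",
    "build_report",
    "render_markdown",
]


def _clean(value):
    """Make numpy scalars and NaN JSON-friendly."""
    if isinstance(value, (np.floating, np.integer)):
        value = value.item()
    if isinstance(value, float) and not math.isfinite(value):
        return None
    return value


def model_to_dict(model: RegressionModel) -> dict:
    return {
        "outcome": model.outcome,
        "n": model.n,
        "intercept": _clean(model.intercept),
        "predictors": list(model.predictors),
        "coefficients": {k: _clean(v) for k, v in model.coefficients.items()},
        "std_errors": {k: _clean(v) for k, v in model.bse.items() if k != "const"},
        "p_values": {k: _clean(v) for k, v in model.pvalues.items() if k != "const"},
        "r2": _clean(model.r2),
        "r2_adj": _clean(model.r2_adj),
    }


def report_to_dict(report: ValidationReport, outcome: str) -> dict:
    d = {k: _clean(v) for k, v in report.to_dict().items()}
    d["rmse_n_display"] = _clean(format_rmse_n(report.rmse_n, get_scale(outcome)))
    return d


def _ssv_section(results: Mapping[str, SSVResult]) -> dict:
    section: dict = {}
    for outcome, res in results.items():
        entry = {
            "split": {
                "n_train": res.split.n_train,
                "n_valid": res.split.n_valid,
                "seed": res.split.seed,
                "train_ids": list(res.split.train_ids),
                "valid_ids": list(res.split.valid_ids),
            },
            "full_model": model_to_dict(res.full_model),
            "model": model_to_dict(res.model),
            "training": report_to_dict(res.train_report, outcome),
            "validation": report_to_dict(res.valid_report, outcome),
        }
        if res.split.balance is not None:
            entry["balance_tests"] = [
                {k: _clean(v) for k, v in row.items()}
                for row in res.split.balance.to_dict("records")
            ]
            entry["four_group_tests"] = [
                {k: _clean(v) for k, v in row.items()}
                for row in res.split.subgroup_balance.to_dict("records")
            ]
        section[outcome] = entry
    return section


def _loocv_section(results: Mapping[str, LOOCVResult]) -> dict:
    section: dict = {}
    for outcome, res in results.items():
        published = PUBLISHED_LOOCV_MODELS[outcome]
        fitted_slope = res.final_model.coefficients.get("mpe_c")
        section[outcome] = {
            "n_fits": res.n_fits,
            "loocv": report_to_dict(res.report, outcome),
            "full_model": model_to_dict(res.full_model),
            "final_model": model_to_dict(res.final_model),
            "published_comparison": {
                "published_intercept": published[0],
                "published_mpe_c_slope": published[1],
                "fitted_intercept": _clean(res.final_model.intercept),
                "fitted_mpe_c_slope": _clean(fitted_slope)
                if fitted_slope is not None
                else None,
            },
        }
    return section


def build_report(
    ssv: Mapping[str, SSVResult] | None = None,
    loocv: Mapping[str, LOOCVResult] | None = None,
    seed: int | None = None,
    config_hash: str | None = None,
) -> dict:
    """Assemble the full JSON-serializable analysis report."""
    report: dict = {"seed": seed, "config_hash": config_hash}
    if ssv is not None:
        report["ssv"] = _ssv_section(ssv)
    if loocv is not None:
        report["loocv"] = _loocv_section(loocv)
    return report


def _fmt(value, digits=3) -> str:
    if value is None:
        return "--"
    return f"{value:.{digits}f}"


def _metric_row(outcome: str, d: dict) -> str:
    return (
        f"| {outcome} | {_fmt(d['rmse'])} | {d['rmse_n_display']} "
        f"| {_fmt(d['r2'])} ({_fmt(d['r2_adj'])}) "
        f"| {_fmt(d['mae'])} ({_fmt(d['mae_n'], 0)}%) "
        f"| {_fmt(d['spearman_r'])} ({d['strength']}) |"
    )


_HEADER = (
    "| Outcome | RMSE | RMSE_n (%) | R2 (R2_adj) | MAE (MAE_n) | Spearman r |\n"
    "|---|---|---|---|---|---|"
)


def render_markdown(report: dict) -> str:
    """Human-readable report: metric tables plus the published comparison."""
    lines = ["# Discharge Motricity Index prediction report", ""]
    lines.append(f"Seed: {report.get('seed')}  ")
    lines.append(f"Config hash: {report.get('config_hash')}")
    lines.append("")

    if "ssv" in report:
        any_entry = next(iter(report["ssv"].values()))
        lines += [
            "## Split-sample validation",
            "",
            f"Training n = {any_entry['split']['n_train']}, "
            f"validation n = {any_entry['split']['n_valid']}.",
            "",
            "### Training set",
            _HEADER,
        ]
        for outcome, entry in report["ssv"].items():
            lines.append(_metric_row(outcome, entry["training"]))
        lines += ["", "### Validation set", _HEADER]
        for outcome, entry in report["ssv"].items():
            lines.append(_metric_row(outcome, entry["validation"]))
        imbalanced = [
            row["variable"]
            for row in any_entry.get("balance_tests", [])
            if row["significant"]
        ]
        lines += [
            "",
            "Balance tests: "
            + (
                "no significant train/validation imbalance."
                if not imbalanced
                else f"imbalance flagged for {', '.join(imbalanced)}."
            ),
            "",
        ]

    if "loocv" in report:
        lines += ["## Leave-one-out cross-validation", "", _HEADER]
        for outcome, entry in report["loocv"].items():
            lines.append(_metric_row(outcome, entry["loocv"]))
        lines += [
            "",
            "### Final models vs published coefficients",
            "",
            "| Outcome | Intercept (fitted / published) | MPE_C slope (fitted / published) |",
            "|---|---|---|",
        ]
        for outcome, entry in report["loocv"].items():
            cmp = entry["published_comparison"]
            lines.append(
                f"| {outcome} | {_fmt(cmp['fitted_intercept'], 2)} / "
                f"{cmp['published_intercept']:.2f} | "
                f"{_fmt(cmp['fitted_mpe_c_slope'], 2)} / "
                f"{cmp['published_mpe_c_slope']:.2f} |"
            )
        lines.append("")
    return "\n".join(lines)
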