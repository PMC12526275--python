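"""End-to-end analysis: configuration, report generation, provenance.

A run is described by a JSON configuration listing input files and
their kinds.  The pipeline fits every single-drug table (Hill and
median-effect), every gating curve, and every combination (per-level CI
plus CI at effect levels), classifies interactions, and writes a
machine-readable JSON report plus a 6-significant-digit CSV summary.
Failures are recorded per input and do not stop the remaining inputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .combination import (
    SYNERGY_THRESHOLDS,
    ci_at_effect_levels,
    ci_table,
    fit_combo_as_single,
)
from .dose_response import fit_hill
from .gating import fit_boltzmann, fit_single_exponential
from .io import read_combination_csv, read_dose_response_csv, read_gating_csv
from .median_effect import fit_median_effect

__all__ = ["AnalysisConfig", "ReportBundle", "run_pipeline", "REPORT_SCHEMA_VERSION"]

logger = logging.getLogger("hergci")

REPORT_SCHEMA_VERSION = 1

DEFAULT_FA_LEVELS = (0.50, 0.75, 0.90, 0.95)

_KINDS = ("dose_response", "combination", "gating")


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated pipeline configuration.

    ``inputs`` is a list of (path, kind) records; combination inputs
    are matched to single-drug fits by the component ids declared in
    their CSV metadata.
    """

    inputs: tuple[tuple[str, str], ...]
    ci_thresholds: tuple[float, float] = SYNERGY_THRESHOLDS
    fa_levels: tuple[float, ...] = DEFAULT_FA_LEVELS
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        lower, upper = self.ci_thresholds
        if not 0 < lower <= upper:
            raise ValueError(f"ci_thresholds must satisfy 0 < lower <= upper, got {self.ci_thresholds}")
        for _, kind in self.inputs:
            if kind not in _KINDS:
                raise ValueError(f"unknown input kind {kind!r}; expected one of {_KINDS}")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        inputs = tuple((item["path"], item["kind"]) for item in raw.get("inputs", []))
        base = Path(path).parent
        inputs = tuple(
            (str(p) if Path(p).is_absolute() else str(base / p), k) for p, k in inputs
        )
        return cls(
            inputs=inputs,
            ci_thresholds=tuple(raw.get("ci_thresholds", SYNERGY_THRESHOLDS)),
            fa_levels=tuple(raw.get("fa_levels", DEFAULT_FA_LEVELS)),
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", ".")),
        )


@dataclass
class ReportBundle:
    """All fits and CI results of one pipeline run, with provenance."""

    singles: dict[str, dict[str, Any]] = field(default_factory=dict)
    gating: dict[str, dict[str, Any]] = field(default_factory=dict)
    combinations: list[dict[str, Any]] = field(default_factory=list)
    errors: list[dict[str, str]] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "singles": self.singles,
            "gating": self.gating,
            "combinations": self.combinations,
            "errors": self.errors,
            "provenance": self.provenance,
        }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _sig6(x: float) -> str:
    return f"{x:.6g}"


def _median_effect_record(fit) -> dict[str, Any]:
    return {
        "m": fit.m,
        "dm": fit.dm,
        "r": fit.r,
        "intercept": fit.intercept,
        "points_used": fit.points_used,
        "excluded_points": [
            {"dose": p.dose, "fa": p.fa, "reason": p.reason} for p in fit.excluded_points
        ],
        "flags": list(fit.flags),
    }


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Fit all inputs, compute combination indices, write report files.

    Deterministic given the configuration.  Returns the bundle; the
    JSON report and CSV summary are written to ``config.output_dir``.
    """
    bundle = ReportBundle()
    bundle.provenance = {
        "package_version": __version__,
        "config": {
            "inputs": [list(i) for i in config.inputs],
            "ci_thresholds": list(config.ci_thresholds),
            "fa_levels": list(config.fa_levels),
            "seed": config.seed,
        },
        "input_hashes": {},
    }

    single_fits = {}
    combos = []
    for path, kind in config.inputs:
        try:
            bundle.provenance["input_hashes"][path] = _sha256(path)
            if kind == "dose_response":
                table = read_dose_response_csv(path)
                me = fit_median_effect(table)
                record = {"input": path, "median_effect": _median_effect_record(me)}
                try:
                    hf = fit_hill(table)
                    record["hill"] = {
                        "ic50": hf.ic50,
                        "n_hill": hf.n_hill,
                        "residual_sum_squares": hf.residual_sum_squares,
                        "converged": hf.converged,
                        "extrapolated": hf.extrapolated,
                    }
                    logger.info(
                        "%s: IC50=%s μM n=%s%s", table.drug_id, _sig6(hf.ic50),
                        _sig6(hf.n_hill), " [extrapolated]" if hf.extrapolated else "",
                    )
                except ValueError as exc:
                    record["hill"] = {"error": str(exc)}
                single_fits[table.drug_id] = me
                bundle.singles[table.drug_id] = record
                logger.info(
                    "%s: m=%s Dm=%s μM r=%s", table.drug_id, _sig6(me.m),
                    _sig6(me.dm), _sig6(me.r),
                )
            elif kind == "gating":
                data = read_gating_csv(path)
                if data.kind.startswith("boltzmann"):
                    bf = fit_boltzmann(data)
                    rec = {
                        "input": path,
                        "kind": data.kind,
                        "v_half": bf.v_half,
                        "k_slope": bf.k_slope,
                        "orientation": bf.orientation,
                        "residual_sum_squares": bf.residual_sum_squares,
                    }
                else:
                    shape = "rise" if data.kind == "exponential_rise" else "decay"
                    ef = fit_single_exponential(data, shape)
                    rec = {
                        "input": path,
                        "kind": data.kind,
                        "tau": ef.tau,
                        "amplitude": ef.amplitude,
                        "offset": ef.offset,
                        "residual_sum_squares": ef.residual_sum_squares,
                        "converged": ef.converged,
                    }
                bundle.gating[path] = rec
            else:
                combos.append((path, read_combination_csv(path)))
        except Exception as exc:
            logger.error("%s (%s): %s", path, kind, exc)
            bundle.errors.append({"input": path, "kind": kind, "error": str(exc)})

    # combinations second: they need the single-drug fits
    for path, combo in combos:
        try:
            missing = [c for c in combo.component_ids if c not in single_fits]
            if missing:
                raise ValueError(
                    f"no single-drug dose-response input for component(s) {missing}"
                )
            singles = [single_fits[c] for c in combo.component_ids]
            result = ci_table(combo, singles, config.ci_thresholds)
            combo_fit = fit_combo_as_single(combo)
            ed = ci_at_effect_levels(combo_fit, singles, combo.weights, config.fa_levels)
            bundle.combinations.append(
                {
                    "input": path,
                    "component_ids": list(combo.component_ids),
                    "design": combo.design_label,
                    "mixture_fit": _median_effect_record(combo_fit),
                    "levels": [
                        {
                            "total_dose": lv.total_dose,
                            "fa": lv.fa,
                            "ci": lv.ci,
                            "terms": list(lv.terms),
                            "interaction": lv.interaction,
                        }
                        for lv in result.per_level
                    ],
                    "ed_levels": {
                        "fa_levels": list(ed.fa_levels),
                        "ci_values": list(ed.ci_values),
                        "total_doses": list(ed.total_doses),
                    },
                }
            )
        except Exception as exc:
            logger.error("%s (combination): %s", path, exc)
            bundle.errors.append({"input": path, "kind": "combination", "error": str(exc)})

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_summary_csv(bundle, outdir / "summary.csv")
    return bundle


def _write_summary_csv(bundle: ReportBundle, path: Path) -> None:
    """One row per fitted entity, 6 significant digits."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["entity", "quantity", "value"])
        for drug, rec in sorted(bundle.singles.items()):
            me = rec["median_effect"]
            for q in ("m", "dm", "r"):
                writer.writerow([drug, q, _sig6(me[q])])
            if "ic50" in rec.get("hill", {}):
                writer.writerow([drug, "ic50", _sig6(rec["hill"]["ic50"])])
                writer.writerow([drug, "n_hill", _sig6(rec["hill"]["n_hill"])])
        for rec in bundle.combinations:
            name = "+".join(rec["component_ids"])
            me = rec["mixture_fit"]
            for q in ("m", "dm", "r"):
                writer.writerow([name, q, _sig6(me[q])])
            for lv in rec["levels"]:
                if lv["ci"] is not None:
                    writer.writerow(
                        [name, f"ci@total={_sig6(lv['total_dose'])}", _sig6(lv["ci"])]
                    )
            for fa, ci in zip(rec["ed_levels"]["fa_levels"], rec["ed_levels"]["ci_values"]):
                writer.writerow([name, f"ci@ed{round(100 * fa)}", _sig6(ci)])
        for p, rec in sorted(bundle.gating.items()):
            name = rec["kind"]
            for q in ("v_half", "k_slope", "tau"):
                if q in rec:
                    writer.writerow([name, q, _sig6(rec[q])])
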