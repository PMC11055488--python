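"""End-to-end orchestration: simulate -> preprocess -> GLMM -> individual analysis.

A run simulates a cohort and its full test-retest design, measures each
virtual listener's SRT50 with the adaptive procedure, conditions the data
(validity window, RT shift, item/list outliers, learning correction), fits
the four study GLMMs (reaction time, answer, recall, repetition), derives
per-measure test-retest thresholds and detection counts, and writes every
artifact (trial CSVs, result JSONs, a manifest with the config hash) to an
output directory.  Re-running with the same configuration reproduces the
outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adaptive_srt import listener_responder, run_track
from .glmm import (ModelFit, ModelSpec, add_interactions_lrt,
                   backward_select_aic, fit_glmm, standardized_coefficients)
from .individual import (ThresholdResult, count_detections,
                         participant_condition_diffs,
                         participant_testretest_diffs, testretest_threshold)
from .preprocess import (correct_learning_effect, detect_item_outliers,
                         outlier_flags, shift_rt, validate_svt_responses)
from .simulate import CohortConfig, make_cohort, simulate_experiment

log = logging.getLogger("effortbench")

__all__ = ["RunConfig", "run_experiment", "report", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_svt_items: int = 30          # per SNR condition, half true / half false
    n_swirt_lists: int = 5         # per SNR condition
    condition_offsets_db: tuple[float, float] = (4.0, 8.0)
    measure_srt: bool = True
    learning_correction: bool = True
    outlier_removal: bool = True
    model_selection: bool = True
    test_interactions: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.condition_offsets_db
        if not lo < hi:
            raise ValueError(
                f"condition offsets must be strictly ordered, got {lo}, {hi}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["condition_offsets_db"] = list(self.condition_offsets_db)
        d["cohort"]["recall_word_type_effects"] = list(
            self.cohort.recall_word_type_effects)
        return d

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML (missing keys keep their defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = CohortConfig(**{
        **raw.get("cohort", {}),
        **({"recall_word_type_effects":
            tuple(raw["cohort"]["recall_word_type_effects"])}
           if "recall_word_type_effects" in raw.get("cohort", {}) else {}),
    })
    top = {k: v for k, v in raw.items() if k != "cohort"}
    if "condition_offsets_db" in top:
        top["condition_offsets_db"] = tuple(top["condition_offsets_db"])
    return RunConfig(cohort=cohort, **top)


# model formulas for the four study variables
_SPECS = {
    "svt_rt": ("rt_shifted_s ~ snr_condition + session + order + "
               "answer_correct + item_truth + word_score_quiet + "
               "(1 + snr_condition | participant_id) + (1 | item_id)",
               "gamma"),
    "svt_answer": ("answer_num ~ snr_condition + session + order + "
                   "item_truth + word_score_quiet + "
                   "(1 + snr_condition | participant_id) + (1 | item_id)",
                   "binomial"),
    "swirt_recall": ("recalled_num ~ snr_condition + session + order + "
                     "position_category + word_type + word_score_quiet + "
                     "(1 + snr_condition | participant_id) + (1 | list_id)",
                     "binomial"),
    "swirt_repeat": ("repeated_num ~ snr_condition + session + order + "
                     "position_category + word_type + word_score_quiet + "
                     "(1 + snr_condition | participant_id) + (1 | list_id)",
                     "binomial"),
}

_INTERACTIONS = {
    "svt_rt": ["snr_condition:session", "snr_condition:order",
               "session:order", "snr_condition:session:order"],
    "swirt_repeat": ["snr_condition:word_score_quiet"],
}


def run_experiment(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write all artifacts to ``outdir``.

    Returns the results bundle (also serialized to JSON files).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable") from exc

    t0 = time.perf_counter()
    bundle: dict = {"config": config.to_dict(),
                    "manifest": {"config_hash": config.config_hash(),
                                 "seed": config.cohort.seed,
                                 "package_version": __version__}}

    # --- simulation -------------------------------------------------------
    svt, swirt, cohort = simulate_experiment(
        config.cohort, n_svt_items=config.n_svt_items,
        n_swirt_lists=config.n_swirt_lists)
    quiet = {l.participant_id: l.word_score_quiet for l in cohort}
    svt["word_score_quiet"] = svt["participant_id"].map(quiet)
    swirt["word_score_quiet"] = swirt["participant_id"].map(quiet)
    log.info("simulated %d SVT and %d SWIRT trials for %d participants "
             "(%.1fs)", len(svt), len(swirt), len(cohort),
             time.perf_counter() - t0)

    if config.measure_srt:
        rows = []
        for listener in cohort:
            rng = np.random.default_rng(np.random.SeedSequence(
                [config.cohort.seed, listener.participant_id, 7]))
            track = run_track(listener_responder(listener, rng=rng))
            rows.append({"participant_id": listener.participant_id,
                         "srt50_true_db": listener.srt50_db,
                         "srt50_est_db": track.srt50_db,
                         **{f"snr_{i + 1}": s
                            for i, s in enumerate(track.snr_sequence_db)}})
        srt = pd.DataFrame(rows)
        _write_csv(srt, outdir / "srt_tracks.csv")
        bundle["srt50"] = {
            "mean_est_db": float(srt.srt50_est_db.mean()),
            "sd_est_db": float(srt.srt50_est_db.std(ddof=1)),
            "mean_abs_error_db": float(
                (srt.srt50_est_db - srt.srt50_true_db).abs().mean()),
        }

    # --- preprocessing ----------------------------------------------------
    svt = validate_svt_responses(svt)
    svt = shift_rt(svt)

    outlier_sets: dict[str, list] = {}
    reports_json = {}
    if config.outlier_removal:
        checks = [
            ("svt_answer", svt[svt.valid], "binary", "answer_correct", "item_id"),
            ("svt_rt", svt[svt.valid], "rt", "rt_shifted_s", "item_id"),
            ("swirt_repeat", swirt, "binary", "repeated_correct", "list_id"),
            ("swirt_recall", swirt, "binary", "recalled_correct", "list_id"),
        ]
        for name, frame, kind, col, unit in checks:
            reps = detect_item_outliers(frame, kind, col, unit)
            outlier_sets[name] = sorted(int(u) for u in outlier_flags(reps))
            reports_json[name] = [dataclasses.asdict(r) for r in reps]
        _write_json(reports_json, outdir / "outliers.json")
    bundle["outliers"] = {k: v for k, v in outlier_sets.items()}

    drop_items = set(outlier_sets.get("svt_answer", [])) \
        | set(outlier_sets.get("svt_rt", []))
    svt["item_outlier"] = svt["item_id"].isin(drop_items)
    drop_lists = set(outlier_sets.get("swirt_repeat", [])) \
        | set(outlier_sets.get("swirt_recall", []))
    swirt["list_outlier"] = swirt["list_id"].isin(drop_lists)

    learning = None
    if config.learning_correction:
        svt, learning = correct_learning_effect(svt)
        bundle["learning"] = {
            "intercept_s": learning.intercept_s, "slope": learning.slope,
            "r_squared": learning.r_squared,
            "correction_per_participant": learning.correction_per_participant,
        }
        _write_json(bundle["learning"], outdir / "learning.json")

    _write_csv(svt, outdir / "svt_trials.csv")
    _write_csv(swirt, outdir / "swirt_trials.csv")

    # --- GLMMs ------------------------------------------------------------
    svt_model = svt[~svt.item_outlier] if config.outlier_removal else svt
    swirt_model = swirt[~swirt.list_outlier] if config.outlier_removal else swirt
    session_cat = pd.CategoricalDtype(["test", "retest"])  # test = reference
    svt_model = svt_model.assign(
        answer_num=svt_model.answer_correct.astype("boolean").astype("Float64"),
        session=svt_model.session.astype(session_cat))
    swirt_model = swirt_model.assign(
        recalled_num=swirt_model.recalled_correct.astype(float),
        repeated_num=swirt_model.repeated_correct.astype(float),
        session=swirt_model.session.astype(session_cat))
    # learning-corrected retest RTs can rarely become nonpositive; the Gamma
    # family requires strictly positive responses, so those rows are dropped
    svt_rt_data = svt_model[svt_model.valid & (svt_model.rt_shifted_s > 0)]
    model_data = {"svt_rt": svt_rt_data, "svt_answer": svt_model,
                  "swirt_recall": swirt_model, "swirt_repeat": swirt_model}

    bundle["glmm"] = {}
    for name, (formula, family) in _SPECS.items():
        t1 = time.perf_counter()
        spec = ModelSpec.from_formula(formula, family)
        data = model_data[name]
        if config.model_selection:
            fit, trace = backward_select_aic(spec, data)
        else:
            fit, trace = fit_glmm(spec, data), []
        lrt = None
        if config.test_interactions and name in _INTERACTIONS and fit.converged:
            aug, lrt = add_interactions_lrt(fit, _INTERACTIONS[name], data)
            if lrt["kept"]:
                fit = aug
        std_fit = standardized_coefficients(fit, data)
        bundle["glmm"][name] = _fit_to_dict(fit, std_fit, trace, lrt)
        log.info("fitted %s (%.1fs, AIC %.1f)", name,
                 time.perf_counter() - t1, fit.aic)
    _write_json(bundle["glmm"], outdir / "glmm.json")

    # --- intra-individual detection --------------------------------------
    measures = [
        ("svt_rt", svt[svt.valid], "rt_shifted_s", "lower_better"),
        ("svt_answer", svt.assign(
            v=svt.answer_correct.astype("boolean").astype("Float64")),
         "v", "higher_better"),
        ("swirt_recall", swirt.assign(v=swirt.recalled_correct.astype(float)),
         "v", "higher_better"),
        ("swirt_repeat", swirt.assign(v=swirt.repeated_correct.astype(float)),
         "v", "higher_better"),
    ]
    bundle["individual"] = {}
    for name, frame, col, direction in measures:
        tr = participant_testretest_diffs(frame, col)
        result = testretest_threshold(tr)
        diffs = participant_condition_diffs(frame, col, direction)
        result = count_detections(diffs, result)
        bundle["individual"][name] = _threshold_to_dict(result)
    _write_json(bundle["individual"], outdir / "thresholds.json")

    _write_json(bundle["manifest"], outdir / "manifest.json")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    _write_json({k: v for k, v in bundle.items() if k != "config"},
                outdir / "results.json")
    log.info("run complete in %.1fs", time.perf_counter() - t0)
    return bundle


def _fit_to_dict(fit: ModelFit, std_fit: ModelFit, trace: list,
                 lrt: dict | None) -> dict:
    return {
        "formula": fit.spec.formula,
        "family": fit.spec.family,
        "converged": fit.converged,
        "singular": fit.singular,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "n_obs": fit.n_obs,
        "variance_components": fit.variance_components,
        "shape": fit.shape,
        "marginal_r2": fit.marginal_r2,
        "conditional_r2": fit.conditional_r2,
        "dispersion_ratio": fit.dispersion_ratio,
        "coefficients": fit.coefficients.to_dict(orient="records"),
        "std_coefficients": std_fit.coefficients.to_dict(orient="records"),
        "interaction_lrt": lrt,
        "selection_trace": trace,
    }


def _threshold_to_dict(r: ThresholdResult) -> dict:
    return {"mu": r.mu, "sigma": r.sigma, "threshold": r.threshold,
            "n_participants": r.n_participants,
            "n_significant": r.n_significant,
            "n_correct_direction": r.n_correct_direction,
            "max_detection_rate": r.max_detection_rate,
            "testretest_diffs": r.testretest_diffs,
            "condition_diffs": r.condition_diffs}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# reporting

_STAR_LEGEND = "*<0.05; **<0.01; ***<0.001"


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def report(bundle: dict) -> str:
    """Render a results bundle as a human-readable markdown summary."""
    lines = ["# Listening-effort feasibility analysis", ""]
    manifest = bundle.get("manifest", {})
    if manifest:
        lines += [f"Config hash `{manifest.get('config_hash')}`, seed "
                  f"{manifest.get('seed')}, effortbench "
                  f"{manifest.get('package_version')}.", ""]
    if "srt50" in bundle:
        s = bundle["srt50"]
        lines += [f"Adaptive SRT50: mean {s['mean_est_db']:.1f} dB "
                  f"(SD {s['sd_est_db']:.1f} dB), mean absolute estimation "
                  f"error {s['mean_abs_error_db']:.2f} dB.", ""]
    if "outliers" in bundle:
        flagged = {k: v for k, v in bundle["outliers"].items() if v}
        lines += ["## Outlying items/lists", ""]
        lines += ([f"- {k}: {v}" for k, v in flagged.items()]
                  if flagged else ["- none flagged"])
        lines += [""]
    if "learning" in bundle:
        lm = bundle["learning"]
        lines += ["## Learning-effect correction (SVT reaction time)", "",
                  f"retest_mean = {lm['intercept_s']:.3f} + "
                  f"{lm['slope']:.3f} * test_mean  (R^2 = "
                  f"{lm['r_squared']:.2f})", ""]
    glmm = bundle.get("glmm")
    if glmm is None:
        lines += ["## Models", "", "*missing from bundle*", ""]
    else:
        for name, fitd in glmm.items():
            lines += [f"## GLMM: {name}", "", f"`{fitd['formula']}`", ""]
            if not fitd["converged"]:
                lines += ["> **WARNING: model did not converge; estimates "
                          "are unreliable.**", ""]
            lines += [f"Family {fitd['family']}; AIC {fitd['aic']:.1f}; "
                      f"marginal R^2 {fitd['marginal_r2']:.2f}, conditional "
                      f"R^2 {fitd['conditional_r2']:.2f}; dispersion ratio "
                      f"{fitd['dispersion_ratio']:.2f}.", ""]
            lines += ["| Parameter | Std. coefficient | 95% C.I. | p value |",
                      "|---|---|---|---|"]
            for row in fitd["std_coefficients"]:
                p = row["p_value"]
                lines.append(
                    f"| {row['term']} | {row['estimate']:.2f} | "
                    f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}] | "
                    f"{_fmt_p(p)}{_stars(p)} |")
            lines += ["", _STAR_LEGEND, ""]
            if fitd.get("interaction_lrt"):
                l = fitd["interaction_lrt"]
                lines += [f"Interaction LRT: chi^2 = {l['chi2']:.2f}, df = "
                          f"{l['df']}, p = {_fmt_p(l['p_value'])}"
                          f" ({'kept' if l['kept'] else 'not kept'}).", ""]
    ind = bundle.get("individual")
    if ind is None:
        lines += ["## Intra-individual detection", "", "*missing from bundle*", ""]
    else:
        lines += ["## Intra-individual detection", "",
                  "| Measure | Threshold | Significant | Correct direction | "
                  "Max detection rate |", "|---|---|---|---|---|"]
        for name, r in ind.items():
            lines.append(
                f"| {name} | {r['threshold']:.3f} | {r['n_significant']}/"
                f"{r['n_participants']} | {r['n_correct_direction']}/"
                f"{r['n_participants']} | {r['max_detection_rate']:.0%} |")
        lines += [""]
    return "\n".join(lines)


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.3f}"
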