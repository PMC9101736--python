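"""Model/results objects tying the pipeline together.

:class:`LEAMQValidation` is built from a questionnaire-response table and
a clinical-panel table (plus optional test-retest data) and its
:meth:`~LEAMQValidation.fit` runs the whole validation procedure in
order: item reliability and removal, key-driven scoring, derivation of
clinical quantities, indicator thresholding and LEA case/control/
excluded classification, the covariate-adjusted association screen over
all screening-variable x clinical-outcome combinations, ROC/Youden
threshold selection for the significantly associated variables, the
minimum-sensitivity retention rule, and the final case-control
comparisons.  The returned :class:`LEAMQValidationResults` carries every
intermediate table, the decision logs, and a ``summary()``.

The screen's "low"/"high" clinical flags are the per-centre lowest/
highest quartile of the *observed* results, whereas the LEA indicators
use the fixed cutoffs or reference-range quartiles of the case
definition; the two deliberately differ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as io_mod
from .clinical import ReferenceConfig, classify_table, derive_panel
from .keys import ScoringKey, default_key
from .questionnaire import score_table
from .validation import (
    ROCResult,
    compare_groups,
    fit_association,
    icc_per_item,
    icc_test_retest,
    drop_unreliable_items,
    retain_variables,
    roc_youden,
)

#: continuous clinical outcome -> (screen flag column, tail)
OUTCOME_FLAGS = {
    "insulin": ("low_insulin_flag", "low"),
    "t3": ("low_t3_flag", "low"),
    "total_testosterone": ("low_total_testosterone_flag", "low"),
    "free_testosterone": ("low_free_testosterone_flag", "low"),
    "igf1": ("low_igf1_flag", "low"),
    "glucose": ("low_glucose_flag", "low"),
    "free_t_cortisol_ratio": ("low_free_t_cortisol_ratio_flag", "low"),
    "cortisol": ("high_cortisol_flag", "high"),
    "cortisol_insulin_ratio": ("high_cortisol_insulin_ratio_flag", "high"),
    "total_chol": ("high_total_chol_flag", "high"),
    "ldl": ("high_ldl_flag", "high"),
}

DEFAULT_PREDICTORS = (
    "dizziness_score",
    "gastrointestinal_score",
    "thermoregulation_score",
    "injury_illness_score",
    "wellbeing_score",
    "fatigue_subscore",
    "low_sex_drive_score",
    "ehmc_score",
    "weight_flux_kg",
)

DEFAULT_CONTINUOUS_OUTCOMES = (
    "glucose",
    "insulin",
    "cortisol",
    "total_testosterone",
    "free_testosterone",
    "t3",
    "igf1",
    "total_chol",
    "ldl",
    "spine_bmd_z",
    "femur_bmd_z",
    "rmr_ratio",
    "cortisol_insulin_ratio",
    "free_t_cortisol_ratio",
)

DEFAULT_BINARY_OUTCOMES = (
    "low_insulin_flag",
    "low_t3_flag",
    "low_total_testosterone_flag",
    "low_free_t_cortisol_ratio_flag",
    "high_cortisol_flag",
    "high_cortisol_insulin_ratio_flag",
    "low_rmr_flag",
    "low_bmd_flag",
)

SCORE_COMPARISON_VARIABLES = (
    "dizziness_score",
    "gastrointestinal_score",
    "thermoregulation_score",
    "injury_illness_score",
    "wellbeing_score",
    "fatigue_subscore",
    "low_sex_drive_score",
    "total_score",
    "ehmc_score",
    "weight_flux_kg",
)

CLINICAL_COMPARISON_VARIABLES = (
    "age", "height", "body_mass", "bmi", "body_fat_pct", "ffm",
    "spine_bmd_z", "femur_bmd_z", "systolic_bp", "diastolic_bp",
    "rmr_kj_kg_ffm", "rmr_ratio", "total_testosterone", "free_testosterone",
    "free_t_cortisol_ratio", "total_t_cortisol_ratio", "igf1", "t3",
    "cortisol", "insulin", "cortisol_insulin_ratio", "glucose",
    "total_chol", "ldl", "hdl", "triglycerides",
)


@dataclass
class PipelineConfig:
    """Tunable analysis constants.

    ``alpha`` is the unadjusted per-test screening threshold;
    ``min_sensitivity`` the retention bound at the Youden-optimal
    operating point (boundary inclusive); ``icc_cutoff`` the per-item
    test-retest reliability below which an item is removed from scoring.
    """

    alpha: float = 0.05
    min_sensitivity: float = 0.60
    icc_cutoff: float = 0.50
    covariates: tuple = ("age", "bmi", "elite")
    predictors: tuple = DEFAULT_PREDICTORS
    continuous_outcomes: tuple = DEFAULT_CONTINUOUS_OUTCOMES
    binary_outcomes: tuple = DEFAULT_BINARY_OUTCOMES
    quartile_by: str = "centre"


def derive_screen_flags(panel: pd.DataFrame, by: str = "centre",
                        ref: Optional[ReferenceConfig] = None) -> pd.DataFrame:
    """Add the empirical quartile "low"/"high" flags used by the screen.

    For each mapped analyte the flag marks the lowest (or highest) 25% of
    the *observed* values within each testing site.  The low-RMR flag
    uses the fixed per-method ratio cutoffs; the low-BMD flag marks a
    Z-score below -1 at either site.
    """
    ref = ref or ReferenceConfig()
    df = panel.copy()
    groups = df[by] if by in df.columns else pd.Series("all", index=df.index)
    for col, (flag, tail) in OUTCOME_FLAGS.items():
        if col not in df.columns:
            df[flag] = np.nan
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        q = vals.groupby(groups).transform(lambda s: s.quantile(0.25 if tail == "low" else 0.75))
        flagged = (vals < q) if tail == "low" else (vals > q)
        df[flag] = flagged.astype(float).where(vals.notna(), np.nan)

    if "rmr_ratio" in df.columns and "rmr_method" in df.columns:
        cutoff = df["rmr_method"].map(ref.rmr_ratio_low)
        ratio = pd.to_numeric(df["rmr_ratio"], errors="coerce")
        df["low_rmr_flag"] = (ratio < cutoff).astype(float).where(ratio.notna() & cutoff.notna(), np.nan)
    else:
        df["low_rmr_flag"] = np.nan

    spine = pd.to_numeric(df.get("spine_bmd_z"), errors="coerce") if "spine_bmd_z" in df else None
    femur = pd.to_numeric(df.get("femur_bmd_z"), errors="coerce") if "femur_bmd_z" in df else None
    if spine is not None or femur is not None:
        spine = spine if spine is not None else pd.Series(np.nan, index=df.index)
        femur = femur if femur is not None else pd.Series(np.nan, index=df.index)
        low = (spine < ref.bmd_z_low) | (femur < ref.bmd_z_low)
        df["low_bmd_flag"] = low.astype(float).where(spine.notna() | femur.notna(), np.nan)
    else:
        df["low_bmd_flag"] = np.nan
    return df


class LEAMQValidation:
    """The validation analysis as a fittable model object.

    Parameters
    ----------
    responses, clinical : DataFrame
        One row per athlete; joined on ``athlete_id``.
    retest : DataFrame, optional
        Columns ``test``/``retest`` of total scores for the reliability
        sub-study.
    item_retest : (DataFrame, DataFrame), optional
        Two administrations with one column per item; items with ICC
        below the configured cutoff are removed before scoring.
    """

    def __init__(
        self,
        responses: pd.DataFrame,
        clinical: pd.DataFrame,
        key: Optional[ScoringKey] = None,
        ref: Optional[ReferenceConfig] = None,
        config: Optional[PipelineConfig] = None,
        retest: Optional[pd.DataFrame] = None,
        item_retest: Optional[tuple] = None,
    ):
        self.responses = responses
        self.clinical = clinical
        self.key = key or default_key()
        self.ref = ref or ReferenceConfig()
        self.config = config or PipelineConfig()
        self.retest = retest
        self.item_retest = item_retest

    @classmethod
    def from_csv(cls, responses_path, clinical_path, **kwargs) -> "LEAMQValidation":
        responses = io_mod.load_table(responses_path, io_mod.RESPONSE_SCHEMA)
        clinical = io_mod.load_table(clinical_path, io_mod.CLINICAL_SCHEMA)
        return cls(responses, clinical, **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> "LEAMQValidationResults":
        cfg = self.config
        logs: dict = {"exclusions": [], "items_removed": []}

        # 1. item reliability and removal
        icc_result = None
        item_iccs = None
        drop_items: tuple = ()
        if self.item_retest is not None:
            item_iccs = icc_per_item(*self.item_retest)
            _, dropped = drop_unreliable_items(item_iccs, cfg.icc_cutoff)
            drop_items = tuple(i for i in dropped if i in self.key)
            logs["items_removed"] = list(drop_items)
        if self.retest is not None:
            icc_result = icc_test_retest(self.retest["test"], self.retest["retest"])

        # 2. scoring
        scores = score_table(self.responses, self.key, drop_items)

        # 3. clinical derivation, screen flags, classification
        panel = derive_panel(self.clinical, self.ref)
        panel = derive_screen_flags(panel, cfg.quartile_by, self.ref)
        classification = classify_table(panel, self.ref)
        for rec in classification[classification["verdict"] == "excluded"].itertuples():
            logs["exclusions"].append(
                {"athlete_id": rec.athlete_id, "stage": "classification", "reason": rec.reason}
            )

        data = scores.merge(panel, on="athlete_id", how="inner", suffixes=("", "_clin"))
        data = data.merge(
            classification[["athlete_id", "verdict"]], on="athlete_id", how="left"
        )
        unmatched = set(scores["athlete_id"]) ^ set(panel["athlete_id"])
        for aid in sorted(unmatched):
            logs["exclusions"].append(
                {"athlete_id": aid, "stage": "join", "reason": "missing key data"}
            )

        # 4. association screen (complete-case per pair, unadjusted alpha)
        assoc_rows = []
        outcomes = [o for o in (*cfg.continuous_outcomes, *cfg.binary_outcomes)
                    if o in data.columns]
        predictors = [p for p in cfg.predictors if p in data.columns]
        for pred in predictors:
            for out in outcomes:
                res = fit_association(data, out, pred, cfg.covariates, cfg.quartile_by)
                assoc_rows.append(res.__dict__ | {"significant": res.p_value < cfg.alpha
                                                  if not math.isnan(res.p_value) else False})
        associations = pd.DataFrame(assoc_rows)
        n_tests = int(associations["p_value"].notna().sum()) if len(associations) else 0

        # 5. ROC / Youden for significant pairs, then retention
        roc_rows = []
        roc_map: list[tuple[str, ROCResult]] = []
        if len(associations):
            sig = associations[associations["significant"]]
            for rec in sig.itertuples():
                out = rec.outcome_id
                flag = out if out in cfg.binary_outcomes else OUTCOME_FLAGS.get(out, (None,))[0]
                if flag is None or flag not in data.columns:
                    continue
                sub = data[[rec.predictor_id, flag]].dropna()
                labels = sub[flag]
                if labels.nunique() < 2 or len(sub) < 4:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    roc = roc_youden(sub[rec.predictor_id], labels)
                roc.retained = roc.sensitivity >= cfg.min_sensitivity
                roc_map.append((rec.predictor_id, roc))
                roc_rows.append(
                    {"predictor_id": rec.predictor_id, "outcome_id": out,
                     "flag": flag, "threshold": roc.threshold,
                     "sensitivity": roc.sensitivity, "specificity": roc.specificity,
                     "youden_j": roc.youden_j, "retained": roc.retained,
                     "n_pos": roc.n_pos, "n_neg": roc.n_neg}
                )
        roc_table = pd.DataFrame(roc_rows)
        retained = retain_variables(roc_map, cfg.min_sensitivity)

        # 6. case-control comparisons
        cc = data[data["verdict"].isin(["case", "control"])]
        score_comparison = compare_groups(
            cc, "verdict", [v for v in SCORE_COMPARISON_VARIABLES if v in cc.columns]
        )
        clinical_comparison = compare_groups(
            cc, "verdict", [v for v in CLINICAL_COMPARISON_VARIABLES if v in cc.columns]
        )

        manifest = {
            "n_input": int(len(self.responses)),
            "n_scored": int(len(scores)),
            "n_classifiable": int((classification["verdict"] != "excluded").sum()) if len(classification) else 0,
            "n_cases": int((classification["verdict"] == "case").sum()) if len(classification) else 0,
            "n_controls": int((classification["verdict"] == "control").sum()) if len(classification) else 0,
            "n_excluded": int((classification["verdict"] == "excluded").sum()) if len(classification) else 0,
            "n_association_tests": n_tests,
            "alpha": cfg.alpha,
            "min_sensitivity": cfg.min_sensitivity,
            "items_removed": logs["items_removed"],
            "exclusion_log": logs["exclusions"],
            "retained_variables": retained,
            "config_digest": io_mod.digest(
                {"alpha": cfg.alpha, "min_sensitivity": cfg.min_sensitivity,
                 "icc_cutoff": cfg.icc_cutoff, "predictors": list(cfg.predictors),
                 "outcomes": list(outcomes), "covariates": list(cfg.covariates)}
            ),
        }
        if icc_result is not None:
            manifest["test_retest_icc"] = icc_result.icc

        return LEAMQValidationResults(
            model=self,
            scores=scores,
            panel=panel,
            classification=classification,
            data=data,
            associations=associations,
            roc=roc_table,
            retained=retained,
            score_comparison=score_comparison,
            clinical_comparison=clinical_comparison,
            icc=icc_result,
            item_iccs=item_iccs,
            n_tests=n_tests,
            manifest=manifest,
        )


@dataclass
class LEAMQValidationResults:
    """Everything the fitted validation produced."""

    model: LEAMQValidation
    scores: pd.DataFrame
    panel: pd.DataFrame
    classification: pd.DataFrame
    data: pd.DataFrame
    associations: pd.DataFrame
    roc: pd.DataFrame
    retained: list
    score_comparison: pd.DataFrame
    clinical_comparison: pd.DataFrame
    icc: object
    item_iccs: Optional[pd.Series]
    n_tests: int
    manifest: dict

    def significant_sections(self, alpha: float = 0.05) -> list[str]:
        """Section-level score variables whose case-control comparison is
        significant at ``alpha``."""
        sc = self.score_comparison
        if not len(sc):
            return []
        section_vars = [v for v in sc["variable"]
                        if v.endswith("_score") and v != "total_score"]
        hit = sc[(sc["variable"].isin(section_vars)) & (sc["p_value"] < alpha)]
        return list(hit["variable"])

    def save(self, out_dir, timestamp: Optional[str] = None):
        return io_mod.write_report(self, out_dir, timestamp)

    def summary(self) -> str:
        m = self.manifest
        lines = [
            "LEAM-Q screening validation",
            "=" * 64,
            f"athletes scored            {m['n_scored']:>6}",
            f"classifiable               {m['n_classifiable']:>6}"
            f"  (cases {m['n_cases']}, controls {m['n_controls']},"
            f" excluded {m['n_excluded']})",
            f"association tests run      {m['n_association_tests']:>6}"
            f"  (unadjusted alpha = {m['alpha']}; interpret the screen"
            " with this multiplicity in mind)",
        ]
        if self.icc is not None:
            lines.append(
                f"test-retest ICC            {self.icc.icc:>6.3f}"
                f"  [{self.icc.ci_low:.3f}, {self.icc.ci_high:.3f}] ({self.icc.model})"
            )
        if m["items_removed"]:
            lines.append(f"items removed (low ICC)    {', '.join(m['items_removed'])}")
        lines.append(f"retained screening vars    {', '.join(self.retained) or '(none)'}")
        if len(self.score_comparison):
            lines.append("")
            lines.append("case-control score comparison (pooled two-sample t):")
            for rec in self.score_comparison.itertuples():
                star = " *" if rec.p_value < 0.05 else ""
                p = "<0.0001" if rec.p_value < 1e-4 else f"{rec.p_value:.4f}"
                lines.append(
                    f"  {rec.variable:<24} {rec.control_mean:6.2f} +/- {rec.control_sd:<5.2f}"
                    f" vs {rec.case_mean:6.2f} +/- {rec.case_sd:<5.2f}"
                    f"  p={p}{star}"
                )
        return "\n".join(lines)


def run_validation_pipeline(
    responses: pd.DataFrame,
    clinical: pd.DataFrame,
    key: Optional[ScoringKey] = None,
    ref: Optional[ReferenceConfig] = None,
    config: Optional[PipelineConfig] = None,
    **kwargs,
) -> LEAMQValidationResults:
    """Functional one-shot wrapper around :class:`LEAMQValidation`."""
    return LEAMQValidation(responses, clinical, key, ref, config, **kwargs).fit()
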