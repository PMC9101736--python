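"""Synthetic multi-centre cohort and test-retest generators.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised without real athlete data:

* a standard-normal latent *severity* per athlete drives correlated
  deviations in the endocrine markers, RMR ratio, BMD Z-scores and the
  sex-drive item codes; each marker's marginal mean/SD is preserved
  exactly regardless of its severity loading because the marker is
  ``mean + sd * (loading * z + sqrt(1 - loading^2) * noise)``;
* ordinal questionnaire codes are produced by thresholding a latent
  standard-normal response at the quantiles of configured marginal code
  frequencies;
* the resting-metabolic-rate ratio is a two-method mixture (25%
  first-principles, 75% metabolic cart) with method-specific means so
  that each method's lowest sample quartile sits near its fixed low-RMR
  cutoff;
* missingness is applied completely at random within blocks, with
  sex-drive and insulin/SHBG blocks structurally missing for version-1
  respondents;
* case prevalence is *not* set directly — it emerges from the indicator
  thresholds applied to the generated markers (about one third of
  classifiable athletes under the defaults).

Default marker marginals follow the published cohort summary table; the
severity loadings are package calibration choices documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .clinical import KCAL_TO_KJ
from .errors import ConfigError
from .keys import ScoringKey, default_key


@dataclass(frozen=True)
class MarkerSpec:
    mean: float
    sd: float
    loading: float = 0.0   # severity loading, in SD units (correlation with z)
    lower: Optional[float] = None  # post-hoc clip

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigError("marker SD must be > 0")
        if abs(self.loading) > 1:
            raise ConfigError("severity loading must lie in [-1, 1]")


def _default_markers() -> dict[str, MarkerSpec]:
    return {
        "age": MarkerSpec(27.9, 6.9, 0.35, lower=18.0),
        "height": MarkerSpec(181.6, 7.7, 0.0, lower=150.0),
        "bmi": MarkerSpec(22.2, 2.0, -0.15, lower=16.0),
        "ffm": MarkerSpec(64.9, 8.7, -0.10, lower=40.0),
        "body_fat_pct": MarkerSpec(11.9, 3.8, 0.0, lower=4.0),
        "spine_bmd_z": MarkerSpec(-0.01, 1.00, -0.50),
        "femur_bmd_z": MarkerSpec(0.35, 1.00, -0.50),
        "systolic_bp": MarkerSpec(118.6, 10.4, -0.30, lower=80.0),
        "diastolic_bp": MarkerSpec(67.6, 7.6, -0.25, lower=45.0),
        "total_testosterone": MarkerSpec(19.8, 5.8, -0.45, lower=2.0),
        "shbg": MarkerSpec(34.0, 10.0, 0.0, lower=8.0),
        "t3": MarkerSpec(5.3, 0.8, -0.60, lower=2.0),
        "igf1": MarkerSpec(28.7, 8.5, -0.55, lower=5.0),
        "cortisol": MarkerSpec(461.5, 127.5, 0.50, lower=100.0),
        "insulin": MarkerSpec(24.2, 10.3, -0.55, lower=3.0),
        "glucose": MarkerSpec(5.0, 0.4, -0.15, lower=3.0),
        "total_chol": MarkerSpec(4.6, 0.9, 0.25, lower=2.0),
        "ldl": MarkerSpec(2.7, 0.8, 0.25, lower=0.5),
        "hdl": MarkerSpec(1.5, 0.3, 0.10, lower=0.5),
        "triglycerides": MarkerSpec(0.9, 0.3, 0.0, lower=0.2),
    }


#: marginal probabilities of the *adjusted* codes 0..3 per item, i.e. the
#: code after reverse adjustment (higher = more adverse)
def _default_item_freqs() -> dict[str, tuple[float, ...]]:
    symptom = (0.62, 0.28, 0.08, 0.02)
    wellbeing = (0.20, 0.32, 0.28, 0.20)
    return {
        "1A": (0.68, 0.24, 0.06, 0.02), "1B": (0.68, 0.24, 0.06, 0.02),
        "2A": symptom, "2B": symptom, "2C": symptom,
        "3A": symptom, "3B": symptom,
        "4A": (0.55, 0.30, 0.10, 0.05), "4B": (0.55, 0.30, 0.10, 0.05),
        "4C": (0.70, 0.20, 0.07, 0.03), "4D": (0.60, 0.28, 0.08, 0.04),
        "4E": (0.60, 0.28, 0.08, 0.04), "4F": (0.48, 0.32, 0.14, 0.06),
        "5A1": (0.22, 0.32, 0.28, 0.18), "5A2": wellbeing, "5A3": wellbeing,
        "5B1": wellbeing, "5B2": wellbeing, "5C1": wellbeing, "5C2": wellbeing,
        "5D1": wellbeing, "5D2": wellbeing, "5D3": wellbeing,
        "5E1": wellbeing, "5E2": wellbeing,
        "6A": (0.24, 0.55, 0.16, 0.05),
        "6B": (0.83, 0.13, 0.025, 0.015),
        "6C": (0.52, 0.20, 0.16, 0.12),
        "6D": (0.83, 0.11, 0.04, 0.02),
    }


#: severity loadings of the latent item responses; only the sex-drive
#: block loads by default (the instrument's discriminating section)
def _default_item_loadings() -> dict[str, float]:
    return {"6A": 0.50, "6B": 0.35, "6C": 0.50, "6D": 0.45}


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_athletes: int = 310
    centre_weights: dict = field(
        default_factory=lambda: {"AUS": 0.40, "OSL": 0.25, "KRS": 0.20, "CPH": 0.15}
    )
    v2_fraction: float = 127.0 / 310.0
    elite_fraction: float = 0.64
    first_principles_fraction: float = 0.25
    rmr_ratio_by_method: dict = field(
        default_factory=lambda: {
            "first_principles": MarkerSpec(1.19, 0.12, -0.60, lower=0.5),
            "metabolic_cart": MarkerSpec(0.95, 0.10, -0.60, lower=0.5),
        }
    )
    markers: dict = field(default_factory=_default_markers)
    item_freqs: dict = field(default_factory=_default_item_freqs)
    item_loadings: dict = field(default_factory=_default_item_loadings)
    weight_flux: MarkerSpec = field(default_factory=lambda: MarkerSpec(8.6, 5.0, 0.48, lower=0.0))
    #: block-wise missing-completely-at-random rates; a dict value gives
    #: per-centre rates ("default" for unlisted centres), mirroring sites
    #: that did not run a given assay at all
    missing_rates: dict = field(
        default_factory=lambda: {
            "bmd": 0.15,
            "bp": {"OSL": 0.50, "default": 0.10},
            "rmr": 0.07,
            "total_testosterone": 0.15,
            "shbg": 0.20,
            "t3": {"AUS": 0.90, "default": 0.10},
            "igf1": {"CPH": 0.90, "default": 0.12},
            "cortisol": {"CPH": 0.90, "default": 0.12},
            "insulin": 0.08,
            "lipids": {"KRS": 0.60, "default": 0.10},
            "glucose": 0.15,
            "items": 0.02,
        }
    )

    def __post_init__(self):
        if self.n_athletes < 0:
            raise ConfigError("n_athletes must be >= 0")
        for p in (self.v2_fraction, self.elite_fraction, self.first_principles_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        for rate in self.missing_rates.values():
            vals = rate.values() if isinstance(rate, dict) else (rate,)
            if any(not 0.0 <= r <= 1.0 for r in vals):
                raise ConfigError("missing rates must lie in [0, 1]")
        for name, freqs in self.item_freqs.items():
            arr = np.asarray(freqs, float)
            if np.any(arr < 0) or not np.isclose(arr.sum(), 1.0):
                raise ConfigError(f"item {name}: code frequencies must be a distribution")

    def null(self) -> "CohortConfig":
        """A copy with every severity loading zeroed (null cohort: the
        questionnaire carries no signal about the clinical state)."""
        cfg = replace(
            self,
            markers={k: replace(v, loading=0.0) for k, v in self.markers.items()},
            rmr_ratio_by_method={
                k: replace(v, loading=0.0) for k, v in self.rmr_ratio_by_method.items()
            },
            item_loadings={},
            weight_flux=replace(self.weight_flux, loading=0.0),
        )
        return cfg


def _draw(rng: np.random.Generator, spec: MarkerSpec, z: np.ndarray) -> np.ndarray:
    lam = spec.loading
    eps = rng.standard_normal(z.size)
    x = spec.mean + spec.sd * (lam * z + np.sqrt(1.0 - lam * lam) * eps)
    if spec.lower is not None:
        x = np.clip(x, spec.lower, None)
    return x


def _draw_codes(
    rng: np.random.Generator, freqs, loading: float, z: np.ndarray
) -> np.ndarray:
    from scipy.stats import norm

    cuts = norm.ppf(np.cumsum(np.asarray(freqs, float))[:-1])
    u = loading * z + np.sqrt(1.0 - loading**2) * rng.standard_normal(z.size)
    return (u[:, None] > cuts[None, :]).sum(axis=1)


def generate_cohort(
    config: Optional[CohortConfig] = None,
    seed: int | np.random.Generator = 0,
    key: Optional[ScoringKey] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (questionnaire responses, clinical panel) tables.

    Deterministic given ``seed``.  Returns two DataFrames joinable on
    ``athlete_id``, using the same schemas as the package's CSV readers.
    """
    config = config or CohortConfig()
    key = key or default_key()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_athletes

    ids = [f"A{i:04d}" for i in range(n)]
    if n == 0:
        resp = pd.DataFrame(columns=["athlete_id", "version"] + list(key.item_ids)
                            + ["highest_weight_kg", "lowest_weight_kg"])
        clin = pd.DataFrame(columns=["athlete_id", "centre"])
        return resp, clin

    centres = list(config.centre_weights)
    w = np.asarray([config.centre_weights[c] for c in centres], float)
    centre = rng.choice(centres, size=n, p=w / w.sum())
    version = np.where(rng.random(n) < config.v2_fraction, "v2", "v1")
    z = rng.standard_normal(n)

    # ---- clinical panel ---------------------------------------------------
    clin = pd.DataFrame({"athlete_id": ids, "centre": centre})
    marks = {name: _draw(rng, spec, z) for name, spec in config.markers.items()}
    clin["age"] = np.clip(marks["age"], 18, 50)
    clin["height"] = marks["height"]
    clin["bmi"] = marks["bmi"]
    clin["body_mass"] = marks["bmi"] * (marks["height"] / 100.0) ** 2
    for name in ("ffm", "body_fat_pct", "spine_bmd_z", "femur_bmd_z", "systolic_bp",
                 "diastolic_bp", "total_testosterone", "shbg", "t3", "igf1",
                 "cortisol", "insulin", "glucose", "total_chol", "ldl", "hdl",
                 "triglycerides"):
        clin[name] = marks[name]

    method = np.where(
        rng.random(n) < config.first_principles_fraction, "first_principles", "metabolic_cart"
    )
    ratio = np.empty(n)
    for m, spec in config.rmr_ratio_by_method.items():
        mask = method == m
        ratio[mask] = _draw(rng, spec, z[mask])
    clin["rmr_method"] = method
    clin["rmr_measured"] = ratio * (500.0 + 22.0 * clin["ffm"]) * KCAL_TO_KJ
    clin["elite"] = (rng.random(n) < config.elite_fraction).astype(int)

    # ---- questionnaire ----------------------------------------------------
    resp = pd.DataFrame({"athlete_id": ids, "version": version})
    v2 = version == "v2"
    for it in key:
        freqs = config.item_freqs.get(it.item_id)
        if freqs is None:
            raise ConfigError(f"no code frequencies configured for item {it.item_id}")
        lam = config.item_loadings.get(it.item_id, 0.0)
        adj = _draw_codes(rng, freqs, lam, z).astype(float)
        raw = (it.max_code - adj) if it.reverse_coded else adj
        if it.version == "v2":
            raw = np.where(v2, raw, np.nan)
        resp[it.item_id] = raw

    flux = _draw(rng, config.weight_flux, z)
    lowest = clin["body_mass"].to_numpy() - 0.45 * flux
    resp["lowest_weight_kg"] = np.round(lowest, 1)
    resp["highest_weight_kg"] = np.round(lowest + flux, 1)

    # ---- missingness ------------------------------------------------------
    rates = config.missing_rates
    blocks = {
        "bmd": ["spine_bmd_z", "femur_bmd_z"],
        "bp": ["systolic_bp", "diastolic_bp"],
        "rmr": ["rmr_measured"],
        "total_testosterone": ["total_testosterone"],
        "shbg": ["shbg"],
        "t3": ["t3"],
        "igf1": ["igf1"],
        "cortisol": ["cortisol"],
        "insulin": ["insulin"],
        "lipids": ["total_chol", "ldl", "hdl", "triglycerides"],
        "glucose": ["glucose"],
    }
    for block, cols in blocks.items():
        rate = rates.get(block, 0.0)
        if isinstance(rate, dict):
            per = np.asarray([rate.get(c, rate.get("default", 0.0)) for c in centre])
        else:
            per = np.full(n, rate)
        drop = rng.random(n) < per
        clin.loc[drop, cols] = np.nan
    # insulin and SHBG panels were run only for version-2 participants
    clin.loc[~v2, ["insulin", "shbg"]] = np.nan

    item_rate = rates.get("items", 0.0)
    if item_rate > 0:
        for it in key:
            drop = rng.random(n) < item_rate
            resp.loc[drop, it.item_id] = np.nan
    return resp, clin


# ---------------------------------------------------------------------------
# test-retest generator
# ---------------------------------------------------------------------------

@dataclass
class TestRetestConfig:
    """Two-occasion design: observed = true score + occasion noise, so the
    target consistency ICC is ``true_sd^2 / (true_sd^2 + noise_sd^2)``."""

    n_subjects: int = 42
    mean: float = 25.0
    true_sd: float = 8.0
    noise_sd: float = 5.13  # default targets ICC ~ 0.71

    def __post_init__(self):
        if self.true_sd <= 0 or self.noise_sd < 0:
            raise ConfigError("SDs must be positive (noise may be 0)")

    @property
    def target_icc(self) -> float:
        v = self.true_sd**2
        return v / (v + self.noise_sd**2)

    @classmethod
    def for_target_icc(cls, icc: float, n_subjects: int = 42,
                       mean: float = 25.0, true_sd: float = 8.0) -> "TestRetestConfig":
        if not 0.0 < icc < 1.0:
            raise ConfigError("target ICC must lie in (0, 1)")
        noise = true_sd * np.sqrt(1.0 / icc - 1.0)
        return cls(n_subjects, mean, true_sd, float(noise))


def generate_test_retest(
    config: Optional[TestRetestConfig] = None, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Paired (test, retest) total scores for ``n_subjects`` athletes."""
    config = config or TestRetestConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true = config.mean + config.true_sd * rng.standard_normal(config.n_subjects)
    test = true + config.noise_sd * rng.standard_normal(config.n_subjects)
    retest = true + config.noise_sd * rng.standard_normal(config.n_subjects)
    return pd.DataFrame(
        {"subject_id": [f"S{i:03d}" for i in range(config.n_subjects)],
         "test": test, "retest": retest}
    )


def generate_item_test_retest(
    item_iccs: dict[str, float],
    n_subjects: int = 42,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two administrations of a multi-item instrument, one column per
    item, each item targeting its own consistency ICC."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    test, retest = {}, {}
    for item, icc in item_iccs.items():
        cfg = TestRetestConfig.for_target_icc(icc, n_subjects, mean=1.5, true_sd=1.0)
        pair = generate_test_retest(cfg, rng)
        test[item], retest[item] = pair["test"].to_numpy(), pair["retest"].to_numpy()
    return pd.DataFrame(test), pd.DataFrame(retest)
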