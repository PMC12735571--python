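"""Synthetic fixtures emulating the study's data-generating processes.

No deposited datasets exist for this workflow, so every stage is exercised on
synthetic inputs built from published summary numbers:

* Box-Behnken response tables drawn from known quadratic truth surfaces (the
  published retained-coefficient models by default) plus Gaussian noise;
* multi-vessel dissolution profiles sampled from Weibull truth curves at the
  in vitro schedule (0.5, 1, 2.5, 5, 13 h) with truncated measurement noise;
* pseudo-"observed" clinical PK datasets for exercising average-fold-error
  validation, produced by perturbing physiological parameters and
  re-simulating the absorption model.

Everything is a pure function of the spec (including its seed).  The default
truth curves are the three-point reference (23/58/77% at 1/2.5/13 h) and
optimized-formulation (22/55/76%) release profiles; all other values are
synthetic stand-ins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .absorption_pbpk import (
    PKMetrics,
    SimulationConfig,
    StudyRecord,
    ValidationSet,
    default_config,
    simulate_config,
)
from .dissolution import DissolutionProfile, DoubleWeibull, fit_double_weibull
from .doe_rsm import FactorSpec, QuadraticModel, generate_bbd, predict_response
from .errors import InvalidParameterError
from .psa import apply_multiplier

__all__ = [
    "ARICEPT_PROFILE",
    "FOPTZ_PROFILE",
    "TABLE_COEFFICIENTS",
    "SyntheticSpec",
    "default_factors",
    "reference_weibull",
    "optimized_weibull",
    "make_bbd_dataset",
    "make_dissolution_dataset",
    "make_clinical_dataset",
]

#: reference (Aricept) three-point release profile: h -> percent released
ARICEPT_PROFILE = {1.0: 23.0, 2.5: 58.0, 13.0: 77.0}
#: optimized-formulation three-point release profile
FOPTZ_PROFILE = {1.0: 22.0, 2.5: 55.0, 13.0: 76.0}

#: published retained-coefficient response-surface models (actual units) for
#: percent released at 1 / 2.5 / 5 / 13 h
TABLE_COEFFICIENTS = {
    "Y1": {"intercept": 43.0, "x1": -0.67, "x2": -0.96, "x3": 1.9,
           "x1^2": 0.007, "x2^2": 0.01, "x3^2": -0.19},
    "Y2": {"intercept": 92.0, "x1": -0.73, "x2": -1.37, "x3": 0.8,
           "x2^2": 0.02},
    "Y3": {"intercept": 91.8, "x1": -0.72, "x2": -1.36, "x3": 0.02,
           "x2^2": 0.02},
    "Y4": {"intercept": 92.0, "x1*x2": -0.034, "x1^2": -0.01, "x3^2": 0.02},
}

#: in vitro sampling schedule, hours
DISSOLUTION_TIMEPOINTS = (0.5, 1.0, 2.5, 5.0, 13.0)


def default_factors() -> tuple[FactorSpec, FactorSpec, FactorSpec]:
    """Synthetic factor levels centered on the optimized composition
    (20% HPMC 100, 20% HPMC 4000, 5% NaCMC)."""
    return (FactorSpec("HPMC100", 10.0, 30.0),
            FactorSpec("HPMC4000", 10.0, 30.0),
            FactorSpec("NaCMC", 2.0, 8.0))


def reference_weibull() -> DoubleWeibull:
    """Weibull release curve fit to the printed reference profile."""
    prof = DissolutionProfile(times=list(ARICEPT_PROFILE),
                              released=list(ARICEPT_PROFILE.values()))
    return fit_double_weibull(prof).params


def optimized_weibull() -> DoubleWeibull:
    """Weibull release curve fit to the printed optimized-formulation profile."""
    prof = DissolutionProfile(times=list(FOPTZ_PROFILE),
                              released=list(FOPTZ_PROFILE.values()))
    return fit_double_weibull(prof).params


@dataclass
class SyntheticSpec:
    """Generating truths and noise levels for all synthetic fixtures."""

    seed: int = 0
    doe_truth: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE_COEFFICIENTS.items()})
    doe_noise_sd: float = 1.0  # percent released
    dissolution_truth: dict[str, DoubleWeibull] | None = None  # default printed fits
    dissolution_noise_sd: float = 1.0  # percent released
    clinical_n_studies: int = 9
    clinical_cv_pct: float = 10.0  # per-study parameter perturbation CV

    def __post_init__(self):
        if min(self.doe_noise_sd, self.dissolution_noise_sd, self.clinical_cv_pct) < 0:
            raise InvalidParameterError("noise levels must be >= 0")
        if self.clinical_n_studies < 1:
            raise InvalidParameterError("need >= 1 clinical study")


def make_bbd_dataset(spec: SyntheticSpec, n_center: int = 5, out_dir=None):
    """17-run Box-Behnken design with responses from the truth quadratics.

    Returns (design_df, response_df, truth_models); optionally writes
    ``bbd_design.csv`` and ``bbd_responses.csv`` to out_dir.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    design = generate_bbd(default_factors(), n_center=n_center)
    design_df = design.to_frame()

    truth_models = {name: QuadraticModel.from_coefficients(name, coefs)
                    for name, coefs in spec.doe_truth.items()}
    resp = {"run_id": design_df["run_id"].to_numpy()}
    for name, model in truth_models.items():
        clean = np.array([predict_response(model, x) for x in design.actual])
        resp[name] = clean + rng.normal(0.0, spec.doe_noise_sd, size=clean.size)
    response_df = pd.DataFrame(resp)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        design_df.to_csv(out_dir / "bbd_design.csv", index=False)
        response_df.to_csv(out_dir / "bbd_responses.csv", index=False)
    return design_df, response_df, truth_models


def make_dissolution_dataset(spec: SyntheticSpec, n_vessels: int = 6,
                             out_dir=None) -> pd.DataFrame:
    """Per-vessel dissolution points from the truth curves plus noise.

    Sampled at the in vitro schedule; noise is Gaussian, clipped to [0, 100],
    and each vessel is made monotone non-decreasing.  Returns a long-format
    frame with columns formulation, vessel_id, time_h, pct_released and
    optionally writes one CSV per formulation.
    """
    if n_vessels < 1:
        raise InvalidParameterError("need >= 1 vessel")
    truths = spec.dissolution_truth
    if truths is None:
        truths = {"reference": reference_weibull(), "test": optimized_weibull()}
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    t = np.array(DISSOLUTION_TIMEPOINTS)

    rows = []
    for name in sorted(truths):
        clean = truths[name].release(t)
        for v in range(1, n_vessels + 1):
            noisy = clean + rng.normal(0.0, spec.dissolution_noise_sd, size=t.size)
            noisy = np.maximum.accumulate(np.clip(noisy, 0.0, 100.0))
            for ti, yi in zip(t, noisy):
                rows.append({"formulation": name, "vessel_id": f"v{v}",
                             "time_h": ti, "pct_released": yi})
    df = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, grp in df.groupby("formulation"):
            grp[["time_h", "pct_released", "vessel_id"]].to_csv(
                out_dir / f"dissolution_{name}.csv", index=False)
    return df


_CLINICAL_PERTURBED = ("peff", "vmax_cyp3a4", "vmax_cyp2d6", "stomach_transit_time")


def make_clinical_dataset(spec: SyntheticSpec,
                          base_config: SimulationConfig | None = None) -> ValidationSet:
    """Pseudo-observed clinical PK studies for AFE validation exercises.

    For each study, the baseline simulation provides the "predicted" PK; the
    "observed" PK comes from re-simulating with per-study log-normal
    perturbations (median 1, stated CV) applied to permeability, CYP Vmax and
    gastric emptying.  With zero CV, predicted == observed and AFE == 1.
    """
    cfg = base_config if base_config is not None else default_config()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    base = simulate_config(cfg)
    predicted = PKMetrics(cmax=base.pk.cmax, tmax=base.pk.tmax,
                          auc_0_t=base.pk.auc_0_t, auc_inf=base.pk.auc_inf)

    sigma = np.sqrt(np.log1p((spec.clinical_cv_pct / 100.0) ** 2))
    studies = []
    for k in range(spec.clinical_n_studies):
        pert = cfg
        for p in _CLINICAL_PERTURBED:
            m = float(np.exp(sigma * rng.standard_normal())) if sigma > 0 else 1.0
            pert = apply_multiplier(pert, p, m)
        obs = simulate_config(pert)
        studies.append(StudyRecord(
            study_id=f"synthetic_study_{k + 1}",
            predicted=predicted,
            observed=PKMetrics(cmax=obs.pk.cmax, tmax=obs.pk.tmax,
                               auc_0_t=obs.pk.auc_0_t, auc_inf=obs.pk.auc_inf)))
    return ValidationSet(studies=studies)
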