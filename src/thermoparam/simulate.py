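"""Synthetic melanoma DSC cohort generator.

Emulates the statistical structure the analysis stages assume, so the whole
pipeline is testable without any patient data:

* three-transition thermograms — a sum of Gaussians near 63 / 70 / 75 °C
  (albumin and globulin denaturation transitions) with per-subject jitter on
  positions and amplitudes, plus white measurement noise;
* a three-group cohort (49 controls / 74 active melanoma / 33 NED) with
  group-specific age distributions, sex imbalance, stage and spread
  descriptors;
* group effects: the peak-2 position is shifted +0.4 °C in active disease
  and melanoma samples have a slightly attenuated peak 1 (lower Area/Peak1);
* a latent per-subject factor ``z`` ~ N(0, 1) that simultaneously deepens
  the Peak 1–2 valley, widens the Peak-3 tail, and raises the overall-
  survival log-hazard by ``beta * z`` in active patients — emulating the
  PC3-like prognostic mode;
* overall-survival times (exponential, per-group baseline hazard) with
  independent exponential censoring at a configurable censoring fraction,
  and a null progression-free-survival process for the NED group.

Each sample draws from its own counter-keyed RNG substream, so generated
cohorts are byte-stable and independent of column evaluation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    TemperatureMesh,
    ThermogramCurve,
    write_clinical_table,
    write_thermogram_matrix,
)

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_thermogram", "generate_cohort", "ground_truth"]

GROUPS = ("control", "active", "NED")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort.

    Cohort sizes, peak geometry, the active-group T_Peak2 shift, age/sex
    distributions and the survival coefficient mirror the study design; the
    jitter scales and hazards are stated conventions (see docs/methods.md).
    """

    # cohort structure
    n_control: int = 49
    n_active: int = 74
    n_ned: int = 33

    # curve geometry (°C, cal/°C·g)
    peak_centers: tuple[float, float, float] = (63.0, 70.0, 75.0)
    peak_sigmas: tuple[float, float, float] = (1.8, 1.6, 2.2)
    amplitudes: tuple[float, float, float] = (0.26, 0.30, 0.10)
    noise_sd: float = 0.004

    # subject-level variability
    tpeak2_subject_sd: float = 0.8      # °C, dominant inter-subject mode
    center1_jitter_sd: float = 0.15     # °C
    center3_jitter_sd: float = 0.25     # °C
    amp_jitter_sd: float = 0.06         # lognormal sigma per peak amplitude
    scale_jitter_sd: float = 0.05       # lognormal sigma, global intensity

    # group / sex effects
    tpeak2_shift_active: float = 0.4    # °C added to peak-2 center, active only
    melanoma_peak1_scale: float = 0.90  # peak-1 amplitude factor for NED+active
    female_peak2_scale: float = 1.03    # peak-2 amplitude factor for females

    # PC3-like latent factor and survival
    survival_beta: float = 0.553        # log-hazard per unit z, active OS
    tail_loading: float = 0.02          # cal/°C·g per unit z, peak-3 tail bump
    valley_loading: float = 0.015       # cal/°C·g per unit z, valley deepening
    baseline_hazard: dict[str, float] = field(
        default_factory=lambda: {"control": 0.03, "NED": 0.05, "active": 0.12}
    )  # events / year
    censoring_rate: float = 0.35        # expected censored fraction, OS
    pfs_hazard: float = 0.05            # events / year, NED recurrence (null)
    pfs_censoring_rate: float = 0.78

    # demographics: group -> (median age, SD, low, high) and P(female)
    age_model: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "control": (59.0, 15.0, 25.0, 93.0),
            "active": (62.0, 14.0, 26.0, 93.0),
            "NED": (53.0, 14.0, 23.0, 79.0),
        }
    )
    female_prob: dict[str, float] = field(
        default_factory=lambda: {"control": 0.653, "active": 0.365, "NED": 0.394}
    )

    def __post_init__(self) -> None:
        if min(self.amplitudes) <= 0 or min(self.peak_sigmas) <= 0:
            raise ValueError("amplitudes and sigmas must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")

    @classmethod
    def null(cls) -> "GeneratorConfig":
        """Zero-effect configuration: identical curve and outcome laws in all
        groups and sexes (for calibration checks)."""
        return cls(
            tpeak2_shift_active=0.0,
            melanoma_peak1_scale=1.0,
            female_peak2_scale=1.0,
            survival_beta=0.0,
        )


def ground_truth(config: GeneratorConfig) -> dict:
    """Generating effect sizes implied by a configuration.

    The NED-vs-active log-odds slopes follow the equal-variance Gaussian
    discriminant identity beta = (mean shift) / variance for each
    class-conditionally Gaussian covariate.
    """
    age_active = config.age_model["active"]
    age_ned = config.age_model["NED"]
    sd_age = age_active[1]
    return {
        "cox_beta": config.survival_beta,
        "tpeak2_shift_active": config.tpeak2_shift_active,
        "logodds_tpeak2": config.tpeak2_shift_active / config.tpeak2_subject_sd**2,
        "logodds_age": (age_active[0] - age_ned[0]) / sd_age**2,
        "melanoma_peak1_scale": config.melanoma_peak1_scale,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
        },
    }


# ---------------------------------------------------------------------------
# Subject-level draws
# ---------------------------------------------------------------------------

def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def _jitter(rng: np.random.Generator, sd: float, clip_sd: float = 2.5) -> float:
    """Truncated-normal subject jitter (clipped at ±clip_sd standard
    deviations so peak centers stay inside their assignment windows)."""
    if sd == 0:
        return 0.0
    return float(np.clip(rng.normal(0.0, sd), -clip_sd * sd, clip_sd * sd))


def _sample_latents(config: GeneratorConfig, group: str, sex: str, rng: np.random.Generator) -> dict:
    mu1, mu2, mu3 = config.peak_centers
    a1, a2, a3 = config.amplitudes
    mu1 = mu1 + _jitter(rng, config.center1_jitter_sd)
    mu2 = mu2 + _jitter(rng, config.tpeak2_subject_sd)
    if group == "active":
        mu2 += config.tpeak2_shift_active
    mu3 = mu3 + _jitter(rng, config.center3_jitter_sd)
    if group in ("active", "NED"):
        a1 = a1 * config.melanoma_peak1_scale
    if sex == "female":
        a2 = a2 * config.female_peak2_scale
    amps = np.array([a1, a2, a3]) * np.exp(
        rng.normal(0.0, config.amp_jitter_sd, size=3)
    )
    scale = float(np.exp(rng.normal(0.0, config.scale_jitter_sd)))
    z = float(rng.normal())
    return {"mu": (mu1, mu2, mu3), "amps": amps, "scale": scale, "z": z}


def _curve_from_latents(
    config: GeneratorConfig,
    latents: dict,
    mesh: TemperatureMesh,
    rng: np.random.Generator,
    sample_id: str,
) -> ThermogramCurve:
    t = mesh.values
    mu1, mu2, mu3 = latents["mu"]
    s1, s2, s3 = config.peak_sigmas
    a1, a2, a3 = latents["amps"]
    cp = latents["scale"] * (
        a1 * _gauss(t, mu1, s1) + a2 * _gauss(t, mu2, s2) + a3 * _gauss(t, mu3, s3)
    )
    z = latents["z"]
    # PC3-like mode: wider peak-3 tail, deeper peak-1/2 valley for high z
    cp = cp + z * config.tail_loading * _gauss(t, 76.5, 2.0)
    cp = cp - z * config.valley_loading * _gauss(t, (mu1 + mu2) / 2.0, 1.2)
    cp = cp + rng.normal(0.0, config.noise_sd, size=t.size)
    return ThermogramCurve(sample_id, mesh, cp)


def generate_thermogram(
    config: GeneratorConfig,
    group: str,
    rng: np.random.Generator,
    sample_id: str = "synthetic",
    sex: str = "male",
) -> ThermogramCurve:
    """Draw one synthetic thermogram for a group on the canonical mesh."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    mesh = TemperatureMesh.canonical()
    latents = _sample_latents(config, group, sex, rng)
    return _curve_from_latents(config, latents, mesh, rng, sample_id)


def _sample_age(config: GeneratorConfig, group: str, rng: np.random.Generator) -> float:
    med, sd, lo, hi = config.age_model[group]
    return float(np.clip(rng.normal(med, sd), lo, hi))


def _survival_draw(
    hazard: float, censoring_rate: float, rng: np.random.Generator
) -> tuple[float, bool]:
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate <= 0:
        return t_event, True
    # independent exponential censoring with P(censored) == censoring_rate
    lam_c = hazard * censoring_rate / (1.0 - censoring_rate)
    t_cens = rng.exponential(1.0 / lam_c)
    if t_event <= t_cens:
        return t_event, True
    return t_cens, False


_STAGE_PROBS = {
    "active": ((2, 3, 4), (0.014, 0.243, 0.743)),
    "NED": ((2, 3), (0.364, 0.636)),
}
_N_AFFECTED = (("1", "2", ">=3"), (0.446, 0.257, 0.297))
_LOCATION = (("localized", "distant"), (0.446, 0.554))


@dataclass
class SyntheticCohort:
    """A generated cohort: curves, clinical table, and the generating truth."""

    curves: list[ThermogramCurve]
    clinical: pd.DataFrame
    truth: dict
    seed: int

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "thermograms": directory / "thermograms.csv",
            "clinical": directory / "clinical.csv",
            "truth": directory / "truth.json",
        }
        write_thermogram_matrix(self.curves, paths["thermograms"])
        write_clinical_table(self.clinical, paths["clinical"])
        truth = dict(self.truth)
        truth["seed"] = self.seed
        paths["truth"].write_text(json.dumps(truth, indent=2, default=list))
        return paths


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full cohort (thermograms + clinical table + truth record).

    Sample ``i`` draws from ``default_rng([seed, i])``, so individual samples
    are reproducible in isolation.
    """
    config = config or GeneratorConfig()
    mesh = TemperatureMesh.canonical()
    plan = (
        [("control", f"C{i+1:03d}") for i in range(config.n_control)]
        + [("active", f"A{i+1:03d}") for i in range(config.n_active)]
        + [("NED", f"N{i+1:03d}") for i in range(config.n_ned)]
    )
    curves: list[ThermogramCurve] = []
    rows: list[dict] = []
    zs: list[float] = []
    n_ned_seen = 0
    for i, (group, sid) in enumerate(plan):
        rng = np.random.default_rng([seed, i])
        sex = "female" if rng.random() < config.female_prob[group] else "male"
        age = _sample_age(config, group, rng)
        latents = _sample_latents(config, group, sex, rng)
        curves.append(_curve_from_latents(config, latents, mesh, rng, sid))
        z = latents["z"]
        zs.append(z)
        hazard = config.baseline_hazard[group]
        if group == "active":
            hazard = hazard * float(np.exp(config.survival_beta * z))
        os_time, os_event = _survival_draw(hazard, config.censoring_rate, rng)
        row: dict = {
            "sample_id": sid, "status": group, "sex": sex, "age": round(age, 1),
            "stage": np.nan, "n_affected": np.nan, "location": np.nan,
            "os_time": os_time, "os_event": os_event,
            "pfs_time": np.nan, "pfs_event": np.nan,
        }
        if group in _STAGE_PROBS:
            stages, probs = _STAGE_PROBS[group]
            row["stage"] = int(rng.choice(stages, p=probs))
        if group == "active":
            row["n_affected"] = str(rng.choice(_N_AFFECTED[0], p=_N_AFFECTED[1]))
            row["location"] = str(rng.choice(_LOCATION[0], p=_LOCATION[1]))
        if group == "NED":
            n_ned_seen += 1
            if n_ned_seen < config.n_ned:  # one NED sample lacks PFS follow-up
                pfs_time, pfs_event = _survival_draw(
                    config.pfs_hazard, config.pfs_censoring_rate, rng
                )
                row["pfs_time"] = pfs_time
                row["pfs_event"] = pfs_event
        rows.append(row)
    clinical = pd.DataFrame(rows)
    truth = ground_truth(config)
    truth["z"] = zs
    truth["sample_id"] = [sid for _, sid in plan]
    return SyntheticCohort(curves, clinical, truth, seed)
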