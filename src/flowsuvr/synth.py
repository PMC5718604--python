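"""Synthetic inputs: arterial input function surrogate and subject cohorts.

The measured arterial data behind the study design (continuous whole-blood
sampling plus manually drawn metabolite-corrected plasma samples) are not
publicly available, so this module supplies a declared, fixed surrogate:

* total plasma follows a tri-exponential bolus model with a linear rise
  (Feng-type), ``(A1 (t-d) - A2 - A3) e^{-l1 (t-d)} + A2 e^{-l2 (t-d)}
  + A3 e^{-l3 (t-d)}`` for t >= d, clipped at zero;
* the parent (unmetabolized) fraction declines as a Hill function
  ``1 / (1 + (t/T50)^h)``, giving the metabolite-corrected input;
* whole blood is a constant multiple ``r_bp`` of total plasma.

Cohorts are drawn per subject as log-normal deviates around configurable
regional parameter means (positivity-preserving, parameterized by mean and
CV); the default HC means are the built-in average-HC baseline. The aMCI and
AD group defaults are illustrative placeholders (higher target k3 as an
amyloid-load surrogate, modestly lower K1), not literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .defaults import HC_BASELINE
from .kinetics import InputFunction, KineticParams, RegionalTAC

__all__ = [
    "AifSpec",
    "CohortSpec",
    "SubjectRecord",
    "default_aif_spec",
    "default_sampling_grid",
    "generate_input_function",
    "sample_cohort",
    "add_noise",
    "default_cohort_specs",
]


@dataclass(frozen=True)
class AifSpec:
    """Parameters of the bolus input-function surrogate.

    A1 (kBq/mL/min) scales the linear rise; A2, A3 (kBq/mL) the two washout
    exponentials with eigenvalues lam1 > lam2 > lam3 (1/min); ``delay`` is the
    injection-to-arrival delay (min). ``t50`` (min) and ``hill`` set the
    parent-fraction decline; ``r_bp`` is the whole-blood-to-plasma ratio.
    """

    A1: float
    A2: float
    A3: float
    lam1: float
    lam2: float
    lam3: float
    delay: float = 0.5
    t50: float = 20.0
    hill: float = 1.5
    r_bp: float = 0.85

    def __post_init__(self) -> None:
        if min(self.A1, self.A2, self.A3, self.t50, self.hill, self.r_bp) <= 0:
            raise ValueError("amplitudes, t50, hill and r_bp must be positive")
        if not self.lam1 > self.lam2 > self.lam3 > 0:
            raise ValueError("eigenvalues must satisfy lam1 > lam2 > lam3 > 0")
        if self.delay < 0:
            raise ValueError("delay must be nonnegative")

    def total_plasma(self, t: np.ndarray) -> np.ndarray:
        tau = np.asarray(t, dtype=float) - self.delay
        tau = np.where(tau > 0, tau, 0.0)
        c = (
            (self.A1 * tau - self.A2 - self.A3) * np.exp(-self.lam1 * tau)
            + self.A2 * np.exp(-self.lam2 * tau)
            + self.A3 * np.exp(-self.lam3 * tau)
        )
        c = np.where(np.asarray(t) >= self.delay, c, 0.0)
        return np.clip(c, 0.0, None)

    def parent_fraction(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return 1.0 / (1.0 + (t / self.t50) ** self.hill)


def default_aif_spec() -> AifSpec:
    """The shipped input-function surrogate (version-controlled config)."""
    with resources.files("flowsuvr.data").joinpath("default_aif.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return AifSpec(**raw)


def default_sampling_grid(t_end: float = 60.0) -> np.ndarray:
    """Dense early sampling around the bolus peak, 0.25-min tail resolution."""
    if t_end < 60.0:
        raise ValueError("grid must cover at least 60 min")
    return np.unique(
        np.concatenate(
            [np.arange(0.0, 3.0, 0.02), np.arange(3.0, 10.0, 0.1),
             np.arange(10.0, t_end + 1e-9, 0.25), [t_end]]
        )
    )


def generate_input_function(
    spec: AifSpec, grid: Sequence[float] | None = None
) -> InputFunction:
    """Sample the surrogate model onto a time grid (minutes, from 0)."""
    t = default_sampling_grid() if grid is None else np.asarray(grid, dtype=float)
    if t[0] != 0:
        raise ValueError("grid must start at 0")
    if t[-1] < 60.0:
        raise ValueError("grid must cover at least [0, 60] min")
    total = spec.total_plasma(t)
    parent = total * spec.parent_fraction(t)
    blood = total * spec.r_bp
    return InputFunction(times=t, plasma=parent, blood=blood)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling recipe for one diagnostic group.

    ``means`` maps region -> KineticParams group means; ``cv`` is the
    coefficient of variation applied to every rate (Vb uses ``cv_vb``).
    ``aif_jitter_cv`` perturbs the input-function amplitudes per subject.
    """

    group: str
    n_subjects: int
    means: Mapping[str, KineticParams] = field(
        default_factory=lambda: dict(HC_BASELINE)
    )
    cv: float = 0.15
    cv_vb: float = 0.10
    aif_jitter_cv: float = 0.10
    aif: AifSpec | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if min(self.cv, self.cv_vb, self.aif_jitter_cv) < 0:
            raise ValueError("CVs must be nonnegative")


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated subject: group label, regional kinetics, input function."""

    subject_id: str
    group: str
    params: Mapping[str, KineticParams]
    input_function: InputFunction


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw with the requested arithmetic mean and coefficient of variation."""
    if mean == 0 or cv == 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def sample_cohort(
    spec: CohortSpec, seed: int | np.random.SeedSequence = 0
) -> list[SubjectRecord]:
    """Draw a reproducible cohort of subjects.

    Each regional rate is log-normal around the group mean with the group CV;
    each subject's input function jitters the AIF amplitudes (A1, A2, A3) by
    ``aif_jitter_cv``, keeping timing parameters fixed.
    """
    rng = np.random.default_rng(seed)
    aif = spec.aif if spec.aif is not None else default_aif_spec()
    subjects = []
    for i in range(spec.n_subjects):
        params = {}
        for region, mean_p in spec.means.items():
            params[region] = KineticParams(
                K1=_lognormal(rng, mean_p.K1, spec.cv),
                k2=_lognormal(rng, mean_p.k2, spec.cv),
                k3=_lognormal(rng, mean_p.k3, spec.cv),
                k4=_lognormal(rng, mean_p.k4, spec.cv),
                Vb=min(_lognormal(rng, mean_p.Vb, spec.cv_vb), 0.5),
            )
        subj_aif = replace(
            aif,
            A1=_lognormal(rng, aif.A1, spec.aif_jitter_cv),
            A2=_lognormal(rng, aif.A2, spec.aif_jitter_cv),
            A3=_lognormal(rng, aif.A3, spec.aif_jitter_cv),
        )
        subjects.append(
            SubjectRecord(
                subject_id=f"{spec.group}{i + 1:03d}",
                group=spec.group,
                params=params,
                input_function=generate_input_function(subj_aif),
            )
        )
    return subjects


def _scaled_means(
    base: Mapping[str, KineticParams], k1_factor: float, target_k3_factor: float
) -> dict[str, KineticParams]:
    out = {}
    for region, p in base.items():
        k3 = p.k3 * (target_k3_factor if region == "precuneus" else 1.0)
        out[region] = KineticParams(
            K1=p.K1 * k1_factor, k2=p.k2 * k1_factor, k3=k3, k4=p.k4, Vb=p.Vb
        )
    return out


def default_cohort_specs(
    n_hc: int = 10, n_amci: int = 15, n_ad: int = 9
) -> dict[str, CohortSpec]:
    """Study-sized cohorts. HC means are the built-in average-HC baseline.

    The aMCI/AD means are ILLUSTRATIVE, not literature values: target k3 is
    raised (x1.5 aMCI, x2 AD) as an amyloid-load surrogate and delivery
    lowered (-7% aMCI, -15% AD, with k2 co-scaled to preserve V_ND). The
    scalings keep the disease target kinetics in the grey-matter regime,
    where a flow reduction still raises the target SUV, only less than in HC.
    """
    return {
        "HC": CohortSpec(group="HC", n_subjects=n_hc),
        "aMCI": CohortSpec(
            group="aMCI",
            n_subjects=n_amci,
            means=_scaled_means(HC_BASELINE, k1_factor=0.93, target_k3_factor=1.5),
        ),
        "AD": CohortSpec(
            group="AD",
            n_subjects=n_ad,
            means=_scaled_means(HC_BASELINE, k1_factor=0.85, target_k3_factor=2.0),
        ),
    }


def add_noise(tac: RegionalTAC, scale: float, seed: int | np.random.SeedSequence) -> RegionalTAC:
    """Add frame-duration-scaled Gaussian count noise to a TAC.

    Per-frame SD = scale * sqrt(value / duration) (longer frames average more
    counts), clipped at the physical floor of zero activity. scale = 0 returns
    the TAC unchanged.
    """
    if scale < 0:
        raise ValueError("noise scale must be nonnegative")
    if scale == 0:
        return tac
    rng = np.random.default_rng(seed)
    sd = scale * np.sqrt(np.clip(tac.values, 0.0, None) / tac.schedule.durations)
    noisy = np.clip(tac.values + rng.normal(0.0, 1.0, size=sd.shape) * sd, 0.0, None)
    return RegionalTAC(region=tac.region, schedule=tac.schedule, values=noisy)
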