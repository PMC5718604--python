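"""Study orchestration: baseline and cohort arms, group statistics, region scan.

Two study arms are provided:

* ``run_baseline_study`` perturbs flow around a single (average healthy
  control) parameter set and produces time courses, dSUVR-vs-dK1 sweep curves
  with cubic fits for target and both reference regions, the two global
  modes, and an optional extra-region scan.
* ``run_cohort_study`` draws per-subject kinetic parameters and input
  functions, sweeps every subject around its own baseline, aggregates
  per-group mean +/- SD curves, and (when the design allows) runs a two-way
  ANOVA of dSUVR on diagnostic group x dK1 with Tukey HSD on group.

Everything is a pure function of (configuration, master seed): the master
seed deterministically spawns one child seed per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .defaults import HC_BASELINE
from .kinetics import (
    DEFAULT_FRAME_SCHEDULE,
    FrameSchedule,
    InputFunction,
    KineticParams,
    simulate_tac,
)
from .perturb import (
    DEFAULT_GRID,
    DEFAULT_WINDOW,
    DeltaSUVRCurve,
    PerturbationSpec,
    compute_suvr,
    delta_suvr,
    delta_suvr_time_course,
    perturb_flow,
    sweep_delta_suvr,
)
from .synth import AifSpec, CohortSpec, default_aif_spec, generate_input_function

__all__ = [
    "StudyConfig",
    "GroupCurve",
    "run_baseline_study",
    "run_cohort_study",
    "anova_tukey",
    "region_vt_correlation",
    "subject_target_deltas",
]


@dataclass(frozen=True)
class StudyConfig:
    """Everything the two study arms need, in one serialisable object."""

    baseline: Mapping[str, KineticParams] = field(
        default_factory=lambda: dict(HC_BASELINE)
    )
    target: str = "precuneus"
    references: tuple[str, ...] = ("CB", "WM")
    grid_pct: tuple[float, ...] = DEFAULT_GRID
    window: tuple[float, float] = DEFAULT_WINDOW
    aif: AifSpec | None = None
    frames: FrameSchedule = DEFAULT_FRAME_SCHEDULE
    extra_regions: Mapping[str, KineticParams] = field(default_factory=dict)
    master_seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.target, *self.references):
            if r not in self.baseline:
                raise ValueError(f"region {r!r} has no baseline parameters")

    def resolved_aif(self) -> AifSpec:
        return self.aif if self.aif is not None else default_aif_spec()

    def to_dict(self) -> dict:
        d = {
            "baseline": {r: asdict(p) for r, p in self.baseline.items()},
            "target": self.target,
            "references": list(self.references),
            "grid_pct": list(self.grid_pct),
            "window": list(self.window),
            "aif": asdict(self.resolved_aif()),
            "frames": [list(f) for f in self.frames.frames],
            "extra_regions": {r: asdict(p) for r, p in self.extra_regions.items()},
            "master_seed": self.master_seed,
        }
        return d


@dataclass
class GroupCurve:
    """Per-group mean +/- SD of subject dSUVR curves on a common dK1 grid."""

    group: str
    grid_pct: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_subjects: int


def run_baseline_study(cfg: StudyConfig) -> dict:
    """Average-baseline arm: sweeps, cubic fits, time courses, region scan."""
    inp = generate_input_function(cfg.resolved_aif())
    curves: dict[str, DeltaSUVRCurve] = {}

    # heterogeneous: one target sweep (reference-independent) and one per reference
    ref0 = cfg.references[0]
    curves["target"] = sweep_delta_suvr(
        cfg.baseline[cfg.target], cfg.baseline[ref0], inp,
        PerturbationSpec(mode="target-only", grid_pct=cfg.grid_pct,
                         window=cfg.window, target=cfg.target, reference=ref0),
        cfg.frames,
    )
    for ref in cfg.references:
        spec = PerturbationSpec(mode="reference-only", grid_pct=cfg.grid_pct,
                                window=cfg.window, target=cfg.target, reference=ref)
        curves[f"reference:{ref}"] = sweep_delta_suvr(
            cfg.baseline[cfg.target], cfg.baseline[ref], inp, spec, cfg.frames
        )
        spec_g = PerturbationSpec(mode="global", grid_pct=cfg.grid_pct,
                                  window=cfg.window, target=cfg.target, reference=ref)
        curves[f"global:{ref}"] = sweep_delta_suvr(
            cfg.baseline[cfg.target], cfg.baseline[ref], inp, spec_g, cfg.frames
        )

    time_courses = {}
    for dk1 in (-40.0, -20.0, 20.0, 40.0):
        mid, tc = delta_suvr_time_course(
            cfg.baseline[cfg.target], cfg.baseline[ref0], inp,
            "target-only", dk1, cfg.frames,
        )
        time_courses[dk1] = tc
    time_courses["midpoints_min"] = mid

    region_scan = None
    if cfg.extra_regions:
        region_scan = region_scan_table(
            {**cfg.extra_regions}, cfg.baseline[ref0], inp, cfg.frames, cfg.window
        )

    return {
        "input_function": inp,
        "curves": curves,
        "time_courses": time_courses,
        "region_scan": region_scan,
        "config": cfg.to_dict(),
    }


def region_scan_table(
    regions: Mapping[str, KineticParams],
    ref_p: KineticParams,
    inp: InputFunction,
    frames: FrameSchedule = DEFAULT_FRAME_SCHEDULE,
    window: tuple[float, float] = DEFAULT_WINDOW,
    dk1_levels: Sequence[float] = (-10.0, -30.0),
) -> pd.DataFrame:
    """Target-only dSUVR per region at a few flow reductions, plus each V_T."""
    from .kinetics import macro_parameters

    rows = []
    for name, p in regions.items():
        base = simulate_tac(p, inp, frames, region=name)
        ref = simulate_tac(ref_p, inp, frames, region="ref")
        suvr0 = compute_suvr(base, ref, window)
        row = {"region": name, "VT": macro_parameters(p).VT}
        for dk1 in dk1_levels:
            tac = simulate_tac(perturb_flow(p, dk1), inp, frames, region=name)
            row[f"delta_suvr_pct_at_{int(dk1)}"] = delta_suvr(
                compute_suvr(tac, ref, window), suvr0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def subject_target_deltas(
    subject_params: KineticParams,
    inp: InputFunction,
    grid_pct: Sequence[float],
    frames: FrameSchedule = DEFAULT_FRAME_SCHEDULE,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> np.ndarray:
    """Target-region dSUVR across the grid for one subject.

    A target-only flow change leaves the reference untouched, so the
    reference cancels from the SUVR ratio and the target SUV alone determines
    dSUVR; no reference simulation is needed.
    """
    base = simulate_tac(subject_params, inp, frames)
    lo, hi = window
    overlap = np.clip(
        np.minimum(frames.ends, hi) - np.maximum(frames.starts, lo), 0.0, None
    )
    suv0 = float((base.values * overlap).sum() / overlap.sum())
    out = []
    for g in grid_pct:
        if g == 0:
            out.append(0.0)
            continue
        tac = simulate_tac(perturb_flow(subject_params, g), inp, frames)
        suv = float((tac.values * overlap).sum() / overlap.sum())
        out.append(100.0 * (suv - suv0) / suv0)
    return np.asarray(out)


def run_cohort_study(
    cohorts: Mapping[str, Sequence],
    cfg: StudyConfig,
    mode: str = "target-only",
    reference: str = "CB",
) -> dict:
    """Subject-specific arm over pre-sampled cohorts.

    ``cohorts`` maps group label -> list of SubjectRecord. Each subject is
    swept around its own baseline; curves are averaged per group. Inference
    (two-way ANOVA + Tukey) runs when >= 2 groups have >= 3 subjects;
    otherwise it is skipped with a warning entry in the result.
    """
    grid = np.asarray(cfg.grid_pct, dtype=float)
    records = []
    group_curves: dict[str, GroupCurve] = {}
    per_subject: dict[str, np.ndarray] = {}

    for group, subjects in cohorts.items():
        mat = []
        for subj in subjects:
            spec = PerturbationSpec(
                mode=mode, grid_pct=tuple(grid), window=cfg.window,
                target=cfg.target, reference=reference,
            )
            curve = sweep_delta_suvr(
                subj.params[cfg.target], subj.params[reference],
                subj.input_function, spec, cfg.frames, fit=False,
            )
            mat.append(curve.delta_suvr_pct)
            per_subject[subj.subject_id] = curve.delta_suvr_pct
            for g, d in zip(grid, curve.delta_suvr_pct):
                records.append(
                    {"subject": subj.subject_id, "group": group,
                     "dk1_pct": g, "delta_suvr_pct": d}
                )
        mat = np.asarray(mat)
        group_curves[group] = GroupCurve(
            group=group, grid_pct=grid, mean=mat.mean(axis=0),
            sd=mat.std(axis=0, ddof=1) if len(mat) > 1 else np.zeros(grid.size),
            n_subjects=len(mat),
        )

    df = pd.DataFrame(records)
    result = {"group_curves": group_curves, "observations": df,
              "per_subject": per_subject}
    eligible = [g for g, s in cohorts.items() if len(s) >= 3]
    if len(eligible) >= 2:
        result["anova"] = anova_tukey(df[df["group"].isin(eligible)])
    else:
        result["anova"] = None
        result["warning"] = "inference skipped: need >=2 groups with >=3 subjects"
    return result


def anova_tukey(observations: pd.DataFrame) -> dict:
    """Two-way fixed-effects ANOVA of dSUVR on group x dK1, Tukey HSD on group.

    Both factors enter as categorical (dK1 has as many levels as grid
    points); the interaction term is included. Valid p-values require
    independent observations in every (group, dK1) cell -- on per-subject
    sweep data, where one subject contributes every dK1 level, treat the
    p-values as descriptive only.
    """
    required = {"group", "dk1_pct", "delta_suvr_pct"}
    if not required.issubset(observations.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    cells = observations.groupby(["group", "dk1_pct"]).size()
    full = (
        observations["group"].nunique() * observations["dk1_pct"].nunique()
    )
    if len(cells) < full:
        have = set(cells.index)
        missing = [
            (g, k)
            for g in observations["group"].unique()
            for k in observations["dk1_pct"].unique()
            if (g, k) not in have
        ]
        raise ValueError(f"empty design cells: {missing}")

    df = observations.copy()
    df["dk1"] = df["dk1_pct"].astype(str)
    model = smf.ols("delta_suvr_pct ~ C(group) * C(dk1)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    tukey = pairwise_tukeyhsd(df["delta_suvr_pct"], df["group"])
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {
        "anova_table": table,
        "tukey": tukey_df,
        "group_F": float(table.loc["C(group)", "F"]),
        "group_p": float(table.loc["C(group)", "PR(>F)"]),
        "interaction_p": float(table.loc["C(group):C(dk1)", "PR(>F)"]),
    }


def anova_type1_experiment(
    n_seeds: int = 100,
    n_per_cell: int = 3,
    groups: Sequence[str] = ("A", "B", "C"),
    grid_pct: Sequence[float] = DEFAULT_GRID,
    master_seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I-error calibration of the group test under identical groups.

    Every (group, dK1) cell receives an independent cohort draw from the SAME
    distribution (the average-HC spec), so the group null holds by
    construction and the fixed-effects model's independence assumption is
    met (one observation per simulated subject). Returns the rejection rate
    of the group main effect at ``alpha`` across ``n_seeds`` replications.
    """
    from .synth import sample_cohort

    root = np.random.SeedSequence(master_seed)
    pvals = []
    for seed_seq in root.spawn(n_seeds):
        children = iter(seed_seq.spawn(len(groups) * len(grid_pct)))
        rows = []
        for group in groups:
            for level in grid_pct:
                spec = CohortSpec(group=group, n_subjects=n_per_cell)
                for subj in sample_cohort(spec, next(children)):
                    d = subject_target_deltas(
                        subj.params["precuneus"], subj.input_function, [level]
                    )[0]
                    rows.append(
                        {"group": group, "dk1_pct": level, "delta_suvr_pct": d}
                    )
        res = anova_tukey(pd.DataFrame(rows))
        pvals.append(res["group_p"])
    pvals = np.asarray(pvals)
    return {
        "p_values": pvals,
        "rejection_rate": float((pvals < alpha).mean()),
        "n_seeds": n_seeds,
        "alpha": alpha,
    }


def region_vt_correlation(
    region_deltas: Mapping[str, float], region_vts: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson correlation of target dSUVR against V_T across regions.

    Returns (r, p); r is NaN when either vector has zero variance.
    """
    regions = sorted(region_deltas)
    if sorted(region_vts) != regions:
        raise ValueError("region sets must match")
    if len(regions) < 3:
        raise ValueError("need at least 3 regions")
    x = np.array([region_vts[r] for r in regions])
    y = np.array([region_deltas[r] for r in regions])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan"), float("nan")
    r, p = stats.pearsonr(y, x)
    return float(r), float(p)
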