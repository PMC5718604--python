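"""Study orchestration: baseline arm, cohort arm, group statistics."""

import numpy as np
import pandas as pd
import pytest

from flowsuvr import (
    CohortSpec,
    KineticParams,
    StudyConfig,
    anova_tukey,
    compose_global,
    region_scan_table,
    region_vt_correlation,
    run_baseline_study,
    run_cohort_study,
    sample_cohort,
)
from flowsuvr.synth import default_cohort_specs


@pytest.fixture(scope="module")
def small_cfg():
    return StudyConfig(grid_pct=(-40.0, -10.0, 10.0, 40.0, 0.0))


class TestBaselineStudy:
    def test_deterministic_reruns(self, small_cfg):
        a = run_baseline_study(small_cfg)
        b = run_baseline_study(small_cfg)
        for key in a["curves"]:
            np.testing.assert_array_equal(
                a["curves"][key].delta_suvr_pct, b["curves"][key].delta_suvr_pct
            )

    def test_zero_grid_gives_flat_curves(self):
        cfg = StudyConfig(grid_pct=(0.0,))
        res = run_baseline_study(cfg)
        for c in res["curves"].values():
            np.testing.assert_array_equal(c.delta_suvr_pct, 0.0)

    def test_global_curve_is_composition(self, small_cfg):
        res = run_baseline_study(small_cfg)
        ct = res["curves"]["target"].delta_suvr_pct
        for ref in ("CB", "WM"):
            cr = res["curves"][f"reference:{ref}"].delta_suvr_pct
            cg = res["curves"][f"global:{ref}"].delta_suvr_pct
            composed = [compose_global(a, b) for a, b in zip(ct, cr)]
            np.testing.assert_allclose(cg, composed, rtol=1e-9, atol=1e-12)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(target="thalamus")


class TestRegionScan:
    @staticmethod
    def _synthetic_regions():
        # four regions spanning V_T in {3, 6, 9, 12} through binding alone:
        # common K1, k2, k4, Vb, with k3 setting BPND = VT/VND - 1
        regions = {}
        for i, vt in enumerate((3.0, 6.0, 9.0, 12.0)):
            k2, k4, vb = 0.17, 0.02, 0.05
            vnd = 3.0
            bp = vt / vnd - 1.0
            regions[f"r{i}"] = KineticParams(K1=vnd * k2, k2=k2, k3=bp * k4,
                                             k4=k4, Vb=vb)
        return regions

    def test_flow_effect_decreases_with_vt(self, input_function, frames, hc):
        scan = region_scan_table(self._synthetic_regions(), hc["CB"],
                                 input_function, frames, dk1_levels=(-30.0,))
        deltas = dict(zip(scan["region"], scan["delta_suvr_pct_at_-30"]))
        vts = dict(zip(scan["region"], scan["VT"]))
        r, p = region_vt_correlation(deltas, vts)
        assert r < 0
        # the low-binding regions show the larger (positive) flow effect
        assert scan["delta_suvr_pct_at_-30"].iloc[0] > 0

    def test_perfect_anticorrelation(self):
        deltas = {"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}
        vts = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        r, p = region_vt_correlation(deltas, vts)
        assert r == pytest.approx(-1.0)

    def test_degenerate_variance_reported_as_nan(self):
        r, p = region_vt_correlation(
            {"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 1.0, "b": 2.0, "c": 3.0}
        )
        assert np.isnan(r) and np.isnan(p)

    def test_needs_three_regions(self):
        with pytest.raises(ValueError):
            region_vt_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


def _toy_observations():
    """Balanced 2x2 design with known sums of squares (hand-worked)."""
    rows = []
    data = {
        ("g1", -10.0): [1.0, 2.0],
        ("g1", 10.0): [3.0, 4.0],
        ("g2", -10.0): [5.0, 6.0],
        ("g2", 10.0): [7.0, 8.0],
    }
    for (g, k), ys in data.items():
        for y in ys:
            rows.append({"group": g, "dk1_pct": k, "delta_suvr_pct": y})
    return pd.DataFrame(rows)


class TestAnovaTukey:
    def test_identical_groups_give_zero_f(self):
        df = _toy_observations()
        dup = pd.concat(
            [df.assign(group="A"), df.assign(group="B")], ignore_index=True
        )
        res = anova_tukey(dup)
        assert res["group_F"] == pytest.approx(0.0, abs=1e-20)

    def test_hand_worked_two_by_two(self):
        # grand mean 4.5; group means 2.5/6.5 -> SS_group = 8*(2^2) = 32
        # dk1 means 3.5/5.5 -> SS_dk1 = 8; interaction 0; SSE = 4*2*0.25 = 2
        # F_group = (32/1)/(2/4) = 64
        res = anova_tukey(_toy_observations())
        t = res["anova_table"]
        assert t.loc["C(group)", "sum_sq"] == pytest.approx(32.0)
        assert t.loc["C(dk1)", "sum_sq"] == pytest.approx(8.0)
        assert t.loc["C(group):C(dk1)", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert res["group_F"] == pytest.approx(64.0)

    def test_empty_cells_named(self):
        df = _toy_observations()
        df = df[~((df["group"] == "g2") & (df["dk1_pct"] == 10.0))]
        with pytest.raises(ValueError, match="g2"):
            anova_tukey(df)

    def test_permuted_labels_give_uniform_p(self):
        """With group labels shuffled, the group effect p-value should be
        approximately uniform: a calibration check of the test statistic."""
        rng = np.random.default_rng(17)
        n, levels = 8, (-40.0, -10.0, 10.0, 40.0)
        base = pd.DataFrame(
            [
                {"group": "x", "dk1_pct": k, "delta_suvr_pct": -0.2 * k + rng.normal()}
                for k in levels
                for _ in range(n)
            ]
        )
        pvals = []
        for _ in range(200):
            df = base.copy()
            labels = np.array(["A", "B"] * (len(df) // 2))
            rng.shuffle(labels)
            df["group"] = labels
            pvals.append(anova_tukey(df)["group_p"])
        pvals = np.asarray(pvals)
        # loose uniformity checks
        assert 0.01 < (pvals < 0.05).mean() < 0.12
        assert 0.35 < (pvals < 0.5).mean() < 0.65


class TestCohortStudy:
    def test_zero_cv_gives_zero_sd(self, small_cfg):
        spec = CohortSpec(group="HC", n_subjects=3, cv=0.0, cv_vb=0.0,
                          aif_jitter_cv=0.0)
        cohorts = {"HC": sample_cohort(spec, seed=0)}
        res = run_cohort_study(cohorts, small_cfg)
        np.testing.assert_array_equal(res["group_curves"]["HC"].sd, 0.0)
        assert res["anova"] is None  # single group: inference skipped

    def test_group_means_equal_subject_average(self, small_cfg):
        specs = default_cohort_specs(n_hc=4, n_amci=3, n_ad=3)
        cohorts = {g: sample_cohort(s, seed=i) for i, (g, s) in enumerate(specs.items())}
        res = run_cohort_study(cohorts, small_cfg)
        for g, subjects in cohorts.items():
            ids = [s.subject_id for s in subjects]
            mat = np.stack([res["per_subject"][i] for i in ids])
            np.testing.assert_allclose(
                res["group_curves"][g].mean, mat.mean(axis=0), rtol=1e-12
            )

    def test_amyloid_load_damps_flow_effect(self, small_cfg):
        """Groups with higher target k3 (amyloid surrogate) must show smaller
        target dSUVR magnitude at -40% flow, mirroring the HC > AD ordering."""
        specs = default_cohort_specs(n_hc=5, n_amci=3, n_ad=5)
        cohorts = {
            "HC": sample_cohort(specs["HC"], seed=1),
            "AD": sample_cohort(specs["AD"], seed=2),
        }
        res = run_cohort_study(cohorts, small_cfg)
        at = int(np.where(res["group_curves"]["HC"].grid_pct == -40.0)[0][0])
        hc_effect = res["group_curves"]["HC"].mean[at]
        ad_effect = res["group_curves"]["AD"].mean[at]
        assert hc_effect > ad_effect > 0
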