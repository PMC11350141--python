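"""First- and second-level GLM: design construction, beta recovery,
mixed-model contrasts, FDR maps."""

import numpy as np
import pandas as pd
import pytest

from cogvasc import glm
from cogvasc import preprocess as pre
from cogvasc.io import CONDITIONS, Block, TaskDesign
from cogvasc.simulate import simulate_cohort, simulate_fnirs_session

from conftest import noiseless_config


class TestBuildDesign:
    def test_one_column_per_condition(self, design):
        X = glm.build_design(design, 3.9, 1600)
        assert list(X.columns) == list(CONDITIONS)

    def test_regressor_causal(self, design):
        X = glm.build_design(design, 3.9, 1600)
        for b in design.blocks:
            before = X[b.condition].to_numpy()[: int(b.onset_s * 3.9) - 1]
            peak = X[b.condition].abs().max()
            assert np.abs(before).max() < 0.01 * peak

    def test_impulse_hrf_returns_boxcar(self, design):
        X = glm.build_design(design, 3.9, 1600, hrf=np.array([1.0]))
        b = design.blocks[0]
        col = X[b.condition].to_numpy()
        i0 = int(round(b.onset_s * 3.9))
        i1 = int(round((b.onset_s + 72.0) * 3.9))
        assert np.all(col[i0:i1] == 1.0)
        assert col[:i0].sum() == 0 and col[i1:].sum() == 0

    def test_overlapping_blocks_rejected(self):
        bad = TaskDesign(blocks=(
            Block(condition="0b_1", onset_s=0.0),
            Block(condition="1b", onset_s=30.0),
        ))
        with pytest.raises(ValueError, match="overlap"):
            glm.build_design(bad, 3.9, 1000)


class TestFirstLevel:
    def test_planted_amplitude_recovered_exactly(self, design):
        cfg = noiseless_config()
        cohort = simulate_cohort(cfg)
        rec = simulate_fnirs_session(cohort.iloc[0], design, cfg)
        series = pre.nvc_preprocess(rec, motion_correction=False)
        X = glm.build_design(design, rec.fs_hz, rec.n_time)
        bt = glm.first_level(series, X, prewhitening=False)
        est = bt[bt["chromophore"] == "HbO"].pivot(
            index="channel", columns="condition", values="beta"
        )
        truth = rec.ground_truth["amplitude"]
        np.testing.assert_allclose(
            est.loc[truth.index].to_numpy(), truth.to_numpy(), atol=1e-8
        )

    def test_null_betas_unbiased(self, design, rng):
        """Pure-noise channels give mean beta ~ 0 across simulations."""
        X = glm.build_design(design, 3.9, 1500)
        betas = []
        for s in range(60):
            r = np.random.default_rng(s)
            series = pre.ChromophoreSeries(
                hbo=r.standard_normal((2, 1500)) * 0.1,
                hbr=r.standard_normal((2, 1500)) * 0.03,
                fs_hz=3.9, branch="nvc",
            )
            bt = glm.first_level(series, X)
            betas.extend(bt.loc[bt["chromophore"] == "HbO", "beta"])
        mean = np.mean(betas)
        sem = np.std(betas) / np.sqrt(len(betas))
        assert abs(mean) < 3 * sem + 1e-4

    def test_collinear_design_named(self, design, rng):
        X = glm.build_design(design, 3.9, 1500)
        X["dup"] = X["2b"]
        series = pre.ChromophoreSeries(
            hbo=rng.standard_normal((1, 1500)), hbr=rng.standard_normal((1, 1500)),
            fs_hz=3.9,
        )
        with pytest.raises(ValueError, match="rank deficient"):
            glm.first_level(series, X)


def _beta_frame(rng, n_per_group=8, effect=0.0, channels=("ch0",), subject_sd=0.5,
                noise_sd=0.3):
    """Balanced synthetic beta table with an optional MCI 2b effect."""
    rows = []
    for g, n in (("CN", n_per_group), ("MCI", n_per_group)):
        for s in range(n):
            sid = f"{g}{s:02d}"
            b_s = rng.normal(0, subject_sd)
            for ch in channels:
                for c in CONDITIONS:
                    val = b_s + rng.normal(0, noise_sd)
                    if g == "MCI" and c == "2b":
                        val += effect
                    rows.append(dict(
                        subject_id=sid, channel=ch, chromophore="HbO",
                        condition=c, beta=val, se=0.1, dof=100,
                    ))
    betas = pd.DataFrame(rows)
    cohort = betas[["subject_id"]].drop_duplicates()
    cohort["group"] = np.where(
        cohort["subject_id"].str.startswith("CN"), "CN", "MCI"
    )
    return betas, cohort


class TestSecondLevel:
    def test_matches_statsmodels_mixedlm(self, rng):
        """Dual route: closed-form balanced solver vs iterative REML fit."""
        import statsmodels.formula.api as smf

        betas, cohort = _beta_frame(rng, effect=0.4)
        out = glm.second_level(betas, cohort, glm.group_difference_contrast("2b"))
        d = betas.merge(cohort, on="subject_id")
        d["cell"] = d["group"] + ":" + d["condition"]
        fit = smf.mixedlm(
            "beta ~ 0 + C(cell)", d, groups=d["subject_id"]
        ).fit(reml=True)
        cells = sorted(d["cell"].unique())
        L = np.array([
            {"MCI:2b": 1.0, "CN:2b": -1.0}.get(c, 0.0) for c in cells
        ])
        names = [f"C(cell)[{c}]" for c in cells]
        est = L @ fit.fe_params[names].to_numpy()
        se = np.sqrt(L @ fit.cov_params().loc[names, names].to_numpy() @ L)
        assert out["estimate"].iloc[0] == pytest.approx(est, rel=1e-6)
        assert out["t_stat"].iloc[0] == pytest.approx(est / se, rel=1e-3)

    def test_zero_contrast_gives_zero_t(self, rng):
        betas, cohort = _beta_frame(rng)
        contrast = {("MCI", "2b"): 0.0, ("CN", "2b"): 0.0}
        out = glm.second_level(betas, cohort, contrast)
        assert out["t_stat"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == 1.0

    def test_contrast_linearity(self, rng):
        betas, cohort = _beta_frame(rng, effect=0.3)
        c1 = glm.group_difference_contrast("2b")
        c2 = glm.group_difference_contrast("1b")
        csum = {k: c1.get(k, 0) + c2.get(k, 0) for k in set(c1) | set(c2)}
        e1 = glm.second_level(betas, cohort, c1)["estimate"].iloc[0]
        e2 = glm.second_level(betas, cohort, c2)["estimate"].iloc[0]
        es = glm.second_level(betas, cohort, csum)["estimate"].iloc[0]
        assert es == pytest.approx(e1 + e2, rel=1e-9)

    def test_single_subject_group_rejected(self, rng):
        betas, cohort = _beta_frame(rng, n_per_group=1)
        with pytest.raises(ValueError, match=">= 2 subjects"):
            glm.second_level(betas, cohort, glm.group_difference_contrast("2b"))

    def test_planted_effect_power_and_sign(self):
        """20+20 subjects, effect = 2x residual SD in 3 of 12 channels:
        those channels are flagged at q < 0.05 with power > 0.8 over
        replicate cohorts, with the planted (negative) sign."""
        channels = [f"ch{i}" for i in range(12)]
        detected = planted_total = 0
        for rep in range(12):
            rng = np.random.default_rng(rep)
            rows = []
            for g, n in (("CN", 20), ("MCI", 20)):
                for s in range(n):
                    sid = f"{g}{s:02d}"
                    b_s = rng.normal(0, 0.2)
                    for ch in channels:
                        for c in CONDITIONS:
                            val = b_s + rng.normal(0, 0.3)
                            if g == "MCI" and ch in channels[:3]:
                                val -= 0.6  # 2x residual SD
                            rows.append(dict(subject_id=sid, channel=ch,
                                             chromophore="HbO", condition=c,
                                             beta=val, se=0.1, dof=100))
            betas = pd.DataFrame(rows)
            cohort = betas[["subject_id"]].drop_duplicates()
            cohort["group"] = np.where(
                cohort["subject_id"].str.startswith("CN"), "CN", "MCI")
            out = glm.second_level(
                betas, cohort, glm.group_difference_contrast("2b"))
            sub = out.set_index("channel").loc[["ch0", "ch1", "ch2"]]
            detected += int(((sub["significant"]) & (sub["t_stat"] < 0)).sum())
            planted_total += 3
        assert detected / planted_total > 0.8


class TestLoadContrast:
    def test_equal_betas_give_zero(self, rng):
        betas, cohort = _beta_frame(rng, noise_sd=0.0, subject_sd=0.3)
        out = glm.cognitive_load_contrast(betas, cohort, group="CN")
        assert out["t_stat"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_missing_condition_rejected(self, rng):
        betas, cohort = _beta_frame(rng)
        betas = betas[betas["condition"] != "1b"]
        with pytest.raises(ValueError, match="missing conditions"):
            glm.cognitive_load_contrast(betas, cohort, group="CN")

    def test_cn_only_effect_gives_negative_group_difference(self, rng):
        """Load response present only in CN -> MCI-CN load contrast < 0."""
        rows = []
        for g, n in (("CN", 12), ("MCI", 12)):
            for s in range(n):
                sid = f"{g}{s:02d}"
                b_s = rng.normal(0, 0.2)
                for c in CONDITIONS:
                    val = b_s + rng.normal(0, 0.15)
                    if g == "CN" and c in ("1b", "2b"):
                        val += 0.5
                    rows.append(dict(subject_id=sid, channel="F3-F5",
                                     chromophore="HbO", condition=c,
                                     beta=val, se=0.1, dof=100))
        betas = pd.DataFrame(rows)
        cohort = betas[["subject_id"]].drop_duplicates()
        cohort["group"] = np.where(
            cohort["subject_id"].str.startswith("CN"), "CN", "MCI")
        out = glm.cognitive_load_contrast(betas, cohort)  # MCI - CN
        assert out["t_stat"].iloc[0] < -2


class TestLdlpfcAverage:
    def _betas(self, values_by_channel, subject="s0"):
        rows = []
        for ch, v in values_by_channel.items():
            for c in CONDITIONS:
                rows.append(dict(subject_id=subject, channel=ch,
                                 chromophore="HbO", condition=c,
                                 beta=v, se=0.1, dof=10))
        return pd.DataFrame(rows)

    def test_mean_of_three_channels(self, montage):
        betas = self._betas({"F3-F5": 1.0, "F3-F1": 2.0, "F3-FC3": 3.0})
        out = glm.ldlpfc_average(betas, montage)
        assert out["s0"] == pytest.approx(2.0)

    def test_permutation_invariant(self, montage):
        betas = self._betas({"F3-FC3": 3.0, "F3-F5": 1.0, "F3-F1": 2.0})
        shuffled = betas.sample(frac=1.0, random_state=1)
        assert glm.ldlpfc_average(shuffled, montage)["s0"] == pytest.approx(2.0)

    def test_missing_ldlpfc_channel_excluded(self, montage):
        betas = self._betas({"F3-F5": 1.0, "F3-F1": 2.0})
        with pytest.raises(ValueError, match="missing LDLPFC"):
            glm.ldlpfc_average(betas, montage)
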