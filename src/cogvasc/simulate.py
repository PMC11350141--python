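"""Synthetic cohorts with planted group effects.

Generates every input the analysis consumes — fNIRS sessions, behavioral
trial tables, EV event tables, and a demographics/cohort table — from a
single seeded configuration, so each downstream stage can be tested
without any external data.

The forward fNIRS model inverts the analysis chain: per-channel ground
truth ΔHbO is (boxcar ⊛ canonical HRF) x a group/region/condition
amplitude, plus shared band-limited fluctuations carrying the functional
connectivity structure, physiological oscillations, drift, AR(1) noise,
and optional motion artifacts; ΔHbR is -1/3 x ΔHbO plus independent
noise.  Chromophores are pushed through the same extinction-coefficient
forward model the analysis inverts (ΔOD, then I = I0·10^(-ΔOD)).

Planted effect directions mirror the study conditions: reduced LDLPFC
task amplitude and LDLPFC coupling in the MCI group, elevated CEEV
fraction, impaired 2-back performance.  Magnitudes are documented in
docs/methods.md.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sig

from .cytometry import CHANNELS, EvEventTable
from .hrf import convolve_boxcar
from .io import CONDITIONS, FnirsRecording, TaskDesign
from .montage import Montage, default_montage
from .preprocess import mbll_forward

__all__ = [
    "SimConfig",
    "subseed",
    "simulate_cohort",
    "simulate_fnirs_session",
    "simulate_behavior",
    "simulate_ev_sample",
]


def subseed(master: int, *parts) -> int:
    """Deterministic child seed (< 2^31) from a master seed and labels."""
    text = ":".join(str(p) for p in parts)
    return (int(master) * 2654435761 + zlib.crc32(text.encode())) % (2**31 - 1)


def _amp_defaults() -> dict:
    # (group, region) -> condition -> μM amplitude at the regressor peak
    return {
        ("CN", "LDLPFC"): {"0b_1": 0.30, "0b_2": 0.30, "1b": 0.45, "2b": 0.55},
        ("MCI", "LDLPFC"): {"0b_1": 0.18, "0b_2": 0.18, "1b": 0.22, "2b": 0.25},
        ("CN", "other"): {c: 0.20 for c in CONDITIONS},
        ("MCI", "other"): {c: 0.20 for c in CONDITIONS},
    }


def _coupling_defaults() -> dict:
    # (group, region) -> latent-factor mixing weight; pairwise HbO
    # correlation of the shared fluctuation is sqrt(w_i * w_j)
    # "reference" is a homotopic right-DLPFC pair with strong, group-
    # independent coupling; it anchors the graph's maximum edge weight so
    # the strength normalization is stable across groups.
    return {
        ("CN", "LDLPFC"): 0.75,
        ("MCI", "LDLPFC"): 0.55,
        ("CN", "other"): 0.40,
        ("MCI", "other"): 0.40,
        ("CN", "reference"): 0.90,
        ("MCI", "reference"): 0.90,
    }


def _behavior_defaults() -> dict:
    hit = {
        "CN": {"0b_1": 0.95, "0b_2": 0.95, "1b": 0.92, "2b": 0.85},
        "MCI": {"0b_1": 0.93, "0b_2": 0.93, "1b": 0.85, "2b": 0.65},
    }
    fa = {
        "CN": {"0b_1": 0.02, "0b_2": 0.02, "1b": 0.03, "2b": 0.05},
        "MCI": {"0b_1": 0.03, "0b_2": 0.03, "1b": 0.06, "2b": 0.12},
    }
    rt = {
        "CN": {"0b_1": 520.0, "0b_2": 520.0, "1b": 580.0, "2b": 640.0},
        "MCI": {"0b_1": 560.0, "0b_2": 560.0, "1b": 640.0, "2b": 780.0},
    }
    return {"hit_p": hit, "fa_p": fa, "rt_mean_ms": rt, "rt_sd_ms": 130.0}


def _ev_defaults() -> dict:
    return {
        # subject-level CEEV fraction ~ Normal(mean, sd) truncated to (0.005, 0.6)
        "ceev_fraction": {"CN": (0.055, 0.025), "MCI": (0.13, 0.05)},
        # event-class mixture weights (endothelial weight split by fraction)
        "class_weights": {
            "debris": 0.30, "platelet": 0.18, "lymphocyte": 0.12,
            "endothelial": 0.25, "mal_other": 0.15,
        },
        "n_events": 50_000,
        "n_events_fmo": 10_000,
        "n_aliquots": 2,
        "dilution_factor": 200.0,
        # log10 fluorescence intensities
        "neg_mean": 2.0, "pos_mean": 3.4, "log_sd": 0.25,
        # diameter log-normal (median nm, sigma of log), clipped to 80-1300
        "diameter_median_nm": 160.0, "diameter_log_sd": 0.6,
    }


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort."""

    n_cn: int = 20
    n_mci: int = 20
    seed: int = 0
    hrf_amplitude: dict = field(default_factory=_amp_defaults)
    amplitude_subject_sd: float = 0.10  # μM, subject offset on LDLPFC amplitudes
    fc_coupling: dict = field(default_factory=_coupling_defaults)
    fc_reference_labels: tuple[str, ...] = ("F4-F6", "F4-F2")
    fc_coupling_subject_sd: float = 0.05  # subject-level jitter on the weights
    fc_signal_amp: float = 0.15  # μM SD of the shared slow fluctuation
    noise: dict = field(default_factory=lambda: {
        "white_sd": 0.03, "ar1_phi": 0.4, "cardiac_amp": 0.10,
        "cardiac_hz": 1.0, "respiration_amp": 0.05, "respiration_hz": 0.25,
        "mayer_amp": 0.05, "mayer_hz": 0.1, "drift_amp": 0.10,
    })
    motion: dict = field(default_factory=lambda: {
        "spike_rate_per_min": 0.0, "spike_amp": 1.0, "shift_prob": 0.0,
    })
    behavior: dict = field(default_factory=_behavior_defaults)
    ev: dict = field(default_factory=_ev_defaults)
    fazekas_ceev_rho: float = 0.7
    montage: Montage = field(default_factory=default_montage)
    fs_hz: float = 3.9

    def __post_init__(self) -> None:
        if self.n_cn < 1 or self.n_mci < 1:
            raise ValueError("subject counts must be >= 1")
        for w in self.fc_coupling.values():
            if not 0 <= w < 1:
                raise ValueError("coupling weights must be in [0, 1)")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Cohort table with demographics, comorbidities, and latent CEEV truth.

    Ages are Normal(~71, 7) truncated at 50; comorbidity rates are
    group-specific; the Fazekas grade (MCI arm) is tied to the subject's
    latent CEEV propensity so the planted ordinal association is
    recoverable.
    """
    rng = np.random.default_rng(subseed(config.seed, "cohort"))
    rows = []
    age_params = {"CN": (70.8, 6.6), "MCI": (71.2, 8.0)}
    female_p = {"CN": 0.75, "MCI": 0.50}
    htn_p = {"CN": 0.30, "MCI": 0.55}
    dep_p = {"CN": 0.10, "MCI": 0.30}
    fluid = {"CN": (57.1, 8.27), "MCI": (38.45, 11.82)}
    rho = config.fazekas_ceev_rho
    for group, n in (("CN", config.n_cn), ("MCI", config.n_mci)):
        mu_a, sd_a = age_params[group]
        mu_c, sd_c = config.ev["ceev_fraction"][group]
        for i in range(n):
            age = 0.0
            while age < 50.0:
                age = rng.normal(mu_a, sd_a)
            z_ceev = rng.standard_normal()
            frac = float(np.clip(mu_c + sd_c * z_ceev, 0.005, 0.6))
            if group == "MCI":
                latent = rho * z_ceev + np.sqrt(1 - rho**2) * rng.standard_normal()
                fazekas = int(np.clip(round(1.19 + 0.8 * latent), 0, 3))
            else:
                fazekas = np.nan
            rows.append({
                "subject_id": f"{group}{i:03d}",
                "group": group,
                "age": round(float(age), 1),
                "sex": "F" if rng.random() < female_p[group] else "M",
                "hypertension": int(rng.random() < htn_p[group]),
                "depression_prior": int(rng.random() < dep_p[group]),
                "fazekas": fazekas,
                "fluid_composite": round(float(rng.normal(*fluid[group])), 1),
                "ceev_fraction_true": frac,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fNIRS forward model
# ---------------------------------------------------------------------------

def _lowpass_noise(rng, n_ch: int, n_t: int, fs: float, cutoff: float = 0.4):
    """Unit-variance band-limited Gaussian processes (slow fluctuations)."""
    w = rng.standard_normal((n_ch, n_t))
    sos = sig.butter(4, cutoff, btype="low", fs=fs, output="sos")
    x = sig.sosfiltfilt(sos, w, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_fnirs_session(
    subject: pd.Series | dict,
    design: TaskDesign,
    config: SimConfig,
    seed: int | None = None,
) -> FnirsRecording:
    """Forward-simulate one dual-wavelength session for a subject.

    The returned recording's ``ground_truth`` dict carries the planted
    per-channel condition amplitudes and coupling weights for recovery
    tests.
    """
    group = subject["group"]
    if seed is None:
        seed = subseed(config.seed, "fnirs", subject["subject_id"])
    rng = np.random.default_rng(seed)
    montage = config.montage
    fs = config.fs_hz
    n_ch = montage.n_channels
    n_t = int(round((design.duration_s + 30.0) * fs))
    ldl = set(montage.ldlpfc_indices())
    region = np.array(["LDLPFC" if i in ldl else "other" for i in range(n_ch)])

    # task-evoked component, per condition regressor shared with the GLM
    subj_offset = {
        "LDLPFC": rng.normal(0.0, config.amplitude_subject_sd),
        "other": rng.normal(0.0, config.amplitude_subject_sd / 2.0),
    }
    amp = np.zeros((n_ch, len(CONDITIONS)))
    hbo = np.zeros((n_ch, n_t))
    regressors = {}
    for j, cond in enumerate(CONDITIONS):
        blk = design.block(cond)
        reg = convolve_boxcar([blk.onset_s], [blk.duration_s], n_t, fs)
        regressors[cond] = reg
        for i in range(n_ch):
            a = config.hrf_amplitude[(group, region[i])][cond] + subj_offset[region[i]]
            amp[i, j] = max(a, 0.0)
            hbo[i] += amp[i, j] * reg

    # shared slow fluctuations carrying the FC structure:
    # s_i = sqrt(w_i) g + sqrt(1 - w_i) eta_i  =>  corr(s_i, s_j) = sqrt(w_i w_j)
    ref = set(config.fc_reference_labels) & set(montage.labels)
    fc_region = np.array([
        "reference" if montage.labels[i] in ref else region[i]
        for i in range(n_ch)
    ])
    w = np.array([
        config.fc_coupling.get((group, r), config.fc_coupling[(group, "other")])
        for r in fc_region
    ])
    if config.fc_coupling_subject_sd:
        jitter = {
            r: rng.normal(0.0, config.fc_coupling_subject_sd)
            for r in ("LDLPFC", "other", "reference")
        }
        w = np.clip(w + np.array([jitter[r] for r in fc_region]), 0.0, 0.98)
    g = _lowpass_noise(rng, 1, n_t, fs)[0]
    eta = _lowpass_noise(rng, n_ch, n_t, fs)
    fluct = np.sqrt(w)[:, None] * g[None, :] + np.sqrt(1.0 - w)[:, None] * eta
    hbo = hbo + config.fc_signal_amp * fluct

    # neural-vascular component: HbR tracks -1/3 of HbO
    hbr = -hbo / 3.0

    # systemic physiology (blood-volume driven: same sign in both
    # chromophores) — oscillations with random phase per channel, drift
    t = np.arange(n_t) / fs
    nz = config.noise
    systemic = np.zeros((n_ch, n_t))
    for amp_key, f_key in (
        ("cardiac_amp", "cardiac_hz"),
        ("respiration_amp", "respiration_hz"),
        ("mayer_amp", "mayer_hz"),
    ):
        a = nz[amp_key]
        if a > 0:
            phases = rng.uniform(0, 2 * np.pi, n_ch)
            systemic += a * np.sin(2 * np.pi * nz[f_key] * t[None, :] + phases[:, None])
    if nz["drift_amp"] > 0:
        slope = rng.normal(0.0, nz["drift_amp"], n_ch)
        systemic += slope[:, None] * (t[None, :] / t[-1])
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        systemic += nz["drift_amp"] * np.sin(
            2 * np.pi * 0.002 * t[None, :] + phases[:, None]
        )
    hbo = hbo + systemic
    hbr = hbr + 0.3 * systemic

    # AR(1) measurement noise, independent per chromophore
    if nz["white_sd"] > 0:
        phi = nz["ar1_phi"]
        for target, scale in ((hbo, 1.0), (hbr, 1.0 / 3.0)):
            e = rng.standard_normal((n_ch, n_t)) * nz["white_sd"] * scale
            if phi:
                e = sig.lfilter([1.0], [1.0, -phi], e, axis=-1) * np.sqrt(1 - phi**2)
            target += e

    # motion artifacts: common-mode spikes and baseline shifts
    mo = config.motion
    n_spikes = rng.poisson(mo["spike_rate_per_min"] * n_t / fs / 60.0)
    for _ in range(n_spikes):
        idx = rng.integers(5, n_t - 5)
        width = rng.integers(1, 4)
        a = mo["spike_amp"] * rng.choice([-1.0, 1.0])
        hbo[:, idx:idx + width] += a
        hbr[:, idx:idx + width] += a * 0.8
    if rng.random() < mo["shift_prob"]:
        idx = rng.integers(n_t // 4, 3 * n_t // 4)
        shift = mo["spike_amp"] * rng.choice([-1.0, 1.0])
        hbo[:, idx:] += shift
        hbr[:, idx:] += shift * 0.8

    od = mbll_forward(hbo, hbr, montage, wavelengths_nm=(760.0, 850.0))
    intensities = 10.0 ** (-od)  # I0 = 1
    rec = FnirsRecording(
        intensities=intensities, wavelengths_nm=(760.0, 850.0), fs_hz=fs,
        montage=montage,
        ground_truth={
            "amplitude": pd.DataFrame(amp, index=montage.labels, columns=CONDITIONS),
            "coupling": dict(zip(montage.labels, w)),
            "hbo": hbo, "hbr": hbr,
        },
    )
    return rec


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(
    subject: pd.Series | dict,
    design: TaskDesign,
    config: SimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Trial-level responses: Bernoulli(hit_p) on targets, Bernoulli(fa_p)
    on non-targets; RTs truncated-Normal for responded trials."""
    group = subject["group"]
    if seed is None:
        seed = subseed(config.seed, "behavior", subject["subject_id"])
    rng = np.random.default_rng(seed)
    beh = config.behavior
    rows = []
    for block in design.blocks:
        hit_p = beh["hit_p"][group][block.condition]
        fa_p = beh["fa_p"][group][block.condition]
        rt_mu = beh["rt_mean_ms"][group][block.condition]
        rt_sd = beh["rt_sd_ms"]
        for k, trial in enumerate(block.trials):
            p = hit_p if trial.is_target else fa_p
            responded = bool(rng.random() < p)
            rt = np.nan
            if responded:
                rt = -1.0
                while rt < 150.0:  # physiological floor
                    rt = rng.normal(rt_mu, rt_sd)
            rows.append({
                "subject_id": subject["subject_id"],
                "condition": block.condition,
                "trial": k,
                "stimulus": trial.stimulus,
                "is_target": trial.is_target,
                "responded": responded,
                "rt_ms": round(float(rt), 1) if responded else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EV event tables
# ---------------------------------------------------------------------------

_CLASS_POSITIVITY = {
    # class -> channels that are positive
    "debris": (),
    "platelet": ("lymph_platelet_ch",),
    "lymphocyte": ("lymph_platelet_ch",),
    "endo_mal_neg": ("endo_ch",),
    "endo_mal_pos": ("endo_ch", "mal_ch"),
    "mal_other": ("mal_ch",),
}


def _draw_events(rng, n: int, weights: dict[str, float], ev_cfg: dict,
                 omit_stain: str | None = None) -> tuple[pd.DataFrame, pd.Series]:
    classes = list(weights)
    p = np.asarray([weights[c] for c in classes], dtype=float)
    p = p / p.sum()
    label_idx = rng.choice(len(classes), size=n, p=p)
    labels = pd.Series(np.asarray(classes, dtype=object)[label_idx], name="true_class")
    cols = {}
    for ch in CHANNELS:
        mean = np.full(n, ev_cfg["neg_mean"])
        if omit_stain != ch:
            pos_by_class = np.array([ch in _CLASS_POSITIVITY[c] for c in classes])
            mean = np.where(pos_by_class[label_idx], ev_cfg["pos_mean"], ev_cfg["neg_mean"])
        cols[ch] = rng.normal(mean, ev_cfg["log_sd"])
    diam = np.exp(
        rng.normal(np.log(ev_cfg["diameter_median_nm"]), ev_cfg["diameter_log_sd"], n)
    )
    cols["diameter_nm"] = np.clip(diam, 80.0, 1300.0)
    return pd.DataFrame(cols), labels


def simulate_ev_sample(
    subject: pd.Series | dict,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[list[EvEventTable], dict[str, EvEventTable]]:
    """Stained aliquot tables plus one FMO control table per channel.

    The subject's ground-truth CEEV fraction splits the endothelial class
    into MAL+ (CEEV) and MAL- subclasses.  Acquisition metadata: 1.5
    μL/min for 120 s at the configured dilution.
    """
    if seed is None:
        seed = subseed(config.seed, "ev", subject["subject_id"])
    rng = np.random.default_rng(seed)
    ev_cfg = config.ev
    frac = float(subject.get("ceev_fraction_true", ev_cfg["ceev_fraction"][subject["group"]][0]))
    cw = dict(ev_cfg["class_weights"])
    endo = cw.pop("endothelial")
    weights = {**cw, "endo_mal_pos": endo * frac, "endo_mal_neg": endo * (1 - frac)}
    meta = dict(dilution_factor=ev_cfg["dilution_factor"])
    stained = []
    for a in range(ev_cfg["n_aliquots"]):
        events, labels = _draw_events(rng, ev_cfg["n_events"], weights, ev_cfg)
        stained.append(EvEventTable(
            events=events, ground_truth=labels,
            sample_id=f"{subject['subject_id']}-aliquot{a}", **meta,
        ))
    fmo = {}
    for ch in CHANNELS:
        events, labels = _draw_events(
            rng, ev_cfg["n_events_fmo"], weights, ev_cfg, omit_stain=ch
        )
        fmo[ch] = EvEventTable(
            events=events, ground_truth=labels,
            sample_id=f"{subject['subject_id']}-fmo-{ch}", **meta,
        )
    return stained, fmo
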