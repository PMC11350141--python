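"""Neurovascular-coupling GLM: first-level betas and second-level contrasts.

First level: per channel and chromophore, ordinary least squares on
AR-prewhitened data against one HRF-convolved boxcar regressor per n-back
condition, yielding a tidy beta table (subject x channel x chromophore x
condition).

Second level: per channel, a mixed model with fixed group-by-condition
cell means (no intercept) and a subject random intercept; contrasts are
evaluated by t tests and the channel family is corrected by
Benjamini-Hochberg FDR (significant at q < 0.05).

For balanced designs (every subject contributes every condition — the
normal case here) the mixed model is solved in closed form via split-plot
ANOVA variance components, which coincide with REML on balanced data;
Satterthwaite's approximation supplies the degrees of freedom.
Unbalanced inputs fall back to an iterative mixed-model fit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CONDITIONS, TaskDesign
from .montage import Montage
from .preprocess import ChromophoreSeries, prewhiten
from .stats import fdr_bh

__all__ = [
    "build_design",
    "first_level",
    "second_level",
    "group_difference_contrast",
    "cognitive_load_contrast",
    "ldlpfc_average",
]


def build_design(
    design: TaskDesign,
    fs_hz: float,
    n_time: int,
    hrf: np.ndarray | None = None,
) -> pd.DataFrame:
    """One regressor per condition: boxcar convolved with the canonical HRF.

    Columns are labeled by condition.  Overlapping blocks are rejected.
    """
    from .hrf import convolve_boxcar

    blocks = sorted(design.blocks, key=lambda b: b.onset_s)
    for b1, b2 in zip(blocks, blocks[1:]):
        if b1.onset_s + b1.duration_s > b2.onset_s:
            raise ValueError(
                f"blocks {b1.condition} and {b2.condition} overlap in time"
            )
    if blocks[-1].onset_s >= n_time / fs_hz:
        raise ValueError("block onset beyond the end of the record")
    cols = {}
    for b in design.blocks:
        cols[b.condition] = convolve_boxcar(
            [b.onset_s], [b.duration_s], n_time, fs_hz, hrf=hrf
        )
    return pd.DataFrame(cols)


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns via QR pivoting
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] < 1e-10 * diag.max()]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def first_level(
    series: ChromophoreSeries,
    design_matrix: pd.DataFrame,
    subject_id: str = "",
    order_max: int = 4,
    prewhitening: bool = True,
) -> pd.DataFrame:
    """Per-channel, per-chromophore OLS betas on (optionally) prewhitened data.

    Returns a tidy frame: subject_id, channel, chromophore, condition,
    beta, se, dof.
    """
    if series.branch == "fc":
        raise ValueError("first_level expects the NVC branch, not FC")
    _check_rank(design_matrix)
    X0 = design_matrix.to_numpy()
    if series.dct_cutoff_hz:
        # the data were DCT high-pass filtered: apply the identical
        # projection to the design, else betas are attenuated
        from .preprocess import dct_highpass

        X0 = dct_highpass(X0.T, series.fs_hz, series.dct_cutoff_hz).T
    labels = series.channel_labels or tuple(
        f"ch{i}" for i in range(series.hbo.shape[0])
    )
    rows = []
    for chrom, data in (("HbO", series.hbo), ("HbR", series.hbr)):
        for i, label in enumerate(labels):
            y = data[i]
            if prewhitening:
                yw, Xw, _ = prewhiten(y, X0, order_max=order_max)
            else:
                yw, Xw = y, X0
            beta, res, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
            dof = yw.size - Xw.shape[1]
            resid = yw - Xw @ beta
            sigma2 = resid @ resid / dof
            cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
            se = np.sqrt(np.diag(cov))
            for j, cond in enumerate(design_matrix.columns):
                rows.append({
                    "subject_id": subject_id, "channel": label,
                    "chromophore": chrom, "condition": cond,
                    "beta": float(beta[j]), "se": float(max(se[j], 1e-12)),
                    "dof": int(dof),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# second level
# ---------------------------------------------------------------------------

def _balanced_cell_contrast(
    y: np.ndarray, groups: np.ndarray, conditions: list[str], contrast: dict
) -> tuple[float, float, float]:
    """Closed-form split-plot contrast on group x condition cell means.

    ``y`` is subjects x conditions (balanced).  Returns (estimate, t, dof);
    p follows from the t distribution.
    """
    uniq = list(dict.fromkeys(groups))
    n_s, n_c = y.shape
    subj_mean = y.mean(axis=1)
    est = 0.0
    a = b = 0.0  # var(contrast) = a*MS_between + b*MS_within
    ss_b = 0.0
    ss_w = 0.0
    for g in uniq:
        sel = groups == g
        n_g = int(sel.sum())
        cell = y[sel].mean(axis=0)  # per-condition cell means
        gmean = subj_mean[sel].mean()
        ss_b += n_c * ((subj_mean[sel] - gmean) ** 2).sum()
        ss_w += ((y[sel] - subj_mean[sel][:, None] - cell[None, :] + gmean) ** 2).sum()
        L = np.array([contrast.get((g, c), 0.0) for c in conditions])
        est += float(L @ cell)
        S, Qd = L.sum(), float(L @ L)
        a += S**2 / (n_c * n_g)
        b += (Qd - S**2 / n_c) / n_g
    df_b = n_s - len(uniq)
    df_w = df_b * (n_c - 1)
    if df_b <= 0 or df_w <= 0:
        return est, np.nan, np.nan
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    var = a * ms_b + b * ms_w
    if var <= 0:
        return est, 0.0, float(df_w)
    num = var**2
    den = 0.0
    if a > 0:
        den += (a * ms_b) ** 2 / df_b
    if b > 0:
        den += (b * ms_w) ** 2 / df_w
    dof = num / den if den > 0 else df_w
    return est, est / np.sqrt(var), float(dof)


def _mixedlm_cell_contrast(
    long: pd.DataFrame, contrast: dict
) -> tuple[float, float, float]:
    """Unbalanced fallback: REML mixed model with cell-mean fixed effects
    and a subject random intercept (statsmodels)."""
    import statsmodels.formula.api as smf

    d = long.copy()
    d["cell"] = list(zip(d["group"], d["condition"]))
    cells = sorted(set(d["cell"]))
    d["cell"] = pd.Categorical(d["cell"], categories=cells)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "beta ~ 0 + C(cell)", data=d, groups=d["subject_id"]
        )
        fit = model.fit(reml=True)
    L = np.array([contrast.get(c, 0.0) for c in cells])
    est = float(L @ fit.fe_params.to_numpy())
    var = float(L @ fit.cov_params().iloc[: len(cells), : len(cells)].to_numpy() @ L)
    dof = float(d["subject_id"].nunique() - d["group"].nunique())
    if var <= 0:
        return est, 0.0, dof
    return est, est / np.sqrt(var), dof


def second_level(
    betas: pd.DataFrame,
    cohort: pd.DataFrame,
    contrast: dict,
    chromophore: str = "HbO",
    alpha_q: float = 0.05,
) -> pd.DataFrame:
    """Channel-wise mixed-model contrast map with BH-FDR q-values.

    ``contrast`` maps (group, condition) cells to weights, e.g.
    ``{("MCI", "2b"): 1, ("CN", "2b"): -1}``.  Channels whose fit is
    singular are flagged and excluded from the FDR family.
    """
    d = betas[betas["chromophore"] == chromophore]
    d = d.drop(columns=[c for c in ("group",) if c in d.columns]).merge(
        cohort[["subject_id", "group"]], on="subject_id"
    )
    groups_in_contrast = {g for g, _ in contrast}
    for g in groups_in_contrast:
        n_g = d.loc[d["group"] == g, "subject_id"].nunique()
        if len(groups_in_contrast) > 1 and n_g < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r} for group contrasts")
    conditions = [c for c in CONDITIONS if c in set(d["condition"])]
    rows = []
    for channel, sub in d.groupby("channel", sort=False):
        pivot = sub.pivot_table(
            index="subject_id", columns="condition", values="beta"
        )
        balanced = not pivot.isna().any().any() and set(pivot.columns) == set(conditions)
        grp = (
            sub.drop_duplicates("subject_id").set_index("subject_id")["group"]
        )
        try:
            if balanced:
                y = pivot[conditions].to_numpy()
                groups = grp.loc[pivot.index].to_numpy()
                est, t, dof = _balanced_cell_contrast(y, groups, conditions, contrast)
            else:
                est, t, dof = _mixedlm_cell_contrast(sub, contrast)
        except Exception as e:  # singular fit
            warnings.warn(f"channel {channel}: singular fit ({e}); excluded from FDR")
            est, t, dof = np.nan, np.nan, np.nan
        if np.isnan(t):
            p = np.nan
        elif t == 0.0:
            p = 1.0
        else:
            p = float(2.0 * sps.t.sf(abs(t), dof))
        rows.append({
            "channel": channel, "estimate": est, "t_stat": t,
            "dof": dof, "p_value": p,
        })
    out = pd.DataFrame(rows)
    qv, reject = fdr_bh(out["p_value"].to_numpy(), q=alpha_q)
    out["q_value"] = qv
    out["significant"] = reject
    out.attrs["contrast"] = dict(contrast)
    out.attrs["chromophore"] = chromophore
    return out


def group_difference_contrast(condition: str) -> dict:
    """MCI - CN on one condition cell."""
    return {("MCI", condition): 1.0, ("CN", condition): -1.0}


def cognitive_load_contrast(
    betas: pd.DataFrame,
    cohort: pd.DataFrame,
    group: str | None = None,
    chromophore: str = "HbO",
    baseline: str = "0b_2",
) -> pd.DataFrame:
    """Cognitive-load contrast (2b + 1b) - 2x baseline (sum-zero weights).

    With ``group`` given, a within-group paired contrast; with ``group=None``,
    the MCI - CN difference of the load contrast.
    """
    present = set(betas["condition"])
    needed = {"2b", "1b", baseline}
    if not needed <= present:
        raise ValueError(f"missing conditions: {sorted(needed - present)}")
    weights = {"2b": 1.0, "1b": 1.0, baseline: -2.0}
    if group is not None:
        contrast = {(group, c): w for c, w in weights.items()}
    else:
        contrast = {("MCI", c): w for c, w in weights.items()}
        contrast.update({("CN", c): -w for c, w in weights.items()})
    return second_level(betas, cohort, contrast, chromophore=chromophore)


def ldlpfc_average(
    betas: pd.DataFrame,
    montage: Montage,
    chromophore: str = "HbO",
    conditions: list[str] | None = None,
) -> pd.Series:
    """Per-subject LDLPFC scalar: HbO beta averaged over the three LDLPFC
    channels and (by default) over all conditions.

    A subject missing any LDLPFC channel is excluded with an error, per
    the quality-screen rule.
    """
    ldl = list(montage.ldlpfc_labels)
    d = betas[
        (betas["chromophore"] == chromophore) & betas["channel"].isin(ldl)
    ]
    if conditions is not None:
        d = d[d["condition"].isin(conditions)]
    out = {}
    for sid, sub in d.groupby("subject_id"):
        have = set(sub["channel"])
        if have != set(ldl):
            raise ValueError(
                f"subject {sid}: missing LDLPFC channel(s) {sorted(set(ldl) - have)}"
            )
        out[sid] = float(sub["beta"].mean())
    return pd.Series(out, name="ldlpfc_beta")
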