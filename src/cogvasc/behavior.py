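"""Signal-detection performance (d') and reaction times per n-back block.

d' = z(hit rate) - z(false-alarm rate), with z the standard-normal
quantile.  Extreme rates (0 or 1) are corrected before the z transform
so d' stays finite; the default is the 1/(2N) rule, a log-linear
(add 0.5 to every cell) alternative is available.  Reaction times are
averaged over correct responses only — responded hits; correct
rejections contribute no RT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

__all__ = ["BlockPerformance", "rates", "d_prime", "mean_rt", "block_performance"]


@dataclass
class BlockPerformance:
    condition: str
    n_targets: int
    n_nontargets: int
    hits: int
    false_alarms: int
    hit_rate: float
    fa_rate: float
    d_prime: float
    mean_rt_correct_ms: float | None


def rates(
    trials: pd.DataFrame, correction: str = "half-count"
) -> tuple[float, float, dict[str, int]]:
    """Hit and false-alarm rates from a trial table.

    Expects boolean columns ``is_target`` and ``responded``.  Raw rates
    are hits/n_targets and FA/n_nontargets; rates of exactly 0 or 1 are
    pulled into the open interval before any z transform:
    ``half-count`` (default) replaces 0 with 1/(2N) and 1 with 1-1/(2N);
    ``log-linear`` adds 0.5 to each count and 1 to each denominator.
    """
    tgt = trials["is_target"].to_numpy(dtype=bool)
    resp = trials["responded"].to_numpy(dtype=bool)
    n_t = int(tgt.sum())
    n_nt = int((~tgt).sum())
    if n_t == 0 or n_nt == 0:
        raise ValueError("need at least one target and one non-target trial")
    hits = int((tgt & resp).sum())
    fas = int((~tgt & resp).sum())
    counts = {
        "n_targets": n_t, "n_nontargets": n_nt,
        "hits": hits, "false_alarms": fas,
    }
    if correction == "log-linear":
        hr = (hits + 0.5) / (n_t + 1.0)
        fr = (fas + 0.5) / (n_nt + 1.0)
    elif correction == "half-count":
        hr = hits / n_t
        fr = fas / n_nt
        if hr == 0.0:
            hr = 1.0 / (2 * n_t)
        elif hr == 1.0:
            hr = 1.0 - 1.0 / (2 * n_t)
        if fr == 0.0:
            fr = 1.0 / (2 * n_nt)
        elif fr == 1.0:
            fr = 1.0 - 1.0 / (2 * n_nt)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return hr, fr, counts


def d_prime(hit_rate: float, fa_rate: float) -> float:
    """d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate)."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must lie in (0, 1); apply extreme-rate correction")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def mean_rt(trials: pd.DataFrame) -> float | None:
    """Mean RT (ms) over correct responses (responded targets)."""
    correct = trials["is_target"].to_numpy(dtype=bool) & trials["responded"].to_numpy(
        dtype=bool
    )
    rts = trials.loc[correct, "rt_ms"].dropna()
    if rts.empty:
        warnings.warn("no correct responses; mean RT undefined")
        return None
    return float(rts.mean())


def block_performance(
    trials: pd.DataFrame, condition: str | None = None, correction: str = "half-count"
) -> BlockPerformance:
    """Full per-block summary for one condition's trials."""
    if condition is not None:
        trials = trials[trials["condition"] == condition]
    elif "condition" in trials.columns and trials["condition"].nunique() == 1:
        condition = str(trials["condition"].iloc[0])
    hr, fr, counts = rates(trials, correction=correction)
    return BlockPerformance(
        condition=condition or "",
        hit_rate=hr, fa_rate=fr, d_prime=d_prime(hr, fr),
        mean_rt_correct_ms=mean_rt(trials), **counts,
    )
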