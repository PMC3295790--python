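"""Expression-change filter on probe-level microarray signals.

Three independent gates select differentially expressed probes between
two sample groups (parental vs generation-5 cells): (1) a detection
gate — at least one group must have fraction presence >= 0.5, where
detection calls score P = 1, M = 0.5, A = 0; (2) a Welch t-test on the
log-transformed signals at p < 0.01; (3) a fold-change gate, by default
|log2 fold change| >= 1.2 (a linear-scale mode interprets the cutoff as
a plain ratio instead). All three quantities are reported for every
probe regardless of pass status.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CALL_SCORES", "fraction_presence", "filter_degs"]

CALL_SCORES = {"P": 1.0, "M": 0.5, "A": 0.0}


def fraction_presence(calls) -> float:
    """Mean detection score of one group's calls (P=1, M=0.5, A=0)."""
    calls = list(calls)
    if not calls:
        raise ValueError("empty call group")
    try:
        return float(np.mean([CALL_SCORES[c] for c in calls]))
    except KeyError as exc:
        raise ValueError(f"invalid detection call {exc.args[0]!r}") from None


def filter_degs(
    signals: pd.DataFrame,
    calls: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    group_order: tuple[str, str] | None = None,
    presence_min: float = 0.5,
    p_max: float = 0.01,
    lfc_min: float = 1.2,
    fold_scale: str = "log2",
) -> pd.DataFrame:
    """Apply the three-gate filter to a probes x samples signal matrix.

    ``signals`` holds log2 signals (probe index, sample columns);
    ``calls`` the congruent P/M/A matrix; ``groups`` maps sample to
    group label. ``group_order`` fixes (reference, treatment) so that
    log2_fc = mean(treatment) - mean(reference); by default the two
    group labels are taken in sorted order. With
    ``fold_scale='linear'`` the fold-change gate is
    ratio >= lfc_min or ratio <= 1/lfc_min on the linear scale.

    Probes with zero within-group variance in both groups have an
    undefined p-value: they are flagged (``p_value`` NaN) and excluded
    from the passing set.
    """
    if signals.shape != calls.shape or not signals.columns.equals(calls.columns):
        raise ValueError("signal and call matrices must be congruent")
    if fold_scale not in ("log2", "linear"):
        raise ValueError(f"fold_scale must be log2|linear, got {fold_scale!r}")
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    labels = sorted(groups.unique()) if group_order is None else list(group_order)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    cols = {lab: [s for s in signals.columns if groups.get(s) == lab] for lab in labels}
    for lab, cs in cols.items():
        if len(cs) < 2:
            raise ValueError(f"group {lab!r} needs >= 2 samples, got {len(cs)}")

    ref, trt = labels
    x_ref = signals[cols[ref]].to_numpy(float)
    x_trt = signals[cols[trt]].to_numpy(float)
    frac_ref = calls[cols[ref]].apply(lambda row: fraction_presence(row), axis=1)
    frac_trt = calls[cols[trt]].apply(lambda row: fraction_presence(row), axis=1)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance probes trigger a precision warning; their p is
        # overwritten with NaN below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x_trt, x_ref, axis=1, equal_var=False)
    zero_var = (x_ref.var(axis=1) == 0) & (x_trt.var(axis=1) == 0)
    p = np.where(zero_var, np.nan, p)
    lfc = x_trt.mean(axis=1) - x_ref.mean(axis=1)

    presence_ok = np.maximum(frac_ref.to_numpy(), frac_trt.to_numpy()) >= presence_min
    p_ok = np.where(np.isnan(p), False, p < p_max)
    if fold_scale == "log2":
        fc_ok = np.abs(lfc) >= lfc_min
    else:
        ratio = np.power(2.0, lfc)
        fc_ok = (ratio >= lfc_min) | (ratio <= 1 / lfc_min)
    return pd.DataFrame(
        {
            "probe_id": signals.index,
            f"frac_presence_{ref}": frac_ref.to_numpy(),
            f"frac_presence_{trt}": frac_trt.to_numpy(),
            "p_value": p,
            "log2_fc": lfc,
            "passes": presence_ok & p_ok & fc_ok,
        }
    ).reset_index(drop=True)
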