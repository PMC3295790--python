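"""Two-color array preprocessing for differential methylation hybridization.

Reads the GPR-dialect scan tables, computes the MA representation
(per-probe log-ratio M and mean log-intensity A) with a delta-method
intra-spot variance from pixel statistics, removes intensity-dependent
dye bias by loess smoothing of M on A, merges dye-swap replicate
hybridizations, and reports between-array channel correlations as a
reproducibility QC.

A *normalized signal* is a :class:`pandas.DataFrame` with columns
``probe_id, M, A, s2_intra, flag`` where ``flag`` is ``ok`` or
``low_signal`` (nonpositive net intensity in either channel; M and A are
NaN for such probes and they pass through every operation untouched).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "GPR_COLUMNS",
    "TwoColorArray",
    "FormatError",
    "ParameterError",
    "AlignmentError",
    "UndefinedCorrelationError",
    "read_gpr",
    "write_gpr",
    "compute_ma",
    "loess_normalize",
    "merge_dye_swap",
    "channel_correlation",
    "swap_pair_qc",
]

LN2 = math.log(2.0)

#: Exact header contract of the scan-table dialect.
GPR_COLUMNS = [
    "probe_id",
    "f_red_mean", "f_red_sd", "b_red_mean", "b_red_sd",
    "f_green_mean", "f_green_sd", "b_green_mean", "b_green_sd",
    "n_pixels",
]


class FormatError(ValueError):
    """A scan table is missing a required column or metadata field."""


class ParameterError(ValueError):
    """An operation parameter is outside its valid range."""


class AlignmentError(ValueError):
    """Two signals that must share a probe universe do not."""


class UndefinedCorrelationError(ValueError):
    """Correlation requested on a zero-variance intensity vector."""


@dataclass
class TwoColorArray:
    """One hybridization: per-probe two-channel fluorescence statistics.

    ``channel_of_progeny`` records which dye carries the progeny
    (generation) sample: ``red`` on regular arrays, ``green`` on
    dye-swap arrays.
    """

    array_id: str
    channel_of_progeny: str  # "red" | "green"
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.channel_of_progeny not in ("red", "green"):
            raise FormatError(
                f"channel_of_progeny must be 'red' or 'green', "
                f"got {self.channel_of_progeny!r}"
            )
        for col in GPR_COLUMNS:
            if col not in self.data.columns:
                raise FormatError(f"missing required column: {col}")
        if self.data["probe_id"].duplicated().any():
            dups = self.data.loc[self.data["probe_id"].duplicated(), "probe_id"]
            raise FormatError(f"duplicate probe_ids: {sorted(set(dups))[:5]}")
        if (self.data["n_pixels"] < 2).any():
            raise FormatError("n_pixels must be >= 2 for every spot")

    @property
    def n_probes(self) -> int:
        return len(self.data)


def write_gpr(array: TwoColorArray, path) -> None:
    """Write the GPR-dialect TSV with '#' metadata comment lines."""
    with open(path, "w") as fh:
        fh.write(f"# array_id={array.array_id}\n")
        fh.write(f"# channel_of_progeny={array.channel_of_progeny}\n")
        array.data.to_csv(fh, sep="\t", index=False, columns=GPR_COLUMNS)


def read_gpr(path) -> TwoColorArray:
    """Read a GPR-dialect TSV written by :func:`write_gpr`."""
    meta = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            pos += len(line)
    data = pd.read_csv(path, sep="\t", comment="#")
    for col in GPR_COLUMNS:
        if col not in data.columns:
            raise FormatError(f"missing required column: {col}")
    if "channel_of_progeny" not in meta:
        raise FormatError("missing metadata line: channel_of_progeny")
    return TwoColorArray(
        array_id=meta.get("array_id", str(path)),
        channel_of_progeny=meta["channel_of_progeny"],
        data=data,
    )


def compute_ma(array: TwoColorArray) -> pd.DataFrame:
    """Background-subtract and transform to the MA representation.

    net = foreground − background per channel;
    M = log2(net_progeny / net_parental);
    A = 0.5·log2(net_progeny · net_parental).

    The intra-spot variance of M comes from a first-order delta method
    on the pixel statistics, with the standard error of each channel
    mean being SD/sqrt(n_pixels)::

        s2_intra = (1/ln 2)^2 · Σ_channels (f_sd^2 + b_sd^2) / (n_pixels · net^2)

    Probes with nonpositive net in either channel are flagged
    ``low_signal`` (M, A, s2_intra = NaN), not imputed.
    """
    d = array.data
    net_red = d["f_red_mean"].to_numpy(float) - d["b_red_mean"].to_numpy(float)
    net_green = d["f_green_mean"].to_numpy(float) - d["b_green_mean"].to_numpy(float)
    if array.channel_of_progeny == "red":
        net_pro, net_par = net_red, net_green
    else:
        net_pro, net_par = net_green, net_red

    ok = (net_pro > 0) & (net_par > 0)
    M = np.full(len(d), np.nan)
    A = np.full(len(d), np.nan)
    M[ok] = np.log2(net_pro[ok] / net_par[ok])
    A[ok] = 0.5 * np.log2(net_pro[ok] * net_par[ok])

    n_pix = d["n_pixels"].to_numpy(float)
    var_red = (d["f_red_sd"].to_numpy(float) ** 2 + d["b_red_sd"].to_numpy(float) ** 2)
    var_green = (d["f_green_sd"].to_numpy(float) ** 2 + d["b_green_sd"].to_numpy(float) ** 2)
    s2 = np.full(len(d), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2_all = (var_red / (n_pix * net_red**2) + var_green / (n_pix * net_green**2)) / LN2**2
    s2[ok] = s2_all[ok]

    return pd.DataFrame(
        {
            "probe_id": d["probe_id"].to_numpy(),
            "M": M,
            "A": A,
            "s2_intra": s2,
            "flag": np.where(ok, "ok", "low_signal"),
        }
    )


def loess_normalize(
    signal: pd.DataFrame, span: float = 0.3, iterations: int = 3
) -> pd.DataFrame:
    """Remove the intensity-dependent trend of M on A.

    Locally weighted linear regression (tricube weights, degree 1,
    ``iterations`` robustifying passes); M' = M − fit(A). A, s2_intra
    and flags are unchanged; low_signal probes pass through untouched.
    """
    if not (0 < span <= 1):
        raise ParameterError(f"span must be in (0, 1], got {span}")
    ok = signal["flag"].to_numpy() == "ok"
    if ok.sum() < 50:
        raise ParameterError(
            f"loess normalization needs >= 50 ok-flagged probes, got {ok.sum()}"
        )
    M = signal["M"].to_numpy(float)
    A = signal["A"].to_numpy(float)
    fit = lowess(M[ok], A[ok], frac=span, it=iterations, return_sorted=False)
    out = signal.copy()
    M_new = M.copy()
    M_new[ok] = M[ok] - fit
    out["M"] = M_new
    return out


def merge_dye_swap(non_swap: pd.DataFrame, swap: pd.DataFrame) -> pd.DataFrame:
    """Average a dye-swap replicate pair of normalized signals.

    Both inputs are already oriented progeny-over-parental (the MA
    computation orients by ``channel_of_progeny``), so the merge is a
    plain average; dye bias of opposite sign cancels. The intra
    variance of the average is (s2_a + s2_b)/4. A probe low_signal in
    either replicate is low_signal in the merge.
    """
    ids_a = list(non_swap["probe_id"])
    ids_b = set(swap["probe_id"])
    missing = sorted(set(ids_a) ^ ids_b)
    if missing:
        raise AlignmentError(f"probe universes differ; unmatched ids: {missing[:10]}")
    b = swap.set_index("probe_id").loc[ids_a].reset_index()
    a = non_swap.reset_index(drop=True)
    ok = (a["flag"].to_numpy() == "ok") & (b["flag"].to_numpy() == "ok")
    M = np.where(ok, (a["M"].to_numpy(float) + b["M"].to_numpy(float)) / 2, np.nan)
    A = np.where(ok, (a["A"].to_numpy(float) + b["A"].to_numpy(float)) / 2, np.nan)
    s2 = np.where(
        ok, (a["s2_intra"].to_numpy(float) + b["s2_intra"].to_numpy(float)) / 4, np.nan
    )
    return pd.DataFrame(
        {
            "probe_id": ids_a,
            "M": M,
            "A": A,
            "s2_intra": s2,
            "flag": np.where(ok, "ok", "low_signal"),
        }
    )


def _log2_net(array: TwoColorArray, role: str) -> pd.Series:
    """log2 net intensity of the channel carrying the given sample role."""
    d = array.data
    channel = (
        array.channel_of_progeny
        if role == "progeny"
        else ("green" if array.channel_of_progeny == "red" else "red")
    )
    net = d[f"f_{channel}_mean"].to_numpy(float) - d[f"b_{channel}_mean"].to_numpy(float)
    vals = np.where(net > 0, np.log2(np.where(net > 0, net, 1.0)), np.nan)
    return pd.Series(vals, index=d["probe_id"].to_numpy())


def _log2_channels_from_signal(signal: pd.DataFrame, role: str) -> pd.Series:
    """Reconstruct per-channel log2 intensity from a normalized signal."""
    half = signal["M"].to_numpy(float) / 2
    A = signal["A"].to_numpy(float)
    vals = A + half if role == "progeny" else A - half
    ok = signal["flag"].to_numpy() == "ok"
    return pd.Series(np.where(ok, vals, np.nan), index=signal["probe_id"].to_numpy())


def channel_correlation(
    a: TwoColorArray,
    b: TwoColorArray,
    channel_role: str = "parental",
    normalized: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> float:
    """Pearson correlation of log2 net intensities of the channels that
    carry the same biological sample in two arrays.

    With ``normalized=(sig_a, sig_b)``, intensities are reconstructed
    from the normalized M/A values instead of the raw scan, giving the
    post-normalization correlation.
    """
    if channel_role not in ("parental", "progeny"):
        raise ParameterError(f"channel_role must be parental|progeny, got {channel_role}")
    if normalized is None:
        xa, xb = _log2_net(a, channel_role), _log2_net(b, channel_role)
    else:
        xa = _log2_channels_from_signal(normalized[0], channel_role)
        xb = _log2_channels_from_signal(normalized[1], channel_role)
    shared = xa.index.intersection(xb.index)
    va, vb = xa.loc[shared].to_numpy(), xb.loc[shared].to_numpy()
    keep = np.isfinite(va) & np.isfinite(vb)
    va, vb = va[keep], vb[keep]
    if len(va) < 3:
        raise ParameterError(f"need >= 3 shared finite probes, got {len(va)}")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise UndefinedCorrelationError("zero variance in an intensity vector")
    return float(np.corrcoef(va, vb)[0, 1])


def swap_pair_qc(
    non_swap: TwoColorArray,
    swap: TwoColorArray,
    normalized: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> dict:
    """Fig-3-style QC: swap/non-swap correlations per sample role,
    before and (if normalized signals are given) after normalization."""
    report = {
        "before": {
            role: channel_correlation(non_swap, swap, role)
            for role in ("parental", "progeny")
        }
    }
    if normalized is not None:
        report["after"] = {
            role: channel_correlation(non_swap, swap, role, normalized=normalized)
            for role in ("parental", "progeny")
        }
    return report
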