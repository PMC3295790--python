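"""Five-way classification of transgenerational methylation propagation.

Each probe carries a triple of differential-methylation direction calls
(generation 1, 3, 5, each vs the parental line) plus relative
fluorescence levels. The triple patterns define:

* stochastic hypomethylation — progressive loss: (down,down,down),
  (even,down,down), (even,even,down);
* stochastic hypermethylation — the up-mirrored patterns;
* random methylation — ten listed patterns mixing up and down;
* heritable high / heritable low — (even,even,even) with consistently
  high (>85% of maximal fluorescence) or low (<15%) levels and at most
  15% change between generations;
* everything else — uncategorized.

Also provides the adjacent-probe (CpG-island cluster) analysis: probes
of the same gene within 1500 bp are chained into clusters, and a
cluster is *consistent* when all members share one category.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

__all__ = [
    "DIRECTIONS",
    "HYPO_PATTERNS",
    "HYPER_PATTERNS",
    "RANDOM_PATTERNS",
    "CATEGORIES",
    "AnnotationError",
    "DegenerateArrayError",
    "classify_probe",
    "classify_all",
    "relative_levels",
    "cluster_adjacent_probes",
    "cluster_consistency",
]

DIRECTIONS = ("up", "down", "even")

HYPO_PATTERNS = frozenset(
    [("down", "down", "down"), ("even", "down", "down"), ("even", "even", "down")]
)
HYPER_PATTERNS = frozenset(
    [("up", "up", "up"), ("even", "up", "up"), ("even", "even", "up")]
)
RANDOM_PATTERNS = frozenset(
    [
        ("down", "up", "down"),
        ("down", "up", "even"),
        ("down", "even", "down"),
        ("even", "up", "down"),
        ("even", "up", "even"),
        ("even", "down", "even"),
        ("even", "down", "up"),
        ("up", "down", "up"),
        ("up", "down", "even"),
        ("up", "even", "up"),
    ]
)

CATEGORIES = (
    "heritable_high",
    "heritable_low",
    "stochastic_hyper",
    "stochastic_hypo",
    "random",
)


class AnnotationError(ValueError):
    """Probe annotation is missing required coordinates."""


class DegenerateArrayError(ValueError):
    """An array's intensity percentiles coincide; levels are undefined."""


def classify_probe(
    d1: str,
    d3: str,
    d5: str,
    levels=None,
    high_floor: float = 0.85,
    low_ceiling: float = 0.15,
    max_delta: float = 0.15,
    merge_unlisted_into_random: bool = False,
) -> str:
    """Map one direction triple (plus levels, for the all-even case) to a
    propagation category. Total: every input yields exactly one label.

    ``levels`` is the (parental, g1, g3, g5) relative-fluorescence
    vector in [0, 1]; it is only consulted for (even, even, even)
    triples, which split into heritable_high / heritable_low /
    uncategorized on the >``high_floor`` / <``low_ceiling`` floors and
    the ≤``max_delta`` between-generation spread. Direction triples not
    listed in any pattern table are uncategorized by default;
    ``merge_unlisted_into_random`` folds them into random instead.
    """
    triple = (d1, d3, d5)
    for d in triple:
        if d not in DIRECTIONS:
            raise ValueError(f"invalid direction {d!r}")
    if triple in HYPO_PATTERNS:
        return "stochastic_hypo"
    if triple in HYPER_PATTERNS:
        return "stochastic_hyper"
    if triple in RANDOM_PATTERNS:
        return "random"
    if triple == ("even", "even", "even"):
        if levels is None:
            return "uncategorized"
        lv = np.asarray(levels, float)
        if len(lv) != 4:
            raise ValueError("levels must give (parental, g1, g3, g5)")
        if not np.all(np.isfinite(lv)):
            return "uncategorized"
        spread = float(lv.max() - lv.min())
        if np.all(lv > high_floor) and spread <= max_delta:
            return "heritable_high"
        if np.all(lv < low_ceiling) and spread <= max_delta:
            return "heritable_low"
        return "uncategorized"
    return "random" if merge_unlisted_into_random else "uncategorized"


def classify_all(triples: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Classify a table with columns ``probe_id, d1, d3, d5,
    L_parental, L_g1, L_g3, L_g5`` (level columns optional)."""
    level_cols = ["L_parental", "L_g1", "L_g3", "L_g5"]
    has_levels = all(c in triples.columns for c in level_cols)
    cats = [
        classify_probe(
            row.d1,
            row.d3,
            row.d5,
            levels=[getattr(row, c) for c in level_cols] if has_levels else None,
            **kwargs,
        )
        for row in triples.itertuples()
    ]
    out = triples.copy()
    out["category"] = cats
    return out


def relative_levels(
    signals: dict[str, pd.DataFrame],
    q_low: float = 0.5,
    q_high: float = 99.5,
) -> pd.DataFrame:
    """Per-probe relative fluorescence level at each timepoint.

    ``signals`` maps generation name ('g1', 'g3', 'g5') to its
    normalized signal. Per array, the probe's log2 net intensity in the
    channel carrying a sample is reconstructed as A ± M/2; the array's
    "maximal fluorescence" is operationalized robustly as the
    ``q_high``-th percentile of both channels pooled (and the floor as
    the ``q_low``-th), and L = (x − q_lo)/(q_hi − q_lo) clipped to
    [0, 1]. The parental sample hybridizes on every array; its level is
    the mean of its per-array levels.
    """
    for g in ("g1", "g3", "g5"):
        if g not in signals:
            raise ValueError(f"all timepoints required; missing {g}")
    frames = {}
    parental = []
    probe_ids = None
    for gen in ("g1", "g3", "g5"):
        sig = signals[gen]
        ids = sig["probe_id"].to_numpy()
        if probe_ids is None:
            probe_ids = ids
        ok = sig["flag"].to_numpy() == "ok"
        A = sig["A"].to_numpy(float)
        half = sig["M"].to_numpy(float) / 2
        x_pro, x_par = A + half, A - half
        pooled = np.concatenate([x_pro[ok], x_par[ok]])
        lo, hi = np.percentile(pooled, [q_low, q_high])
        if hi <= lo:
            raise DegenerateArrayError(f"degenerate intensity range on {gen}")

        def scale(x):
            out = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
            return np.where(ok, out, np.nan)

        frames[f"L_{gen}"] = pd.Series(scale(x_pro), index=ids)
        parental.append(pd.Series(scale(x_par), index=ids))
    out = pd.DataFrame({"probe_id": probe_ids}).set_index("probe_id", drop=False)
    out["L_parental"] = pd.concat(parental, axis=1).mean(axis=1, skipna=False)
    for k, v in frames.items():
        out[k] = v
    return out.reset_index(drop=True)


def cluster_adjacent_probes(annotation: pd.DataFrame, max_gap: int = 1500) -> pd.DataFrame:
    """Chain same-gene probes whose midpoints are ≤ ``max_gap`` bp apart.

    Single-linkage: per gene, probes are sorted by midpoint and
    consecutive probes within the gap are linked; each connected chain
    is one cluster (singletons allowed). Coordinates are 0-based
    half-open. Returns columns ``cluster_id, gene_id, probe_id``.
    """
    required = ["probe_id", "gene_id", "start", "end"]
    for col in required:
        if col not in annotation.columns:
            raise AnnotationError(f"annotation missing column {col}")
    bad = annotation.loc[
        annotation[["start", "end"]].isna().any(axis=1), "probe_id"
    ].tolist()
    if bad:
        raise AnnotationError(f"probes missing coordinates: {bad[:10]}")
    ann = annotation.copy()
    ann["midpoint"] = (ann["start"].to_numpy(float) + ann["end"].to_numpy(float)) / 2
    rows = []
    cluster_idx = 0
    for gene_id, grp in ann.groupby("gene_id", sort=True):
        grp = grp.sort_values(["midpoint", "probe_id"])
        mids = grp["midpoint"].to_numpy()
        breaks = np.diff(mids) > max_gap
        member = np.concatenate([[0], np.cumsum(breaks)])
        for local in np.unique(member):
            cid = f"c{cluster_idx:06d}"
            cluster_idx += 1
            for pid in grp["probe_id"].to_numpy()[member == local]:
                rows.append((cid, gene_id, pid))
    return pd.DataFrame(rows, columns=["cluster_id", "gene_id", "probe_id"])


def cluster_consistency(
    clusters: pd.DataFrame, assignments: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Flag clusters whose members all share one category.

    Returns a per-cluster table (``cluster_id, gene_id, n_probes,
    consistent, categories``) and, per category, the fraction of
    multi-probe clusters containing at least one probe of that category
    that are consistent.
    """
    cat = assignments.set_index("probe_id")["category"]
    missing = [p for p in clusters["probe_id"] if p not in cat.index]
    if missing:
        raise AnnotationError(f"probes without assignment: {missing[:10]}")
    rows = []
    for (cid, gid), grp in clusters.groupby(["cluster_id", "gene_id"], sort=True):
        cats = sorted(set(cat.loc[grp["probe_id"]].tolist()))
        rows.append((cid, gid, len(grp), len(cats) == 1, ",".join(cats)))
    table = pd.DataFrame(
        rows, columns=["cluster_id", "gene_id", "n_probes", "consistent", "categories"]
    )
    summary: dict[str, float] = {}
    multi = table[table["n_probes"] > 1]
    all_cats = set(itertools.chain.from_iterable(c.split(",") for c in table["categories"]))
    for c in sorted(all_cats):
        sel = multi[multi["categories"].str.split(",").apply(lambda xs: c in xs)]
        if len(sel):
            summary[c] = float(sel["consistent"].mean())
    return table, summary
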