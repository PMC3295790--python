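"""Weight-matrix TFBS scanning and category enrichment testing.

Motifs are position frequency matrices (TRANSFAC flat-file dialect)
scored MATCH-style: each position carries an information weight
I(i) = sum_b f(i,b) ln(4 f(i,b)), a window's raw score is
sum_i I(i) f(i, base_i), and the matrix similarity score (MSS) min-max
normalizes that between the per-position minimum and maximum
frequencies. The core similarity score (CSS) applies the same formula
to the 5-position window of maximal summed information.

Enrichment compares, per motif, the number of category sequences with
at least one hit against a matched background set with a one-sided
Fisher exact test under a Bonferroni threshold of
alpha / (n_matrices x n_categories); with the 459-motif TRANSFAC
library and five categories that threshold is 0.05/459/5 = 2.2e-5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "WeightMatrix",
    "TransfacParseError",
    "parse_transfac",
    "write_transfac",
    "matrix_from_counts",
    "synthetic_matrix_library",
    "consensus",
    "reverse_complement",
    "gc_fraction",
    "match_score",
    "scan_sequence",
    "scan_sequences",
    "build_background",
    "fisher_enrichment",
    "bonferroni_threshold",
    "category_overlap",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CORE_WIDTH = 5


class TransfacParseError(ValueError):
    """Malformed TRANSFAC flat-file input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


@dataclass(frozen=True)
class WeightMatrix:
    """A position frequency matrix with MATCH scoring metadata.

    ``freq`` is length x 4 over (A, C, G, T), rows summing to 1 after
    pseudocount normalization; ``information`` holds the per-position
    weights I(i) >= 0; ``core_start`` indexes the 5-position window of
    maximal summed information (the full matrix for shorter motifs).
    """

    matrix_id: str
    tf_name: str
    freq: np.ndarray
    information: np.ndarray
    core_start: int

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    @property
    def core_length(self) -> int:
        return min(CORE_WIDTH, self.length)


def matrix_from_counts(
    matrix_id: str, counts, tf_name: str = "", pseudocount: float = 0.25
) -> WeightMatrix:
    """Build a weight matrix from raw per-position base counts.

    A pseudocount (default 0.25 per cell) keeps minimum frequencies
    strictly positive so the min-max MSS normalization is stable.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise TransfacParseError(f"{matrix_id}: counts must be L x 4")
    if (counts.sum(axis=1) == 0).any():
        raise TransfacParseError(f"{matrix_id}: all-zero count row")
    padded = counts + pseudocount
    freq = padded / padded.sum(axis=1, keepdims=True)
    info = (freq * np.log(4.0 * freq)).sum(axis=1)
    info = np.maximum(info, 0.0)  # clip -0.0 / rounding
    L = freq.shape[0]
    if L <= CORE_WIDTH:
        core_start = 0
    else:
        sums = np.convolve(info, np.ones(CORE_WIDTH), mode="valid")
        core_start = int(np.argmax(sums))
    return WeightMatrix(matrix_id, tf_name, freq, info, core_start)


def parse_transfac(path, pseudocount: float = 0.25) -> list[WeightMatrix]:
    """Parse a TRANSFAC flat file (ID / NA lines, numbered count rows
    with four counts and an optional consensus letter, '//' terminator)."""
    matrices: list[WeightMatrix] = []
    matrix_id, tf_name = None, ""
    rows: list[list[float]] = []

    def flush(lineno):
        nonlocal matrix_id, tf_name, rows
        if matrix_id is not None:
            if not rows:
                raise TransfacParseError(f"line {lineno}: matrix {matrix_id} has no rows")
            matrices.append(matrix_from_counts(matrix_id, rows, tf_name, pseudocount))
        matrix_id, tf_name, rows = None, "", []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("XX", "P0", "PO", "BF", "CC", "AC")):
                continue
            if line.startswith("//"):
                flush(lineno)
                continue
            if line.startswith("ID"):
                flush(lineno)
                matrix_id = line.split(maxsplit=1)[1].strip() if " " in line else ""
                continue
            if line.startswith("NA"):
                tf_name = line.split(maxsplit=1)[1].strip() if " " in line else ""
                continue
            fields = line.split()
            if fields[0].lstrip("0").isdigit() or fields[0] == "0" * len(fields[0]):
                vals = fields[1:]
                if vals and not _is_number(vals[-1]):
                    vals = vals[:-1]  # trailing consensus letter
                if len(vals) != 4 or not all(_is_number(v) for v in vals):
                    raise TransfacParseError(
                        f"line {lineno}: expected 4 counts, got {fields[1:]!r}"
                    )
                row = [float(v) for v in vals]
                if sum(row) == 0:
                    raise TransfacParseError(f"line {lineno}: all-zero count row")
                rows.append(row)
                continue
            raise TransfacParseError(f"line {lineno}: unrecognized line {line!r}")
    flush("EOF")
    return matrices


def write_transfac(matrices, path, counts_scale: float = 100.0) -> None:
    """Write matrices back to the flat-file dialect (frequencies scaled
    to pseudo-counts); used to persist synthetic motif libraries."""
    with open(path, "w") as fh:
        for m in matrices:
            fh.write(f"ID {m.matrix_id}\n")
            if m.tf_name:
                fh.write(f"NA {m.tf_name}\n")
            for i, row in enumerate(np.round(m.freq * counts_scale, 3), start=1):
                fh.write(f"{i:02d} " + " ".join(f"{v:g}" for v in row) + "\n")
            fh.write("//\n")


def consensus(matrix: WeightMatrix) -> str:
    """Per-position argmax consensus sequence (ties -> first of ACGT)."""
    return "".join(BASES[i] for i in np.argmax(matrix.freq, axis=1))


def synthetic_matrix_library(
    n_matrices: int, seed: int = 0, length_range: tuple[int, int] = (10, 12)
) -> list[WeightMatrix]:
    """Seeded library of informative synthetic motifs (a dominant base
    per position, count 12 against 1), for pipelines run without a
    TRANSFAC file and for tests."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_matrices):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        counts = np.ones((L, 4))
        counts[np.arange(L), rng.integers(0, 4, size=L)] = 12.0
        out.append(matrix_from_counts(f"M{k:03d}", counts, tf_name=f"SYNTF{k}"))
    return out


def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3, anything else (N) to 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _score_table(matrix: WeightMatrix) -> tuple[np.ndarray, float, float]:
    """Per-position lookup of I(i)·f(i, b) with column 4 for N (=min),
    plus the attainable score min and max."""
    weighted = matrix.information[:, None] * matrix.freq  # L x 4
    col_n = weighted.min(axis=1, keepdims=True)
    table = np.hstack([weighted, col_n])
    return table, float(weighted.min(axis=1).sum()), float(weighted.max(axis=1).sum())


def match_score(matrix: WeightMatrix, window: str) -> tuple[float, float]:
    """MATCH similarity of one window: (mss, css), both in [0, 1].

    mss = (Current − Min)/(Max − Min) over the full matrix; css is the
    same quantity over the core window. A zero-information matrix
    (Max = Min) scores 1 by definition. N bases contribute the
    per-position minimum frequency.
    """
    if len(window) != matrix.length:
        raise ValueError(
            f"window length {len(window)} != matrix length {matrix.length}"
        )
    mss_all, css_all = _score_windows(matrix, _encode(window)[None, :])
    return float(mss_all[0]), float(css_all[0])


def _score_windows(matrix: WeightMatrix, windows: np.ndarray):
    """Vectorized MSS/CSS for an (n, L) array of encoded windows."""
    table, lo, hi = _score_table(matrix)
    idx = np.arange(matrix.length)
    cur = table[idx, windows].sum(axis=1)
    mss = (cur - lo) / (hi - lo) if hi > lo else np.ones(len(windows))
    cs, cl = matrix.core_start, matrix.core_length
    ct = table[cs : cs + cl]
    clo = ct[:, :4].min(axis=1).sum()
    chi = ct[:, :4].max(axis=1).sum()
    ccur = ct[np.arange(cl), windows[:, cs : cs + cl]].sum(axis=1)
    css = (ccur - clo) / (chi - clo) if chi > clo else np.ones(len(windows))
    return mss, css


def scan_sequence(
    sequence_id: str,
    sequence: str,
    matrices,
    mss_cutoff: float = 0.85,
    css_cutoff: float = 0.75,
) -> pd.DataFrame:
    """Slide every matrix over both strands; report all windows passing
    css >= css_cutoff and mss >= mss_cutoff.

    Offsets are 0-based in the input sequence's coordinates for both
    strands (a '-' hit at offset o means the reverse complement of
    ``sequence[o:o+L]`` matches the motif).
    """
    for c in (mss_cutoff, css_cutoff):
        if not (0 <= c <= 1):
            raise ValueError(f"cutoffs must be in [0, 1], got {c}")
    enc_fwd = _encode(sequence)
    enc_rev = _encode(reverse_complement(sequence))
    n = len(sequence)
    rows = []
    for m in matrices:
        L = m.length
        if L > n:
            continue
        for strand, enc in (("+", enc_fwd), ("-", enc_rev)):
            windows = np.lib.stride_tricks.sliding_window_view(enc, L)
            mss, css = _score_windows(m, windows)
            hit = (mss >= mss_cutoff) & (css >= css_cutoff)
            for j in np.nonzero(hit)[0]:
                offset = int(j) if strand == "+" else n - L - int(j)
                rows.append(
                    (sequence_id, m.matrix_id, offset, strand, float(mss[j]), float(css[j]))
                )
    return pd.DataFrame(
        rows, columns=["sequence_id", "matrix_id", "offset", "strand", "mss", "css"]
    )


def scan_sequences(
    sequences: dict[str, str], matrices, mss_cutoff: float = 0.85, css_cutoff: float = 0.75
) -> pd.DataFrame:
    frames = [
        df
        for sid, seq in sequences.items()
        if len(df := scan_sequence(sid, seq, matrices, mss_cutoff, css_cutoff))
    ]
    if not frames:
        return pd.DataFrame(
            columns=["sequence_id", "matrix_id", "offset", "strand", "mss", "css"]
        )
    return pd.concat(frames, ignore_index=True)


def build_background(
    mode: str,
    categorized_sequences: dict[str, str],
    uncategorized_pool: dict[str, str] | None = None,
    k: int = 1,
    seed: int = 0,
    gc_tolerance: float = 0.05,
) -> tuple[dict[str, str], dict]:
    """Build one of the two matched background sequence sets.

    ``set1_random``: per categorized sequence, k random sequences of
    identical length with bases drawn to match its GC fraction.
    ``set2_uncategorized``: per categorized sequence, k uncategorized
    probe sequences of identical length with GC within ±``gc_tolerance``
    (nearest-GC fallback), sampled without replacement while the pool
    lasts; exhaustion falls back to sampling with replacement and is
    recorded in the report.
    """
    if mode == "set1_random":
        from .synthetic import generate_matched_background

        return generate_matched_background(categorized_sequences, k, seed), {
            "mode": mode,
            "with_replacement": 0,
        }
    if mode != "set2_uncategorized":
        raise ValueError(f"mode must be set1_random|set2_uncategorized, got {mode!r}")
    if not uncategorized_pool:
        raise ValueError("set2 background requires a nonempty uncategorized pool")
    rng = np.random.default_rng(seed)
    pool_ids = sorted(uncategorized_pool)
    pool_gc = {pid: gc_fraction(uncategorized_pool[pid]) for pid in pool_ids}
    pool_len = {pid: len(uncategorized_pool[pid]) for pid in pool_ids}
    unused = set(pool_ids)
    out: dict[str, str] = {}
    replaced = 0
    for sid in sorted(categorized_sequences):
        g = gc_fraction(categorized_sequences[sid])
        L = len(categorized_sequences[sid])
        for i in range(k):
            same_len = [p for p in pool_ids if pool_len[p] == L]
            if not same_len:
                raise ValueError(f"no pool sequence of length {L} for {sid}")
            fresh = [p for p in same_len if p in unused]
            candidates = fresh if fresh else same_len
            if not fresh:
                replaced += 1
            close = [p for p in candidates if abs(pool_gc[p] - g) <= gc_tolerance]
            if close:
                chosen = close[rng.integers(len(close))]
            else:
                deltas = np.array([abs(pool_gc[p] - g) for p in candidates])
                chosen = candidates[int(np.argmin(deltas))]
            unused.discard(chosen)
            out[f"{sid}|bg{i}"] = uncategorized_pool[chosen]
    return out, {"mode": mode, "with_replacement": replaced}


def bonferroni_threshold(alpha: float, n_matrices: int, n_categories: int) -> float:
    """Family-wise threshold alpha/(n_matrices · n_categories)."""
    if alpha <= 0 or n_matrices <= 0 or n_categories <= 0:
        raise ValueError("alpha, n_matrices and n_categories must be positive")
    return alpha / (n_matrices * n_categories)


def _presence(hits: pd.DataFrame, matrix_id: str, ids: set[str]) -> int:
    sub = hits[hits["matrix_id"] == matrix_id]
    return len(set(sub["sequence_id"]) & ids)


def fisher_enrichment(
    category_hits: pd.DataFrame,
    background_hits: pd.DataFrame,
    category_ids,
    background_ids,
    matrices,
    category: str,
    alpha: float = 0.05,
    n_categories: int = 5,
    count_mode: str = "presence",
) -> pd.DataFrame:
    """Per-motif 2x2 enrichment of a category against its background.

    The sampling unit is the sequence: a = category sequences with >= 1
    hit, c = background sequences with >= 1 hit; one-sided (greater)
    Fisher exact p; significant iff p < alpha/(n_matrices·n_categories).
    ``count_mode='hits'`` counts total hits instead of presence (the
    margins then being total window opportunities approximated by
    sequence counts times nothing — kept simple as raw hit counts).
    """
    cat_ids, bg_ids = set(category_ids), set(background_ids)
    if not cat_ids:
        raise ValueError(f"category {category!r} is empty")
    if not bg_ids:
        raise ValueError("background set is empty")
    threshold = bonferroni_threshold(alpha, len(matrices), n_categories)
    rows = []
    for m in matrices:
        if count_mode == "presence":
            a = _presence(category_hits, m.matrix_id, cat_ids)
            c = _presence(background_hits, m.matrix_id, bg_ids)
            b, d = len(cat_ids) - a, len(bg_ids) - c
        elif count_mode == "hits":
            a = int((category_hits["matrix_id"] == m.matrix_id).sum())
            c = int((background_hits["matrix_id"] == m.matrix_id).sum())
            b = max(len(category_hits) - a, 0)
            d = max(len(background_hits) - c, 0)
        else:
            raise ValueError(f"count_mode must be presence|hits, got {count_mode!r}")
        odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((m.matrix_id, category, a, b, c, d, float(odds), float(p), p < threshold))
    return pd.DataFrame(
        rows,
        columns=[
            "matrix_id", "category", "a", "b", "c", "d",
            "odds_ratio", "p_value", "significant",
        ],
    )


def category_overlap(enrichment: pd.DataFrame):
    """Pairwise overlap of significantly enriched motif sets.

    Returns a categories x categories count matrix and a dict mapping
    each unordered pair to the sorted list of motifs significant in
    both.
    """
    cats = sorted(enrichment["category"].unique())
    if len(cats) < 2:
        raise ValueError("overlap needs >= 2 categories")
    sig = {
        c: set(
            enrichment.loc[
                (enrichment["category"] == c) & enrichment["significant"], "matrix_id"
            ]
        )
        for c in cats
    }
    counts = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    members: dict[tuple[str, str], list[str]] = {}
    for i, ci in enumerate(cats):
        for cj in cats[i:]:
            shared = sorted(sig[ci] & sig[cj])
            counts.loc[ci, cj] = counts.loc[cj, ci] = len(shared)
            if ci != cj:
                members[(ci, cj)] = shared
    return counts, members


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
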