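"""End-to-end synthetic-to-report pipeline and configuration schema.

Chains the analysis stages in experiment order: simulate scans ->
MA transform + loess normalization (with the generation-3 dye-swap
merge) -> empirical-Bayes differential calling per generation ->
propagation-category classification and CpG-island cluster consistency
-> TFBS enrichment against both matched background sets -> run report.
Every intermediate is persisted as TSV/FASTA/JSON so any stage can be
rerun in isolation; a single global seed derives all per-stage
substreams, and rerunning the same configuration reproduces identical
file digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import categories as cat
from . import ebayes, normalize, synthetic, tfbs

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "validate_config",
    "config_to_dict",
    "write_config",
    "run_pipeline",
]

log = logging.getLogger("methfid")


class ConfigError(ValueError):
    """Configuration schema or constraint violation."""


@dataclass
class NormalizationSection:
    span: float = 0.3
    iterations: int = 3


@dataclass
class CallerSection:
    threshold: float = 0.80
    max_iter: int = 200
    tol: float = 1e-6


@dataclass
class ClassifierSection:
    high_floor: float = 0.85
    low_ceiling: float = 0.15
    max_delta: float = 0.15
    cluster_gap: int = 1500
    merge_unlisted_into_random: bool = False


@dataclass
class RiggsSection:
    mu: float = 0.98
    delta: float = 0.02
    n_cells: int = 1000
    n_sites: int = 100
    n_generations: int = 30
    init_meth_fraction: float = 0.5


@dataclass
class TfbsSection:
    mss_cutoff: float = 0.85
    css_cutoff: float = 0.75
    alpha: float = 0.05
    k_background: int = 2
    matrices_path: str | None = None
    n_synthetic_matrices: int = 12
    count_mode: str = "presence"


@dataclass
class ExpressionSection:
    presence_min: float = 0.5
    p_max: float = 0.01
    lfc_min: float = 1.2
    fold_scale: str = "log2"


@dataclass
class SyntheticSection:
    n_probes_per_category: int = 400
    gc_mean: float = 0.65
    gc_sd: float = 0.05
    dye_bias_amplitude: float = 0.3
    pixel_sd_scale: float = 0.08
    n_pixels: int = 25
    effect_size: float = 1.0
    motif_plant_rate: float = 0.3
    bio_sd: float = 0.1
    intensity_range_log2: float = 8.0
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 0.25
    background_mean: float = 64.0
    uncategorized_multiplier: int = 4


@dataclass
class PipelineConfig:
    seed: int = 0
    synthetic: SyntheticSection = field(default_factory=SyntheticSection)
    normalization: NormalizationSection = field(default_factory=NormalizationSection)
    caller: CallerSection = field(default_factory=CallerSection)
    classifier: ClassifierSection = field(default_factory=ClassifierSection)
    riggs: RiggsSection = field(default_factory=RiggsSection)
    tfbs: TfbsSection = field(default_factory=TfbsSection)
    expression: ExpressionSection = field(default_factory=ExpressionSection)

    def simulation_config(self) -> synthetic.SimulationConfig:
        return synthetic.SimulationConfig(
            seed=self.seed, **dataclasses.asdict(self.synthetic)
        )


_SECTIONS = {
    "synthetic": SyntheticSection,
    "normalization": NormalizationSection,
    "caller": CallerSection,
    "classifier": ClassifierSection,
    "riggs": RiggsSection,
    "tfbs": TfbsSection,
    "expression": ExpressionSection,
}


def _build_config(raw: dict) -> PipelineConfig:
    errors: list[str] = []
    kwargs: dict = {}
    for key, val in raw.items():
        if key == "seed":
            kwargs["seed"] = int(val)
        elif key in _SECTIONS:
            cls = _SECTIONS[key]
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(val or {}) - known
            errors.extend(f"unknown key: {key}.{k}" for k in sorted(unknown))
            kwargs[key] = cls(**{k: v for k, v in (val or {}).items() if k in known})
        else:
            errors.append(f"unknown key: {key}")
    config = PipelineConfig(**kwargs)
    errors.extend(_constraint_errors(config))
    if errors:
        raise ConfigError("; ".join(errors))
    return config


def _constraint_errors(c: PipelineConfig) -> list[str]:
    errs = []
    if not (0 < c.normalization.span <= 1):
        errs.append("normalization.span must be in (0, 1]")
    if not (0 < c.caller.threshold < 1):
        errs.append("caller.threshold must be in (0, 1)")
    if not (c.classifier.low_ceiling < c.classifier.high_floor):
        errs.append("classifier.high_floor must exceed classifier.low_ceiling")
    if c.classifier.cluster_gap <= 0:
        errs.append("classifier.cluster_gap must be positive")
    if not (0 <= c.riggs.mu <= 1 and 0 <= c.riggs.delta <= 1):
        errs.append("riggs.mu and riggs.delta must be in [0, 1]")
    if not (0 <= c.riggs.init_meth_fraction <= 1):
        errs.append("riggs.init_meth_fraction must be in [0, 1]")
    for name in ("mss_cutoff", "css_cutoff"):
        if not (0 <= getattr(c.tfbs, name) <= 1):
            errs.append(f"tfbs.{name} must be in [0, 1]")
    if not (0 < c.tfbs.alpha < 1):
        errs.append("tfbs.alpha must be in (0, 1)")
    if c.tfbs.k_background < 1:
        errs.append("tfbs.k_background must be >= 1")
    if c.expression.fold_scale not in ("log2", "linear"):
        errs.append("expression.fold_scale must be log2|linear")
    try:
        c.simulation_config()
    except synthetic.ConfigError as exc:
        errs.append(f"synthetic: {exc}")
    return errs


def validate_config(path) -> PipelineConfig:
    """Load a YAML configuration; an empty file yields all defaults;
    unknown keys and constraint violations are all reported at once."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    return _build_config(raw)


def config_to_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


def write_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full synthetic-to-report run; returns the run report
    (also written to ``outdir/run_report.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config_to_dict(config),
        "stages": {},
    }
    t_start = time.time()

    def stage_done(name, **info):
        report["stages"][name] = {"seconds": round(time.time() - t_start, 3), **info}
        log.info("stage %s done (%.1fs)", name, time.time() - t_start)

    # --- simulate -----------------------------------------------------
    sim = config.simulation_config()
    probes = synthetic.generate_probe_set(sim)
    if config.tfbs.matrices_path:
        matrices = tfbs.parse_transfac(config.tfbs.matrices_path)
    else:
        matrices = tfbs.synthetic_matrix_library(
            config.tfbs.n_synthetic_matrices, seed=config.seed
        )
    probes, manifest = synthetic.plant_motifs(probes, matrices, sim)
    arrays = {
        "g1": synthetic.simulate_array_scan(probes, "g1", False, sim),
        "g3": synthetic.simulate_array_scan(probes, "g3", False, sim),
        "g3_swap": synthetic.simulate_array_scan(probes, "g3", True, sim),
        "g5": synthetic.simulate_array_scan(probes, "g5", False, sim),
    }
    annotation = synthetic.probes_to_annotation(probes)
    for name, arr in arrays.items():
        normalize.write_gpr(arr, outdir / f"scan_{name}.gpr")
    _write_tsv(annotation, outdir / "annotation.tsv")
    _write_tsv(manifest, outdir / "motif_manifest.tsv")
    synthetic.write_fasta(synthetic.probe_sequences(probes), outdir / "probes.fasta")
    tfbs.write_transfac(matrices, outdir / "matrices.transfac")
    stage_done("simulate", n_probes=len(probes), n_matrices=len(matrices))

    # --- normalize ----------------------------------------------------
    signals = {}
    for name, arr in arrays.items():
        sig = normalize.compute_ma(arr)
        sig = normalize.loess_normalize(
            sig, span=config.normalization.span, iterations=config.normalization.iterations
        )
        signals[name] = sig
    qc = normalize.swap_pair_qc(
        arrays["g3"], arrays["g3_swap"], normalized=(signals["g3"], signals["g3_swap"])
    )
    g3_merged = normalize.merge_dye_swap(signals["g3"], signals["g3_swap"])
    signals["g3_merged"] = g3_merged
    for name, sig in signals.items():
        _write_tsv(sig, outdir / f"normalized_{name}.tsv")
    (outdir / "qc_report.json").write_text(json.dumps(qc, indent=2, sort_keys=True))
    stage_done("normalize", qc=qc)

    # --- call ---------------------------------------------------------
    per_gen = {"g1": signals["g1"], "g3": signals["g3_merged"], "g5": signals["g5"]}
    calls = {}
    fits = {}
    for gen, sig in per_gen.items():
        fit = ebayes.fit_eb_mixture(
            sig, max_iter=config.caller.max_iter, tol=config.caller.tol
        )
        fits[gen] = fit
        calls[gen] = ebayes.call_differential(
            sig, fit, threshold=config.caller.threshold, generation=gen
        )
    calls_long = pd.concat(calls.values(), ignore_index=True)
    _write_tsv(calls_long, outdir / "calls.tsv")
    stage_done(
        "call",
        fits={
            g: {"pi1": f.pi1, "tau0_2": f.tau0_2, "tau1_2": f.tau1_2, "n_iter": f.n_iter}
            for g, f in fits.items()
        },
    )

    # --- classify -----------------------------------------------------
    levels = cat.relative_levels(per_gen)
    triples = levels.copy()
    for gen in ("g1", "g3", "g5"):
        d = calls[gen].set_index("probe_id")["direction"]
        triples[f"d{gen[1]}"] = d.loc[triples["probe_id"]].to_numpy()
    assignments = cat.classify_all(
        triples,
        high_floor=config.classifier.high_floor,
        low_ceiling=config.classifier.low_ceiling,
        max_delta=config.classifier.max_delta,
        merge_unlisted_into_random=config.classifier.merge_unlisted_into_random,
    )
    _write_tsv(assignments, outdir / "categories.tsv")
    clusters = cat.cluster_adjacent_probes(annotation, max_gap=config.classifier.cluster_gap)
    cluster_table, consistency = cat.cluster_consistency(clusters, assignments)
    _write_tsv(cluster_table, outdir / "clusters.tsv")
    counts = assignments["category"].value_counts().to_dict()
    truth = annotation.set_index("probe_id")["true_category"]
    confusion = (
        pd.crosstab(
            truth.loc[assignments["probe_id"]].to_numpy(),
            assignments["category"],
            rownames=["true"],
            colnames=["predicted"],
        )
        .astype(int)
    )
    _write_tsv(confusion.reset_index(), outdir / "confusion.tsv")
    stage_done(
        "classify",
        category_counts={k: int(v) for k, v in sorted(counts.items())},
        cluster_consistency=consistency,
    )

    # --- enrich -------------------------------------------------------
    seqs = synthetic.probe_sequences(probes)
    assigned = assignments.set_index("probe_id")["category"]
    cat_ids = {
        c: [p for p in assigned.index if assigned[p] == c] for c in cat.CATEGORIES
    }
    uncat_pool = {p: seqs[p] for p in assigned.index if assigned[p] == "uncategorized"}
    all_cat_seqs = {p: seqs[p] for ids in cat_ids.values() for p in ids}
    cat_hits = tfbs.scan_sequences(
        all_cat_seqs, matrices, config.tfbs.mss_cutoff, config.tfbs.css_cutoff
    )
    enrich_frames = {"set1": [], "set2": []}
    bg_reports = {}
    for mode, key in (("set1_random", "set1"), ("set2_uncategorized", "set2")):
        for c in cat.CATEGORIES:
            if not cat_ids[c]:
                continue
            cseqs = {p: seqs[p] for p in cat_ids[c]}
            bg, bg_report = tfbs.build_background(
                mode,
                cseqs,
                uncategorized_pool=uncat_pool,
                k=config.tfbs.k_background,
                seed=config.seed + 17,
            )
            bg_reports[f"{key}:{c}"] = bg_report
            bg_hits = tfbs.scan_sequences(
                bg, matrices, config.tfbs.mss_cutoff, config.tfbs.css_cutoff
            )
            enrich_frames[key].append(
                tfbs.fisher_enrichment(
                    cat_hits,
                    bg_hits,
                    cat_ids[c],
                    list(bg),
                    matrices,
                    category=c,
                    alpha=config.tfbs.alpha,
                    n_categories=len(cat.CATEGORIES),
                    count_mode=config.tfbs.count_mode,
                )
            )
    enrichment = {}
    for key, frames in enrich_frames.items():
        enrichment[key] = pd.concat(frames, ignore_index=True)
        _write_tsv(enrichment[key], outdir / f"enrichment_{key}.tsv")
    overlap_counts, _members = tfbs.category_overlap(enrichment["set1"])
    _write_tsv(overlap_counts.reset_index(names="category"), outdir / "overlap_set1.tsv")
    sig_counts = {
        key: {
            c: int(df[(df["category"] == c) & df["significant"]].shape[0])
            for c in sorted(df["category"].unique())
        }
        for key, df in enrichment.items()
    }
    stage_done("enrich", significant_counts=sig_counts, backgrounds=bg_reports)

    # --- report -------------------------------------------------------
    recall = {}
    for c in cat.CATEGORIES:
        n_true = int((truth == c).sum())
        hit = int(confusion.loc[c, c]) if c in confusion.index and c in confusion.columns else 0
        recall[c] = hit / n_true if n_true else float("nan")
    report["category_counts"] = {k: int(v) for k, v in sorted(counts.items())}
    report["recall"] = recall
    report["significant_motifs"] = sig_counts
    report["overlap_set1"] = overlap_counts.to_dict()
    report["qc"] = qc
    report["digests"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "run_report.json"
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
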