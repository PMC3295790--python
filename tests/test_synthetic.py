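"""Generator contracts: determinism, GC control, noise-free fidelity,
dye-swap antisymmetry, motif planting, matched backgrounds."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from methfid import normalize, tfbs
from methfid.synthetic import (
    ConfigError,
    SimulationConfig,
    generate_matched_background,
    generate_probe_set,
    plant_motifs,
    probe_sequences,
    probes_to_annotation,
    simulate_array_scan,
)
from methfid.tfbs import gc_fraction, matrix_from_counts, synthetic_matrix_library

NOISE_FREE = SimulationConfig(
    n_probes_per_category=40,
    seed=3,
    dye_bias_amplitude=0.0,
    pixel_sd_scale=0.0,
    bio_sd=0.0,
)


def true_log_ratio(probe, timepoint, config):
    idx = {"g1": 1, "g3": 2, "g5": 3}[timepoint]
    return config.intensity_range_log2 * (probe.true_level[idx] - probe.true_level[0])


class TestGenerateProbeSet:
    def test_empty_config_yields_empty_collection(self):
        assert generate_probe_set(SimulationConfig(n_probes_per_category=0)) == []

    def test_fixed_seed_is_deterministic(self):
        a = generate_probe_set(SimulationConfig(n_probes_per_category=25, seed=7))
        b = generate_probe_set(SimulationConfig(n_probes_per_category=25, seed=7))
        assert a == b

    def test_all_truth_labels_present_with_valid_invariants(self, small_probes):
        labels = {p.true_category for p in small_probes}
        assert labels == {
            "heritable_high", "heritable_low", "stochastic_hyper",
            "stochastic_hypo", "random", "uncategorized",
        }
        for p in small_probes:
            assert len(p.sequence) == 60
            assert all(0 <= v <= 1 for v in p.true_level)
            lv = p.true_level
            if p.true_category == "stochastic_hyper":
                assert lv[0] <= lv[1] <= lv[2] <= lv[3]
                assert lv[3] - lv[0] >= 1.0 / 8.0  # one effect-size level step
            if p.true_category == "stochastic_hypo":
                assert lv[0] >= lv[1] >= lv[2] >= lv[3]
            if p.true_category.startswith("heritable"):
                assert max(lv) - min(lv) <= 0.15

    def test_gc_content_tracks_configured_mean(self):
        config = SimulationConfig(n_probes_per_category=167, gc_mean=0.6, seed=5)
        probes = generate_probe_set(config)  # > 1000 sequences
        observed = np.mean([gc_fraction(p.sequence) for p in probes])
        assert abs(observed - 0.6) < 0.02

    def test_some_genes_have_adjacent_probes(self, small_probes):
        ann = probes_to_annotation(small_probes)
        mids = ann.assign(mid=(ann.start + ann.end) / 2)
        close = 0
        for _, grp in mids.groupby("gene_id"):
            gaps = np.diff(np.sort(grp["mid"]))
            close += int((gaps <= 1500).sum())
        assert close > 10

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="gc_mean"):
            SimulationConfig(gc_mean=1.5)
        with pytest.raises(ConfigError, match="n_pixels"):
            SimulationConfig(n_pixels=1)


class TestSimulateArrayScan:
    def test_noise_free_heritable_probe_has_zero_log_ratio(self):
        probes = generate_probe_set(NOISE_FREE)
        arr = simulate_array_scan(probes, "g5", False, NOISE_FREE)
        sig = normalize.compute_ma(arr).set_index("probe_id")
        for p in probes:
            if p.true_category.startswith("heritable"):
                assert sig.loc[p.probe_id, "M"] == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_recovers_true_log_ratio_exactly(self):
        probes = generate_probe_set(NOISE_FREE)
        for tp in ("g1", "g3", "g5"):
            arr = simulate_array_scan(probes, tp, False, NOISE_FREE)
            sig = normalize.compute_ma(arr).set_index("probe_id")
            for p in probes:
                expected = true_log_ratio(p, tp, NOISE_FREE)
                assert sig.loc[p.probe_id, "M"] == pytest.approx(expected, abs=1e-9)

    def test_dye_swap_negates_red_green_ratio_noise_free(self):
        probes = generate_probe_set(NOISE_FREE)
        plain = simulate_array_scan(probes, "g3", False, NOISE_FREE)
        swap = simulate_array_scan(probes, "g3", True, NOISE_FREE)
        for arr, sign in ((plain, 1.0), (swap, -1.0)):
            d = arr.data
            ratio = np.log2(
                (d.f_red_mean - d.b_red_mean) / (d.f_green_mean - d.b_green_mean)
            )
            expected = sign * np.array(
                [true_log_ratio(p, "g3", NOISE_FREE) for p in probes]
            )
            np.testing.assert_allclose(ratio, expected, atol=1e-9)

    def test_swap_array_oriented_ma_matches_truth(self):
        # after orientation by channel_of_progeny the swap array gives the
        # same progeny-over-parental M as the regular array (noise-free)
        probes = generate_probe_set(NOISE_FREE)
        swap = simulate_array_scan(probes, "g3", True, NOISE_FREE)
        sig = normalize.compute_ma(swap).set_index("probe_id")
        for p in probes[:50]:
            assert sig.loc[p.probe_id, "M"] == pytest.approx(
                true_log_ratio(p, "g3", NOISE_FREE), abs=1e-9
            )

    def test_expected_log_ratio_matches_generative_definition(self):
        # a strictly increasing probe observed at g5 carries a 1.5x step
        config = dataclasses.replace(NOISE_FREE, effect_size=1.0)
        probes = generate_probe_set(config)
        arr = simulate_array_scan(probes, "g5", False, config)
        sig = normalize.compute_ma(arr).set_index("probe_id")
        hyper = [p for p in probes if p.true_category == "stochastic_hyper"]
        ms = np.array([sig.loc[p.probe_id, "M"] for p in hyper])
        # all three hyper patterns end "up": shift is +1.5 x effect_size
        np.testing.assert_allclose(ms, 1.5, atol=1e-9)

    def test_scan_determinism_and_timepoint_validation(self, small_probes, small_config):
        a = simulate_array_scan(small_probes, "g1", False, small_config)
        b = simulate_array_scan(small_probes, "g1", False, small_config)
        pd.testing.assert_frame_equal(a.data, b.data)
        with pytest.raises(ConfigError, match="timepoint"):
            simulate_array_scan(small_probes, "parental", False, small_config)

    def test_pixel_sd_columns_encode_standard_error(self, small_probes, small_config):
        # the delta-method closed loop: reported SD / sqrt(n_pixels) is the
        # standard error used to generate the observed channel means
        arrs = [
            simulate_array_scan(small_probes, "g1", False, small_config)
            for _ in range(1)
        ]
        d = arrs[0].data
        assert (d.n_pixels == small_config.n_pixels).all()
        expected_sd = small_config.pixel_sd_scale * small_config.background_mean
        np.testing.assert_allclose(d.b_red_sd, expected_sd)


class TestPlantMotifs:
    def test_zero_rate_gives_empty_manifest(self, small_probes, small_config):
        config = dataclasses.replace(small_config, motif_plant_rate=0.0)
        mats = synthetic_matrix_library(4, seed=1)
        planted, manifest = plant_motifs(small_probes, mats, config)
        assert manifest.empty
        assert [p.sequence for p in planted] == [p.sequence for p in small_probes]

    def test_random_and_uncategorized_probes_never_planted(self, small_probes, small_config):
        config = dataclasses.replace(small_config, motif_plant_rate=1.0)
        mats = synthetic_matrix_library(4, seed=1)
        _, manifest = plant_motifs(small_probes, mats, config)
        truth = {p.probe_id: p.true_category for p in small_probes}
        cats = {truth[pid] for pid in manifest.probe_id}
        assert "random" not in cats and "uncategorized" not in cats
        assert len(manifest) == sum(
            1 for p in small_probes
            if p.true_category not in ("random", "uncategorized")
        )

    def test_planted_consensus_found_at_recorded_offset(self, small_probes, small_config):
        config = dataclasses.replace(small_config, motif_plant_rate=1.0)
        mats = synthetic_matrix_library(3, seed=2)
        planted, manifest = plant_motifs(small_probes, mats, config)
        seqs = probe_sequences(planted)
        by_id = {m.matrix_id: m for m in mats}
        for row in manifest.head(40).itertuples():
            hits = tfbs.scan_sequence(
                row.probe_id, seqs[row.probe_id], [by_id[row.matrix_id]],
                mss_cutoff=0.99, css_cutoff=0.99,
            )
            match = hits[(hits.offset == row.offset) & (hits.strand == row.strand)]
            assert len(match) == 1, f"{row.probe_id}: consensus not at offset"
            assert match.mss.iloc[0] == pytest.approx(1.0)

    def test_motif_longer_than_probe_rejected(self, small_probes, small_config):
        too_long = matrix_from_counts("long", np.ones((61, 4)))
        with pytest.raises(ConfigError, match="longer"):
            plant_motifs(small_probes, [too_long], small_config)

    def test_planted_vs_unplanted_fisher_enrichment(self):
        """200 planted vs 200 unplanted sequences: presence counts give a
        hypergeometric tail far below a Bonferroni threshold (oracle:
        exact hypergeometric enumeration, not the scanner pipeline)."""
        rng = np.random.default_rng(9)
        mat = synthetic_matrix_library(1, seed=4)[0]
        cons = tfbs.consensus(mat)

        def rand_seq():
            return "".join(rng.choice(list("ACGT"), size=60))

        planted_seqs = {}
        for i in range(200):
            s = rand_seq()
            off = int(rng.integers(0, 61 - mat.length))
            planted_seqs[f"pl{i}"] = s[:off] + cons + s[off + mat.length:]
        unplanted = {f"un{i}": rand_seq() for i in range(200)}
        hits_p = tfbs.scan_sequences(planted_seqs, [mat], 0.95, 0.95)
        hits_u = tfbs.scan_sequences(unplanted, [mat], 0.95, 0.95)
        a = hits_p.sequence_id.nunique()
        c = hits_u.sequence_id.nunique()
        assert a == 200
        # independent oracle: exact one-sided hypergeometric tail
        p_oracle = exact_fisher_greater(a, 200 - a, c, 200 - c)
        assert p_oracle < 0.05 / 459 / 5

    def test_half_library_split_creates_shared_starting_level_structure(
        self, small_probes, small_config
    ):
        config = dataclasses.replace(small_config, motif_plant_rate=1.0)
        mats = synthetic_matrix_library(4, seed=1)
        _, manifest = plant_motifs(small_probes, mats, config)
        truth = {p.probe_id: p.true_category for p in small_probes}
        planted = manifest.assign(cat=[truth[p] for p in manifest.probe_id])
        group_x = {"M000", "M001"}
        for cat, expected in [
            ("heritable_high", group_x),
            ("stochastic_hypo", group_x),
            ("heritable_low", {"M002", "M003"}),
            ("stochastic_hyper", {"M002", "M003"}),
        ]:
            assert set(planted[planted.cat == cat].matrix_id) <= expected


def exact_fisher_greater(a, b, c, d):
    """One-sided Fisher p by exhaustive hypergeometric enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, col1)
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k <= c + d:
            p += math.comb(row1, k) * math.comb(n - row1, col1 - k) / denom
    return p


class TestMatchedBackground:
    def test_pure_gc_template_gives_pure_gc_background(self):
        out = generate_matched_background({"t": "GGCC"}, 1, seed=0)
        assert set(out) == {"t|bg0"}
        assert set(out["t|bg0"]) <= {"G", "C"}

    def test_lengths_match_template(self):
        seqs = {"a": "A" * 60, "b": "ACGT" * 15}
        out = generate_matched_background(seqs, 3, seed=1)
        assert len(out) == 6
        assert all(len(s) == 60 for s in out.values())

    def test_mean_gc_converges_to_template_gc(self):
        template = {"t": "ACGT" * 15}  # GC = 0.5, length 60
        out = generate_matched_background(template, 1000, seed=2)
        mean_gc = np.mean([gc_fraction(s) for s in out.values()])
        assert abs(mean_gc - 0.5) < 0.01

    def test_empty_input_and_bad_k(self):
        assert generate_matched_background({}, 2, seed=0) == {}
        with pytest.raises(ConfigError):
            generate_matched_background({"t": "ACGT"}, 0, seed=0)

    def test_deterministic_under_seed(self):
        seqs = {"a": "ACGTACGTAC"}
        assert generate_matched_background(seqs, 5, seed=3) == generate_matched_background(
            seqs, 5, seed=3
        )
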