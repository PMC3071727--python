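import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from earmir import mirna_diffexp as md
from earmir.data_io import DataIOError, TwoColorMirnaArray
from earmir.synthetic_data import PlantedFamily, SyntheticConfig, generate_study


def build_arrays(rows):
    return TwoColorMirnaArray(
        pd.DataFrame(
            rows,
            columns=[
                "probe_id",
                "sample_id",
                "biological_replicate",
                "channel",
                "tissue",
                "fg_intensity",
                "bg_intensity",
                "dye_swap_pair_id",
            ],
        )
    )


def hyb_rows(probe_fg, sample_id, rep, a_channel, pair_id, bg=1.0):
    """Rows for one hybridization; probe_fg maps probe -> (fg_A, fg_B)."""
    rows = []
    for probe, (fa, fb) in probe_fg.items():
        for channel in ("Hy3", "Hy5"):
            tissue = "A" if channel == a_channel else "B"
            fg = fa if tissue == "A" else fb
            rows.append((probe, sample_id, rep, channel, tissue, fg, bg, pair_id))
    return rows


class TestNormalizeMeanScale:
    def test_unequal_sample_means_rescaled_to_grand_mean(self):
        rows = hyb_rows({"p1": (100.0, 200.0), "p2": (100.0, 200.0)}, "h1", 1, "Hy3", "pr1")
        rows += hyb_rows({"p1": (100.0, 200.0), "p2": (100.0, 200.0)}, "h2", 1, "Hy5", "pr1")
        out = md.normalize_mean_scale(build_arrays(rows)).records
        means = out.groupby(["sample_id", "channel"])["fg_intensity"].mean()
        assert np.allclose(means, 150.0)
        # sample with mean 100 scaled by 1.5, with mean 200 by 0.75
        assert np.allclose(
            sorted(out["fg_intensity"].unique()), [150.0]
        )

    def test_equal_means_are_identity(self, null_study):
        once = md.normalize_mean_scale(null_study.mirna_arrays)
        twice = md.normalize_mean_scale(once)
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_random_fixture_means_equal_within_1e9(self, null_study):
        out = md.normalize_mean_scale(null_study.mirna_arrays).records
        means = out.groupby(["sample_id", "channel"])["fg_intensity"].mean()
        assert means.max() - means.min() < 1e-9

    def test_all_zero_sample_is_hard_error(self):
        rows = hyb_rows({"p1": (0.0, 10.0)}, "h1", 1, "Hy3", "pr1")
        rows += hyb_rows({"p1": (0.0, 10.0)}, "h2", 1, "Hy5", "pr1")
        with pytest.raises(DataIOError, match="all-zero"):
            md.normalize_mean_scale(build_arrays(rows))


class TestDetectionCall:
    def _arrays_with_pass_pattern(self, passes):
        """3 bio replicates; target probe exceeds threshold in given reps.

        20 filler probes with alternating background values make the per-
        hybridization background mean and SD estimable.
        """
        rows = []
        for rep in (1, 2, 3):
            for tech, a_channel in ((1, "Hy3"), (2, "Hy5")):
                sample = f"h{rep}_{tech}"
                for i in range(20):
                    bg = 90.0 if i % 2 == 0 else 110.0
                    for channel in ("Hy3", "Hy5"):
                        tissue = "A" if channel == a_channel else "B"
                        rows.append(
                            (f"fill{i}", sample, rep, channel, tissue, 95.0, bg, f"pr{rep}")
                        )
                # threshold = 100 + 2 * sd(filler bg); target fg set around it
                bg_sd = np.std([90.0, 110.0] * 10 + [100.0, 100.0], ddof=1)
                high = 100.0 + 2 * bg_sd + 50.0
                low = 100.0 + 2 * bg_sd - 50.0
                fg_a = high if rep in passes else low
                for channel in ("Hy3", "Hy5"):
                    tissue = "A" if channel == a_channel else "B"
                    fg = fg_a if tissue == "A" else low
                    rows.append(("target", sample, rep, channel, tissue, fg, 100.0, f"pr{rep}"))
        return build_arrays(rows)

    def test_pass_in_two_of_three_replicates_is_detected(self):
        detected = md.detection_call(self._arrays_with_pass_pattern({1, 2}))
        assert detected.loc["target", "detected_in_A"]

    def test_pass_in_one_of_three_is_not_detected(self):
        detected = md.detection_call(self._arrays_with_pass_pattern({2}))
        assert not detected.loc["target", "detected_in_A"]

    def test_too_few_replicates_is_hard_error(self):
        rows = hyb_rows({"p1": (10.0, 10.0)}, "h1", 1, "Hy3", "pr1")
        rows += hyb_rows({"p1": (10.0, 10.0)}, "h2", 1, "Hy5", "pr1")
        with pytest.raises(DataIOError, match="replicates"):
            md.detection_call(build_arrays(rows), min_samples=2)

    def test_spurious_detection_rate_matches_gaussian_tail(self):
        """Unexpressed spots trip the 2-SD rule at the Gaussian tail rate.

        For a signal-free spot, foreground equals its background draw
        N(mu, sigma); averaging the dye-swap pair halves the variance, so a
        biological replicate passes with P(Z >= 2*sqrt(2)) ~ 0.00234.
        """
        cfg = SyntheticConfig(
            n_genes=50,
            n_families=2,
            targets_per_family=10,
            n_null_probes=5,
            n_unexpressed_probes=2000,
            seed=13,
        )
        study = generate_study(cfg)
        df = study.mirna_arrays.records
        bg_stats = df.groupby("sample_id")["bg_intensity"].agg(["mean", "std"])
        thr = bg_stats["mean"] + 2 * bg_stats["std"]
        work = df.assign(threshold=df["sample_id"].map(thr))
        decoys = work[work["probe_id"].str.startswith("unexpr")]
        per_rep = (
            decoys.groupby(["probe_id", "tissue", "biological_replicate"])[
                ["fg_intensity", "threshold"]
            ].mean()
        )
        rate = float((per_rep["fg_intensity"] >= per_rep["threshold"]).mean())
        expected = float(stats.norm.sf(2 * math.sqrt(2)))
        n = len(per_rep)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) < 4 * se


class TestDyeSwapAveraging:
    def test_technical_ratios_average_arithmetically(self):
        rows = hyb_rows({"p1": (2.0**1.0 * 100, 100.0)}, "h1", 1, "Hy3", "pr1")
        rows += hyb_rows({"p1": (2.0**0.6 * 100, 100.0)}, "h2", 1, "Hy5", "pr1")
        ratios = md.average_dye_swaps(build_arrays(rows))
        assert ratios.loc["p1", 1] == pytest.approx(0.8)

    def test_symmetric_pair_returns_its_ratio(self):
        rows = hyb_rows({"p1": (400.0, 100.0)}, "h1", 1, "Hy3", "pr1")
        rows += hyb_rows({"p1": (400.0, 100.0)}, "h2", 1, "Hy5", "pr1")
        ratios = md.average_dye_swaps(build_arrays(rows))
        assert ratios.loc["p1", 1] == pytest.approx(2.0)

    def test_dye_bias_cancels_in_expectation(self):
        """A strong multiplicative channel bias leaves averaged ratios unbiased."""
        cfg = SyntheticConfig(seed=21, dye_bias=2.0, n_unexpressed_probes=0)
        study = generate_study(cfg)
        ratios = md.average_dye_swaps(md.normalize_mean_scale(study.mirna_arrays))
        null_probes = [p for p in ratios.index if "null" in p or "FAM" in p]
        assert abs(ratios.loc[null_probes].to_numpy().mean()) < 0.02

    def test_improper_pair_is_hard_error(self):
        rows = hyb_rows({"p1": (10.0, 10.0)}, "h1", 1, "Hy3", "pr1")
        rows += hyb_rows({"p1": (10.0, 10.0)}, "h2", 1, "Hy3", "pr1")  # no swap
        with pytest.raises(DataIOError, match="pr1"):
            md.average_dye_swaps(build_arrays(rows))

    def test_orientation_invariance_under_channel_relabeling(self, null_study):
        """Swapping every channel label (with tissue kept) changes nothing."""
        ratios = md.average_dye_swaps(null_study.mirna_arrays)
        flipped = null_study.mirna_arrays.records.copy()
        flipped["channel"] = flipped["channel"].map({"Hy3": "Hy5", "Hy5": "Hy3"})
        ratios_flipped = md.average_dye_swaps(TwoColorMirnaArray(flipped))
        pd.testing.assert_frame_equal(ratios, ratios_flipped)


class TestOneSampleT:
    def test_zero_variance_nonzero_mean_is_degenerate(self):
        t, p, degenerate = md.one_sample_t([0.5, 0.5, 0.5])
        assert degenerate and p == 0.0

    def test_symmetric_sample_gives_p_one(self):
        t, p, _ = md.one_sample_t([1.0, -1.0, 0.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_textbook_example(self):
        t, p, degenerate = md.one_sample_t([0.8, 1.0, 1.2])
        assert t == pytest.approx(8.660, abs=1e-3)
        assert p == pytest.approx(0.01307, abs=1e-5)
        assert not degenerate


class TestCallDeMirnas:
    def _results(self, mean, p):
        return pd.DataFrame(
            {
                "mean_log2_ratio": [mean],
                "t": [1.0],
                "p": [p],
                "degenerate": [False],
                "detected_in_A": [True],
                "detected_in_B": [False],
            },
            index=pd.Index(["p1"], name="probe_id"),
        )

    def test_boundary_fold_is_inclusive(self):
        out = md.call_de_mirnas(self._results(math.log2(1.25), 0.049))
        assert out.loc["p1", "de_call"] == "up_in_A"

    def test_below_fold_is_not_de_even_if_significant(self):
        out = md.call_de_mirnas(self._results(math.log2(1.24), 0.001))
        assert out.loc["p1", "de_call"] == "not_de"

    def test_undetected_probe_is_never_de(self):
        res = self._results(1.0, 0.001)
        res["detected_in_A"] = False
        out = md.call_de_mirnas(res)
        assert out.loc["p1", "de_call"] == "not_de"

    def test_planted_probes_recovered_nulls_controlled(self, protein_only_study):
        """Planted fold-2.5 probes recovered; null false-positive rate <= alpha."""
        out = md.mirna_de(protein_only_study.mirna_arrays)
        planted_probes = [
            p
            for p, f in protein_only_study.probe_to_family.items()
            if f in protein_only_study.truth.families
        ]
        recovered = (out.loc[planted_probes, "de_call"] == "up_in_A").sum()
        assert recovered >= math.ceil(0.9 * len(planted_probes))
        nulls = [
            p
            for p in out.index
            if p not in planted_probes and not p.startswith("unexpr")
        ]
        fpr = (out.loc[nulls, "de_call"] != "not_de").mean()
        ci = 1.96 * math.sqrt(0.05 * 0.95 / len(nulls))
        assert fpr <= 0.05 + ci


class TestFamilyMapping:
    def _results(self, probes, ratios, de_flags):
        return pd.DataFrame(
            {
                "mean_log2_ratio": ratios,
                "t": 1.0,
                "p": 0.5,
                "degenerate": False,
                "detected_in_A": True,
                "detected_in_B": True,
                "de_call": ["up_in_A" if d else "not_de" for d in de_flags],
            },
            index=pd.Index(probes, name="probe_id"),
        )

    def test_family_ratio_is_mean_of_members(self):
        res = self._results(["p1", "p2"], [0.4, 0.6], [False, False])
        summary, _ = md.map_to_families(res, {"p1": "F1", "p2": "F1"})
        assert summary.loc["F1", "mean_log2_ratio"] == pytest.approx(0.5)

    def test_one_de_member_makes_family_de(self):
        res = self._results(["p1", "p2"], [0.4, 0.6], [True, False])
        summary, _ = md.map_to_families(res, {"p1": "F1", "p2": "F1"})
        assert summary.loc["F1", "any_de"]
        assert summary.loc["F1", "direction"] == "up_in_A"

    def test_ambiguous_probe_mapping_is_hard_error(self):
        res = self._results(["p1"], [0.4], [False])
        mapping = pd.DataFrame(
            {"probe_id": ["p1", "p1"], "family_id": ["F1", "F2"]}
        )
        with pytest.raises(DataIOError, match="multiple families"):
            md.map_to_families(res, mapping)

    def test_families_without_probes_counted(self):
        res = self._results([f"p{i}" for i in range(15)], [0.1] * 15, [False] * 15)
        mapping = {f"p{i}": f"F{i}" for i in range(15)}
        families = [f"F{i}" for i in range(20)]
        summary, n_without = md.map_to_families(res, mapping, families=families)
        assert len(summary) == 15
        assert n_without == 5


def test_same_family_probes_estimate_similar_ratios():
    """Probes sharing a true ratio (hairpin-mate analog) correlate strongly."""
    planted = tuple(
        PlantedFamily(f"FAM{i:03d}", "protein_only", 0.3, 0.4) for i in range(1, 11)
    )
    study = generate_study(SyntheticConfig(seed=17, planted_families=planted))
    out = md.probe_statistics(study.mirna_arrays)
    fam_members = {}
    for probe, fam in study.probe_to_family.items():
        fam_members.setdefault(fam, []).append(probe)
    m1 = [out.loc[ps[0], "mean_log2_ratio"] for ps in fam_members.values()]
    m2 = [out.loc[ps[1], "mean_log2_ratio"] for ps in fam_members.values()]
    assert np.corrcoef(m1, m2)[0, 1] > 0.9
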