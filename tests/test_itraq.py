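import numpy as np
import pandas as pd
import pytest

from renalmark import (
    PipelineConfig,
    ReporterRunTable,
    call_de_proteins,
    gen_itraq,
    normalize_run,
    protein_ratios,
)


def make_run(intensities: dict, cmap=None, run_id="run1") -> ReporterRunTable:
    cmap = cmap or {"114": "H", "115": "R", "116": "C", "117": "M"}
    df = pd.DataFrame(intensities)
    df.index = [f"P{i}" for i in range(len(df))]
    return ReporterRunTable(run_id=run_id, intensities=df, channel_to_group=cmap)


class TestNormalizeRun:
    def test_identical_channels_unchanged(self):
        run = make_run({c: [1.0, 2.0, 3.0] for c in ("114", "115", "116", "117")})
        out = normalize_run(run)
        assert np.array_equal(out.intensities.to_numpy(), run.intensities.to_numpy())

    def test_doubled_channel_scaled_back(self):
        base = [1.0, 2.0, 3.0]
        run = make_run({"114": base, "115": [2 * v for v in base],
                        "116": base, "117": base})
        out = normalize_run(run)
        assert np.allclose(out.intensities["115"], base)

    def test_per_channel_median_ratio_is_one(self):
        rng = np.random.default_rng(0)
        eff = {"114": 1.0, "115": 0.5, "116": 2.3, "117": 1.7}
        base = rng.lognormal(10, 1, size=101)
        run = make_run({c: base * f * rng.lognormal(0, 0.2, size=101)
                        for c, f in eff.items()})
        out = normalize_run(run)
        ref = out.intensities["114"].to_numpy()
        for c in ("115", "116", "117"):
            med = np.median(out.intensities[c].to_numpy() / ref)
            assert med == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        run = make_run({c: rng.lognormal(8, 1, size=51) for c in ("114", "115", "116", "117")})
        once = normalize_run(run)
        twice = normalize_run(once)
        assert np.allclose(once.intensities.to_numpy(), twice.intensities.to_numpy())

    def test_scale_invariance_of_ratios(self):
        rng = np.random.default_rng(2)
        data = {c: rng.lognormal(8, 1, size=31) for c in ("114", "115", "116", "117")}
        run_a = make_run(data)
        scaled = dict(data)
        scaled["116"] = data["116"] * 7.5
        run_b = make_run(scaled)
        ra = normalize_run(run_a).intensities
        rb = normalize_run(run_b).intensities
        assert np.allclose((ra["115"] / ra["116"]).to_numpy(),
                           (rb["115"] / rb["116"]).to_numpy())

    def test_nonpositive_intensity_rejected_with_names(self):
        with pytest.raises(ValueError, match=r"P1.*115"):
            make_run({"114": [1.0, 1.0], "115": [1.0, 0.0],
                      "116": [1.0, 1.0], "117": [1.0, 1.0]})


class TestProteinRatios:
    def test_two_run_average_matches_printed_style_example(self):
        # run ratios 4.0 and 4.9886 average to 4.4943
        run1 = make_run({"114": [1.0], "115": [4.0], "116": [1.0], "117": [1.0]})
        run2 = make_run({"114": [4.9886], "115": [1.0], "116": [4.9886], "117": [4.9886]},
                        cmap={"114": "R", "115": "H", "116": "M", "117": "C"},
                        run_id="run2")
        rec = protein_ratios(run1, run2)[0]
        assert rec.ratio_RH == pytest.approx(4.4943, abs=1e-12)

    def test_identical_runs_average_to_same_ratio(self):
        run1 = make_run({"114": [2.0], "115": [6.0], "116": [3.0], "117": [4.0]})
        run2 = make_run({"114": [2.0], "115": [6.0], "116": [3.0], "117": [4.0]},
                        run_id="run2")
        rec = protein_ratios(run1, run2)[0]
        assert rec.ratio_RH == pytest.approx(3.0)
        assert rec.ratio_RC == pytest.approx(2.0)
        assert rec.ratio_RM == pytest.approx(1.5)

    def test_label_swap_symmetry(self):
        """Relabelling channels in both runs leaves averaged ratios invariant."""
        rng = np.random.default_rng(3)
        data1 = {c: rng.lognormal(8, 0.5, size=20) for c in ("114", "115", "116", "117")}
        data2 = {c: rng.lognormal(8, 0.5, size=20) for c in ("114", "115", "116", "117")}
        m1 = {"114": "H", "115": "R", "116": "C", "117": "M"}
        m2 = {"114": "R", "115": "H", "116": "M", "117": "C"}
        base = protein_ratios(make_run(data1, m1), make_run(data2, m2, "run2"))
        # permute the channel labels consistently in data and maps
        perm = {"114": "117", "115": "116", "116": "115", "117": "114"}
        data1p = {perm[c]: v for c, v in data1.items()}
        data2p = {perm[c]: v for c, v in data2.items()}
        m1p = {perm[c]: g for c, g in m1.items()}
        m2p = {perm[c]: g for c, g in m2.items()}
        swapped = protein_ratios(make_run(data1p, m1p), make_run(data2p, m2p, "run2"))
        for a, b in zip(base, swapped):
            assert a.ratio_RH == pytest.approx(b.ratio_RH)
            assert a.ratio_RC == pytest.approx(b.ratio_RC)
            assert a.ratio_RM == pytest.approx(b.ratio_RM)

    def test_zero_noise_synthetic_recovery(self):
        truth_ratios = {"PA": (4.0, 2.0, 1.5), "PB": (0.5, 0.6, 0.4)}
        run1, run2, truth = gen_itraq(30, truth_ratios, seed=5)
        recs = {r.protein: r for r in protein_ratios(normalize_run(run1), normalize_run(run2))}
        for prot, (rh, rc, rm) in truth.itraq_true_ratios.items():
            assert recs[prot].ratio_RH == pytest.approx(rh, abs=1e-12)
            assert recs[prot].ratio_RC == pytest.approx(rc, abs=1e-12)
            assert recs[prot].ratio_RM == pytest.approx(rm, abs=1e-12)

    def test_single_run_protein_flagged(self):
        run1 = make_run({"114": [1.0, 1.0], "115": [4.0, 2.0],
                         "116": [1.0, 1.0], "117": [1.0, 1.0]})
        run2 = make_run({"114": [1.0], "115": [4.0], "116": [1.0], "117": [1.0]},
                        run_id="run2")
        recs = {r.protein: r for r in protein_ratios(run1, run2)}
        assert recs["P1"].runs_present == 1


class TestCalls:
    @pytest.mark.parametrize(
        "ratios,expected_calls,expected_up",
        [
            ((4.4943, 4.060075, 2.269848), ("up", "up", "up"), True),
            ((1.0, 1.0, 1.0), ("unchanged", "unchanged", "unchanged"), False),
            ((1.5, 1.5, 1.5), ("up", "up", "up"), True),   # inclusive boundary
            ((0.67, 0.67, 0.67), ("down", "down", "down"), False),
            ((1.49, 2.0, 2.0), ("unchanged", "up", "up"), False),
        ],
    )
    def test_threshold_calls(self, ratios, expected_calls, expected_up):
        from renalmark.itraq import ProteinRatioRecord

        rec = ProteinRatioRecord(protein="P", gene="G", ratio_RH=ratios[0],
                                 ratio_RC=ratios[1], ratio_RM=ratios[2], per_run={})
        call_de_proteins([rec], PipelineConfig())
        assert (rec.calls["R:H"], rec.calls["R:C"], rec.calls["R:M"]) == expected_calls
        assert rec.rcc_upregulated is expected_up
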