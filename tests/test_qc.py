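import numpy as np
import pandas as pd
import pytest

from snparray import qc
from snparray.calling import NOCALL
from snparray.qc import PROTOCOLS, QcThresholds


def _calls_frame(data, samples=None):
    df = pd.DataFrame(data, dtype=object)
    if samples is not None:
        df.index = samples
    return df


class TestThresholds:
    def test_defaults_match_protocol_table(self):
        d = PROTOCOLS["default"]
        assert d.dqc_min == 0.82
        assert d.sample_cr_min == 0.97
        assert d.plate_pass_fraction_min == 0.95
        assert d.plate_cr_min == 0.985
        assert d.snp_cr_cutoff == 0.97
        assert d.confidence_threshold == 0.15
        assert d.rescue_cr_cutoff is None

    def test_modified_protocol(self):
        m = PROTOCOLS["modified"]
        assert m.dqc_min == 0.50
        assert m.sample_cr_min == 0.80
        assert m.snp_cr_cutoff == 0.95
        assert m.rescue_cr_cutoff == 0.80
        assert m.rescue_confidence_threshold == 0.10

    def test_rescue_cutoffs(self):
        for pct in (90, 80, 70, 60):
            assert PROTOCOLS[f"rescue{pct}"].rescue_cr_cutoff == pct / 100

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            QcThresholds(dqc_min=1.5)
        with pytest.raises(ValueError):
            QcThresholds(snp_cr_cutoff=0.5, rescue_cr_cutoff=0.9)


class TestSamplePlateQc:
    @staticmethod
    def _setup(dqc_values, n_probesets=10):
        n = len(dqc_values)
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "plate_id": "p1",
                "dqc": dqc_values,
            }
        )
        calls = _calls_frame(
            np.full((n, n_probesets), "AA"), samples["sample_id"]
        )
        return samples, calls

    def test_low_dqc_fails_default(self):
        samples, calls = self._setup([0.80] + [0.95] * 99)
        kept, _ = qc.sample_plate_qc(samples, calls, PROTOCOLS["default"])
        assert "s0" not in kept
        assert len(kept) == 99

    def test_low_dqc_passes_modified(self):
        samples, calls = self._setup([0.80] + [0.95] * 99)
        kept, _ = qc.sample_plate_qc(samples, calls, PROTOCOLS["modified"])
        assert "s0" in kept

    def test_plate_pass_fraction_boundary(self):
        # 96 of 100 passing = 0.96 >= 0.95: plate survives
        samples, calls = self._setup([0.5] * 4 + [0.95] * 96)
        kept, report = qc.sample_plate_qc(samples, calls, PROTOCOLS["default"])
        assert report.loc[0, "plate_pass"]
        assert len(kept) == 96

    def test_failing_plate_drops_all_samples(self):
        samples, calls = self._setup([0.5] * 10 + [0.95] * 90)
        kept, report = qc.sample_plate_qc(samples, calls, PROTOCOLS["default"])
        assert not report.loc[0, "plate_pass"]
        assert kept == []

    def test_sample_call_rate_filter(self):
        samples, calls = self._setup([0.95] * 10, n_probesets=100)
        calls.iloc[0, :10] = NOCALL  # sample CR 0.90 < 0.97
        kept, _ = qc.sample_plate_qc(samples, calls, PROTOCOLS["default"])
        assert "s0" not in kept

    def test_plate_cr_uses_passing_samples_only(self):
        samples, calls = self._setup([0.95] * 97 + [0.5] * 3, n_probesets=100)
        calls.iloc[-3:, :50] = NOCALL  # failing samples have terrible CR
        _, report = qc.sample_plate_qc(samples, calls, PROTOCOLS["default"])
        assert report.loc[0, "plate_call_rate"] == pytest.approx(1.0)


class TestClassifySnp:
    thresholds = PROTOCOLS["default"]

    def test_monomorphic(self):
        calls = np.array(["AA"] * 100, dtype=object)
        out = qc.classify_snp(calls, 0.0, True, self.thresholds)
        assert out["category"] == "MonoHighResolution"
        assert not out["successful"]

    def test_no_minor_hom(self):
        calls = np.array(["AA"] * 80 + ["AB"] * 15 + [NOCALL], dtype=object)
        out = qc.classify_snp(calls, 0.0, True, self.thresholds)
        assert out["category"] == "NoMinorHom"

    def test_call_rate_below_threshold(self):
        calls = np.array(
            ["AA"] * 60 + ["AB"] * 20 + ["BB"] * 10 + [NOCALL] * 10, dtype=object
        )
        out = qc.classify_snp(calls, 0.0, True, self.thresholds)
        assert out["category"] == "CallRateBelowThreshold"
        assert out["call_rate"] == pytest.approx(0.90)

    def test_poly_high_resolution(self):
        calls = np.array(["AA"] * 50 + ["AB"] * 30 + ["BB"] * 20, dtype=object)
        out = qc.classify_snp(calls, 0.0, True, self.thresholds)
        assert out["category"] == "PolyHighResolution"
        assert out["successful"]

    def test_otv_takes_precedence(self):
        calls = np.array(["AA"] * 50 + ["AB"] * 50, dtype=object)
        out = qc.classify_snp(calls, 0.30, True, self.thresholds)
        assert out["category"] == "OTV"

    def test_unresolved_is_other(self):
        calls = np.array(["AA"] * 100, dtype=object)
        out = qc.classify_snp(calls, 0.0, False, self.thresholds)
        assert out["category"] == "Other"

    def test_zero_samples_raises(self):
        with pytest.raises(ValueError, match="zero"):
            qc.classify_snp(np.array([], dtype=object), 0.0, True, self.thresholds)


class TestRescue:
    @staticmethod
    def _dataset(conf_values, calls_values, category):
        n = len(calls_values)
        calls = _calls_frame(
            {"ps1": calls_values}, [f"s{i}" for i in range(n)]
        )
        conf = pd.DataFrame(
            {"ps1": conf_values}, index=[f"s{i}" for i in range(n)]
        )
        cls = pd.DataFrame(
            [
                {
                    "probeset_id": "ps1",
                    "category": category,
                    "call_rate": float(
                        np.mean(np.asarray(calls_values, dtype=object) != NOCALL)
                    ),
                    "n_aa": sum(c == "AA" for c in calls_values),
                    "n_ab": sum(c == "AB" for c in calls_values),
                    "n_bb": sum(c == "BB" for c in calls_values),
                    "n_nc": sum(c == NOCALL for c in calls_values),
                    "successful": False,
                }
            ]
        )
        return cls, calls, conf

    def test_other_rescued(self):
        calls_v = ["AA"] * 50 + ["AB"] * 25 + ["BB"] * 10 + [NOCALL] * 15
        conf_v = [0.05] * 85 + [0.5] * 15
        cls, calls, conf = self._dataset(conf_v, calls_v, "Other")
        out = qc.rescue_snps(cls, calls, conf, PROTOCOLS["rescue80"])
        assert out.loc[0, "category"] == "Rescued"
        assert out.loc[0, "successful"]
        assert out.loc[0, "call_rate"] == pytest.approx(0.85)

    def test_boundary_cr_not_rescued(self):
        # re-thresholded CR 0.55 < cutoff 0.60: unchanged
        calls_v = ["AA"] * 40 + ["AB"] * 15 + [NOCALL] * 45
        conf_v = [0.05] * 55 + [0.5] * 45
        cls, calls, conf = self._dataset(conf_v, calls_v, "CallRateBelowThreshold")
        out = qc.rescue_snps(cls, calls, conf, PROTOCOLS["rescue60"])
        assert out.loc[0, "category"] == "CallRateBelowThreshold"

    def test_monomorphic_after_rethreshold_not_successful(self):
        calls_v = ["AA"] * 95 + [NOCALL] * 5
        conf_v = [0.05] * 100
        cls, calls, conf = self._dataset(conf_v, calls_v, "Other")
        out = qc.rescue_snps(cls, calls, conf, PROTOCOLS["rescue80"])
        assert not out.loc[0, "successful"]

    def test_rethreshold_only_adds_nocalls(self):
        calls_v = ["AA"] * 60 + ["AB"] * 40
        conf_v = [0.12] * 50 + [0.05] * 50
        cls, calls, conf = self._dataset(conf_v, calls_v, "Other")
        out = qc.rescue_snps(cls, calls, conf, PROTOCOLS["rescue60"])
        # 50 calls at conf 0.12 > 0.10 become NoCall: CR 0.5 < 0.6
        assert out.loc[0, "category"] == "Other"

    def test_untouched_categories(self):
        calls_v = ["AA"] * 50 + ["AB"] * 50
        conf_v = [0.05] * 100
        cls, calls, conf = self._dataset(conf_v, calls_v, "PolyHighResolution")
        cls["successful"] = True
        out = qc.rescue_snps(cls, calls, conf, PROTOCOLS["rescue60"])
        assert out.loc[0, "category"] == "PolyHighResolution"

    def test_missing_cutoff_raises(self):
        cls, calls, conf = self._dataset([0.05], ["AA"], "Other")
        with pytest.raises(ValueError, match="rescue_cr_cutoff"):
            qc.rescue_snps(cls, calls, conf, PROTOCOLS["default"])


class TestSummarizeCategories:
    def test_printed_protocol_arithmetic(self):
        counts = {
            "PolyHighResolution": 31,
            "NoMinorHom": 13,
            "MonoHighResolution": 16,
            "Rescued": 13,
            "Other": 24,
            "CallRateBelowThreshold": 2,
            "OTV": 1,
        }
        out = qc.summarize_categories(counts)
        assert out["converted"] == 73
        assert out["percent_successful"] == 44.0

    def test_all_poly_fraction_one(self):
        out = qc.summarize_categories({"PolyHighResolution": 57})
        assert out["percent_successful"] == 100.0
        assert out["successful"] == 57

    def test_partition_sums(self):
        counts = dict(zip(qc.CATEGORIES, [3, 5, 7, 11, 13, 17, 19]))
        out = qc.summarize_categories(counts)
        assert sum(out["counts"].values()) == out["total"]


class TestRunProtocol:
    def test_rescue_monotonicity(self, truth, called):
        calls, conf, diags = called
        successes = []
        for name in ("rescue60", "rescue70", "rescue80", "rescue90", "default"):
            res = qc.run_protocol_populations(
                calls, conf, diags, truth.samples, name
            )
            successes.append(res["successful_sum"])
        assert successes == sorted(successes, reverse=True)

    def test_category_partition(self, truth, called):
        calls, conf, diags = called
        res = qc.run_protocol(calls, conf, diags, truth.samples, "rescue60")
        cls = res["classifications"]
        assert cls["category"].isin(qc.CATEGORIES).all()
        assert len(cls) == calls.shape[1]
        assert res["summary"]["total"] == len(cls)

    def test_unknown_protocol(self, truth, called):
        calls, conf, diags = called
        with pytest.raises(ValueError, match="unknown protocol"):
            qc.run_protocol(calls, conf, diags, truth.samples, "bogus")

    def test_bruteforce_reclassifier_equivalence(self, truth, called):
        # exhaustive recomputation of categories from raw confidences on a
        # small probeset slice must agree with the pipeline output
        calls, conf, diags = called
        thresholds = PROTOCOLS["rescue70"]
        panel = qc.qc_panel(calls, diags, thresholds)
        kept, _ = qc.sample_plate_qc(truth.samples, calls, thresholds, panel)
        sub_c, sub_q = calls.loc[kept], conf.loc[kept]
        subset = list(calls.columns[:50])
        pipeline = qc.rescue_snps(
            qc.classify_all(sub_c[subset], diags, thresholds),
            sub_c[subset],
            sub_q[subset],
            thresholds,
        ).set_index("probeset_id")
        diag_idx = diags.set_index("probeset_id")
        for ps in subset:
            vec = sub_c[ps].to_numpy(dtype=object)
            counts = qc.genotype_counts(vec)
            cat = qc._category_from_counts(
                counts,
                float(diag_idx.loc[ps, "otv_fraction"]),
                bool(diag_idx.loc[ps, "resolved"]),
                thresholds,
            )
            if cat in ("Other", "CallRateBelowThreshold"):
                vec2 = vec.copy()
                vec2[sub_q[ps].to_numpy() > 0.10] = NOCALL
                c2 = qc.genotype_counts(vec2)
                n_called = c2["n_aa"] + c2["n_ab"] + c2["n_bb"]
                cr = n_called / len(vec2)
                classes = sum(c2[k] > 0 for k in ("n_aa", "n_ab", "n_bb"))
                if cr >= 0.70 and classes >= 2:
                    cat = "Rescued"
            assert pipeline.loc[ps, "category"] == cat


class TestDuplicateAccuracy:
    @staticmethod
    def _pair_calls(calls_a, calls_b):
        calls = _calls_frame(
            np.array([calls_a, calls_b], dtype=object), ["s1", "s2"]
        )
        samples = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "tree_id": ["t1", "t1"]}
        )
        return calls, samples

    def test_counting_example(self):
        # 10 SNPs, 9 concordant, 1 pair AA vs AB
        a = ["AA"] * 10
        b = ["AA"] * 9 + ["AB"]
        calls, samples = self._pair_calls(a, b)
        out = qc.duplicate_accuracy(calls, samples)
        assert out["genotype_accuracy"] == pytest.approx(0.90)
        assert out["allele_accuracy"] == pytest.approx(0.95)
        assert out["missing_fraction"] == 0.0

    def test_opposite_homozygotes(self):
        calls, samples = self._pair_calls(["AA"], ["BB"])
        out = qc.duplicate_accuracy(calls, samples)
        assert out["genotype_accuracy"] == 0.0
        assert out["allele_accuracy"] == 0.0

    def test_missing_excluded(self):
        calls, samples = self._pair_calls(
            ["AA", NOCALL], ["AA", "AB"]
        )
        out = qc.duplicate_accuracy(calls, samples)
        assert out["genotype_accuracy"] == 1.0
        assert out["missing_fraction"] == pytest.approx(0.5)

    def test_no_duplicates_raises(self):
        calls = _calls_frame(np.array([["AA"]], dtype=object), ["s1"])
        samples = pd.DataFrame({"sample_id": ["s1"], "tree_id": ["t1"]})
        with pytest.raises(ValueError, match="duplicate"):
            qc.duplicate_accuracy(calls, samples)

    def test_allele_ge_genotype_accuracy(self, truth, called):
        calls, _, _ = called
        out = qc.duplicate_accuracy(calls, truth.samples)
        assert out["allele_accuracy"] >= out["genotype_accuracy"]

    def test_allele_ge_genotype_random(self):
        rng = np.random.default_rng(0)
        genos = np.array(["AA", "AB", "BB", NOCALL], dtype=object)
        for _ in range(20):
            a = rng.choice(genos, 30)
            b = rng.choice(genos, 30)
            calls = _calls_frame(np.array([a, b], dtype=object), ["s1", "s2"])
            samples = pd.DataFrame(
                {"sample_id": ["s1", "s2"], "tree_id": ["t1", "t1"]}
            )
            both = (a != NOCALL) & (b != NOCALL)
            if not both.any():
                continue
            out = qc.duplicate_accuracy(calls, samples)
            assert out["allele_accuracy"] >= out["genotype_accuracy"] - 1e-12
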