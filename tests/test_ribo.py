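import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_footprints, run_de

from ribomics import ribo, synthio
from ribomics.normde import AbundanceMatrix, NormalizedMatrix, SizeFactors, compute_size_factors, normalize_matrix
from ribomics.ribo import (
    TranscriptModel,
    assign_psites,
    classify_dteg,
    codon_occupancy,
    compute_te,
    differential_te,
    dteg_partition,
    flagged_percent,
    pause_scores,
    riboseq_qc,
)


def _norm(df, conditions):
    sf = SizeFactors(
        pd.Series(1.0, index=df.index), pd.Series(1.0, index=df.columns)
    )
    return NormalizedMatrix(df, sf, conditions)


COND = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}


class TestAssignPsites:
    def test_additive_rule(self):
        model = TranscriptModel("T", 20, 60, 20)
        fp = pd.DataFrame({"transcript_id": ["T"], "pos5": [0], "length": [28]})
        out, dropped = assign_psites(fp, {"T": model}, offsets={28: 12})
        assert dropped == 0
        assert out.loc[0, "psite"] == 12
        assert out.loc[0, "asite"] == 15

    def test_missing_length_without_default_raises(self):
        model = TranscriptModel("T", 20, 60, 20)
        fp = pd.DataFrame({"transcript_id": ["T"], "pos5": [0], "length": [35]})
        with pytest.raises(KeyError, match="35"):
            assign_psites(fp, {"T": model})

    def test_missing_length_with_default(self):
        model = TranscriptModel("T", 20, 60, 20)
        fp = pd.DataFrame({"transcript_id": ["T"], "pos5": [0], "length": [35]})
        out, _ = assign_psites(fp, {"T": model}, default_offset=12)
        assert out.loc[0, "psite"] == 12

    def test_out_of_bounds_dropped_and_counted(self):
        model = TranscriptModel("T", 20, 60, 20)
        fp = pd.DataFrame(
            {"transcript_id": ["T", "T"], "pos5": [95, 10], "length": [28, 28]}
        )
        out, dropped = assign_psites(fp, {"T": model})
        assert dropped == 1
        assert len(out) == 1 and out.loc[0, "psite"] == 22


class TestQC:
    def test_all_orf(self):
        model = TranscriptModel("T", 20, 60, 20)
        fp = make_footprints(model, [1] * 20)
        assigned, _ = assign_psites(fp, {"T": model})
        report = riboseq_qc(assigned, {"T": model})
        assert report.region_fractions["orf"] == 1.0

    def test_counting_example(self):
        model = TranscriptModel("T", 30, 30, 30)
        rows = (
            [("T", p, 30) for p in [0, 5]]          # psite 12, 17 -> utr5
            + [("T", p, 30) for p in [20, 25, 30, 35, 40, 45]]  # 32..57 -> orf
            + [("T", p, 30) for p in [50, 55]]      # 62, 67 -> utr3
        )
        fp = pd.DataFrame(rows, columns=["transcript_id", "pos5", "length"])
        assigned, dropped = assign_psites(fp, {"T": model})
        assert dropped == 0
        report = riboseq_qc(assigned, {"T": model})
        assert report.region_fractions == {"utr5": 0.2, "orf": 0.6, "utr3": 0.2, "other": 0.0}

    def test_noncoding_counts_as_other(self):
        model = TranscriptModel("N", 0, 0, 100, coding=False)
        fp = pd.DataFrame({"transcript_id": ["N"], "pos5": [10], "length": [28]})
        assigned, _ = assign_psites(fp, {"N": model})
        report = riboseq_qc(assigned, {"N": model})
        assert report.region_fractions["other"] == 1.0

    def test_fractions_sum_to_one(self, transcript_model):
        fp = synthio.generate_footprints(
            transcript_model, synthio.FootprintSimConfig(n_reads=2000, seed=0)
        )
        assigned, _ = assign_psites(fp, {transcript_model.transcript_id: transcript_model})
        report = riboseq_qc(assigned, {transcript_model.transcript_id: transcript_model})
        assert sum(report.region_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            riboseq_qc(pd.DataFrame(columns=["transcript_id", "psite", "length"]), {})


class TestComputeTE:
    def test_equal_matrices_zero_te(self):
        df = pd.DataFrame(np.full((3, 4), 8.0), columns=list(COND),
                          index=["g0", "g1", "g2"])
        te = compute_te(_norm(df, COND), _norm(df.copy(), COND), min_mean=0, pseudocount=0.5)
        assert np.allclose(te.log2_te, 0.0)

    def test_fourfold_rpf(self):
        rna = pd.DataFrame(np.full((2, 4), 5.0), columns=list(COND), index=["g0", "g1"])
        te = compute_te(_norm(rna, COND), _norm(rna * 4, COND), min_mean=0, pseudocount=0)
        assert np.allclose(te.log2_te, 2.0)

    def test_low_expression_excluded_with_reason(self):
        rna = pd.DataFrame(
            [[0.1] * 4, [10.0] * 4], columns=list(COND), index=["low", "high"]
        )
        rpf = pd.DataFrame(np.full((2, 4), 10.0), columns=list(COND), index=["low", "high"])
        te = compute_te(_norm(rna, COND), _norm(rpf, COND), min_mean=1.0)
        assert list(te.log2_te.index) == ["high"]
        assert te.excluded.loc["low", "reason"] == "low_rna"

    def test_no_overlap_rejected(self):
        a = pd.DataFrame([[1.0] * 4], columns=list(COND), index=["x"])
        b = pd.DataFrame([[1.0] * 4], columns=list(COND), index=["y"])
        with pytest.raises(ValueError, match="overlap"):
            compute_te(_norm(a, COND), _norm(b, COND))


class TestDifferentialTE:
    def test_identical_te_not_significant(self):
        df = pd.DataFrame(np.full((2, 4), 4.0), columns=list(COND), index=["g0", "g1"])
        te = compute_te(_norm(df, COND), _norm(df.copy(), COND), min_mean=0)
        te = differential_te(te)
        assert (te.stats["p"] == 1.0).all()
        assert not te.stats["te_significant"].any()

    def test_single_replicate_rejected(self):
        cond = {"c1": "control", "t1": "treated", "t2": "treated"}
        df = pd.DataFrame(np.ones((2, 3)), columns=list(cond), index=["g0", "g1"])
        te = compute_te(_norm(df, cond), _norm(df.copy(), cond), min_mean=0)
        with pytest.raises(ValueError, match="2 replicates"):
            differential_te(te)

    def test_planted_te_effect_recovered_with_adequate_power(self):
        # the classifier needs a resolvable dispersion at n=4; alpha=0.005
        # gives the per-gene Welch test enough power after BH
        hits = 0
        for seed in range(6):
            cfg = synthio.SimulationConfig(
                n_genes=1000, n_reps_per_condition=4, nb_dispersion=0.005,
                baseline_mean=500.0, baseline_log2_sd=0.5, seed=seed,
                class_proportions={"exclusive": 0.1, "null": 0.9},
            )
            data = synthio.generate_multiomics(cfg)
            rna_norm, _ = run_de(data.rna)
            rpf_norm, _ = run_de(data.rpf)
            te = differential_te(compute_te(rna_norm, rpf_norm, min_mean=1.0))
            planted = data.truth.index[data.truth["true_class"] == "exclusive"]
            recovered = te.stats.loc[
                te.stats.index.intersection(planted), "te_significant"
            ].mean()
            hits += recovered > 0.7
        assert hits >= 5

    def test_null_pvalues_uniform(self):
        # permutation-style oracle: no effect anywhere -> p ~ U(0,1)
        cfg = synthio.SimulationConfig(
            n_genes=1500, n_reps_per_condition=4, seed=10,
            class_proportions={"null": 1.0},
        )
        data = synthio.generate_multiomics(cfg)
        rna_norm, _ = run_de(data.rna)
        rpf_norm, _ = run_de(data.rpf)
        te = differential_te(compute_te(rna_norm, rpf_norm, min_mean=1.0))
        ks = stats.kstest(te.stats["p"], "uniform")
        assert ks.pvalue > 0.01


class TestClassifyDTEG:
    def _frame(self, sig, direction):
        return pd.DataFrame(
            {"significant": [sig], "direction": [direction],
             "te_significant": [sig], "log2fc": [0.0]}, index=["g"]
        )

    def _one(self, rna_sig, rna_dir, te_sig, te_dir):
        rna = pd.DataFrame({"significant": [rna_sig], "direction": [rna_dir]}, index=["g"])
        te = pd.DataFrame({"te_significant": [te_sig], "direction": [te_dir]}, index=["g"])
        rec = classify_dteg(rna, te)
        return rec.loc["g", "dteg_class"], rec.loc["g", "unclassifiable"]

    def test_exclusive(self):
        assert self._one(False, "up", True, "up") == ("exclusive", False)

    def test_buffered(self):
        assert self._one(True, "up", True, "down") == ("buffered", False)

    def test_neither_none(self):
        assert self._one(False, "up", False, "down") == ("none", False)

    def test_flat_significant_flagged(self):
        cls, flag = self._one(True, "flat", False, "up")
        assert cls == "unclassifiable" and flag

    def test_exhaustive_rule_table(self):
        def oracle(rna_sig, rna_dir, te_sig, te_dir):
            if (rna_sig and rna_dir == "flat") or (te_sig and te_dir == "flat"):
                return "unclassifiable"
            if te_sig and not rna_sig:
                return "exclusive"
            if te_sig and rna_sig:
                return "intensified" if rna_dir == te_dir else "buffered"
            if rna_sig:
                return "forwarded"
            return "none"

        for rna_sig, rna_dir, te_sig, te_dir in itertools.product(
            [False, True], ["up", "down", "flat"], [False, True], ["up", "down", "flat"]
        ):
            got, _ = self._one(rna_sig, rna_dir, te_sig, te_dir)
            assert got == oracle(rna_sig, rna_dir, te_sig, te_dir), (
                rna_sig, rna_dir, te_sig, te_dir
            )

    def test_partition_counts(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(200)]
        rna = pd.DataFrame(
            {
                "significant": rng.random(200) < 0.4,
                "direction": rng.choice(["up", "down"], 200),
            },
            index=genes,
        )
        te = pd.DataFrame(
            {
                "te_significant": rng.random(200) < 0.4,
                "direction": rng.choice(["up", "down"], 200),
            },
            index=genes,
        )
        rec = classify_dteg(rna, te)
        counts = dteg_partition(rec)
        assert counts["dteg_total"] == int(te["te_significant"].sum())
        assert (rec.groupby(level=0).size() == 1).all()


class TestCodonOccupancy:
    def test_uniform_single_codon_identity(self):
        seq = "A" * 12 + "GCT" * 20 + "A" * 12
        model = TranscriptModel("T", 12, 60, 12, seq)
        fp = make_footprints(model, [5] * 20)
        assigned, _ = assign_psites(fp, {"T": model})
        # use the P-site so every placed read stays on its codon
        occ = codon_occupancy(assigned, {"T": model}, site="P", edge_trim=0, min_coverage=0.5)
        assert occ.loc["GCT", "occupancy"] == pytest.approx(1.0)
        assert occ.loc["GCT", "n_positions"] == 20

    def test_weighted_mean_is_one(self, transcript_model):
        fp = synthio.generate_footprints(
            transcript_model,
            synthio.FootprintSimConfig(n_reads=20_000, pause_multipliers={"AAA": 3.0}, seed=2),
        )
        assigned, _ = assign_psites(fp, {transcript_model.transcript_id: transcript_model})
        occ = codon_occupancy(assigned, {transcript_model.transcript_id: transcript_model})
        mask = occ["n_positions"] > 0
        weighted = (occ.loc[mask, "occupancy"] * occ.loc[mask, "n_positions"]).sum()
        assert weighted / occ["n_positions"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_rejected(self):
        model = TranscriptModel("T", 12, 60, 12, "A" * 84)
        with pytest.raises(ValueError, match="empty"):
            codon_occupancy(pd.DataFrame(columns=["transcript_id", "asite"]), {"T": model})

    def test_no_transcript_passing_coverage_rejected(self, transcript_model):
        fp = make_footprints(transcript_model, [1])
        assigned, _ = assign_psites(fp, {transcript_model.transcript_id: transcript_model})
        with pytest.raises(ValueError, match="min_coverage"):
            codon_occupancy(
                assigned, {transcript_model.transcript_id: transcript_model},
                min_coverage=5.0,
            )


class TestPauseScores:
    def test_uniform_scores_one(self):
        model = TranscriptModel("T", 12, 30, 12, "A" * 54)
        fp = make_footprints(model, [4] * 10)
        assigned, _ = assign_psites(fp, {"T": model})
        scores = pause_scores(assigned, {"T": model}, edge_trim=0, min_coverage=0.5)
        assert np.allclose(scores["pause_score"], 1.0)

    def test_worked_example(self):
        model = TranscriptModel("T", 12, 30, 12, "A" * 54)
        fp = make_footprints(model, [10, 1, 1, 1, 1, 1, 1, 1, 1, 1])
        assigned, _ = assign_psites(fp, {"T": model})
        scores = pause_scores(assigned, {"T": model}, edge_trim=0, min_coverage=0.5)
        first = scores[scores["codon_index"] == 0]["pause_score"].iloc[0]
        assert first == pytest.approx(10 / 1.9, abs=1e-9)
        assert scores["pause_score"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_low_coverage_flagged(self):
        model = TranscriptModel("T", 12, 30, 12, "A" * 54)
        fp = make_footprints(model, [1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        assigned, _ = assign_psites(fp, {"T": model})
        scores = pause_scores(assigned, {"T": model}, edge_trim=0, min_coverage=0.5)
        assert not scores["coverage_ok"].any()
        assert len(scores) == 10


class TestSummaries:
    def test_flagged_percent(self):
        table = pd.DataFrame({"occupancy_up": [True] * 93 + [False] * 9})
        assert flagged_percent(table, "occupancy_up") == 91.2

    def test_flagged_percent_empty_rejected(self):
        with pytest.raises(ValueError):
            flagged_percent(pd.DataFrame({"x": []}), "x")
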