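"""Enrichment testing: recovery rule, normalization, NB exact test, ranking."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import binderqc as b
from binderqc.screen import (
    CountMatrix,
    estimate_dispersion,
    sequence_identity,
)
from binderqc.simulate import DesignClass


def _cm(rows, ids=None, n_rep=3):
    cols = ["input"] + [f"cd20pos_{i}" for i in range(1, n_rep + 1)] + [
        f"cd20neg_{i}" for i in range(1, n_rep + 1)
    ]
    df = pd.DataFrame(rows, columns=cols[: len(rows[0])],
                      index=ids or [f"d{i}" for i in range(len(rows))])
    return CountMatrix.from_frame(df)


class TestCountMatrix:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _cm([[1] * 7, [2] * 7], ids=["d0", "d0"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            _cm([[1, 1, 1, 1, 1, 1, -1]])

    def test_missing_condition_rejected(self):
        df = pd.DataFrame({"input": [1], "cd20pos_1": [2]}, index=["d0"])
        with pytest.raises(ValueError, match="cd20neg"):
            CountMatrix.from_frame(df)

    def test_unknown_column_rejected(self):
        df = pd.DataFrame({"weird": [1]}, index=["d0"])
        with pytest.raises(ValueError, match="weird"):
            CountMatrix.from_frame(df)


class TestRecovery:
    def test_boundary_inclusive(self):
        cm = _cm([[0, 25, 25, 25, 25, 25, 25]])
        assert b.classify_recovery(cm).all()

    def test_single_low_replicate_fails(self):
        cm = _cm([[1000, 24, 100, 100, 100, 100, 100]])
        assert not b.classify_recovery(cm).any()

    def test_all_zero_not_recovered(self):
        cm = _cm([[0] * 7, [30] * 7])
        rec = b.classify_recovery(cm)
        assert list(rec) == [False, True]

    def test_input_column_excluded_from_rule(self):
        cm = _cm([[0, 30, 30, 30, 30, 30, 30]])
        assert b.classify_recovery(cm).all()


class TestNormalization:
    def test_cpm_single_design(self):
        cm = _cm([[10, 10, 10, 10, 10, 10, 10]])
        assert (b.normalize_cpm(cm) == 1e6).all().all()

    def test_cpm_scale_invariance(self):
        cm1 = _cm([[5, 10, 20, 30, 40, 50, 60], [5, 10, 20, 30, 40, 50, 60]])
        doubled = cm1.counts.copy()
        doubled["cd20pos_1"] *= 2
        cm2 = CountMatrix.from_frame(doubled)
        pd.testing.assert_frame_equal(b.normalize_cpm(cm1), b.normalize_cpm(cm2))

    def test_zero_library_rejected(self):
        cm = _cm([[0, 0, 1, 1, 1, 1, 1]])
        with pytest.raises(ValueError, match="zero library"):
            b.normalize_cpm(cm)

    def test_tmm_factors_unity_for_proportional_columns(self, rng):
        base = rng.integers(10, 1000, size=50).astype(float)
        df = pd.DataFrame(
            {f"cd20pos_{i}": (base * k).astype(int) for i, k in [(1, 1), (2, 2), (3, 5)]}
            | {f"cd20neg_{i}": (base * k).astype(int) for i, k in [(1, 3), (2, 1), (3, 4)]}
        )
        factors = b.tmm_factors(df)
        assert np.allclose(factors, 1.0, atol=1e-9)


def binom_double_tail(ya, yb, na, nb):
    s = ya + yb
    probs = binom.pmf(np.arange(s + 1), s, na / (na + nb))
    return min(1.0, float(probs[probs <= probs[ya] * (1 + 1e-10)].sum()))


class TestNBExactTest:
    def test_zero_total(self):
        assert b.nb_exact_test(0, 0, 3, 3, 0.1) == 1.0

    def test_balanced_split_p_one(self):
        assert b.nb_exact_test(40, 40, 3, 3, 0.1) == pytest.approx(1.0)

    def test_poisson_limit_matches_binomial_oracle(self):
        for ya in range(0, 50, 3):
            for yb in range(0, 50, 7):
                if ya + yb == 0:
                    continue
                p_nb = b.nb_exact_test(ya, yb, 3, 3, 1e-8)
                assert p_nb == pytest.approx(binom_double_tail(ya, yb, 3, 3), abs=1e-6)

    def test_unequal_group_sizes_poisson_limit(self):
        p_nb = b.nb_exact_test(30, 10, 2, 4, 1e-8)
        assert p_nb == pytest.approx(binom_double_tail(30, 10, 2, 4), abs=1e-6)

    def test_dispersion_widens_tails(self):
        assert b.nb_exact_test(60, 30, 3, 3, 0.2) > b.nb_exact_test(60, 30, 3, 3, 0.01)


class TestEnrichment:
    def test_null_identical_counts(self):
        cm = _cm([[50, 100, 100, 100, 100, 100, 100]] * 3)
        res = b.test_enrichment(cm, dispersion=0.05)
        assert (res["logFC"] == 0).all()
        assert (res["p_value"] == 1.0).all()
        assert (res["category"] == "neutral").all()

    def test_exact_twofold_logfc(self):
        # two designs so each column has equal library size; c -> 0
        rows = [
            [10, 200, 200, 200, 100, 100, 100],
            [10, 100, 100, 100, 200, 200, 200],
        ]
        cm = _cm(rows)
        res = b.test_enrichment(cm, pseudocount_cpm=0.0, dispersion=0.05)
        assert res["logFC"].iloc[0] == pytest.approx(1.0)
        assert res["logFC"].iloc[1] == pytest.approx(-1.0)

    def test_not_recovered_carry_no_p(self):
        rows = [[10, 5, 100, 100, 100, 100, 100], [10, 100, 100, 100, 100, 100, 100]]
        res = b.test_enrichment(_cm(rows), dispersion=0.05)
        assert res["category"].iloc[0] == "not_recovered"
        assert np.isnan(res["p_value"].iloc[0]) and np.isnan(res["fdr"].iloc[0])
        assert np.isfinite(res["p_value"].iloc[1])

    def test_bh_preserves_p_order(self, small_cohort):
        *_, results, _ = small_cohort
        rec = results.dropna(subset=["p_value"]).sort_values("p_value")
        fdr = rec["fdr"].to_numpy()
        assert (np.diff(fdr) >= -1e-12).all()
        assert (fdr >= rec["p_value"].to_numpy() - 1e-12).all()

    def test_uniform_scaling_shifts_logfc_constant(self, rng):
        counts = rng.integers(50, 500, size=(30, 7))
        cm1 = _cm(counts.tolist())
        scaled = counts.copy()
        scaled[:, 1:4] *= 4  # scale the cd20pos replicates
        cm2 = _cm(scaled.tolist())
        equal_lib = pd.Series(1e6, index=cm1.counts.columns)
        kw = dict(pseudocount_cpm=0.0, dispersion=0.1, library_sizes=equal_lib)
        r1 = b.test_enrichment(cm1, **kw)
        r2 = b.test_enrichment(cm2, **kw)
        shift = r2["logFC"] - r1["logFC"]
        assert np.allclose(shift, 2.0, atol=1e-9)


class TestDispersionEstimate:
    def test_recovers_true_dispersion(self):
        classes = {"neutral": DesignClass("neutral", 0.04, 0.55)}
        cfg = b.SimConfig(
            n_designs={"neutral": 500}, classes=classes,
            depth_per_replicate=500_000, nb_dispersion=0.1, seed=2,
        )
        designs, _ = b.generate_designs(cfg)
        cm = b.simulate_screen(designs, cfg)
        phi = estimate_dispersion(cm, tagwise_weight=0.0)
        assert 0.05 < phi.iloc[0] < 0.2


class TestTypeIError:
    def test_null_screen_fdr_call_rate(self):
        """No planted effects: BH at 5% calls essentially nothing."""
        classes = {"neutral": DesignClass("neutral", 0.04, 0.55)}
        cfg = b.SimConfig(
            n_designs={"neutral": 400}, classes=classes,
            depth_per_replicate=400_000, nb_dispersion=0.1, seed=0,
        )
        designs, _ = b.generate_designs(cfg)
        rates = []
        for seed in range(3):
            cm = b.simulate_screen(designs, dataclasses.replace(cfg, seed=seed))
            res = b.test_enrichment(cm)
            rec = res["recovered"]
            rates.append((res.loc[rec, "fdr"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / (400 * 3))
        assert np.mean(rates) <= 0.05 + 3 * se


class TestRankAndSelect:
    def _results(self, scores, categories=None):
        ids = [f"d{i}" for i in range(len(scores))]
        return pd.DataFrame(
            {
                "rank_score": scores,
                "category": categories or ["enriched"] * len(scores),
            },
            index=pd.Index(ids, name="design_id"),
        )

    def test_identical_sequences_keep_higher_score(self):
        res = self._results([5.0, 4.0])
        seqs = {"d0": "KAKAKA", "d1": "KAKAKA"}
        assert b.rank_and_select(res, seqs, n=10) == ["d0"]

    def test_distinct_sequences_top_n_by_score(self):
        res = self._results([1.0, 3.0, 2.0])
        seqs = {"d0": "AAAA", "d1": "CCCC", "d2": "KKKK"}
        assert b.rank_and_select(res, seqs, n=2) == ["d1", "d2"]

    def test_only_enriched_considered(self):
        res = self._results([5.0, 9.0], categories=["enriched", "depleted"])
        seqs = {"d0": "AAAA", "d1": "CCCC"}
        assert b.rank_and_select(res, seqs, n=2) == ["d0"]

    def test_warns_when_fewer_than_requested(self):
        res = self._results([5.0])
        with pytest.warns(UserWarning, match="only 1"):
            b.rank_and_select(res, {"d0": "AAAA"}, n=3)

    def test_matches_independent_greedy_oracle(self, rng):
        """Constructed pool with known identities vs. a re-derived oracle."""
        n = 6
        alphabet = np.array(list("AK"))
        seqs = {f"d{i}": "".join(rng.choice(alphabet, size=8)) for i in range(n)}
        scores = rng.uniform(0, 10, size=n).round(3)
        res = self._results(list(scores))

        def oracle(n_select, thr):
            order = sorted(res.index, key=lambda i: (-res.loc[i, "rank_score"], i))
            chosen = []
            for i in order:
                if len(chosen) == n_select:
                    break
                if all(
                    sum(a == b_ for a, b_ in zip(seqs[i], seqs[j])) / 8 < thr
                    for j in chosen
                ):
                    chosen.append(i)
            return chosen

        for thr in (0.3, 0.5, 0.8):
            assert b.rank_and_select(res, seqs, n=3, identity_threshold=thr) == oracle(3, thr)

    def test_sequence_identity_definition(self):
        assert sequence_identity("AAAA", "AATA") == 0.75
        assert sequence_identity("AAAA", "AAAAAA") == pytest.approx(4 / 6)
        assert sequence_identity("", "AA") == 0.0


class TestSummarizeByTeam:
    def test_single_team_changed_fraction(self):
        results = pd.DataFrame(
            {
                "recovered": [True] * 10,
                "category": ["enriched"] * 2 + ["depleted"] + ["neutral"] * 7,
            },
            index=pd.Index([f"d{i}" for i in range(10)], name="design_id"),
        )
        meta = pd.DataFrame({"design_id": [f"d{i}" for i in range(10)], "team": ["t1"] * 10})
        summary = b.summarize_by_team(results, meta)
        assert summary.loc["t1", "pct_changed"] == pytest.approx(30.0)
        assert summary.loc["t1", "pct_enriched"] == pytest.approx(20.0)

    def test_empty_team_flagged(self):
        results = pd.DataFrame(
            {"recovered": [True], "category": ["neutral"]},
            index=pd.Index(["d0"], name="design_id"),
        )
        meta = pd.DataFrame(
            {"design_id": ["d0", "ghost"], "team": ["t1", "t2"]}
        )
        summary = b.summarize_by_team(results, meta)
        assert bool(summary.loc["t2", "no_designs"])
        assert summary.loc["t2", "n"] == 0

    def test_synthetic_cohort_rates_match_planted_classes(self, small_cfg, small_cohort):
        designs, truth, _, results, _ = small_cohort
        meta = pd.DataFrame(
            {
                "design_id": [d.design_id for d in designs],
                "team": [d.team for d in designs],
            }
        )
        summary = b.summarize_by_team(results, meta)
        overall_changed = (summary["pct_changed"] * summary["n"]).sum() / summary["n"].sum()
        planted_changed = (truth["log2_effect_cd20"] != 0).mean() * 100
        # binomial tolerance at cohort size 130
        assert abs(overall_changed - planted_changed) < 15


class TestCountBarcodes:
    def _write_fastq(self, path, reads):
        with open(path, "w") as fh:
            for i, r in enumerate(reads):
                fh.write(f"@r{i}\n{r}\n+\n{'I' * len(r)}\n")

    def test_exact_matches_counted(self, tmp_path):
        lib = {"d1": "ATGAAAGAA", "d2": "ATGCCCGGG"}
        fq = tmp_path / "reads.fastq"
        self._write_fastq(fq, ["ATGAAAGAA"] * 3 + ["TTTTTTTTT"])
        counts, unassigned = b.count_barcodes(fq, lib)
        assert counts["d1"] == 3 and counts["d2"] == 0
        assert unassigned == 1

    def test_empty_library_rejected(self, tmp_path):
        fq = tmp_path / "reads.fastq"
        self._write_fastq(fq, ["AAA"])
        with pytest.raises(ValueError, match="empty"):
            b.count_barcodes(fq, {})

    def test_duplicate_library_collapsed_with_warning(self, tmp_path):
        fq = tmp_path / "reads.fastq"
        self._write_fastq(fq, ["ATGAAAGAA"])
        with pytest.warns(UserWarning, match="duplicate"):
            counts, _ = b.count_barcodes(fq, {"d1": "ATGAAAGAA", "d2": "ATGAAAGAA"})
        assert counts["d1"] == 1 and counts["d2"] == 0

    def test_gzipped_fastq(self, tmp_path):
        import gzip

        fq = tmp_path / "reads.fastq.gz"
        with gzip.open(fq, "wt") as fh:
            fh.write("@r0\nATGAAAGAA\n+\nIIIIIIIII\n")
        counts, unassigned = b.count_barcodes(fq, {"d1": "ATGAAAGAA"})
        assert counts["d1"] == 1 and unassigned == 0

    def test_one_mismatch_rescue(self, tmp_path):
        fq = tmp_path / "reads.fastq"
        self._write_fastq(fq, ["ATGAAAGAT"])
        counts0, un0 = b.count_barcodes(fq, {"d1": "ATGAAAGAA"}, max_mismatches=0)
        counts1, un1 = b.count_barcodes(fq, {"d1": "ATGAAAGAA"}, max_mismatches=1)
        assert counts0["d1"] == 0 and un0 == 1
        assert counts1["d1"] == 1 and un1 == 0

    def test_simulated_counts_roundtrip(self, tmp_path):
        """FASTQ regenerated from a simulated column recounts exactly."""
        cfg = b.SimConfig(
            n_designs={"neutral": 8},
            classes={"neutral": DesignClass("neutral", 0.04, 0.55)},
            depth_per_replicate=300,
            seed=4,
        )
        designs, _ = b.generate_designs(cfg)
        cm = b.simulate_screen(designs, cfg)
        lib = {d.design_id: d.dna for d in designs}
        reads = []
        for d in designs:
            reads.extend([d.dna] * int(cm.counts.loc[d.design_id, "cd20pos_1"]))
        fq = tmp_path / "rep.fastq"
        self._write_fastq(fq, reads)
        counts, unassigned = b.count_barcodes(fq, lib)
        assert unassigned == 0
        assert (counts.sort_index() == cm.counts["cd20pos_1"].sort_index()).all()
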