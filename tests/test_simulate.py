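import json

import numpy as np
import pandas as pd
import pytest

from tcscore.io import read_airr
from tcscore.overlap import directional_topk_mh, overlap_partition
from tcscore.simulate import (
    TRBJ_GENES,
    TRBV_GENES,
    SimulationConfig,
    cohort_context,
    content_hash,
    simulate_cohort,
    simulate_followup,
    simulate_paired_tissue_blood,
    simulate_repertoire,
)
from tcscore.tcs import sample_tcs_vector
from tcscore.chaos import DistanceParams
from tcscore.vj import f50, group_by_vj, vj_key
from tcscore.classify import welch_test


SMALL = SimulationConfig(clonotypes_per_sample=1500, master_seed=7)
PARAMS = DistanceParams(subsample_cap=500)


def test_gene_universe_brackets_the_observed_vj_grid():
    assert len(TRBV_GENES) == 48 and len(TRBJ_GENES) == 13
    assert len(TRBV_GENES) * len(TRBJ_GENES) == 624


class TestSimulateRepertoire:
    def test_frequencies_sum_to_one(self):
        s = simulate_repertoire(SMALL, "GO", seed=1)
        assert sum(c.frequency for c in s.clonotypes) == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_bit_identical(self):
        a = simulate_repertoire(SMALL, "GH", seed=2)
        b = simulate_repertoire(SMALL, "GH", seed=2)
        assert content_hash(a) == content_hash(b)

    def test_different_seeds_differ(self):
        a = simulate_repertoire(SMALL, "GH", seed=2)
        b = simulate_repertoire(SMALL, "GH", seed=3)
        assert content_hash(a) != content_hash(b)

    def test_full_penetrance_plants_expanded_clone_in_every_signal_vj(self):
        config = SimulationConfig(
            clonotypes_per_sample=1500, effect_penetrance=1.0, master_seed=7
        )
        ctx = cohort_context(config)
        s = simulate_repertoire(config, "GO", seed=4, context=ctx)
        by_vj = {p.key: p for p in group_by_vj(s)}
        for key in ctx.signal_vjs:
            top_freq = max(f for _, f in by_vj[key].members)
            assert top_freq >= 0.009  # expansion lower bound minus count rounding
            # when the expanded clone alone crosses 50% of its V-J, F50 equals it
            res = f50(by_vj[key])
            if res.crossing_index == 1:
                assert res.value == pytest.approx(top_freq)

    def test_gh_samples_carry_no_planted_signal(self):
        ctx = cohort_context(SMALL)
        go = simulate_repertoire(SMALL, "GO", seed=5, context=ctx)
        gh = simulate_repertoire(SMALL, "GH", seed=5, context=ctx)
        assert len(go.clonotypes) > len(gh.clonotypes)  # clusters + expansions added


class TestSimulateCohort:
    def test_files_metadata_and_ground_truth(self, tmp_path):
        config = SimulationConfig(
            n_GO=3, n_GH=2, clonotypes_per_sample=300, master_seed=1
        )
        cohort = simulate_cohort(config, outdir=tmp_path)
        assert sorted(p.name for p in tmp_path.glob("S*.tsv")) == [
            "S001.tsv", "S002.tsv", "S003.tsv", "S004.tsv", "S005.tsv"
        ]
        meta = pd.read_csv(tmp_path / "metadata.csv")
        assert list(meta["label"]) == ["GO"] * 3 + ["GH"] * 2
        truth = json.loads((tmp_path / "ground_truth.json").read_text())
        universe = {vj_key(v, j) for v in TRBV_GENES for j in TRBJ_GENES}
        assert set(truth["signal_vjs"]) <= universe
        assert len(truth["signal_vjs"]) == config.n_signal_vjs
        # generated files round-trip through the reader unchanged
        back = read_airr(tmp_path / "S001.tsv")
        assert content_hash(back) == content_hash(cohort.samples[0])

    def test_master_seed_changes_content(self):
        c1 = simulate_cohort(SimulationConfig(n_GO=1, n_GH=1, clonotypes_per_sample=200, master_seed=1))
        c2 = simulate_cohort(SimulationConfig(n_GO=1, n_GH=1, clonotypes_per_sample=200, master_seed=2))
        assert content_hash(c1.samples[0]) != content_hash(c2.samples[0])

    def test_signal_moves_tcs_in_designed_direction(self):
        """Mean TCS over signal V-Js is higher in GO than GH, paired across seeds."""
        wins = 0
        n_seeds = 10
        ctx = cohort_context(SMALL)
        for seed in range(n_seeds):
            go = simulate_repertoire(SMALL, "GO", seed=100 + seed, context=ctx)
            gh = simulate_repertoire(SMALL, "GH", seed=200 + seed, context=ctx)
            go_tcs = sample_tcs_vector(go, PARAMS)
            gh_tcs = sample_tcs_vector(gh, PARAMS)
            go_mean = np.mean([go_tcs.get(k, 0.0) for k in ctx.signal_vjs])
            gh_mean = np.mean([gh_tcs.get(k, 0.0) for k in ctx.signal_vjs])
            wins += go_mean > gh_mean
        assert wins >= 9

    def test_null_mode_retains_few_features(self):
        """With zero penetrance the Welch filter keeps about alpha of the V-Js."""
        config = SimulationConfig(
            n_GO=10, n_GH=10, clonotypes_per_sample=1000, effect_penetrance=0.0, master_seed=3
        )
        cohort = simulate_cohort(config)
        from tcscore.pipeline import RunConfig, score_cohort

        rc = RunConfig(distance=DistanceParams(subsample_cap=500))
        m = score_cohort(cohort, rc)
        res = welch_test(m.values, m.labels)
        assert (res["p"] < 0.05).mean() <= 0.10


class TestPairedTissueBlood:
    def test_over_threshold_bin_fully_overlapping(self):
        thyroid, blood = simulate_paired_tissue_blood(SMALL, seed=1)
        part = overlap_partition(thyroid, blood, threshold=0.001)
        assert part.over.n_specific == 0
        assert part.over.n_overlapping > 0

    def test_top20_correlates_better_than_ranks_21_1000(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            thyroid, blood = simulate_paired_tissue_blood(SMALL, seed=seed)
            hi = min(1000, len(thyroid.clonotypes))
            top = directional_topk_mh(thyroid, blood, 1, 20).value
            mid = directional_topk_mh(thyroid, blood, 21, hi).value
            wins += top > mid
        # sign test: under no effect wins ~ Binomial(20, 1/2); 15+ is p < 0.02
        assert wins >= 15

    def test_fixed_seed_reproducible(self):
        t1, b1 = simulate_paired_tissue_blood(SMALL, seed=6)
        t2, b2 = simulate_paired_tissue_blood(SMALL, seed=6)
        assert content_hash(t1) == content_hash(t2)
        assert content_hash(b1) == content_hash(b2)


class TestFollowup:
    assignments = pd.DataFrame(
        {
            "sample_id": [f"v{i}" for i in range(6)],
            "label": ["GH_to_GO"] * 3 + ["GH"] * 3,
            "group": ["predicted_GO"] * 3 + ["predicted_GH"] * 3,
        }
    )

    def test_non_progressors_censored_at_horizon(self):
        recs = simulate_followup(self.assignments, SMALL, seed=1)
        for r in recs[3:]:
            assert r.time == 18.0 and not r.event

    def test_event_time_median_matches_parameterization(self):
        big = pd.DataFrame(
            {"sample_id": [f"p{i}" for i in range(500)], "label": ["GH_to_GO"] * 500,
             "group": ["predicted_GO"] * 500}
        )
        recs = simulate_followup(big, SMALL, seed=2)
        times = [r.time for r in recs if r.event]
        assert 5.0 <= float(np.median(times)) <= 8.0

    def test_seeded_reproducibility(self):
        a = simulate_followup(self.assignments, SMALL, seed=3)
        b = simulate_followup(self.assignments, SMALL, seed=3)
        assert [(r.time, r.event) for r in a] == [(r.time, r.event) for r in b]
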