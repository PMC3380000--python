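import numpy as np
import pytest

from clrnet.synthetic import (
    SyntheticParams,
    evaluate_recovery,
    generate_dataset,
    generate_gene_sets,
    generate_knockdown_matrix,
)
from clrnet.topology import rank_bottlenecks


class TestGenerateDataset:
    def test_same_seed_bit_identical(self, small_params):
        m1, d1, a1, t1 = generate_dataset(small_params)
        m2, d2, a2, t2 = generate_dataset(small_params)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert m1.probe_ids == m2.probe_ids
        assert a1.mapping == a2.mapping
        np.testing.assert_array_equal(t1.profiles, t2.profiles)

    def test_different_seed_changes_values_not_genes(self, small_params):
        import dataclasses

        m1, _, _, t1 = generate_dataset(small_params)
        m2, _, _, t2 = generate_dataset(dataclasses.replace(small_params, seed=99))
        assert m1.probe_ids == m2.probe_ids  # planted identities shared
        assert t1.bridge_genes == t2.bridge_genes
        assert not np.array_equal(m1.values, m2.values)

    def test_dimensions_follow_parameters(self, small_params):
        matrix, design, annot, truth = generate_dataset(small_params)
        p = small_params
        n_genes = p.n_modules * p.genes_per_module + p.n_bridge_genes + p.n_background_genes
        n_samples = (
            len(p.conditions) * len(p.timepoints) * p.replicates + p.n_baseline_controls
        )
        assert matrix.n_probes == n_genes  # no duplicates at fraction 0
        assert matrix.n_samples == n_samples
        assert set(matrix.sample_ids) == set(design.sample_ids)
        assert set(matrix.probe_ids) == set(annot.mapping)

    def test_duplicate_probes_added(self, small_params):
        import dataclasses

        params = dataclasses.replace(small_params, duplicate_probe_fraction=0.25)
        matrix, _, annot, truth = generate_dataset(params)
        n_genes = len(truth.gene_module)
        expected_dups = int(round(0.25 * n_genes))
        assert matrix.n_probes == n_genes + expected_dups
        dup_probes = [p for p in matrix.probe_ids if p.endswith("_p2")]
        assert len(dup_probes) == expected_dups
        # duplicates map to the same gene as their sibling probe
        for p in dup_probes:
            assert annot.gene_of(p) == annot.gene_of(p.replace("_p2", "_p1"))

    def test_low_noise_same_module_genes_near_perfectly_correlated(self, small_params):
        import dataclasses

        params = dataclasses.replace(small_params, noise_sd=1e-6)
        matrix, _, _, truth = generate_dataset(params)
        g1, g2 = truth.module_members(0)[:2]
        r = np.corrcoef(matrix.row(g1 + "_p1"), matrix.row(g2 + "_p1"))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_module_profiles_are_uncorrelated(self, small_params):
        _, _, _, truth = generate_dataset(small_params)
        corr = np.corrcoef(truth.profiles)
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert np.all(np.abs(off) < 1e-8)

    def test_planted_signal_spans_exceed_fold_change_floor(self, small_params):
        _, _, _, truth = generate_dataset(small_params)
        for m in range(small_params.n_modules):
            assert truth.profiles[m].max() - truth.profiles[m].min() >= 2.0

    def test_bridges_mix_two_distinct_modules(self, small_params):
        _, _, _, truth = generate_dataset(small_params)
        pairs = set()
        for g, mixing in truth.bridge_mixing.items():
            assert len(mixing) == 2
            assert sum(mixing.values()) == pytest.approx(1.0)
            pairs.add(tuple(sorted(mixing)))
        assert len(pairs) == len(truth.bridge_mixing)  # all pairs distinct

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SyntheticParams(noise_sd=0.0).validate()
        with pytest.raises(ValueError):
            SyntheticParams(n_modules=1, n_bridge_genes=1).validate()
        with pytest.raises(ValueError):
            SyntheticParams(duplicate_probe_fraction=1.5).validate()

    def test_truth_serializes_to_json(self, small_dataset):
        import json

        _, _, _, truth = small_dataset
        blob = json.loads(truth.to_json())
        assert blob["params"]["seed"] == truth.params.seed
        assert set(blob["gene_module"]) == set(truth.gene_module)


class TestGenerateGeneSets:
    def test_one_term_per_module_plus_decoys(self, small_dataset):
        _, _, _, truth = small_dataset
        coll = generate_gene_sets(truth, n_decoys=10)
        assert len(coll) == truth.params.n_modules + 10

    def test_module_terms_disjoint_and_exclude_bridges(self, small_dataset):
        _, _, _, truth = small_dataset
        coll = generate_gene_sets(truth)
        module_terms = [
            coll.members(f"MODULE_{m}") for m in range(truth.params.n_modules)
        ]
        for i, a in enumerate(module_terms):
            assert not (a & truth.bridge_genes)
            for b in module_terms[i + 1:]:
                assert not (a & b)

    def test_decoy_sizes_match_module_sizes(self, small_dataset):
        _, _, _, truth = small_dataset
        coll = generate_gene_sets(truth, n_decoys=6)
        module_sizes = sorted(
            len(coll.members(f"MODULE_{m}")) for m in range(truth.params.n_modules)
        )
        decoy_sizes = {len(coll.members(f"DECOY_{d}")) for d in range(6)}
        assert decoy_sizes <= set(module_sizes)


class TestKnockdownMatrix:
    def test_same_seed_identical(self, small_dataset):
        _, _, _, truth = small_dataset
        a = generate_knockdown_matrix(truth, 30, seed=5)
        b = generate_knockdown_matrix(truth, 30, seed=5)
        assert a.equals(b)

    def test_same_module_genes_positively_correlated(self, small_dataset):
        _, _, _, truth = small_dataset
        mat = generate_knockdown_matrix(truth, 60, seed=1)
        members = truth.module_members(0)
        rs = [
            np.corrcoef(mat.loc[members[i]], mat.loc[members[j]])[0, 1]
            for i in range(3)
            for j in range(i + 1, 4)
        ]
        assert np.mean(rs) > 0.2

    def test_background_pairs_uncorrelated_on_average(self, small_dataset):
        """Mean |corr| of a background gene pair stays near zero over seeds."""
        _, _, _, truth = small_dataset
        bg = [g for g, lab in truth.gene_module.items() if lab == "background"][:2]
        rs = []
        for seed in range(100):
            mat = generate_knockdown_matrix(truth, 30, seed=seed)
            rs.append(np.corrcoef(mat.loc[bg[0]], mat.loc[bg[1]])[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_invalid_regulator_count_rejected(self, small_dataset):
        _, _, _, truth = small_dataset
        with pytest.raises(ValueError):
            generate_knockdown_matrix(truth, 0, seed=0)


class TestEvaluateRecovery:
    def _ranking_for(self, truth, flagged_probes, all_probes):
        scores = {p: (1.0 if p in flagged_probes else 0.0) for p in all_probes}
        frac = max(len(flagged_probes) / len(all_probes), 1e-9)
        return rank_bottlenecks(scores, fraction=frac)

    def test_perfect_recovery(self, small_dataset):
        matrix, _, _, truth = small_dataset
        bridges = {g + "_p1" for g in truth.bridge_genes}
        ranking = self._ranking_for(truth, bridges, matrix.probe_ids)
        precision, recall = evaluate_recovery(ranking, truth)
        assert precision == 1.0 and recall == 1.0

    def test_no_bridges_flagged_zero_recall(self, small_dataset):
        matrix, _, _, truth = small_dataset
        background = {p for p in matrix.probe_ids if p.startswith("BG")}
        ranking = self._ranking_for(truth, set(list(background)[:2]), matrix.probe_ids)
        precision, recall = evaluate_recovery(ranking, truth)
        assert recall == 0.0 and precision == 0.0

    def test_random_flags_recall_matches_binomial_expectation(self, small_dataset):
        """Flagging a random fraction f of probes recovers ~f of bridges."""
        matrix, _, _, truth = small_dataset
        f = 0.3
        recalls = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            flagged = set(
                rng.choice(
                    matrix.probe_ids,
                    size=int(f * matrix.n_probes),
                    replace=False,
                )
            )
            ranking = self._ranking_for(truth, flagged, matrix.probe_ids)
            _, recall = evaluate_recovery(ranking, truth)
            recalls.append(recall)
        n_b = len(truth.bridge_genes)
        se = np.sqrt(f * (1 - f) / (50 * n_b))
        assert abs(np.mean(recalls) - f) < 4 * se

    def test_disjoint_universes_rejected(self, small_dataset):
        _, _, _, truth = small_dataset
        ranking = rank_bottlenecks({"zz1": 1.0, "zz2": 0.5}, 0.5)
        with pytest.raises(ValueError):
            evaluate_recovery(ranking, truth)
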