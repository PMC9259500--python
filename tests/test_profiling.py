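"""Fractional insert assignment, normalization, roll-ups and activity."""

import numpy as np
import pandas as pd
import pytest

from seascape import profiling
from seascape.profiling import (
    assign_inserts,
    average_genome_size,
    bgc_abundance,
    cell_normalize,
    family_abundance,
    filter_alignments,
    length_normalize,
    prevalence,
    transcript_activity,
)


def _aln(rows):
    return pd.DataFrame(
        rows,
        columns=["insert_id", "target_gene_id", "aln_len_bp", "pct_identity",
                 "read_cov_fraction"],
    )


class TestFilterAlignments:
    def test_length_floor(self):
        records = _aln([("i1", "g1", 44, 99.0, 0.9), ("i2", "g1", 45, 99.0, 0.9)])
        assert list(filter_alignments(records, preset="genome")["insert_id"]) == ["i2"]

    def test_genome_preset_boundaries_inclusive(self):
        records = _aln([("i1", "g1", 100, 97.0, 0.80)])
        assert len(filter_alignments(records, preset="genome")) == 1
        records = _aln([("i1", "g1", 100, 96.9, 0.80), ("i2", "g1", 100, 97.0, 0.79)])
        assert filter_alignments(records, preset="genome").empty

    def test_gene_preset_ignores_coverage(self):
        records = _aln([("i1", "g1", 50, 95.0, 0.01)])
        assert len(filter_alignments(records, preset="gene")) == 1

    def test_empty_input(self):
        assert filter_alignments(_aln([]), preset="gene").empty


def _assign_oracle(pairs):
    """Per-insert enumeration oracle, independent of the implementation."""
    targets = {}
    for insert, gene in pairs:
        targets.setdefault(insert, [])
        if gene not in targets[insert]:
            targets[insert].append(gene)
    unique = {}
    for genes in targets.values():
        if len(genes) == 1:
            unique[genes[0]] = unique.get(genes[0], 0) + 1
    counts = dict(unique)
    for genes in targets.values():
        if len(genes) == 1:
            continue
        total = sum(unique.get(g, 0) for g in genes)
        for g in genes:
            share = unique.get(g, 0) / total if total else 1 / len(genes)
            counts[g] = counts.get(g, 0.0) + share
    return counts


def _records(pairs):
    return pd.DataFrame(pairs, columns=["insert_id", "target_gene_id"])


class TestAssignInserts:
    def test_proportional_split(self):
        pairs = [("u1", "A"), ("u2", "A"), ("u3", "A"), ("u4", "B"), ("x", "A"), ("x", "B")]
        counts = assign_inserts(_records(pairs))
        assert counts["A"] == pytest.approx(3.75)
        assert counts["B"] == pytest.approx(1.25)

    def test_uniform_fallback(self):
        counts = assign_inserts(_records([("x", "A"), ("x", "B")]))
        assert counts["A"] == pytest.approx(0.5) and counts["B"] == pytest.approx(0.5)

    def test_no_ambiguity_counts_equal_uniques(self):
        counts = assign_inserts(_records([("u1", "A"), ("u2", "B"), ("u3", "B")]))
        assert counts.to_dict() == {"A": 1.0, "B": 2.0}

    def test_matches_per_insert_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        genes = list("ABCDE")
        for _ in range(40):
            n_inserts = int(rng.integers(1, 21))
            pairs = []
            for i in range(n_inserts):
                k = 1 if rng.random() > 0.4 else int(rng.integers(2, 4))
                chosen = rng.choice(genes, size=k, replace=False)
                pairs.extend((f"i{i}", g) for g in chosen)
            got = assign_inserts(_records(pairs)).to_dict()
            expected = _assign_oracle(pairs)
            assert set(got) == set(expected)
            for g in got:
                assert got[g] == pytest.approx(expected[g])
            # conservation: total assigned equals number of inserts
            assert sum(got.values()) == pytest.approx(n_inserts, abs=1e-9 * n_inserts)

    def test_conservation_on_synthetic_sample(self, profiles):
        sample = profiles.alignments[profiles.alignments["sample_id"] == "s_0001"]
        counts = assign_inserts(sample)
        n_inserts = sample["insert_id"].nunique()
        assert counts.sum() == pytest.approx(n_inserts, abs=1e-9 * n_inserts)


class TestNormalization:
    def test_inserts_per_kilobase(self):
        counts = pd.Series({"g": 10.0})
        lengths = pd.Series({"g": 2000})
        assert length_normalize(counts, lengths)["g"] == pytest.approx(5)

    def test_zero_and_scale_property(self):
        lengths = pd.Series({"g": 700})
        assert length_normalize(pd.Series({"g": 0.0}), lengths)["g"] == 0
        a = length_normalize(pd.Series({"g": 4.0}), pd.Series({"g": 800}))["g"]
        b = length_normalize(pd.Series({"g": 8.0}), pd.Series({"g": 1600}))["g"]
        assert a == pytest.approx(b)

    def test_missing_or_zero_length_rejected(self):
        with pytest.raises(ValueError):
            length_normalize(pd.Series({"g": 1.0}), pd.Series({"h": 100}))
        with pytest.raises(ValueError):
            length_normalize(pd.Series({"g": 1.0}), pd.Series({"g": 0}))

    @pytest.mark.parametrize("values,expected", [((1, 3, 5), 3), ((1, 3), 2), ((0, 0), 0)])
    def test_bgc_median(self, values, expected):
        ab = pd.Series({f"g{i}": v for i, v in enumerate(values)}, dtype=float)
        assert bgc_abundance(ab, list(ab.index)) == pytest.approx(expected)

    def test_bgc_median_empty_rejected(self):
        with pytest.raises(ValueError):
            bgc_abundance(pd.Series(dtype=float), [])

    def test_family_sum_additive(self):
        assert family_abundance([2, 3]) == pytest.approx(5)
        assert family_abundance([7]) == pytest.approx(7)
        assert family_abundance([2, 3]) + family_abundance([4]) == pytest.approx(
            family_abundance([2, 3, 4])
        )

    def test_cell_normalize_and_missing_contract(self):
        assert cell_normalize(6.0, 3.0) == pytest.approx(2.0)
        assert np.isnan(cell_normalize(6.0, 0.0))
        # depth invariance: doubling genes and markers together cancels
        assert cell_normalize(12.0, 6.0) == pytest.approx(cell_normalize(6.0, 3.0))

    @pytest.mark.parametrize(
        "values,expected", [((0, 0.1, 0.3, 0), 50), ((0, 0, 0), 0), ((1, 2), 100)]
    )
    def test_prevalence(self, values, expected):
        assert prevalence(values) == pytest.approx(expected)


class TestDepthInvariance:
    def test_doubling_depth_factor_doubles_raw_counts(self):
        """Two samples identical but for a doubled depth factor have exactly
        doubled per-gene insert counts and marker abundances."""
        from seascape.simulate import SimulationConfig, simulate_bgc_universe, simulate_profiles

        cfg = SimulationConfig(seed=5, n_samples=4, ambiguous_frac=0.0)
        _, bgcs, truth = simulate_bgc_universe(cfg)
        prof = simulate_profiles(cfg, bgcs, truth)
        depth = prof.samples.set_index("sample_id")["depth_factor"]
        for sample_id, d in depth.items():
            counts = (
                prof.alignments[prof.alignments["sample_id"] == sample_id]
                .groupby("target_gene_id")["insert_id"].nunique()
            )
            assert (counts % d == 0).all()

    def test_per_cell_abundance_invariant_under_depth(self):
        """Scaling a sample's raw gene counts and marker normalizer by the
        same depth factor leaves per-cell family abundance unchanged."""
        gene_ab = pd.Series({"g1": 2.0, "g2": 6.0})
        base = cell_normalize(family_abundance([bgc_abundance(gene_ab, ["g1", "g2"])]), 8.0)
        for factor in (2, 3, 10):
            scaled = cell_normalize(
                family_abundance([bgc_abundance(gene_ab * factor, ["g1", "g2"])]),
                8.0 * factor,
            )
            assert scaled == pytest.approx(base)


class TestAverageGenomeSize:
    def _members(self, rows):
        return pd.DataFrame(rows, columns=["motu_id", "length_bp", "completeness_pct"])

    def test_weighted_mean(self):
        members = self._members([("m1", 2e6, 100), ("m2", 4e6, 100)])
        rel = pd.Series({"m1": 0.5, "m2": 0.5})
        assert average_genome_size(rel, members) == pytest.approx(3e6)

    def test_single_motu_and_completeness_floor(self):
        members = self._members([("m1", 3e6, 75), ("m1", 9e6, 69)])
        rel = pd.Series({"m1": 1.0})
        # 69%-complete member is excluded; corrected size is 3/0.75 = 4 Mb
        assert average_genome_size(rel, members) == pytest.approx(4e6)

    def test_no_survivor_is_missing(self):
        members = self._members([("m1", 3e6, 50)])
        assert np.isnan(average_genome_size(pd.Series({"m1": 1.0}), members))


class TestTranscriptActivity:
    def _setup(self, marker_counts, gene_count, gene_len=1000):
        markers = [f"mk{i}" for i in range(10)]
        counts = pd.Series({**{m: c for m, c in zip(markers, marker_counts)},
                            "gene": float(gene_count)})
        lengths = pd.Series({**{m: 1000 for m in markers}, "gene": gene_len})
        return counts, lengths, markers

    def test_gene_at_marker_median_is_zero(self):
        counts, lengths, markers = self._setup([4.0] * 10, 4.0)
        activity, detected = transcript_activity(counts, lengths, markers)
        assert detected and activity["gene"] == pytest.approx(0.0)

    def test_fourfold_gene_is_two(self):
        counts, lengths, markers = self._setup([4.0] * 10, 16.0)
        activity, _ = transcript_activity(counts, lengths, markers)
        assert activity["gene"] == pytest.approx(2.0)

    def test_detection_rule_strictly_more_than_five(self):
        counts, lengths, markers = self._setup([1.0] * 5 + [0.0] * 5, 3.0)
        _, detected = transcript_activity(counts, lengths, markers)
        assert not detected
        counts, lengths, markers = self._setup([1.0] * 6 + [0.0] * 4, 3.0)
        activity, detected = transcript_activity(counts, lengths, markers)
        assert detected
        # zero-count genes are missing, never -inf
        assert activity[[m for m in markers[6:]]].isna().all()

    def test_all_markers_zero_undetected(self):
        counts, lengths, markers = self._setup([0.0] * 10, 3.0)
        activity, detected = transcript_activity(counts, lengths, markers)
        assert activity is None and not detected
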