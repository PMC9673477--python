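"""Genotype container, synthesis, filters, encodings, and table I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gsbench.genotypes import (GenotypeFormatError, GenotypeMatrix, compute_maf,
                               decode_onehot, encode, filter_duplicates, filter_maf,
                               generate_synthetic_genotypes, read_genotype_table,
                               read_phenotype_table, write_genotype_table,
                               write_phenotype_table)
from conftest import random_genotypes


def make(cols, ids=None):
    vals = np.asarray(cols).T
    return GenotypeMatrix([f"s{i}" for i in range(vals.shape[0])],
                          ids or [f"m{j}" for j in range(vals.shape[1])], vals)


class TestMAF:
    @pytest.mark.parametrize("column,expected", [
        ([0, 0, 0, 2], 0.25),
        ([0, 0, 0, 0], 0.0),
        ([1, 2, 0, 1], 0.5),
    ])
    def test_direct_values(self, column, expected):
        assert compute_maf(make([column]))[0] == pytest.approx(expected)

    def test_filter_boundary_kept(self):
        # columns engineered to MAF 0.05, 0.10, 0.25 over 10 samples
        g = make([[1] + [0] * 9, [2] + [0] * 9, [2, 2, 1, 0, 0, 0, 0, 0, 0, 0]])
        assert compute_maf(g).tolist() == [0.05, 0.10, 0.25]
        kept = filter_maf(g, 0.10)
        assert kept.marker_ids == ["m1", "m2"]

    def test_filter_zero_threshold_is_identity(self, small_panel):
        assert filter_maf(small_panel, 0.0).marker_ids == small_panel.marker_ids

    def test_filter_all_removed_raises(self):
        with pytest.raises(ValueError, match="removed all"):
            filter_maf(make([[0, 0, 0, 0]]), 0.1)

    def test_filter_idempotent(self, small_panel):
        once = filter_maf(small_panel, 0.2)
        twice = filter_maf(once, 0.2)
        assert once.marker_ids == twice.marker_ids

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_filter_matches_per_column_oracle(self, seed):
        g = random_genotypes(12, 50, seed)
        threshold = 0.2
        maf = [min(c.sum() / 24, 1 - c.sum() / 24) for c in g.values.T]
        expected = [g.marker_ids[j] for j in range(50) if maf[j] >= threshold]
        if not expected:
            return
        assert filter_maf(g, threshold).marker_ids == expected


class TestDuplicates:
    def test_first_of_pair_survives(self):
        g = make([[0, 1, 2], [0, 1, 2], [2, 1, 0]], ids=["a", "b", "c"])
        assert filter_duplicates(g).marker_ids == ["a", "c"]

    def test_no_duplicates_identity(self, small_panel):
        assert filter_duplicates(small_panel).marker_ids == small_panel.marker_ids

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        base = rng.choice([0, 1, 2], size=(8, 10))
        # plant duplicate triples: columns 10..15 copy columns 0,0,3,3,7,7
        vals = np.hstack([base, base[:, [0, 0, 3, 3, 7, 7]]])
        g = GenotypeMatrix([f"s{i}" for i in range(8)],
                           [f"m{j}" for j in range(16)], vals)
        survivors = filter_duplicates(g).marker_ids
        # O(m^2) oracle: keep column j iff no earlier identical column
        expected = []
        for j in range(16):
            if not any((vals[:, i] == vals[:, j]).all() for i in range(j)):
                expected.append(f"m{j}")
        assert survivors == expected


class TestSyntheticGeneration:
    def test_maf_band_and_homozygosity(self):
        g = generate_synthetic_genotypes(200, 300, 0.10, 0.5, seed=1)
        maf = compute_maf(g)
        assert g.values.shape == (200, 300)
        assert (maf > 0.10).all() and (maf <= 0.5).all()
        assert set(np.unique(g.values)) <= {0, 2}

    def test_smallest_representable_maf(self):
        # n=4 homozygous: one minor homozygote is MAF 0.25; band forces exactly one
        g = generate_synthetic_genotypes(4, 1, 0.2, 0.25, seed=3)
        assert (g.values[:, 0] == 2).sum() == 1

    def test_infeasible_band_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_synthetic_genotypes(4, 5, 0.01, 0.1, seed=0)

    def test_seed_determinism_and_divergence(self):
        a = generate_synthetic_genotypes(50, 80, seed=7)
        b = generate_synthetic_genotypes(50, 80, seed=7)
        c = generate_synthetic_genotypes(50, 80, seed=8)
        assert (a.values == b.values).all()
        assert (a.values != c.values).any()

    def test_no_duplicate_columns(self, small_panel):
        assert len({small_panel.values[:, j].tobytes()
                    for j in range(small_panel.n_markers)}) == small_panel.n_markers

    def test_ld_blocks_raise_within_block_correlation(self):
        g = generate_synthetic_genotypes(500, 50, ld_block_size=10, ld_rho=0.8, seed=7)
        corr = np.corrcoef(g.values.T.astype(float))
        blocks = np.arange(50) // 10
        same = blocks[:, None] == blocks[None, :]
        off = ~np.eye(50, dtype=bool)
        within = np.abs(corr[same & off]).mean()
        between = np.abs(corr[~same]).mean()
        assert within > between + 0.1


class TestEncoding:
    def test_centered_maps_counts_to_signed(self):
        enc = encode(make([[0, 1, 2]]), "additive_centered")
        assert enc.values.ravel().tolist() == [-1.0, 0.0, 1.0]

    def test_additive_identity_preserves_shape(self, small_panel):
        enc = encode(small_panel, "additive012")
        assert (enc.values == small_panel.values).all()

    def test_onehot_rows_sum_to_marker_count(self, small_panel):
        enc = encode(small_panel, "onehot")
        assert np.allclose(enc.values.sum(axis=1), small_panel.n_markers)

    def test_onehot_emits_observed_states_only(self):
        enc = encode(make([[0, 2, 0]]), "onehot")
        assert enc.values.shape == (3, 2)
        assert np.allclose(enc.values.sum(axis=1), 1)

    def test_onehot_round_trip(self):
        g = random_genotypes(10, 15, seed=2)
        enc = encode(g, "onehot")
        back = decode_onehot(enc, sample_ids=g.sample_ids)
        assert (back.values == g.values).all()

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="unknown encoding"):
            encode(make([[0, 1]]), "dominance")


class TestTableIO:
    def test_round_trip(self, tmp_path):
        g = random_genotypes(5, 8, seed=4)
        path = tmp_path / "geno.csv"
        write_genotype_table(g, path)
        back = read_genotype_table(path)
        assert back.sample_ids == g.sample_ids
        assert back.marker_ids == g.marker_ids
        assert (back.values == g.values).all()

    def test_invalid_value_names_cell(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,m0,m1\ns0,0,1\ns1,3,2\n")
        with pytest.raises(GenotypeFormatError, match=r"'3'.*sample 's1'.*marker 'm0'"):
            read_genotype_table(path)

    def test_duplicate_marker_id_named(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("sample_id,mA,mA\ns0,0,1\n")
        with pytest.raises(GenotypeFormatError, match="mA"):
            read_genotype_table(path)

    def test_tab_delimiter_autodetected(self, tmp_path):
        path = tmp_path / "geno.tsv"
        write_genotype_table(random_genotypes(4, 3, seed=9), path, sep="\t")
        assert read_genotype_table(path).values.shape == (4, 3)

    def test_phenotype_round_trip(self, tmp_path):
        path = tmp_path / "pheno.csv"
        y = np.array([1.5, -2.0, 0.25])
        write_phenotype_table(["a", "b", "c"], y, path)
        s = read_phenotype_table(path)
        assert list(s.index) == ["a", "b", "c"]
        assert np.allclose(s.to_numpy(), y)
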