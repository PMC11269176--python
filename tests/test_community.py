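"""Community structure: distances, ordination, variance partitioning."""

import io as _io

import numpy as np
import pandas as pd
import pytest

from aerospora import community, simulate
from aerospora.phylo import RANKS

import aerospora as ap


def _profiles(matrix, otus=None, n_samples=10):
    otus = otus or [f"O{i}" for i in range(len(matrix[0]))]
    df = pd.DataFrame(matrix, columns=otus,
                      index=pd.Index([f"S{i}" for i in range(len(matrix))], name="site_id"))
    df.insert(0, "n_samples", n_samples)
    return df


class TestPrevalence:
    def test_prevalence_fraction(self, small_presence, small_ds):
        prof = community.site_prevalence(small_presence.astype(int), small_ds.samples)
        site = prof.index[0]
        meta = small_ds.samples.set_index("sample_id").loc[small_presence.index]
        ids = meta.index[meta["site_id"] == site]
        otu = small_presence.columns[0]
        expected = small_presence.loc[ids, otu].mean()
        assert prof.loc[site, otu] == pytest.approx(expected)
        assert prof[[c for c in prof.columns if c != "n_samples"]].to_numpy().min() >= 0

    def test_sum_prevalence_times_n_equals_sum_richness(self, small_presence, small_ds):
        prof = community.site_prevalence(small_presence.astype(int), small_ds.samples)
        otu_cols = [c for c in prof.columns if c != "n_samples"]
        lhs = (prof[otu_cols].sum(axis=1) * prof["n_samples"]).sum()
        rhs = small_presence.sum(axis=1).sum()
        assert lhs == pytest.approx(rhs)


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        d = community.bray_curtis(_profiles([[0.2, 0.4], [0.2, 0.4]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        d = community.bray_curtis(_profiles([[0.5, 0.0], [0.0, 0.3]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        d = community.bray_curtis(_profiles([[0.2, 0.4], [0.4, 0.0]]))
        assert d.iloc[0, 1] == pytest.approx(0.6)

    def test_all_zero_pair_defined_zero_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            d = community.bray_curtis(_profiles([[0.0, 0.0], [0.0, 0.0]]))
        assert d.iloc[0, 1] == 0.0

    def test_symmetry_zero_diagonal_range(self, small_presence, small_ds):
        prof = community.site_prevalence(small_presence.astype(int), small_ds.samples)
        d = community.bray_curtis(prof).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1


def _newick_from_taxonomy(taxonomy: pd.DataFrame) -> str:
    """Newick rooted at the kingdom with unit edges at the 6 levels below."""

    def clade(df, depth):
        if depth == len(RANKS):
            assert len(df) == 1
            return f"{df['otu_id'].iloc[0]}:1"
        parts = [
            clade(sub, depth + 1) for _, sub in df.groupby(RANKS[depth], sort=True)
        ]
        inner = ",".join(parts)
        return f"({inner}):1" if depth > 1 else f"({inner})root;"

    return clade(taxonomy, 1)


class TestUnifrac:
    def test_identical_presence_zero(self, toy_taxonomy):
        prof = _profiles([[1, 1, 0, 0, 0, 0]] * 2, otus=list(toy_taxonomy["otu_id"]))
        d = community.unifrac_taxonomic(prof, toy_taxonomy)
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_no_shared_ranks_below_kingdom_gives_one(self, toy_taxonomy):
        # A (P1/C1/...) vs E (P2/C2/...): same kingdom, nothing below
        prof = _profiles([[1, 0, 0, 0, 0, 0], [0, 0, 0, 0, 1, 0]],
                         otus=list(toy_taxonomy["otu_id"]))
        d = community.unifrac_taxonomic(prof, toy_taxonomy)
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_enumerated_toy_tree(self):
        # sites {A,B} vs {A,C}; A,B congeneric, C in another phylum:
        # shared branches 6, union 13 -> 7/13
        rows = [
            ("A", "K", "P1", "C1", "O1", "F1", "G1", "sA"),
            ("B", "K", "P1", "C1", "O1", "F1", "G1", "sB"),
            ("C", "K", "P2", "C2", "O2", "F2", "G2", "sC"),
        ]
        tax = pd.DataFrame(rows, columns=["otu_id", *RANKS])
        prof = _profiles([[1, 1, 0], [1, 0, 1]], otus=["A", "B", "C"])
        d = community.unifrac_taxonomic(prof, tax)
        assert d.iloc[0, 1] == pytest.approx(7 / 13)

    def test_missing_otu_errors(self, toy_taxonomy):
        prof = _profiles([[1, 0], [0, 1]], otus=["A", "ZZZ"])
        with pytest.raises(KeyError):
            community.unifrac_taxonomic(prof, toy_taxonomy)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_skbio_oracle_on_random_taxonomies(self, seed):
        """Independent cross-check against scikit-bio's UniFrac on the
        explicit tree (<= 16 leaves)."""
        from skbio import TreeNode
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(seed)
        cfg = ap.SimConfig(seed=seed, ranks_fanout=(2, 2, 1, 2, 1, 2))  # 16 species
        tax = simulate.simulate_taxonomy(cfg)
        presence = rng.random((5, len(tax))) < 0.4
        presence[:, 0] = True  # no empty sites
        prof = _profiles(presence.astype(float), otus=list(tax["otu_id"]), n_samples=1)
        mine = community.unifrac_taxonomic(prof, tax)
        tree = TreeNode.read(_io.StringIO(_newick_from_taxonomy(tax)))
        oracle = beta_diversity(
            "unweighted_unifrac",
            presence.astype(int),
            ids=list(prof.index),
            tree=tree,
            taxa=list(tax["otu_id"]),
        )
        np.testing.assert_allclose(
            mine.to_numpy(), oracle.data, atol=1e-12
        )


class TestNMDS:
    def test_line_configuration_low_stress(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.5, 7.0])
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]),
                         index=[f"S{i}" for i in range(6)],
                         columns=[f"S{i}" for i in range(6)])
        res = community.nmds(d, seed=3)
        assert res.stress < 0.01

    def test_duplicate_rows_coincide(self):
        x = np.array([0.0, 0.0, 2.0, 3.0, 5.0])
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
        res = community.nmds(d, seed=0)
        c = res.coordinates.to_numpy()
        span = np.linalg.norm(c.max(0) - c.min(0))
        assert np.linalg.norm(c[0] - c[1]) < 0.05 * span

    def test_deterministic_under_seed(self, small_presence, small_ds):
        prof = community.site_prevalence(small_presence.astype(int), small_ds.samples)
        d = community.bray_curtis(prof)
        a = community.nmds(d, seed=7)
        b = community.nmds(d, seed=7)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_asymmetric_input_errors(self):
        d = pd.DataFrame(np.arange(16, dtype=float).reshape(4, 4))
        with pytest.raises(ValueError):
            community.nmds(d)


class TestSurfaceDeviance:
    def _ordination(self, coords):
        return community.OrdinationResult(
            coordinates=pd.DataFrame(coords, columns=["axis1", "axis2"],
                                     index=[f"S{i}" for i in range(len(coords))]),
            stress=0.05, n_restarts=1, seed=0,
        )

    def test_linear_covariate_near_one(self, rng):
        xy = rng.normal(size=(47, 2))
        ordn = self._ordination(xy)
        cov = pd.Series(2 * xy[:, 0] - xy[:, 1] + 3, index=ordn.coordinates.index)
        assert community.surface_deviance(ordn, cov) > 0.99

    def test_independent_noise_penalised(self, rng):
        xy = rng.normal(size=(47, 2))
        ordn = self._ordination(xy)
        cov = pd.Series(rng.normal(size=47), index=ordn.coordinates.index)
        assert community.surface_deviance(ordn, cov) < 0.3

    def test_constant_covariate_zero(self, rng):
        ordn = self._ordination(rng.normal(size=(10, 2)))
        with pytest.warns(UserWarning, match="constant"):
            dev = community.surface_deviance(
                ordn, pd.Series(5.0, index=ordn.coordinates.index)
            )
        assert dev == 0.0


class TestVariancePartition:
    def test_whittaker_identity_on_printed_triple(self):
        vp = community.whittaker_partition(0.41, 0.34, 0.29)
        assert vp.space_alone == pytest.approx(0.12)
        assert vp.env_alone == pytest.approx(0.07)
        assert vp.shared == pytest.approx(0.22)
        assert sum(vp.as_tuple()) == pytest.approx(1.0, abs=1e-12)

    def test_components_always_sum_to_one(self, rng):
        for _ in range(20):
            r2g, r2e = rng.uniform(0, 0.6, 2)
            r2f = max(r2g, r2e) + rng.uniform(0, 0.3)
            vp = community.whittaker_partition(min(r2f, 1.0), r2g, r2e)
            assert sum(vp.as_tuple()) == pytest.approx(1.0, abs=1e-12)

    def _dm(self, mat, ids):
        return pd.DataFrame(mat, index=ids, columns=ids)

    def test_orthogonal_env_limit(self, rng):
        n = 40
        ids = [f"S{i}" for i in range(n)]
        g = rng.random((n, n)); g = (g + g.T) / 2; np.fill_diagonal(g, 0)
        e = rng.random((n, n)); e = (e + e.T) / 2; np.fill_diagonal(e, 0)
        comm_d = g * 0.8 + rng.normal(0, 0.01, (n, n))
        comm_d = (comm_d + comm_d.T) / 2; np.fill_diagonal(comm_d, 0)
        vp = community.variance_partition(
            self._dm(comm_d, ids), self._dm(g, ids), self._dm(e, ids)
        )
        assert vp.space_alone > 0.9
        assert abs(vp.shared) < 0.05

    def test_identical_predictors_all_shared(self, rng):
        n = 20
        ids = [f"S{i}" for i in range(n)]
        g = rng.random((n, n)); g = (g + g.T) / 2; np.fill_diagonal(g, 0)
        comm_d = 0.5 * g + 0.1
        np.fill_diagonal(comm_d, 0)
        vp = community.variance_partition(
            self._dm(comm_d, ids), self._dm(g, ids), self._dm(g.copy(), ids)
        )
        assert vp.space_alone == pytest.approx(0.0, abs=1e-9)
        assert vp.env_alone == pytest.approx(0.0, abs=1e-9)
        assert vp.shared > 0.9


class TestZoneOverlap:
    def test_overlap_cells_partition_taxa(self, small_presence, small_ds):
        zo = community.zone_overlap(
            small_presence.astype(int), small_ds.samples, small_ds.sites,
            small_ds.taxonomy, "species",
        )
        observed = small_presence.columns[small_presence.any(axis=0)]
        assert sum(zo[c] for c in community.VENN_CELLS) == len(observed)

    def test_triple_share_non_decreasing_with_coarser_rank(self, small_presence, small_ds):
        shares = {
            rank: community.zone_overlap(
                small_presence.astype(int), small_ds.samples, small_ds.sites,
                small_ds.taxonomy, rank,
            )["share_all_three"]
            for rank in ("species", "genus", "order")
        }
        assert shares["genus"] >= shares["species"]
        assert shares["order"] >= shares["genus"]

    def test_unknown_rank_errors(self, small_presence, small_ds):
        with pytest.raises(ValueError):
            community.zone_overlap(
                small_presence.astype(int), small_ds.samples, small_ds.sites,
                small_ds.taxonomy, "tribe",
            )


class TestTopGenera:
    def test_genus_prevalence_at_least_max_member(self, small_presence, small_ds):
        ranked = community.top_prevalent_genera(
            small_presence.astype(int), small_ds.samples, small_ds.taxonomy, n=5
        )
        genus_of = small_ds.taxonomy.set_index("otu_id")["genus"]
        for _, row in ranked.iterrows():
            members = genus_of.index[genus_of == row["genus"]]
            member_max = small_presence[members].sum(axis=0).max()
            assert row["n_samples"] >= member_max

    def test_tie_break_lexicographic(self):
        tab = pd.DataFrame(
            [[1, 1], [1, 1]], columns=["O1", "O2"],
            index=pd.Index(["s0", "s1"], name="sample_id"),
        )
        samples = pd.DataFrame(
            {"sample_id": ["s0", "s1"], "site_id": "S0", "date": "2021-01-01"}
        )
        tax = pd.DataFrame(
            [("O1", "K", "P", "C", "O", "F", "g_b", "s1"),
             ("O2", "K", "P", "C", "O", "F", "g_a", "s2")],
            columns=["otu_id", *RANKS],
        )
        ranked = community.top_prevalent_genera(tab, samples, tax, n=2)
        assert list(ranked["genus"]) == ["g_a", "g_b"]
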