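import numpy as np
import pytest

import seqspace as ss
from seqspace.mds import fit_mds
from seqspace.projection import project_supplementary
from seqspace.seqstats import GroupPartition, frequency_correlation
from seqspace.synthetic import (
    ClusteredSpec,
    clustered_msa,
    drifting_supplementary,
    random_msa,
)


class TestRandomMsa:
    def test_shape_and_alphabet(self):
        aln = random_msa(283, 236, seed=0)
        assert aln.n_sequences == 283
        assert aln.length == 236
        assert "-" not in "".join(aln.rows)

    def test_seed_reproducibility(self):
        assert random_msa(20, 30, seed=5) == random_msa(20, 30, seed=5)
        assert random_msa(20, 30, seed=5) != random_msa(20, 30, seed=6)

    def test_uniform_residue_frequencies(self):
        aln = random_msa(283, 236, seed=1)
        arr = aln.to_array()
        n_cells = arr.size
        p = 1 / 20
        sd = np.sqrt(p * (1 - p) / n_cells)
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            freq = (arr == aa).mean()
            assert abs(freq - p) < 3 * sd + 1e-12

    def test_composition_matched_mode(self):
        freqs = np.zeros(20)
        freqs[0] = 1.0  # all alanine
        aln = random_msa(5, 10, seed=2, frequencies=freqs)
        assert set("".join(aln.rows)) == {"A"}


class TestClusteredMsa:
    def test_zero_mutation_collapses_to_identity(self):
        spec = ClusteredSpec(
            n_columns=40,
            group_sizes=((2, 2), (2, 2)),
            p_group=0.0,
            p_subfam=0.0,
            p_leaf=0.0,
            seed=3,
        )
        fx = clustered_msa(spec)
        assert len(set(fx.alignment.rows)) == 1
        D = ss.active_distance_matrix(fx.alignment)
        assert np.all(D.values == 0)

    def test_marker_column_fully_determines_group(self):
        spec = ClusteredSpec(
            n_columns=30,
            group_sizes=((4, 4), (4, 4)),
            marker_columns={5: ("P", "A")},
            seed=4,
        )
        fx = clustered_msa(spec)
        assignment = dict(zip(fx.groups["id"], fx.groups["group"]))
        part = GroupPartition(assignment, "G0")
        assert frequency_correlation(fx.alignment, part, 5) == pytest.approx(1.0)

    def test_hierarchical_distance_ordering(self):
        spec = ClusteredSpec(
            group_sizes=((20, 20, 20),) * 4,
            p_group=0.6,
            p_subfam=0.3,
            p_leaf=0.1,
            seed=42,
        )
        fx = clustered_msa(spec)
        D = ss.active_distance_matrix(fx.alignment).distances()
        groups = fx.groups["group"].to_numpy()
        subfams = fx.groups["subfamily"].to_numpy()
        same_sub = subfams[:, None] == subfams[None, :]
        same_grp = groups[:, None] == groups[None, :]
        off = ~np.eye(len(groups), dtype=bool)
        within_sub = D[same_sub & off].mean()
        within_grp = D[same_grp & ~same_sub].mean()
        between = D[~same_grp].mean()
        assert within_sub < within_grp < between

    def test_inconsistent_marker_spec_rejected(self):
        with pytest.raises(ValueError, match="one residue per group"):
            ClusteredSpec(
                group_sizes=((2,), (2,)), marker_columns={0: ("P",)}
            )

    def test_pure_function_of_seed(self):
        spec = ClusteredSpec(n_columns=50, group_sizes=((3, 3), (3, 3)), seed=8)
        assert clustered_msa(spec).alignment == clustered_msa(spec).alignment


@pytest.fixture(scope="module")
def space():
    fx = clustered_msa(ClusteredSpec(seed=11))
    D = ss.active_distance_matrix(fx.alignment)
    model = fit_mds(D)
    groups = fx.groups["group"].to_numpy()
    centroids = {
        g: model.embedding_[groups == g, :2].mean(axis=0) for g in ("G0", "G1")
    }
    return fx, model, centroids


class TestDrift:
    def project_barycenter(self, fx, model, t, seed=13):
        sup = drifting_supplementary(
            fx.group_ancestors[0], fx.group_ancestors[1], n=10, t=t, seed=seed
        )
        D_sup = ss.supplementary_distance_matrix(sup, fx.alignment)
        res = project_supplementary(D_sup, model)
        return res.scores[:, :2].mean(axis=0)

    def test_endpoints_land_in_their_clusters(self, space):
        fx, model, centroids = space
        b0 = self.project_barycenter(fx, model, t=0.0)
        b1 = self.project_barycenter(fx, model, t=1.0)
        assert np.linalg.norm(b0 - centroids["G0"]) < np.linalg.norm(
            b0 - centroids["G1"]
        )
        assert np.linalg.norm(b1 - centroids["G1"]) < np.linalg.norm(
            b1 - centroids["G0"]
        )

    def test_barycenter_drifts_monotonically(self, space):
        fx, model, centroids = space
        dists = []
        for t in (0.0, 0.25, 0.5, 0.75, 1.0):
            b = self.project_barycenter(fx, model, t=t)
            dists.append(np.linalg.norm(b - centroids["G1"]))
        assert all(d2 < d1 for d1, d2 in zip(dists, dists[1:]))

    def test_t_outside_unit_interval_rejected(self, space):
        fx, *_ = space
        with pytest.raises(ValueError, match="t must"):
            drifting_supplementary(
                fx.group_ancestors[0], fx.group_ancestors[1], 5, t=1.5, seed=0
            )


class TestSpectrumContrast:
    def test_random_msa_spectrum_is_near_flat(self):
        # structureless control: positive eigenvalues decay slowly, while the
        # clustered alignment concentrates variance in its leading components
        rand = random_msa(100, 236, seed=21)
        lam_r = fit_mds(ss.active_distance_matrix(rand)).eigenvalues_
        pos_r = lam_r[lam_r > 0]
        ratio_rand = pos_r[0] / np.median(pos_r)

        fx = clustered_msa(ClusteredSpec(seed=21))
        lam_c = fit_mds(ss.active_distance_matrix(fx.alignment)).eigenvalues_
        pos_c = lam_c[lam_c > 0]
        ratio_clust = pos_c[0] / np.median(pos_c)

        assert ratio_rand < 3
        assert ratio_clust > 5 * ratio_rand
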