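import numpy as np
import pytest

import fasym
from fasym.simulate import (
    asymmetric_deviation,
    nuisance_transform,
    symmetric_deviation,
)
from fasym.symmetry import (
    AlignedShape,
    SymmetryDecomposition,
    center_and_scale,
    decompose,
    fa_scores,
    gpa,
    optimal_rotation,
    reflect_relabel,
)


class TestReflectRelabel:
    def test_involution(self, toy_scheme, rng):
        x = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(
            reflect_relabel(reflect_relabel(x, toy_scheme), toy_scheme), x
        )

    def test_symmetric_configuration_is_fixed_point(self, toy_scheme):
        x = np.array(
            [[1.0, 2.0, 3.0], [-1.0, 2.0, 3.0],
             [0.5, -1.0, 0.0], [-0.5, -1.0, 0.0],
             [0.0, 4.0, -2.0]]
        )
        np.testing.assert_allclose(reflect_relabel(x, toy_scheme), x, atol=1e-9)

    def test_hand_computed_asymmetric_perturbation(self, toy_scheme):
        """Direct coordinate arithmetic oracle on a 2-pair + 1-midline toy."""
        base = np.array(
            [[1.0, 2.0, 3.0], [-1.0, 2.0, 3.0],
             [0.5, -1.0, 0.0], [-0.5, -1.0, 0.0],
             [0.0, 4.0, -2.0]]
        )
        delta = np.array([0.1, -0.2, 0.3])
        x = base.copy()
        x[0] += delta  # perturb the left member of the first pair only
        # oracle, written out longhand: negate x everywhere, then swap pair rows
        expected = np.empty_like(x)
        expected[0] = [-(-1.0), 2.0, 3.0]                      # was row 1
        expected[1] = [-(1.0 + 0.1), 2.0 - 0.2, 3.0 + 0.3]     # was row 0
        expected[2] = [0.5, -1.0, 0.0]                         # was row 3
        expected[3] = [-0.5, -1.0, 0.0]                        # was row 2
        expected[4] = [0.0, 4.0, -2.0]
        np.testing.assert_allclose(reflect_relabel(x, toy_scheme), expected, atol=1e-12)


class TestGPA:
    def test_symmetric_single_configuration_recovered(self, toy_scheme):
        x = np.array(
            [[1.0, 2.0, 3.0], [-1.0, 2.0, 3.0],
             [0.5, -1.0, 0.0], [-0.5, -1.0, 0.0],
             [0.0, 4.0, -2.0]]
        )
        consensus, aligned = gpa([x, reflect_relabel(x, toy_scheme)], toy_scheme)
        expected = center_and_scale(x)
        # consensus equals the centered/scaled input up to an orientation change
        q = optimal_rotation(expected, consensus)
        np.testing.assert_allclose(expected @ q, consensus, atol=1e-9)
        for a in aligned:
            assert abs(np.sqrt((a.coords**2).sum()) - 1.0) < 1e-9
            np.testing.assert_allclose(a.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_rigid_copies_align_identically(self, toy_scheme, rng):
        """Similarity-transformed copies of one shape collapse to a point."""
        x = rng.normal(size=(5, 3)) * 5
        observations = []
        for i in range(4):
            moved = nuisance_transform(x, rng)
            observations.append(AlignedShape("s", i + 1, False, moved))
            observations.append(
                AlignedShape("s", i + 1, True, reflect_relabel(moved, toy_scheme))
            )
        _, aligned = gpa(observations, toy_scheme)
        originals = [a.coords for a in aligned if not a.is_mirror]
        for other in originals[1:]:
            assert np.sqrt(((originals[0] - other) ** 2).sum()) < 1e-8

    def test_triangle_distance_matches_rotation_grid_oracle(self):
        """Full Procrustes distance of two planar triangles vs. brute force.

        The oracle scans in-plane rotations and the proper 3-D flip family
        (rotation by pi about an in-plane axis composed with in-plane
        rotation) on a fine angular grid.
        """
        a = center_and_scale(np.array([[0.0, 0, 0], [4.0, 0, 0], [1.0, 3.0, 0]]))
        b = center_and_scale(np.array([[0.0, 0, 0], [5.0, 1.0, 0], [0.0, 2.5, 0]]))
        d_impl = np.sqrt(((a @ optimal_rotation(a, b) - b) ** 2).sum())

        thetas = np.linspace(0, 2 * np.pi, 62832, endpoint=False)  # ~1e-4 rad
        cos, sin = np.cos(thetas), np.sin(thetas)
        rz = np.zeros((len(thetas), 3, 3))
        rz[:, 0, 0], rz[:, 0, 1] = cos, -sin
        rz[:, 1, 0], rz[:, 1, 1] = sin, cos
        rz[:, 2, 2] = 1.0
        flip = np.diag([1.0, -1.0, -1.0])  # pi about x, proper
        best = np.inf
        for family in (rz, flip @ rz):
            dists = np.sqrt(((a @ family - b) ** 2).sum(axis=(1, 2)))
            best = min(best, dists.min())
        assert d_impl <= best + 1e-12
        assert abs(d_impl - best) < 1e-4

    def test_degenerate_configuration_raises(self, toy_scheme):
        x = np.zeros((5, 3))
        with pytest.raises(fasym.symmetry.GPAError, match="centroid size"):
            gpa([x, x], toy_scheme)


class TestDecomposition:
    def test_consensus_is_reflection_invariant(self, small_results, small_params):
        c = small_results.consensus
        np.testing.assert_allclose(
            reflect_relabel(c, small_params.scheme), c, atol=1e-9
        )

    def test_aligned_mirror_is_reflection_of_aligned_original(
        self, small_results, small_params
    ):
        scheme = small_params.scheme
        originals = {a.key: a for a in small_results.aligned if not a.is_mirror}
        mirrors = {a.key: a for a in small_results.aligned if a.is_mirror}
        for key, orig in originals.items():
            np.testing.assert_allclose(
                mirrors[key].coords, reflect_relabel(orig.coords, scheme), atol=1e-9
            )

    def test_pythagorean_split_every_observation(self, small_results):
        """sym + asym reproduces the total deviation; the parts are orthogonal."""
        d = small_results.decomposition
        originals = {a.key: a for a in small_results.aligned if not a.is_mirror}
        for i, key in enumerate(d.keys):
            total = originals[key].coords - d.consensus
            np.testing.assert_allclose(
                d.symmetric[i] + d.asymmetric[i], total, atol=1e-9
            )
            inner = float((d.symmetric[i] * d.asymmetric[i]).sum())
            assert abs(inner) < 1e-9
            assert (d.symmetric[i] ** 2).sum() + (d.asymmetric[i] ** 2).sum() == (
                pytest.approx(float((total**2).sum()), abs=1e-9)
            )

    def test_component_construction_is_inverted(self):
        """Observations built as consensus + s + a give back s and a."""
        p, u = 3, 2
        scheme = fasym.SimulationParams(p=p, u=u).scheme
        template = center_and_scale(fasym.make_template(p, u, size=1.0))
        rng = np.random.default_rng(5)
        s = fasym.project_out_similarity(
            symmetric_deviation(rng, p, u, 1e-4), template
        )
        a = fasym.project_out_similarity(
            asymmetric_deviation(rng, p, u, 1e-4), template
        )
        obs = []
        for sid, sign in (("plus", 1.0), ("minus", -1.0)):
            x = template + sign * s + sign * a
            obs.append(AlignedShape(sid, 1, False, x))
            obs.append(AlignedShape(sid, 1, True, reflect_relabel(x, scheme)))
        consensus, aligned = gpa(obs, scheme)
        d = decompose(aligned, consensus, scheme)
        idx = {sid: i for i, (sid, _) in enumerate(d.keys)}
        np.testing.assert_allclose(d.symmetric[idx["plus"]], s, atol=1e-6)
        np.testing.assert_allclose(d.asymmetric[idx["plus"]], a, atol=1e-6)
        np.testing.assert_allclose(d.symmetric[idx["minus"]], -s, atol=1e-6)
        np.testing.assert_allclose(d.asymmetric[idx["minus"]], -a, atol=1e-6)

    def test_missing_mirror_partner_named(self, small_results):
        aligned = [a for a in small_results.aligned if not (a.is_mirror and a.key == ("S0001", 1))]
        with pytest.raises(fasym.symmetry.GPAError, match="S0001"):
            decompose(aligned, small_results.consensus, small_results.decomposition.scheme)


def _toy_decomposition(asym_list, scheme):
    k = scheme.n_landmarks
    n = len(asym_list)
    asym = np.stack(asym_list)
    return SymmetryDecomposition(
        consensus=np.zeros((k, 3)),
        keys=tuple((f"i{j}", 1) for j in range(n)),
        symmetric=np.zeros((n, k, 3)),
        asymmetric=asym,
        da_vector=asym.mean(axis=0),
        scheme=scheme,
        n=n,
        r=1,
    )


class TestFAScores:
    def test_uniform_asymmetry_scores_zero(self, toy_scheme, rng):
        w = rng.normal(size=(5, 3))
        d = _toy_decomposition([w, w, w], toy_scheme)
        assert (fa_scores(d)["fa_score"] < 1e-12).all()

    def test_three_individual_toy(self, toy_scheme, rng):
        v = rng.normal(size=(5, 3))
        d = _toy_decomposition([np.zeros((5, 3)), v, -v], toy_scheme)
        scores = fa_scores(d).set_index("specimen_id")["fa_score"]
        vnorm = float(np.linalg.norm(v))
        assert scores["i0"] == pytest.approx(0.0, abs=1e-12)
        assert scores["i1"] == pytest.approx(vnorm, rel=1e-12)
        assert scores["i2"] == pytest.approx(vnorm, rel=1e-12)

    def test_doubling_asymmetry_doubles_scores(self):
        base = dict(n=10, r=2, p=3, u=2, sigma_err=0.0, da_magnitude=0.2, seed=8)
        s1 = fasym.ObjectSymmetryModel(
            fasym.simulate_dataset(sigma_fa=0.05, **base)
        ).fit().fa_scores()["fa_score"]
        s2 = fasym.ObjectSymmetryModel(
            fasym.simulate_dataset(sigma_fa=0.10, **base)
        ).fit().fa_scores()["fa_score"]
        np.testing.assert_allclose(s2 / s1, 2.0, rtol=0.01)

    def test_invariance_to_nuisance_similarity_transforms(self, small_params):
        """FA scores agree whether or not arbitrary rigid motions + scalings
        are applied to every input configuration."""
        plain = fasym.ObjectSymmetryModel(
            fasym.simulate_dataset(small_params, apply_nuisance=False)
        ).fit().fa_scores()["fa_score"]
        moved = fasym.ObjectSymmetryModel(
            fasym.simulate_dataset(small_params, apply_nuisance=True)
        ).fit().fa_scores()["fa_score"]
        np.testing.assert_allclose(plain, moved, atol=1e-6)


class TestScoreSummaries:
    def test_loader_and_summary_roundtrip(self, tmp_path, rng):
        scores = np.abs(rng.normal(0.015, 0.004, size=100))
        path = tmp_path / "scores.csv"
        import pandas as pd

        pd.DataFrame({"id": [f"s{i}" for i in range(100)], "fa_score": scores}).to_csv(
            path, index=False
        )
        table = fasym.load_fa_score_table(path)
        summary = fasym.summarize_fa_scores(table)
        assert summary["mean"] == pytest.approx(float(scores.mean()), rel=1e-12)
        assert summary["median"] == pytest.approx(float(np.median(scores)), rel=1e-12)
        assert summary["sd"] == pytest.approx(float(scores.std(ddof=1)), rel=1e-12)
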