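"""Five-stage positioning pipeline: rig, volumetrise, weight, embed, skin."""

import io

import numpy as np
import pytest
import trimesh

from virtradiol.phantoms import PhantomSpec, make_phantom
from virtradiol.posing import (
    Bone,
    Joint,
    Pose,
    PoseError,
    Skeleton,
    VolumetricCage,
    bone_transforms,
    compute_weights,
    embed_tissues,
    fit_skeleton,
    harmonic_weights,
    load_pose,
    load_skeleton,
    pose_tissues,
    save_pose,
    save_skeleton,
    skin_cage,
    volumetrise,
)


def two_bone_skeleton(a=(0.0, 0.0, -150.0), b=(0.0, 0.0, 0.0), c=(0.0, 0.0, 150.0)):
    return Skeleton(
        joints=(Joint("proximal", np.array(a)),
                Joint("elbow", np.array(b), parent="proximal"),
                Joint("distal", np.array(c), parent="elbow")),
        bones=(Bone("upper", ("proximal", "elbow"), ("bone_upper",)),
               Bone("lower", ("elbow", "distal"), ("bone_lower",))),
    )


@pytest.fixture(scope="module")
def limb():
    scene, skeleton = make_phantom(PhantomSpec("two_bone_limb", mesh_resolution=2))
    return {t.name: t.mesh for t in scene}, skeleton


@pytest.fixture(scope="module")
def limb_cage(limb):
    meshes, skeleton = limb
    bones = {"upper": meshes["bone_upper"], "lower": meshes["bone_lower"]}
    return volumetrise(meshes["skin"], bones, lattice_spacing=15.0)


class TestSkeleton:
    def test_tree_invariants(self):
        with pytest.raises(PoseError, match="root"):
            Skeleton(joints=(Joint("a", np.zeros(3)),
                             Joint("b", np.ones(3))), bones=())
        with pytest.raises(PoseError, match="unknown parent"):
            Skeleton(joints=(Joint("a", np.zeros(3)),
                             Joint("b", np.ones(3), parent="ghost")), bones=())

    def test_fit_two_spheres_joint_at_gap_midpoint(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        upper = sph.copy()
        lower = sph.copy()
        lower.apply_translation([40.0, 0.0, 0.0])
        template = Skeleton(
            joints=(Joint("p", np.array([-10.0, 0.0, 0.0])),
                    Joint("j", np.array([15.0, 0.0, 0.0]), parent="p"),
                    Joint("d", np.array([50.0, 0.0, 0.0]), parent="j")),
            bones=(Bone("u", ("p", "j"), ("upper",)),
                   Bone("l", ("j", "d"), ("lower",))),
        )
        fitted = fit_skeleton(template, {"upper": upper, "lower": lower})
        np.testing.assert_allclose(fitted.joint("j").rest_position,
                                   [20.0, 0.0, 0.0], atol=1e-9)

    def test_fit_rigid_equivariance(self):
        rot90 = trimesh.transformations.rotation_matrix(np.pi / 2, [0, 1, 0])
        upper = trimesh.creation.capsule(height=20.0, radius=2.0,
                                         transform=rot90)
        lower = upper.copy()
        lower.apply_translation([40.0, 0.0, 0.0])
        template = Skeleton(
            joints=(Joint("p", np.array([0.0, 0.0, 0.0])),
                    Joint("j", np.array([20.0, 0.0, 0.0]), parent="p")),
            bones=(Bone("u", ("p", "j"), ("upper",)),
                   Bone("l", ("j",) * 2, ("lower",))),
        )
        rot = trimesh.transformations.rotation_matrix(0.8, [0.0, 0.0, 1.0],
                                                      [5.0, -3.0, 2.0])
        fit0 = fit_skeleton(template, {"upper": upper, "lower": lower})
        upper2, lower2 = upper.copy(), lower.copy()
        upper2.apply_transform(rot)
        lower2.apply_transform(rot)
        t2 = Skeleton(
            joints=tuple(Joint(j.name, (rot[:3, :3] @ j.rest_position) + rot[:3, 3],
                               j.parent) for j in template.joints),
            bones=template.bones)
        fit1 = fit_skeleton(t2, {"upper": upper2, "lower": lower2})
        for j in fit0.joints:
            moved = rot[:3, :3] @ j.rest_position + rot[:3, 3]
            np.testing.assert_allclose(fit1.joint(j.name).rest_position, moved,
                                       atol=1e-6)

    def test_fit_missing_bone_mesh_named(self):
        template = two_bone_skeleton()
        with pytest.raises(PoseError, match="upper"):
            fit_skeleton(template, {"bone_lower": trimesh.creation.box()})


class TestVolumetrise:
    def test_cube_skin_vertex_count_near_bcc_density(self):
        skin = trimesh.creation.box(extents=(100.0, 100.0, 100.0))
        bone = trimesh.creation.box(extents=(80.0, 80.0, 10.0))
        cage = volumetrise(skin, {"b": bone}, lattice_spacing=10.0)
        # BCC: corners + centres give 2 vertices per s^3 cell; interior
        # counts are depressed by the one-cell boundary shell
        expect = 2.0 * (100.0 / 10.0) ** 3
        interior = 2.0 * 9**3  # conservative bracket from one fewer cell/axis
        assert interior * 0.9 <= len(cage.vertices) <= expect * 1.1

    def test_all_vertices_inside_skin(self):
        skin = trimesh.creation.icosphere(subdivisions=3, radius=50.0)
        bone = trimesh.creation.icosphere(subdivisions=2, radius=15.0)
        cage = volumetrise(skin, {"b": bone}, lattice_spacing=12.0)
        r = np.linalg.norm(cage.vertices, axis=1)
        assert np.all(r < 50.0)

    def test_bone_labels_respect_containment(self):
        skin = trimesh.creation.box(extents=(100.0, 100.0, 100.0))
        bone = trimesh.creation.box(extents=(50.0, 100.0, 100.0))
        bone.apply_translation([-25.0, 0.0, 0.0])  # left half
        cage = volumetrise(skin, {"left": bone}, lattice_spacing=10.0)
        labelled = np.array([lb == "left" for lb in cage.vertex_labels])
        assert labelled.any()
        assert np.all(cage.vertices[labelled, 0] < 0.0)

    def test_positive_tet_orientation(self, limb_cage):
        v, t = limb_cage.vertices, limb_cage.tetrahedra
        a, b, c, d = (v[t[:, i]] for i in range(4))
        vol6 = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)
        assert np.all(vol6 > 0)

    def test_too_coarse_spacing_names_bone(self):
        skin = trimesh.creation.box(extents=(100.0, 100.0, 100.0))
        bone = trimesh.creation.icosphere(subdivisions=2, radius=2.0)
        with pytest.raises(PoseError, match="b"):
            volumetrise(skin, {"b": bone}, lattice_spacing=30.0)


class TestWeights:
    def test_single_bone_cage_all_ones(self):
        skin = trimesh.creation.box(extents=(60.0, 60.0, 60.0))
        bone = trimesh.creation.box(extents=(20.0, 20.0, 20.0))
        cage = volumetrise(skin, {"only": bone}, lattice_spacing=10.0)
        w = compute_weights(cage)
        assert np.all(w.weights == 1.0)

    def test_chain_harmonic_ramp_is_linear(self):
        # harmonic functions on a 1-D chain are linear: w_A(k) = 1 - k/10
        n = 11
        edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
        labels = ["A"] + [None] * (n - 2) + ["B"]
        w = harmonic_weights(n, edges, labels, ["A", "B"])
        np.testing.assert_allclose(w.weights[:, 0], 1 - np.arange(n) / 10.0,
                                   atol=1e-9)
        np.testing.assert_allclose(w.weights.sum(axis=1), 1.0, atol=1e-9)

    def test_maximum_principle_and_partition(self, limb_cage):
        w = compute_weights(limb_cage)
        assert np.all(w.weights >= 0.0) and np.all(w.weights <= 1.0)
        np.testing.assert_allclose(w.weights.sum(axis=1), 1.0, atol=1e-6)

    def test_weights_decay_along_two_bone_chain(self):
        n = 9
        edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
        labels = ["A", None, None, None, None, None, None, None, "B"]
        w = harmonic_weights(n, edges, labels, ["A", "B"])
        assert np.all(np.diff(w.weights[:, 0]) < 0)

    def test_disconnected_free_component_rejected(self):
        edges = np.array([[0, 1], [2, 3]])
        with pytest.raises(PoseError, match="component"):
            harmonic_weights(4, edges, ["A", None, None, None], ["A"])


class TestEmbedding:
    def setup_method(self):
        self.cage = VolumetricCage(
            vertices=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0],
                               [0.0, 10.0, 0.0], [0.0, 0.0, 10.0]]),
            tetrahedra=np.array([[0, 1, 2, 3]]),
            vertex_labels=["A", "A", "A", "A"],
        )

    def test_vertex_coincident_with_cage_vertex(self):
        mesh = trimesh.Trimesh(vertices=[[10.0, 0.0, 0.0], [1.0, 1.0, 1.0],
                                         [1.0, 2.0, 1.0]],
                               faces=[[0, 1, 2]], process=False)
        emb = embed_tissues({"t": mesh}, self.cage)
        bary = emb.barycentric["t"][0]
        assert sorted(bary) == pytest.approx([0.0, 0.0, 0.0, 1.0], abs=1e-12)

    def test_centroid_is_uniform_barycentre(self):
        centroid = self.cage.vertices.mean(axis=0)
        mesh = trimesh.Trimesh(vertices=[centroid, [1.0, 1.0, 1.0], [1.0, 2.0, 1.0]],
                               faces=[[0, 1, 2]], process=False)
        emb = embed_tissues({"t": mesh}, self.cage)
        np.testing.assert_allclose(emb.barycentric["t"][0], 0.25, atol=1e-12)

    def test_rest_reconstruction_identity(self, limb, limb_cage):
        meshes, _ = limb
        emb = embed_tissues(meshes, limb_cage)
        posed = pose_tissues(meshes, emb, limb_cage, limb_cage.vertices)
        for name, mesh in meshes.items():
            np.testing.assert_array_equal(posed[name].vertices, mesh.vertices)

    def test_outside_vertices_snapped(self):
        mesh = trimesh.Trimesh(vertices=[[50.0, 50.0, 50.0], [1.0, 1.0, 1.0],
                                         [1.0, 2.0, 1.0]],
                               faces=[[0, 1, 2]], process=False)
        emb = embed_tissues({"t": mesh}, self.cage)
        assert emb.snapped["t"] == 1
        bary = emb.barycentric["t"][0]
        assert bary.sum() == pytest.approx(1.0, abs=1e-9)
        # affine-extension coordinates reconstruct the vertex exactly
        tet = self.cage.tetrahedra[emb.tet_index["t"][0]]
        rec = bary @ self.cage.vertices[tet]
        np.testing.assert_allclose(rec, [50.0, 50.0, 50.0], atol=1e-9)


class TestSkinning:
    def test_identity_pose_is_bit_exact_noop(self, limb, limb_cage):
        meshes, skeleton = limb
        w = compute_weights(limb_cage)
        pose = Pose.identity(skeleton)
        deformed = skin_cage(limb_cage, w, skeleton, pose)
        np.testing.assert_array_equal(deformed, limb_cage.vertices)

    def test_single_bone_rigid_rotation(self):
        skel = Skeleton(joints=(Joint("root", np.array([1.0, 2.0, 3.0])),),
                        bones=(Bone("only", ("root", "root"), ()),))
        cage = VolumetricCage(
            vertices=np.random.default_rng(0).uniform(-10, 10, (50, 3)),
            tetrahedra=np.zeros((0, 4), dtype=int),
            vertex_labels=["only"] * 50,
        )
        from virtradiol.posing import WeightField

        w = WeightField(("only",), np.ones((50, 1)))
        angle = np.deg2rad(37.0)
        q = (np.cos(angle / 2), 0.0, np.sin(angle / 2), 0.0)  # about +y
        pose = Pose({"root": q})
        deformed = skin_cage(cage, w, skel, pose)
        rot = trimesh.transformations.rotation_matrix(angle, [0, 1, 0],
                                                      [1.0, 2.0, 3.0])
        expect = cage.vertices @ rot[:3, :3].T + rot[:3, 3]
        np.testing.assert_allclose(deformed, expect, atol=1e-6)

    def test_half_weights_under_translations_blend(self):
        # two root-level bones cannot share one tree; emulate with transforms
        skel = Skeleton(
            joints=(Joint("r", np.zeros(3)),
                    Joint("c", np.array([1.0, 0.0, 0.0]), parent="r")),
            bones=(Bone("a", ("r", "c"), ()), Bone("b", ("c", "c"), ())),
        )
        from virtradiol.posing import WeightField

        cage = VolumetricCage(vertices=np.array([[5.0, 5.0, 5.0]]),
                              tetrahedra=np.zeros((0, 4), dtype=int),
                              vertex_labels=[None])
        w = WeightField(("a", "b"), np.array([[0.5, 0.5]]))
        pose = Pose({"r": (1.0, 0.0, 0.0, 0.0), "c": (1.0, 0.0, 0.0, 0.0)},
                    root_translation=np.array([2.0, 0.0, 0.0]))
        # root translation moves both bones: displacement is the full 2 mm;
        # check the blend arithmetic with distinct transforms instead
        deformed = skin_cage(cage, w, skel, pose)
        np.testing.assert_allclose(deformed[0], [7.0, 5.0, 5.0], atol=1e-12)

    def test_missing_joint_in_pose_rejected(self, limb):
        _, skeleton = limb
        with pytest.raises(PoseError, match="elbow"):
            bone_transforms(skeleton, Pose({"proximal": (1.0, 0.0, 0.0, 0.0),
                                            "distal": (1.0, 0.0, 0.0, 0.0)}))

    def test_cage_rigid_transform_carries_to_tissues(self, limb, limb_cage):
        meshes, _ = limb
        emb = embed_tissues(meshes, limb_cage)
        rot = trimesh.transformations.rotation_matrix(0.5, [1, 1, 0], [0, 0, 40.0])
        moved = limb_cage.vertices @ rot[:3, :3].T + rot[:3, 3]
        posed = pose_tissues(meshes, emb, limb_cage, moved)
        for name, mesh in meshes.items():
            expect = mesh.vertices @ rot[:3, :3].T + rot[:3, 3]
            err = np.linalg.norm(posed[name].vertices - expect, axis=1)
            assert err.max() < 1e-6

    def test_cage_uniform_scale_carries_to_tissues(self):
        cage = VolumetricCage(
            vertices=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0],
                               [0.0, 10.0, 0.0], [0.0, 0.0, 10.0]]),
            tetrahedra=np.array([[0, 1, 2, 3]]),
            vertex_labels=["A"] * 4,
        )
        mesh = trimesh.Trimesh(vertices=[[2.0, 3.0, 1.0], [1.0, 1.0, 1.0],
                                         [4.0, 1.0, 1.0]],
                               faces=[[0, 1, 2]], process=False)
        emb = embed_tissues({"t": mesh}, cage)
        posed = pose_tissues({"t": mesh}, emb, cage, cage.vertices * 2.0)
        np.testing.assert_allclose(posed["t"].vertices,
                                   np.asarray(mesh.vertices) * 2.0, atol=1e-9)


class TestPoseIO:
    def test_round_trip_identity(self, limb):
        _, skeleton = limb
        pose = Pose({"proximal": (1.0, 0.0, 0.0, 0.0),
                     "elbow": (np.sqrt(0.5), -np.sqrt(0.5), 0.0, 0.0),
                     "distal": (1.0, 0.0, 0.0, 0.0)},
                    root_translation=np.array([1.0, -2.0, 3.0]), standing=False)
        buf = io.StringIO()
        save_pose(pose, buf)
        buf.seek(0)
        loaded = load_pose(buf, skeleton)
        assert loaded.rotations == pose.rotations
        np.testing.assert_array_equal(loaded.root_translation, pose.root_translation)
        assert loaded.standing is False

    def test_unknown_joint_rejected(self, limb):
        _, skeleton = limb
        buf = io.StringIO()
        save_pose(Pose({"wrist": (1.0, 0.0, 0.0, 0.0)}), buf)
        buf.seek(0)
        with pytest.raises(PoseError, match="wrist"):
            load_pose(buf, skeleton)

    def test_skeleton_round_trip(self, limb):
        _, skeleton = limb
        buf = io.StringIO()
        save_skeleton(skeleton, buf)
        buf.seek(0)
        loaded = load_skeleton(buf)
        assert [j.name for j in loaded.joints] == [j.name for j in skeleton.joints]
        assert loaded.bones == skeleton.bones

    def test_pose_file_and_direct_api_agree_bit_exactly(self, limb, limb_cage):
        meshes, skeleton = limb
        q = (np.sqrt(0.5), -np.sqrt(0.5), 0.0, 0.0)
        direct = Pose({"proximal": (1.0, 0.0, 0.0, 0.0), "elbow": q,
                       "distal": (1.0, 0.0, 0.0, 0.0)})
        buf = io.StringIO()
        save_pose(direct, buf)
        buf.seek(0)
        from_file = load_pose(buf, skeleton)
        w = compute_weights(limb_cage)
        a = skin_cage(limb_cage, w, skeleton, direct)
        b = skin_cage(limb_cage, w, skeleton, from_file)
        np.testing.assert_array_equal(a, b)
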