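"""Structural-property metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from unfoldmap import metrics, synth
from unfoldmap.errors import ConfigError, ShapeError, TopologyError, UndefinedMetricError
from unfoldmap.io import SelectionConfig, Trajectory

from conftest import ca_structure


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def qsh_oracle(frame_ca, native_ca, min_sep=7, cutoff=10.0):
    """Exhaustive pair-scan native-contact fraction."""
    n_native = 0
    n_kept = 0
    for i in range(len(native_ca)):
        for j in range(i + min_sep, len(native_ca)):
            if np.linalg.norm(native_ca[i] - native_ca[j]) < cutoff:
                n_native += 1
                if np.linalg.norm(frame_ca[i] - frame_ca[j]) < cutoff:
                    n_kept += 1
    return n_kept / n_native if n_native else None


def drms_oracle(a, b):
    acc = 0.0
    cnt = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a)):
            da = np.linalg.norm(a[i] - a[j])
            db = np.linalg.norm(b[i] - b[j])
            acc += (da - db) ** 2
            cnt += 1
    return np.sqrt(acc / cnt)


def rg_oracle(coords):
    c = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - c) ** 2, axis=1)))


def rmsd_grid_oracle(a, b):
    """Proper-rotation RMSD by Euler-grid search + local refinement."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def f(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((a - b @ R.T) ** 2, axis=1)))

    best, best_angles = np.inf, None
    grid = np.linspace(-np.pi, np.pi, 13)
    for az in grid:
        for ay in grid[:7]:
            for ax in grid:
                v = f((az, ay, ax))
                if v < best:
                    best, best_angles = v, (az, ay, ax)
    res = minimize(f, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14})
    return min(best, res.fun)


def sphere_cap_asa(r1, r2, dist, probe):
    """Analytic accessible areas of two intersecting solvent-expanded spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if dist >= R1 + R2:
        return 4 * np.pi * R1**2, 4 * np.pi * R2**2
    # heights of the buried spherical caps
    h1 = R1 - (dist**2 + R1**2 - R2**2) / (2 * dist)
    h2 = R2 - (dist**2 + R2**2 - R1**2) / (2 * dist)
    return (
        4 * np.pi * R1**2 - 2 * np.pi * R1 * h1,
        4 * np.pi * R2**2 - 2 * np.pi * R2 * h2,
    )


# ---------------------------------------------------------------------------
# native contacts / Qsh
# ---------------------------------------------------------------------------

class TestNativeContacts:
    def test_straight_chain_has_none(self):
        coords = np.column_stack([3.8 * np.arange(20), np.zeros(20), np.zeros(20)])
        cs = metrics.native_contacts(ca_structure(coords))
        assert cs.n_native == 0  # sep-7 distance is 26.6 Å

    def test_hairpin_contact_found(self):
        # straight arm out, tight turn, arm back: residues 1 and 10 close
        out = np.column_stack([3.8 * np.arange(5), np.zeros(5), np.zeros(5)])
        back = out[::-1] + [0.0, 6.0, 0.0]
        coords = np.vstack([out, back])
        cs = metrics.native_contacts(ca_structure(coords), min_seq_sep=7)
        assert (0, 9) in {tuple(p) for p in cs.pairs}  # residues 1 and 10 (0-based)

    def test_min_seq_sep_excludes_closer_pairs(self):
        out = np.column_stack([3.8 * np.arange(5), np.zeros(5), np.zeros(5)])
        back = out[::-1] + [0.0, 5.0, 0.0]
        coords = np.vstack([out, back])
        cs = metrics.native_contacts(ca_structure(coords), min_seq_sep=7)
        seps = cs.pairs[:, 1] - cs.pairs[:, 0]
        assert np.all(seps >= 7)
        # pair (2, 8) is only 6 apart and ~5 Å: must be absent
        assert (2, 8) not in {tuple(p) for p in cs.pairs}

    def test_too_short_chain_warns_empty(self):
        coords = np.random.default_rng(0).normal(size=(5, 3)) * 3
        with pytest.warns(UserWarning):
            cs = metrics.native_contacts(ca_structure(coords))
        assert cs.n_native == 0


class TestQsh:
    def test_native_is_one(self, toy_native):
        cs = metrics.native_contacts(toy_native)
        assert metrics.compute_qsh(toy_native, cs, mode="hard") == 1.0

    @pytest.mark.parametrize("scale", [1.5, 3.0])
    def test_scaled_frame_matches_oracle(self, scale):
        native = synth.make_toy_polymer(10, seed=7)
        cs = metrics.native_contacts(native)
        centroid = native.coord.mean(axis=0)
        frame = native.with_coords(centroid + scale * (native.coord - centroid))
        got = metrics.compute_qsh(frame, cs, mode="hard")
        want = qsh_oracle(frame.ca_coords, native.ca_coords)
        assert got == pytest.approx(want, abs=1e-12)

    def test_soft_midpoint_is_half(self, toy_native):
        cs = metrics.native_contacts(toy_native)
        centroid = toy_native.coord.mean(axis=0)
        # scaling by λ puts every pair exactly at the logistic midpoint
        frame = toy_native.with_coords(centroid + 1.2 * (toy_native.coord - centroid))
        assert metrics.compute_qsh(frame, cs, mode="soft", lam=1.2) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_empty_contacts_error(self):
        cs = metrics.ContactSet(np.empty((0, 2), int), np.empty(0), 7, 10.0)
        coords = np.column_stack([3.8 * np.arange(10), np.zeros(10), np.zeros(10)])
        with pytest.raises(UndefinedMetricError):
            metrics.compute_qsh(ca_structure(coords), cs)


# ---------------------------------------------------------------------------
# RMSD / dRMS / Rg
# ---------------------------------------------------------------------------

class TestRmsd:
    def test_rigid_motion_is_zero(self, toy_native):
        R = Rotation.from_euler("zyx", [0.3, -1.1, 2.0]).as_matrix()
        moved = toy_native.with_coords(toy_native.coord @ R.T + [5.0, -2.0, 7.0])
        assert metrics.rmsd_ca(moved, toy_native) <= 1e-6

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(3, 3)) * 4
        b = rng.normal(size=(3, 3)) * 4
        got = metrics.rmsd_ca(ca_structure(a), ca_structure(b))
        want = rmsd_grid_oracle(a, b)
        assert got == pytest.approx(want, abs=1e-3)

    def test_reflection_not_matched(self):
        """Only proper rotations: a mirror image keeps RMSD > 0."""
        rng = np.random.default_rng(5)
        a = rng.normal(size=(6, 3)) * 4  # generic chiral set
        m = a.copy()
        m[:, 0] *= -1
        assert metrics.rmsd_ca(ca_structure(m), ca_structure(a)) > 0.5

    def test_count_mismatch(self, toy_native):
        other = ca_structure(np.zeros((3, 3)))
        with pytest.raises(TopologyError):
            metrics.rmsd_ca(other, toy_native)

    def test_pairwise_matches_single(self, toy_native):
        rng = np.random.default_rng(2)
        frames = [
            toy_native.coord[toy_native.ca_mask] + rng.normal(size=(20, 3)) * s
            for s in (0.1, 0.5, 1.0, 2.0)
        ]
        stack = np.stack(frames)
        R = metrics.pairwise_rmsd(stack, stack)
        for i in range(4):
            for j in range(4):
                want = metrics.rmsd_ca(ca_structure(frames[i]), ca_structure(frames[j]))
                assert R[i, j] == pytest.approx(want, abs=1e-6)
        assert np.allclose(np.diag(R), 0.0, atol=1e-6)


class TestDrms:
    def test_identity(self, toy_native):
        assert metrics.drms(toy_native, toy_native) == 0.0

    def test_collinear_hand_case(self):
        a = ca_structure([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        b = ca_structure([[0, 0, 0], [2, 0, 0], [4, 0, 0]])
        # pair deviations (1, 1, 2) → √((1+1+4)/3) = √2
        assert metrics.drms(b, a) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_rotation_invariant(self, toy_native):
        R = Rotation.from_euler("xyz", [1.0, 0.5, -0.7]).as_matrix()
        frame = toy_native.with_coords(toy_native.coord * 1.5)
        rotated = frame.with_coords(frame.coord @ R.T)
        assert metrics.drms(frame, toy_native) == pytest.approx(
            metrics.drms(rotated, toy_native), abs=1e-9
        )

    def test_single_residue_error(self):
        s = ca_structure([[0, 0, 0]])
        with pytest.raises(UndefinedMetricError):
            metrics.drms(s, s)


class TestRg:
    def test_single_atom(self):
        assert metrics.radius_of_gyration(ca_structure([[1, 2, 3]])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_points_half_separation(self):
        s = ca_structure([[0, 0, 0], [2, 0, 0]])  # equal masses
        assert metrics.radius_of_gyration(s) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k", [0.5, 2.0, 3.7])
    def test_homogeneity(self, toy_native, k):
        rg = metrics.radius_of_gyration(toy_native)
        centroid = toy_native.coord.mean(axis=0)
        scaled = toy_native.with_coords(centroid + k * (toy_native.coord - centroid))
        assert metrics.radius_of_gyration(scaled) == pytest.approx(k * rg, rel=1e-12)


class TestBruteForceEquivalence:
    """Qsh / dRMS / Rg vs independent direct-summation oracles on small chains."""

    @pytest.mark.parametrize("seed", range(4))
    def test_small_chain_equivalence(self, seed):
        native = synth.make_toy_polymer(12, seed=seed)
        rng = np.random.default_rng(seed + 100)
        frame = native.with_coords(native.coord * 1.4 + rng.normal(size=native.coord.shape))
        cs = metrics.native_contacts(native)
        assert metrics.compute_qsh(frame, cs) == pytest.approx(
            qsh_oracle(frame.ca_coords, native.ca_coords), rel=1e-9
        )
        assert metrics.drms(frame, native) == pytest.approx(
            drms_oracle(frame.ca_coords, native.ca_coords), rel=1e-9
        )
        assert metrics.radius_of_gyration(frame, weighting="uniform") == pytest.approx(
            rg_oracle(frame.coord), rel=1e-9
        )


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

class TestSasa:
    def test_isolated_sphere(self):
        s = ca_structure([[0, 0, 0]])
        area = metrics.sasa(s, probe=1.4, n_points=960)[0]
        assert area == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_just_touching_spheres_full(self):
        d = 2 * (1.7 + 1.4)
        s = ca_structure([[0, 0, 0], [d, 0, 0]])
        areas = metrics.sasa(s, probe=1.4, n_points=960)
        full = 4 * np.pi * 3.1**2
        np.testing.assert_allclose(areas, full, rtol=0.01)

    def test_overlapping_vs_cap_formula(self):
        from conftest import ca_structure as mk

        dist = 3.0
        s = mk([[0, 0, 0], [dist, 0, 0]])
        areas = metrics.sasa(s, probe=1.4, n_points=960)
        want = sphere_cap_asa(1.7, 1.7, dist, 1.4)
        np.testing.assert_allclose(areas, want, rtol=0.02)

    def test_unknown_element_errors(self):
        s = ca_structure([[0, 0, 0]])
        s.element = np.array(["XX"])
        with pytest.raises(ConfigError):
            metrics.sasa(s)

    def test_cross_check_against_biotite(self, toy_native):
        """Independent implementation check: biotite's Shrake–Rupley with the
        same element radii should agree closely on a compact chain."""
        import biotite.structure as bts

        arr = bts.AtomArray(toy_native.n_atoms)
        arr.coord = toy_native.coord.astype(np.float32)
        arr.atom_name = toy_native.atom_name
        arr.element = toy_native.element
        arr.res_id = toy_native.res_id
        arr.res_name = toy_native.res_name
        arr.chain_id = toy_native.chain_id
        arr.hetero = np.zeros(toy_native.n_atoms, dtype=bool)
        ref = bts.sasa(arr, probe_radius=1.4, point_number=1000, vdw_radii="Single")
        mine = metrics.sasa(toy_native, probe=1.4, n_points=1000)
        assert mine.sum() == pytest.approx(ref.sum(), rel=0.02)


class TestAsaAggregates:
    def test_partition_identity(self, toy_native):
        areas = metrics.sasa(toy_native)
        agg = metrics.asa_aggregates(areas, toy_native)
        assert agg["t.ASA"] == pytest.approx(agg["t.p.ASA"] + agg["t.np.ASA"], abs=1e-9)
        assert agg["s.ASA"] == pytest.approx(agg["s.p.ASA"] + agg["s.np.ASA"], abs=1e-9)
        assert agg["s.ASA"] <= agg["t.ASA"]
        assert agg["W.ASA"] <= agg["t.ASA"]

    def test_hand_sums_three_residue_peptide(self):
        coords = [[0, 0, 0], [1.5, 0, 0], [8, 0, 0], [9.5, 0, 0], [16, 0, 0], [17.5, 0, 0]]
        s = ca_structure(np.array(coords)[[0, 2, 4]])
        # build explicitly with side-chain atoms
        from unfoldmap.io import Structure

        s = Structure(
            atom_name=np.array(["CA", "CB"] * 3),
            element=np.array(["C"] * 6),
            res_id=np.repeat([1, 2, 3], 2),
            res_name=np.repeat(["SER", "ALA", "TRP"], 2),
            chain_id=np.array(["A"] * 6),
            coord=np.array(coords, dtype=float),
            hetero=np.zeros(6, dtype=bool),
        )
        areas = metrics.sasa(s)
        agg = metrics.asa_aggregates(areas, s)
        assert agg["t.ASA"] == pytest.approx(areas.sum(), abs=1e-9)
        assert agg["t.p.ASA"] == pytest.approx(areas[[0, 1, 4, 5]].sum(), abs=1e-9)  # SER+TRP
        assert agg["t.np.ASA"] == pytest.approx(areas[[2, 3]].sum(), abs=1e-9)  # ALA
        assert agg["s.ASA"] == pytest.approx(areas[[1, 3, 5]].sum(), abs=1e-9)
        assert agg["W.ASA"] == pytest.approx(areas[[4, 5]].sum(), abs=1e-9)
        assert agg["s.W3.ASA"] == pytest.approx(areas[5], abs=1e-9)

    def test_selection_modes(self, toy_native):
        areas = metrics.sasa(toy_native)
        sel = SelectionConfig(
            selections={"site_t": [1, 2, 3], "site_s": [1, 2, 3]},
            modes={"site_s": "sidechain"},
        )
        agg = metrics.asa_aggregates(areas, toy_native, sel)
        assert 0 < agg["site_s"] < agg["site_t"] <= agg["t.ASA"]


# ---------------------------------------------------------------------------
# ss melting / dipole / ΔCp
# ---------------------------------------------------------------------------

class TestSsMelting:
    def test_identity(self):
        assert metrics.ss_melting("HHEEC", "HHEEC") == (0.0, 0.0, 0.0)

    def test_full_melt(self):
        assert metrics.ss_melting("CCCCCCCC", "HHHHEEEE") == (100.0, 100.0, 100.0)

    def test_half_helix(self):
        lh, le, lc = metrics.ss_melting("HHCC", "HHHH")
        assert lh == 50.0

    def test_clamps_at_zero(self):
        # more helix than native: no negative melting
        lh, _, _ = metrics.ss_melting("HHHH", "HHCC")
        assert lh == 0.0

    def test_alphabet_violation(self):
        with pytest.raises(ConfigError):
            metrics.ss_melting("HHXX", "HHHH")

    def test_zero_denominator_flagged(self):
        with pytest.warns(UserWarning):
            out = metrics.ss_melting("CCC", "CCC")
        assert out == (0.0, 0.0, 0.0)


class TestDipole:
    def test_zero_charges(self, toy_native):
        assert metrics.dipole_moment(toy_native, np.zeros(toy_native.n_atoms)) == 0.0

    def test_unit_dipole(self):
        s = ca_structure([[0, 0, 0], [1, 0, 0]])
        mu = metrics.dipole_moment(s, np.array([1.0, -1.0]))
        assert mu == pytest.approx(4.80320, abs=1e-9)

    def test_translation_invariance_neutral(self, toy_native):
        q = toy_native.charge
        mu0 = metrics.dipole_moment(toy_native)
        shifted = toy_native.with_coords(toy_native.coord + [100.0, -50.0, 3.0])
        assert metrics.dipole_moment(shifted, q) == pytest.approx(mu0, abs=1e-9)

    def test_missing_charges(self):
        s = ca_structure([[0, 0, 0]])
        with pytest.raises(ConfigError):
            metrics.dipole_moment(s)


class TestDeltaCp:
    def test_zero(self):
        assert metrics.delta_cp(0.0, 0.0) == 0.0

    def test_hand_arithmetic(self):
        assert metrics.delta_cp(50.0, 100.0, coeffs=(0.3, -0.1)) == pytest.approx(25.0)

    def test_linearity(self):
        one = metrics.delta_cp(50.0, 100.0)
        two = metrics.delta_cp(100.0, 200.0)
        assert two == pytest.approx(2 * one, rel=1e-12)


# ---------------------------------------------------------------------------
# property matrix
# ---------------------------------------------------------------------------

class TestPropertyMatrix:
    def test_single_state_identical_rows(self, toy_native):
        spec = synth.SyntheticTrajectorySpec(
            n_residues=20, n_frames=5, states=[(1.0, 1.0, 0.0)], seed=1
        )
        traj, _ = synth.simulate_unfolding_trajectory(toy_native, spec)
        pm = metrics.property_matrix(traj)
        assert np.all(pm.values == pm.values[0])

    def test_column_count_and_qsh_componentwise(self, expanding_trajectory,
                                                expanding_property_matrix):
        traj, _ = expanding_trajectory
        pm = expanding_property_matrix
        conf = metrics.PropertyConfig()
        # per_trp expands into one column per tryptophan (residues 10, 20)
        assert len(pm.property_names) == len(set(pm.property_names))
        assert pm.values.shape == (len(traj), len(pm.property_names))
        cs = metrics.native_contacts(traj.frames[0])
        want = [metrics.compute_qsh(f, cs) for f in traj.frames]
        np.testing.assert_allclose(pm.column("Qsh"), want, atol=1e-12)

    def test_monotone_expansion_invariants(self, expanding_trajectory,
                                           expanding_property_matrix):
        """Rg strictly increases, hard Qsh non-increasing, dRMS increases
        across state blocks on the zero-noise expanding trajectory."""
        _, labels = expanding_trajectory
        pm = expanding_property_matrix
        for name, check in (("Rgyr", "inc"), ("dRMS", "inc"), ("Qsh", "dec")):
            col = pm.column(name)
            block_means = [col[labels == s].mean() for s in np.unique(labels)]
            if check == "inc":
                assert np.all(np.diff(block_means) > 0)
            else:
                assert np.all(np.diff(block_means) <= 1e-12)

    def test_missing_ss_errors(self, toy_native):
        frames = [toy_native.with_coords(toy_native.coord) for _ in range(3)]
        for f in frames:
            f.ss = None
        traj = Trajectory(frames=frames, native_pool={0})
        with pytest.raises(ConfigError, match="ss"):
            metrics.property_matrix(traj)
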