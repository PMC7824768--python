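"""Disulfide detection, turn typing, ICK topology, superposition, Q-score,
NOE calibration, restraints, and hydrophobicity profiles."""

import itertools
import math

import numpy as np
import pytest

from venomkit._tables import WHITE_WIMLEY_INTERFACE
from venomkit.simulate import backbone_from_torsions, gen_toy_structure
from venomkit.structure import (AlignmentStats, DisulfideBond, Residue,
                                StructureModel, backbone_dihedrals,
                                classify_ick, classify_turns,
                                detect_disulfides, disulfide_restraints,
                                hydrophobicity_profile, noe_calibrate,
                                q_score, superpose)

#: Disulfide pairing of the flagship toxin, mature numbering.
TBO_PAIRS = [(1, 15), (8, 20), (14, 31), (17, 39), (22, 29)]


def _two_cys_model(distance):
    def res(i, offset):
        atoms = {"N": np.array([0.0, 0, 0]) + offset,
                 "CA": np.array([1.5, 0, 0]) + offset,
                 "C": np.array([2.0, 1.4, 0]) + offset,
                 "O": np.array([2.0, 2.6, 0]) + offset,
                 "SG": np.array([1.5, 0, 1.8]) + offset}
        return Residue(i, "C", atoms)
    return StructureModel((res(1, np.zeros(3)),
                           res(2, np.array([0.0, 0, distance]))))


class TestDetectDisulfides:
    def test_canonical_bond_length_pairs(self):
        bonds = detect_disulfides(_two_cys_model(2.03))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.03)

    def test_distant_sulfurs_no_bond(self):
        assert detect_disulfides(_two_cys_model(5.0)) == []

    def test_flagship_scaffold_pinned_pairs(self, tbo_mature):
        model = gen_toy_structure(tbo_mature, TBO_PAIRS, seed=1)
        bonds = detect_disulfides(model)
        assert [(b.i, b.j) for b in bonds] == TBO_PAIRS

    def test_recovery_across_fifty_seeds(self, tbo_mature):
        """100% precision/recall of pinned pairs over 50 random scaffolds."""
        for seed in range(50):
            model = gen_toy_structure(tbo_mature, TBO_PAIRS, seed=seed)
            bonds = detect_disulfides(model)
            assert [(b.i, b.j) for b in bonds] == TBO_PAIRS

    def test_missing_sg_warns_and_skips(self):
        model = _two_cys_model(2.03)
        stripped = StructureModel((
            model.residues[0],
            Residue(2, "C", {k: v for k, v in model.residues[1].atoms.items()
                             if k != "SG"})))
        with pytest.warns(UserWarning):
            assert detect_disulfides(stripped) == []


class TestTurns:
    def _fragment(self, mid1, mid2):
        flank = (-130.0, 135.0)
        torsions = [flank, flank, mid1, mid2, flank, flank]
        return backbone_from_torsions("AAAAAA", torsions)

    @pytest.mark.parametrize("mid1,mid2,expected", [
        ((-60.0, -30.0), (-90.0, 0.0), "I"),
        ((-60.0, -30.0), (-120.0, 120.0), "VIII"),
        ((60.0, 30.0), (90.0, 0.0), "I'"),
        ((-60.0, 120.0), (80.0, 0.0), "II"),
    ])
    def test_canonical_types(self, mid1, mid2, expected):
        turns = classify_turns(self._fragment(mid1, mid2))
        beta = {interval: t for interval, t in turns
                if t not in ("gamma", "inverse-gamma")}
        assert beta.get((2, 5)) == expected

    def test_off_canonical_compact_window_is_type_iv(self):
        """20 degrees off every canonical type, but CA distance < 7 A."""
        canonical = [(-60.0, -30.0), (-90.0, 0.0)]
        shifted = [(phi + 50.0, psi - 50.0) for phi, psi in canonical]
        model = self._fragment(*shifted)
        ca = [r.atoms["CA"] for r in model.residues]
        turns = dict(classify_turns(model))
        if np.linalg.norm(ca[1] - ca[4]) <= 7.0:
            assert turns.get((2, 5)) == "IV"

    def test_gamma_turn_detected(self):
        model = backbone_from_torsions(
            "AAAAA", [(-130, 135), (-130, 135), (-79.0, 69.0),
                      (-130, 135), (-130, 135)])
        turns = classify_turns(model)
        assert ((2, 4), "inverse-gamma") in turns

    def test_torsion_round_trip(self):
        """The chain builder and the dihedral reader invert each other."""
        torsions = [(-57.0, -47.0), (-120.0, 130.0), (60.0, 30.0),
                    (-90.0, 0.0), (-139.0, 135.0)]
        model = backbone_from_torsions("AAAAA", torsions)
        observed = backbone_dihedrals(model)
        for i in range(1, 4):
            assert observed[i][0] == pytest.approx(torsions[i][0], abs=1e-6)
            assert observed[i][1] == pytest.approx(torsions[i][1], abs=1e-6)


class TestQScore:
    @pytest.mark.parametrize("nres1,nalgn,rmsd,expected", [
        (34, 33, 1.68, 0.63),   # SGTX1
        (42, 38, 2.06, 0.60),   # robustoxin
        (35, 30, 1.43, 0.54),   # gurmarin
        (35, 31, 1.72, 0.53),   # purotoxin-1
        (40, 33, 1.77, 0.52),   # psalmotoxin-1
        (40, 34, 2.52, 0.43),   # ASIP fragment
        (46, 33, 1.92, 0.43),   # AGRP fragment
        (46, 31, 2.24, 0.34),   # Magi3
    ])
    def test_printed_alignment_table_values(self, nres1, nalgn, rmsd, expected):
        """All eight published alignments against the 39-residue toxin."""
        stats = AlignmentStats(nres1, 39, nalgn, rmsd)
        assert round(q_score(stats), 2) == expected

    def test_perfect_self_match(self):
        assert q_score(AlignmentStats(25, 25, 25, 0.0)) == 1.0

    def test_invalid_stats_rejected(self):
        with pytest.raises(ValueError):
            AlignmentStats(10, 10, 11, 1.0)
        with pytest.raises(ValueError):
            AlignmentStats(0, 10, 0, 1.0)


class TestSuperpose:
    def _cloud(self, n=8, seed=0):
        return np.random.default_rng(seed).normal(size=(n, 3)) * 5.0

    def test_identical_sets_zero_rmsd(self):
        a = self._cloud()
        _, _, rmsd = superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_invariance(self):
        from scipy.spatial.transform import Rotation
        a = self._cloud(seed=1)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        b = a @ rot.T + np.array([5.0, -3.0, 11.0])
        matrix, translation, rmsd = superpose(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(b @ matrix.T + translation, a, atol=1e-5)

    def test_single_displaced_atom_rmsd(self):
        """Compare against a brute-force rotation grid on a 4-point toy."""
        from scipy.spatial.transform import Rotation
        a = np.array([[0.0, 0, 0], [4.0, 0, 0], [0.0, 4, 0], [0.0, 0, 4]])
        b = a.copy()
        b[3] += np.array([0.4, -0.2, 0.3])
        _, _, rmsd = superpose(a, b)
        best = np.inf
        grid = np.linspace(-0.2, 0.2, 9)
        ca, cb = a.mean(axis=0), b.mean(axis=0)
        for angles in itertools.product(grid, grid, grid):
            rot = Rotation.from_euler("xyz", angles).as_matrix()
            moved = (b - cb) @ rot.T + ca
            best = min(best, float(np.sqrt(((moved - a) ** 2).sum() / 4)))
        assert rmsd <= best + 1e-6

    def test_collinear_rejected(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError):
            superpose(line, line)


def _bond(i, j):
    return DisulfideBond(i, j, 2.03)


def ick_oracle(bonds, cys_positions):
    """Independent abcabc check: the core three-subset, if any, is the one
    whose rank-ordered six cysteines connect 1-4, 2-5, 3-6."""
    for subset in itertools.combinations(bonds, 3):
        six = sorted({p for b in subset for p in (b.i, b.j)})
        if len(six) != 6:
            continue
        rank = {p: r + 1 for r, p in enumerate(six)}
        conn = {frozenset((rank[b.i], rank[b.j])) for b in subset}
        if conn == {frozenset((1, 4)), frozenset((2, 5)),
                    frozenset((3, 6))}:
            return True
    return False


class TestIck:
    def test_flagship_topology(self, tbo_mature):
        cys = [i + 1 for i, a in enumerate(tbo_mature) if a == "C"]
        bonds = [_bond(*p) for p in TBO_PAIRS]
        result = classify_ick(bonds, cys)
        assert {(b.i, b.j) for b in result["core"]} == \
            {(1, 15), (8, 20), (14, 31)}
        roles = {(b.i, b.j): r for b, r in result["extra_roles"].items()}
        assert roles == {(17, 39): "C-terminal clamp",
                         (22, 29): "hairpin staple"}

    def test_classic_three_bond_knot(self):
        cys = [1, 5, 10, 15, 20, 25]
        bonds = [_bond(1, 15), _bond(5, 20), _bond(10, 25)]
        result = classify_ick(bonds, cys)
        assert result["core"] is not None
        assert result["extra_roles"] == {}

    def test_ladder_is_not_a_knot(self):
        cys = [1, 5, 10, 15, 20, 25]
        bonds = [_bond(1, 5), _bond(10, 15), _bond(20, 25)]
        assert classify_ick(bonds, cys)["core"] is None

    def test_duplicate_cysteine_rejected(self):
        with pytest.raises(ValueError):
            classify_ick([_bond(1, 5), _bond(5, 10)], [1, 5, 10])

    def test_matches_brute_force_oracle_on_random_topologies(self):
        """500 random 4-6-bond pairings: core existence agrees with oracle."""
        rng = np.random.default_rng(99)
        for _ in range(500):
            n_bonds = int(rng.integers(4, 7))
            cys = sorted(rng.choice(np.arange(1, 60), size=2 * n_bonds,
                                    replace=False).tolist())
            order = rng.permutation(2 * n_bonds)
            bonds = [_bond(*sorted((cys[order[2 * k]], cys[order[2 * k + 1]])))
                     for k in range(n_bonds)]
            result = classify_ick(bonds, cys)
            assert (result["core"] is not None) == ick_oracle(bonds, cys)
            if result["core"] is not None:
                assert ick_oracle(result["core"],
                                  sorted(p for b in result["core"]
                                         for p in (b.i, b.j)))


class TestRestraints:
    def test_five_bonds_fifteen_upper_fifteen_lower(self):
        restraints = disulfide_restraints([_bond(*p) for p in TBO_PAIRS])
        assert len(restraints) == 15  # each carries an upper AND a lower
        assert all(r.lower <= r.upper for r in restraints)

    def test_single_bond_three_pairs(self):
        restraints = disulfide_restraints([_bond(1, 5)])
        assert len(restraints) == 3
        kinds = {(r.atom1.split()[0], r.atom2.split()[0]) for r in restraints}
        assert kinds == {("SG", "SG"), ("CB", "SG"), ("SG", "CB")}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            disulfide_restraints([])


class TestNoeCalibration:
    def test_reference_intensity_returns_reference_distance(self):
        assert noe_calibrate(2.0, 2.0, 3.0) == 3.0

    def test_sixty_fourfold_weaker_doubles_distance(self):
        assert noe_calibrate(1.0, 64.0, 2.5) == pytest.approx(5.0)

    def test_monotone_decreasing_in_intensity(self):
        ds = [noe_calibrate(i, 1.0, 3.0) for i in (0.5, 1.0, 2.0, 4.0)]
        assert ds == sorted(ds, reverse=True)

    def test_clipping_window(self):
        assert noe_calibrate(1e9, 1.0, 3.0) == 2.0
        assert noe_calibrate(1e-9, 1.0, 3.0) == 6.0

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            noe_calibrate(0.0, 1.0, 3.0)


class TestHydrophobicity:
    def test_constant_sequence_constant_profile(self):
        profile = hydrophobicity_profile("G" * 11, window=5)
        assert all(v == pytest.approx(WHITE_WIMLEY_INTERFACE["G"])
                   for v in profile)

    def test_reversal_symmetry(self, tbo_mature):
        forward = hydrophobicity_profile(tbo_mature, 5)
        backward = hydrophobicity_profile(tbo_mature[::-1], 5)
        assert forward == pytest.approx(backward[::-1])

    def test_profile_bounded_by_scale_extremes(self, tbo_mature):
        profile = hydrophobicity_profile(tbo_mature, 5)
        most_hydrophobic = min(WHITE_WIMLEY_INTERFACE.values())
        most_hydrophilic = max(WHITE_WIMLEY_INTERFACE.values())
        assert all(most_hydrophobic <= v <= most_hydrophilic
                   for v in profile)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hydrophobicity_profile("GGGG", 2)
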