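import numpy as np
import pytest

from abensemble.core import Atom, Ensemble, StructureModel
from abensemble.interactions import (
    InteractionContext,
    InteractionCriteria,
    MissingHydrogensError,
    count_intramolecular,
    define_interface,
    detect_bridging_waters,
    detect_cation_pi,
    detect_hydrogen_bonds,
    detect_hydrophobic,
    detect_ion_contacts,
    detect_pi_stacking,
    detect_salt_bridges,
    nonsolvent_fraction,
    summarize_trajectory,
)
from abensemble.synthetic import ComplexSpec, build_toy_complex

from conftest import random_interaction_model
from oracles import (
    brute_cation_pi,
    brute_hbonds,
    brute_hydrophobic_residues,
    brute_pi_stack,
    brute_salt,
)

CRIT = InteractionCriteria()


def _structure(spec):
    """spec: list of (chain, resid, resname, name, element, xyz)."""
    atoms, coords = [], []
    roles = {}
    for serial, (chain, resid, resname, name, element, xyz) in enumerate(spec, 1):
        atoms.append(Atom(serial=serial, name=name, element=element,
                          residue_name=resname, residue_id=resid, chain_id=chain))
        coords.append(xyz)
        roles.setdefault(chain, {"F": "heavy", "G": "antigen", "W": "water", "I": "ion"}[chain])
    model = StructureModel(atoms=atoms, roles=roles)
    xyz = np.asarray(coords, dtype=float)
    return model, xyz, InteractionContext.from_model(model, xyz, CRIT)


def _chain_idx(model, chain):
    return np.array([i for i, a in enumerate(model.atoms) if a.chain_id == chain])


class TestInterfaceDefinition:
    @pytest.mark.parametrize(
        "separation,expected", [(4.4, 1), (4.5, 1), (4.6, 0)]
    )
    def test_heavy_atom_cutoff_is_inclusive(self, separation, expected):
        model, xyz, _ = _structure([
            ("F", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("G", 1, "GLY", "CA", "C", (separation, 0, 0)),
        ])
        fv, ag = define_interface(xyz, model, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)
        assert len(fv) == len(ag) == expected

    def test_hydrogens_do_not_define_the_interface(self):
        model, xyz, _ = _structure([
            ("F", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("F", 1, "GLY", "HA", "H", (0, 1.1, 0)),
            ("G", 1, "GLY", "HA", "H", (0, 4.1, 0)),  # H-H only 3.0 A
            ("G", 1, "GLY", "CA", "C", (0, 5.2, 0)),
        ])
        fv, ag = define_interface(xyz, model, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)
        assert not fv and not ag


class TestHydrogenBonds:
    def _nho(self, d_oa, angle_ok=True):
        # N(0,0,0)-H(1,0,0) donor; acceptor placed on the H axis
        return _structure([
            ("F", 1, "GLY", "N", "N", (0, 0, 0)),
            ("F", 1, "GLY", "H", "H", (1, 0, 0)),
            ("G", 1, "GLY", "O", "O", (d_oa, 0, 0)),
        ])

    @pytest.mark.parametrize("d,expected", [(3.4, 1), (3.5, 1), (3.6, 0)])
    def test_distance_threshold_inclusive(self, d, expected):
        model, xyz, ctx = self._nho(d)
        recs = detect_hydrogen_bonds(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)
        assert len(recs) == expected
        if recs:
            assert recs[0].angle == pytest.approx(180.0)

    @pytest.mark.parametrize("angle,expected", [(119.0, 0), (120.0, 1), (180.0, 1)])
    def test_angle_window_closed_at_120(self, angle, expected):
        # acceptor 2.0 A from H, placed so that the D-H-A angle is `angle`
        acc = (1 - 2.0 * np.cos(np.radians(angle)), 2.0 * np.sin(np.radians(angle)), 0.0)
        model, xyz, ctx = _structure([
            ("F", 1, "GLY", "N", "N", (0, 0, 0)),
            ("F", 1, "GLY", "H", "H", (1, 0, 0)),
            ("G", 1, "GLY", "O", "O", acc),
        ])
        recs = detect_hydrogen_bonds(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)
        assert len(recs) == expected

    def test_no_hydrogens_raises_not_silent_zero(self):
        model, xyz, ctx = _structure([
            ("F", 1, "GLY", "N", "N", (0, 0, 0)),
            ("G", 1, "GLY", "O", "O", (3.0, 0, 0)),
        ])
        with pytest.raises(MissingHydrogensError):
            detect_hydrogen_bonds(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)


class TestSaltBridges:
    @pytest.mark.parametrize("d,expected", [(4.5, 1), (4.6, 0)])
    def test_cutoff_inclusive(self, d, expected):
        model, xyz, ctx = _structure([
            ("F", 1, "LYS", "NZ", "N", (0, 0, 0)),
            ("G", 1, "ASP", "OD1", "O", (d, 0, 0)),
        ])
        recs = detect_salt_bridges(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)
        assert len(recs) == expected

    def test_backbone_carbonyl_does_not_qualify(self):
        model, xyz, ctx = _structure([
            ("F", 1, "LYS", "NZ", "N", (0, 0, 0)),
            ("G", 1, "GLY", "O", "O", (3.0, 0, 0)),  # backbone O, not side-chain
        ])
        recs = detect_salt_bridges(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)
        assert recs == []


def _phe_ring(chain, resid, center, normal="z"):
    out = []
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    for k, name in enumerate(names):
        ang = np.radians(60.0 * k)
        if normal == "z":
            offset = 1.4 * np.array([np.cos(ang), np.sin(ang), 0.0])
        else:  # normal along x
            offset = 1.4 * np.array([0.0, np.cos(ang), np.sin(ang)])
        out.append((chain, resid, "PHE", name, "C", tuple(np.asarray(center) + offset)))
    return out


class TestCationPi:
    @pytest.mark.parametrize(
        "height,lateral,expected",
        [
            (5.9, 0.0, 1),     # 5.9 A along the normal, angle 0
            (0.0, 5.0, 0),     # in-plane: angle 90
            (6.1, 0.0, 0),     # beyond the distance cutoff
        ],
    )
    def test_distance_and_angle_windows(self, height, lateral, expected):
        spec = _phe_ring("G", 1, (0, 0, 0)) + [("F", 1, "LYS", "NZ", "N", (lateral, 0, height))]
        model, xyz, ctx = _structure(spec)
        recs = detect_cation_pi(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)
        assert len(recs) == expected

    def test_angle_20_degrees_counts(self):
        r = 5.0
        pos = (r * np.sin(np.radians(20)), 0.0, r * np.cos(np.radians(20)))
        spec = _phe_ring("G", 1, (0, 0, 0)) + [("F", 1, "LYS", "NZ", "N", pos)]
        model, xyz, ctx = _structure(spec)
        recs = detect_cation_pi(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)
        assert len(recs) == 1
        assert recs[0].angle == pytest.approx(20.0, abs=0.5) or recs[0].angle == pytest.approx(160.0, abs=0.5)


class TestPiStacking:
    @pytest.mark.parametrize("d,expected", [(5.9, 1), (6.0, 1), (6.1, 0)])
    def test_centroid_distance_only(self, d, expected):
        spec = _phe_ring("F", 1, (0, 0, 0)) + _phe_ring("G", 1, (0, 0, d))
        model, xyz, ctx = _structure(spec)
        recs = detect_pi_stacking(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)
        assert len(recs) == expected

    def test_perpendicular_rings_still_count(self):
        spec = _phe_ring("F", 1, (0, 0, 0), normal="z") + _phe_ring("G", 1, (0, 0, 5.0), normal="x")
        model, xyz, ctx = _structure(spec)
        recs = detect_pi_stacking(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)
        assert len(recs) == 1


class TestHydrophobic:
    def test_multiplicities_collapse_to_one_residue_pair(self):
        spec = [
            ("F", 1, "LEU", "CD1", "C", (0, 0, 0)),
            ("F", 1, "LEU", "CD2", "C", (1.5, 0, 0)),
            ("G", 1, "LEU", "CD1", "C", (0, 3.8, 0)),
            ("G", 1, "LEU", "CD2", "C", (1.5, 4.2, 0)),
        ]
        model, xyz, ctx = _structure(spec)
        recs = detect_hydrophobic(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT)
        assert len(recs) == 1

    def test_beyond_cutoff_is_nothing(self):
        spec = [
            ("F", 1, "LEU", "CD1", "C", (0, 0, 0)),
            ("G", 1, "LEU", "CD1", "C", (0, 4.6, 0)),
        ]
        model, xyz, ctx = _structure(spec)
        assert detect_hydrophobic(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT) == []


class TestBridgingWaters:
    def _bridge_system(self, with_ag_bond=True):
        spec = [
            ("F", 1, "GLY", "N", "N", (0, 0, 0)),
            ("F", 1, "GLY", "H", "H", (1.0, 0, 0)),
            ("W", 1, "HOH", "O", "O", (2.9, 0, 0)),
            ("W", 1, "HOH", "H1", "H", (3.5, 0.7, 0)),
            ("W", 1, "HOH", "H2", "H", (3.5, -0.7, 0)),
        ]
        if with_ag_bond:
            spec.append(("G", 1, "GLY", "O", "O", (5.0, 2.0, 0)))
        else:
            spec.append(("G", 1, "GLY", "O", "O", (15.0, 0, 0)))
        return _structure(spec)

    def test_water_bonded_to_both_sides_bridges(self):
        model, xyz, ctx = self._bridge_system(True)
        recs, bridging = detect_bridging_waters(
            xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT
        )
        assert bridging == {("W", 1)}
        assert len(recs) == 1  # one antibody-side hydrogen bond

    def test_water_bonded_to_fv_only_is_not_bridging(self):
        model, xyz, ctx = self._bridge_system(False)
        recs, bridging = detect_bridging_waters(
            xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT
        )
        assert not bridging and recs == []

    def test_water_chain_to_antigen_is_not_first_order_bridging(self):
        # W1 bonded to Fv; W2 bonded to W1 and to the antigen: no bridge
        spec = [
            ("F", 1, "GLY", "N", "N", (0, 0, 0)),
            ("F", 1, "GLY", "H", "H", (1.0, 0, 0)),
            ("W", 1, "HOH", "O", "O", (2.9, 0, 0)),
            ("W", 1, "HOH", "H1", "H", (3.66, 0.58, 0)),
            ("W", 1, "HOH", "H2", "H", (2.5, -0.85, 0.3)),
            ("W", 2, "HOH", "O", "O", (5.7, 0.6, 0)),
            ("W", 2, "HOH", "H1", "H", (6.46, 1.18, 0)),
            ("W", 2, "HOH", "H2", "H", (5.3, 1.2, -0.6)),
            ("G", 1, "GLY", "O", "O", (8.5, 1.2, 0)),
        ]
        model, xyz, ctx = _structure(spec)
        recs, bridging = detect_bridging_waters(
            xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "G"), CRIT
        )
        assert bridging == set()
        assert recs == []


class TestIonContacts:
    @pytest.mark.parametrize("d,expected", [(4.4, 1), (4.6, 0)])
    def test_salt_thresholds_apply(self, d, expected):
        model, xyz, ctx = _structure([
            ("F", 1, "ASP", "OD1", "O", (0, 0, 0)),
            ("I", 1, "NA", "NA", "Na", (d, 0, 0)),
        ])
        recs = detect_ion_contacts(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "I"), CRIT)
        assert len(recs) == expected

    def test_carbon_partners_do_not_count(self):
        model, xyz, ctx = _structure([
            ("F", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("I", 1, "NA", "NA", "Na", (3.0, 0, 0)),
        ])
        assert detect_ion_contacts(xyz, model, ctx, _chain_idx(model, "F"), _chain_idx(model, "I"), CRIT) == []


class TestIntramolecular:
    def test_sequence_neighbours_included(self):
        # hydrophobic contact between residues i and i+1 counts
        spec = [
            ("F", 1, "LEU", "CD1", "C", (0, 0, 0)),
            ("F", 2, "LEU", "CD1", "C", (0, 4.0, 0)),
        ]
        model, xyz, ctx = _structure(spec)
        counts = count_intramolecular(xyz, model, ctx, np.arange(2), CRIT)
        assert counts["hydrophobic_residue"] == 1

    def test_matches_brute_force_on_random_fixture(self):
        model, xyz, ctx = random_interaction_model(seed=123)
        sel = _chain_idx(model, "F")
        counts = count_intramolecular(xyz, model, ctx, sel, CRIT)
        sel_set = set(sel.tolist())
        donors = [(d, h) for d, h in ctx.donor_h if d in sel_set]
        acceptors = [a for a in ctx.acceptors if a in sel_set]
        expected_hb = {
            (d, h, a)
            for d, h, a in brute_hbonds(xyz, donors, acceptors)
            if model.residue_key_of(d) != model.residue_key_of(a)
        }
        assert counts["hbond_direct"] == len(expected_hb)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_detectors_match_brute_force(self, seed):
        model, xyz, ctx = random_interaction_model(seed)
        fv = _chain_idx(model, "F")
        ag = _chain_idx(model, "G")
        fv_set, ag_set = set(fv.tolist()), set(ag.tolist())

        got = detect_hydrogen_bonds(xyz, model, ctx, fv, ag, CRIT) if any(
            d in fv_set for d, _ in ctx.donor_h
        ) else []
        want = brute_hbonds(
            xyz,
            [(d, h) for d, h in ctx.donor_h if d in fv_set],
            [a for a in ctx.acceptors if a in ag_set],
        )
        assert {(r.atoms[0], r.atoms[1], r.atoms[2]) for r in got} == want

        got_salt = detect_salt_bridges(xyz, model, ctx, fv, ag, CRIT)
        want_salt = brute_salt(
            xyz,
            [p for p in ctx.positive if p in fv_set],
            [n for n in ctx.negative if n in ag_set],
        ) | {
            (p, n)
            for p, n in brute_salt(
                xyz,
                [p for p in ctx.positive if p in ag_set],
                [n for n in ctx.negative if n in fv_set],
            )
        }
        assert {tuple(r.atoms) for r in got_salt} == want_salt

        rings_ag = [r for key, r in ctx.rings if set(r.tolist()) <= ag_set]
        got_cpi = detect_cation_pi(xyz, model, ctx, fv, ag, CRIT)
        want_cpi = brute_cation_pi(xyz, [c for c in ctx.cations if c in fv_set], rings_ag)
        rings_fv = [r for key, r in ctx.rings if set(r.tolist()) <= fv_set]
        want_cpi |= {
            (c, ri) for c, ri in brute_cation_pi(xyz, [c for c in ctx.cations if c in ag_set], rings_fv)
        }
        assert len(got_cpi) == len(want_cpi)

        got_pi = detect_pi_stacking(xyz, model, ctx, fv, ag, CRIT)
        want_pi = brute_pi_stack(xyz, rings_fv, rings_ag)
        assert len(got_pi) == len(want_pi)

        got_phob = detect_hydrophobic(xyz, model, ctx, fv, ag, CRIT)
        want_phob = brute_hydrophobic_residues(
            xyz,
            [i for i in ctx.hydrophobic if i in fv_set],
            [i for i in ctx.hydrophobic if i in ag_set],
            model.residue_key_of,
        )
        assert {tuple(sorted(r.residues)) for r in got_phob} == want_phob


class TestSummaries:
    def test_static_complex_has_zero_sd_and_planted_means(self, toy_complex):
        from conftest import FULL_PLANTED
        from abensemble.synthetic import PLANTED_KIND_MAP

        summary = summarize_trajectory(toy_complex)
        assert (summary.sds == 0).all()
        for name, kind in PLANTED_KIND_MAP.items():
            assert summary.means[kind] == FULL_PLANTED.get(name, 0)

    def test_fixed_equals_fluctuating_on_static_frame(self, toy_complex):
        model = toy_complex.topology
        first = Ensemble(model, toy_complex.frames[:1])
        ref = define_interface(
            first.frames[0], model,
            model.role_indices("heavy", "light"), model.role_indices("antigen"), CRIT,
        )
        fixed = summarize_trajectory(first, mode="fixed_interface", reference_interface=ref)
        fluct = summarize_trajectory(first, mode="fluctuating_interface")
        # interface-localized kinds agree; the fixed reference restricts
        # detectors to interface residues, which hold every planted contact
        # except those built outside the 4.5 A interface shell
        assert fixed.counts["hbond_direct"].iloc[0] == fluct.counts["hbond_direct"].iloc[0]
        assert fixed.counts["hbond_solvent"].iloc[0] == fluct.counts["hbond_solvent"].iloc[0]

    def test_fixed_mode_requires_reference(self, toy_complex):
        with pytest.raises(ValueError):
            summarize_trajectory(toy_complex, mode="fixed_interface")

    def test_broken_contact_halves_the_mean(self):
        ens = build_toy_complex(ComplexSpec(planted_counts={"hbond": 2}, seed=3, n_frames=4))
        frames = ens.frames.copy()
        model = ens.topology
        # displace the second motif's antigen acceptor far away in frames 2,3
        ag_o = [i for i, a in enumerate(model.atoms)
                if a.chain_id == "A" and a.residue_id == 2 and a.name == "O"][0]
        frames[2:, ag_o, :] += 50.0
        broken = Ensemble(model, frames)
        summary = summarize_trajectory(broken)
        assert summary.means["hbond_direct"] == pytest.approx(2 - 0.5)

    def test_frame_permutation_leaves_mean_sd_invariant(self, small_complex):
        summary = summarize_trajectory(small_complex)
        perm = np.random.default_rng(0).permutation(small_complex.n_frames)
        permuted = Ensemble(small_complex.topology, small_complex.frames[perm])
        summary2 = summarize_trajectory(permuted)
        assert np.allclose(summary.means, summary2.means)
        assert np.allclose(summary.sds, summary2.sds)


class TestNonsolventFraction:
    def test_stated_arithmetic(self):
        import pandas as pd
        from abensemble.interactions import KINDS, InteractionSummary

        row = {k: 0 for k in KINDS}
        row.update(hbond_direct=5, salt_bridge=1, hbond_bridge=4,
                   hydrophobic_residue=6, hbond_solvent=4)
        summary = InteractionSummary(counts=pd.DataFrame([row], columns=list(KINDS)), mode="fluctuating_interface")
        out = nonsolvent_fraction(summary)
        assert out["total_mean_interactions"] == 20
        assert out["nonsolvent_pct"] == pytest.approx(80.0)
        assert out["nonsolvent_nonhydrophobic_pct"] == pytest.approx(50.0)

    @pytest.mark.parametrize("solvent,expected", [(0, 100.0), (7, 0.0)])
    def test_extremes(self, solvent, expected):
        import pandas as pd
        from abensemble.interactions import KINDS, InteractionSummary

        row = {k: 0 for k in KINDS}
        if expected == 100.0:
            row.update(hbond_direct=7)
        row["hbond_solvent"] = solvent
        summary = InteractionSummary(counts=pd.DataFrame([row], columns=list(KINDS)), mode="fluctuating_interface")
        assert nonsolvent_fraction(summary)["nonsolvent_pct"] == pytest.approx(expected)

    def test_hbond_classes_partition_without_double_count(self, toy_complex):
        summary = summarize_trajectory(toy_complex, keep_records=True)
        hb = [r for r in summary.records if r.kind.startswith("hbond")]
        seen = {}
        for r in hb:
            key = (r.frame, tuple(sorted(r.atoms)))
            assert key not in seen, f"{key} classified as both {seen.get(key)} and {r.kind}"
            seen[key] = r.kind
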