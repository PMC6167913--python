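import numpy as np
import pytest

from promab import ensemble_ss as ss
from promab import synthetic_data as sd
from promab.ensemble import read_multimodel_pdb, write_multimodel_pdb
from promab.errors import EnsembleFormatError, InputError


class TestAssignment:
    def test_ideal_helix_has_long_h_run(self):
        ens = sd.build_ideal_backbone("helix", 12)
        states = "".join(ss.assign_secondary_structure(ens)[0])
        assert "H" * 8 in states

    def test_hairpin_strands_are_beta_turn_is_turn(self):
        ens = sd.build_ideal_backbone("hairpin", 16)
        cats = ss.to_categories(ss.assign_secondary_structure(ens))[0]
        # strands flank the 4-residue turn at positions 6..9
        assert (cats[1:6] == "Beta").all()
        assert (cats[10:15] == "Beta").all()
        assert (cats[7:9] == "Turn").all()

    def test_isolated_strand_has_no_beta(self):
        ens = sd.build_ideal_backbone("strand", 12)
        states = ss.assign_secondary_structure(ens)[0]
        assert not np.isin(states, ("E", "B")).any()

    def test_short_chain_is_all_coil(self):
        ens = sd.build_ideal_backbone("helix", 4)
        # truncate roster to 2 residues
        sub = ens.with_coords(ens.coords[:, :8])
        sub.atom_names = ens.atom_names[:8]
        sub.res_index = ens.res_index[:8]
        sub.res_numbers = ens.res_numbers[:2]
        sub.ins_codes = ens.ins_codes[:2]
        sub.res_names = ens.res_names[:2]
        sub.chain_ids = ens.chain_ids[:2]
        assert (ss.assign_secondary_structure(sub) == "C").all()

    def test_termini_never_helix_or_strand(self, small_hairpin_ensemble):
        states = ss.assign_secondary_structure(small_hairpin_ensemble)
        for col in (0, -1):
            assert not np.isin(states[:, col], ("H", "G", "I", "E", "B")).any()

    def test_category_mapping_total(self):
        detailed = np.array([list(ss.DETAILED_STATES)])
        cats = ss.to_categories(detailed)
        assert list(cats[0]) == ["Helix", "Helix", "Helix", "Beta", "Beta",
                                 "Turn", "Turn", "Coil"]


class TestReferenceOracle:
    def test_agreement_with_reference_dssp(self, tmp_path):
        """Category agreement with an independent DSSP implementation on
        ideal single-frame fixtures."""
        import mdtraj as md
        total, agree = 0, 0
        cases = [("helix", n, 0) for n in (10, 16)] + \
                [("hairpin", n, 0) for n in (12, 20)] + \
                [("coil", 14, s) for s in (1, 2)]
        for kind, n, seed in cases:
            ens = sd.build_ideal_backbone(kind, n, seed=seed)
            path = tmp_path / f"{kind}{n}{seed}.pdb"
            write_multimodel_pdb(ens, path)
            ref = md.compute_dssp(md.load(str(path)), simplified=False)[0]
            ref = np.char.replace(ref.astype("U1"), " ", "C")
            mine = ss.assign_secondary_structure(ens)[0]
            mc = ss.to_categories(mine[None])[0][1:-1]
            rc = ss.to_categories(ref[None])[0][1:-1]
            agree += (mc == rc).sum()
            total += len(mc)
        assert agree / total >= 0.9


class TestOccupancy:
    def test_all_helix_assignment_gives_unit_probability(self):
        states = np.full((20, 10), "H")
        occ = ss.occupancy(states, seed=0)
        assert occ.probabilities["Helix"] == 1.0
        assert occ.probabilities["Beta"] == 0.0

    def test_probabilities_sum_to_one(self, small_hairpin_ensemble):
        states = ss.assign_secondary_structure(small_hairpin_ensemble)
        occ = ss.occupancy(states, seed=3)
        assert sum(occ.probabilities.values()) == pytest.approx(1.0,
                                                                abs=1e-9)

    def test_constant_ensemble_zero_width_ci(self):
        states = np.full((50, 8), "E")
        occ = ss.occupancy(states, n_boot=100, seed=1)
        assert occ.ci_low["Beta"] == occ.ci_high["Beta"] == 1.0

    def test_ci_brackets_point_estimate(self, small_hairpin_ensemble):
        states = ss.assign_secondary_structure(small_hairpin_ensemble)
        occ = ss.occupancy(states, seed=5)
        for c in ss.CATEGORIES:
            assert occ.ci_low[c] <= occ.probabilities[c] <= occ.ci_high[c]

    def test_empty_region_rejected(self):
        with pytest.raises(InputError):
            ss.occupancy(np.full((5, 4), "C"), region_residues=[])

    def test_bootstrap_ci_coverage_on_known_binomial(self):
        """95% frame-bootstrap CIs cover a known occupancy probability in
        90-99% of seeded binomial simulations."""
        p_true = 0.3
        rng = np.random.default_rng(42)
        hits = 0
        n_trials = 500
        for t in range(n_trials):
            draws = rng.random((60, 1)) < p_true
            states = np.where(draws, "E", "C")
            occ = ss.occupancy(states, n_boot=100, seed=t)
            hits += occ.ci_low["Beta"] <= p_true <= occ.ci_high["Beta"]
        assert 0.90 <= hits / n_trials <= 0.99


class TestContrast:
    def test_identical_groups_null(self):
        states = np.where(np.random.default_rng(0).random((100, 6)) < 0.4,
                          "E", "C")
        con = ss.contrast_groups([(states, None)], [(states, None)],
                                 n_resamples=2000, seed=0)
        assert con.relative_difference_pct["Beta"] == pytest.approx(0.0)
        assert con.p_values["Beta"] > 0.5

    def test_swap_changes_sign(self):
        rng = np.random.default_rng(1)
        a = np.where(rng.random((200, 6)) < 0.6, "E", "C")
        b = np.where(rng.random((200, 6)) < 0.3, "E", "C")
        fwd = ss.contrast_groups([(a, None)], [(b, None)],
                                 n_resamples=500, seed=0)
        rev = ss.contrast_groups([(b, None)], [(a, None)],
                                 n_resamples=500, seed=0)
        assert fwd.relative_difference_pct["Beta"] > 0
        assert rev.relative_difference_pct["Beta"] < 0

    def test_zero_reference_reported_as_nan(self):
        a = np.full((10, 4), "E")
        b = np.full((10, 4), "C")
        con = ss.contrast_groups([(a, None)], [(b, None)],
                                 n_resamples=100, seed=0)
        assert np.isnan(con.relative_difference_pct["Beta"])

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            ss.contrast_groups([], [(np.full((2, 2), "C"), None)])


class TestPdbRoundTrip:
    def test_ensemble_round_trip(self, small_hairpin_ensemble, tmp_path):
        path = tmp_path / "ens.pdb"
        write_multimodel_pdb(small_hairpin_ensemble, path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == small_hairpin_ensemble.n_frames
        assert np.abs(back.coords
                      - small_hairpin_ensemble.coords).max() < 1e-2
        assert list(back.residue_labels()) == \
            list(small_hairpin_ensemble.residue_labels())

    def test_roster_mismatch_names_model(self, tmp_path):
        ens = sd.build_ideal_backbone("strand", 5)
        two = ens.with_coords(np.repeat(ens.coords, 2, axis=0))
        path = tmp_path / "bad.pdb"
        write_multimodel_pdb(two, path)
        lines = path.read_text().splitlines()
        # drop one ATOM record from MODEL 2
        out, in_model2, dropped = [], False, False
        for ln in lines:
            if ln.startswith("MODEL") and "2" in ln.split():
                in_model2 = True
            if in_model2 and not dropped and ln.startswith("ATOM"):
                dropped = True
                continue
            out.append(ln)
        path.write_text("\n".join(out) + "\n")
        with pytest.raises(EnsembleFormatError, match="2"):
            read_multimodel_pdb(path)

    def test_insertion_codes_survive(self, tmp_path):
        ens = sd.build_ideal_backbone("strand", 5)
        ens.res_numbers = np.array([99, 100, 100, 100, 101])
        ens.ins_codes = np.array(["", "", "A", "B", ""], dtype=object)
        path = tmp_path / "ins.pdb"
        write_multimodel_pdb(ens, path)
        back = read_multimodel_pdb(path)
        assert back.residue_labels() == ["99", "100", "100A", "100B", "101"]
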