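import numpy as np
import pandas as pd
import pytest

import deepdom as dd
from deepdom.alignment import AlignedMatrix
from deepdom.assignment import (DEFAULT_CONTAMINANTS, PROTON_MASS,
                                AssignmentParams, assign_formulas,
                                enumerate_candidates, mass_error_ppm,
                                verify_isotopologue)
from deepdom.formulas import MolecularFormula, exact_mass, parse_formula

from _oracles import brute_force_candidates


def matrix_from_neutral_masses(masses, intensities=None, n_samples=2, sn=1e4):
    """Aligned matrix whose measured m/z are [M-H]- ions of the given
    neutral masses, present in every sample."""
    masses = np.asarray(sorted(masses), float)
    mz = masses - PROTON_MASS
    inten = np.tile(np.asarray(intensities if intensities is not None
                               else np.ones(len(masses)))[:, None], (1, n_samples))
    cols = [f"s{i}" for i in range(n_samples)]
    return AlignedMatrix(
        feature_mz=mz,
        intensities=pd.DataFrame(inten, columns=cols),
        sn=pd.DataFrame(np.full_like(inten, sn), columns=cols),
        tol_ppm=0.5)


class TestEnumerate:
    def test_round_trip_contains_origin(self):
        f = parse_formula("C16H32O2")
        cands = enumerate_candidates(exact_mass(f))
        assert f in cands
        assert cands[0] == f  # zero error sorts first

    def test_methane_unique(self):
        cands = enumerate_candidates(16.0313001283)
        assert cands == [parse_formula("CH4")]

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates(-5.0)

    def test_above_range_rejected(self):
        with pytest.raises(ValueError, match="above assignment range"):
            enumerate_candidates(1200.0)

    def test_all_candidates_within_tolerance(self):
        for mass in (256.2402, 413.1213, 500.0):
            for f in enumerate_candidates(mass):
                assert abs(mass_error_ppm(f, mass)) <= 0.5

    @pytest.mark.parametrize("mass", [180.0634, 256.2402, 342.1162, 471.2008])
    def test_equals_brute_force_grid(self, mass):
        fast = enumerate_candidates(mass)
        slow = brute_force_candidates(mass)
        assert fast == slow


class TestIsotopologue:
    def _matrix_with_companion(self, f, ratio_scale=1.0):
        parent = exact_mass(f)
        companion = parent + 1.0033548378
        inten = np.array([[100.0, 100.0],
                          [100 * 0.0107 * f.c * ratio_scale] * 2])
        mz = np.array([parent, companion]) - PROTON_MASS
        return AlignedMatrix(
            feature_mz=mz,
            intensities=pd.DataFrame(inten, columns=["s0", "s1"]),
            sn=pd.DataFrame(inten * 10, columns=["s0", "s1"]),
            tol_ppm=0.5)

    def test_good_companion_passes(self):
        f = parse_formula("C20H22O10")
        m = self._matrix_with_companion(f)
        ok, ev = verify_isotopologue(m, 0, f)
        assert ok and ev["13C"]["found"]
        assert ev["13C"]["ratio"] == pytest.approx(0.214)

    def test_gross_mismatch_fails(self):
        f = parse_formula("C20H22O10")
        m = self._matrix_with_companion(f, ratio_scale=10.0)
        ok, _ = verify_isotopologue(m, 0, f)
        assert not ok

    def test_weak_parent_without_companion_passes(self):
        f = parse_formula("C10H12O5")
        parent = exact_mass(f)
        m = AlignedMatrix(
            feature_mz=np.array([parent - PROTON_MASS]),
            intensities=pd.DataFrame([[5.0, 5.0]], columns=["s0", "s1"]),
            sn=pd.DataFrame([[4.0, 4.0]], columns=["s0", "s1"]),
            tol_ppm=0.5)
        # expected companion S/N = 4 x 0.107 << mdl -> insufficient evidence
        ok, ev = verify_isotopologue(m, 0, f)
        assert ok and not ev["13C"]["found"]


class TestAssign:
    def test_contaminant_feature_removed(self):
        cont = parse_formula("C16H32O2")
        clean = parse_formula("C15H22O7")
        m = matrix_from_neutral_masses([exact_mass(cont), exact_mass(clean)])
        out = assign_formulas(m)
        assert out.filter_log["contaminant_features_removed"] == 1
        assert set(out.features["formula"]) == {str(clean)}

    def test_heteroelement_rule(self):
        params = AssignmentParams()
        from deepdom.assignment import _passes_heteroelement_rule
        assert not _passes_heteroelement_rule(
            MolecularFormula(c=10, h=20, n=2, s=2, p=1, o=2), params)
        assert _passes_heteroelement_rule(
            MolecularFormula(c=10, h=12, n=4, o=10), params)  # N4 exception
        assert _passes_heteroelement_rule(
            MolecularFormula(c=10, h=20, n=1, s=1, p=1, o=2), params)

    def test_assignment_errors_within_tolerance(self, annotated_noisefree):
        ann = annotated_noisefree
        errs = ann.features.loc[ann.annotated.to_numpy(), "error_ppm"]
        assert (errs.abs() <= 0.5 + 1e-9).all()

    def test_noisefree_roundtrip_recovers_unique_candidates(
            self, annotated_noisefree, noisefree_dataset):
        """Features whose neutral mass admits exactly one in-tolerance
        candidate must recover the generating formula (>= 99 %)."""
        _, _, truth = noisefree_dataset
        truth_formulas = {str(f): f for f in map(parse_formula, truth.index)}
        ann = annotated_noisefree
        hits = misses = 0
        for _, row in ann.features.iterrows():
            if row["neutral_mass"] > 1000:
                continue
            cands = enumerate_candidates(row["neutral_mass"])
            if len(cands) != 1:
                continue
            expect = str(cands[0])
            if expect not in truth_formulas:
                continue  # an isotopologue or contaminant remnant
            if row["formula"] == expect:
                hits += 1
            else:
                misses += 1
        assert hits > 50
        assert hits / (hits + misses) >= 0.99

    def test_isotopologue_companions_dropped(self, annotated_noisefree,
                                             noisefree_dataset):
        _, _, truth = noisefree_dataset
        ann = annotated_noisefree
        assert ann.filter_log["isotopologue_features_removed"] > 100
        # no surviving feature sits exactly one 13C shift above another
        mz = np.sort(ann.features["mz"].to_numpy())
        diffs = mz[:, None] - mz[None, :] - 1.0033548378
        assert not (np.abs(diffs) < 1e-4).any()

    def test_empty_matrix_rejected(self):
        m = AlignedMatrix(feature_mz=np.array([]),
                          intensities=pd.DataFrame(columns=["a"]),
                          sn=pd.DataFrame(columns=["a"]), tol_ppm=0.5)
        with pytest.raises(ValueError):
            assign_formulas(m)


class TestOracleEquivalence:
    def test_assignment_matches_brute_force(self):
        """Optimized assignment equals exhaustive enumeration + identical
        rules on synthetic masses (no isotopologue evidence present)."""
        lib = sorted(dd.generate_formula_library(3, seed=77))
        raw = sorted({exact_mass(f) for f in lib if exact_mass(f) <= 600})
        masses = []
        for m_ in raw:  # keep masses > 2 ppm apart so features stay distinct
            if not masses or (m_ - masses[-1]) / masses[-1] * 1e6 > 2.0:
                masses.append(m_)
        masses = masses[:20]
        m = matrix_from_neutral_masses(masses)
        out = assign_formulas(m, AssignmentParams(contaminants=frozenset()))
        got = dict(zip(np.round(out.features["neutral_mass"], 6),
                       out.features["formula"]))
        from _oracles import brute_force_heteroelement_rule
        for mass in masses:
            cands = [f for f in brute_force_candidates(mass)
                     if brute_force_heteroelement_rule(f)]
            expect = str(cands[0]) if cands else ""
            assert got[round(mass, 6)] == expect
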