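import numpy as np
import pandas as pd
import pytest

import deepdom as dd
from deepdom.formulas import class_region, exact_mass
from deepdom.synthetic import (EndmemberSpec, HYDROCHEM_VARS,
                               generate_asv_table, generate_formula_library,
                               generate_sample_peaklists,
                               make_planted_modules)


class TestFormulaLibrary:
    def test_empty_request(self):
        assert generate_formula_library(0, seed=1) == set()

    def test_lignin_request_in_region(self):
        lib = generate_formula_library({"lignin_like": 5}, seed=2)
        assert len(lib) == 5
        region = class_region("lignin_like")
        for f in lib:
            assert region(f.oc, f.hc)
            assert f.is_valid()

    def test_determinism(self):
        assert generate_formula_library(4, seed=9) == generate_formula_library(4, seed=9)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown compound classes"):
            generate_formula_library({"banana": 1}, seed=0)

    def test_all_classes_populated_and_valid(self):
        lib = generate_formula_library(3, seed=5)
        assert len(lib) == 21
        for f in lib:
            assert f.is_valid()
            assert f.dbe == int(f.dbe) >= 0


class TestPeaklists:
    def test_noise_free_limit_exact(self, endmembers):
        pls, chem, truth = generate_sample_peaklists(
            endmembers, [0.5], mass_error_ppm=0.0, noise_cv=0.0,
            contaminants=frozenset(), add_isotopologues=False, seed=1,
            ion_mode="neutral", chem_noise_cv=0.0)
        em_a, em_b = endmembers
        wa = dict(zip(map(str, em_a.formula_pool), em_a.intensity_profile))
        wb = dict(zip(map(str, em_b.formula_pool), em_b.intensity_profile))
        # every observed m/z is exactly a formula mass and every intensity
        # exactly the 50:50 profile mixture
        by_mass = {round(exact_mass(f), 9): str(f)
                   for f in set(em_a.formula_pool) | set(em_b.formula_pool)}
        obs = pls[0].peaks
        total = obs["intensity"].sum()
        for mz, inten in zip(obs["mz"], obs["intensity"]):
            fstr = by_mass[round(mz, 9)]
            expect = 0.5 * wa.get(fstr, 0) + 0.5 * wb.get(fstr, 0)
            assert inten / total == pytest.approx(expect, rel=1e-9)
            assert truth.loc[fstr, "S01"] == pytest.approx(expect, rel=1e-9)

    def test_endmember_purity(self, endmembers):
        pls, _, _ = generate_sample_peaklists(
            endmembers, [1.0, 0.0], mass_error_ppm=0.0, noise_cv=0.0,
            contaminants=frozenset(), add_isotopologues=False, seed=2,
            ion_mode="neutral")
        em_a, em_b = endmembers
        masses_a = {round(exact_mass(f), 9) for f in em_a.formula_pool}
        masses_b = {round(exact_mass(f), 9) for f in em_b.formula_pool}
        assert {round(m, 9) for m in pls[0].peaks["mz"]} == masses_a
        assert {round(m, 9) for m in pls[1].peaks["mz"]} == masses_b

    def test_shared_core_in_every_sample(self, endmembers):
        em_a, em_b = endmembers
        shared = set(em_a.formula_pool) & set(em_b.formula_pool)
        assert len(shared) > 50
        pls, _, truth = generate_sample_peaklists(
            endmembers, np.linspace(1, 0, 5), seed=3)
        for f in list(shared)[:20]:
            assert (truth.loc[str(f)] > 0).all()

    def test_mass_error_bounded(self, endmembers):
        pls, _, _ = generate_sample_peaklists(
            endmembers, [0.5], mass_error_ppm=0.2, noise_cv=0.0,
            contaminants=frozenset(), add_isotopologues=False, seed=4,
            ion_mode="neutral")
        pool = set(endmembers[0].formula_pool) | set(endmembers[1].formula_pool)
        true_masses = np.sort([exact_mass(f) for f in pool])
        for mz in pls[0].peaks["mz"]:
            nearest = true_masses[np.argmin(np.abs(true_masses - mz))]
            assert abs(mz - nearest) / nearest * 1e6 <= 3 * 0.2 + 1e-9

    def test_isotopologue_companion_ratio(self, endmembers):
        pls, _, _ = generate_sample_peaklists(
            endmembers, [1.0], mass_error_ppm=0.0, noise_cv=0.0,
            contaminants=frozenset(), add_isotopologues=True, seed=5,
            ion_mode="neutral")
        peaks = pls[0].peaks
        f = endmembers[0].formula_pool[0]
        parent_mz = exact_mass(f)
        parent = peaks.loc[np.isclose(peaks["mz"], parent_mz, atol=1e-6)]
        comp = peaks.loc[np.isclose(peaks["mz"], parent_mz + 1.0033548378, atol=1e-6)]
        assert len(parent) == 1 and len(comp) == 1
        ratio = comp["intensity"].iloc[0] / parent["intensity"].iloc[0]
        assert ratio == pytest.approx(0.0107 * f.c, rel=1e-9)

    def test_mz_strictly_increasing(self, noisy_dataset):
        for pl in noisy_dataset[0]:
            assert (np.diff(pl.peaks["mz"]) > 0).all()

    def test_chemistry_affine_in_fraction(self, endmembers):
        fr = np.linspace(1, 0, 7)
        _, chem, _ = generate_sample_peaklists(
            endmembers, fr, seed=6, chem_noise_cv=0.0)
        em_a, em_b = endmembers
        for v in HYDROCHEM_VARS:
            expect = fr * em_a.chem_profile[v] + (1 - fr) * em_b.chem_profile[v]
            np.testing.assert_allclose(chem[v], expect, rtol=1e-9)

    def test_invalid_fraction_rejected(self, endmembers):
        with pytest.raises(ValueError):
            generate_sample_peaklists(endmembers, [1.5], seed=0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty formula pool"):
            EndmemberSpec(name="x", formula_pool=(), intensity_profile=np.array([]),
                          chem_profile={v: 0.0 for v in HYDROCHEM_VARS}, doc_mgL=1.0)


class TestAsvTable:
    def test_shape_and_closure(self):
        table, _ = generate_asv_table(25, 8, seed=1)
        num = table.drop(columns="taxonomy")
        assert num.shape == (25, 8)
        np.testing.assert_allclose(num.sum(axis=0), 1.0, atol=1e-12)
        assert table["taxonomy"].str.count(";").eq(6).all()  # 7 ranks

    def test_proportional_members_at_zero_noise(self):
        planted = make_planted_modules(n_modules=2, latent_strength=3.0)
        table, truth = generate_asv_table(10, 12, planted, seed=2, noise_sd=0.0)
        num = table.drop(columns="taxonomy")
        a1, a2 = planted[0].asv_members[:2]
        from deepdom.network import clr_transform
        g = clr_transform(num)
        diff = g.values.loc[a1] - g.values.loc[a2]
        assert np.allclose(diff, diff.iloc[0])  # constant shift -> rho = 1

    def test_no_signal_null_recovery_at_chance(self):
        """With latent_strength = 0 the planted links carry no signal: the
        strongest cross-block rho is no larger than background."""
        planted = make_planted_modules(n_modules=2, latent_strength=0.0,
                                       asv_per_module=2, mf_per_module=3)
        hits = 0
        for seed in range(8):
            table, truth = generate_asv_table(10, 12, planted, seed=seed,
                                              noise_sd=0.5)
            num = table.drop(columns="taxonomy")
            from deepdom.network import clr_transform, proportionality_rho, stack_blocks
            combined = stack_blocks(clr_transform(truth["mf_intensities"], "MF"),
                                    clr_transform(num, "ASV"))
            rho = proportionality_rho(combined)
            cross = rho.loc[truth["mf_intensities"].index, num.index]
            link_rho = np.mean([abs(cross.loc[m, a]) for m, a in truth["links"]])
            other = cross.abs().to_numpy().mean()
            hits += link_rho > other
        # planted links indistinguishable from background about half the time
        assert 1 <= hits <= 7

    def test_unknown_member_rejected(self):
        from deepdom.synthetic import PlantedAssociation
        bad = PlantedAssociation(module_id=0, mf_members=("MF0001",),
                                 asv_members=("ASV999",))
        with pytest.raises(ValueError, match="ASV999"):
            generate_asv_table(5, 6, [bad], seed=0)

    def test_overlapping_modules_rejected(self):
        from deepdom.synthetic import PlantedAssociation
        mods = [PlantedAssociation(0, ("MF0001",), ("ASV001",)),
                PlantedAssociation(1, ("MF0002",), ("ASV001",))]
        with pytest.raises(ValueError, match="more than one module"):
            generate_asv_table(5, 6, mods, seed=0)

    def test_default_scale_matches_study(self):
        table, _ = generate_asv_table(229, 10, seed=3)
        assert table.drop(columns="taxonomy").shape == (229, 10)
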