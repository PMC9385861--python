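import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import deepdom as dd

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def endmembers():
    return dd.default_endmembers(seed=11)


@pytest.fixture(scope="session")
def noisefree_dataset(endmembers):
    """Noise-free 6-sample transect: peak lists, chemistry, truth."""
    return dd.generate_sample_peaklists(
        endmembers, np.linspace(1.0, 0.0, 6), mass_error_ppm=0.0,
        noise_cv=0.0, seed=21)


@pytest.fixture(scope="session")
def noisy_dataset(endmembers):
    return dd.generate_sample_peaklists(
        endmembers, np.linspace(1.0, 0.0, 10), mass_error_ppm=0.15,
        noise_cv=0.1, seed=22)


@pytest.fixture(scope="session")
def annotated_noisefree(noisefree_dataset):
    peaklists, _, _ = noisefree_dataset
    aligned = dd.remove_singletons(dd.join_mass_lists(peaklists, tol_ppm=0.5))
    return dd.assign_formulas(aligned)


@pytest.fixture()
def small_annotated():
    """Tiny hand-built annotated matrix with known descriptor values."""
    formulas = ["C10H10O5", "C10H20O5", "C20H10O2", "C6H12O6"]
    rows = []
    for fstr in formulas:
        f = dd.parse_formula(fstr)
        rows.append({
            "mz": f.mass - 1.00727646, "neutral_mass": f.mass, "formula": fstr,
            "error_ppm": 0.0, "c": f.c, "h": f.h, "n": f.n, "o": f.o, "s": f.s,
            "p": f.p, "dbe": f.dbe, "hc": f.hc, "oc": f.oc, "nc": f.nc,
            "sc": f.sc, "pc": f.pc, "ai_mod": dd.ai_mod(f),
            "compound_class": dd.compound_class(f), "isotope_verified": True})
    features = pd.DataFrame(rows)
    intensities = pd.DataFrame(
        {"A": [0.4, 0.4, 0.1, 0.1], "B": [0.25, 0.25, 0.25, 0.25]})
    return dd.AnnotatedMatrix(features=features, intensities=intensities,
                              normalized=True)
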