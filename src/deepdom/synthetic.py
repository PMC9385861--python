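"""Synthetic data with known ground truth.

Emulates the study design of a brackish-sea-to-saline deep-groundwater
transect: two endmember DOM pools (a Baltic-like surface pool and an old
saline pool) sharing a dominant terrigenous lignin-like core, mixed along
a per-sample fraction; mass-measurement error at the sub-ppm level;
ubiquitous contaminant peaks; 13C isotopologue companions; hydrochemistry
affine in the mixing fraction; and ASV tables with planted MF-ASV
association modules driven by shared latent factors, so that network
recovery can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import PeakList
from .assignment import DEFAULT_CONTAMINANTS, PROTON_MASS, ISOTOPE_MASS_SHIFT, ISOTOPE_ABUNDANCE_RATIO
from .formulas import COMPOUND_CLASSES, MolecularFormula, class_region, exact_mass

__all__ = [
    "EndmemberSpec",
    "PlantedAssociation",
    "generate_formula_library",
    "default_endmembers",
    "generate_sample_peaklists",
    "make_planted_modules",
    "generate_asv_table",
    "HYDROCHEM_VARS",
]

#: The eight hydrochemistry variables carried with every synthetic sample.
HYDROCHEM_VARS = ("Na", "K", "Ca", "Mg", "d18O", "d2H", "SO4", "Cl")


@dataclass
class EndmemberSpec:
    """One water-source endmember: a formula pool with relative
    intensities, a hydrochemical signature, and a DOC concentration."""

    name: str
    formula_pool: tuple
    intensity_profile: np.ndarray  # per formula, >= 0, sums to 1
    chem_profile: dict
    doc_mgL: float

    def __post_init__(self) -> None:
        self.intensity_profile = np.asarray(self.intensity_profile, float)
        if len(self.formula_pool) == 0:
            raise ValueError(f"endmember {self.name!r}: empty formula pool")
        if len(self.intensity_profile) != len(self.formula_pool):
            raise ValueError(f"endmember {self.name!r}: profile/pool length mismatch")
        if (self.intensity_profile < 0).any():
            raise ValueError(f"endmember {self.name!r}: negative intensity weight")
        if abs(self.intensity_profile.sum() - 1.0) > 1e-9:
            raise ValueError(f"endmember {self.name!r}: intensity profile must sum to 1")
        missing = set(HYDROCHEM_VARS) - set(self.chem_profile)
        if missing:
            raise ValueError(f"endmember {self.name!r}: missing chemistry {sorted(missing)}")


@dataclass
class PlantedAssociation:
    """Ground-truth association module: MF and ASV members share a latent
    log-scale factor of the given strength."""

    module_id: int
    mf_members: tuple
    asv_members: tuple
    latent_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.latent_strength < 0:
            raise ValueError("latent_strength must be >= 0")
        self.mf_members = tuple(self.mf_members)
        self.asv_members = tuple(self.asv_members)


def _sample_formula_in_class(rng: np.random.Generator, cls: str,
                             heteroatoms: bool, max_tries: int = 5000) -> MolecularFormula:
    region = class_region(cls)
    eps = 1e-6
    for _ in range(max_tries):
        c = int(rng.integers(10, 36))
        # draw a target point inside the region, then round to integers
        oc = float(rng.uniform(0.0 + eps, min(1.2, (c + 2) / c)))
        hc = float(rng.uniform(0.3, 2.5))
        if not region(oc, hc):
            continue
        o = int(round(oc * c))
        h = int(round(hc * c))
        n = int(rng.choice([0, 0, 0, 1, 2])) if heteroatoms else 0
        s = int(rng.random() < 0.15) if heteroatoms else 0
        p = int(rng.random() < 0.05) if heteroatoms else 0
        if (h + n + p) % 2 == 1:
            h += 1  # enforce integer DBE
        if h < 1 or h > 100 or o > min(70, c + 2):
            continue
        f = MolecularFormula(c=c, h=h, n=n, o=o, s=s, p=p)
        if not f.is_valid():
            continue
        if not region(f.oc, f.hc):
            continue
        if not 92 < f.mass < 1000:
            continue
        return f
    raise ValueError(f"no valid formula found in compound-class region {cls!r}")


def generate_formula_library(n_per_class, seed: int,
                             heteroatoms: bool = True) -> set:
    """Deterministically sample chemically valid formulas per van Krevelen
    class region.

    ``n_per_class`` is an int (same count for every class) or a mapping
    class name -> count. Every returned formula is valid under the
    assignment bounds and its (O/C, H/C) lies in the requested region.
    """
    if isinstance(n_per_class, int):
        counts = {cls: n_per_class for cls in COMPOUND_CLASSES}
    else:
        unknown = set(n_per_class) - set(COMPOUND_CLASSES)
        if unknown:
            raise ValueError(f"unknown compound classes {sorted(unknown)}")
        counts = dict(n_per_class)
    rng = np.random.default_rng(seed)
    library: set = set()
    for cls in COMPOUND_CLASSES:  # fixed order for determinism
        want = counts.get(cls, 0)
        if want < 0:
            raise ValueError("counts must be >= 0")
        got: set = set()
        tries = 0
        while len(got) < want:
            f = _sample_formula_in_class(rng, cls, heteroatoms)
            if f not in library:
                got.add(f)
            tries += 1
            if tries > 200 * max(want, 1):
                raise ValueError(f"cannot draw {want} distinct formulas in class {cls!r}")
        library |= got
    return library


def default_endmembers(seed: int = 0) -> tuple[EndmemberSpec, EndmemberSpec]:
    """The two default endmembers of the mixing transect.

    Both share a dominant terrigenous lignin-like core; the Baltic-like
    pool adds tannin-like and condensed-aromatic formulas, the saline pool
    adds aliphatic (high H/C) and S-containing formulas and carries an
    order of magnitude less DOC.
    """
    rng_seed = int(seed)
    core = sorted(generate_formula_library(
        {"lignin_like": 120, "unsaturated": 30, "tannin_like": 15}, seed=rng_seed))
    baltic_extra = sorted(generate_formula_library(
        {"tannin_like": 35, "condensed_aromatic": 20, "carbohydrate_like": 10},
        seed=rng_seed + 1))
    saline_extra = sorted(generate_formula_library(
        {"unsaturated_o_poor": 25, "unsaturated_hydrocarbon": 20, "unsaturated": 15},
        seed=rng_seed + 2))

    rng = np.random.default_rng(rng_seed + 3)

    def profile(pool):
        w = rng.lognormal(mean=0.0, sigma=1.0, size=len(pool))
        return w / w.sum()

    baltic_pool = tuple(core + [f for f in baltic_extra if f not in core])
    saline_pool = tuple(core + [f for f in saline_extra if f not in core])
    baltic = EndmemberSpec(
        name="baltic",
        formula_pool=baltic_pool,
        intensity_profile=profile(baltic_pool),
        chem_profile={"Na": 1700.0, "K": 60.0, "Ca": 95.0, "Mg": 220.0,
                      "d18O": -6.5, "d2H": -55.0, "SO4": 480.0, "Cl": 3500.0},
        doc_mgL=5.4,
    )
    saline = EndmemberSpec(
        name="saline",
        formula_pool=saline_pool,
        intensity_profile=profile(saline_pool),
        chem_profile={"Na": 7000.0, "K": 9.0, "Ca": 5200.0, "Mg": 31.0,
                      "d18O": -10.5, "d2H": -82.0, "SO4": 600.0, "Cl": 14500.0},
        doc_mgL=0.9,
    )
    return baltic, saline


def generate_sample_peaklists(endmembers: tuple[EndmemberSpec, EndmemberSpec],
                              mixing_fractions,
                              mass_error_ppm: float = 0.15,
                              noise_cv: float = 0.2,
                              contaminants: frozenset = DEFAULT_CONTAMINANTS,
                              add_isotopologues: bool = True,
                              seed: int = 0,
                              ion_mode: str = "negative",
                              chem_noise_cv: float = 0.02,
                              intensity_scale: float = 1e8,
                              contaminant_weight: float = 0.01,
                              ) -> tuple[list[PeakList], pd.DataFrame, pd.DataFrame]:
    """Simulate per-sample peak lists along the two-endmember transect.

    Sample i mixes the endmember profiles at fraction f_i (1 = pure first
    endmember). Intensities get multiplicative lognormal noise of
    coefficient of variation ``noise_cv``; m/z values get Gaussian ppm
    error of sd ``mass_error_ppm`` truncated at 3 sd; contaminant formulas
    are spiked into every sample; 13C isotopologue companions are added at
    0.0107 x C x parent intensity. Hydrochemistry (and DOC) is affine in
    the mixing fraction plus relative noise ``chem_noise_cv``.

    Returns (peak lists, chemistry table, truth): truth is the noise-free
    relative intensity of every endmember formula per sample (rows keyed
    by formula string, columns by sample id, each column summing to 1).
    """
    em_a, em_b = endmembers
    fractions = np.asarray(mixing_fractions, float)
    if ((fractions < 0) | (fractions > 1)).any():
        raise ValueError("mixing fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:02d}" for i in range(len(fractions))]

    pool = sorted(set(em_a.formula_pool) | set(em_b.formula_pool))
    wa = dict(zip(em_a.formula_pool, em_a.intensity_profile))
    wb = dict(zip(em_b.formula_pool, em_b.intensity_profile))
    a = np.array([wa.get(f, 0.0) for f in pool])
    b = np.array([wb.get(f, 0.0) for f in pool])
    masses = np.array([exact_mass(f) for f in pool])
    carbons = np.array([f.c for f in pool])

    sigma = np.sqrt(np.log1p(noise_cv ** 2)) if noise_cv > 0 else 0.0
    ion_shift = -PROTON_MASS if ion_mode == "negative" else 0.0
    shift_13c = ISOTOPE_MASS_SHIFT["13C"]
    rate_13c = ISOTOPE_ABUNDANCE_RATIO["13C"]

    truth = np.zeros((len(pool), len(fractions)))
    peaklists: list[PeakList] = []
    chem_rows = []
    cont = sorted(contaminants) if contaminants else []
    cont_masses = np.array([exact_mass(f) for f in cont])
    cont_carbons = np.array([f.c for f in cont])

    for j, (sid, f) in enumerate(zip(sample_ids, fractions)):
        base = f * a + (1 - f) * b
        total = base.sum()
        if total <= 0:
            raise ValueError(f"sample {sid}: mixture has zero intensity")
        truth[:, j] = base / total

        present = base > 0
        inten = base[present] * intensity_scale
        if sigma > 0:
            inten = inten * rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=len(inten))
        mz_true = masses[present] + ion_shift
        mz_list = [mz_true]
        int_list = [inten]
        if add_isotopologues:
            iso_int = inten * rate_13c * carbons[present]
            if sigma > 0:
                iso_int = iso_int * rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                                                  size=len(iso_int))
            mz_list.append(mz_true + shift_13c)
            int_list.append(iso_int)
        if cont:
            c_int = np.full(len(cont), contaminant_weight * inten.sum() / max(len(cont), 1))
            if sigma > 0:
                c_int = c_int * rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=len(c_int))
            mz_list.append(cont_masses + ion_shift)
            int_list.append(c_int)
            if add_isotopologues:
                mz_list.append(cont_masses + ion_shift + shift_13c)
                int_list.append(c_int * rate_13c * cont_carbons)

        mz = np.concatenate(mz_list)
        ints = np.concatenate(int_list)
        if mass_error_ppm > 0:
            err = rng.normal(0.0, mass_error_ppm, size=len(mz))
            err = np.clip(err, -3 * mass_error_ppm, 3 * mass_error_ppm)
            mz = mz * (1 + err * 1e-6)
        noise_floor = ints[ints > 0].min() / 10.0
        sn = ints / noise_floor
        df = pd.DataFrame({"mz": mz, "intensity": ints, "sn": sn})
        peaklists.append(PeakList(sample_id=sid, peaks=df))

        chem = {v: f * em_a.chem_profile[v] + (1 - f) * em_b.chem_profile[v]
                for v in HYDROCHEM_VARS}
        chem["DOC"] = f * em_a.doc_mgL + (1 - f) * em_b.doc_mgL
        if chem_noise_cv > 0:
            for v in chem:
                chem[v] = chem[v] + rng.normal(0.0, chem_noise_cv * abs(chem[v]))
        chem["mixing_fraction"] = f
        chem_rows.append(pd.Series(chem, name=sid))

    chem_table = pd.DataFrame(chem_rows)
    chem_table.index.name = "sample"
    truth_df = pd.DataFrame(truth, index=[str(f) for f in pool], columns=sample_ids)
    return peaklists, chem_table, truth_df


_TAXON_POOL = (
    "Patescibacteria;Paceibacteria", "Patescibacteria;ABY1",
    "Patescibacteria;Gracilibacteria", "Proteobacteria;Gammaproteobacteria",
    "Proteobacteria;Alphaproteobacteria", "Campylobacterota;Campylobacteria",
    "Desulfobacterota;Desulfobacteria", "Desulfobacterota;Desulfobulbia",
    "Chloroflexota;Anaerolineae", "Unclassified;Unclassified",
)


def _taxonomy_string(rng: np.random.Generator, i: int) -> str:
    phylum, cls = _TAXON_POOL[int(rng.integers(len(_TAXON_POOL)))].split(";")
    return (f"d__Bacteria;p__{phylum};c__{cls};o__o{i % 17};"
            f"f__f{i % 11};g__g{i % 7};s__")


def make_planted_modules(n_modules: int = 10, asv_per_module: int = 3,
                         mf_per_module: int = 8,
                         latent_strength: float = 2.0) -> list[PlantedAssociation]:
    """Disjoint planted modules with systematic member ids (ASV001...,
    MF0001...)."""
    planted = []
    ai = mi = 0
    for m in range(n_modules):
        asvs = tuple(f"ASV{ai + k + 1:03d}" for k in range(asv_per_module))
        mfs = tuple(f"MF{mi + k + 1:04d}" for k in range(mf_per_module))
        ai += asv_per_module
        mi += mf_per_module
        planted.append(PlantedAssociation(module_id=m, mf_members=mfs,
                                          asv_members=asvs,
                                          latent_strength=latent_strength))
    return planted


def generate_asv_table(n_asvs: int, n_samples: int,
                       planted: list[PlantedAssociation] | None = None,
                       seed: int = 0, noise_sd: float = 0.0,
                       base_sd: float = 0.8,
                       sample_ids: list[str] | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """ASV relative-abundance table with planted MF-ASV modules.

    Members of a planted module (both its ASVs and its MFs) share a
    standard-normal latent factor across samples scaled by
    ``latent_strength``, plus independent Gaussian measurement noise of sd
    ``noise_sd`` on the log scale; non-member ASVs vary independently with
    log-sd ``base_sd``. Columns are renormalized to relative abundance.

    Returns (table, truth). The table has one row per ASV, sample columns
    and a final 7-rank ``taxonomy`` column. ``truth`` carries the planted
    links, per-module latent factors, and a positive MF intensity block
    (rows = all planted MF members) sharing the same latents, for stacking
    with background MF features.
    """
    planted = planted or []
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    if len(sample_ids) != n_samples:
        raise ValueError("sample_ids length must equal n_samples")

    asv_ids = [f"ASV{i + 1:03d}" for i in range(n_asvs)]
    member_of: dict[str, PlantedAssociation] = {}
    seen: set[str] = set()
    for mod in planted:
        for member in mod.mf_members + mod.asv_members:
            if member in seen:
                raise ValueError(f"member {member!r} appears in more than one module")
            seen.add(member)
        for a in mod.asv_members:
            if a not in asv_ids:
                raise ValueError(f"planted ASV {a!r} not among generated ids")
            member_of[a] = mod

    latents = {mod.module_id: rng.standard_normal(n_samples) for mod in planted}

    log_abund = np.empty((n_asvs, n_samples))
    for i, aid in enumerate(asv_ids):
        mu = rng.normal(-2.0, 1.0)
        if aid in member_of:
            mod = member_of[aid]
            signal = mod.latent_strength * latents[mod.module_id]
        else:
            signal = base_sd * rng.standard_normal(n_samples)
        eps = noise_sd * rng.standard_normal(n_samples) if noise_sd > 0 else 0.0
        log_abund[i] = mu + signal + eps
    abund = np.exp(log_abund)
    abund = abund / abund.sum(axis=0, keepdims=True)

    table = pd.DataFrame(abund, index=asv_ids, columns=sample_ids)
    table["taxonomy"] = [_taxonomy_string(rng, i) for i in range(n_asvs)]

    mf_rows = []
    mf_ids = []
    links = []
    for mod in planted:
        for mf in mod.mf_members:
            mu = rng.normal(-8.0, 1.0)
            eps = noise_sd * rng.standard_normal(n_samples) if noise_sd > 0 else 0.0
            mf_rows.append(np.exp(mu + mod.latent_strength * latents[mod.module_id] + eps))
            mf_ids.append(mf)
            links.extend((mf, a) for a in mod.asv_members)
    mf_block = pd.DataFrame(mf_rows, index=mf_ids, columns=sample_ids) if mf_rows \
        else pd.DataFrame(columns=sample_ids)

    truth = {
        "modules": planted,
        "latents": pd.DataFrame(latents, index=sample_ids),
        "mf_intensities": mf_block,
        "links": links,
        "member_module": {m: mod.module_id for mod in planted
                          for m in mod.mf_members + mod.asv_members},
    }
    return table, truth
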