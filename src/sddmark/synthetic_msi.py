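"""Synthetic MALDI IMS retina phantoms with known ground truth.

The phantom emulates a sectioned retina imaged at ~10 um pitch: horizontal
tissue strata (inner retina, photoreceptor/bacillary layer, RPE, choroid),
dome-shaped subretinal deposit lesions sitting on the RPE boundary, and a
per-stratum lipid panel. Deposit-exclusive lysolipid-like species, species
shared between deposits and photoreceptors, and a deposit-excluded species
give downstream classification and SHAP ranking a known answer key.

Signal model per emitted peak: theoretical m/z perturbed by a smooth
per-pixel ppm drift field, intensity = base x isotope ratio x pixel scale x
lognormal jitter + Gaussian noise floor (truncated at zero). Occasional
single-peak outlier spikes exercise robust normalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .annotate import (
    C13_MASS_DIFF,
    LipidSpecies,
    adduct_mz,
    lipid_class_formula,
    monoisotopic_mass,
    parse_formula,
)
from .msio import CentroidSpectrum, IMSDataset

__all__ = [
    "SpeciesSpec",
    "PhantomConfig",
    "GroundTruth",
    "build_default_panel",
    "default_calibrants",
    "generate_phantom",
    "drift_field",
]

#: Natural abundance of carbon-13; sets isotopologue intensity ratios.
_P_C13 = 0.0107


@dataclass(frozen=True)
class SpeciesSpec:
    """One panel member: a lipid ion emitted in a set of tissue compartments."""

    name: str
    formula: dict[str, int] = field(hash=False)
    adduct: str
    base_intensity: float
    compartments: frozenset[str] = field(hash=False)
    n_isotopes: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "formula", parse_formula(self.formula))
        object.__setattr__(self, "compartments", frozenset(self.compartments))
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")
        if self.n_isotopes < 1:
            raise ValueError("n_isotopes must be >= 1")
        if not self.compartments:
            raise ValueError("compartments must be non-empty")
        if self.n_isotopes > 1 and self.formula.get("C", 0) < 1:
            raise ValueError("isotopologues require at least one carbon")

    @property
    def monoisotopic_mz(self) -> float:
        return adduct_mz(monoisotopic_mass(self.formula), self.adduct)

    def isotope_mzs(self) -> np.ndarray:
        return self.monoisotopic_mz + C13_MASS_DIFF * np.arange(self.n_isotopes)

    def isotope_ratios(self) -> np.ndarray:
        """Relative isotopologue abundances (binomial in the carbon count)."""
        n_c = self.formula.get("C", 0)
        ks = np.arange(self.n_isotopes)
        ratios = np.array(
            [math.comb(n_c, int(k)) * (_P_C13 / (1 - _P_C13)) ** int(k) for k in ks]
        )
        return ratios / ratios[0]

    def as_lipid(self, n13c: int = 0) -> LipidSpecies:
        return LipidSpecies(
            name=self.name, formula=self.formula, adduct=self.adduct, n13c=n13c
        )


#: Default strata as (name, (row_start, row_stop)) on the 120-row grid.
DEFAULT_STRATA: tuple[tuple[str, tuple[int, int]], ...] = (
    ("inner_retina", (0, 40)),
    ("bacillary", (40, 70)),
    ("RPE", (70, 80)),
    ("choroid", (80, 120)),
)


def default_strata(grid_height: int) -> tuple[tuple[str, tuple[int, int]], ...]:
    """The default four-layer anatomy scaled to an arbitrary grid height."""
    scale = grid_height / 120.0
    bands = []
    prev = 0
    for i, (name, (_r0, r1)) in enumerate(DEFAULT_STRATA):
        top = grid_height if i == len(DEFAULT_STRATA) - 1 else int(round(r1 * scale))
        top = max(top, prev + 1)
        bands.append((name, (prev, top)))
        prev = top
    return tuple(bands)


@dataclass(frozen=True)
class PhantomConfig:
    """Everything that defines one phantom realization (all seeded)."""

    grid_width: int = 200
    grid_height: int = 120
    strata: tuple[tuple[str, tuple[int, int]], ...] = ()
    n_deposits: int = 12
    deposit_size_px: tuple[int, int] = (8, 12)
    deposit_stratum: str = "RPE"
    species_panel: tuple[SpeciesSpec, ...] = ()
    drift_ppm_range: float = 15.0
    pixel_scale_range: tuple[float, float] = (0.5, 2.0)
    intensity_sigma: float = 0.25
    noise_floor: float = 1.0
    spike_rate: float = 0.02
    spike_factor: float = 100.0
    polarity: str = "positive"
    mz_range: tuple[float, float] = (300.0, 2000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_width < 10 or self.grid_height < 10:
            raise ValueError("grid dimensions must be >= 10 pixels")
        if self.drift_ppm_range < 0:
            raise ValueError("drift_ppm_range must be >= 0")
        lo, hi = self.pixel_scale_range
        if not (0 < lo <= hi):
            raise ValueError("pixel_scale_range bounds must be positive and ordered")
        if self.noise_floor < 0 or not (0 <= self.spike_rate <= 1):
            raise ValueError("noise_floor >= 0 and 0 <= spike_rate <= 1 required")
        if not self.strata:
            object.__setattr__(self, "strata", default_strata(self.grid_height))
        names = [n for n, _ in self.strata]
        if len(set(names)) != len(names):
            raise ValueError("stratum names must be unique")
        covered: set[int] = set()
        for _, (r0, r1) in self.strata:
            band = set(range(r0, r1))
            if not band or band & covered:
                raise ValueError("strata row bands must be non-empty and disjoint")
            if r1 > self.grid_height:
                raise ValueError("stratum band exceeds grid height")
            covered |= band
        if self.deposit_stratum not in names:
            raise ValueError(f"deposit_stratum {self.deposit_stratum!r} not a stratum")
        if not self.species_panel:
            object.__setattr__(self, "species_panel", tuple(build_default_panel()))

    @property
    def stratum_names(self) -> list[str]:
        return [n for n, _ in self.strata]

    def deposit_boundary_row(self) -> int:
        """Row on which deposit domes are centered (top of the deposit stratum)."""
        for name, (r0, _r1) in self.strata:
            if name == self.deposit_stratum:
                return r0
        raise ValueError(self.deposit_stratum)

    def peak_table(self) -> pd.DataFrame:
        """All theoretical peaks (isotopologues expanded) in the panel."""
        rows = []
        for sp in self.species_panel:
            for k, (mz, ratio) in enumerate(zip(sp.isotope_mzs(), sp.isotope_ratios())):
                rows.append(
                    {
                        "name": sp.name,
                        "adduct": sp.adduct,
                        "n13c": k,
                        "mz": mz,
                        "rel_abundance": ratio,
                        "base_intensity": sp.base_intensity,
                        "compartments": "|".join(sorted(sp.compartments)),
                        "deposit_exclusive": sp.compartments == frozenset({"deposit"}),
                    }
                )
        return pd.DataFrame(rows).sort_values("mz", ignore_index=True)


@dataclass
class GroundTruth:
    """Answer key for one phantom: geometry, perturbations, and marker m/z."""

    deposit_mask: np.ndarray  # (height, width) bool
    stratum_map: np.ndarray  # (height, width) int, -1 where uncovered
    stratum_names: list[str]
    true_marker_mz: np.ndarray  # deposit-exclusive peaks incl. isotopologues
    applied_drift_ppm: np.ndarray  # (height, width)
    applied_scale: np.ndarray  # (height, width)
    peak_table: pd.DataFrame
    deposit_centers: list[tuple[int, int, int]]  # (x, y, radius)

    @property
    def deposit_area_fraction(self) -> float:
        return float(self.deposit_mask.mean())


def _named(name: str, c: int, db: int, adduct: str, base: float,
           compartments: set[str], n_isotopes: int = 3) -> SpeciesSpec:
    cls = name.split("(")[0]
    return SpeciesSpec(
        name=name,
        formula=lipid_class_formula(cls, c, db),
        adduct=adduct,
        base_intensity=base,
        compartments=frozenset(compartments),
        n_isotopes=n_isotopes,
    )


def build_default_panel(min_separation_ppm: float = 30.0) -> list[SpeciesSpec]:
    """The default retina-phantom species panel (~100 species, ~290 peaks).

    Contents, mirroring the localization classes the pipeline must resolve:

    * deposit-exclusive lysolipids (the positive-marker class), e.g.
      LPC(18:3) [M+H]+ and LPE(18:0) [M-H]-;
    * species shared between deposits and the photoreceptor stratum;
    * one deposit-excluded sphingomyelin (present in photoreceptors, absent
      inside deposits — the negative-marker class);
    * ubiquitous species present in every compartment, which double as
      alignment reference peaks and calibrants (PC(32:0)+Na, PC(34:1)+H/+Na,
      PI(38:4)-H among them);
    * per-stratum filler species to populate a realistic feature space.

    Species whose full isotope envelopes would come within
    ``min_separation_ppm`` of an already-accepted peak are dropped so that
    every theoretical peak is resolvable on a 1.5 ppm common axis.
    """
    panel: list[SpeciesSpec] = []
    strata = ["inner_retina", "bacillary", "RPE", "choroid"]
    everywhere = set(strata) | {"deposit"}

    # Ubiquitous: alignment references + the recalibration species.
    panel += [
        _named("LPA(18:1)", 18, 1, "-H", 90.0, everywhere),
        _named("LPC(16:0)", 16, 0, "+H", 110.0, everywhere),
        _named("SM(34:1)", 34, 1, "+H", 120.0, everywhere),
        _named("PC(32:0)", 32, 0, "+Na", 100.0, everywhere),
        _named("PC(34:1)", 34, 1, "+H", 130.0, everywhere),
        _named("PC(34:1)", 34, 1, "+Na", 80.0, everywhere),
        _named("PC(40:6)", 40, 6, "+H", 95.0, everywhere),
        _named("PI(38:4)", 38, 4, "-H", 115.0, everywhere),
    ]
    # Deposit-exclusive lysolipids (positive markers). Two isotopologues
    # each: at C16-C26 the M+2 abundance (2-3% of base) sits below the
    # phantom's additive noise floor, so only M and M+1 are emitted.
    panel += [
        _named("LPC(18:3)", 18, 3, "+H", 120.0, {"deposit"}, n_isotopes=2),
        _named("LPE(18:0)", 18, 0, "-H", 110.0, {"deposit"}, n_isotopes=2),
        _named("LPA(16:0)", 16, 0, "-H", 100.0, {"deposit"}, n_isotopes=2),
    ]
    # Shared deposit / photoreceptor species.
    panel += [
        _named("PC(36:4)", 36, 4, "+H", 85.0, {"deposit", "bacillary"}),
        _named("PE(38:6)", 38, 6, "-H", 75.0, {"deposit", "bacillary"}),
        _named("PA(34:1)", 34, 1, "-H", 70.0, {"deposit", "bacillary"}),
    ]
    # Deposit-excluded species (negative marker): expressed throughout the
    # tissue but displaced by deposits, so its intensity drops to zero in SDD.
    panel += [
        _named("SM(42:1)", 42, 1, "+H", 95.0, set(strata)),
    ]

    # Deterministic per-stratum filler panel.
    filler_classes = ["PC", "PE", "SM", "PI", "PA", "PE-NMe2"]
    adduct_cycle = {"PC": "+H", "PE": "-H", "SM": "+H", "PI": "-H", "PA": "-H",
                    "PE-NMe2": "+H"}
    i = 0
    for stratum in strata:
        for j in range(22):
            cls = filler_classes[(i + j) % len(filler_classes)]
            c = 28 + ((i * 5 + j * 3) % 17)  # 28..44 carbons
            db = (i + 2 * j) % 7
            base = 20.0 + ((i * 7 + j * 11) % 60)
            try:
                spec = _named(f"{cls}({c}:{db})", c, db, adduct_cycle[cls],
                              base, {stratum})
            except ValueError:
                continue
            panel.append(spec)
        i += 1

    return _drop_clashing(panel, min_separation_ppm)


def _drop_clashing(panel: list[SpeciesSpec], min_sep_ppm: float) -> list[SpeciesSpec]:
    accepted: list[SpeciesSpec] = []
    taken: list[float] = []
    for sp in panel:
        mzs = sp.isotope_mzs()
        ok = all(
            abs(m - t) / t * 1e6 >= min_sep_ppm for m in mzs for t in taken
        )
        if ok:
            accepted.append(sp)
            taken.extend(mzs.tolist())
    return accepted


def default_calibrants() -> pd.DataFrame:
    """The recalibration reference species shipped with the default panel."""
    rows = [
        ("PI(38:4)", "C47H83O13P", "-H"),
        ("PC(32:0)", "C40H80NO8P", "+Na"),
        ("PC(34:1)", "C42H82NO8P", "+H"),
        ("PC(34:1)", "C42H82NO8P", "+Na"),
    ]
    out = []
    for name, formula, adduct in rows:
        out.append(
            {
                "name": name,
                "formula": formula,
                "adduct": adduct,
                "mz": adduct_mz(monoisotopic_mass(formula), adduct),
            }
        )
    return pd.DataFrame(out)


def drift_field(config: PhantomConfig) -> np.ndarray:
    """Smooth per-pixel mass-drift field (ppm), bounded by +/- drift_ppm_range.

    Low-pass filtered white noise, rescaled so the extreme value touches the
    configured bound; smoothness scale is a quarter of the short grid side.
    """
    h, w = config.grid_height, config.grid_width
    if config.drift_ppm_range == 0:
        return np.zeros((h, w))
    rng = np.random.default_rng([config.seed, 101])
    raw = rng.standard_normal((h, w))
    sigma = max(min(h, w) / 4.0, 1.0)
    smooth = gaussian_filter(raw, sigma=sigma, mode="reflect")
    peak = np.abs(smooth).max()
    if peak == 0:
        return np.zeros((h, w))
    return smooth * (config.drift_ppm_range / peak)


def _scale_field(config: PhantomConfig) -> np.ndarray:
    """Smooth multiplicative per-pixel intensity scale within the given range."""
    h, w = config.grid_height, config.grid_width
    rng = np.random.default_rng([config.seed, 102])
    raw = gaussian_filter(rng.standard_normal((h, w)), sigma=max(min(h, w) / 8.0, 1.0))
    lo, hi = config.pixel_scale_range
    if raw.max() == raw.min():
        return np.full((h, w), (lo + hi) / 2.0)
    unit = (raw - raw.min()) / (raw.max() - raw.min())
    return lo + unit * (hi - lo)


def _place_deposits(config: PhantomConfig) -> list[tuple[int, int, int]]:
    rng = np.random.default_rng([config.seed, 103])
    y0 = config.deposit_boundary_row()
    r_lo, r_hi = config.deposit_size_px
    if r_lo > r_hi or r_lo < 1:
        raise ValueError("deposit_size_px must be an ordered positive range")
    if y0 - r_hi < 0 or y0 + r_hi >= config.grid_height or 2 * r_hi >= config.grid_width:
        raise ValueError(
            "deposits do not fit on the designated stratum boundary within the grid"
        )
    # One jittered slot per deposit across the section width. Neighboring
    # domes may partially merge, mimicking confluent late-stage deposits,
    # but each lesion keeps a distinct apex.
    n = config.n_deposits
    centers: list[tuple[int, int, int]] = []
    slot = config.grid_width / max(n, 1)
    for i in range(n):
        r = int(rng.integers(r_lo, r_hi + 1))
        jitter = rng.uniform(-slot / 4, slot / 4)
        x = int(np.clip((i + 0.5) * slot + jitter, r, config.grid_width - 1 - r))
        centers.append((x, y0, r))
    return centers


def _deposit_mask(config: PhantomConfig, centers: list[tuple[int, int, int]]) -> np.ndarray:
    h, w = config.grid_height, config.grid_width
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for x, y, r in centers:
        mask |= (xx - x) ** 2 + (yy - y) ** 2 <= r**2
    return mask


def _stratum_map(config: PhantomConfig) -> np.ndarray:
    h, w = config.grid_height, config.grid_width
    smap = np.full((h, w), -1, dtype=np.int64)
    for idx, (_name, (r0, r1)) in enumerate(config.strata):
        smap[r0:r1, :] = idx
    return smap


def generate_phantom(config: PhantomConfig) -> tuple[IMSDataset, GroundTruth]:
    """Generate one seeded phantom dataset plus its ground truth.

    Compartment rule: a deposit pixel emits exactly the species whose
    compartments include ``"deposit"``; every other pixel emits the species
    assigned to its stratum. This makes deposit-exclusive species vanish
    outside lesions and deposit-excluded species vanish inside them.
    """
    centers = _place_deposits(config)
    mask = _deposit_mask(config, centers)
    smap = _stratum_map(config)
    drift = drift_field(config)
    scale = _scale_field(config)
    rng = np.random.default_rng([config.seed, 104])

    names = config.stratum_names
    # Pre-group peaks by compartment key: "deposit" or stratum index.
    peaks_by_comp: dict[object, tuple[np.ndarray, np.ndarray]] = {}

    def _peaks_for(selector) -> tuple[np.ndarray, np.ndarray]:
        mzs, bases = [], []
        for sp in config.species_panel:
            if not selector(sp):
                continue
            for mz, ratio in zip(sp.isotope_mzs(), sp.isotope_ratios()):
                mzs.append(mz)
                bases.append(sp.base_intensity * ratio)
        order = np.argsort(mzs)
        return np.asarray(mzs)[order], np.asarray(bases)[order]

    peaks_by_comp["deposit"] = _peaks_for(lambda sp: "deposit" in sp.compartments)
    for idx, name in enumerate(names):
        peaks_by_comp[idx] = _peaks_for(lambda sp, n=name: n in sp.compartments)

    mz_lo, mz_hi = config.mz_range
    spectra = []
    for y in range(config.grid_height):
        for x in range(config.grid_width):
            key: object = "deposit" if mask[y, x] else int(smap[y, x])
            if key == -1:
                mz_theo = np.empty(0)
                base = np.empty(0)
            else:
                mz_theo, base = peaks_by_comp[key]
            n = mz_theo.size
            inten = np.empty(0)
            mz_obs = np.empty(0)
            if n:
                jitter = rng.lognormal(mean=0.0, sigma=config.intensity_sigma, size=n)
                inten = base * scale[y, x] * jitter
                if config.noise_floor > 0:
                    inten = inten + rng.normal(0.0, config.noise_floor, size=n)
                keep = inten > 0
                mz_obs = mz_theo[keep] * (1.0 + drift[y, x] * 1e-6)
                inten = inten[keep]
            if config.spike_rate > 0 and rng.random() < config.spike_rate:
                spike_mz = rng.uniform(mz_lo, mz_hi)
                spike_val = config.spike_factor * (inten.max() if inten.size else 1.0)
                mz_obs = np.append(mz_obs, spike_mz)
                inten = np.append(inten, spike_val)
            spectra.append(CentroidSpectrum(mz=mz_obs, intensity=inten, pixel=(x, y)))

    dataset = IMSDataset(
        spectra=spectra,
        polarity=config.polarity,
        mz_range=config.mz_range,
        grid_shape=(config.grid_width, config.grid_height),
        provenance={"generator": "sddmark.synthetic_msi", "seed": config.seed},
    )
    table = config.peak_table()
    truth = GroundTruth(
        deposit_mask=mask,
        stratum_map=smap,
        stratum_names=names,
        true_marker_mz=table.loc[table["deposit_exclusive"], "mz"].to_numpy(),
        applied_drift_ppm=drift,
        applied_scale=scale,
        peak_table=table,
        deposit_centers=centers,
    )
    return dataset, truth
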