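"""Synthetic berry populations and NIR spectra.

The generator emulates a harvest study of seedless table grape: berries are
sampled from field blocks (3 blocks x 3 bags x 30 berries by default), each
berry is scanned on several faces, and per-berry reference values are
measured destructively afterwards (total soluble solids by refractometry and
a double-compression texture profile: hardness BH, springiness BS,
cohesiveness BCo, with gumminess BG = BH*BCo and chewiness
BCh = BH*BCo*BS).

The spectral model is additive Beer-Lambert mixing: each chemical component
(water, sugars, organic acids, pectins) contributes a sum of Gaussian bands
in wavenumber, weighted by a latent concentration, followed by per-face
multiplicative scatter, additive offset, a linear baseline and white noise.
Latent ripeness drives both the concentrations (linearly) and the reference
values: TSS is linear in berry density, while the texture parameters are
smooth but *nonlinear* (logistic) in ripeness with a berry-diameter
interaction — so a linear calibration underfits texture and a nonlinear
regressor has genuine headroom, which is the situation the pipeline is
built for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .spectra_io import SpectraSet

__all__ = [
    "StudyDesign",
    "BandLibrary",
    "NoiseModel",
    "LinkSpec",
    "BerryRecord",
    "default_grid",
    "generate_study",
    "texture_identities",
    "records_to_frame",
]


def default_grid(n_points: int = 1001, high: float = 12000.0, low: float = 4000.0) -> np.ndarray:
    """Instrument grid, descending cm^-1 (12,000 -> 4000 at 8 cm^-1 => 1001 points)."""
    return np.linspace(high, low, n_points)


@dataclass
class StudyDesign:
    """Sampling design of the synthetic study.

    Defaults mirror a three-block harvest with three bags per block and 30
    analysed berries per bag, each scanned on three faces.
    """

    n_blocks: int = 3
    n_bags_per_block: int = 3
    n_berries_per_bag: int = 30
    n_faces: int = 3
    density_classes: tuple = (
        ("low", 1.00, 1.0 / 3.0),
        ("mid", 1.04, 1.0 / 3.0),
        ("high", 1.08, 1.0 / 3.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_blocks", "n_bags_per_block", "n_berries_per_bag", "n_faces"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        w = sum(c[2] for c in self.density_classes)
        if abs(w - 1.0) > 1e-12:
            raise ValueError(f"density-class mixing weights sum to {w}, not 1")

    @property
    def n_berries(self) -> int:
        return self.n_blocks * self.n_bags_per_block * self.n_berries_per_bag


#: Band centers (cm^-1) follow the usual NIR assignments for grape tissue:
#: water O-H overtones/combinations at 10,526, 6849, 6896 and 5128 cm^-1;
#: sugar C-H/O-H bands at 8333, 5917, 5714, 4424 and 4344 cm^-1; organic
#: acids near 10,101 and 4344 cm^-1; pectin C-H/O-H combination bands.
DEFAULT_BANDS = {
    "water": [(10526.0, 220.0, 0.10), (6896.0, 260.0, 0.55), (6849.0, 180.0, 0.35), (5128.0, 300.0, 1.00)],
    "sugars": [(8333.0, 180.0, 0.18), (5917.0, 120.0, 0.12), (5714.0, 140.0, 0.15), (4424.0, 110.0, 0.22), (4344.0, 100.0, 0.20)],
    "organic_acids": [(10101.0, 150.0, 0.06), (4344.0, 90.0, 0.08)],
    "pectins": [(4700.0, 160.0, 0.12), (5600.0, 200.0, 0.08)],
}


@dataclass
class BandLibrary:
    """Gaussian band profiles per chemical component: (center cm^-1, width cm^-1, amplitude)."""

    bands: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()})

    def validate(self, grid: np.ndarray) -> None:
        lo, hi = float(np.min(grid)), float(np.max(grid))
        for comp, lst in self.bands.items():
            for center, width, amp in lst:
                if not (lo <= center <= hi):
                    raise ValueError(
                        f"band center {center} cm^-1 of component {comp!r} "
                        f"outside grid range [{lo}, {hi}]"
                    )
                if width <= 0:
                    raise ValueError(f"band width must be > 0 for component {comp!r}")

    def profile(self, component: str, grid: np.ndarray) -> np.ndarray:
        """Unit-concentration spectrum of one component on the grid."""
        out = np.zeros_like(grid, dtype=float)
        for center, width, amp in self.bands[component]:
            out += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
        return out


@dataclass
class NoiseModel:
    """Instrumental/sample noise. All SDs >= 0; zero everywhere => exact mixtures.

    multiplicative_sd   per-face multiplicative scatter gain SD
    additive_sd         per-face additive offset SD (absorbance units)
    baseline_slope_sd   per-face linear-baseline slope SD (over the full grid)
    white_sd            per-point white noise SD
    face_sd             extra per-face gain variation (berry inhomogeneity)
    block_offset_sd     per-block additive offset SD (field/handling effect,
                        set to 0 to switch the block effect off)
    """

    multiplicative_sd: float = 0.05
    additive_sd: float = 0.02
    baseline_slope_sd: float = 0.01
    white_sd: float = 0.002
    face_sd: float = 0.01
    block_offset_sd: float = 0.015

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class LinkSpec:
    """Latent -> reference-value links.

    Ripeness r is the density mapped to roughly [0, 1]; concentrations are
    linear in r; TSS is linear in density with refractometer-scale noise;
    texture parameters are logistic in r with a diameter interaction.
    Units: density g/mL, diameter mm, TSS deg Brix, BH N, BS mm, BCo unitless.
    """

    density_class_sd: float = 0.012
    # TSS = tss_slope * density + tss_intercept + N(0, tss_sd); spans ~14.5-19
    tss_slope: float = 56.25
    tss_intercept: float = -41.75
    tss_sd: float = 0.30
    diameter_mean: float = 19.0
    diameter_sd: float = 1.5
    weight_sd: float = 0.15
    # concentrations, linear in ripeness r
    conc_water: tuple = (1.00, -0.15)
    conc_sugars: tuple = (0.35, 0.45)
    conc_acids: tuple = (0.30, -0.18)
    conc_pectins: tuple = (0.22, 0.30)
    conc_sd: float = 0.02
    # hardness: base + amp * sigmoid((r - mid)/scale) + diameter terms
    bh_base: float = 8.0
    bh_amp: float = 9.0
    bh_mid: float = 0.45
    bh_scale: float = 0.18
    bh_diam: float = -0.30
    bh_interact: float = 0.50
    bh_sd: float = 0.60
    # springiness
    bs_base: float = 1.60
    bs_amp: float = 0.80
    bs_mid: float = 0.50
    bs_scale: float = 0.12
    bs_diam: float = -0.040
    bs_interact: float = 0.120
    bs_sd: float = 0.050
    # cohesiveness: nearly constant (0.24 +/- 0.03), mostly unpredictable
    bco_mean: float = 0.24
    bco_slope: float = 0.015
    bco_sd: float = 0.03


@dataclass
class BerryRecord:
    berry_id: str
    block: int
    bag: int
    density_class: str
    density: float
    weight: float
    diameter: float
    tss: float
    bh: float
    bs: float
    bco: float
    bg: float
    bch: float

    def __post_init__(self) -> None:
        if not 0.0 < self.bco < 1.0:
            raise ValueError(f"BCo must be in (0, 1), got {self.bco}")
        if self.diameter <= 0 or self.tss <= 0:
            raise ValueError("diameter and TSS must be positive")


def texture_identities(bh: float, bs: float, bco: float) -> tuple[float, float]:
    """Gumminess and chewiness from the primary texture parameters.

    BG = BH * BCo (N); BCh = BH * BCo * BS (mJ, force x distance).
    """
    bh = float(bh)
    bs = float(bs)
    bco = float(bco)
    if not (math.isfinite(bh) and math.isfinite(bs) and math.isfinite(bco)):
        raise ValueError("inputs must be finite")
    if bh < 0 or bs < 0:
        raise ValueError("BH and BS must be >= 0")
    if not 0.0 < bco < 1.0:
        raise ValueError(f"BCo must be in (0, 1), got {bco}")
    bg = bh * bco
    bch = bh * bco * bs
    return bg, bch


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_study(
    design: StudyDesign | None = None,
    bands: BandLibrary | None = None,
    noise: NoiseModel | None = None,
    link: LinkSpec | None = None,
    grid: np.ndarray | None = None,
) -> tuple[SpectraSet, list[BerryRecord]]:
    """Generate one synthetic study: face-level spectra plus berry records.

    Returns ``n_blocks * n_bags * n_berries`` records and ``n_faces`` raw
    spectra per berry (replicate averaging is a downstream step).  Fixing
    ``design.seed`` makes the output byte-identical across calls.
    """
    design = design or StudyDesign()
    bands = bands or BandLibrary()
    noise = noise or NoiseModel()
    link = link or LinkSpec()
    if grid is None:
        grid = default_grid()
    bands.validate(grid)
    rng = np.random.default_rng(design.seed)

    labels = [c[0] for c in design.density_classes]
    means = np.array([c[1] for c in design.density_classes])
    weights = np.array([c[2] for c in design.density_classes])
    d_lo, d_hi = float(means.min()), float(means.max())
    d_span = max(d_hi - d_lo, 1e-9)

    profiles = {c: bands.profile(c, grid) for c in bands.bands}
    gcoord = np.linspace(-0.5, 0.5, grid.size)  # normalized baseline coordinate

    block_offsets = rng.normal(0.0, noise.block_offset_sd, size=design.n_blocks)

    records: list[BerryRecord] = []
    spectra_rows = []
    ids = []
    meta_rows = []
    for block in range(1, design.n_blocks + 1):
        for bag in range(1, design.n_bags_per_block + 1):
            for berry in range(1, design.n_berries_per_bag + 1):
                cls = int(rng.choice(len(labels), p=weights))
                density = rng.normal(means[cls], link.density_class_sd)
                r = (density - d_lo) / d_span  # ripeness, roughly [0, 1]
                diameter = rng.normal(link.diameter_mean, link.diameter_sd)
                vol_ml = math.pi / 6.0 * (diameter / 10.0) ** 3
                weight = max(vol_ml * density + rng.normal(0.0, link.weight_sd), 0.1)
                tss = max(
                    link.tss_slope * density + link.tss_intercept + rng.normal(0.0, link.tss_sd),
                    0.5,
                )
                dd = diameter - link.diameter_mean
                sig_h = _sigmoid((r - link.bh_mid) / link.bh_scale)
                bh = max(
                    link.bh_base
                    + link.bh_amp * sig_h
                    + (link.bh_diam + link.bh_interact * sig_h) * dd
                    + rng.normal(0.0, link.bh_sd),
                    0.1,
                )
                sig_s = _sigmoid((r - link.bs_mid) / link.bs_scale)
                bs = max(
                    link.bs_base
                    + link.bs_amp * sig_s
                    + (link.bs_diam + link.bs_interact * sig_s) * dd
                    + rng.normal(0.0, link.bs_sd),
                    0.05,
                )
                bco = float(
                    np.clip(
                        link.bco_mean + link.bco_slope * (r - 0.5) + rng.normal(0.0, link.bco_sd),
                        0.05,
                        0.95,
                    )
                )
                bg, bch = texture_identities(bh, bs, bco)
                berry_id = f"b{block}-g{bag}-n{berry:02d}"
                records.append(
                    BerryRecord(
                        berry_id=berry_id,
                        block=block,
                        bag=bag,
                        density_class=labels[cls],
                        density=float(density),
                        weight=float(weight),
                        diameter=float(diameter),
                        tss=float(tss),
                        bh=float(bh),
                        bs=float(bs),
                        bco=bco,
                        bg=float(bg),
                        bch=float(bch),
                    )
                )

                conc = {
                    "water": link.conc_water[0] + link.conc_water[1] * r,
                    "sugars": link.conc_sugars[0] + link.conc_sugars[1] * r,
                    "organic_acids": link.conc_acids[0] + link.conc_acids[1] * r,
                    "pectins": link.conc_pectins[0] + link.conc_pectins[1] * r,
                }
                pure = np.zeros_like(grid)
                for comp, prof in profiles.items():
                    c = conc.get(comp, 0.0) + (
                        rng.normal(0.0, link.conc_sd) if link.conc_sd > 0 else 0.0
                    )
                    pure += c * prof

                for face in range(1, design.n_faces + 1):
                    gain = (1.0 + rng.normal(0.0, noise.multiplicative_sd)) * (
                        1.0 + rng.normal(0.0, noise.face_sd)
                    )
                    offset = rng.normal(0.0, noise.additive_sd)
                    slope = rng.normal(0.0, noise.baseline_slope_sd)
                    white = (
                        rng.normal(0.0, noise.white_sd, size=grid.size)
                        if noise.white_sd > 0
                        else 0.0
                    )
                    spec = gain * pure + offset + slope * gcoord + white
                    spec = spec + block_offsets[block - 1]
                    spectra_rows.append(spec)
                    ids.append(f"{berry_id}-f{face}")
                    meta_rows.append(
                        {"berry_id": berry_id, "block": block, "bag": bag, "face": face}
                    )

    spectra = SpectraSet(
        grid=grid,
        absorbance=np.vstack(spectra_rows),
        sample_ids=ids,
        meta=pd.DataFrame(meta_rows),
    )
    return spectra, records


def records_to_frame(records: list[BerryRecord]) -> pd.DataFrame:
    """Reference table, one row per berry, indexed by berry_id."""
    df = pd.DataFrame([asdict(r) for r in records]).set_index("berry_id")
    return df
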