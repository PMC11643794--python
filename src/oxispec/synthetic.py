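"""Synthetic shelf-life datasets: factorial design, oxidation chemistry, NIR-like spectra.

The generator emulates a cold-pressed seed-oil storage trial: oil packed in
vials of four materials (PP polypropylene, CG clear glass, AG amber glass,
AGA amber glass + aluminium foil), stored at 10 °C (dark) or 25 °C (diffused
light), sampled at nine time points over 270 days.  Every dataset carries a
known ground truth so the downstream decomposition, permutation test and
calibration stages are testable without instrument data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "OxidationParams",
    "SpectralBasis",
    "generate_design",
    "simulate_chemistry",
    "simulate_spectra",
    "simulate_dataset",
    "DEFAULT_GRID",
]

#: FT-NIR wavenumber grid, cm^-1 (4000-9000 at 8 cm^-1 spacing).
DEFAULT_GRID = np.arange(4000.0, 9001.0, 8.0)

#: Main absorption bands of an unsaturated vegetable oil, cm^-1
#: (C-H / C=C combinations, CH2/CH3 overtones, carbonyl).
DEFAULT_BAND_CENTERS = np.array(
    [4602.0, 4667.0, 4700.0, 5180.0, 5269.0, 5678.0, 5790.0, 5892.0,
     5963.0, 7070.0, 7190.0, 7260.0, 8260.0, 8395.0, 8580.0]
)


class InvalidSpecError(ValueError):
    """A design spec violates its invariants."""


class InvalidParamsError(ValueError):
    """Oxidation-kinetics parameters violate their invariants."""


@dataclass(frozen=True)
class DesignSpec:
    """Balanced full-factorial storage design: time x temperature x material."""

    time_levels: tuple = (15, 30, 45, 60, 90, 120, 150, 190, 270)
    temperature_levels: tuple = (10, 25)
    material_levels: tuple = ("PP", "CG", "AG", "AGA")
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("time_levels", "temperature_levels", "material_levels"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise InvalidSpecError(f"{name} must be non-empty")
            if len(set(levels)) != len(levels):
                raise InvalidSpecError(f"{name} contains duplicate levels")
        if self.n_replicates < 1:
            raise InvalidSpecError("n_replicates must be >= 1")


@dataclass(frozen=True)
class OxidationParams:
    """Rise-then-decay peroxide kinetics modulated by temperature and packaging.

    PV(t) = pv0 + A * r * (1 - exp(-g*r*t)) * exp(-d*r*t) with
    r = temp_factor * material_factor: hydroperoxides accumulate (rate g),
    then decompose into secondary products (rate d).  K232 co-moves with PV
    (conjugated dienes); K268 rises monotonically (conjugated trienes /
    carbonyls).  Material factors encode oxygen permeability x light
    transmittance: PP (permeable, clear) worst, foil-wrapped amber glass best.
    """

    pv0: float = 3.0                  # meq O2/kg at bottling
    k232_0: float = 4.26              # time-zero conjugated-diene extinction
    k268_0: float = 1.25              # time-zero conjugated-triene extinction
    amplitude: float = 45.0           # meq O2/kg, peak-scale of the PV excursion
    growth_rate: float = 0.02         # 1/day, primary oxidation
    decay_rate: float = 0.00105       # 1/day, hydroperoxide decomposition
    k232_per_pv: float = 0.17         # diene extinction per meq O2/kg
    k268_gain: float = 1.40           # triene extinction amplitude
    temp_factor: dict = field(default_factory=lambda: {10: 0.40, 25: 1.0})
    material_factor: dict = field(
        default_factory=lambda: {"PP": 1.0, "CG": 0.55, "AG": 0.35, "AGA": 0.12}
    )
    noise_sd: float = 0.5             # meq O2/kg measurement noise on PV

    def validate(self, design: pd.DataFrame | None = None) -> None:
        for name in ("pv0", "amplitude", "growth_rate", "decay_rate",
                     "k232_per_pv", "k268_gain", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParamsError(f"{name} must be >= 0")
        if any(v < 0 for v in self.temp_factor.values()):
            raise InvalidParamsError("temp_factor entries must be >= 0")
        if any(v < 0 for v in self.material_factor.values()):
            raise InvalidParamsError("material_factor entries must be >= 0")
        if design is not None:
            missing_t = set(design["temperature"]) - set(self.temp_factor)
            missing_m = set(design["material"]) - set(self.material_factor)
            if missing_t:
                raise InvalidParamsError(f"no temp_factor for levels {sorted(missing_t)}")
            if missing_m:
                raise InvalidParamsError(f"no material_factor for levels {sorted(missing_m)}")


@dataclass(frozen=True)
class SpectralBasis:
    """Gaussian band model of a transmission NIR oil spectrum.

    Each band has a fixed centre/width, a base amplitude, and a 2-vector
    sensitivity mapping the standardized (PV, K268) oxidation state to an
    amplitude change.  Channels inside ``saturation_regions`` rail above the
    detector's linear range (> 2.5 AU), as happens at a 4 mm optical path.
    """

    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    band_centers: np.ndarray = field(default_factory=lambda: DEFAULT_BAND_CENTERS.copy())
    band_widths: np.ndarray = field(
        default_factory=lambda: np.array(
            [35.0, 30.0, 40.0, 45.0, 40.0, 35.0, 30.0, 32.0, 38.0,
             55.0, 45.0, 40.0, 50.0, 45.0, 60.0]
        )
    )
    band_base_amplitudes: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.9, 1.1, 0.8, 0.45, 0.25, 1.6, 1.3, 1.2, 0.9,
             0.5, 0.55, 0.4, 0.22, 0.2, 0.12]
        )
    )
    #: d(amplitude)/d(z-score) for [z(PV), z(K268)]; AU per standard deviation.
    band_sensitivities: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [-0.040, 0.010],   # C-H/C=C combination: double bonds consumed
                [-0.050, 0.000],   # cis =C-H combination
                [-0.030, 0.020],
                [0.015, 0.050],    # C=O second overtone grows with carbonyls
                [0.005, 0.010],
                [0.060, -0.020],   # CH2 sym overtone
                [0.045, -0.015],
                [-0.055, 0.025],   # CH3 asym overtone
                [-0.035, 0.010],
                [0.020, 0.015],
                [0.015, 0.010],
                [-0.010, 0.012],
                [0.008, 0.006],
                [-0.006, 0.008],
                [0.004, 0.030],    # aliphatic carbonyl
            ]
        )
    )
    saturation_regions: tuple = ((4000.0, 4440.0), (5770.0, 5875.0))
    clip_max: float = 3.0            # detector ceiling, AU
    baseline_offset_sd: float = 0.02  # per-spectrum turbidity offset, AU
    baseline_slope_sd: float = 0.01   # per-spectrum tilt over the full grid, AU
    noise_sd: float = 0.002           # per-channel iid noise, AU

    def validate(self) -> None:
        lo, hi = self.grid.min(), self.grid.max()
        if np.any((self.band_centers < lo) | (self.band_centers > hi)):
            raise ValueError("band centers must lie within the wavenumber grid")
        if np.any(self.band_widths <= 0):
            raise ValueError("band widths must be > 0")
        n = len(self.band_centers)
        if not (len(self.band_widths) == len(self.band_base_amplitudes)
                == self.band_sensitivities.shape[0] == n):
            raise ValueError("band arrays must have matching lengths")


def generate_design(spec: DesignSpec = DesignSpec()) -> pd.DataFrame:
    """Complete crossing of time x temperature x material with replicates.

    Returns one row per measurement with a unique ``sample_id``; the row
    count is the product of the level counts times ``n_replicates``.
    """
    spec.validate()
    rows = [
        {"time": t, "temperature": temp, "material": m, "replicate": r}
        for t, temp, m, r in itertools.product(
            spec.time_levels, spec.temperature_levels,
            spec.material_levels, range(1, spec.n_replicates + 1),
        )
    ]
    design = pd.DataFrame(rows)
    design.insert(
        0,
        "sample_id",
        [
            f"t{row.time}_T{row.temperature}_{row.material}_r{row.replicate}"
            for row in design.itertuples()
        ],
    )
    return design


def _rate_multiplier(design: pd.DataFrame, params: OxidationParams) -> np.ndarray:
    temp = design["temperature"].map(params.temp_factor).to_numpy(float)
    mat = design["material"].map(params.material_factor).to_numpy(float)
    return temp * mat


def peroxide_trajectory(t: np.ndarray, r: np.ndarray, params: OxidationParams) -> np.ndarray:
    """Noise-free PV(t) for rate multiplier r (vectorised)."""
    g, d = params.growth_rate, params.decay_rate
    return params.pv0 + params.amplitude * r * (1.0 - np.exp(-g * r * t)) * np.exp(-d * r * t)


def simulate_chemistry(
    design: pd.DataFrame, params: OxidationParams = OxidationParams(), seed: int = 0
) -> pd.DataFrame:
    """Per-row PV / K232 / K268 following rise-then-decay oxidation kinetics.

    PV and K232 (conjugated dienes, primary oxidation) co-move; K268
    (trienes and carbonyls, secondary oxidation) rises monotonically.
    Outputs are clipped at zero; deterministic given ``seed``.
    """
    params.validate(design)
    rng = np.random.default_rng(seed)
    t = design["time"].to_numpy(float)
    r = _rate_multiplier(design, params)

    pv = peroxide_trajectory(t, r, params)
    k232 = params.k232_0 + params.k232_per_pv * (pv - params.pv0)
    k268 = params.k268_0 + params.k268_gain * r * (1.0 - np.exp(-params.growth_rate * r * t))

    n = len(design)
    pv = pv + rng.normal(0.0, params.noise_sd, n)
    k232 = k232 + rng.normal(0.0, 0.10 * params.noise_sd, n)
    k268 = k268 + rng.normal(0.0, 0.04 * params.noise_sd, n)

    return pd.DataFrame(
        {
            "sample_id": design["sample_id"].to_numpy(),
            "pv": np.clip(pv, 0.0, None),
            "k232": np.clip(k232, 0.0, None),
            "k268": np.clip(k268, 0.0, None),
        }
    )


def _oxidation_state(chem: pd.DataFrame) -> np.ndarray:
    """Standardized (PV, K268) pair, the latent state driving band amplitudes."""
    out = np.zeros((len(chem), 2))
    for j, col in enumerate(("pv", "k268")):
        v = chem[col].to_numpy(float)
        sd = v.std()
        if sd > 0:
            out[:, j] = (v - v.mean()) / sd
    return out


def simulate_spectra(
    chem: pd.DataFrame, basis: SpectralBasis = SpectralBasis(), seed: int = 0
) -> pd.DataFrame:
    """Forward-model NIR spectra from the chemistry table.

    spectrum = baseline(offset + slope*nu) + sum of Gaussian bands whose
    amplitudes respond linearly to the standardized (PV, K268) state,
    + iid channel noise; channels in the saturation regions rail at the
    detector ceiling (> 2.5 AU).  Returns a DataFrame indexed by sample_id
    with float wavenumber columns.
    """
    basis.validate()
    rng = np.random.default_rng(seed)
    grid = basis.grid
    n, p = len(chem), len(grid)

    ox = _oxidation_state(chem)                       # (n, 2)
    amps = basis.band_base_amplitudes[None, :] + ox @ basis.band_sensitivities.T  # (n, bands)

    # Gaussian band shapes on the grid: (bands, p)
    shapes = np.exp(
        -0.5 * ((grid[None, :] - basis.band_centers[:, None]) / basis.band_widths[:, None]) ** 2
    )
    X = amps @ shapes

    nu01 = (grid - grid.min()) / (grid.max() - grid.min())
    offset = rng.normal(0.0, basis.baseline_offset_sd, n)
    slope = rng.normal(0.0, basis.baseline_slope_sd, n)
    X += offset[:, None] + slope[:, None] * nu01[None, :]
    X += rng.normal(0.0, basis.noise_sd, (n, p))

    # Detector saturation: strong absorbers push these regions past the ceiling.
    for lo, hi in basis.saturation_regions:
        X[:, (grid >= lo) & (grid <= hi)] += basis.clip_max + 0.5
    np.clip(X, None, basis.clip_max, out=X)

    return pd.DataFrame(X, index=pd.Index(chem["sample_id"], name="sample_id"), columns=grid)


def simulate_effect_injection(
    design: pd.DataFrame,
    shares: dict | None = None,
    n_channels: int = 80,
    noise_sd: float = 0.004,
    seed: int = 0,
) -> np.ndarray:
    """Centered matrix with a known share of variance injected per effect.

    Each effect receives a rank-1 component lying exactly in its design
    subspace along its own orthonormal spectral direction, scaled so the
    component's sum of squares equals ``shares[effect]`` (total signal = 1),
    plus iid noise.  Default shares are deliberately strong relative to each
    effect's permutation null (which scales with subspace rank / (n - 1)),
    so every permutation p-value bottoms out at 1/B.  This is the
    ground-truth construction for decomposition-recovery and significance
    tests; it bypasses the oil forward model.
    """
    from .asca import EFFECT_NAMES, _effect_basis

    if shares is None:
        shares = {"time": 0.20, "temp": 0.08, "mat": 0.08,
                  "time:temp": 0.20, "temp:mat": 0.08, "mat:time": 0.34}
    rng = np.random.default_rng(seed)
    n = len(design)
    V, _ = np.linalg.qr(rng.normal(size=(n_channels, len(shares))))
    X = np.zeros((n, n_channels))
    for j, name in enumerate(EFFECT_NAMES):
        if name not in shares or shares[name] <= 0:
            continue
        C = _effect_basis(design, name)
        u = C @ rng.normal(size=C.shape[1])
        u /= np.linalg.norm(u)
        X += np.sqrt(shares[name]) * np.outer(u, V[:, j])
    X += noise_sd * rng.normal(size=(n, n_channels))
    return X


def simulate_dataset(
    spec: DesignSpec = DesignSpec(),
    params: OxidationParams = OxidationParams(),
    basis: SpectralBasis = SpectralBasis(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: (design, chemistry, spectra) from one seed."""
    ss = np.random.SeedSequence(seed)
    chem_seed, spec_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    design = generate_design(spec)
    chem = simulate_chemistry(design, params, seed=chem_seed)
    spectra = simulate_spectra(chem, basis, seed=spec_seed)
    return design, chem, spectra
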