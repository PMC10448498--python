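"""Synthetic frame-stack generator with per-emitter ground truth.

Emulates camera frames of freely diffusing upconversion-nanoparticle (UCNP)
bioconjugates imaged through a dispersive prism: sparse spot patterns of
single Tm-biotin particles, single Er-streptavidin particles, and their
Tm-Er bioaffinity clusters on a dark background.  Per-frame emitter counts
are Poisson with mean set by molar concentration and the effective detection
volume (a thin disc in the focal plane); each emitter renders its
filter-dependent spot pattern as Gaussian PSF peaks with lognormal
brightness, then Poisson shot noise and Gaussian read noise are applied.

Spot separations default to measured values (Tm 30.2 px full spectrum,
Er 9.4 px, Tm-Er cluster 6.5 px under a 600 nm long-pass filter) rather
than being derived from the optics module, because the effective centroid of
the Er green multi-line band makes the physics prediction ambiguous; the
optics module remains available for wavelength assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .optics import CameraGeometry, field_width

__all__ = [
    "N_A",
    "FilterConfig",
    "SpeciesSpec",
    "DetectionSlab",
    "NoiseSpec",
    "FrameStack",
    "expected_emitters",
    "tm_biotin_spec",
    "er_streptavidin_spec",
    "cluster_spec",
    "default_species",
    "render_frame",
    "simulate_stack",
    "simulate_dilution_series",
    "cluster_fraction",
    "simulate_dose_response",
    "sample_dose_response_counts",
    "true_pair_counts",
    "sample_spot_intensities",
]

#: Avogadro constant, 1/mol.
N_A = 6.02214076e23

# Measured spot-pair separations (px) used as species defaults.
TM_FULL_SEPARATION_PX = 30.2   # 450 vs 802 nm, full spectrum
ER_FULL_SEPARATION_PX = 9.4    # 554 vs 660 nm, full spectrum
CLUSTER_LP_SEPARATION_PX = 6.5  # 660 vs 802 nm, 600 nm long-pass

TRUTH_COLUMNS = [
    "frame", "emitter_id", "species", "n_mer",
    "row", "col", "spot_index", "d_row", "d_col", "photons",
]


@dataclass(frozen=True)
class FilterConfig:
    """Emission filter in front of the prism.

    mode is one of ``full`` (no extra filter), ``bandpass`` (center and
    half-width in nm) or ``longpass`` (cutoff in nm).
    """

    mode: str = "longpass"
    center_nm: float | None = None
    half_width_nm: float | None = None
    cutoff_nm: float | None = 600.0

    def __post_init__(self) -> None:
        if self.mode not in ("full", "bandpass", "longpass"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.mode == "bandpass":
            if not self.center_nm or not self.half_width_nm or self.half_width_nm <= 0:
                raise ValueError("bandpass filter needs center and positive half-width")
        if self.mode == "longpass" and not self.cutoff_nm:
            raise ValueError("longpass filter needs a cutoff wavelength")

    def passes(self, wavelength_nm: float) -> bool:
        if self.mode == "full":
            return True
        if self.mode == "longpass":
            return wavelength_nm >= float(self.cutoff_nm)
        return abs(wavelength_nm - float(self.center_nm)) <= float(self.half_width_nm)


@dataclass(frozen=True)
class SpeciesSpec:
    """One simulated particle species and its dispersed spot pattern.

    ``spot_offsets_px`` lists (d_row, d_col, relative_intensity) for each
    spot of the pattern, relative to the emitter's nominal position.
    ``brightness_mean`` is the mean integrated photon count of a
    unit-intensity spot per exposure; per-emitter brightness is lognormal
    with coefficient of variation ``brightness_cv`` and scales linearly with
    the aggregation multiplicity n_mer.  ``monomer_fraction`` sets the share
    of emitters with n_mer = 1.
    """

    name: str
    spot_offsets_px: tuple[tuple[float, float, float], ...]
    brightness_mean: float = 2000.0
    brightness_cv: float = 0.25
    monomer_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.monomer_fraction <= 1.0:
            raise ValueError("monomer_fraction must be in [0, 1]")
        if any(rel <= 0 for _, _, rel in self.spot_offsets_px):
            raise ValueError("relative spot intensities must be positive")

    @property
    def n_spots(self) -> int:
        return len(self.spot_offsets_px)


def _pattern(separations_from_anchor: list[tuple[float, float]]) -> tuple:
    """Spots along the horizontal dispersion axis; anchor spot at (0, 0),
    shorter wavelengths at negative column offsets."""
    return tuple((0.0, -d, rel) for d, rel in separations_from_anchor)


def tm_biotin_spec(filt: FilterConfig, **kw) -> SpeciesSpec:
    """UCNP-Tm-biotin: 450/802 nm emission; double spot at 30.2 px in full
    spectrum, single 802 nm spot under the 600 nm long-pass."""
    if filt.mode == "longpass":
        offsets = _pattern([(0.0, 1.0)])
    else:
        offsets = _pattern([(0.0, 1.0), (TM_FULL_SEPARATION_PX, 0.8)])
    kw.setdefault("monomer_fraction", 0.77)
    return SpeciesSpec("tm_biotin", offsets, **kw)


def er_streptavidin_spec(filt: FilterConfig, **kw) -> SpeciesSpec:
    """UCNP-Er-streptavidin: 554/660 nm emission; double spot at 9.4 px in
    full spectrum, single 660 nm spot under the 600 nm long-pass."""
    if filt.mode == "longpass":
        offsets = _pattern([(0.0, 1.0)])
    else:
        offsets = _pattern([(0.0, 1.0), (ER_FULL_SEPARATION_PX, 0.9)])
    kw.setdefault("monomer_fraction", 0.81)
    return SpeciesSpec("er_streptavidin", offsets, **kw)


def cluster_spec(filt: FilterConfig, **kw) -> SpeciesSpec:
    """Tm-Er bioaffinity cluster.

    Under the 600 nm long-pass filter the cluster is the two-spot pattern
    (802 nm Tm + 660 nm Er, 6.5 px apart) that the double-spot counter
    targets; in full spectrum it is the union of both double spots (4 spots).
    """
    if filt.mode == "longpass":
        offsets = _pattern([(0.0, 1.0), (CLUSTER_LP_SEPARATION_PX, 0.9)])
    else:
        offsets = _pattern([
            (0.0, 1.0),                                    # Tm 802
            (TM_FULL_SEPARATION_PX, 0.8),                  # Tm 450
            (CLUSTER_LP_SEPARATION_PX, 0.9),               # Er 660
            (CLUSTER_LP_SEPARATION_PX + ER_FULL_SEPARATION_PX, 0.8),  # Er 554
        ])
    kw.setdefault("monomer_fraction", 1.0)
    return SpeciesSpec("cluster", offsets, **kw)


def default_species(filt: FilterConfig) -> dict[str, SpeciesSpec]:
    return {
        "tm_biotin": tm_biotin_spec(filt),
        "er_streptavidin": er_streptavidin_spec(filt),
        "cluster": cluster_spec(filt),
    }


@dataclass(frozen=True)
class DetectionSlab:
    """Effective detection volume: a disc in the focal plane.

    Defaults: diameter 111 um (the field of view) and thickness 0.7 um
    (the effective focal slab).  Emitters outside the slab are not rendered
    (binary in/out; the axial intensity profile is not modeled).
    """

    disc_diameter_um: float = 111.0
    thickness_um: float = 0.7

    def __post_init__(self) -> None:
        if self.disc_diameter_um <= 0 or self.thickness_um <= 0:
            raise ValueError("slab dimensions must be positive")

    @property
    def volume_fL(self) -> float:
        """Slab volume in fL (1 um^3 = 1 fL)."""
        return math.pi * (self.disc_diameter_um / 2.0) ** 2 * self.thickness_um

    @classmethod
    def for_geometry(cls, geom: CameraGeometry, thickness_um: float = 0.7) -> "DetectionSlab":
        return cls(disc_diameter_um=field_width(geom), thickness_um=thickness_um)


@dataclass(frozen=True)
class NoiseSpec:
    """Camera noise model: flat background (counts/px) entering the Poisson
    shot noise together with the signal, plus additive Gaussian read noise."""

    background: float = 100.0
    read_noise_sd: float = 2.0


@dataclass
class FrameStack:
    """A stack of synthetic camera frames with acquisition metadata."""

    frames: np.ndarray  # (n_frames, H, W) uint16
    geometry: CameraGeometry
    filter: FilterConfig
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.frames.dtype != np.uint16:
            raise ValueError("frames must be uint16")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def expected_emitters(concentration_mol_per_L: float, volume_fL: float) -> float:
    """Mean emitter count in a sampled volume: c * N_A * V.

    ``concentration_mol_per_L`` in mol/L, ``volume_fL`` in fL (1e-15 L).
    At 10 pmol/L, 1000 fL holds ~6 particles on average.
    """
    if concentration_mol_per_L < 0:
        raise ValueError("concentration must be nonnegative")
    if volume_fL <= 0:
        raise ValueError("volume must be positive")
    return concentration_mol_per_L * N_A * volume_fL * 1e-15


# dimer:trimer:tetramer split of the aggregated fraction
_AGGREGATE_WEIGHTS = np.array([0.7, 0.2, 0.1])


def _sample_n_mer(rng: np.random.Generator, monomer_fraction: float, size: int) -> np.ndarray:
    n = np.ones(size, dtype=int)
    agg = rng.random(size) >= monomer_fraction
    k = agg.sum()
    if k:
        n[agg] = rng.choice([2, 3, 4], size=k, p=_AGGREGATE_WEIGHTS)
    return n


def _stamp_gaussian(img: np.ndarray, row: float, col: float, photons: float,
                    sigma: float) -> float:
    """Add a pixel-integrated Gaussian spot; returns photons actually
    deposited (pattern parts outside the frame are clipped)."""
    h, w = img.shape
    half = int(math.ceil(4 * sigma))
    r0, r1 = int(math.floor(row)) - half, int(math.floor(row)) + half + 1
    c0, c1 = int(math.floor(col)) - half, int(math.floor(col)) + half + 1
    r0c, r1c = max(r0, 0), min(r1, h)
    c0c, c1c = max(c0, 0), min(c1, w)
    if r0c >= r1c or c0c >= c1c:
        return 0.0
    rows = np.arange(r0c, r1c)
    cols = np.arange(c0c, c1c)
    s = sigma * math.sqrt(2.0)
    fr = 0.5 * (erf((rows + 0.5 - row) / s) - erf((rows - 0.5 - row) / s))
    fc = 0.5 * (erf((cols + 0.5 - col) / s) - erf((cols - 0.5 - col) / s))
    patch = photons * np.outer(fr, fc)
    img[r0c:r1c, c0c:c1c] += patch
    return float(patch.sum())


def render_frame(
    species_mix: list[tuple[SpeciesSpec, float]],
    slab: DetectionSlab,
    geom: CameraGeometry,
    filt: FilterConfig,
    psf_sigma_px: float = 1.3,
    noise: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | int | None = None,
    frame_index: int = 0,
    return_signal: bool = False,
):
    """Render one camera frame and its ground-truth spot table.

    Per species, the emitter count is Poisson with mean
    ``expected_emitters(concentration, slab.volume_fL)``; positions are
    uniform in the field disc (the slab's disc mapped to pixels); each
    emitter's spots are pixel-integrated Gaussians whose total photon count
    is lognormal (mean ``brightness_mean``, CV ``brightness_cv``) scaled by
    relative spot intensity and aggregation multiplicity.  The noiseless
    signal plus background receives Poisson shot noise, then Gaussian read
    noise, and is clipped to the 16-bit range.

    Returns the uint16 frame and a long-format truth table (one row per
    rendered spot) whose ``photons`` column holds the photons actually
    deposited, so that the truth sum equals the pre-noise signal sum exactly.
    """
    rng = np.random.default_rng(rng)
    h = w = geom.frame_size_px
    signal = np.zeros((h, w), dtype=float)
    scale_um_per_px = geom.pixel_pitch_um / geom.magnification
    disc_radius_px = min(slab.disc_diameter_um / scale_um_per_px / 2.0, w / 2.0)
    center = (h - 1) / 2.0

    rows_out = []
    emitter_id = 0
    for spec, conc in species_mix:
        if conc < 0:
            raise ValueError("concentrations must be nonnegative")
        mean = expected_emitters(conc, slab.volume_fL)
        count = rng.poisson(mean)
        if count == 0:
            continue
        # uniform in the disc
        r = disc_radius_px * np.sqrt(rng.random(count))
        phi = rng.uniform(0, 2 * math.pi, count)
        erow = center + r * np.sin(phi)
        ecol = center + r * np.cos(phi)
        n_mer = _sample_n_mer(rng, spec.monomer_fraction, count)
        # lognormal with mean brightness_mean and CV brightness_cv
        cv2 = spec.brightness_cv**2
        sig_ln = math.sqrt(math.log1p(cv2))
        mu_ln = math.log(spec.brightness_mean) - 0.5 * sig_ln**2
        base = rng.lognormal(mu_ln, sig_ln, count)
        for i in range(count):
            for j, (dr, dc, rel) in enumerate(spec.spot_offsets_px):
                photons = base[i] * rel * n_mer[i]
                dep = _stamp_gaussian(signal, erow[i] + dr, ecol[i] + dc,
                                      photons, psf_sigma_px)
                rows_out.append((frame_index, emitter_id, spec.name, int(n_mer[i]),
                                 erow[i], ecol[i], j, dr, dc, dep))
            emitter_id += 1

    expected = signal + noise.background
    frame = rng.poisson(expected).astype(float)
    if noise.read_noise_sd > 0:
        frame += rng.normal(0.0, noise.read_noise_sd, frame.shape)
    frame = np.clip(np.rint(frame), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(rows_out, columns=TRUTH_COLUMNS)
    if return_signal:
        return frame, truth, signal
    return frame, truth


def _frame_rng(master_seed: int, *stream_key: int) -> np.random.Generator:
    """Independent substream per (stack, frame) so stacks are reproducible
    under partial regeneration."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, stream_key)]))


def simulate_stack(
    species_mix: list[tuple[SpeciesSpec, float]],
    n_frames: int,
    slab: DetectionSlab,
    geom: CameraGeometry,
    filt: FilterConfig,
    psf_sigma_px: float = 1.3,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    stack_id: int = 0,
) -> tuple[FrameStack, pd.DataFrame]:
    """Render ``n_frames`` frames; deterministic for a fixed seed."""
    frames = np.zeros((n_frames, geom.frame_size_px, geom.frame_size_px),
                      dtype=np.uint16)
    truths = []
    for k in range(n_frames):
        rng = _frame_rng(seed, stack_id, k)
        frames[k], t = render_frame(species_mix, slab, geom, filt,
                                    psf_sigma_px, noise, rng, frame_index=k)
        truths.append(t)
    nonempty = [t for t in truths if len(t)]
    truth = (pd.concat(nonempty, ignore_index=True) if nonempty
             else pd.DataFrame(columns=TRUTH_COLUMNS))
    meta = {
        "seed": int(seed),
        "stack_id": int(stack_id),
        "n_frames": int(n_frames),
        "species": {s.name: float(c) for s, c in species_mix},
        "slab_volume_fL": slab.volume_fL,
        "psf_sigma_px": psf_sigma_px,
        "background": noise.background,
        "read_noise_sd": noise.read_noise_sd,
        "filter_mode": filt.mode,
    }
    return FrameStack(frames, geom, filt, meta), truth


def simulate_dilution_series(
    concentrations_mol_per_L: list[float],
    frames_per_level: int,
    species: SpeciesSpec | None = None,
    slab: DetectionSlab | None = None,
    geom: CameraGeometry | None = None,
    filt: FilterConfig | None = None,
    seed: int = 0,
    **render_kw,
) -> list[tuple[FrameStack, pd.DataFrame]]:
    """One stack per concentration level of a single double-spot species.

    Defaults emulate the dilution-series experiment: Er-streptavidin-like
    particles that show a double spot, imaged with shared geometry.  Levels
    may include blanks (concentration 0).
    """
    geom = geom or CameraGeometry()
    filt = filt or FilterConfig("full")
    slab = slab or DetectionSlab.for_geometry(geom)
    if species is None:
        # Er-streptavidin shows a 9.4 px double spot in full spectrum, so each
        # particle contributes one double-spot count
        species = er_streptavidin_spec(filt)
    out = []
    for lvl, conc in enumerate(concentrations_mol_per_L):
        if conc < 0:
            raise ValueError("concentrations must be nonnegative")
        stack, truth = simulate_stack([(species, conc)], frames_per_level,
                                      slab, geom, filt, seed=seed,
                                      stack_id=lvl, **render_kw)
        stack.metadata["concentration_mol_per_L"] = float(conc)
        out.append((stack, truth))
    return out


def cluster_fraction(biotin_mol_per_L: float, p_max: float, p_bg: float,
                     ic50_mol_per_L: float, slope: float) -> float:
    """Generator-side dose response: fraction of Tm-Er pairs that form
    bioaffinity clusters at a given free-biotin concentration.

    Four-parameter logistic in shape: p_bg + (p_max - p_bg) /
    (1 + (biotin/IC50)^S); free biotin competes for streptavidin sites, so
    the cluster fraction falls from p_max (no biotin) to p_bg (saturation).
    """
    if not (0.0 <= p_bg <= p_max <= 1.0):
        raise ValueError("need 0 <= p_bg <= p_max <= 1")
    if ic50_mol_per_L <= 0 or slope <= 0:
        raise ValueError("ic50 and slope must be positive")
    if biotin_mol_per_L < 0:
        raise ValueError("biotin concentration must be nonnegative")
    if biotin_mol_per_L == 0:
        return p_max
    return p_bg + (p_max - p_bg) / (1.0 + (biotin_mol_per_L / ic50_mol_per_L) ** slope)


def simulate_dose_response(
    biotin_levels_mol_per_L: list[float],
    cluster_model: tuple[float, float, float, float] = (0.9, 0.05, 17e-9, 1.5),
    base_concentration_mol_per_L: float = 10e-12,
    frames_per_level: int = 50,
    slab: DetectionSlab | None = None,
    geom: CameraGeometry | None = None,
    seed: int = 0,
    **render_kw,
) -> list[tuple[FrameStack, pd.DataFrame]]:
    """Competitive-assay frame stacks: at each biotin level a fraction of the
    Tm/Er particle pairs (set by :func:`cluster_fraction`) is rendered as
    two-spot clusters, the remainder as single-spot monomer species, under
    the 600 nm long-pass filter."""
    p_max, p_bg, ic50, s = cluster_model
    geom = geom or CameraGeometry()
    filt = FilterConfig("longpass", cutoff_nm=600.0)
    slab = slab or DetectionSlab.for_geometry(geom)
    cl = cluster_spec(filt)
    tm = tm_biotin_spec(filt)
    er = er_streptavidin_spec(filt)
    out = []
    for lvl, biotin in enumerate(biotin_levels_mol_per_L):
        f = cluster_fraction(biotin, p_max, p_bg, ic50, s)
        mix = [
            (cl, f * base_concentration_mol_per_L),
            (tm, (1 - f) * base_concentration_mol_per_L),
            (er, (1 - f) * base_concentration_mol_per_L),
        ]
        stack, truth = simulate_stack(mix, frames_per_level, slab, geom, filt,
                                      seed=seed, stack_id=lvl, **render_kw)
        stack.metadata["biotin_mol_per_L"] = float(biotin)
        stack.metadata["cluster_fraction"] = float(f)
        out.append((stack, truth))
    return out


def sample_dose_response_counts(
    biotin_levels_mol_per_L: np.ndarray,
    dsc_max: float,
    dsc_bg: float,
    ic50_mol_per_L: float,
    slope: float,
    noise_cv: float = 0.10,
    n_replicates: int = 2,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Count-level dose-response generator (no frame rendering).

    Mean DSC follows the four-parameter logistic; replicates get
    multiplicative Gaussian noise with coefficient of variation ``noise_cv``.
    Returns a table with per-level mean and SD over replicates.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for b in np.asarray(biotin_levels_mol_per_L, dtype=float):
        span = cluster_fraction(b, 1.0, 0.0, ic50_mol_per_L, slope)
        mean = dsc_bg + (dsc_max - dsc_bg) * span
        reps = mean * (1.0 + noise_cv * rng.standard_normal(n_replicates))
        reps = np.clip(reps, 0.0, None)
        rows.append((b, reps.mean(), reps.std(ddof=1), n_replicates))
    return pd.DataFrame(rows, columns=["biotin_mol_per_L", "dsc_mean", "dsc_sd",
                                       "n_replicates"])


def true_pair_counts(truth: pd.DataFrame, n_frames: int,
                     species: str | None = None) -> np.ndarray:
    """Per-frame count of true double-spot emitters in a truth table.

    An emitter counts as a double spot when its rendered pattern has exactly
    two spots (optionally restricted to one species).
    """
    counts = np.zeros(n_frames, dtype=int)
    if len(truth) == 0:
        return counts
    sel = truth if species is None else truth[truth.species == species]
    sel = sel[sel.frame < n_frames]
    per_emitter = sel.groupby(["frame", "emitter_id"]).size()
    pairs = per_emitter[per_emitter == 2]
    if len(pairs) == 0:
        return counts
    got = pairs.groupby(level="frame").size()
    counts[got.index.to_numpy()] = got.to_numpy()
    return counts


def sample_spot_intensities(
    n: int,
    unit_intensity: float = 2000.0,
    fractions: tuple[float, ...] = (0.8, 0.15, 0.05),
    cv: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spot-intensity sample for a partly aggregated particle population.

    A k-mer spot has mean intensity k * unit_intensity and fractional width
    ``cv``.  Returns (intensities, k) for use as ground truth in
    monomer-fraction estimation.
    """
    rng = np.random.default_rng(rng)
    p = np.asarray(fractions, dtype=float)
    p = p / p.sum()
    k = rng.choice(np.arange(1, len(p) + 1), size=n, p=p)
    vals = k * unit_intensity * (1.0 + cv * rng.standard_normal(n))
    return np.clip(vals, 1e-9, None), k
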