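"""Synthetic imaging-flow-cytometry data for gamma-H2AX biodosimetry.

Two generators share one statistical model:

* an image-level generator that renders per-event brightfield/fluorescence
  raster pairs (a lymphocyte nucleus with Poisson-distributed gamma-H2AX
  foci, plus apoptotic/debris contaminants), and
* a feature-level generator that emits per-sample (and optionally per-cell)
  endpoint tables directly, skipping rendering.

The dose response built in is the one the downstream analysis assumes:
mean fluorescence intensity (MFI) is affine in dose, ``alpha * D + beta``,
while spot count and spot area follow the saturating form
``v * (1 - exp(-xi * D))`` — at high dose foci crowd the 2-D nuclear
projection and merge, so detected-spot endpoints plateau even though total
fluorescence keeps rising.  In the image-level generator the saturation is
emergent (spatial overlap of rendered foci); in the feature-level generator
it is imposed through the saturating form directly.

All randomness flows through an explicit ``numpy.random.Generator`` so every
output is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationParams",
    "CellImage",
    "StudyDesign",
    "CALIBRATION_DOSES_GY",
    "simulate_cell_image",
    "simulate_contaminant_image",
    "simulate_sample_images",
    "simulate_feature_table",
    "simulate_calibration_study",
    "default_calibration_design",
    "validation_design",
    "substream",
]

#: Delivered dose points of the reference calibration design (Gy): two
#: non-irradiated controls and seven irradiated samples per donor.
CALIBRATION_DOSES_GY: tuple[float, ...] = (0.0, 0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive an independent, reproducible random stream for a named stage."""
    import zlib

    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for the synthetic IFC study.

    Parameters
    ----------
    alpha_true : float
        Increase in integrated gamma-H2AX fluorescence per Gy (a.u./Gy).
    beta_true : float
        Background fluorescence at 0 Gy (a.u.).
    focus_rate : float
        Expected number of true double-strand-break foci per cell per Gy.
    focus_sigma : float
        Radial spread of one rendered focus (pixels).
    nucleus_radius : int
        Nucleus disc radius in the rendered images (pixels).
    cell_noise_sd : float
        SD of per-cell multiplicative (log-normal, mean-one) noise.
    sample_noise_sd : float
        SD of per-sample technical noise (staining, handling, acquisition
        run), multiplicative and independent per endpoint.  Unlike cell
        noise it is not averaged away by acquiring more cells.
    donor_sd : float
        SD of the between-donor multiplicative (log-normal, mean-one) effect
        on MFI; spot-derived endpoints receive half this SD (staining
        efficiency varies between donors more than focus yield per Gy).
    contaminant_fraction : float
        Fraction of acquired events that are apoptotic cells or debris.
    cells_per_sample : int
        Gated lymphocytes acquired per sample.
    image_size : int
        Raster side length in pixels (square images).
    seed : int
        Default seed when no stream is supplied.
    spot_count_plateau, spot_count_rate : float
        Saturating spot-count response: plateau v (spots) and steepness
        xi (1/Gy) used by the feature-level generator.
    spot_area_plateau, spot_area_rate : float
        Same for total spot area (pixels^2 and 1/Gy).
    """

    alpha_true: float = 30.0
    beta_true: float = 100.0
    focus_rate: float = 2.5
    focus_sigma: float = 1.5
    nucleus_radius: int = 20
    cell_noise_sd: float = 0.15
    sample_noise_sd: float = 0.05
    donor_sd: float = 0.10
    contaminant_fraction: float = 0.05
    cells_per_sample: int = 3000
    image_size: int = 64
    seed: int = 0
    spot_count_plateau: float = 25.0
    spot_count_rate: float = 0.25
    spot_area_plateau: float = 120.0
    spot_area_rate: float = 0.22

    def __post_init__(self) -> None:
        for name in (
            "alpha_true",
            "focus_rate",
            "focus_sigma",
            "cell_noise_sd",
            "sample_noise_sd",
            "donor_sd",
            "beta_true",
            "spot_count_plateau",
            "spot_count_rate",
            "spot_area_plateau",
            "spot_area_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"SimulationParams.{name} must be >= 0, got {getattr(self, name)}")
        if not (0.0 <= self.contaminant_fraction < 1.0):
            raise ValueError(f"SimulationParams.contaminant_fraction must be in [0, 1), got {self.contaminant_fraction}")
        if self.cells_per_sample < 1:
            raise ValueError(f"SimulationParams.cells_per_sample must be >= 1, got {self.cells_per_sample}")
        if self.nucleus_radius >= self.image_size / 2:
            raise ValueError(
                f"SimulationParams.nucleus_radius ({self.nucleus_radius}) must be < image_size/2 ({self.image_size / 2})"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class CellImage:
    """One acquired event: paired brightfield and fluorescence rasters.

    ``truth`` holds ground-truth focus annotations, one ``(row, col,
    integrated_intensity)`` triple per rendered focus; it is present exactly
    when the image is simulated.
    """

    brightfield: np.ndarray
    fluorescence: np.ndarray
    truth: Optional[list[tuple[float, float, float]]] = None
    label: Literal["lymphocyte", "apoptotic", "debris"] = "lymphocyte"

    def __post_init__(self) -> None:
        if self.brightfield.shape != self.fluorescence.shape:
            raise ValueError("brightfield and fluorescence rasters must share a shape")
        if (self.brightfield < 0).any() or (self.fluorescence < 0).any():
            raise ValueError("image intensities must be >= 0")

    @property
    def true_focus_count(self) -> Optional[int]:
        return None if self.truth is None else len(self.truth)


@dataclass(frozen=True)
class StudyDesign:
    """Which donor provides which delivered dose.

    ``donors[i]`` and ``doses_gy[i]`` describe sample ``i``;
    ``is_control[i]`` marks the non-irradiated controls.
    """

    donors: tuple[str, ...]
    doses_gy: tuple[float, ...]
    is_control: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.doses_gy) == 0:
            raise ValueError("StudyDesign needs at least one sample")
        if len(self.donors) != len(self.doses_gy):
            raise ValueError("donors and doses_gy must have equal length")
        if any(d < 0 for d in self.doses_gy):
            raise ValueError("doses must be >= 0 Gy")
        if not self.is_control:
            object.__setattr__(self, "is_control", tuple(d == 0.0 for d in self.doses_gy))
        if len(self.is_control) != len(self.doses_gy):
            raise ValueError("is_control must match the number of samples")

    @property
    def n_samples(self) -> int:
        return len(self.doses_gy)

    @property
    def donor_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for d in self.donors:
            seen.setdefault(d, None)
        return tuple(seen)


def default_calibration_design(n_donors: int = 10) -> StudyDesign:
    """The reference 10-donor calibration design: per donor, two control
    samples plus 0.5, 1, 2, 4, 6, 8 and 10 Gy (nine samples per donor)."""
    donors, doses = [], []
    for i in range(n_donors):
        for d in CALIBRATION_DOSES_GY:
            donors.append(f"D{i + 1:02d}")
            doses.append(d)
    return StudyDesign(tuple(donors), tuple(doses))


def validation_design(
    n_samples: int = 75,
    n_donors: int = 9,
    dose_levels: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0),
    stream: Optional[np.random.Generator] = None,
) -> StudyDesign:
    """A blinded-validation design: ``n_samples`` samples from fresh donors,
    each irradiated at one of the calibration dose levels (balanced, then
    shuffled)."""
    stream = np.random.default_rng(0) if stream is None else stream
    reps = int(np.ceil(n_samples / len(dose_levels)))
    doses = np.tile(np.asarray(dose_levels, dtype=float), reps)[:n_samples]
    stream.shuffle(doses)
    donors = tuple(f"V{(i % n_donors) + 1:02d}" for i in range(n_samples))
    return StudyDesign(donors, tuple(doses))


# ---------------------------------------------------------------------------
# image-level generation
# ---------------------------------------------------------------------------


def _disc_mask(size: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _mean_one_lognormal(stream: np.random.Generator, sd: float, size=None):
    """Multiplicative noise with E[.] = 1 exactly when sd = 0."""
    if sd == 0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(stream.normal(-0.5 * sd**2, sd, size=size))


def _gaussian_bump(size: int, center: tuple[float, float], sigma: float, integral: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    g = np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2.0 * sigma**2))
    s = g.sum()
    return g * (integral / s) if s > 0 else g


def simulate_cell_image(
    dose_gy: float,
    params: SimulationParams,
    stream: Optional[np.random.Generator] = None,
) -> CellImage:
    """Render one healthy lymphocyte at the given dose.

    The true focus count is Poisson with mean ``focus_rate * dose_gy``; foci
    are placed uniformly inside the nucleus interior as 2-D Gaussian bumps,
    each carrying integrated intensity ``alpha_true / focus_rate`` so the
    expected integrated fluorescence is ``alpha_true * dose_gy + beta_true``.
    Ground truth records every focus even when two overlap spatially — the
    detector, not the generator, is what loses merged foci.
    """
    if dose_gy < 0:
        raise ValueError(f"dose_gy must be >= 0, got {dose_gy}")
    stream = params.rng() if stream is None else stream
    n = params.image_size
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    r = params.nucleus_radius

    nucleus = _disc_mask(n, center, r)

    bf = np.full((n, n), 0.05)
    bf[nucleus] = 1.0
    # mild internal texture; healthy lymphocytes are smooth relative to contaminants
    bf[nucleus] *= 1.0 + 0.02 * stream.standard_normal(int(nucleus.sum()))
    from scipy.ndimage import gaussian_filter

    bf = np.clip(gaussian_filter(bf, 1.0), 0.0, None)

    fl = np.zeros((n, n))
    area = float(nucleus.sum())
    if params.beta_true > 0:
        fl[nucleus] = params.beta_true / area

    n_foci = int(stream.poisson(params.focus_rate * dose_gy)) if params.focus_rate * dose_gy > 0 else 0
    truth: list[tuple[float, float, float]] = []
    inner = max(1.0, r - 4.0 - params.focus_sigma)  # keep foci inside the eroded nucleus
    per_focus = params.alpha_true / params.focus_rate if params.focus_rate > 0 else 0.0
    for _ in range(n_foci):
        while True:
            dr, dc = stream.uniform(-inner, inner, size=2)
            if dr * dr + dc * dc <= inner * inner:
                break
        fr, fc = center[0] + dr, center[1] + dc
        fl += _gaussian_bump(n, (fr, fc), params.focus_sigma, per_focus)
        truth.append((fr, fc, per_focus))

    fl *= _mean_one_lognormal(stream, params.cell_noise_sd)
    return CellImage(brightfield=bf, fluorescence=np.clip(fl, 0.0, None), truth=truth, label="lymphocyte")


def simulate_contaminant_image(
    kind: Literal["apoptotic", "debris"],
    params: SimulationParams,
    stream: Optional[np.random.Generator] = None,
    fluor_gain: float = 1.0,
) -> CellImage:
    """Render a non-lymphocyte event.

    Apoptotic cells appear as several bright condensed fragments; debris as a
    dim amorphous blob.  Both are markedly less circular and more textured
    than the lymphocyte renderer's output, which is what the healthy-cell
    classifier keys on.
    """
    if kind not in ("apoptotic", "debris"):
        raise ValueError(f"unknown contaminant kind: {kind!r}")
    stream = params.rng() if stream is None else stream
    n = params.image_size
    c = (n - 1) / 2.0
    bf = np.full((n, n), 0.05)
    fl = np.zeros((n, n))

    if kind == "apoptotic":
        n_frag = 3 + int(stream.poisson(2))
        spread = params.nucleus_radius
        for _ in range(n_frag):
            fr = c + stream.uniform(-spread, spread)
            fc = c + stream.uniform(-spread, spread)
            rad = stream.uniform(2.0, 4.5)
            m = _disc_mask(n, (fr, fc), rad)
            bf[m] = 1.0 + 0.3 * stream.random()
            # condensed chromatin fragments stain brightly
            fl += fluor_gain * _gaussian_bump(n, (fr, fc), rad, params.beta_true * stream.uniform(0.5, 1.5))
    else:  # debris: a ragged low-contrast blob built from a short random walk
        fr, fc = c, c
        for _ in range(8):
            fr += stream.uniform(-4, 4)
            fc += stream.uniform(-4, 4)
            rad = stream.uniform(2.0, 6.0)
            m = _disc_mask(n, (fr, fc), rad)
            bf[m] = 0.35 + 0.25 * stream.random()
        if fluor_gain > 0:
            fl[bf > 0.2] = fluor_gain * 0.02 * params.beta_true / max(1, (bf > 0.2).sum())

    from scipy.ndimage import gaussian_filter

    bf = np.clip(gaussian_filter(bf, 0.8) * (1.0 + 0.08 * stream.standard_normal((n, n))), 0.0, None)
    return CellImage(brightfield=bf, fluorescence=np.clip(fl, 0.0, None), truth=[], label=kind)


def simulate_sample_images(
    dose_gy: float,
    params: SimulationParams,
    stream: Optional[np.random.Generator] = None,
    n_cells: Optional[int] = None,
) -> list[CellImage]:
    """Render one sample's worth of events: ``n_cells`` lymphocytes plus
    contaminants injected at ``contaminant_fraction`` of total events."""
    stream = params.rng() if stream is None else stream
    n_cells = params.cells_per_sample if n_cells is None else n_cells
    images: list[CellImage] = []
    for _ in range(n_cells):
        if params.contaminant_fraction > 0 and stream.random() < params.contaminant_fraction:
            kind = "apoptotic" if stream.random() < 0.5 else "debris"
            images.append(simulate_contaminant_image(kind, params, stream))
        else:
            images.append(simulate_cell_image(dose_gy, params, stream))
    return images


# ---------------------------------------------------------------------------
# feature-level generation
# ---------------------------------------------------------------------------

PER_SAMPLE_COLUMNS = ["sample_id", "donor_id", "dose_gy", "mfi", "spot_count", "spot_area", "n_cells"]
PER_CELL_COLUMNS = [
    "sample_id",
    "donor_id",
    "dose_gy",
    "label",
    "mfi",
    "spot_count",
    "spot_area",
    "circularity",
    "texture_contrast",
    "gradient_rms_proxy",
    "area",
    "aspect_ratio",
]


def _saturating(dose: float, v: float, xi: float) -> float:
    return v * (1.0 - np.exp(-xi * dose))


def simulate_feature_table(
    design: StudyDesign,
    params: SimulationParams,
    stream: Optional[np.random.Generator] = None,
    per_cell: bool = False,
) -> pd.DataFrame:
    """Emit endpoint tables directly from the statistical model.

    Per sample: draws the donor effects (one per donor, shared across that
    donor's samples), then

    * ``mfi`` = donor_effect x (alpha_true * D + beta_true) x noise,
    * ``spot_count`` = donor_spot_effect x v_c (1 - exp(-xi_c D)) x noise,
    * ``spot_area``  = donor_spot_effect x v_a (1 - exp(-xi_a D)) x noise,

    where the per-sample noise combines two mean-one log-normal terms: the
    residual of per-cell noise after averaging ~``cells_per_sample`` cells
    (SD ``cell_noise_sd / sqrt(cells_per_sample)``) and technical
    sample-level noise (SD ``sample_noise_sd``, independent per endpoint).
    Multiplicative donor and sample noise make the absolute MFI scatter grow
    with dose — the high-dose heteroscedasticity the calibration-curve
    method struggles with.

    With ``per_cell=True`` returns one row per acquired event instead,
    including contaminant events at ``contaminant_fraction``.
    """
    stream = params.rng() if stream is None else stream
    sample_sd = float(
        np.sqrt(params.sample_noise_sd**2 + params.cell_noise_sd**2 / params.cells_per_sample)
    )

    mfi_eff = {d: _mean_one_lognormal(stream, params.donor_sd) for d in design.donor_ids}
    spot_eff = {d: _mean_one_lognormal(stream, params.donor_sd / 2.0) for d in design.donor_ids}

    rows = []
    for i, (donor, dose) in enumerate(zip(design.donors, design.doses_gy)):
        sid = f"S{i + 1:03d}"
        mfi = mfi_eff[donor] * (params.alpha_true * dose + params.beta_true) * _mean_one_lognormal(stream, sample_sd)
        cnt = (
            spot_eff[donor]
            * _saturating(dose, params.spot_count_plateau, params.spot_count_rate)
            * _mean_one_lognormal(stream, sample_sd)
        )
        ar = (
            spot_eff[donor]
            * _saturating(dose, params.spot_area_plateau, params.spot_area_rate)
            * _mean_one_lognormal(stream, sample_sd)
        )
        rows.append((sid, donor, dose, mfi, cnt, ar))

    if not per_cell:
        return pd.DataFrame(
            [(sid, d, dose, m, c, a, params.cells_per_sample) for sid, d, dose, m, c, a in rows],
            columns=PER_SAMPLE_COLUMNS,
        )

    cell_rows = []
    for sid, donor, dose, mfi_s, cnt_s, area_s in rows:
        n_lymph = params.cells_per_sample
        for _ in range(n_lymph):
            mfi_c = mfi_s * _mean_one_lognormal(stream, params.cell_noise_sd)
            k = int(stream.poisson(max(cnt_s, 0.0)))
            per_spot = area_s / cnt_s if cnt_s > 0 else 0.0
            area_c = float(k * per_spot * _mean_one_lognormal(stream, 0.2)) if k > 0 else 0.0
            cell_rows.append(
                (
                    sid,
                    donor,
                    dose,
                    "lymphocyte",
                    mfi_c,
                    k,
                    area_c,
                    float(np.clip(stream.normal(0.93, 0.03), 0.0, 1.0)),
                    abs(stream.normal(0.05, 0.02)),
                    abs(stream.normal(70.0, 5.0)),
                    abs(stream.normal(np.pi * params.nucleus_radius**2, 40.0)),
                    float(np.clip(stream.normal(0.92, 0.04), 0.0, 1.0)),
                )
            )
        if params.contaminant_fraction > 0:
            n_cont = int(round(n_lymph * params.contaminant_fraction / (1.0 - params.contaminant_fraction)))
            for _ in range(n_cont):
                kind = "apoptotic" if stream.random() < 0.5 else "debris"
                cell_rows.append(
                    (
                        sid,
                        donor,
                        dose,
                        kind,
                        mfi_s * stream.uniform(0.3, 2.0),
                        int(stream.poisson(1.0)),
                        abs(stream.normal(5.0, 3.0)),
                        float(np.clip(stream.normal(0.45, 0.12), 0.0, 1.0)),
                        abs(stream.normal(0.35, 0.08)),
                        abs(stream.normal(60.0, 15.0)),
                        abs(stream.normal(np.pi * params.nucleus_radius**2 * 0.7, 200.0)),
                        float(np.clip(stream.normal(0.7, 0.15), 0.0, 1.0)),
                    )
                )
    return pd.DataFrame(cell_rows, columns=PER_CELL_COLUMNS)


def simulate_calibration_study(
    params: SimulationParams,
    stream: Optional[np.random.Generator] = None,
    n_donors: int = 10,
    level: Literal["feature", "image"] = "feature",
    per_cell: bool = False,
):
    """Produce the default 10-donor calibration study.

    ``level='feature'`` returns the per-sample endpoint table (optionally
    per-cell).  ``level='image'`` returns ``(design, samples)`` where
    ``samples`` is a list of per-sample image lists, for routing through the
    imaging pipeline.
    """
    stream = params.rng() if stream is None else stream
    design = default_calibration_design(n_donors)
    if level == "feature":
        return design, simulate_feature_table(design, params, stream, per_cell=per_cell)
    if level == "image":
        samples = [simulate_sample_images(dose, params, stream) for dose in design.doses_gy]
        return design, samples
    raise ValueError(f"unknown level: {level!r}")
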