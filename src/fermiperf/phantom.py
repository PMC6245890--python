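"""Synthetic first-pass perfusion phantoms with known ground truth.

The generator emulates a dual-bolus stress/rest perfusion acquisition:
3 short-axis slices, 120 dynamics per slice, 1.9 mm pixels, a 1:10
diluted pre-bolus for the arterial input function, and an annular
left-ventricular myocardium whose pixel time-courses follow the Fermi
forward model with per-segment flow parameters.  Every downstream stage
(motion correction, contouring, deconvolution, ischemia calling) can be
tested against the returned :class:`GroundTruth`.

Also provides a reader-call simulator for the diagnostic-accuracy
statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .contours import TERRITORIES, segment_labels_from_radii
from .data import DynamicSeries, SampledCurve
from .exceptions import ConfigError, InvalidParameterError
from .kinetics import AifParams, FermiParams, make_aif, tissue_curve_values

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "make_phantom",
    "make_reader_calls",
    "DEFAULT_REST_MBF",
    "DEFAULT_STRESS_MBF",
]

#: Default true flows (arbitrary flow units; the time axis is seconds).
#: The rest/stress pair gives a healthy myocardial perfusion reserve of 3.
DEFAULT_REST_MBF = 1.0 / 60.0
DEFAULT_STRESS_MBF = 3.0 / 60.0

SLICE_ROLES = ("basal", "mid", "apical")


def _uniform_params(mbf: float, k: float = 0.25, tau0: float = 4.0,
                    td: float = 1.5) -> dict:
    return {seg: FermiParams.from_mbf(mbf, k=k, tau0=tau0, td=td)
            for seg in range(1, 17)}


@dataclass
class PhantomConfig:
    """Acquisition and anatomy parameters of the synthetic study.

    Defaults mirror the emulated protocol: 3 short-axis slices covering
    the 16 AHA segments, 120 dynamics per slice, 1.9 mm pixels, and a
    pre-bolus at 1/10 of the main contrast dose.
    """

    n_slices: int = 3
    n_frames: int = 120
    frame_interval: float = 0.5      # s between dynamics
    matrix: int = 72                 # square image size, pixels
    pixel_size: float = 1.9          # mm
    slice_thickness: float = 10.0    # mm
    endo_radius: float = 8.0         # pixels
    epi_radius: float = 14.0         # pixels
    baseline_signal: float = 1.0     # pre-contrast tissue/blood signal
    aif: AifParams = field(default_factory=lambda: AifParams(
        amplitude=4.0, onset=8.0, alpha=3.0, beta=2.0,
        recirculation_fraction=0.15, recirculation_delay=25.0, baseline=0.0))
    prebolus_dilution: float = 10.0  # main dose / pre-bolus dose
    segment_params_stress: dict = field(
        default_factory=lambda: _uniform_params(DEFAULT_STRESS_MBF))
    segment_params_rest: dict = field(
        default_factory=lambda: _uniform_params(DEFAULT_REST_MBF))
    noise_sd: float = 0.05           # additive Gaussian, signal units
    prebolus_noise_sd: float | None = None   # defaults to noise_sd
    motion_amplitude: float = 2.0    # pixels, respiratory-like drift
    motion_period: float = 5.0       # s
    dark_rim_enabled: bool = False
    dark_rim_factor: float = 0.6
    reference_angle: float = 90.0    # anterior RV insertion, degrees
    seed: int = 0

    def validate(self) -> None:
        if self.n_slices != 3:
            raise ConfigError("the 16-segment AHA model requires exactly 3 slices")
        if not (0 < self.endo_radius < self.epi_radius < self.matrix / 2):
            raise ConfigError(
                "radii must satisfy 0 < endo < epi < matrix/2 "
                "(got endo=%g, epi=%g, matrix=%d)"
                % (self.endo_radius, self.epi_radius, self.matrix))
        if self.n_frames < 2 or self.frame_interval <= 0:
            raise ConfigError("need >= 2 frames with a positive frame interval")
        if self.noise_sd < 0 or self.motion_amplitude < 0:
            raise ConfigError("noise_sd and motion_amplitude must be >= 0")
        if self.prebolus_dilution <= 0:
            raise ConfigError("prebolus_dilution must be positive")
        for d in (self.segment_params_stress, self.segment_params_rest):
            if sorted(d) != list(range(1, 17)):
                raise ConfigError("segment parameter maps must cover segments 1-16")

    def with_segment_mpr(self, mpr_by_segment: dict,
                         rest_mbf: float = DEFAULT_REST_MBF,
                         default_mpr: float = 3.0) -> "PhantomConfig":
        """Derived config with prescribed per-segment true MPR.

        Rest flow is uniform at ``rest_mbf``; stress flow per segment is
        ``mpr * rest_mbf`` (``default_mpr`` where unspecified).  Shape
        parameters (k, tau0, td) are kept at the rest defaults.
        """
        rest = _uniform_params(rest_mbf)
        stress = {}
        for seg in range(1, 17):
            mpr = float(mpr_by_segment.get(seg, default_mpr))
            rp = rest[seg]
            stress[seg] = FermiParams.from_mbf(mpr * rest_mbf, k=rp.k,
                                               tau0=rp.tau0, td=rp.td)
        return replace(self, segment_params_rest=rest,
                       segment_params_stress=stress)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class GroundTruth:
    """Everything the generator knows about a phantom."""

    config: PhantomConfig
    label_maps: np.ndarray            # (slice, row, col) AHA labels, 0=bg
    blood_pool_mask: np.ndarray       # (slice, row, col) bool, pure blood
    myocardium_mask: np.ndarray       # (slice, row, col) bool, full ring
    pure_myocardium_mask: np.ndarray  # bool, pixels free of partial volume
    center: tuple                     # (row, col) LV centre, all slices
    mbf_stress: dict                  # segment -> true h(0)
    mbf_rest: dict
    mpr: dict
    ischemic: dict                    # segment -> bool (MPR < 1.5, strict)
    territory_status: dict            # LAD/RCA/LCX -> bool
    patient_status: bool
    frame_translations: np.ndarray    # (n_frames, 2) applied (drow, dcol)
    aif_bolus: SampledCurve           # baseline-free main-bolus AIF
    tissue_curves_stress: dict        # segment -> noiseless enhancement
    tissue_curves_rest: dict

    def true_tissue_curve(self, segment: int, phase: str = "stress") -> SampledCurve:
        src = self.tissue_curves_stress if phase == "stress" else self.tissue_curves_rest
        return SampledCurve(self.aif_bolus.times, src[segment])


def _motion_trace(config: PhantomConfig) -> np.ndarray:
    """Smooth respiratory-like per-frame translations, zero at frame 0."""
    t = config.frame_times
    a = config.motion_amplitude
    w = 2 * np.pi / config.motion_period
    dcol = a * np.sin(w * t)
    drow = 0.6 * a * np.sin(0.5 * w * t)
    return np.stack([drow, dcol], axis=1)


def _render_series(config: PhantomConfig, bolus: np.ndarray,
                   tissue_by_segment: dict, render_labels: np.ndarray,
                   weights: tuple, translations: np.ndarray,
                   noise_sd: float, rng: np.random.Generator,
                   name: str) -> DynamicSeries:
    w_blood, w_myo, w_base = weights   # (row, col) partial-volume weights
    n_sl, rows, cols = render_labels.shape
    n_fr = config.n_frames
    data = np.zeros((n_sl, n_fr, rows, cols))
    for sl in range(n_sl):
        stack = np.empty((n_fr, rows, cols))
        stack[:] = config.baseline_signal * w_base
        stack += bolus[:, None, None] * w_blood
        for seg in np.unique(render_labels[sl]):
            if seg == 0:
                continue
            m = render_labels[sl] == seg
            stack[:, m] += np.outer(tissue_by_segment[int(seg)], w_myo[m])
        if config.dark_rim_enabled:
            radius = _radius_map(config)
            rim = (render_labels[sl] > 0) & (radius < config.endo_radius + 1.0)
            peak_f = int(np.argmax(bolus))
            f0, f1 = max(0, peak_f - 2), min(n_fr, peak_f + 3)
            stack[f0:f1, rim] *= config.dark_rim_factor
        data[sl] = stack
    if translations is not None and np.any(translations != 0):
        for f in range(n_fr):
            if np.any(translations[f] != 0):
                for sl in range(n_sl):
                    data[sl, f] = ndimage.shift(
                        data[sl, f], translations[f], order=1, mode="nearest")
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return DynamicSeries(data, config.frame_times, config.pixel_size,
                         config.slice_thickness, name=name)


def _radius_map(config: PhantomConfig) -> np.ndarray:
    c = (config.matrix - 1) / 2.0
    rr, cc = np.indices((config.matrix, config.matrix))
    return np.hypot(rr - c, cc - c)


def make_phantom(config: PhantomConfig | None = None):
    """Generate stress, rest and pre-bolus series plus ground truth.

    With zero noise and motion, every myocardial pixel's time-course is
    exactly ``baseline + make_tissue_curve`` for its segment, the blood
    pool follows the AIF, and the pre-bolus series carries the bolus
    scaled by ``1/prebolus_dilution``.  Identical seeds give
    bit-identical output.

    Returns
    -------
    (stress, rest, prebolus, truth) :
        Three :class:`DynamicSeries` and a :class:`GroundTruth`.
    """
    config = config or PhantomConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = config.frame_times
    center = ((config.matrix - 1) / 2.0, (config.matrix - 1) / 2.0)
    shape = (config.matrix, config.matrix)

    label_maps = np.stack([
        segment_labels_from_radii(shape, center, config.endo_radius,
                                  config.epi_radius, role,
                                  config.reference_angle)
        for role in SLICE_ROLES])
    # render labels extend half a pixel each way to cover the 1-px
    # partial-volume transition bands
    render_labels = np.stack([
        segment_labels_from_radii(shape, center, config.endo_radius - 0.5,
                                  config.epi_radius + 0.5, role,
                                  config.reference_angle)
        for role in SLICE_ROLES])
    radius = _radius_map(config)
    s_endo = np.clip(radius - (config.endo_radius - 0.5), 0.0, 1.0)
    s_epi = np.clip(radius - (config.epi_radius - 0.5), 0.0, 1.0)
    weights = (1.0 - s_endo,            # blood
               s_endo * (1.0 - s_epi),  # myocardium
               1.0 - s_epi)             # baseline-bearing tissue
    blood_mask = np.stack([(radius < config.endo_radius - 0.5)]
                          * config.n_slices)
    myo_mask = label_maps > 0
    pure_myo = np.stack([(radius >= config.endo_radius + 0.5)
                         & (radius <= config.epi_radius - 0.5)]
                        * config.n_slices) & myo_mask

    bolus_params = replace(config.aif, baseline=0.0)
    bolus = make_aif(bolus_params, times).values
    prebolus_vals = bolus / config.prebolus_dilution

    def tissue_dict(params_by_seg, scale=1.0):
        return {seg: tissue_curve_values(bolus * scale, times, p)
                for seg, p in params_by_seg.items()}

    tissue_stress = tissue_dict(config.segment_params_stress)
    tissue_rest = tissue_dict(config.segment_params_rest)
    tissue_pre = tissue_dict(config.segment_params_rest,
                             scale=1.0 / config.prebolus_dilution)

    translations = _motion_trace(config)
    pre_sd = config.noise_sd if config.prebolus_noise_sd is None \
        else config.prebolus_noise_sd

    stress = _render_series(config, bolus, tissue_stress, render_labels,
                            weights, translations, config.noise_sd, rng,
                            "stress")
    rest = _render_series(config, bolus, tissue_rest, render_labels,
                          weights, translations, config.noise_sd, rng,
                          "rest")
    prebolus = _render_series(config, prebolus_vals, tissue_pre, render_labels,
                              weights, translations, pre_sd, rng,
                              "prebolus")

    mbf_stress = {s: p.mbf for s, p in config.segment_params_stress.items()}
    mbf_rest = {s: p.mbf for s, p in config.segment_params_rest.items()}
    mpr = {s: mbf_stress[s] / mbf_rest[s] for s in mbf_stress}
    ischemic = {s: mpr[s] < 1.5 for s in mpr}
    territory_status = {t: any(ischemic[s] for s in segs)
                        for t, segs in TERRITORIES.items()}
    patient_status = any(territory_status.values())

    truth = GroundTruth(
        config=config, label_maps=label_maps, blood_pool_mask=blood_mask,
        myocardium_mask=myo_mask, pure_myocardium_mask=pure_myo,
        center=center, mbf_stress=mbf_stress,
        mbf_rest=mbf_rest, mpr=mpr, ischemic=ischemic,
        territory_status=territory_status, patient_status=patient_status,
        frame_translations=translations,
        aif_bolus=SampledCurve(times, bolus),
        tissue_curves_stress=tissue_stress, tissue_curves_rest=tissue_rest)
    return stress, rest, prebolus, truth


def make_reader_calls(n_patients: int, prevalence: float, sens: float,
                      spec: float, seed: int = 0,
                      reader: str = "reader") -> pd.DataFrame:
    """Simulate one reader's dichotomous calls against Bernoulli truth.

    Truth is drawn at ``prevalence``; for true positives the call is
    positive with probability ``sens``, for true negatives negative with
    probability ``spec``.  Reproducible by ``seed``.
    """
    for name, v in (("prevalence", prevalence), ("sens", sens), ("spec", spec)):
        if not (0.0 <= v <= 1.0):
            raise InvalidParameterError("%s must be in [0, 1]" % name)
    if n_patients <= 0:
        raise InvalidParameterError("n_patients must be positive")
    rng = np.random.default_rng(seed)
    truth = rng.random(n_patients) < prevalence
    u = rng.random(n_patients)
    call = np.where(truth, u < sens, u >= spec)
    return pd.DataFrame({
        "patient_id": np.arange(n_patients),
        "truth": truth.astype(int),
        "call": call.astype(int),
        "group": reader,
    })
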