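"""End-to-end perfusion study: the :class:`PerfusionStudy` model and its
:class:`PerfusionResults`.

Stages run in fixed order: motion correction -> contour delineation (or
manual override) -> dual-bolus AIF extraction and quality control ->
pixel-wise Fermi deconvolution of stress and rest -> segment MBF/MPR
summary -> territory and patient ischemia calls.  A failed AIF QC stops
the pipeline with status ``quantification-failed`` and no flow output —
the behaviour observed for degraded pre-bolus acquisitions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import contours as ct
from . import io as fio
from . import motion as mo
from . import quant as qt
from .data import DynamicSeries
from .exceptions import ConfigError, FermiperfError
from .quant import Aif, MbfMap, SegmentTable

__all__ = ["PipelineConfig", "PerfusionStudy", "PerfusionResults",
           "run_pipeline"]

log = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_QC_FAILED = "quantification-failed"


@dataclass
class PipelineConfig:
    """Paths and options of one quantitative perfusion analysis."""

    stress_path: str = ""
    rest_path: str = ""
    prebolus_path: str = ""
    contours_path: str | None = None
    out_dir: str | None = None
    dilution: float = qt.DEFAULT_DILUTION
    qc_min_quality: float = qt.DEFAULT_MIN_QUALITY
    n_baseline_frames: int = 5
    fit_window: tuple | None = None      # frame (start, stop); None = arrival-to-end
    presmooth: bool = False
    segment_statistic: str = "median"    # 'median' or 'mean'
    mpr_threshold: float = 1.5
    min_ischemic_segments: int = 1
    motion_correction: bool = True
    independent_contours: bool = False   # delineate rest separately
    reference_angle: float = 90.0
    slice_roles: tuple = ("basal", "mid", "apical")
    seed: int = 0

    def validate_paths(self) -> None:
        for label, p in (("stress", self.stress_path), ("rest", self.rest_path),
                         ("prebolus", self.prebolus_path)):
            if not p or not Path(p).exists():
                raise ConfigError("%s series path does not exist: %r" % (label, p))
        if self.contours_path and not Path(self.contours_path).exists():
            raise ConfigError("contours path does not exist: %r"
                              % self.contours_path)

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load a YAML/JSON config document; keyword overrides win."""
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError("unknown config keys: %s" % sorted(unknown))
        if "slice_roles" in payload:
            payload["slice_roles"] = tuple(payload["slice_roles"])
        if "fit_window" in payload and payload["fit_window"] is not None:
            payload["fit_window"] = tuple(payload["fit_window"])
        return cls(**payload)


class PerfusionStudy:
    """A dual-bolus stress/rest perfusion study to be quantified.

    Statsmodels-style model object: construct from in-memory series (or
    :meth:`from_paths`), then :meth:`fit` to obtain
    :class:`PerfusionResults`.
    """

    def __init__(self, stress: DynamicSeries, rest: DynamicSeries,
                 prebolus: DynamicSeries,
                 config: PipelineConfig | None = None,
                 manual_contours=None):
        for name, s in (("stress", stress), ("rest", rest),
                        ("prebolus", prebolus)):
            if s.n_slices != len((config or PipelineConfig()).slice_roles):
                raise ConfigError("%s series has %d slices; expected %d"
                                  % (name, s.n_slices,
                                     len((config or PipelineConfig()).slice_roles)))
        self.stress = stress
        self.rest = rest
        self.prebolus = prebolus
        self.config = config or PipelineConfig()
        self.manual_contours = manual_contours

    @classmethod
    def from_paths(cls, config: PipelineConfig) -> "PerfusionStudy":
        config.validate_paths()
        stress = fio.read_series(config.stress_path)
        rest = fio.read_series(config.rest_path)
        prebolus = fio.read_series(config.prebolus_path)
        manual = fio.read_contours(config.contours_path) \
            if config.contours_path else None
        return cls(stress, rest, prebolus, config, manual)

    # -- stages ---------------------------------------------------------
    def _correct(self, series: DynamicSeries):
        if not self.config.motion_correction:
            return series, None
        corrected, transforms = mo.register_series(series)
        return corrected, transforms

    def fit(self) -> "PerfusionResults":
        cfg = self.config
        stage = "motion"
        try:
            stress, tf_stress = self._correct(self.stress)
            rest, tf_rest = self._correct(self.rest)
            prebolus, tf_pre = self._correct(self.prebolus)

            stage = "contours"
            auto = ct.delineate_series(stress, cfg.reference_angle)
            stress_contours = ct.override_contours(auto, self.manual_contours)
            if cfg.independent_contours:
                rest_contours = ct.override_contours(
                    ct.delineate_series(rest, cfg.reference_angle),
                    self.manual_contours)
            else:
                rest_contours = stress_contours
            shape = stress.spatial_shape
            segmap = ct.build_segment_map(stress_contours, cfg.slice_roles,
                                          shape)

            stage = "aif"
            pool = ct.blood_pool_mask(stress_contours, shape)
            aif = qt.extract_aif(prebolus, pool, cfg.dilution,
                                 cfg.n_baseline_frames)
            if not qt.qc_aif(aif, cfg.qc_min_quality):
                log.warning("AIF quality %.2f below threshold %.2f: "
                            "quantification failed", aif.quality,
                            cfg.qc_min_quality)
                return PerfusionResults(
                    self, status=STATUS_QC_FAILED, aif=aif,
                    contours=stress_contours, segment_map=segmap,
                    transforms={"stress": tf_stress, "rest": tf_rest,
                                "prebolus": tf_pre})

            stage = "pixelwise-mbf"
            window = slice(*cfg.fit_window) if cfg.fit_window else None
            stress_mask = segmap.labels > 0
            rest_mask = stress_mask if not cfg.independent_contours else \
                ct.myocardium_mask(rest_contours, shape)
            stress_map = qt.pixelwise_mbf(stress, aif, stress_mask,
                                          cfg.n_baseline_frames,
                                          cfg.presmooth, window)
            rest_map = qt.pixelwise_mbf(rest, aif, rest_mask,
                                        cfg.n_baseline_frames,
                                        cfg.presmooth, window)

            stage = "segment-summary"
            seg_table = qt.segment_summary(stress_map, rest_map, segmap,
                                           cfg.segment_statistic,
                                           cfg.mpr_threshold,
                                           cfg.min_ischemic_segments)
        except FermiperfError as exc:
            raise type(exc)("stage %r: %s" % (stage, exc)) from exc

        return PerfusionResults(
            self, status=STATUS_OK, aif=aif, contours=stress_contours,
            segment_map=segmap, stress_map=stress_map, rest_map=rest_map,
            segment_table=seg_table,
            transforms={"stress": tf_stress, "rest": tf_rest,
                        "prebolus": tf_pre})


@dataclass
class PerfusionResults:
    """Fitted outputs of a :class:`PerfusionStudy`."""

    model: PerfusionStudy
    status: str
    aif: Aif | None = None
    contours: object = None
    segment_map: object = None
    stress_map: MbfMap | None = None
    rest_map: MbfMap | None = None
    segment_table: SegmentTable | None = None
    transforms: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK

    @property
    def patient_call(self):
        return self.segment_table.patient_call if self.ok else None

    @property
    def territory_calls(self):
        return self.segment_table.territory_calls if self.ok else None

    def summary(self) -> str:
        lines = ["Quantitative perfusion analysis",
                 "=" * 44,
                 "status:        %s" % self.status]
        if self.aif is not None:
            q = self.aif.quality
            lines += ["AIF quality:   %s" % ("inf" if np.isinf(q)
                                             else "%.2f" % q),
                      "AIF arrival:   %s s" % (
                          "%.1f" % self.aif.arrival_time
                          if self.aif.arrival_defined else "undetected")]
        if self.ok:
            lines += ["", self.segment_table.summary()]
        else:
            lines += ["no MBF output (pre-bolus AIF failed quality control)"]
        return "\n".join(lines)

    def to_payload(self) -> dict:
        payload = {"status": self.status,
                   "config": {k: (list(v) if isinstance(v, tuple) else v)
                              for k, v in asdict(self.model.config).items()}}
        if self.aif is not None:
            q = float(self.aif.quality)
            payload["aif"] = {
                "quality": None if np.isinf(q) else q,
                "quality_is_infinite": bool(np.isinf(q)),
                "arrival_time_s": (self.aif.arrival_time
                                   if self.aif.arrival_defined else None),
                "dilution": self.aif.dilution,
            }
        if self.ok:
            payload["patient_call"] = bool(self.patient_call)
            payload["territory_calls"] = {
                k: bool(v) for k, v in self.territory_calls.items()}
            t = self.segment_table.table.reset_index()
            payload["segments"] = json.loads(
                t.to_json(orient="records", double_precision=10))
        return payload

    def save(self, out_dir) -> Path:
        """Write all artifacts (summary JSON, segment CSV, contours,
        maps, transforms) to a directory; returns the directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fio.write_json(self.to_payload(), out / "result.json")
        if self.contours is not None:
            fio.write_contours(self.contours, out / "contours.json")
        if self.segment_map is not None:
            fio.write_segment_map(self.segment_map, out / "segments.nii",
                                  out / "segments_legend.csv")
        if self.ok:
            fio.write_segment_table(self.segment_table,
                                    out / "segment_table.csv")
            import nibabel as nib
            for name, mp in (("mbf_stress", self.stress_map),
                             ("mbf_rest", self.rest_map)):
                vol = np.transpose(mp.mbf, (2, 1, 0))
                nib.save(nib.Nifti1Image(vol, np.eye(4)),
                         str(out / ("%s.nii" % name)))
        self._save_transforms(out / "transforms.csv")
        return out

    def _save_transforms(self, path) -> None:
        import pandas as pd
        rows = []
        for series, tfs in self.transforms.items():
            if tfs is None:
                continue
            for sl, per_slice in enumerate(tfs):
                for f, tf in enumerate(per_slice):
                    m = tf.M
                    rows.append({"series": series, "slice": sl, "frame": f,
                                 "m00": m[0, 0], "m01": m[0, 1],
                                 "m10": m[1, 0], "m11": m[1, 1],
                                 "t_row": tf.t[0], "t_col": tf.t[1]})
        if rows:
            pd.DataFrame(rows).to_csv(path, index=False)

    def plot_mbf_maps(self, path=None):
        """Stress/rest MBF maps per slice (matplotlib figure)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if not self.ok:
            raise FermiperfError("no maps to plot: status %s" % self.status)
        n_sl = self.stress_map.mbf.shape[0]
        fig, axes = plt.subplots(2, n_sl, figsize=(3 * n_sl, 6))
        for row, (label, mp) in enumerate((("stress", self.stress_map),
                                           ("rest", self.rest_map))):
            for sl in range(n_sl):
                ax = axes[row, sl]
                im = ax.imshow(mp.mbf[sl], interpolation="nearest")
                ax.set_title("%s slice %d" % (label, sl))
                ax.axis("off")
                fig.colorbar(im, ax=ax, fraction=0.046)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=110)
            plt.close(fig)
        return fig


def run_pipeline(config: PipelineConfig) -> PerfusionResults:
    """Load inputs, fit the study and write artifacts to
    ``config.out_dir`` (if set).  Deterministic: the same config and
    inputs produce byte-identical CSV/JSON outputs."""
    study = PerfusionStudy.from_paths(config)
    results = study.fit()
    if config.out_dir:
        results.save(config.out_dir)
    return results
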