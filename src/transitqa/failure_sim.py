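"""Synthetic transit-dosimetry scenario generator.

A deliberately simple forward model of EPID transit imaging: the in-air
fluence of a (possibly modulated) beam aperture, blurred by a Gaussian
penumbra, attenuated exponentially by the water-equivalent thickness of the
patient along each ray,

    D(x, y) = k . MU . [aperture (x) Gaussian(sigma)](x, y) . exp(-mu . t_eff(x, y)),

with ``t_eff`` the density-weighted thickness. On top of this model the
generator builds the study suite: base/erroneous transit dose-image pairs
for five failure modes — linac hardware errors (MLC aperture, collimator
angle, MU, and the fully retracted MLC of the New York incident), breathing
phase mismatches, patient swaps, wrong/outdated CT (pleural fluid change),
and a missing bolus — 22 erroneous scenarios in the default configuration.

Each scenario carries a surrogate PTV mean-dose change: the mean over the
projected PTV of the same forward model evaluated at *mid-depth*
(``t_eff / 2``), the erroneous value computed with the delivered beam and
anatomy. The surrogate is exactly linear in MU and monotone in attenuation
changes, which is all the downstream ROC labeling needs; it does not emulate
TPS dose-volume metrics.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, shift as nd_shift

from .dose_image import DoseImage, read_dose_plane, write_dose_plane
from .plan_perturbation import Beam, ControlPoint, PlanError, perturb_plan, project_aperture

__all__ = [
    "PatientModel",
    "BeamModel",
    "Scenario",
    "SuiteConfig",
    "DegenerateScenarioError",
    "transit_dose",
    "surrogate_ptv_dmean",
    "apply_linac_error",
    "apply_anatomy_error",
    "generate_suite",
    "export_suite",
    "load_suite",
    "sub_seed",
]

DEFAULT_GRID_N = 256
DEFAULT_SPACING = 1.0  # mm at the image plane; the 150 cm SID is metadata only


class DegenerateScenarioError(ValueError):
    """A perturbation produced a scenario with no usable beam/target overlap."""


def sub_seed(master_seed: int, name: str) -> int:
    """Stable per-scenario sub-seed derived from the master seed."""
    return (zlib.crc32(name.encode()) ^ int(master_seed)) % (2**31)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PatientModel:
    """Projected patient anatomy on the detector grid.

    ``thickness_map`` is the base water-equivalent thickness (mm) along each
    ray. ``region_masks``/``densities`` modulate it: inside a named region
    the effective thickness is the base thickness times the region's
    column-average relative density multiplier (e.g. a lung column at 0.3,
    a fluid-filled one at ~1). Masks applied in insertion order, later
    regions overriding earlier ones where they overlap.
    """

    thickness_map: np.ndarray
    ptv_mask: np.ndarray
    region_masks: dict[str, np.ndarray] = field(default_factory=dict)
    densities: dict[str, float] = field(default_factory=dict)
    spacing: tuple[float, float] = (DEFAULT_SPACING, DEFAULT_SPACING)
    origin: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.thickness_map = np.asarray(self.thickness_map, dtype=float)
        if np.any(self.thickness_map < 0) or not np.all(np.isfinite(self.thickness_map)):
            raise ValueError("thickness map must be finite and non-negative")
        self.ptv_mask = np.asarray(self.ptv_mask, dtype=bool)
        if self.ptv_mask.shape != self.thickness_map.shape:
            raise ValueError("ptv_mask shape must match thickness_map")
        if not self.ptv_mask.any():
            raise ValueError("ptv_mask must be non-empty")
        for name, m in self.region_masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.thickness_map.shape:
                raise ValueError(f"region mask {name!r} shape mismatch")
            self.region_masks[name] = m
        if self.origin is None:
            n0, n1 = self.thickness_map.shape
            self.origin = (-(n0 - 1) / 2.0 * self.spacing[0],
                           -(n1 - 1) / 2.0 * self.spacing[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.thickness_map.shape

    def effective_thickness(self) -> np.ndarray:
        t = self.thickness_map.copy()
        for name, mask in self.region_masks.items():
            if name in self.densities:
                t[mask] = self.thickness_map[mask] * self.densities[name]
        return t

    def copy(self) -> "PatientModel":
        return PatientModel(
            self.thickness_map.copy(), self.ptv_mask.copy(),
            {k: v.copy() for k, v in self.region_masks.items()},
            dict(self.densities), self.spacing, self.origin,
        )


@dataclass
class BeamModel:
    """Beam for the toy transit model: MLC/jaw geometry (a
    :class:`~transitqa.plan_perturbation.Beam`, whose control points act as
    the modulation segments), monitor units, open-air output calibration,
    penumbra width and effective attenuation coefficient."""

    beam: Beam
    mu: float = 1.0
    output_per_mu: float = 1.0
    penumbra_sigma_mm: float = 3.0
    mu_atten_per_mm: float = 0.005

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.output_per_mu <= 0 or self.penumbra_sigma_mm <= 0:
            raise ValueError("mu, output_per_mu and penumbra_sigma_mm must be positive")
        if not (0 < self.mu_atten_per_mm < 1):
            raise ValueError("mu_atten_per_mm must be in (0, 1)")

    @property
    def collimator_angle_deg(self) -> float:
        return self.beam.collimator_angle_deg

    def aperture(self, shape, spacing, origin) -> np.ndarray:
        """Composite fluence-weighted opening: mean of the control-point
        apertures (sub-pixel edge weighting, collimator rotation applied)."""
        masks = [
            project_aperture(self.beam, ci, shape, spacing, origin)
            for ci in range(len(self.beam.control_points))
        ]
        return np.mean(masks, axis=0)


@dataclass
class Scenario:
    """One (base, erroneous) transit image pair with its label."""

    scenario_id: str
    failure_mode: str
    parameters: dict
    reference: DoseImage
    evaluated: DoseImage
    delta_dmean_pct: float

    def __post_init__(self) -> None:
        if self.reference.shape != self.evaluated.shape or \
                self.reference.spacing != self.evaluated.spacing or \
                self.reference.origin != self.evaluated.origin:
            raise ValueError("reference and evaluated must share the grid")
        if not np.isfinite(self.delta_dmean_pct):
            raise ValueError("delta_dmean_pct must be finite")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _blurred_fluence(patient: PatientModel, beam: BeamModel) -> np.ndarray:
    flu = beam.aperture(patient.shape, patient.spacing, patient.origin)
    sigma = (beam.penumbra_sigma_mm / patient.spacing[0],
             beam.penumbra_sigma_mm / patient.spacing[1])
    return gaussian_filter(flu, sigma, mode="constant")


def transit_dose(patient: PatientModel, beam: BeamModel) -> DoseImage:
    """Transit dose image of ``beam`` through ``patient`` on the patient grid."""
    blurred = _blurred_fluence(patient, beam)
    t_eff = patient.effective_thickness()
    if t_eff.shape != blurred.shape:
        raise ValueError("patient and beam grids are inconsistent")
    dose = beam.output_per_mu * beam.mu * blurred * np.exp(-beam.mu_atten_per_mm * t_eff)
    return DoseImage(dose, patient.spacing, patient.origin, unit_label="a.u.")


def surrogate_ptv_dmean(
    patient: PatientModel,
    beam: BeamModel,
    ptv_mask: np.ndarray | None = None,
) -> float:
    """Surrogate PTV mean dose: the forward model at mid-depth (half the
    effective thickness) averaged over the projected PTV.

    ``ptv_mask`` defaults to the patient's own PTV; scenario labels pass the
    *planning* PTV while evaluating the delivered anatomy.
    """
    mask = patient.ptv_mask if ptv_mask is None else np.asarray(ptv_mask, dtype=bool)
    blurred = _blurred_fluence(patient, beam)
    if not (blurred[mask] > 1e-9).any():
        raise DegenerateScenarioError("aperture does not overlap the PTV")
    t_mid = patient.effective_thickness() / 2.0
    dose = beam.output_per_mu * beam.mu * blurred * np.exp(-beam.mu_atten_per_mm * t_mid)
    return float(dose[mask].mean())


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------

_LINAC_KIND_MAP = {
    "mlc_shift": "mlc_gap_mm",
    "mlc_shift_central": "mlc_gap_central_mm",
    "collimator": "collimator_deg",
    "mu_scale": "mu_pct",
    "mlc_retracted": "retract_mlc",
}


def apply_linac_error(beam: BeamModel, kind: str, magnitude: float | None = None) -> BeamModel:
    """Linac-hardware error on a beam: MLC gap change (all or central leaves),
    collimator rotation, MU scaling, or full MLC retraction at unchanged MU."""
    if kind not in _LINAC_KIND_MAP:
        raise ValueError(f"unknown linac error kind {kind!r}")
    from .plan_perturbation import PlanModel

    try:
        perturbed = perturb_plan(PlanModel([beam.beam]), _LINAC_KIND_MAP[kind], magnitude)
    except PlanError as exc:
        raise DegenerateScenarioError(str(exc)) from exc
    new_mu = beam.mu * (1.0 + magnitude / 100.0) if kind == "mu_scale" else beam.mu
    return replace(beam, beam=perturbed.beams[0], mu=new_mu)


def _shift_mask(mask: np.ndarray, dy_px: float, dx_px: float) -> np.ndarray:
    if dy_px == 0 and dx_px == 0:
        return mask.copy()
    return nd_shift(mask.astype(float), (dy_px, dx_px), order=1, mode="constant") >= 0.5


def apply_anatomy_error(
    patient: PatientModel,
    kind: str,
    parameters: Mapping | None = None,
    seed: int | None = None,
) -> PatientModel:
    """Anatomy-side failure modes.

    ``breath_shift``: translate the lung region and the embedded GTV blob by
    ``displacement_mm`` (scalar y displacement or ``(dy, dx)``).
    ``patient_swap``: an independently generated patient (see
    :func:`random_breast_patient`).
    ``fluid_change``: set a region's density multiplier (``region``,
    ``density``), toggling e.g. pleural fluid against aerated lung.
    ``bolus_removed``: subtract ``thickness_mm`` (default 10) over the bolus
    footprint; a negative thickness re-adds the bolus.
    """
    p = dict(parameters or {})
    if kind == "breath_shift":
        d = p.get("displacement_mm", 0.0)
        dy, dx = (float(d), 0.0) if np.isscalar(d) else (float(d[0]), float(d[1]))
        out = patient.copy()
        if dy == 0 and dx == 0:
            return out
        for name in ("lung", "gtv"):
            if name in out.region_masks:
                shifted = _shift_mask(out.region_masks[name],
                                      dy / patient.spacing[0], dx / patient.spacing[1])
                if name == "gtv" and shifted.sum() < 0.95 * out.region_masks[name].sum():
                    raise ValueError("breath shift moves the GTV outside the grid")
                out.region_masks[name] = shifted
        return out
    if kind == "patient_swap":
        return random_breast_patient(seed if seed is not None else 0,
                                     shape=patient.shape, spacing=patient.spacing)
    if kind == "fluid_change":
        out = patient.copy()
        region = p.get("region", "fluid")
        if region not in out.region_masks:
            raise ValueError(f"no region {region!r} in patient")
        out.densities[region] = float(p["density"])
        return out
    if kind == "bolus_removed":
        out = patient.copy()
        if "bolus" not in out.region_masks:
            raise ValueError("patient has no bolus footprint")
        thickness = float(p.get("thickness_mm", 10.0))
        out.thickness_map = np.clip(
            out.thickness_map - thickness * out.region_masks["bolus"], 0.0, None)
        return out
    raise ValueError(f"unknown anatomy error kind {kind!r}")


# ---------------------------------------------------------------------------
# anatomy and plan builders
# ---------------------------------------------------------------------------

def _grid_coords(shape, spacing):
    n0, n1 = shape
    y = (np.arange(n0) - (n0 - 1) / 2.0) * spacing[0]
    x = (np.arange(n1) - (n1 - 1) / 2.0) * spacing[1]
    return np.meshgrid(y, x, indexing="ij")


def _ellipse(Y, X, cy, cx, ry, rx):
    return ((Y - cy) / ry) ** 2 + ((X - cx) / rx) ** 2 <= 1.0


def _dome(Y, X, cy, cx, ry, rx, peak):
    q = 1.0 - ((Y - cy) / ry) ** 2 - ((X - cx) / rx) ** 2
    return peak * np.sqrt(np.clip(q, 0.0, None))


def _rect_beam(cy, cx, half_y, half_x, n_pairs=48, leaf_mm=5.0, jaw_margin=5.0,
               mu=1.0) -> Beam:
    """Single-segment rectangular aperture centered on (cy, cx)."""
    bounds = (np.arange(n_pairs + 1) - n_pairs / 2.0) * leaf_mm
    a = np.full(n_pairs, 0.0)
    b = np.full(n_pairs, 0.0)
    inside = (bounds[1:] > cy - half_y) & (bounds[:-1] < cy + half_y)
    a[inside] = cx - half_x
    b[inside] = cx + half_x
    cp = ControlPoint(a, b, (cx - half_x - jaw_margin, cx + half_x + jaw_margin),
                      (cy - half_y - jaw_margin, cy + half_y + jaw_margin))
    return Beam(0.0, mu, [cp], bounds)


def head_neck_patient(shape=(DEFAULT_GRID_N, DEFAULT_GRID_N),
                      spacing=(DEFAULT_SPACING, DEFAULT_SPACING)) -> PatientModel:
    """Neck-like slab: smooth dome thickness, elliptical nodal PTV."""
    Y, X = _grid_coords(shape, spacing)
    t = _dome(Y, X, 0, 0, 115, 95, 130.0)
    ptv = _ellipse(Y, X, 0, 0, 42, 32)
    return PatientModel(t, ptv, spacing=spacing)


def head_neck_plan(seed: int, n_segments: int = 5, mu: float = 1.0) -> Beam:
    """VMAT-like modulated beam: each control point is a randomly modulated
    aperture; the composite fluence covers the PTV only partially, as a
    modulated delivery does at any instant."""
    rng = np.random.default_rng(seed)
    n_pairs = 40
    leaf_mm = 5.0
    bounds = (np.arange(n_pairs + 1) - n_pairs / 2.0) * leaf_mm
    jaw = 55.0
    cps = []
    for _ in range(n_segments):
        a = np.zeros(n_pairs)
        b = np.zeros(n_pairs)
        inside = (bounds[1:] > -jaw) & (bounds[:-1] < jaw)
        for i in np.nonzero(inside)[0]:
            c = rng.uniform(-25.0, 25.0)
            w = rng.uniform(20.0, 60.0)
            a[i] = max(c - w / 2.0, -jaw)
            b[i] = min(c + w / 2.0, jaw)
        cps.append(ControlPoint(a, b, (-jaw, jaw), (-jaw, jaw)))
    return Beam(0.0, mu, cps, bounds)


def lung_patient(displacement_mm: float = 0.0,
                 shape=(DEFAULT_GRID_N, DEFAULT_GRID_N),
                 spacing=(DEFAULT_SPACING, DEFAULT_SPACING),
                 ptv_displacement_mm: float | None = None) -> PatientModel:
    """Lung SBRT anatomy: chest dome, aerated lung (low column density), a
    GTV blob inside the lung. ``displacement_mm`` moves lung + GTV caudally
    (breathing phase); the PTV is the GTV at ``ptv_displacement_mm`` (default:
    the same phase) expanded by a 5 mm margin."""
    Y, X = _grid_coords(shape, spacing)
    t = _dome(Y, X, 0, 0, 105, 115, 210.0)
    d = float(displacement_mm)
    pd_ = d if ptv_displacement_mm is None else float(ptv_displacement_mm)
    lung = _ellipse(Y, X, 5 + d, 35, 85, 55)
    gtv = _ellipse(Y, X, -25 + d, 35, 15, 15)
    ptv = _ellipse(Y, X, -25 + pd_, 35, 20, 20)
    return PatientModel(
        t, ptv,
        region_masks={"lung": lung, "gtv": gtv},
        densities={"lung": 0.30, "gtv": 1.05},
        spacing=spacing,
    )


def averaged_lung_patient(displacements_mm: Sequence[float],
                          ptv_displacement_mm: float,
                          shape=(DEFAULT_GRID_N, DEFAULT_GRID_N),
                          spacing=(DEFAULT_SPACING, DEFAULT_SPACING)) -> PatientModel:
    """Phase-averaged anatomy: displacement-weighted average of the effective
    thickness maps of the individual phases (the 4D-CT averaging analog).
    The averaged map carries no separate low-density regions."""
    maps = [
        lung_patient(d, shape, spacing).effective_thickness()
        for d in displacements_mm
    ]
    ptv = lung_patient(ptv_displacement_mm, shape, spacing).ptv_mask
    return PatientModel(np.mean(maps, axis=0), ptv, spacing=spacing)


def random_breast_patient(seed: int,
                          shape=(DEFAULT_GRID_N, DEFAULT_GRID_N),
                          spacing=(DEFAULT_SPACING, DEFAULT_SPACING),
                          with_bolus: bool = False,
                          habitus: float | None = None) -> PatientModel:
    """Breast anatomy with randomized geometry: body dome plus a Gaussian
    breast mound; PTV centered on the mound. ``habitus`` in [0, 1] scales
    the body (drawn at random when not given). Optionally a 10 mm bolus slab
    over the PTV footprint (expanded 10 mm)."""
    rng = np.random.default_rng(seed)
    h = float(rng.uniform(0.0, 1.0) if habitus is None else habitus)
    Y, X = _grid_coords(shape, spacing)
    peak = 105.0 + 85.0 * h
    cy, cx = rng.uniform(-20, 20), rng.uniform(-35, -5)
    bump = 22.0 + 28.0 * h
    sb = rng.uniform(26.0, 38.0)
    t = _dome(Y, X, 0, 0, 95.0 + 35.0 * h, 85.0 + 35.0 * h, peak)
    body = t > 0
    t = t + bump * np.exp(-(((Y - cy) ** 2 + (X - cx) ** 2) / (2 * sb ** 2))) * body
    ptv = _ellipse(Y, X, cy, cx, 25, 25)
    regions: dict[str, np.ndarray] = {}
    if with_bolus:
        regions["bolus"] = _ellipse(Y, X, cy, cx, 35, 35)
        t = t + 10.0 * regions["bolus"]
    return PatientModel(t, ptv, region_masks=regions, spacing=spacing)


def effusion_patient(fluid_present: bool,
                     shape=(DEFAULT_GRID_N, DEFAULT_GRID_N),
                     spacing=(DEFAULT_SPACING, DEFAULT_SPACING)) -> PatientModel:
    """Palliative lung anatomy with a dependent pleural-fluid zone occupying
    the lower lung; its column density toggles between fluid-filled (~soft
    tissue) and drained/aerated lung."""
    Y, X = _grid_coords(shape, spacing)
    t = _dome(Y, X, 0, 0, 105, 115, 210.0)
    lung = _ellipse(Y, X, 0, 35, 85, 55)
    fluid = lung & (Y > -15)
    ptv = _ellipse(Y, X, 0, 35, 22, 22)
    return PatientModel(
        t, ptv,
        region_masks={"lung": lung, "fluid": fluid},
        densities={"lung": 0.30, "fluid": 0.95 if fluid_present else 0.30},
        spacing=spacing,
    )


# ---------------------------------------------------------------------------
# suite generation
# ---------------------------------------------------------------------------

#: the paper-shaped linac error grid: 10 single-error plans + the New York
#: incident (MLC fully retracted behind the jaws, MU unchanged)
DEFAULT_LINAC_ERRORS: tuple[tuple[str, float | None], ...] = (
    ("mlc_shift", +1.0), ("mlc_shift", -1.0),
    ("mlc_shift", +1.5), ("mlc_shift", -1.5),
    ("mlc_shift_central", +2.0), ("mlc_shift_central", +5.0),
    ("collimator", +1.0), ("collimator", -1.0),
    ("mu_scale", +2.0), ("mu_scale", -2.0),
    ("mlc_retracted", None),
)

ALL_FAILURE_MODES = ("linac_hardware", "breathing", "patient_id", "wrong_ct", "bolus")


@dataclass
class SuiteConfig:
    """Study-suite conditions; the defaults are the study conditions."""

    grid_n: int = DEFAULT_GRID_N
    spacing_mm: float = DEFAULT_SPACING
    mu_atten_per_mm: float = 0.005
    penumbra_sigma_mm: float = 3.0
    breathing_amplitude_mm: float = 25.0
    n_segments: int = 5
    linac_errors: tuple = DEFAULT_LINAC_ERRORS
    modes: tuple = ALL_FAILURE_MODES
    #: zero all error magnitudes (identity suite; for degenerate-run tests)
    identity: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid_n, self.grid_n)

    @property
    def grid_spacing(self) -> tuple[float, float]:
        return (self.spacing_mm, self.spacing_mm)


def _calibrated_beam(geom: Beam, patient: PatientModel, cfg: SuiteConfig) -> BeamModel:
    """Calibrate output so the base *open-field* (jaws-only) transit image
    peaks at 100 dose units for this patient."""
    from .plan_perturbation import PlanModel

    open_geom = perturb_plan(PlanModel([geom]), "retract_mlc").beams[0]
    probe = BeamModel(open_geom, mu=1.0, output_per_mu=1.0,
                      penumbra_sigma_mm=cfg.penumbra_sigma_mm,
                      mu_atten_per_mm=cfg.mu_atten_per_mm)
    peak = float(transit_dose(patient, probe).values.max())
    if peak <= 0:
        raise DegenerateScenarioError("open-field transit image is empty")
    return BeamModel(geom, mu=1.0, output_per_mu=100.0 / peak,
                     penumbra_sigma_mm=cfg.penumbra_sigma_mm,
                     mu_atten_per_mm=cfg.mu_atten_per_mm)


def _scenario(sid: str, mode: str, params: dict,
              base_patient: PatientModel, base_beam: BeamModel,
              err_patient: PatientModel, err_beam: BeamModel) -> Scenario:
    ptv = base_patient.ptv_mask
    d_base = surrogate_ptv_dmean(base_patient, base_beam, ptv)
    d_err = surrogate_ptv_dmean(err_patient, err_beam, ptv)
    delta = 100.0 * (d_err - d_base) / d_base
    return Scenario(
        sid, mode, params,
        reference=transit_dose(base_patient, base_beam),
        evaluated=transit_dose(err_patient, err_beam),
        delta_dmean_pct=delta,
    )


def _phase_displacement(phase: float, amplitude: float) -> float:
    """Breathing waveform: 0 at inspiration (phase 0), ``amplitude`` at
    expiration (phase 0.5). The exponent < 1 makes the cycle dwell near
    exhale, as real breathing does, so the free-breathing average anatomy
    sits close to the expiration phase."""
    return amplitude * abs(np.sin(np.pi * phase)) ** 0.4


def generate_suite(config: SuiteConfig | None = None, seed: int = 0) -> list[Scenario]:
    """Build the full scenario suite (22 scenarios with the default config:
    11 linac, 6 breathing, 2 patient-swap, 2 wrong-CT, 1 bolus)."""
    cfg = config or SuiteConfig()
    shape, spacing = cfg.shape, cfg.grid_spacing
    zero = cfg.identity
    scenarios: list[Scenario] = []

    if "linac_hardware" in cfg.modes:
        patient = head_neck_patient(shape, spacing)
        geom = head_neck_plan(sub_seed(seed, "hn_plan"), cfg.n_segments)
        base = _calibrated_beam(geom, patient, cfg)
        for kind, mag in cfg.linac_errors:
            tag = "ny" if kind == "mlc_retracted" else f"{kind}_{mag:+g}mm" \
                if "mlc" in kind else f"{kind}_{mag:+g}"
            sid = f"linac_{tag}"
            if zero and kind != "mlc_retracted":
                err = apply_linac_error(base, kind, 0.0)
            elif zero:
                err = base
            else:
                err = apply_linac_error(base, kind, mag)
            scenarios.append(_scenario(
                sid, "linac_hardware", {"kind": kind, "magnitude": mag},
                patient, base, patient, err))

    if "breathing" in cfg.modes:
        amp = 0.0 if zero else cfg.breathing_amplitude_mm
        d_insp, d_exp = 0.0, amp
        phases_3060 = [0.3, 0.4, 0.5, 0.6]
        phases_all = [p / 10.0 for p in range(10)]
        bases = {"insp": d_insp, "exp": d_exp}
        delivered = {
            "exp": lambda: lung_patient(d_exp, shape, spacing),
            "insp": lambda: lung_patient(d_insp, shape, spacing),
            "3060": lambda: averaged_lung_patient(
                [_phase_displacement(p, amp) for p in phases_3060], 0.0, shape, spacing),
            "avg": lambda: averaged_lung_patient(
                [_phase_displacement(p, amp) for p in phases_all], 0.0, shape, spacing),
        }
        for planned, d_plan in bases.items():
            patient = lung_patient(d_plan, shape, spacing)
            geom = _rect_beam(-25 + d_plan, 35, 30.0, 30.0)
            base = _calibrated_beam(geom, patient, cfg)
            for deliv in [k for k in ("exp", "insp", "3060", "avg") if k != planned]:
                err_patient = delivered[deliv]()
                # planning PTV travels with the base plan; delivered anatomy differs
                err_patient = replace_ptv(err_patient, patient.ptv_mask)
                scenarios.append(_scenario(
                    f"breath_{planned}_to_{deliv}", "breathing",
                    {"planned": planned, "delivered": deliv, "amplitude_mm": amp},
                    patient, base, err_patient, base))

    if "patient_id" in cfg.modes:
        # deliberately contrasting habitus: misidentification between two
        # patients of similar size would be caught by neither system
        pa = random_breast_patient(sub_seed(seed, "breast_A"), shape, spacing,
                                   habitus=0.95)
        pb = random_breast_patient(sub_seed(seed, "breast_B"), shape, spacing,
                                   habitus=0.05)
        for sid, planned, other in (("swap_a_on_b", pa, pb), ("swap_b_on_a", pb, pa)):
            cy, cx = _mask_centroid(planned.ptv_mask, planned)
            geom = _rect_beam(cy, cx, 40.0, 40.0)
            base = _calibrated_beam(geom, planned, cfg)
            err_patient = planned if zero else replace_ptv(other, planned.ptv_mask)
            scenarios.append(_scenario(
                sid, "patient_id", {"planned": sid.split("_")[1]},
                planned, base, err_patient, base))

    if "wrong_ct" in cfg.modes:
        p_fluid = effusion_patient(True, shape, spacing)
        p_drained = effusion_patient(False, shape, spacing)
        geom = _rect_beam(0, 35, 32.0, 32.0)
        for sid, planned, other in (("wrongct_fluid_plan_on_drained", p_fluid, p_drained),
                                    ("wrongct_drained_plan_on_fluid", p_drained, p_fluid)):
            base = _calibrated_beam(geom, planned, cfg)
            err_patient = planned if zero else other
            scenarios.append(_scenario(
                sid, "wrong_ct", {"planned": sid.split("_")[1]},
                planned, base, err_patient, base))

    if "bolus" in cfg.modes:
        patient = random_breast_patient(sub_seed(seed, "bolus_patient"), shape, spacing,
                                        with_bolus=True)
        cy, cx = _mask_centroid(patient.ptv_mask, patient)
        geom = _rect_beam(cy, cx, 40.0, 40.0)
        base = _calibrated_beam(geom, patient, cfg)
        err_patient = patient if zero else apply_anatomy_error(
            patient, "bolus_removed", {"thickness_mm": 10.0})
        scenarios.append(_scenario(
            "bolus_removed", "bolus", {"thickness_mm": 10.0},
            patient, base, err_patient, base))

    return scenarios


def replace_ptv(patient: PatientModel, ptv_mask: np.ndarray) -> PatientModel:
    out = patient.copy()
    out.ptv_mask = np.asarray(ptv_mask, dtype=bool)
    return out


def _mask_centroid(mask: np.ndarray, patient: PatientModel) -> tuple[float, float]:
    ii, jj = np.nonzero(mask)
    return (patient.origin[0] + ii.mean() * patient.spacing[0],
            patient.origin[1] + jj.mean() * patient.spacing[1])


# ---------------------------------------------------------------------------
# suite export / reload
# ---------------------------------------------------------------------------

def export_suite(scenarios: Iterable[Scenario], directory: str,
                 format: str = "text-grid") -> str:
    """Write every scenario's reference/evaluated planes plus a manifest CSV;
    returns the manifest path."""
    os.makedirs(directory, exist_ok=True)
    ext = ".dcm" if format == "dicom-rtdose" else ".txt"
    rows = []
    for sc in scenarios:
        ref_path = os.path.join(directory, f"{sc.scenario_id}_ref{ext}")
        ev_path = os.path.join(directory, f"{sc.scenario_id}_eval{ext}")
        write_dose_plane(sc.reference, ref_path, format)
        write_dose_plane(sc.evaluated, ev_path, format)
        rows.append({
            "scenario_id": sc.scenario_id,
            "failure_mode": sc.failure_mode,
            "parameters": json.dumps(sc.parameters),
            "delta_dmean_pct": sc.delta_dmean_pct,
            "reference_file": os.path.basename(ref_path),
            "evaluated_file": os.path.basename(ev_path),
        })
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_suite(directory: str) -> list[Scenario]:
    """Re-load a suite written by :func:`export_suite`."""
    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
    scenarios = []
    for _, row in manifest.iterrows():
        scenarios.append(Scenario(
            row["scenario_id"], row["failure_mode"], json.loads(row["parameters"]),
            read_dose_plane(os.path.join(directory, row["reference_file"])),
            read_dose_plane(os.path.join(directory, row["evaluated_file"])),
            float(row["delta_dmean_pct"]),
        ))
    return scenarios
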