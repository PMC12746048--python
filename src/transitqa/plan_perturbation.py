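"""Error injection into minimal treatment-plan structures.

Models the plan attributes that the studied failure modes touch — MLC bank
positions per control point, jaw positions, collimator angle and beam
meterset — with DICOM RT Plan read/modify/write, so that known errors can be
introduced into real or fixture plans: symmetric MLC gap changes (whole
field or central leaves only), collimator-angle offsets, MU scaling, and the
fully retracted MLC (the "New York incident" pattern: leaves parked behind
the jaws while jaws and MU stay as planned).

Sign conventions follow DICOM: leaf positions are in mm at the machine
plane along the leaf-travel (x) axis, bank A on the negative side, and for
every leaf pair ``bank_A <= bank_B``. A positive gap change increases the
distance between opposite leaves (each bank moves outward by half the
magnitude).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ControlPoint",
    "Beam",
    "PlanModel",
    "PlanError",
    "read_rtplan",
    "write_rtplan",
    "make_fixture_plan",
    "perturb_plan",
    "project_aperture",
    "central_pair_indices",
]

_RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"

#: leaf pairs with a base gap at or below this are treated as closed and are
#: not moved by gap perturbations (shared decision with the simulator)
DEFAULT_CLOSED_GAP_MM = 0.5


class PlanError(ValueError):
    pass


@dataclass
class ControlPoint:
    """MLC bank positions (one entry per leaf pair, leaf-travel axis, mm)
    and jaw positions of one control point."""

    bank_a_mm: np.ndarray
    bank_b_mm: np.ndarray
    jaw_x_mm: tuple[float, float]
    jaw_y_mm: tuple[float, float]

    def __post_init__(self) -> None:
        self.bank_a_mm = np.asarray(self.bank_a_mm, dtype=float)
        self.bank_b_mm = np.asarray(self.bank_b_mm, dtype=float)
        if self.bank_a_mm.shape != self.bank_b_mm.shape or self.bank_a_mm.ndim != 1:
            raise PlanError("MLC banks must be 1D arrays of equal length")
        if np.any(self.bank_a_mm > self.bank_b_mm + 1e-9):
            raise PlanError("bank A position must not exceed bank B for any pair")
        self.jaw_x_mm = (float(self.jaw_x_mm[0]), float(self.jaw_x_mm[1]))
        self.jaw_y_mm = (float(self.jaw_y_mm[0]), float(self.jaw_y_mm[1]))
        if self.jaw_x_mm[0] >= self.jaw_x_mm[1] or self.jaw_y_mm[0] >= self.jaw_y_mm[1]:
            raise PlanError("jaw intervals must be non-degenerate (x1 < x2, y1 < y2)")

    @property
    def n_pairs(self) -> int:
        return self.bank_a_mm.size

    def gaps(self) -> np.ndarray:
        return self.bank_b_mm - self.bank_a_mm


@dataclass
class Beam:
    collimator_angle_deg: float
    mu: float
    control_points: list[ControlPoint]
    #: n_pairs+1 leaf-pair edges along y (mm), ascending
    leaf_boundaries_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise PlanError("beam meterset (MU) must be positive")
        if not self.control_points:
            raise PlanError("beam must have at least one control point")
        n = self.control_points[0].n_pairs
        if any(cp.n_pairs != n for cp in self.control_points):
            raise PlanError("all control points of a beam must share the leaf count")
        if self.leaf_boundaries_mm is None:
            # default: 5 mm leaves centered on y = 0
            self.leaf_boundaries_mm = (np.arange(n + 1) - n / 2.0) * 5.0
        self.leaf_boundaries_mm = np.asarray(self.leaf_boundaries_mm, dtype=float)
        if self.leaf_boundaries_mm.size != n + 1:
            raise PlanError("leaf_boundaries_mm must have n_pairs + 1 entries")
        if np.any(np.diff(self.leaf_boundaries_mm) <= 0):
            raise PlanError("leaf boundaries must be strictly ascending")


@dataclass
class PlanModel:
    beams: list[Beam]

    def __post_init__(self) -> None:
        if not self.beams:
            raise PlanError("plan must have at least one beam")


# ---------------------------------------------------------------------------
# DICOM RT Plan I/O
# ---------------------------------------------------------------------------

def _bld_positions(cp_ds, bld_type: str):
    for item in getattr(cp_ds, "BeamLimitingDevicePositionSequence", []):
        if item.RTBeamLimitingDeviceType == bld_type:
            return [float(v) for v in item.LeafJawPositions]
    return None


def read_rtplan(path: str) -> PlanModel:
    """Parse the modeled attributes of a DICOM RT Plan.

    Jaw or MLC positions omitted on later control points inherit from the
    most recent control point that carried them (DICOM delta encoding).
    """
    import pydicom

    ds = pydicom.dcmread(path)
    metersets: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    beams = []
    for beam_ds in getattr(ds, "BeamSequence", []):
        n_pairs = None
        boundaries = None
        for bld in getattr(beam_ds, "BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType.startswith("MLC"):
                n_pairs = int(bld.NumberOfLeafJawPairs)
                if "LeafPositionBoundaries" in bld:
                    boundaries = np.asarray(
                        [float(v) for v in bld.LeafPositionBoundaries])
        if n_pairs is None:
            raise PlanError(f"beam {beam_ds.BeamNumber}: no MLC device sequence")

        angle = 0.0
        jaw_x = jaw_y = None
        banks = None
        cps = []
        for cp_ds in beam_ds.ControlPointSequence:
            if "BeamLimitingDeviceAngle" in cp_ds:
                angle = float(cp_ds.BeamLimitingDeviceAngle)
            jx = _bld_positions(cp_ds, "ASYMX") or _bld_positions(cp_ds, "X")
            jy = _bld_positions(cp_ds, "ASYMY") or _bld_positions(cp_ds, "Y")
            mlc = _bld_positions(cp_ds, "MLCX")
            jaw_x = tuple(jx) if jx else jaw_x
            jaw_y = tuple(jy) if jy else jaw_y
            if mlc is not None:
                if len(mlc) != 2 * n_pairs:
                    raise PlanError("MLCX positions do not match the leaf count")
                banks = (np.asarray(mlc[:n_pairs]), np.asarray(mlc[n_pairs:]))
            if jaw_x is None or jaw_y is None or banks is None:
                raise PlanError("first control point must define jaws and MLC")
            cps.append(ControlPoint(banks[0].copy(), banks[1].copy(), jaw_x, jaw_y))
        mu = metersets.get(int(beam_ds.BeamNumber), 100.0)
        beams.append(Beam(angle, mu, cps, boundaries))
    if not beams:
        raise PlanError(f"{path}: no beams found")
    return PlanModel(beams)


def write_rtplan(plan: PlanModel, path: str, template=None) -> None:
    """Write a DICOM RT Plan carrying the modeled attributes.

    With ``template`` (a ``pydicom`` dataset or a path to one) the modeled
    attributes are replaced in a copy of the template and everything else is
    passed through unmodified; otherwise a minimal valid plan is built.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    if template is not None:
        ds = (pydicom.dcmread(template) if isinstance(template, (str, bytes))
              else copy.deepcopy(template))
    else:
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = _RTPLAN_SOP_CLASS
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(path, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = _RTPLAN_SOP_CLASS
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTPLAN"
        ds.PatientName = "transitqa"
        ds.PatientID = "transitqa"
        ds.RTPlanLabel = "transitqa"
        ds.BeamSequence = []
        ds.FractionGroupSequence = []

    def _bld_item(bld_type: str, positions) -> "Dataset":
        item = Dataset()
        item.RTBeamLimitingDeviceType = bld_type
        item.LeafJawPositions = [float(v) for v in positions]
        return item

    beam_seq = []
    ref_beams = []
    for bi, beam in enumerate(plan.beams, start=1):
        bds = Dataset()
        bds.BeamNumber = bi
        bds.BeamName = f"beam{bi}"
        n = beam.control_points[0].n_pairs

        dev_x = Dataset(); dev_x.RTBeamLimitingDeviceType = "ASYMX"; dev_x.NumberOfLeafJawPairs = 1
        dev_y = Dataset(); dev_y.RTBeamLimitingDeviceType = "ASYMY"; dev_y.NumberOfLeafJawPairs = 1
        dev_m = Dataset(); dev_m.RTBeamLimitingDeviceType = "MLCX"; dev_m.NumberOfLeafJawPairs = n
        dev_m.LeafPositionBoundaries = [float(v) for v in beam.leaf_boundaries_mm]
        bds.BeamLimitingDeviceSequence = [dev_x, dev_y, dev_m]

        cp_seq = []
        for ci, cp in enumerate(beam.control_points):
            cpd = Dataset()
            cpd.ControlPointIndex = ci
            if ci == 0:
                cpd.BeamLimitingDeviceAngle = float(beam.collimator_angle_deg)
            cpd.BeamLimitingDevicePositionSequence = [
                _bld_item("ASYMX", cp.jaw_x_mm),
                _bld_item("ASYMY", cp.jaw_y_mm),
                _bld_item("MLCX", np.concatenate([cp.bank_a_mm, cp.bank_b_mm])),
            ]
            cp_seq.append(cpd)
        bds.ControlPointSequence = cp_seq
        bds.NumberOfControlPoints = len(cp_seq)
        beam_seq.append(bds)

        rb = Dataset()
        rb.ReferencedBeamNumber = bi
        rb.BeamMeterset = float(beam.mu)
        ref_beams.append(rb)

    ds.BeamSequence = beam_seq
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.ReferencedBeamSequence = ref_beams
    ds.FractionGroupSequence = [fg]
    pydicom.dcmwrite(path, ds, little_endian=True, implicit_vr=False)


def make_fixture_plan(
    n_pairs: int = 10,
    n_control_points: int = 2,
    gap_mm: float = 20.0,
    jaw_half_mm: float = 30.0,
    collimator_angle_deg: float = 0.0,
    mu: float = 100.0,
) -> PlanModel:
    """A minimal valid plan for tests: rectangular aperture, ``n_pairs``
    leaf pairs, identical control points."""
    cps = [
        ControlPoint(
            np.full(n_pairs, -gap_mm / 2.0),
            np.full(n_pairs, gap_mm / 2.0),
            (-jaw_half_mm, jaw_half_mm),
            (-jaw_half_mm, jaw_half_mm),
        )
        for _ in range(n_control_points)
    ]
    return PlanModel([Beam(collimator_angle_deg, mu, cps)])


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def central_pair_indices(open_mask: np.ndarray, fraction: float = 1.0 / 3.0) -> np.ndarray:
    """Indices of the central band of open leaf pairs: the middle ``fraction``
    (at least one pair) of the pairs intersecting the field."""
    open_idx = np.nonzero(open_mask)[0]
    if open_idx.size == 0:
        return open_idx
    k = max(1, int(round(open_idx.size * fraction)))
    start = (open_idx.size - k) // 2
    return open_idx[start:start + k]


def perturb_plan(
    plan: PlanModel,
    error: str,
    magnitude: float | None = None,
    closed_gap_mm: float = DEFAULT_CLOSED_GAP_MM,
    central_fraction: float = 1.0 / 3.0,
    clamp_warn_fraction: float = 0.25,
) -> PlanModel:
    """Return a perturbed copy of ``plan``.

    ``error`` is one of ``mlc_gap_mm`` (every open pair's gap changes by the
    magnitude, banks moving symmetrically), ``mlc_gap_central_mm`` (central
    band of open pairs only), ``collimator_deg``, ``mu_pct``, or
    ``retract_mlc`` (leaves parked beyond the jaws; jaws and MU unchanged).
    Gap erosion clamps crossing pairs at their midpoint; a warning is issued
    when more than ``clamp_warn_fraction`` of the open pairs clamp, and an
    error raised when *all* open pairs end closed.
    """
    out = copy.deepcopy(plan)
    if error == "mu_pct":
        for beam in out.beams:
            beam.mu *= 1.0 + float(magnitude) / 100.0
        return out
    if error == "collimator_deg":
        for beam in out.beams:
            beam.collimator_angle_deg += float(magnitude)
        return out
    if error == "retract_mlc":
        for beam in out.beams:
            for cp in beam.control_points:
                margin = 20.0
                cp.bank_a_mm[:] = cp.jaw_x_mm[0] - margin
                cp.bank_b_mm[:] = cp.jaw_x_mm[1] + margin
        return out
    if error not in ("mlc_gap_mm", "mlc_gap_central_mm"):
        raise PlanError(f"unknown plan error kind {error!r}")

    half = float(magnitude) / 2.0
    for beam in out.beams:
        for cp in beam.control_points:
            open_mask = cp.gaps() > closed_gap_mm
            if error == "mlc_gap_central_mm":
                idx = central_pair_indices(open_mask, central_fraction)
            else:
                idx = np.nonzero(open_mask)[0]
            a = cp.bank_a_mm[idx] - half
            b = cp.bank_b_mm[idx] + half
            crossed = a > b
            if crossed.any():
                mid = 0.5 * (a[crossed] + b[crossed])
                a[crossed] = mid
                b[crossed] = mid
                if crossed.sum() > clamp_warn_fraction * max(len(idx), 1):
                    warnings.warn(
                        f"gap change {magnitude} mm clamped {int(crossed.sum())}"
                        f"/{len(idx)} open leaf pairs", stacklevel=2)
            cp.bank_a_mm[idx] = a
            cp.bank_b_mm[idx] = b
            if open_mask.any() and not np.any(cp.gaps() > closed_gap_mm):
                raise PlanError("gap erosion closed every open leaf pair")
    return out


# ---------------------------------------------------------------------------
# aperture rasterization
# ---------------------------------------------------------------------------

def project_aperture(
    beam: Beam,
    cp_index: int = 0,
    shape: tuple[int, int] = (256, 256),
    spacing: tuple[float, float] = (1.0, 1.0),
    origin: tuple[float, float] | None = None,
    supersample: int = 8,
) -> np.ndarray:
    """Rasterize the MLC-and-jaw opening of one control point onto a grid.

    Returns a float coverage mask in [0, 1] with sub-pixel edge weighting.
    The collimator rotation is applied about the beam axis, taken to be the
    physical origin (0, 0). With zero rotation the coverage is computed
    exactly from interval overlaps; otherwise the pixel is supersampled.
    """
    cp = beam.control_points[cp_index]
    if origin is None:
        origin = (-(shape[0] - 1) / 2.0 * spacing[0], -(shape[1] - 1) / 2.0 * spacing[1])
    ys = origin[0] + np.arange(shape[0]) * spacing[0]
    xs = origin[1] + np.arange(shape[1]) * spacing[1]
    bounds = beam.leaf_boundaries_mm
    jx1, jx2 = cp.jaw_x_mm
    jy1, jy2 = cp.jaw_y_mm

    angle = np.deg2rad(beam.collimator_angle_deg % 360.0)
    if abs(np.sin(angle)) < 1e-12 and np.cos(angle) > 0:
        # exact interval-overlap rasterization
        mask = np.zeros(shape)
        ylo, yhi = ys - spacing[0] / 2.0, ys + spacing[0] / 2.0
        xlo, xhi = xs - spacing[1] / 2.0, xs + spacing[1] / 2.0
        for p in range(cp.n_pairs):
            y1 = max(bounds[p], jy1)
            y2 = min(bounds[p + 1], jy2)
            x1 = max(cp.bank_a_mm[p], jx1)
            x2 = min(cp.bank_b_mm[p], jx2)
            if y2 <= y1 or x2 <= x1:
                continue
            yov = np.clip(np.minimum(yhi, y2) - np.maximum(ylo, y1), 0.0, None)
            xov = np.clip(np.minimum(xhi, x2) - np.maximum(xlo, x1), 0.0, None)
            mask += np.outer(yov, xov) / (spacing[0] * spacing[1])
        return np.clip(mask, 0.0, 1.0)

    # supersampled rasterization in the rotated collimator frame
    s = int(supersample)
    sub = (np.arange(s) + 0.5) / s - 0.5
    yy = (ys[:, None] + sub[None, :] * spacing[0]).ravel()
    xx = (xs[:, None] + sub[None, :] * spacing[1]).ravel()
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    ca, sa = np.cos(-angle), np.sin(-angle)
    Xc = ca * X - sa * Y
    Yc = sa * X + ca * Y
    row = np.searchsorted(bounds, Yc) - 1
    valid_row = (row >= 0) & (row < cp.n_pairs)
    row_c = np.clip(row, 0, cp.n_pairs - 1)
    inside = (
        valid_row
        & (Xc >= cp.bank_a_mm[row_c]) & (Xc <= cp.bank_b_mm[row_c])
        & (Xc >= jx1) & (Xc <= jx2) & (Yc >= jy1) & (Yc <= jy2)
    )
    cover = inside.reshape(shape[0], s, shape[1], s).mean(axis=(1, 3))
    return cover
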