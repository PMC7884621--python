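"""Neural-activation estimation from the probed electric field.

Activation is approximated by two field estimators evaluated on a regular
probe lattice (0.05 mm spacing, within 2 mm of the core contact centre):
the field magnitude |E| and the magnitude of its divergence |div E|, a
direction-free surrogate of the activating function.  A point counts as
activated when the estimator strictly exceeds its threshold; the defaults,
0.323 V/mm for |E| and 0.309 V/mm^2 for |div E|, are median axon-model
thresholds for 2.5 um axons from the source literature.  Activated volume is
the supra-threshold point count times (0.05 mm)^3; electrode performance is
the share (%) of the activated volume falling inside the target nucleus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import TissuePhantom
from .electrodes import ElectrodeDesign, Placement, core_contact_center

logger = logging.getLogger("dbsfem.activation")

PROBE_SPACING = 0.05        # mm
PROBE_RADIUS = 2.0          # mm around the core contact centre
THRESHOLD_E = 0.323         # V/mm
THRESHOLD_DIV = 0.309       # V/mm^2


@dataclass
class ProbeGrid:
    """Regular probe lattice around the core contact.

    The full cubic lattice (needed by the finite-difference divergence) is
    kept together with masks selecting the reported probe points: inside the
    2 mm ball and outside the electrode body.
    """

    center: np.ndarray                  # mm, core contact centre
    spacing: float                      # mm
    shape: tuple[int, int, int]
    points: np.ndarray                  # (N, 3) all lattice points
    ball_mask: np.ndarray               # (N,) within PROBE_RADIUS
    electrode_mask: np.ndarray          # (N,) inside the electrode solid

    @property
    def valid_mask(self) -> np.ndarray:
        return self.ball_mask & ~self.electrode_mask

    @property
    def n_probe_points(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def point_volume(self) -> float:
        return self.spacing ** 3


def seed_probe_grid(placement: Placement, design: ElectrodeDesign,
                    spacing: float = PROBE_SPACING,
                    radius: float = PROBE_RADIUS) -> ProbeGrid:
    """Probe lattice aligned to the electrode tip, spacing 0.05 mm, restricted
    to the 2 mm vicinity of the core contact centre; points inside the
    electrode solid are excluded."""
    center = core_contact_center(design, placement)
    n_half = int(np.floor(radius / spacing))
    offs = spacing * np.arange(-n_half, n_half + 1)
    X, Y, Z = np.meshgrid(*(center[a] + offs for a in range(3)), indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    ball = np.linalg.norm(pts - center, axis=1) <= radius + 1e-12
    zl, rho = placement.local_coords(pts)
    inside = design.inside(zl, rho)
    grid = ProbeGrid(center=center, spacing=spacing,
                     shape=(len(offs),) * 3, points=pts,
                     ball_mask=ball, electrode_mask=inside)
    logger.info("probe grid: %d lattice points, %d probe points",
                len(pts), grid.n_probe_points)
    return grid


def field_divergence(E_grid: np.ndarray, spacing: float = PROBE_SPACING
                     ) -> np.ndarray:
    """Divergence of a vector field sampled on the full regular lattice.

    Central second-order finite differences in the interior, one-sided at the
    lattice boundary.  ``E_grid`` has shape (nx, ny, nz, 3) and may be real
    (peak field) or complex (per-band transfer); the scalar divergence with
    the same dtype is returned, shape (nx, ny, nz).
    """
    E_grid = np.asarray(E_grid)
    if E_grid.ndim != 4 or E_grid.shape[-1] != 3:
        raise ValueError("E_grid must have shape (nx, ny, nz, 3)")
    div = np.zeros(E_grid.shape[:-1], dtype=E_grid.dtype)
    for a in range(3):
        div += np.gradient(E_grid[..., a], spacing, axis=a)
    return div


def classify(values: np.ndarray, threshold: float) -> np.ndarray:
    """Binary activation: metric strictly above threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return np.asarray(values) > threshold


@dataclass
class ActivationReport:
    """Volumes and target shares for one design/target/metric combination."""

    design_name: str
    target_name: str
    thresholds: dict                    # metric -> threshold
    total_volume: dict = field(default_factory=dict)    # metric -> mm^3
    region_volume: dict = field(default_factory=dict)   # metric -> {region: mm^3}
    target_share: dict = field(default_factory=dict)    # metric -> %

    def to_dict(self) -> dict:
        return {"design": self.design_name, "target": self.target_name,
                "thresholds": self.thresholds,
                "total_volume_mm3": self.total_volume,
                "region_volume_mm3": self.region_volume,
                "target_share_pct": self.target_share}


def evaluate_performance(metric_values: dict, grid: ProbeGrid,
                         phantom: TissuePhantom, target_name: str,
                         design_name: str = "",
                         thresholds: dict | None = None,
                         regions: tuple = ("STN", "EPN", "THALAMUS", "IC"),
                         ) -> ActivationReport:
    """Classify probe points and compute activated volumes and target share.

    ``metric_values`` maps metric name ("E" in V/mm, "divE" in V/mm^2) to the
    per-lattice-point peak value.  Volumes count supra-threshold probe points
    (inside the 2 mm ball, outside the electrode) times the point volume;
    region volumes attribute each point to the region of its nearest phantom
    voxel.  The share is 100 * V(target & active) / V(active); with no
    activation it is undefined and reported as NaN with a warning.
    """
    thresholds = dict(thresholds or
                      {"E": THRESHOLD_E, "divE": THRESHOLD_DIV})
    for name in regions:
        if name not in phantom.region_masks:
            raise KeyError(f"unknown region '{name}'")
    if target_name not in regions:
        raise KeyError(f"unknown target region '{target_name}'")
    valid = grid.valid_mask
    pts = grid.points[valid]
    in_region = {name: phantom.mask_at(name, pts) for name in regions}
    vol = grid.point_volume

    report = ActivationReport(design_name=design_name, target_name=target_name,
                              thresholds=thresholds)
    for metric, values in metric_values.items():
        active = classify(np.asarray(values)[valid], thresholds[metric])
        n_act = int(active.sum())
        report.total_volume[metric] = n_act * vol
        report.region_volume[metric] = {
            name: float((active & in_region[name]).sum() * vol)
            for name in regions}
        if n_act == 0:
            warnings.warn(f"no activated points for metric {metric}; "
                          "target share undefined")
            report.target_share[metric] = float("nan")
        else:
            report.target_share[metric] = float(
                100.0 * report.region_volume[metric][target_name]
                / report.total_volume[metric])
    return report


def compare_designs(reports: list[ActivationReport]) -> pd.DataFrame:
    """Tabulate target shares (%) and activated volumes per design.

    One row per (design, target); share and volume columns per metric —
    the layout of the study's performance table.
    """
    rows = []
    for r in reports:
        row = {"design": r.design_name, "target": r.target_name}
        for metric in r.target_share:
            row[f"share_{metric}_pct"] = r.target_share[metric]
            row[f"total_volume_{metric}_mm3"] = r.total_volume[metric]
            row[f"target_volume_{metric}_mm3"] = \
                r.region_volume[metric][r.target_name]
        rows.append(row)
    return pd.DataFrame(rows)
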