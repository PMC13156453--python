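"""Excitation-mode synthesis and NRMSE metrics between B1+ maps.

A mode is a complex weight vector applied to the per-channel B1+ maps; the
error between a simulated and a measured mode map is summarized as the
normalized root-mean-square error (NRMSE), which also defines the
per-channel perturbation bounds used by the Monte-Carlo sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Reference-magnitude floor, as a fraction of the mask-median magnitude,
#: below which voxels are excluded from NRMSE (noise-dominated voxels).
DEFAULT_MAGNITUDE_FLOOR = 0.01


class UndefinedMetricError(ValueError):
    """NRMSE is undefined (zero-norm reference or empty mask)."""


@dataclass
class ExcitationMode:
    """Dimensionless complex channel weights with a human-readable label."""

    weights: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=complex).ravel()
        if self.weights.size == 0 or not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be a finite, nonempty complex vector")
        if not np.any(self.weights != 0):
            raise ValueError("at least one weight must be nonzero")

    @property
    def n_channels(self) -> int:
        return self.weights.size


@dataclass
class MeasuredB1Set:
    """Per-channel measured (or ground-truth) complex B1+ maps.

    ``eval_mask`` is the region where the measurement is trusted; it may be
    a subset of the phantom mask (e.g. a few axial slices).
    """

    b_plus_meas: np.ndarray
    eval_mask: np.ndarray

    def __post_init__(self):
        self.b_plus_meas = np.asarray(self.b_plus_meas, dtype=complex)
        self.eval_mask = np.asarray(self.eval_mask, dtype=bool)
        if self.b_plus_meas.ndim != 4:
            raise ValueError("b_plus_meas must have shape (n_channels, nx, ny, nz)")
        if self.eval_mask.shape != self.b_plus_meas.shape[1:]:
            raise ValueError("eval_mask shape must match the map grid")
        if not self.eval_mask.any():
            raise ValueError("eval_mask is empty")
        if not np.all(np.isfinite(self.b_plus_meas[:, self.eval_mask])):
            raise ValueError("measured maps contain non-finite values inside eval_mask")

    @property
    def n_channels(self) -> int:
        return self.b_plus_meas.shape[0]


@dataclass
class PerChannelErrors:
    """Per-channel NRMSE between simulated and measured B1+ maps.

    These are the box bounds for the real and imaginary perturbations of
    each channel weight in the Monte-Carlo error-space sampler.
    """

    eps_k: np.ndarray

    def __post_init__(self):
        self.eps_k = np.asarray(self.eps_k, dtype=float).ravel()
        if np.any(~np.isfinite(self.eps_k)) or np.any(self.eps_k < 0):
            raise ValueError("per-channel errors must be finite and >= 0")

    @property
    def n_channels(self) -> int:
        return self.eps_k.size


def synthesize_mode(b_plus: np.ndarray, mode: ExcitationMode) -> np.ndarray:
    """Voxelwise weighted sum of per-channel B1+ maps: sum_k w_k * b_k."""
    b_plus = np.asarray(b_plus, dtype=complex)
    if b_plus.shape[0] != mode.n_channels:
        raise ValueError(
            f"mode has {mode.n_channels} weights but maps have {b_plus.shape[0]} channels")
    return np.tensordot(mode.weights, b_plus, axes=1)


def reference_floor_mask(reference: np.ndarray, mask: np.ndarray,
                         floor_rel: float = DEFAULT_MAGNITUDE_FLOOR) -> np.ndarray:
    """Mask excluding voxels whose reference magnitude falls below the floor."""
    ref_mag = np.abs(reference)
    med = np.median(ref_mag[mask])
    keep = mask & (ref_mag >= floor_rel * med)
    n_dropped = int(mask.sum() - keep.sum())
    if n_dropped:
        logger.debug("NRMSE floor excluded %d low-magnitude voxels", n_dropped)
    return keep


def nrmse(a: np.ndarray, b: np.ndarray, mask: np.ndarray,
          magnitude_only: bool = False,
          floor_rel: float = DEFAULT_MAGNITUDE_FLOOR) -> float:
    """NRMSE of map ``a`` against reference map ``b`` over ``mask``.

        sqrt( sum_mask |a - b|^2 ) / sqrt( sum_mask |b|^2 )

    The difference is taken between complex values by default, so phase
    errors count; ``magnitude_only=True`` compares |a| and |b| instead.
    Voxels where |b| is below ``floor_rel`` times the mask-median |b| are
    excluded (they carry no signal and would inflate the metric).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise UndefinedMetricError("mask is empty")
    if floor_rel > 0:
        mask = reference_floor_mask(b, mask, floor_rel)
        if not mask.any():
            raise UndefinedMetricError("all voxels fall below the reference floor")
    av, bv = a[mask], b[mask]
    if magnitude_only:
        av, bv = np.abs(av), np.abs(bv)
    den = np.linalg.norm(bv)
    if den == 0.0:
        raise UndefinedMetricError("reference map has zero norm on the mask")
    return float(np.linalg.norm(av - bv) / den)


def align_global_phase(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Least-squares complex scalar c minimizing ||c*a - b|| over the mask.

    Returns ``c * a``.  Off by default in all pipelines; provided for
    sensitivity analysis when measured maps carry an arbitrary global phase.
    """
    av, bv = a[mask], b[mask]
    denom = np.vdot(av, av)
    if denom == 0:
        raise UndefinedMetricError("cannot phase-align a zero map")
    c = np.vdot(av, bv) / denom
    return c * a


def per_channel_errors(sim_b_plus: np.ndarray, meas: MeasuredB1Set,
                       magnitude_only: bool = False,
                       floor_rel: float = DEFAULT_MAGNITUDE_FLOOR) -> PerChannelErrors:
    """Per-channel NRMSE of the measured maps against the simulated maps.

    The simulated map is the reference, so a uniform relative deviation of
    10% on one channel yields eps_k = 0.10 exactly for that channel.
    """
    sim_b_plus = np.asarray(sim_b_plus, dtype=complex)
    if sim_b_plus.shape[0] != meas.n_channels:
        raise ValueError(
            f"channel count mismatch: {sim_b_plus.shape[0]} simulated vs "
            f"{meas.n_channels} measured")
    eps = [
        nrmse(meas.b_plus_meas[k], sim_b_plus[k], meas.eval_mask,
              magnitude_only=magnitude_only, floor_rel=floor_rel)
        for k in range(meas.n_channels)
    ]
    return PerChannelErrors(eps_k=np.array(eps))
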