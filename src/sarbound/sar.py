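"""Voxelwise and 10 g mass-averaged SAR, Q-matrices and probe-based SAR.

SAR at a voxel is sigma*|E|^2/(2*rho) for peak-phasor fields (the 1/2 is
the time average).  The regulated quantity is the peak of SAR averaged over
contiguous 10 g regions (pSAR10g); here the averaging region is a cube
centered on each voxel, grown symmetrically until it encloses the target
mass of phantom material, with the outermost shell weighted fractionally so
every region averages over exactly the target mass.

For an Nc-channel transmit array the averaged SAR at location r is the
quadratic form w^H Q(r) w in the channel weight vector w, with Q(r) the
Hermitian PSD Q-matrix.  This makes mode-dependent SAR evaluation a dense
linear-algebra operation, which the Monte-Carlo error propagation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .fieldsets import ChannelFieldSet, GridSpec, PhantomModel
from .metrics import ExcitationMode


class PeakSAR(NamedTuple):
    value: float            # W/kg per unit |w|^2
    location: int           # linear voxel index (or probe index for labeled sets)
    label: str | None = None


def voxel_sar(E: np.ndarray, mode: ExcitationMode, phantom: PhantomModel) -> np.ndarray:
    """SAR(r) = sigma(r) * |sum_k w_k E_k(r)|^2 / (2 rho(r)), zero outside mask."""
    E = np.asarray(E, dtype=complex)
    if E.ndim != 5 or E.shape[1] != 3:
        raise ValueError("E must have shape (n_channels, 3, nx, ny, nz)")
    if E.shape[0] != mode.n_channels:
        raise ValueError("channel count mismatch between E and mode")
    total = np.tensordot(mode.weights, E, axes=1)
    sar = phantom.sigma_S_per_m * np.sum(np.abs(total) ** 2, axis=0) / (2.0 * phantom.rho_kg_per_m3)
    return np.where(phantom.mask, sar, 0.0)


def _padded_cumsum(X: np.ndarray) -> np.ndarray:
    P = np.zeros(tuple(n + 1 for n in X.shape), dtype=X.dtype)
    P[1:, 1:, 1:] = X.cumsum(0).cumsum(1).cumsum(2)
    return P


def _cube_sums(P: np.ndarray, h: int) -> np.ndarray:
    """Sum of the integrand over the side-(2h+1) cube centered at every voxel.

    Cubes are clipped at the grid boundary.  ``P`` is the padded integral
    volume from :func:`_padded_cumsum`.
    """
    shape = tuple(n - 1 for n in P.shape)
    los, his = [], []
    for n in shape:
        idx = np.arange(n)
        los.append(np.maximum(idx - h, 0))
        his.append(np.minimum(idx + h + 1, n))
    lx, ly, lz = los
    hx, hy, hz = his
    return (P[np.ix_(hx, hy, hz)]
            - P[np.ix_(lx, hy, hz)] - P[np.ix_(hx, ly, hz)] - P[np.ix_(hx, hy, lz)]
            + P[np.ix_(lx, ly, hz)] + P[np.ix_(lx, hy, lz)] + P[np.ix_(hx, ly, lz)]
            - P[np.ix_(lx, ly, lz)])


class MassAverager:
    """Mass-averaging operator over grown cubes of fixed enclosed mass.

    Precomputes, for every masked voxel, the cube half-width ``h`` at which
    the enclosed masked mass first reaches ``mass_g`` and the fractional
    weight of the outermost shell, so that every region averages over
    exactly ``mass_g`` grams.  ``average`` then applies those weights to any
    scalar volume in a handful of integral-image passes.
    """

    def __init__(self, phantom: PhantomModel, grid: GridSpec,
                 mass_g: float = 10.0, mask: np.ndarray | None = None):
        if mass_g <= 0:
            raise ValueError("averaging mass must be positive")
        self.grid = grid
        self.mass_g = float(mass_g)
        self.mask = phantom.mask if mask is None else (np.asarray(mask, bool) & phantom.mask)
        # voxel mass in grams, zero outside the mask
        self.voxel_mass_g = np.where(
            self.mask, phantom.rho_kg_per_m3 * grid.voxel_volume_m3 * 1e3, 0.0)
        total = float(self.voxel_mass_g.sum())
        if total < self.mass_g:
            raise ValueError(
                f"total phantom mass {total:.2f} g is below the averaging mass {mass_g} g")
        self._P_mass = _padded_cumsum(self.voxel_mass_g)

        shape = grid.shape
        h_map = np.full(shape, -1, dtype=int)
        inner_mass = np.zeros(shape)
        shell_frac = np.zeros(shape)
        prev = np.zeros(shape)
        unresolved = self.mask.copy()
        for h in range(0, max(shape)):
            cur = _cube_sums(self._P_mass, h)
            newly = unresolved & (cur >= self.mass_g)
            h_map[newly] = h
            inner_mass[newly] = prev[newly]
            shell = cur[newly] - prev[newly]
            shell_frac[newly] = (self.mass_g - prev[newly]) / shell
            unresolved &= ~newly
            prev = cur
            if not unresolved.any():
                break
        self.valid_mask = self.mask & (h_map >= 0)
        self.halfwidth = h_map
        self._inner_mass = inner_mass
        self._shell_frac = shell_frac

    def average(self, volume: np.ndarray) -> np.ndarray:
        """Mass-weighted cube average of ``volume``; zero outside valid_mask."""
        Y = np.asarray(volume) * self.voxel_mass_g
        P = _padded_cumsum(Y.astype(complex) if np.iscomplexobj(Y) else Y)
        out = np.zeros(self.grid.shape, dtype=P.dtype)
        hs = np.unique(self.halfwidth[self.valid_mask])
        cache: dict[int, np.ndarray] = {}

        def S(h):
            if h not in cache:
                cache[h] = _cube_sums(P, h)
            return cache[h]

        for h in hs:
            sel = self.valid_mask & (self.halfwidth == h)
            inner = S(h - 1)[sel] if h > 0 else 0.0
            shell = S(h)[sel] - inner
            out[sel] = (inner + self._shell_frac[sel] * shell) / self.mass_g
        return out


@dataclass
class MassAveragedVolume:
    values: np.ndarray
    valid_mask: np.ndarray
    halfwidth: np.ndarray
    mass_g: float


def average_10g(sar: np.ndarray, phantom: PhantomModel, grid: GridSpec,
                mass_g: float = 10.0, mask: np.ndarray | None = None,
                averager: MassAverager | None = None) -> MassAveragedVolume:
    """Mass-average a SAR volume over grown cubes of ``mass_g`` grams.

    Voxels whose cube cannot gather ``mass_g`` of masked material within the
    grid are excluded from ``valid_mask``.
    """
    if averager is None:
        averager = MassAverager(phantom, grid, mass_g=mass_g, mask=mask)
    return MassAveragedVolume(
        values=averager.average(np.asarray(sar, dtype=float)),
        valid_mask=averager.valid_mask,
        halfwidth=averager.halfwidth,
        mass_g=averager.mass_g,
    )


@dataclass
class QMatrixSet:
    """Hermitian PSD Nc x Nc matrices encoding mass-averaged SAR quadratic forms.

    ``locations`` are linear voxel indices into the grid (sorted ascending
    when built from a mask, which fixes the argmax tie-break); labeled probe
    sets carry ``labels`` instead of meaningful grid indices.
    """

    Q: np.ndarray
    locations: np.ndarray
    averaging_mass_g: float = 10.0
    labels: list[str] | None = None
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=complex)
        self.locations = np.asarray(self.locations, dtype=int).ravel()
        if self.Q.ndim != 3 or self.Q.shape[1] != self.Q.shape[2]:
            raise ValueError("Q must have shape (n_locations, Nc, Nc)")
        if self.Q.shape[0] != self.locations.size:
            raise ValueError("locations length must match number of Q matrices")
        if self.labels is not None and len(self.labels) != self.locations.size:
            raise ValueError("labels length must match number of Q matrices")

    @property
    def n_locations(self) -> int:
        return self.Q.shape[0]

    @property
    def n_channels(self) -> int:
        return self.Q.shape[1]

    def validate(self, herm_tol: float = 1e-12, psd_tol: float = 1e-10) -> None:
        """Raise if any matrix is non-Hermitian or indefinite beyond tolerance."""
        scale = np.abs(self.Q).max() or 1.0
        herm_dev = np.abs(self.Q - self.Q.conj().transpose(0, 2, 1)).max()
        if herm_dev > herm_tol * scale:
            raise ValueError(f"Q set not Hermitian: max deviation {herm_dev:.3e}")
        eigs = np.linalg.eigvalsh(0.5 * (self.Q + self.Q.conj().transpose(0, 2, 1)))
        if eigs.min() < -psd_tol * max(eigs.max(), 0.0):
            raise ValueError(f"Q set not PSD: min eigenvalue {eigs.min():.3e}")

    def subset(self, indices: Sequence[int]) -> "QMatrixSet":
        indices = np.asarray(indices, dtype=int)
        return QMatrixSet(
            Q=self.Q[indices], locations=self.locations[indices],
            averaging_mass_g=self.averaging_mass_g,
            labels=None if self.labels is None else [self.labels[i] for i in indices],
            grid_shape=self.grid_shape)

    def pruned(self, quantile: float = 0.95) -> "QMatrixSet":
        """Keep locations whose spectral norm is in the top (1-quantile) tail.

        Heuristic accelerator for Monte-Carlo sweeps: high-|w| peaks live at
        locations with large spectral norm.  Callers should verify winning
        modes on the full set (see uncertainty.estimate_eemm).
        """
        norms = np.linalg.norm(self.Q, ord=2, axis=(1, 2))
        keep = np.flatnonzero(norms >= np.quantile(norms, quantile))
        return self.subset(keep)


def build_qmatrices(E: np.ndarray, phantom: PhantomModel, grid: GridSpec,
                    locations: np.ndarray | None = None,
                    mass_g: float = 10.0,
                    field_mask: np.ndarray | None = None,
                    labels: list[str] | None = None) -> QMatrixSet:
    """Q(r)[j,k] = mass-average over region(r) of sigma * Ej^* . Ek / (2 rho).

    Guarantees w^H Q(r) w == average_10g(voxel_sar(w)) at r, since both use
    the same averaging weights.  ``field_mask`` restricts the averaging
    domain to voxels where E is valid (typically the interior mask).
    ``locations`` defaults to every valid voxel, sorted by linear index.
    """
    E = np.asarray(E, dtype=complex)
    if E.ndim != 5 or E.shape[1] != 3:
        raise ValueError("E must have shape (n_channels, 3, nx, ny, nz)")
    nc = E.shape[0]
    averager = MassAverager(phantom, grid, mass_g=mass_g, mask=field_mask)
    coef = np.where(averager.mask, phantom.sigma_S_per_m / (2.0 * phantom.rho_kg_per_m3), 0.0)

    if locations is None:
        locations = np.flatnonzero(averager.valid_mask.ravel())
    else:
        locations = np.asarray(locations, dtype=int).ravel()
        if not averager.valid_mask.ravel()[locations].all():
            raise ValueError("some requested locations are not valid averaging centers")
    loc_idx = np.unravel_index(locations, grid.shape)

    Q = np.empty((locations.size, nc, nc), dtype=complex)
    for j in range(nc):
        for k in range(j, nc):
            vol = coef * np.sum(E[j].conj() * E[k], axis=0)
            avg = averager.average(vol)
            Q[:, j, k] = avg[loc_idx]
            if k != j:
                Q[:, k, j] = Q[:, j, k].conj()
    return QMatrixSet(Q=Q, locations=locations, averaging_mass_g=mass_g,
                      labels=labels, grid_shape=tuple(grid.shape))


def qmatrices_from_fieldset(fieldset: ChannelFieldSet, **kwargs) -> QMatrixSet:
    """Convenience wrapper using the field set's E field and validity mask."""
    if fieldset.E is None:
        raise ValueError("field set has no E field; call with_efield() first")
    kwargs.setdefault("field_mask", fieldset.e_mask)
    return build_qmatrices(fieldset.E, fieldset.phantom, fieldset.grid, **kwargs)


def psar10g(q: QMatrixSet, mode: ExcitationMode) -> PeakSAR:
    """Peak quadratic form max_r Re(w^H Q(r) w); ties break at lowest index."""
    if q.n_locations == 0:
        raise ValueError("Q-matrix set is empty")
    if mode.n_channels != q.n_channels:
        raise ValueError("channel count mismatch between mode and Q set")
    w = mode.weights
    vals = np.einsum("ljk,j,k->l", q.Q, w.conj(), w).real
    idx = int(np.argmax(vals))
    label = None if q.labels is None else q.labels[idx]
    return PeakSAR(value=float(vals[idx]), location=int(q.locations[idx]), label=label)


def psar_batch(q: QMatrixSet, W: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Peak SAR for a batch of weight vectors W (n_modes, Nc); returns (n_modes,)."""
    W = np.asarray(W, dtype=complex)
    out = np.empty(W.shape[0])
    for start in range(0, W.shape[0], chunk):
        Wc = W[start:start + chunk]
        vals = np.einsum("ljk,nj,nk->nl", q.Q, Wc.conj(), Wc, optimize=True).real
        out[start:start + chunk] = vals.max(axis=1)
    return out


def sar_at_locations(q: QMatrixSet, mode: ExcitationMode) -> np.ndarray:
    """Re(w^H Q w) at every location of the set (no max)."""
    w = mode.weights
    return np.einsum("ljk,j,k->l", q.Q, w.conj(), w).real


@dataclass
class TemperatureSeries:
    """Probe temperature time series for slope-based SAR estimation.

    SAR at a probe tip follows from the initial linear temperature rise,
    SAR = c_rho * dT/dt, with c_rho the specific heat capacity of the
    phantom material (default 3500 J/kg/K).
    """

    times_s: np.ndarray
    temps_K: np.ndarray
    c_rho_J_per_kgK: float = 3500.0
    probe_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float).ravel()
        self.temps_K = np.atleast_2d(np.asarray(self.temps_K, dtype=float))
        if self.times_s.size < 3:
            raise ValueError("need at least 3 time samples for slope fitting")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.temps_K.shape[1] != self.times_s.size:
            raise ValueError("temps_K must have shape (n_probes, n_times)")
        if self.c_rho_J_per_kgK <= 0:
            raise ValueError("specific heat capacity must be positive")
        if not self.probe_labels:
            self.probe_labels = [f"probe{i}" for i in range(self.temps_K.shape[0])]

    @property
    def n_probes(self) -> int:
        return self.temps_K.shape[0]


def probe_sar_from_temperature(ts: TemperatureSeries,
                               window_s: tuple[float, float] = (0.0, 60.0)) -> np.ndarray:
    """Per-probe SAR (W/kg) from the initial linear temperature rise.

    Fits a least-squares line to the samples inside ``window_s`` (inclusive)
    and returns c_rho * slope for each probe.  The window should cover the
    initial linear region, before conduction flattens the curve.
    """
    t0, t1 = window_s
    if not t1 > t0:
        raise ValueError("fitting window has zero or negative time span")
    sel = (ts.times_s >= t0) & (ts.times_s <= t1)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 samples inside the fitting window")
    t = ts.times_s[sel]
    slopes = np.polyfit(t, ts.temps_K[:, sel].T, deg=1)[0]
    return ts.c_rho_J_per_kgK * slopes
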