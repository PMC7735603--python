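"""Fourier features: low-pass filtering and rotational alignment.

Weighted maps are 2D-Fourier transformed (both axes treated as
periodic; the angular axis is naturally periodic and the area weighting
tapers the radial axis toward the centre).  "Filter size" ``f`` keeps
the low-frequency block with radial and angular frequency indices in
``{0, +-1, ..., +-f}``.  Residual orientation differences between
specimens are removed by a generalized-Procrustes-style iteration over
integer rotations about the z-axis, which act on the retained block as
phase factors.  Feature vectors concatenate the real and imaginary
parts of the aligned blocks over the chosen map combination.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .maps import MapSet, MorphoMap, apply_weights

__all__ = [
    "COMBOS",
    "SpectralMap",
    "FeatureVector",
    "forward_fft",
    "lowpass_select",
    "reconstruct",
    "rotational_align",
    "assemble_features",
    "feature_length",
]

#: map-variable combinations explored by the data-mining grids
COMBOS = {
    "chr": ("c", "h", "r"),
    "c": ("c",),
    "hr": ("h", "r"),
    "Nxyz": ("Nx", "Ny", "Nz"),
    "Nxy": ("Nx", "Ny"),
    "Nxyzr": ("Nx", "Ny", "Nz", "r"),
    "chrNxyz": ("c", "h", "r", "Nx", "Ny", "Nz"),
}


@dataclass
class SpectralMap:
    """Unnormalized 2D DFT of one weighted map (DC at index (0, 0))."""

    coefficients: np.ndarray  # (K, L) complex
    parameter: str


@dataclass
class FeatureVector:
    """Concatenated retained Fourier coefficients of one specimen."""

    values: np.ndarray
    combo: str
    filter_size: int
    grid_shape: tuple
    specimen_id: str = ""
    group: str = ""


def forward_fft(morphomap: MorphoMap) -> SpectralMap:
    """Standard unnormalized 2D DFT of a weighted map."""
    if not morphomap.weighted:
        raise InputError("apply area weights before the Fourier transform")
    return SpectralMap(
        coefficients=np.fft.fft2(morphomap.values), parameter=morphomap.parameter
    )


def _freqs(f: int, n: int) -> np.ndarray:
    """Retained frequency indices for one axis of length n.

    The symmetric set {0, +-1, .., +-f}; once 2f+1 reaches n the whole
    axis is retained (indices -n//2 .. n - n//2 - 1), so the maximal
    filter is lossless and Parseval-exact even for even n.
    """
    if 2 * f + 1 >= n:
        return np.arange(-(n // 2), n - n // 2)
    return np.arange(-f, f + 1)


def lowpass_select(spec: SpectralMap, f: int) -> np.ndarray:
    """Retain the (2f+1) x (2f+1) low-frequency block.

    Returned in centred order (frequencies -f..f along each axis).  The
    valid range is ``0 <= f <= min(K, L) // 2``; at the top of the range
    the block is clipped to the axis length and retains everything.
    """
    K, L = spec.coefficients.shape
    if f < 0 or f > min(K, L) // 2:
        raise InputError(f"filter size {f} out of range for grid {K}x{L}")
    fu = _freqs(f, K)
    fv = _freqs(f, L)
    return spec.coefficients[np.ix_(fu % K, fv % L)]


def reconstruct(block: np.ndarray, grid_shape: tuple) -> np.ndarray:
    """Inverse transform of a retained block, zero-filling the rest."""
    K, L = grid_shape
    nu, nv = block.shape
    fu = _freqs((nu - 1) // 2 if nu < K else K // 2, K)
    fv = _freqs((nv - 1) // 2 if nv < L else L // 2, L)
    full = np.zeros((K, L), dtype=complex)
    full[np.ix_(fu % K, fv % L)] = block
    return np.real(np.fft.ifft2(full))


def _phase_table(v_freqs: np.ndarray, L: int) -> np.ndarray:
    """(L, n_v) phases undoing a rotation by s columns, s = 0..L-1."""
    s = np.arange(L)
    return np.exp(2j * np.pi * np.outer(s, v_freqs) / L)


def rotational_align(blocks, L: int, max_iter: int = 100, tol: float = 1e-9):
    """Optimal rotational fitting about the z-axis in Fourier space.

    ``blocks`` is a list of per-specimen arrays ``(n_maps, n_u, n_v)``
    (retained blocks in centred frequency order, stacked over the maps
    of a combo).  A crown rotated by ``s`` grid columns has its block
    multiplied by ``exp(-2i pi v s / L)``; alignment finds, for each
    specimen, the integer shift whose removal minimizes distance to the
    current consensus, iterating shifts and consensus until the total
    squared distance decreases by less than ``tol`` (relative).

    Returns ``(aligned blocks, shifts)`` where ``shifts[i]`` is the
    column rotation that was removed from specimen i.
    """
    blocks = [np.asarray(b) for b in blocks]
    if len(blocks) < 2:
        return [b.copy() for b in blocks], [0] * len(blocks)
    n_v = blocks[0].shape[-1]
    v_freqs = _freqs((n_v - 1) // 2 if n_v < L else L // 2, L)
    phases = _phase_table(v_freqs, L)  # (L, n_v); phases[s] undoes shift s

    X = np.stack(blocks)  # (n, m, nu, nv)
    shifts = np.zeros(len(blocks), dtype=int)
    mean = X[0].copy()
    prev_obj = np.inf
    for _ in range(max_iter):
        # cross-correlation with the consensus, aggregated over maps and u
        g = np.einsum("nmuv,muv->nv", X, np.conj(mean))  # (n, nv)
        scores = np.real(g @ phases.T)  # (n, L): score of undoing shift s
        shifts = np.argmax(scores, axis=1)
        aligned = X * phases[shifts][:, None, None, :]
        mean = aligned.mean(axis=0)
        obj = float(np.sum(np.abs(aligned - mean) ** 2))
        if prev_obj - obj <= tol * max(obj, 1.0):
            break
        prev_obj = obj
    else:
        warnings.warn("rotational alignment did not converge; returning best so far")
    return list(aligned), [int(s) for s in shifts]


def feature_length(combo: str, f: int) -> int:
    """Vector length ``n_maps * 2 * (2f+1)^2`` for a combo and filter."""
    return len(COMBOS[combo]) * 2 * (2 * f + 1) ** 2


def assemble_features(
    mapsets, combo: str, f: int, align: bool = True
) -> tuple[list, list]:
    """Weight, transform, filter and align a sample of specimens.

    For each specimen the maps selected by ``combo`` are area-weighted,
    Fourier-transformed and low-pass filtered; all specimens are then
    jointly aligned by rotation about z on the concatenated blocks, and
    each specimen's aligned block is flattened as real parts followed by
    imaginary parts, map by map in combo order.

    Returns ``(feature_vectors, shifts)``.
    """
    if combo not in COMBOS:
        raise InputError(f"unknown map combination {combo!r}")
    shapes = {ms.grid_shape for ms in mapsets}
    if len(shapes) != 1:
        raise InputError("specimens have mixed grid dimensions")
    K, L = shapes.pop()

    blocks = []
    for ms in mapsets:
        wms = ms if ms.weighted else apply_weights(ms)
        per_map = [
            lowpass_select(forward_fft(wms[p]), f) for p in COMBOS[combo]
        ]
        blocks.append(np.stack(per_map))

    if align:
        blocks, shifts = rotational_align(blocks, L)
    else:
        shifts = [0] * len(blocks)

    vectors = []
    for ms, blk in zip(mapsets, blocks):
        parts = []
        for m in range(blk.shape[0]):
            parts.append(blk[m].real.ravel())
            parts.append(blk[m].imag.ravel())
        vectors.append(
            FeatureVector(
                values=np.concatenate(parts),
                combo=combo,
                filter_size=f,
                grid_shape=(K, L),
                specimen_id=ms.specimen_id,
                group=ms.group,
            )
        )
    return vectors, shifts
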