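"""Orthonormal Haar analysis/synthesis of ordered expression signals.

A signal of length ``n`` (one sample's log2 expression values in genomic
order along a chromosome) is symmetrically extended to the least power of
two ``N >= n`` and decomposed to full depth with the orthonormal Haar
basis, so the coarsest level holds a single scaling coefficient — the
(scaled) chromosome-wide average.  Each detail coefficient contrasts the
averages of two adjacent blocks of 1, 2, 4, 8... probes, which is what
makes spatially coherent runs of probes visible at the scale they occupy.

The transform is decimated and orthonormal: the coefficient count equals
the padded length and energy is preserved (Parseval), so statistics done
in coefficient space are equivalent to statistics on the padded signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import InputError

__all__ = ["WaveletDecomposition", "haar_dwt", "haar_idwt"]

_WAVELET = "haar"
_MODE = "periodization"  # on dyadic lengths this is the plain orthonormal DWT


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


@dataclass
class WaveletDecomposition:
    """Full-depth Haar coefficients of one padded signal.

    Attributes
    ----------
    levels:
        Detail coefficients from finest (length ``N/2``) to coarsest
        (length 1).
    approximation:
        The single coarsest scaling coefficient (length-1 array).
    original_length:
        Length of the signal before padding; inversion strips back to it.
    pad_spec:
        ``(left, right)`` number of samples added by symmetric extension.
    """

    levels: list[np.ndarray]
    approximation: np.ndarray
    original_length: int
    pad_spec: tuple[int, int] = field(default=(0, 0))

    @property
    def padded_length(self) -> int:
        return self.original_length + self.pad_spec[0] + self.pad_spec[1]

    def coefficient_count(self) -> int:
        return self.approximation.size + sum(d.size for d in self.levels)

    # -- flat-vector view -------------------------------------------------
    # Ordering: [approximation, coarsest detail, ..., finest detail].
    # Pattern extraction stacks these vectors into the coefficient x sample
    # matrix that the SVD factorizes.

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.approximation] + self.levels[::-1])

    def with_vector(self, vec: np.ndarray) -> "WaveletDecomposition":
        """Return a structurally identical decomposition holding ``vec``."""
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.coefficient_count():
            raise InputError(
                f"coefficient vector has length {vec.size}, "
                f"expected {self.coefficient_count()}"
            )
        out: list[np.ndarray] = []
        pos = self.approximation.size
        approx = vec[:pos].copy()
        for d in self.levels[::-1]:
            out.append(vec[pos : pos + d.size].copy())
            pos += d.size
        return WaveletDecomposition(
            levels=out[::-1],
            approximation=approx,
            original_length=self.original_length,
            pad_spec=self.pad_spec,
        )

    def finest_detail(self) -> np.ndarray:
        return self.levels[0]

    def _validate(self) -> None:
        n_pad = self.padded_length
        if n_pad != _next_pow2(self.original_length):
            raise InputError("padded length is not the least power of two >= original")
        if self.coefficient_count() != n_pad:
            raise InputError(
                f"coefficient count {self.coefficient_count()} does not match "
                f"padded length {n_pad}"
            )
        expected = n_pad // 2
        for d in self.levels:
            if d.size != expected:
                raise InputError("inconsistent detail-level sizes")
            expected //= 2


def haar_dwt(signal: np.ndarray) -> WaveletDecomposition:
    """Full-depth orthonormal Haar transform of a 1-D signal.

    The signal is extended on the right by symmetric (mirror) reflection to
    the least power of two, then decomposed down to a single approximation
    coefficient.  Energy of the padded signal is preserved exactly.

    Raises
    ------
    InputError
        If the signal is shorter than 2 or contains non-finite values.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 2:
        raise InputError(f"signal length {x.size} < 2")
    if not np.all(np.isfinite(x)):
        raise InputError("signal contains non-finite values")

    n = x.size
    n_pad = _next_pow2(n)
    pad = n_pad - n
    padded = np.pad(x, (0, pad), mode="symmetric") if pad else x

    depth = int(np.log2(n_pad))
    coeffs = pywt.wavedec(padded, _WAVELET, mode=_MODE, level=depth)
    # pywt returns [cA_depth, cD_depth, ..., cD_1] (coarsest -> finest)
    return WaveletDecomposition(
        levels=[np.asarray(c, dtype=float) for c in coeffs[:0:-1]],
        approximation=np.asarray(coeffs[0], dtype=float),
        original_length=n,
        pad_spec=(0, pad),
    )


def haar_idwt(decomp: WaveletDecomposition) -> np.ndarray:
    """Invert :func:`haar_dwt`, stripping the padding.

    Exact inverse: ``haar_idwt(haar_dwt(x)) == x`` to floating-point
    round-off for any length >= 2.
    """
    decomp._validate()
    coeffs = [decomp.approximation] + decomp.levels[::-1]
    rec = pywt.waverec(coeffs, _WAVELET, mode=_MODE)
    left = decomp.pad_spec[0]
    return np.asarray(rec[left : left + decomp.original_length], dtype=float)
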