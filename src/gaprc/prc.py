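"""Positron-range correction operators.

Three modes:

* ``none`` - identity.
* ``tissue_independent`` - one stationary convolution of the whole image with
  the water kernel.
* ``tdsv`` - tissue-dependent, spatially-variant: for each tissue i the image
  is convolved with that tissue's kernel and the result is masked by the
  tissue's binary mask; the n per-tissue images are summed,

      img_prc = sum_i (img (*) kernel_i) (.) mask_i .

The exact adjoint, needed in the OSEM backprojection step, is
sum_i kernel_i-flipped (*) (img (.) mask_i). Convolutions are zero-padded at
the volume border (activity outside the field of view is zero) and evaluated
spectrally with cached kernel FFTs; delta kernels short-circuit to identity so
a correction built from delta kernels is bitwise transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .kernels import PositronKernel
from .segmentation import TissueMaskSet
from .volumes import ActivityVolume

__all__ = ["PRCOperator", "apply_tdsv", "apply_adjoint", "apply_tissue_independent"]


class _ConvPlan:
    """Cached zero-padded FFT convolution of one image shape with one kernel."""

    def __init__(self, img_shape, kernel: np.ndarray):
        self.img_shape = tuple(img_shape)
        self.k_shape = kernel.shape
        full = [i + k - 1 for i, k in zip(img_shape, kernel.shape)]
        self.fshape = [sfft.next_fast_len(s, real=True) for s in full]
        self.kf = sfft.rfftn(kernel, self.fshape)
        self.kf_flip = sfft.rfftn(kernel[::-1, ::-1, ::-1].copy(), self.fshape)
        # 'same' slice: centred part of the full convolution
        self.slices = tuple(
            slice((k - 1) // 2, (k - 1) // 2 + i)
            for i, k in zip(img_shape, kernel.shape)
        )

    def conv(self, img: np.ndarray, flipped: bool = False) -> np.ndarray:
        kf = self.kf_flip if flipped else self.kf
        out = sfft.irfftn(sfft.rfftn(img, self.fshape) * kf, self.fshape)
        return out[self.slices]


@dataclass
class PRCOperator:
    """Positron-range correction operator; build via the factory classmethods."""

    mode: str  # none | tissue_independent | tdsv
    kernels: tuple[PositronKernel, ...] = ()
    masks: TissueMaskSet | None = None
    _plans: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def none(cls) -> "PRCOperator":
        return cls(mode="none")

    @classmethod
    def tissue_independent(cls, water_kernel: PositronKernel) -> "PRCOperator":
        return cls(mode="tissue_independent", kernels=(water_kernel,))

    @classmethod
    def tdsv(cls, kernels, masks: TissueMaskSet) -> "PRCOperator":
        """Pair per-tissue kernels with the mask set, matched by material name.

        ``kernels`` may be a mapping name -> kernel or a sequence aligned with
        ``masks.materials``.
        """
        if hasattr(kernels, "get"):
            try:
                ordered = tuple(kernels[m.name] for m in masks.materials)
            except KeyError as e:
                raise ValueError(f"missing kernel for tissue {e}") from e
        else:
            ordered = tuple(kernels)
            if len(ordered) != masks.n:
                raise ValueError("kernel count does not match mask count")
        return cls(mode="tdsv", kernels=ordered, masks=masks)

    # -- internals ---------------------------------------------------------

    def _plan(self, shape, kernel: PositronKernel) -> _ConvPlan:
        key = (tuple(shape), id(kernel))
        plan = self._plans.get(key)
        if plan is None:
            plan = _ConvPlan(shape, kernel.weights)
            self._plans[key] = plan
        return plan

    def _conv(self, data, kernel, flipped):
        if kernel.is_delta():
            return data if not flipped else data
        return self._plan(data.shape, kernel).conv(data, flipped=flipped)

    def _check(self, img: ActivityVolume):
        if self.mode == "tdsv":
            if self.masks is None:
                raise ValueError("tdsv operator requires masks")
            if tuple(img.data.shape) != tuple(self.masks.grid.shape):
                raise ValueError("image grid does not match mask grid")

    def is_identity(self) -> bool:
        return self.mode == "none" or all(k.is_delta() for k in self.kernels)

    # -- forward / adjoint --------------------------------------------------

    def apply_array(self, data: np.ndarray, adjoint: bool = False) -> np.ndarray:
        """Apply the operator (or its exact transpose) to a raw array.

        No clamping or validation: this is the linear operator used inside
        the forward/backward projection steps of the reconstruction.
        """
        if self.is_identity():
            return data
        if self.mode == "tissue_independent":
            return self._conv(data, self.kernels[0], flipped=adjoint)
        if not adjoint:
            out = np.zeros_like(data)
            for kernel, (_, mask) in zip(self.kernels, self.masks.masks()):
                conv = self._conv(data, kernel, flipped=False)
                out[mask] = conv[mask]
            return out
        out = np.zeros_like(data)
        for kernel, (_, mask) in zip(self.kernels, self.masks.masks()):
            out += self._conv(np.where(mask, data, 0.0), kernel, flipped=True)
        return out

    def apply(self, img: ActivityVolume) -> ActivityVolume:
        """Forward correction (convolve-then-mask for tdsv).

        Tiny negative FFT round-off is clipped to keep the activity volume
        valid; the raw linear operator is ``apply_array``.
        """
        self._check(img)
        if self.is_identity():
            return img
        return img.with_data(np.maximum(self.apply_array(img.data), 0.0))

    def apply_adjoint(self, img: ActivityVolume) -> ActivityVolume:
        """Exact transpose: sum_i flip(kernel_i) (*) (img (.) mask_i)."""
        self._check(img)
        if self.is_identity():
            return img
        return img.with_data(
            np.maximum(self.apply_array(img.data, adjoint=True), 0.0))


def apply_tdsv(img: ActivityVolume, op: PRCOperator) -> ActivityVolume:
    """Tissue-dependent spatially-variant correction (op.mode must be tdsv)."""
    if op.mode != "tdsv":
        raise ValueError(f"operator mode is {op.mode!r}, expected 'tdsv'")
    return op.apply(img)


def apply_tissue_independent(img: ActivityVolume, op: PRCOperator) -> ActivityVolume:
    """Stationary water-kernel correction (op.mode must be tissue_independent)."""
    if op.mode != "tissue_independent":
        raise ValueError(
            f"operator mode is {op.mode!r}, expected 'tissue_independent'")
    return op.apply(img)


def apply_adjoint(img: ActivityVolume, op: PRCOperator) -> ActivityVolume:
    """Adjoint of the configured correction."""
    return op.apply_adjoint(img)
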