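# cython: boundscheck=False, wraparound=False, cdivision=True, language_level=3
"""Fused float32 kernels for the training hot path.

Single-pass C implementations of the GELU forward/backward elementwise
work, pair max-pooling and the Adam update. Numerics match the numpy
fallbacks in ``cnn.py`` (same erf approximation) to float32 precision.
"""

from libc.math cimport expf, fabsf, sqrtf
from libc.string cimport memset

cdef float _P = 0.3275911
cdef float _S = 0.70710678118654752
cdef float _C1 = 0.254829592
cdef float _C2 = -0.284496736
cdef float _C3 = 1.421413741
cdef float _C4 = -1.453152027
cdef float _C5 = 1.061405429
cdef float _INV_SQRT_2PI = 0.3989422804014327


def act_forward(const float[::1] a, float[::1] h, float[::1] phi,
                float[::1] gauss):
    """h = a * Phi(a); also emits Phi(a) and exp(-a^2/2) for the backward."""
    cdef Py_ssize_t i, n = a.shape[0]
    cdef float x, t, poly, g, ph
    for i in range(n):
        x = a[i]
        g = expf(-0.5 * x * x)
        t = 1.0 / (1.0 + _P * (fabsf(x) * _S))
        poly = t * (_C1 + t * (_C2 + t * (_C3 + t * (_C4 + t * _C5)))) * g
        if x >= 0:
            ph = 1.0 - 0.5 * poly
        else:
            ph = 0.5 * poly
        phi[i] = ph
        gauss[i] = g
        h[i] = x * ph


def gelu_vjp(const float[::1] dh, const float[::1] a, const float[::1] phi,
             const float[::1] gauss, float[::1] out):
    """out = dh * (Phi(a) + a * pdf(a)), with pdf from the cached Gaussian."""
    cdef Py_ssize_t i, n = a.shape[0]
    for i in range(n):
        out[i] = dh[i] * (phi[i] + a[i] * _INV_SQRT_2PI * gauss[i])


def pool2_forward(const float[::1] h, float[::1] out, char[::1] mask,
                  Py_ssize_t b, Py_ssize_t l, Py_ssize_t c):
    """Max over adjacent position pairs of a (b, l, c) row-major array.

    ``mask`` records whether the earlier position won (ties included),
    for gradient routing. The trailing odd position is dropped.
    """
    cdef Py_ssize_t lp = l // 2
    cdef Py_ssize_t ib, ip, ic, src, dst
    cdef float left, right
    for ib in range(b):
        for ip in range(lp):
            src = (ib * l + 2 * ip) * c
            dst = (ib * lp + ip) * c
            for ic in range(c):
                left = h[src + ic]
                right = h[src + c + ic]
                if left >= right:
                    out[dst + ic] = left
                    mask[dst + ic] = 1
                else:
                    out[dst + ic] = right
                    mask[dst + ic] = 0


def pool2_backward(const float[::1] dout, const char[::1] mask,
                   float[::1] dh, Py_ssize_t b, Py_ssize_t l, Py_ssize_t c):
    """Scatter pooled gradients back to the winning positions (dh zeroed)."""
    cdef Py_ssize_t lp = l // 2
    cdef Py_ssize_t ib, ip, ic, src, dst
    memset(&dh[0], 0, dh.shape[0] * sizeof(float))
    for ib in range(b):
        for ip in range(lp):
            dst = (ib * l + 2 * ip) * c
            src = (ib * lp + ip) * c
            for ic in range(c):
                if mask[src + ic]:
                    dh[dst + ic] = dout[src + ic]
                else:
                    dh[dst + c + ic] = dout[src + ic]


def im2col(const float[::1] x, float[::1] col,
           Py_ssize_t b, Py_ssize_t l, Py_ssize_t c, Py_ssize_t k):
    """(b, l, c) -> (b, l-k+1, k*c) sliding patches, kernel-offset major."""
    cdef Py_ssize_t lout = l - k + 1
    cdef Py_ssize_t ib, ip, ij, ic, src, dst
    for ib in range(b):
        for ip in range(lout):
            dst = (ib * lout + ip) * k * c
            src = (ib * l + ip) * c
            for ij in range(k):
                for ic in range(c):
                    col[dst + ij * c + ic] = x[src + ij * c + ic]


def col2im(const float[::1] dcol, float[::1] dx,
           Py_ssize_t b, Py_ssize_t l, Py_ssize_t c, Py_ssize_t k):
    """Adjoint of im2col: scatter-add patch gradients (dx zeroed here)."""
    cdef Py_ssize_t lout = l - k + 1
    cdef Py_ssize_t ib, ip, ij, ic, src, dst
    memset(&dx[0], 0, dx.shape[0] * sizeof(float))
    for ib in range(b):
        for ip in range(lout):
            src = (ib * lout + ip) * k * c
            dst = (ib * l + ip) * c
            for ij in range(k):
                for ic in range(c):
                    dx[dst + ij * c + ic] += dcol[src + ij * c + ic]


def adam_step(float[::1] w, const float[::1] g, float[::1] m, float[::1] v,
              float lr_t, float beta1, float beta2, float eps):
    """One fused Adam update with bias-corrected step size ``lr_t``."""
    cdef Py_ssize_t i, n = w.shape[0]
    cdef float mi, vi
    for i in range(n):
        mi = beta1 * m[i] + (1.0 - beta1) * g[i]
        vi = beta2 * v[i] + (1.0 - beta2) * g[i] * g[i]
        m[i] = mi
        v[i] = vi
        w[i] = w[i] - lr_t * mi / (sqrtf(vi) + eps)
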