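"""Diagonal state-space recurrence kernels.

The recurrence is the discrete linear system

    H(t) = A H(t-1) + B X(t)
    Y(t) = C H(t) + D X(t)

applied independently per channel with a diagonal state matrix of size N.
Forward and backward passes are compiled with numba; backpropagation
through the recurrence is the standard adjoint recursion
lambda(t) = C dY(t) + A lambda(t+1).

Two variants exist: a time-invariant one (per-channel constant A, B, C —
the faithful reading of the recurrence as written) and a selective one
where the step size and the B/C projections depend on the input at each
position, following the Mamba convention.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .tensor import Tensor, grad_enabled


# ---------------------------------------------------------------------------
# time-invariant kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lti_fwd(u, abar, bbar, c, d, y, h, store):
    B, D, T = u.shape
    N = abar.shape[1]
    for b in range(B):
        for ch in range(D):
            hloc = np.zeros(N, dtype=u.dtype)
            for t in range(T):
                x = u[b, ch, t]
                acc = 0.0
                for n in range(N):
                    hv = abar[ch, n] * hloc[n] + bbar[ch, n] * x
                    hloc[n] = hv
                    acc += c[ch, n] * hv
                    if store:
                        h[b, ch, t, n] = hv
                y[b, ch, t] = acc + d[ch] * x


@njit(cache=True)
def _lti_bwd(u, abar, bbar, c, d, h, dy, du, dab, dbb, dc, dd):
    B, D, T = u.shape
    N = abar.shape[1]
    for b in range(B):
        for ch in range(D):
            lam = np.zeros(N, dtype=u.dtype)
            for t in range(T - 1, -1, -1):
                x = u[b, ch, t]
                g = dy[b, ch, t]
                acc = 0.0
                for n in range(N):
                    ln = c[ch, n] * g + lam[n]
                    hprev = h[b, ch, t - 1, n] if t > 0 else 0.0
                    dab[ch, n] += ln * hprev
                    dbb[ch, n] += ln * x
                    dc[ch, n] += h[b, ch, t, n] * g
                    acc += bbar[ch, n] * ln
                    lam[n] = abar[ch, n] * ln
                du[b, ch, t] = acc + d[ch] * g
                dd[ch] += x * g


# ---------------------------------------------------------------------------
# selective (input-dependent) kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sel_fwd(u, acont, delta, bseq, cseq, d, y, h, store):
    B, D, T = u.shape
    N = acont.shape[1]
    for b in range(B):
        for ch in range(D):
            hloc = np.zeros(N, dtype=u.dtype)
            for t in range(T):
                x = u[b, ch, t]
                dt = delta[b, ch, t]
                acc = 0.0
                for n in range(N):
                    ab = np.exp(acont[ch, n] * dt)
                    hv = ab * hloc[n] + dt * bseq[b, n, t] * x
                    hloc[n] = hv
                    acc += cseq[b, n, t] * hv
                    if store:
                        h[b, ch, t, n] = hv
                y[b, ch, t] = acc + d[ch] * x


@njit(cache=True)
def _sel_bwd(u, acont, delta, bseq, cseq, d, h, dy,
             du, dacont, ddelta, dbseq, dcseq, dd):
    B, D, T = u.shape
    N = acont.shape[1]
    for b in range(B):
        for ch in range(D):
            lam = np.zeros(N, dtype=u.dtype)
            for t in range(T - 1, -1, -1):
                x = u[b, ch, t]
                dt = delta[b, ch, t]
                g = dy[b, ch, t]
                du_acc = 0.0
                ddt_acc = 0.0
                for n in range(N):
                    ab = np.exp(acont[ch, n] * dt)
                    ln = cseq[b, n, t] * g + lam[n]
                    hprev = h[b, ch, t - 1, n] if t > 0 else 0.0
                    dcseq[b, n, t] += h[b, ch, t, n] * g
                    dacont[ch, n] += ln * hprev * dt * ab
                    ddt_acc += ln * (hprev * acont[ch, n] * ab + bseq[b, n, t] * x)
                    dbseq[b, n, t] += ln * dt * x
                    du_acc += ln * dt * bseq[b, n, t]
                    lam[n] = ab * ln
                du[b, ch, t] = du_acc + d[ch] * g
                ddelta[b, ch, t] = ddt_acc
                dd[ch] += x * g


# ---------------------------------------------------------------------------
# autodiff wrappers
# ---------------------------------------------------------------------------

def _f32(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(a, dtype=np.float32)


def ssm_scan(u: Tensor, abar: Tensor, bbar: Tensor, c: Tensor, d: Tensor) -> Tensor:
    """Time-invariant diagonal SSM scan.

    Parameters
    ----------
    u : (B, D, T) input sequences per channel.
    abar, bbar, c : (D, N) discrete diagonal transition, input and output maps.
    d : (D,) skip gain.
    """
    ud, ab, bb, cc, dd_ = (_f32(t.data) for t in (u, abar, bbar, c, d))
    B, D, T = ud.shape
    N = ab.shape[1]
    store = grad_enabled() and any(t.requires_grad for t in (u, abar, bbar, c, d))
    y = np.empty_like(ud)
    h = np.empty((B, D, T, N), dtype=np.float32) if store else np.empty((1, 1, 1, 1), dtype=np.float32)
    _lti_fwd(ud, ab, bb, cc, dd_, y, h, store)

    def bw(g):
        du = np.empty_like(ud)
        dab = np.zeros_like(ab)
        dbb = np.zeros_like(bb)
        dc = np.zeros_like(cc)
        ddk = np.zeros_like(dd_)
        _lti_bwd(ud, ab, bb, cc, dd_, h, _f32(g), du, dab, dbb, dc, ddk)
        if u.requires_grad:
            u._accum(du)
        if abar.requires_grad:
            abar._accum(dab)
        if bbar.requires_grad:
            bbar._accum(dbb)
        if c.requires_grad:
            c._accum(dc)
        if d.requires_grad:
            d._accum(ddk)

    return Tensor._result(y, (u, abar, bbar, c, d), bw)


def selective_scan(u: Tensor, acont: Tensor, delta: Tensor,
                   bseq: Tensor, cseq: Tensor, d: Tensor) -> Tensor:
    """Input-dependent (Mamba-style) diagonal SSM scan.

    u : (B, D, T); acont : (D, N) continuous-time diagonal (negative);
    delta : (B, D, T) per-position step; bseq, cseq : (B, N, T) shared
    input/output projections; d : (D,) skip gain.
    """
    ud, ac, dl, bs, cs, dd_ = (_f32(t.data) for t in (u, acont, delta, bseq, cseq, d))
    B, D, T = ud.shape
    N = ac.shape[1]
    parents = (u, acont, delta, bseq, cseq, d)
    store = grad_enabled() and any(t.requires_grad for t in parents)
    y = np.empty_like(ud)
    h = np.empty((B, D, T, N), dtype=np.float32) if store else np.empty((1, 1, 1, 1), dtype=np.float32)
    _sel_fwd(ud, ac, dl, bs, cs, dd_, y, h, store)

    def bw(g):
        du = np.empty_like(ud)
        dac = np.zeros_like(ac)
        ddl = np.empty_like(dl)
        dbs = np.zeros_like(bs)
        dcs = np.zeros_like(cs)
        ddk = np.zeros_like(dd_)
        _sel_bwd(ud, ac, dl, bs, cs, dd_, h, _f32(g), du, dac, ddl, dbs, dcs, ddk)
        for t, gr in zip(parents, (du, dac, ddl, dbs, dcs, ddk)):
            if t.requires_grad:
                t._accum(gr)

    return Tensor._result(y, parents, bw)
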