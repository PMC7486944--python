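"""Single-site Gibbs sweep over the mixed-model equations (numba hot loop).

One call draws every location effect once from its scalar Gaussian full
conditional, using the current (co)variance components.  The coefficient
matrix is never assembled: the data part enters through the cross-product
``W'W`` (CSR) scaled by ``1/sigma_e^2`` and the random-effect penalties are
applied on the fly -- the genetic (a_D, a_S) rows read the relationship
kernel inverse K (CSR) scaled by the entries of C^-1, the litter/early-life
rows add the 2x2 litter-block precision, and pen/group/permanent-environment
rows add scalar precisions.
"""

import math

from numba import njit


@njit(cache=True)
def gibbs_sweep(
    wdata, windices, windptr, rhs, theta, inv_se,
    kdata, kindices, kindptr,
    nped, off_aD, off_c, nc, off_g, ng, off_pe, npe, off_l, nl,
    c00, c01, c11, l00, l01, l11,
    inv_sc, inv_sg, inv_spe, z,
):
    n = theta.shape[0]
    off_aS = off_aD + nped
    off_k = off_l + nl
    for i in range(n):
        s = 0.0
        dw = 0.0
        for idx in range(windptr[i], windptr[i + 1]):
            j = windices[idx]
            if j == i:
                dw = wdata[idx]
            else:
                s += wdata[idx] * theta[j]
        poff = 0.0
        pdiag = 0.0
        if off_aD <= i < off_aS:
            m = i - off_aD
            sD = 0.0
            sS = 0.0
            hd = 0.0
            for idx in range(kindptr[m], kindptr[m + 1]):
                j = kindices[idx]
                v = kdata[idx]
                if j == m:
                    hd = v
                sD += v * theta[off_aD + j]
                sS += v * theta[off_aS + j]
            pdiag = c00 * hd
            poff = c00 * sD + c01 * sS - pdiag * theta[i]
        elif off_aS <= i < off_aS + nped:
            m = i - off_aS
            sD = 0.0
            sS = 0.0
            hd = 0.0
            for idx in range(kindptr[m], kindptr[m + 1]):
                j = kindices[idx]
                v = kdata[idx]
                if j == m:
                    hd = v
                sD += v * theta[off_aD + j]
                sS += v * theta[off_aS + j]
            pdiag = c11 * hd
            poff = c01 * sD + c11 * sS - pdiag * theta[i]
        elif off_c <= i < off_c + nc:
            pdiag = inv_sc
        elif off_g <= i < off_g + ng:
            pdiag = inv_sg
        elif off_pe <= i < off_pe + npe:
            pdiag = inv_spe
        elif off_l <= i < off_k:
            pdiag = l00
            poff = l01 * theta[off_k + i - off_l]
        elif off_k <= i < off_k + nl:
            pdiag = l11
            poff = l01 * theta[off_l + i - off_k]
        prec = dw * inv_se + pdiag
        mean = (rhs[i] * inv_se - s * inv_se - poff) / prec
        theta[i] = mean + z[i] / math.sqrt(prec)
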