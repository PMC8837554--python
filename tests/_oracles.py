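"""Independent oracles used by the test suite.

Each oracle recomputes a pipeline quantity by a different route (numerical
integration, individual-level regression, brute-force enumeration) and is
kept deliberately independent of the implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


# -- subtype classifier: marginal likelihoods by adaptive quadrature --------

def quad_log_ml(b_mo, b_ma, se_mo, se_ma, c, tau):
    """Log marginal likelihoods of the four models by numerical integration.

    NULL needs no integration; MO, MA and the fixed half of BOTH are 1-D
    integrals over the shared/nonzero effect; the independent half of BOTH
    is a 2-D integral. The integrand over the effect is a Gaussian bump;
    Gaussian algebra locates its mode and width only to center the
    integration window and shift the exponent out of the danger zone — the
    integral itself is fully numeric.
    """
    b = np.array([b_mo, b_ma])
    sigma = np.array([[se_mo ** 2, c * se_mo * se_ma],
                      [c * se_mo * se_ma, se_ma ** 2]])
    sigma_inv = np.linalg.inv(sigma)
    logdet = float(np.linalg.slogdet(sigma)[1])
    log_tau_norm = -0.5 * np.log(2 * np.pi) - np.log(tau)

    def loglike(r1, r2):
        quad_form = (sigma_inv[0, 0] * r1 * r1
                     + 2 * sigma_inv[0, 1] * r1 * r2
                     + sigma_inv[1, 1] * r2 * r2)
        return -np.log(2 * np.pi) - 0.5 * logdet - 0.5 * quad_form

    def logprior(t):
        return log_tau_norm - 0.5 * (t / tau) ** 2

    out = {"NULL": float(loglike(b[0], b[1]))}

    def one_dim(a_vec):
        """Integrate N(b; a t, Sigma) N(t; 0, tau^2) dt in log space."""
        prec = float(a_vec @ sigma_inv @ a_vec) + 1.0 / tau ** 2
        mode = float(a_vec @ sigma_inv @ b) / prec
        width = 1.0 / np.sqrt(prec)

        def log_f(t):
            return loglike(b[0] - a_vec[0] * t, b[1] - a_vec[1] * t) \
                + logprior(t)

        shift = log_f(mode)

        def g(t):
            return np.exp(log_f(t) - shift)

        val, _ = integrate.quad(g, mode - 12 * width, mode + 12 * width,
                                epsabs=1e-14, epsrel=1e-10, limit=200)
        return shift + np.log(val)

    out["MO"] = one_dim(np.array([1.0, 0.0]))
    out["MA"] = one_dim(np.array([0.0, 1.0]))
    log_fixed = one_dim(np.array([1.0, 1.0]))

    # independent-effects component: 2-D integral with a mode-centered box
    v_post = np.linalg.inv(sigma_inv + np.eye(2) / tau ** 2)
    mode2 = v_post @ sigma_inv @ b
    w1, w2 = np.sqrt(np.diag(v_post))

    def log_f2(t1, t2):
        return (loglike(b[0] - t1, b[1] - t2)
                + logprior(t1) + logprior(t2))

    shift2 = log_f2(*mode2)

    def g2(t2, t1):
        return np.exp(log_f2(t1, t2) - shift2)

    val2, _ = integrate.dblquad(
        g2, mode2[0] - 12 * w1, mode2[0] + 12 * w1,
        mode2[1] - 12 * w2, mode2[1] + 12 * w2,
        epsabs=1e-12, epsrel=1e-9)
    log_indep = shift2 + np.log(val2)

    out["BOTH"] = np.logaddexp(log_fixed, log_indep) - np.log(2.0)
    return out


# -- meta-analysis: intercept-only weighted least squares -------------------

def wls_pool(betas, ses):
    """Pooled (beta, se) from an intercept-only WLS fit, from first
    principles: ``beta = (X'WX)^{-1} X'Wy`` with X = 1, W = diag(1/se^2)."""
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    xtwx = w.sum()
    beta = float((w * np.asarray(betas, dtype=float)).sum() / xtwx)
    return beta, float(np.sqrt(1.0 / xtwx))


# -- conditional analysis: individual-level forward selection ---------------

def marginal_sumstats(x, y):
    """Per-variant marginal OLS estimates (beta, se, z) from raw data."""
    n = len(y)
    betas, ses = [], []
    for j in range(x.shape[1]):
        xj = x[:, j]
        sxx = xj @ xj
        b = (xj @ y) / sxx
        resid = y - b * xj
        sigma2 = (resid @ resid) / (n - 2)
        betas.append(b)
        ses.append(np.sqrt(sigma2 / sxx))
    betas = np.array(betas)
    ses = np.array(ses)
    return betas, ses, betas / ses


def forward_selection(x, y, p_stop):
    """Joint-regression forward stepwise selection on individual-level data.

    Seeds with the minimum marginal-p variant, then repeatedly refits the
    joint OLS with each remaining candidate and adds the one with the
    smallest Wald p while it stays below *p_stop*.
    """
    n, m = x.shape
    _, _, z = marginal_sumstats(x, y)
    p_marg = 2 * stats.norm.sf(np.abs(z))
    selected = [int(np.argmin(p_marg))]
    remaining = [j for j in range(m) if j != selected[0]]
    while remaining:
        best = None
        for j in remaining:
            cols = selected + [j]
            xs = x[:, cols]
            coef, _, rank, _ = np.linalg.lstsq(xs, y, rcond=None)
            if rank < len(cols):
                continue
            resid = y - xs @ coef
            sigma2 = (resid @ resid) / (n - len(cols))
            cov = sigma2 * np.linalg.inv(xs.T @ xs)
            zj = coef[-1] / np.sqrt(cov[-1, -1])
            pj = 2 * stats.norm.sf(abs(zj))
            if best is None or pj < best[0]:
                best = (pj, j)
        if best is None or best[0] >= p_stop:
            break
        selected.append(best[1])
        remaining.remove(best[1])
    return selected


# -- risk loci: brute-force invariant checker -------------------------------

def check_loci(loci, gws, panel, r2_index=0.1, merge_gap=250_000):
    """Exhaustively verify the locus-calling invariants on a small instance.

    Every GWS variant belongs to exactly one locus; no two final loci on a
    chromosome are within *merge_gap* of each other; no pair of index
    variants has known r^2 > *r2_index*; members lie within their locus
    interval and on its chromosome.
    """
    membership = {}
    for i, lo in enumerate(loci):
        for m in lo.members:
            assert m not in membership, f"variant {m} in two loci"
            membership[m] = i
    assert set(membership) == set(gws["SNP"]), "coverage of GWS variants"

    info = gws.set_index("SNP")
    for lo in loci:
        assert lo.start <= lo.end
        for m in lo.members:
            assert str(info.loc[m, "CHR"]) == lo.chrom
            assert lo.start <= int(info.loc[m, "BP"]) <= lo.end

    by_chrom = {}
    for lo in loci:
        by_chrom.setdefault(lo.chrom, []).append(lo)
    for group in by_chrom.values():
        group = sorted(group, key=lambda lo: lo.start)
        for a, b in zip(group[:-1], group[1:]):
            assert b.start - a.end >= merge_gap, "loci closer than merge gap"

    indices = [ix for lo in loci for ix in lo.index_variants]
    for i, a in enumerate(indices):
        for b in indices[i + 1:]:
            if panel.has(a) and panel.has(b):
                assert panel.r2(a, b) <= r2_index, \
                    f"index pair {a},{b} with r2 > {r2_index}"
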