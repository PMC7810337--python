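"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity through a different computational route
than the library (full recounts, dense decompositions, explicit densities)
so agreement is evidence of correctness, not shared code.
"""

import numpy as np
import scipy.linalg
import scipy.stats

from breedtrace.genotype_io import MISSING
from breedtrace.roh import RohParams, RohSegment


def roh_scan_oracle(genotypes, positions, params: RohParams,
                    sample_id="", chromosome=""):
    """Exhaustive-window consecutive scan: every window is re-validated from
    scratch with full numpy recounts (no incremental counters)."""
    g = np.asarray(genotypes)
    pos = np.asarray(positions, dtype=np.int64)
    n = g.size

    def window_valid(s, e):
        w = g[s : e + 1]
        if int(np.sum(w == 1)) > params.max_het:
            return False
        if int(np.sum(w == MISSING)) > params.max_miss:
            return False
        if params.max_gap_bp is not None and e > s:
            if int(np.max(np.diff(pos[s : e + 1]))) > params.max_gap_bp:
                return False
        return True

    out = []
    s = 0
    while s < n:
        if not window_valid(s, s):
            s += 1
            continue
        e = s
        while e + 1 < n and window_valid(s, e + 1):
            e += 1
        if e - s + 1 >= params.min_snp and pos[e] - pos[s] >= params.min_length_bp:
            out.append(
                RohSegment(sample_id, chromosome, int(pos[s]), int(pos[e]), e - s + 1)
            )
        if e + 1 >= n:
            inside = [
                int(i)
                for i in np.flatnonzero((g[s : e + 1] == 1) | (g[s : e + 1] == MISSING))
            ]
            if not inside:
                break
            s = s + inside[0] + 1
            continue
        nxt = e + 1
        gap_violated = (
            params.max_gap_bp is not None and pos[nxt] - pos[e] > params.max_gap_bp
        )
        if gap_violated:
            s = nxt
        elif g[nxt] == 1:
            hets = [int(i) for i in np.flatnonzero(g[s : e + 1] == 1)]
            s = s + hets[0] + 1 if hets else e + 2
        else:  # missing-call violation
            misses = [int(i) for i in np.flatnonzero(g[s : e + 1] == MISSING)]
            s = s + misses[0] + 1 if misses else e + 2
    return out


def admixture_loglik_naive(G, Q, F):
    """Term-by-term double-loop binomial log-likelihood."""
    total = 0.0
    eps = 1e-6
    n, m = np.asarray(G).shape
    for i in range(n):
        for j in range(m):
            g = G[i][j] if not isinstance(G, np.ndarray) else G[i, j]
            if g == MISSING:
                continue
            p = min(max(sum(Q[i][k] * F[k][j] for k in range(len(F))), eps), 1 - eps)
            total += g * np.log(p) + (2 - g) * np.log(1 - p)
    return total


def pca_eigen_oracle(Xc):
    """Scores of a centered matrix from the dense covariance eigenproblem."""
    n = Xc.shape[0]
    C = (Xc.T @ Xc) / 1.0
    w, V = scipy.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    return Xc @ V, np.clip(w, 0, None)


def lda_posterior_oracle(scores_train, y, scores_test, ridge=1e-6):
    """Gaussian class posteriors via explicit multivariate-normal densities."""
    classes = sorted(set(y))
    n, d = scores_train.shape
    mus = {}
    Sw = np.zeros((d, d))
    for c in classes:
        Z = scores_train[np.asarray(y) == c]
        mus[c] = Z.mean(axis=0)
        D = Z - mus[c]
        Sw += D.T @ D
    Sw /= max(n - len(classes), 1)
    Sw += ridge * (np.trace(Sw) / d) * np.eye(d)
    priors = {c: (np.asarray(y) == c).mean() for c in classes}
    out = np.zeros((scores_test.shape[0], len(classes)))
    for i, x in enumerate(scores_test):
        dens = np.array(
            [
                priors[c] * scipy.stats.multivariate_normal.pdf(x, mus[c], Sw)
                for c in classes
            ]
        )
        out[i] = dens / dens.sum()
    return out


def hudson_fst(calls_a, calls_b):
    """Hudson's FST estimator (ratio of averages) from two dosage matrices."""
    def freq_and_n(calls):
        G = np.asarray(calls, dtype=float)
        obs = G != MISSING
        n_allele = 2 * obs.sum(axis=0)
        cnt = np.where(obs, G, 0.0).sum(axis=0)
        return cnt / np.maximum(n_allele, 1), n_allele

    p1, n1 = freq_and_n(calls_a)
    p2, n2 = freq_and_n(calls_b)
    ok = (n1 > 2) & (n2 > 2)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())


def random_roh_vector(rng, n=300, span_bp=30_000_000):
    """Random dosage vector + positions with a homozygosity-skewed mix."""
    g = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8), size=n,
        p=[0.42, 0.18, 0.35, 0.05],
    )
    pos = np.unique(rng.integers(1, span_bp, size=n))
    while pos.size < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, span_bp, size=n - pos.size)]))
    return g, pos
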