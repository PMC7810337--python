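"""Population structure: genotype PCA and maximum-likelihood admixture.

The admixture model treats each individual i as a mixture over K ancestral
populations with proportions q_ik (rows of Q sum to one) and per-ancestry
allele frequencies f_kj.  Each genotype g_ij in {0,1,2} is Binomial(2,
pi_ij) with pi_ij = sum_k q_ik f_kj, so the log-likelihood is

    l(Q, F) = sum_ij [ g_ij log(pi_ij) + (2 - g_ij) log(1 - pi_ij) ]

with missing entries skipped.  Fitting alternates exact EM updates of Q and
F, which never decrease the likelihood; random restarts guard against local
optima.  The number of ancestries K is chosen by 10-fold cross-validation
that masks genotype *entries*, refits, and scores the squared error of the
expected dosage 2*pi on the masked entries — the same scheme as the
ADMIXTURE software's --cv option.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

EPS_FREQ = 1e-6  # frequency clamp: f in [EPS_FREQ, 1 - EPS_FREQ]


@dataclass
class PcaResult:
    """Thin-SVD PCA of a centered genotype matrix."""

    scores: np.ndarray  # samples x components (U * S)
    loadings: np.ndarray  # loci x components (V)
    explained_variance: np.ndarray  # fraction per component, non-increasing


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # n x K ancestry fractions
    F: np.ndarray  # K x m ancestral allele frequencies
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray | None = None  # per-iteration trace of the best restart


@dataclass
class KSelectionReport:
    cv_errors: dict[int, float]  # K -> mean masked-entry squared error
    selected_K: int


# ---------------------------------------------------------------------------
# Standardization and PCA
# ---------------------------------------------------------------------------

def standardize_genotypes(
    ds_or_calls: GenotypeDataset | np.ndarray, scale: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-impute missing calls and center columns.

    Returns ``(matrix, column_means, kept_columns)``; columns monomorphic
    after imputation (zero variance) are dropped and their absence reported
    through *kept_columns* (boolean over the input columns).  Unit-variance
    scaling is off by default.
    """
    calls = ds_or_calls.calls if isinstance(ds_or_calls, GenotypeDataset) else ds_or_calls
    X = np.asarray(calls, dtype=float)
    miss = X == MISSING
    if miss.all(axis=0).any():
        bad = int(np.flatnonzero(miss.all(axis=0))[0])
        raise ValueError(f"column {bad} is entirely missing")
    X = np.where(miss, np.nan, X)
    means = np.nanmean(X, axis=0)
    X = np.where(miss, means[None, :], X)
    Xc = X - means[None, :]
    var = Xc.var(axis=0)
    keep = var > 0
    Xc = Xc[:, keep]
    if scale:
        Xc = Xc / np.sqrt(var[keep])[None, :]
    return Xc, means, keep


def genotype_pca(matrix: np.ndarray, n_components: int | None = None) -> PcaResult:
    """Thin SVD of a centered matrix; scores = U*S, loadings = V."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    k = len(s) if n_components is None else min(n_components, len(s))
    return PcaResult(
        scores=u[:, :k] * s[:k],
        loadings=vt[:k].T,
        explained_variance=explained[:k],
    )


# ---------------------------------------------------------------------------
# Admixture likelihood and EM
# ---------------------------------------------------------------------------

def _as_float_geno(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(dosages with missing as nan, observed mask)."""
    G = np.asarray(G, dtype=float)
    obs = G != MISSING
    return np.where(obs, G, np.nan), obs


def admixture_loglik(G: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    """Binomial admixture log-likelihood; missing entries contribute zero."""
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    Gf, obs = _as_float_geno(G)
    if Q.shape[0] != Gf.shape[0] or F.shape[1] != Gf.shape[1] or Q.shape[1] != F.shape[0]:
        raise ValueError("dimension mismatch between G, Q and F")
    P = np.clip(Q @ F, EPS_FREQ, 1 - EPS_FREQ)
    g = np.where(obs, Gf, 0.0)
    terms = g * np.log(P) + (2.0 - g) * np.log1p(-P)
    return float(np.where(obs, terms, 0.0).sum())


def _em_step(g1, g0, denom, Q, F):
    """One EM update of (Q, F) from shared responsibilities.

    *g1* holds allele-1 copy counts (missing pre-zeroed), *g0* the allele-2
    counts 2-g (also zero at missing), *denom* the per-sample 2 x observed
    count.  Both blocks are updated from the same E-step, the classic EM with
    the ascent property; returns the new (Q, F) and the log-likelihood of the
    *incoming* parameters (computed from the same probability matrix).
    """
    P = np.clip(Q @ F, EPS_FREQ, 1 - EPS_FREQ)  # n x m
    ll = float(np.sum(g1 * np.log(P)) + np.sum(g0 * np.log1p(-P)))
    w1 = g1 / P            # weight of allele-1 copies (zero at missing)
    w0 = g0 / (1.0 - P)
    # E-step responsibilities folded into the M-step sums:
    A = (w1 @ F.T) * Q     # n x K: expected allele-1 copies from ancestry k
    B = (w0 @ (1.0 - F).T) * Q
    Q_new = (A + B) / denom
    rs = Q_new.sum(axis=1, keepdims=True)
    Q_new = np.where(rs > 0, Q_new / np.maximum(rs, 1e-300), 1.0 / Q.shape[1])

    num = F * (Q.T @ w1)           # K x m
    den = num + (1.0 - F) * (Q.T @ w0)
    F_new = np.where(den > 0, num / np.maximum(den, 1e-300), F)
    F_new = np.clip(F_new, EPS_FREQ, 1 - EPS_FREQ)
    return Q_new, F_new, ll


def admixture_fit(
    G: np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 3,
    record_path: bool = False,
) -> AdmixtureFit:
    """Maximum-likelihood admixture with K ancestries via alternating EM.

    *tol* is the relative log-likelihood gain below which iteration stops;
    the best of *n_restarts* random initializations is kept.  Non-convergence
    is reported through ``converged=False``, never raised.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Gf, obs = _as_float_geno(G)
    n, m = Gf.shape
    g1 = np.where(obs, Gf, 0.0)
    g0 = np.where(obs, 2.0 - Gf, 0.0)
    denom = np.maximum(2.0 * obs.sum(axis=1, keepdims=True), 1.0)
    rng = np.random.default_rng(seed)
    best: AdmixtureFit | None = None
    for _ in range(max(1, n_restarts)):
        Q = rng.dirichlet(np.ones(K), size=n)
        F = np.clip(rng.uniform(0.05, 0.95, size=(K, m)), EPS_FREQ, 1 - EPS_FREQ)
        path = []
        ll_prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            Q, F, ll = _em_step(g1, g0, denom, Q, F)
            path.append(ll)
            if np.isfinite(ll_prev) and ll - ll_prev <= tol * (abs(ll_prev) + 1.0):
                converged = True
                break
            ll_prev = ll
        final_ll = admixture_loglik(G, Q, F)
        path.append(final_ll)
        fit = AdmixtureFit(
            K=K, Q=Q, F=F, loglik=final_ll, n_iter=it, converged=converged,
            loglik_path=np.array(path) if record_path else None,
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def align_ancestries(Q_hat: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute the columns of Q_hat to best match Q_true (Hungarian assignment)."""
    from scipy.optimize import linear_sum_assignment

    cost = np.zeros((Q_hat.shape[1], Q_true.shape[1]))
    for a in range(Q_hat.shape[1]):
        for b in range(Q_true.shape[1]):
            cost[a, b] = np.abs(Q_hat[:, a] - Q_true[:, b]).sum()
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty_like(rows)
    perm[cols] = rows
    return Q_hat[:, perm]


# ---------------------------------------------------------------------------
# Cross-validated choice of K
# ---------------------------------------------------------------------------

def select_k_cv(
    G: np.ndarray,
    K_range=range(2, 11),
    folds: int = 10,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
    n_restarts: int = 1,
) -> KSelectionReport:
    """Choose K by masking genotype entries fold-wise and scoring prediction error.

    Non-missing entries are partitioned into *folds* folds; for each fold
    and K the fold's entries are hidden, the model refit, and the error is
    the mean squared difference between the hidden dosages and their
    expected value 2*sum_k q_ik f_kj.  Ties go to the smallest K.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("empty K range")
    G = np.asarray(G)
    obs_idx = np.argwhere(G != MISSING)
    if len(obs_idx) < folds:
        raise ValueError("fewer observed entries than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(obs_idx))
    fold_of = np.empty(len(obs_idx), dtype=int)
    fold_of[perm] = np.arange(len(obs_idx)) % folds

    errors = {K: [] for K in K_range}
    for f in range(folds):
        mask = obs_idx[fold_of == f]
        if len(mask) == 0:
            raise ValueError(f"fold {f} has zero masked entries")
        G_train = G.copy()
        G_train[mask[:, 0], mask[:, 1]] = MISSING
        truth = G[mask[:, 0], mask[:, 1]].astype(float)
        for K in K_range:
            fit = admixture_fit(
                G_train, K, seed=int(rng.integers(2**31)),
                tol=tol, max_iter=max_iter, n_restarts=n_restarts,
            )
            pred = 2.0 * np.einsum(
                "ik,ki->i", fit.Q[mask[:, 0]], fit.F[:, mask[:, 1]]
            )
            errors[K].append(float(np.mean((truth - pred) ** 2)))

    mean_err = {K: float(np.mean(v)) for K, v in errors.items()}
    best = min(mean_err, key=lambda K: (mean_err[K], K))
    return KSelectionReport(cv_errors=mean_err, selected_K=best)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_admixture_outputs(
    fit: AdmixtureFit, ds: GenotypeDataset, out_dir: str | Path
) -> dict[str, Path]:
    """Write Q / F as whitespace-delimited matrices plus per-breed mean Q."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    q_path = out_dir / f"admixture.{fit.K}.Q"
    f_path = out_dir / f"admixture.{fit.K}.P"
    np.savetxt(q_path, fit.Q, fmt="%.6f")
    np.savetxt(f_path, fit.F.T, fmt="%.6f")  # loci x K, as .P files are laid out
    qdf = pd.DataFrame(fit.Q, columns=[f"Q{k+1}" for k in range(fit.K)])
    qdf.insert(0, "breed", ds.breeds)
    mean_q = qdf.groupby("breed").mean()
    mq_path = out_dir / f"admixture.{fit.K}.breed_mean_Q.tsv"
    mean_q.to_csv(mq_path, sep="\t")
    return {"Q": q_path, "P": f_path, "breed_mean_Q": mq_path}


def write_k_selection(report: KSelectionReport, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("K\tcv_error\tselected\n")
        for K in sorted(report.cv_errors):
            sel = int(K == report.selected_K)
            fh.write(f"{K}\t{report.cv_errors[K]:.6f}\t{sel}\n")
    return path
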