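"""Discriminant analysis of principal components (DAPC) for breed traceability.

DAPC is a two-step classifier: genotypes are first reduced by PCA, then a
linear discriminant analysis (LDA) is fitted on a small number of retained
principal components.  The number of retained PCs is chosen by repeated
stratified k-fold cross-validation, keeping the count with the highest mean
assignment success.  Three validation scenarios are provided:

* supervised  — train and report on the full panel (upper bound);
* semi-supervised — hold out a few individuals of one target breed, train
  on everything else (the target breed stays represented), classify the
  holdout; repeated and averaged;
* unsupervised — the target breed is absent from training; its individuals
  must be attributed to one of the remaining breeds, at a range of
  training-set sizes.  This doubles as a genomic-similarity probe.

All randomness is driven by explicit seeds; results are reproducible
bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class DapcModel:
    """Trained PCA rotation + LDA discriminants with projection metadata."""

    snp_ids: list[str]
    pca_center: np.ndarray       # per-SNP training means (imputation values)
    pca_loadings: np.ndarray     # loci x n_pc
    n_pc: int
    class_labels: list[str]      # sorted breed labels
    class_priors: np.ndarray
    lda_means: np.ndarray        # classes x n_pc, in PC space
    lda_cov_inv: np.ndarray      # regularized pooled within-class covariance inverse
    lda_discriminants: np.ndarray  # n_pc x (n_classes - 1) canonical axes
    explained_variance_share: float  # variance share of the retained PCs


@dataclass
class AssignmentResult:
    sample_id: str
    true_breed: str | None
    predicted_breed: str
    posterior: dict[str, float]


@dataclass
class CvReport:
    success_by_n_pc: pd.DataFrame  # columns: n_pc, mean_success, sd_success
    selected_n_pc: int
    per_breed_success: pd.Series | None = None
    model: DapcModel | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Linear algebra helpers
# ---------------------------------------------------------------------------

def impute_center(calls: np.ndarray, means: np.ndarray | None = None):
    """Replace missing calls by (training) column means and center."""
    X = np.asarray(calls, dtype=float)
    miss = X == MISSING
    X = np.where(miss, np.nan, X)
    if means is None:
        means = np.nanmean(X, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
    X = np.where(miss, means[None, :], X)
    return X - means[None, :], means


def _pca_rotation(Xc: np.ndarray, n_comp: int):
    """Top-*n_comp* right singular vectors of the centered matrix.

    Uses the Gram-matrix eigendecomposition when loci outnumber samples
    (identical to the thin SVD, far cheaper for n << m).  Returns
    (loadings m x k, explained-variance fractions over ALL components).
    """
    n, m = Xc.shape
    n_comp = min(n_comp, n - 1 if n > 1 else 1, m)
    if m > n:
        Gm = Xc @ Xc.T
        w, U = scipy.linalg.eigh(Gm)
        w = w[::-1]
        U = U[:, ::-1]
        w = np.clip(w, 0.0, None)
        total = w.sum()
        s = np.sqrt(w[:n_comp])
        nz = s > 1e-12
        V = np.zeros((m, n_comp))
        V[:, nz] = Xc.T @ (U[:, :n_comp][:, nz] / s[nz])
        ev = w / total if total > 0 else np.zeros_like(w)
        return V, ev
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    ev = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return vt[:n_comp].T, ev


# ---------------------------------------------------------------------------
# Fit / predict
# ---------------------------------------------------------------------------

class SingularWithinCovariance(Exception):
    pass


def fit_dapc(
    train: GenotypeDataset | np.ndarray,
    labels: list[str] | np.ndarray | None = None,
    n_pc: int = 40,
    ridge: float = 1e-6,
    snp_ids: list[str] | None = None,
) -> DapcModel:
    """Fit PCA followed by LDA on the retained principal components.

    *ridge* scales an identity added to the pooled within-class covariance
    (ridge * mean diagonal), making near-singular fits explicit rather than
    silently pseudo-inverted.
    """
    if isinstance(train, GenotypeDataset):
        calls = train.calls
        labels = train.breeds if labels is None else list(labels)
        snp_ids = train.loci["snp_id"].tolist()
    else:
        calls = train
        if labels is None:
            raise ValueError("labels required when passing a raw matrix")
        labels = list(labels)
        snp_ids = snp_ids or [f"snp{j}" for j in range(calls.shape[1])]

    y = np.asarray(labels)
    classes = sorted(set(labels))
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        small = [c for c, v in counts.items() if v < 2]
        raise ValueError(f"every class needs >= 2 training samples; short: {small}")
    n = calls.shape[0]
    if n_pc > n - 1 or n_pc > calls.shape[1] or n_pc < 1:
        raise ValueError(f"n_pc={n_pc} outside [1, min(n_train-1, n_loci)]")

    Xc, means = impute_center(calls)
    V, ev = _pca_rotation(Xc, n_pc)
    scores = Xc @ V  # n x n_pc

    mu = np.vstack([scores[y == c].mean(axis=0) for c in classes])
    C = len(classes)
    Sw = np.zeros((n_pc, n_pc))
    for k, c in enumerate(classes):
        D = scores[y == c] - mu[k]
        Sw += D.T @ D
    Sw /= max(n - C, 1)
    if ridge > 0:
        scale = np.trace(Sw) / n_pc
        if scale <= 0:  # perfectly separable classes: zero within-class scatter
            scale = 1.0
        Sw_reg = Sw + ridge * scale * np.eye(n_pc)
    else:
        Sw_reg = Sw
    cond = np.linalg.cond(Sw_reg)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularWithinCovariance(
            "pooled within-class covariance is singular; pass ridge > 0"
        )
    cov_inv = np.linalg.inv(Sw_reg)

    grand = scores.mean(axis=0)
    Sb = np.zeros((n_pc, n_pc))
    for k, c in enumerate(classes):
        d = (mu[k] - grand)[:, None]
        Sb += counts[c] * (d @ d.T)
    Sb /= n
    w_eig, w_vec = scipy.linalg.eigh(Sb, Sw_reg)
    order = np.argsort(w_eig)[::-1][: C - 1]
    discriminants = w_vec[:, order]

    priors = np.array([counts[c] / n for c in classes])
    return DapcModel(
        snp_ids=list(snp_ids),
        pca_center=means,
        pca_loadings=V,
        n_pc=n_pc,
        class_labels=classes,
        class_priors=priors,
        lda_means=mu,
        lda_cov_inv=cov_inv,
        lda_discriminants=discriminants,
        explained_variance_share=float(ev[:n_pc].sum()),
    )


def _posterior_from_scores(model: DapcModel, scores: np.ndarray) -> np.ndarray:
    """Gaussian LDA posteriors (shared covariance, class priors)."""
    # delta_c(x) = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log pi_c
    Sm = model.lda_cov_inv @ model.lda_means.T  # n_pc x C
    lin = scores @ Sm
    quad = 0.5 * np.einsum("ck,kc->c", model.lda_means, Sm)
    logp = lin - quad[None, :] + np.log(model.class_priors)[None, :]
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def project_scores(model: DapcModel, ds: GenotypeDataset | np.ndarray) -> np.ndarray:
    """Center new samples with TRAINING means and project on training loadings."""
    if isinstance(ds, GenotypeDataset):
        col = {s: j for j, s in enumerate(model.snp_ids)}
        keep = [j for j, s in enumerate(ds.loci["snp_id"]) if s in col]
        if not keep:
            raise ValueError("no loci overlap the trained model")
        calls = np.full((ds.n_samples, len(model.snp_ids)), MISSING, dtype=np.int8)
        for j in keep:
            calls[:, col[ds.loci["snp_id"].iloc[j]]] = ds.calls[:, j]
    else:
        calls = ds
    Xc, _ = impute_center(calls, means=model.pca_center)
    return Xc @ model.pca_loadings


def predict_membership(
    model: DapcModel, ds: GenotypeDataset | np.ndarray,
    sample_ids: list[str] | None = None, true_breeds: list[str] | None = None,
) -> list[AssignmentResult]:
    """Classify new samples with the stored rotation and discriminants.

    A sample with no observed genotype carries no information; its posterior
    is the vector of class priors by convention.
    """
    if isinstance(ds, GenotypeDataset):
        sample_ids = sample_ids or ds.sample_ids
        true_breeds = true_breeds or ds.breeds
        calls = ds.calls
    else:
        calls = ds
        sample_ids = sample_ids or [f"s{i}" for i in range(calls.shape[0])]
    scores = project_scores(model, ds)
    post = _posterior_from_scores(model, scores)
    all_missing = (np.asarray(calls) == MISSING).all(axis=1)
    post[all_missing] = model.class_priors[None, :]

    out = []
    for i, sid in enumerate(sample_ids):
        # ties broken alphabetically: argmax over labels already sorted
        pred = model.class_labels[int(np.argmax(post[i]))]
        out.append(
            AssignmentResult(
                sample_id=sid,
                true_breed=None if true_breeds is None else true_breeds[i],
                predicted_breed=pred,
                posterior={c: float(p) for c, p in zip(model.class_labels, post[i])},
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cross-validated choice of the number of PCs
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    """Round-robin fold assignment per class; warns when a class < folds."""
    fold_of = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < folds:
            warnings.warn(
                f"class {c!r} has {len(idx)} samples for {folds} folds; "
                "its validation degrades toward leave-one-out",
                stacklevel=3,
            )
        idx = rng.permutation(idx)
        fold_of[idx] = (np.arange(len(idx)) + rng.integers(folds)) % folds
    return fold_of


def _lda_on_scores(scores, y, classes, n_pc, ridge):
    """LDA pieces on the first n_pc columns; returns a scorer for new scores."""
    S = scores[:, :n_pc]
    n = len(y)
    counts = np.array([(y == c).sum() for c in classes], dtype=float)
    mu = np.vstack([S[y == c].mean(axis=0) for c in classes])
    Sw = np.zeros((n_pc, n_pc))
    for k, c in enumerate(classes):
        D = S[y == c] - mu[k]
        Sw += D.T @ D
    Sw /= max(n - len(classes), 1)
    scale = np.trace(Sw) / n_pc
    if scale <= 0:
        scale = 1.0
    Sw += ridge * scale * np.eye(n_pc)
    Sm = np.linalg.solve(Sw, mu.T)
    quad = 0.5 * np.einsum("ck,kc->c", mu, Sm)
    logpri = np.log(counts / n)

    def predict(new_scores):
        lp = new_scores[:, :n_pc] @ Sm - quad[None, :] + logpri[None, :]
        return np.argmax(lp, axis=1)

    return predict


def select_n_pc_cv(
    train: GenotypeDataset | np.ndarray,
    labels: list[str] | None = None,
    folds: int = 10,
    repetitions: int = 30,
    max_pc: int = 259,
    grid: list[int] | None = None,
    grid_step: int = 10,
    seed: int = 0,
    ridge: float = 1e-6,
) -> CvReport:
    """Pick the retained-PC count with the highest mean CV assignment success.

    Stratified *folds*-fold CV repeated *repetitions* times; the candidate
    grid defaults to {grid_step, 2*grid_step, ...} up to min(max_pc,
    n_train - 1 minus the largest fold).  Ties go to the smallest count.
    """
    if isinstance(train, GenotypeDataset):
        calls, labels = train.calls, train.breeds
    else:
        calls = train
        if labels is None:
            raise ValueError("labels required with a raw matrix")
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    n = len(y)
    if max_pc < 1:
        raise ValueError("max_pc must be >= 1")
    train_min = n - (n // folds + folds)  # conservative smallest training size
    cap = max(1, min(max_pc, train_min - 1, calls.shape[1]))
    if grid is None:
        grid = [p for p in range(grid_step, cap + 1, grid_step)] or [cap]
    else:
        grid = sorted({min(p, cap) for p in grid})
    top = max(grid)

    rng = np.random.default_rng(seed)
    success = {p: [] for p in grid}
    for _ in range(repetitions):
        fold_of = _stratified_folds(y, folds, rng)
        for f in range(folds):
            tr = fold_of != f
            te = ~tr
            if not te.any():
                continue
            Xc, means = impute_center(calls[tr])
            V, _ = _pca_rotation(Xc, top)
            s_tr = Xc @ V
            Xte, _ = impute_center(calls[te], means=means)
            s_te = Xte @ V
            y_tr = y[tr]
            y_te = y[te]
            te_codes = np.array([classes.index(c) for c in y_te])
            for p in grid:
                if p > s_tr.shape[1]:
                    continue
                pred = _lda_on_scores(s_tr, y_tr, classes, p, ridge)(s_te)
                success[p].append(float((pred == te_codes).mean()))

    rows = [
        (p, float(np.mean(v)), float(np.std(v)))
        for p, v in success.items() if v
    ]
    df = pd.DataFrame(rows, columns=["n_pc", "mean_success", "sd_success"])
    best = df.sort_values(["mean_success", "n_pc"], ascending=[False, True])
    selected = int(best.iloc[0]["n_pc"])
    return CvReport(success_by_n_pc=df, selected_n_pc=selected)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def scenario_supervised(
    ds: GenotypeDataset,
    folds: int = 10,
    repetitions: int = 30,
    max_pc: int = 259,
    grid: list[int] | None = None,
    seed: int = 0,
    ridge: float = 1e-6,
) -> CvReport:
    """Train and evaluate on the full panel (all breeds supervised)."""
    if len(set(ds.breeds)) < 2:
        raise ValueError("need at least 2 breeds")
    report = select_n_pc_cv(
        ds, folds=folds, repetitions=repetitions, max_pc=max_pc,
        grid=grid, seed=seed, ridge=ridge,
    )
    model = fit_dapc(ds, n_pc=report.selected_n_pc, ridge=ridge)
    assignments = predict_membership(model, ds)
    df = pd.DataFrame(
        [(a.true_breed, a.predicted_breed) for a in assignments],
        columns=["true", "pred"],
    )
    per_breed = df.assign(ok=df["true"] == df["pred"]).groupby("true")["ok"].mean()
    scores = project_scores(model, ds) @ model.lda_discriminants
    report.per_breed_success = per_breed
    report.model = model
    report.extras = {
        "discriminant_scores": pd.DataFrame(
            scores, index=ds.sample_ids,
            columns=[f"LD{i+1}" for i in range(scores.shape[1])],
        ),
        "explained_variance_share": model.explained_variance_share,
        "overall_success": float((df["true"] == df["pred"]).mean()),
    }
    return report


def scenario_semisupervised(
    ds: GenotypeDataset,
    target_breed: str,
    holdout_n: int = 5,
    repetitions: int = 10,
    seed: int = 0,
    cv_folds: int = 10,
    cv_repetitions: int = 30,
    max_pc: int = 259,
    grid: list[int] | None = None,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Hold out a few target-breed samples, train on the rest, classify them.

    Returns the assignment percentage of held-out target samples to each
    breed, averaged over repetitions (rows: breed; plus the selected PC
    count per repetition as attrs).
    """
    tgt = ds.breed_index(target_breed)
    if holdout_n >= len(tgt):
        raise ValueError("holdout_n must be smaller than the target breed size")
    rng = np.random.default_rng(seed)
    breeds = sorted(set(ds.breeds))
    tallies = pd.DataFrame(0.0, index=breeds, columns=range(repetitions))
    n_pc_used = []
    for r in range(repetitions):
        held = rng.choice(tgt, size=holdout_n, replace=False)
        tr_idx = np.setdiff1d(np.arange(ds.n_samples), held)
        train = ds.subset(sample_idx=tr_idx)
        rep = select_n_pc_cv(
            train, folds=cv_folds, repetitions=cv_repetitions, max_pc=max_pc,
            grid=grid, seed=int(rng.integers(2**31)), ridge=ridge,
        )
        model = fit_dapc(train, n_pc=rep.selected_n_pc, ridge=ridge)
        test = ds.subset(sample_idx=held)
        for a in predict_membership(model, test):
            tallies.loc[a.predicted_breed, r] += 100.0 / holdout_n
        n_pc_used.append(rep.selected_n_pc)
    out = tallies.mean(axis=1).to_frame("assigned_pct")
    out.attrs["n_pc_per_repetition"] = n_pc_used
    return out


def scenario_unsupervised(
    ds: GenotypeDataset,
    target_breed: str,
    test_fraction: float = 0.80,
    train_fractions=tuple(np.round(np.arange(0.2, 0.91, 0.1), 2)),
    repetitions: int = 10,
    seed: int = 0,
    cv_folds: int = 10,
    cv_repetitions: int = 30,
    max_pc: int = 259,
    grid: list[int] | None = None,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Leave-breed-out attribution: classify target samples among other breeds.

    For each training fraction and repetition, that fraction of every
    non-target breed forms the training set, *test_fraction* of the target
    breed is classified, and percentages are averaged over repetitions.
    Returns breeds x train_fractions percentages (columns sum to 100).
    """
    tgt = ds.breed_index(target_breed)
    others = sorted(set(ds.breeds) - {target_breed})
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(0.0, index=others, columns=list(train_fractions))
    n_test = max(1, int(round(test_fraction * len(tgt))))
    for frac in train_fractions:
        tally = pd.Series(0.0, index=others)
        for _ in range(repetitions):
            tr_rows = []
            for b in others:
                idx = ds.breed_index(b)
                k = int(round(frac * len(idx)))
                if k < 2:
                    raise ValueError(
                        f"train_fraction {frac} leaves breed {b} with {k} < 2 samples"
                    )
                tr_rows.append(rng.choice(idx, size=k, replace=False))
            train = ds.subset(sample_idx=np.sort(np.concatenate(tr_rows)))
            test = ds.subset(
                sample_idx=np.sort(rng.choice(tgt, size=n_test, replace=False))
            )
            rep = select_n_pc_cv(
                train, folds=cv_folds, repetitions=cv_repetitions, max_pc=max_pc,
                grid=grid, seed=int(rng.integers(2**31)), ridge=ridge,
            )
            model = fit_dapc(train, n_pc=rep.selected_n_pc, ridge=ridge)
            for a in predict_membership(model, test):
                tally[a.predicted_breed] += 100.0 / n_test
        out[frac] = tally / repetitions
    return out
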