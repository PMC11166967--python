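"""Interpretable two-gene classifier search.

An open, fixed grammar of small functional forms maps the (z-scored)
expression of at most two genes to the probability of spaceflight status:

* ``single``       σ(θ0 + θ1·a)
* ``additive``     σ(θ0 + θ1·a + θ2·b)
* ``interaction``  σ(θ0 + θ1·a + θ2·b + θ3·a·b)
* ``product``      σ(θ0 + θ1·a·b)
* ``gaussian_bump``σ(θ0 + θ1·exp(−((a−θ2)² + (b−θ3)²)/θ4²))
* ``tanh``         σ(θ0 + θ1·tanh(θ2·a + θ3·b))

Every form is fitted by penalized maximum likelihood (L2, λ=1e-3): the
linear-in-features forms by Newton iterations (convex), the two non-convex
forms by multi-start quasi-Newton optimization. Candidates are ranked by
cross-validated AUC (stratified 5-fold, out-of-fold scores pooled), with
ties broken by lower complexity then lower log-loss; the exhaustive sweep
over pairs deliberately replaces any evolutionary search so that results
are deterministic under a fixed seed. A greedy maximally-relevant /
minimally-redundant pass selects top models sharing no genes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import mutual_info_classif
from sklearn.model_selection import StratifiedKFold

from ._utils import ValidationError, check_binary_labels

DEFAULT_LAMBDA = 1e-3
TRACTABILITY_CAP = 5000       # genes admitted to "full" mode without force
PRESCREEN_TOP = 500           # mutual-information screen above this pool size

TWO_GENE_FORMS = ("additive", "interaction", "product", "gaussian_bump",
                  "tanh")
FORM_COMPLEXITY = {"single": 2, "additive": 3, "interaction": 4,
                   "product": 2, "gaussian_bump": 5, "tanh": 4}
_LINEAR_FORMS = {"single", "additive", "interaction", "product"}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _features(form: str, a: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    if form == "single":
        return a[:, None]
    if form == "additive":
        return np.column_stack([a, b])
    if form == "interaction":
        return np.column_stack([a, b, a * b])
    if form == "product":
        return (a * b)[:, None]
    raise ValidationError(f"{form!r} is not a linear-in-features form")


# ---------------------------------------------------------------------------
# fitting primitives

def _logistic_newton(F: np.ndarray, y: np.ndarray, lam: float = DEFAULT_LAMBDA,
                     max_iter: int = 30, tol: float = 1e-9) -> np.ndarray:
    """Ridge-penalized logistic regression; F excludes the intercept column.
    The intercept is unpenalized. Returns θ = (intercept, coefs)."""
    n, p = F.shape
    X = np.column_stack([np.ones(n), F])
    theta = np.zeros(p + 1)
    pen = np.diag([0.0] + [2 * lam] * p)
    for _ in range(max_iter):
        eta = X @ theta
        mu = _sigmoid(eta)
        grad = X.T @ (mu - y) / n + pen @ theta
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = (X * w[:, None]).T @ X / n + pen
        step = np.linalg.solve(H, grad)
        theta = theta - step
        if np.max(np.abs(step)) < tol:
            break
    return theta


def _eta_nonconvex(form: str, theta: np.ndarray, a: np.ndarray,
                   b: np.ndarray) -> np.ndarray:
    if form == "gaussian_bump":
        t0, t1, t2, t3, t4 = theta
        d2 = (a - t2) ** 2 + (b - t3) ** 2
        return t0 + t1 * np.exp(-d2 / (t4 ** 2 + 1e-12))
    if form == "tanh":
        t0, t1, t2, t3 = theta
        return t0 + t1 * np.tanh(t2 * a + t3 * b)
    raise ValidationError(f"unknown non-convex form {form!r}")


def _nll_grad(form: str, theta: np.ndarray, a: np.ndarray, b: np.ndarray,
              y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    n = y.size
    if form == "gaussian_bump":
        t0, t1, t2, t3, t4 = theta
        s2 = t4 ** 2 + 1e-12
        d2 = (a - t2) ** 2 + (b - t3) ** 2
        g = np.exp(-d2 / s2)
        eta = t0 + t1 * g
        deta = [np.ones(n), g, t1 * g * 2 * (a - t2) / s2,
                t1 * g * 2 * (b - t3) / s2, t1 * g * 2 * d2 / (s2 * t4)]
    else:  # tanh
        t0, t1, t2, t3 = theta
        t = np.tanh(t2 * a + t3 * b)
        eta = t0 + t1 * t
        sech2 = 1 - t ** 2
        deta = [np.ones(n), t, t1 * sech2 * a, t1 * sech2 * b]
    mu = _sigmoid(eta)
    nll = -np.mean(y * np.log(mu + 1e-12) + (1 - y) * np.log(1 - mu + 1e-12))
    nll += lam * np.sum(theta[1:] ** 2)
    resid = (mu - y) / n
    grad = np.array([np.sum(resid * d) for d in deta])
    grad[1:] += 2 * lam * theta[1:]
    return float(nll), grad


def _fit_nonconvex(form: str, a: np.ndarray, b: np.ndarray, y: np.ndarray,
                   lam: float, rng: np.random.Generator,
                   restarts: int = 5) -> np.ndarray:
    p = FORM_COMPLEXITY[form]
    best_theta, best_nll = None, math.inf
    for r in range(restarts):
        if r == 0:
            x0 = np.zeros(p)
            x0[1] = 1.0
            if form == "gaussian_bump":
                x0[4] = 1.0
            else:
                x0[2] = x0[3] = 0.5
        else:
            x0 = rng.normal(scale=1.0, size=p)
            if form == "gaussian_bump":
                x0[4] = abs(x0[4]) + 0.5
        res = scipy.optimize.minimize(
            lambda th: _nll_grad(form, th, a, b, y, lam), x0, jac=True,
            method="L-BFGS-B", options={"maxiter": 100})
        if res.fun < best_nll:
            best_nll, best_theta = res.fun, res.x
    return best_theta


def _fit_form(form: str, a: np.ndarray, b: np.ndarray | None, y: np.ndarray,
              lam: float, rng: np.random.Generator,
              restarts: int = 5) -> np.ndarray:
    if form in _LINEAR_FORMS:
        return _logistic_newton(_features(form, a, b), y, lam)
    return _fit_nonconvex(form, a, b, y, lam, rng, restarts)


def _predict_eta(form: str, theta: np.ndarray, a: np.ndarray,
                 b: np.ndarray | None) -> np.ndarray:
    if form in _LINEAR_FORMS:
        F = _features(form, a, b)
        return theta[0] + F @ theta[1:]
    return _eta_nonconvex(form, theta, a, b)


# ---------------------------------------------------------------------------
# AUC

def auc(scores, labels) -> float:
    """Mann–Whitney AUC with midrank tie handling: the probability that a
    positive sample outscores a negative one (ties count half)."""
    y = check_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    ranks = scipy.stats.rankdata(s)
    n1 = int(y.sum())
    n0 = y.size - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# fitted models

@dataclass
class PairModel:
    """A fitted (at most) two-gene classifier."""

    gene_a: str
    gene_b: str | None
    form: str
    theta: np.ndarray
    auc_train: float
    logloss: float
    complexity: int
    auc_cv: float = math.nan
    # z-score parameters on the training data, for original-scale evaluation
    standardize: dict = field(default_factory=dict)

    def predict_proba(self, a, b=None) -> np.ndarray:
        a = (np.asarray(a, float) - self.standardize["mean_a"]) \
            / self.standardize["std_a"]
        if self.gene_b is not None:
            if b is None:
                raise ValidationError("two-gene model needs both inputs")
            b = (np.asarray(b, float) - self.standardize["mean_b"]) \
                / self.standardize["std_b"]
        return _sigmoid(_predict_eta(self.form, self.theta, a, b))


def _standardize(v: np.ndarray, what: str) -> tuple[np.ndarray, float, float]:
    m, s = float(np.mean(v)), float(np.std(v))
    if s == 0:
        raise ValidationError(f"constant feature for gene {what}")
    return (v - m) / s, m, s


def fit_pair(a, b, labels, form: str = "interaction",
             lam: float = DEFAULT_LAMBDA, seed: int = 0, cv_folds: int = 5,
             gene_a: str = "a", gene_b: str | None = "b",
             restarts: int = 5, compute_cv: bool = True) -> PairModel:
    """Fit one grammar form to a gene pair (or a single gene).

    Inputs are z-scored internally; θ maximizes the L2-penalized Bernoulli
    likelihood. Training AUC uses midranks; the cross-validated AUC pools
    out-of-fold scores from a seeded stratified K-fold (each fold re-fits
    and re-standardizes on its training part).
    """
    y = check_binary_labels(labels)
    if y.sum() < 4 or (y.size - y.sum()) < 4:
        raise ValidationError("need at least 4 samples per class")
    a = np.asarray(a, dtype=float)
    uses_b = form != "single"
    if uses_b and b is None:
        raise ValidationError(f"form {form!r} needs two genes")
    if form not in FORM_COMPLEXITY:
        raise ValidationError(f"unknown form {form!r}")
    rng = np.random.default_rng([int(seed), 41])

    za, ma, sa = _standardize(a, gene_a)
    std = {"mean_a": ma, "std_a": sa}
    if uses_b:
        bb = np.asarray(b, dtype=float)
        zb, mb, sb = _standardize(bb, gene_b or "b")
        std.update(mean_b=mb, std_b=sb)
    else:
        zb = None

    theta = _fit_form(form, za, zb, y, lam, rng, restarts)
    eta = _predict_eta(form, theta, za, zb)
    mu = _sigmoid(eta)
    logloss = float(-np.mean(y * np.log(mu + 1e-12)
                             + (1 - y) * np.log(1 - mu + 1e-12)))
    model = PairModel(gene_a=gene_a, gene_b=gene_b if uses_b else None,
                      form=form, theta=theta, auc_train=auc(eta, y),
                      logloss=logloss, complexity=FORM_COMPLEXITY[form],
                      standardize=std)
    if compute_cv:
        model.auc_cv = _cv_auc(form, a, np.asarray(b, float) if uses_b else
                               None, y, lam, seed, cv_folds, restarts)
    return model


def _cv_auc(form: str, a: np.ndarray, b: np.ndarray | None, y: np.ndarray,
            lam: float, seed: int, cv_folds: int, restarts: int) -> float:
    """Mean of per-fold out-of-sample AUCs.

    Per-fold averaging (rather than pooling out-of-fold scores into one
    ranking) keeps folds with differently calibrated score scales — common
    for the non-linear forms — from corrupting each other's ordering.
    """
    rng = np.random.default_rng([int(seed), 43])
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                          random_state=int(seed) % (2**32 - 1))
    fold_aucs = []
    for train, test in skf.split(np.zeros(y.size), y):
        ma, sa = np.mean(a[train]), np.std(a[train])
        sa = sa if sa > 0 else 1.0
        za_tr, za_te = (a[train] - ma) / sa, (a[test] - ma) / sa
        if b is not None:
            mb, sb = np.mean(b[train]), np.std(b[train])
            sb = sb if sb > 0 else 1.0
            zb_tr, zb_te = (b[train] - mb) / sb, (b[test] - mb) / sb
        else:
            zb_tr = zb_te = None
        theta = _fit_form(form, za_tr, zb_tr, y[train], lam, rng, restarts)
        fold_aucs.append(auc(_predict_eta(form, theta, za_te, zb_te),
                             y[test]))
    return float(np.mean(fold_aucs))


# ---------------------------------------------------------------------------
# sklearn-style estimator over the grammar

class PairClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator wrapping one grammar form on (a, b) columns.

    ``X`` is (n_samples, 2) — or (n_samples, 1) for the single-gene form.
    """

    def __init__(self, form: str = "interaction", lam: float = DEFAULT_LAMBDA,
                 seed: int = 0, restarts: int = 5):
        self.form = form
        self.lam = lam
        self.seed = seed
        self.restarts = restarts

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        a = X[:, 0]
        b = X[:, 1] if self.form != "single" else None
        self.model_ = fit_pair(a, b, y, form=self.form, lam=self.lam,
                               seed=self.seed, restarts=self.restarts,
                               compute_cv=False)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        b = X[:, 1] if self.model_.gene_b is not None else None
        p1 = self.model_.predict_proba(X[:, 0], b)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# batched screening fits (linear forms over many candidate pairs at once)

def _batched_nll_grad(form: str, theta: np.ndarray, A: np.ndarray,
                      B: np.ndarray, y: np.ndarray, lam: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Penalized NLL and gradient for a non-convex form over many candidate
    pairs at once. ``theta`` is (c, p); A, B are (c, n); returns ((c,), (c, p))."""
    n = y.size
    if form == "gaussian_bump":
        t0, t1, t2, t3, t4 = (theta[:, i][:, None] for i in range(5))
        s2 = t4 ** 2 + 1e-12
        da, db = A - t2, B - t3
        d2 = da ** 2 + db ** 2
        g = np.exp(-d2 / s2)
        eta = t0 + t1 * g
    else:  # tanh
        t0, t1, t2, t3 = (theta[:, i][:, None] for i in range(4))
        t = np.tanh(t2 * A + t3 * B)
        eta = t0 + t1 * t
    mu = _sigmoid(eta)
    nll = -np.mean(y[None, :] * np.log(mu + 1e-12)
                   + (1 - y[None, :]) * np.log(1 - mu + 1e-12), axis=1)
    nll = nll + lam * np.sum(theta[:, 1:] ** 2, axis=1)
    resid = (mu - y[None, :]) / n
    # gradient components without materializing a (c, n, p) tensor
    if form == "gaussian_bump":
        rg = resid * g
        grad = np.stack([
            resid.sum(axis=1),
            rg.sum(axis=1),
            ((rg * da).sum(axis=1)[:, None] * t1 * 2 / s2).ravel(),
            ((rg * db).sum(axis=1)[:, None] * t1 * 2 / s2).ravel(),
            ((rg * d2).sum(axis=1)[:, None] * t1 * 2 / (s2 * t4)).ravel(),
        ], axis=1)
    else:
        rs = resid * (1 - t ** 2) * t1
        grad = np.stack([
            resid.sum(axis=1),
            (resid * t).sum(axis=1),
            (rs * A).sum(axis=1),
            (rs * B).sum(axis=1),
        ], axis=1)
    grad[:, 1:] += 2 * lam * theta[:, 1:]
    return nll, grad


def _batched_nonconvex(form: str, A: np.ndarray, B: np.ndarray,
                       y: np.ndarray, lam: float, rng: np.random.Generator,
                       restarts: int = 2, iters: int = 250,
                       lr: float = 0.15) -> tuple[np.ndarray, np.ndarray]:
    """Screening-stage fits of a non-convex form for all candidate pairs at
    once (Adam); returns the best θ per candidate and its final η."""
    c = A.shape[0]
    p = FORM_COMPLEXITY[form]
    best_theta = np.zeros((c, p))
    best_nll = np.full(c, np.inf)
    for r in range(restarts):
        if r == 0:
            theta = np.zeros((c, p))
            theta[:, 1] = 1.0
            if form == "gaussian_bump":
                theta[:, 4] = 1.0
            else:
                theta[:, 2] = theta[:, 3] = 0.5
        else:
            theta = rng.normal(scale=1.0, size=(c, p))
            if form == "gaussian_bump":
                theta[:, 4] = np.abs(theta[:, 4]) + 0.5
        m = np.zeros_like(theta)
        v = np.zeros_like(theta)
        for it in range(1, iters + 1):
            nll, grad = _batched_nll_grad(form, theta, A, B, y, lam)
            m = 0.9 * m + 0.1 * grad
            v = 0.999 * v + 0.001 * grad ** 2
            mh = m / (1 - 0.9 ** it)
            vh = v / (1 - 0.999 ** it)
            theta = theta - lr * mh / (np.sqrt(vh) + 1e-8)
        nll, _ = _batched_nll_grad(form, theta, A, B, y, lam)
        better = nll < best_nll
        best_theta[better] = theta[better]
        best_nll[better] = nll[better]
    eta = np.stack([_eta_nonconvex(form, best_theta[i], A[i], B[i])
                    for i in range(c)])
    return best_theta, eta


def _batched_logistic(F: np.ndarray, y: np.ndarray,
                      lam: float = DEFAULT_LAMBDA, max_iter: int = 30,
                      tol: float = 1e-8) -> np.ndarray:
    """Newton iterations for many small logistic fits at once.

    ``F`` is (n_candidates, n_samples, p) of non-intercept features; returns
    θ of shape (n_candidates, p+1) with the intercept first.
    """
    c, n, p = F.shape
    X = np.concatenate([np.ones((c, n, 1)), F], axis=2)
    theta = np.zeros((c, p + 1))
    pen = np.diag([0.0] + [2 * lam] * p)
    active = np.ones(c, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        Xa = X[active]
        eta = np.einsum("cnp,cp->cn", Xa, theta[active])
        mu = _sigmoid(eta)
        grad = np.einsum("cnp,cn->cp", Xa, mu - y[None, :]) / n \
            + theta[active] @ pen
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = np.einsum("cnp,cn,cnq->cpq", Xa, w, Xa) / n + pen[None, :, :]
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        theta[active] -= step
        done = np.max(np.abs(step), axis=1) < tol
        idx = np.flatnonzero(active)
        active[idx[done]] = False
    return theta


# ---------------------------------------------------------------------------
# search

def search_pairs(matrix: pd.DataFrame, labels, gene_pool: list[str] | None
                 = None, forms: tuple = TWO_GENE_FORMS, top_k: int = 10,
                 seed: int = 0, lam: float = DEFAULT_LAMBDA,
                 cv_top: int = 50, screen_restarts: int = 2,
                 cv_restarts: int = 5, force: bool = False) -> list[PairModel]:
    """Exhaustive two-gene model sweep ranked by cross-validated AUC.

    Every unordered gene pair × two-gene form, plus the single-gene form
    per gene, is fitted on the full data (C(m,2)·f + m candidates). The
    ``cv_top`` candidates with the best training AUC (ties: lower
    complexity, then lower log-loss) are re-scored by stratified 5-fold
    cross-validation, and the final ranking is by CV-AUC with the same
    tie-breaking. Because that ranking maximizes over many noisy estimates,
    the ``auc_cv`` reported on the returned models is re-estimated on a
    fresh set of folds after selection (the selected order is kept), which
    removes the winner's-curse bias from the reported numbers.
    Pools larger than ``PRESCREEN_TOP`` genes are first
    reduced by a single-pass mutual-information screen; pools beyond the
    tractability cap require ``force=True``.
    """
    y = check_binary_labels(labels)
    pool = list(gene_pool) if gene_pool is not None else list(matrix.index)
    missing = [g for g in pool if g not in matrix.index]
    if missing:
        raise ValidationError(f"pool gene {missing[0]!r} absent from matrix")
    if len(pool) < 2:
        raise ValidationError("gene pool must contain at least 2 genes")
    n_two_forms = len(forms)
    if len(pool) > TRACTABILITY_CAP and not force:
        n_cand = len(pool) * (len(pool) - 1) // 2 * n_two_forms + len(pool)
        raise ValidationError(
            f"pool of {len(pool)} genes implies {n_cand} candidates; pass "
            "force=True to proceed"
        )
    if len(pool) > PRESCREEN_TOP:
        mi = mutual_info_classif(matrix.loc[pool].to_numpy().T, y,
                                 random_state=int(seed) % (2**32 - 1))
        order = np.argsort(-mi, kind="stable")[:PRESCREEN_TOP]
        pool = [pool[i] for i in sorted(order)]

    X = matrix.loc[pool].to_numpy(dtype=float)
    stds = X.std(axis=1)
    if (stds == 0).any():
        bad = pool[int(np.flatnonzero(stds == 0)[0])]
        raise ValidationError(f"constant expression for pool gene {bad!r}")
    Z = (X - X.mean(axis=1, keepdims=True)) / stds[:, None]
    rng = np.random.default_rng([int(seed), 47])

    pairs = list(itertools.combinations(range(len(pool)), 2))
    candidates: list[dict] = []
    n1 = int(y.sum())
    n0 = y.size - n1

    def _screen_record_batch(form, idx_pairs, thetas, etas):
        ranks = scipy.stats.rankdata(etas, axis=1)
        aucs = (ranks[:, y == 1].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)
        mu = _sigmoid(etas)
        lls = -np.mean(y[None, :] * np.log(mu + 1e-12)
                       + (1 - y[None, :]) * np.log(1 - mu + 1e-12), axis=1)
        for c, (ia, ib) in enumerate(idx_pairs):
            candidates.append({"form": form, "ia": ia, "ib": ib,
                               "theta": thetas[c], "auc_train": float(aucs[c]),
                               "logloss": float(lls[c]),
                               "complexity": FORM_COMPLEXITY[form]})

    # single-gene candidates (batched: one linear feature each)
    F = Z[:, :, None]
    thetas = _batched_logistic(F, y, lam)
    etas = thetas[:, 0:1] + Z * thetas[:, 1:2]
    _screen_record_batch("single", [(i, None) for i in range(len(pool))],
                         thetas, etas)

    # two-gene candidates
    if pairs:
        A = Z[[i for i, _ in pairs]]
        B = Z[[j for _, j in pairs]]
        for form in forms:
            if form in _LINEAR_FORMS:
                if form == "additive":
                    F = np.stack([A, B], axis=2)
                elif form == "interaction":
                    F = np.stack([A, B, A * B], axis=2)
                else:  # product
                    F = (A * B)[:, :, None]
                thetas = _batched_logistic(F, y, lam)
                etas = thetas[:, 0:1] + np.einsum("cnp,cp->cn", F,
                                                  thetas[:, 1:])
            else:
                thetas, etas = _batched_nonconvex(form, A, B, y, lam, rng,
                                                  restarts=screen_restarts)
            _screen_record_batch(form, pairs, thetas, etas)

    # CV re-scoring of the screening leaders, final rank by CV-AUC
    candidates.sort(key=lambda d: (-d["auc_train"], d["complexity"],
                                   d["logloss"], d["form"], d["ia"],
                                   d["ib"] if d["ib"] is not None else -1))
    finalists = candidates[:cv_top]
    models = []
    for cand in finalists:
        a_raw = X[cand["ia"]]
        b_raw = X[cand["ib"]] if cand["ib"] is not None else None
        m = fit_pair(a_raw, b_raw, y, form=cand["form"], lam=lam, seed=seed,
                     gene_a=pool[cand["ia"]],
                     gene_b=pool[cand["ib"]] if cand["ib"] is not None
                     else None,
                     restarts=cv_restarts)
        models.append(m)
    models.sort(key=lambda m: (-m.auc_cv, m.complexity, m.logloss, m.form,
                               m.gene_a, m.gene_b or ""))
    winners = models[:top_k]
    # the ranking maximizes over many noisy CV estimates, so the winner's
    # own estimate carries selection (winner's-curse) bias; re-estimate the
    # reported CV-AUC of the returned models on a fresh set of folds
    for m in winners:
        a_raw = X[pool.index(m.gene_a)]
        b_raw = X[pool.index(m.gene_b)] if m.gene_b is not None else None
        m.auc_cv = _cv_auc(m.form, a_raw, b_raw, y, lam,
                           (int(seed) + 500009) % (2**31 - 1), 5,
                           cv_restarts)
    return winners


def models_table(models: list[PairModel]) -> pd.DataFrame:
    rows = [{"gene_a": m.gene_a, "gene_b": m.gene_b or "", "form": m.form,
             "params": ",".join(f"{t:.6g}" for t in m.theta),
             "auc_cv": m.auc_cv, "auc_train": m.auc_train,
             "logloss": m.logloss, "complexity": m.complexity}
            for m in models]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "form", "params",
                                       "auc_cv", "auc_train", "logloss",
                                       "complexity"])


# ---------------------------------------------------------------------------
# model selection and boundaries

def select_mrmr(models: list[PairModel], k: int = 2,
                auc_tolerance: float = 0.02) -> list[PairModel]:
    """Greedy maximally-relevant minimally-redundant selection.

    Takes the best model first; at each later step, among the remaining
    models within ``auc_tolerance`` of the next-best CV-AUC, prefers one
    sharing no gene with the selection so far (falling back to plain AUC
    order when redundancy is unavoidable).
    """
    if k > len(models):
        import logging
        logging.getLogger(__name__).warning(
            "select_mrmr: requested %d models but only %d available", k,
            len(models))
    remaining = list(models)
    selected: list[PairModel] = []
    used_genes: set[str] = set()
    while remaining and len(selected) < k:
        best = remaining[0]
        window = [m for m in remaining
                  if best.auc_cv - m.auc_cv <= auc_tolerance]
        disjoint = [m for m in window
                    if not ({m.gene_a, m.gene_b} - {None}) & used_genes]
        pick = disjoint[0] if disjoint else best
        selected.append(pick)
        used_genes |= {pick.gene_a}
        if pick.gene_b is not None:
            used_genes.add(pick.gene_b)
        remaining.remove(pick)
    return selected


def decision_boundary(model: PairModel, a_values, b_values,
                      grid_resolution: int = 101) -> pd.DataFrame:
    """Probability raster over the observed (a, b) range extended by 10%.

    Returns a long-format frame (a, b, probability); the 0.5 contour can be
    read off as the level set of the probability column. Raster values
    equal direct model evaluation at the grid points.
    """
    if model.gene_b is None:
        raise ValidationError("single-gene models have no 2-D boundary")
    a_values = np.asarray(a_values, dtype=float)
    b_values = np.asarray(b_values, dtype=float)

    def _range(v):
        lo, hi = float(v.min()), float(v.max())
        pad = 0.1 * (hi - lo)
        return lo - pad, hi + pad

    a_lo, a_hi = _range(a_values)
    b_lo, b_hi = _range(b_values)
    ga = np.linspace(a_lo, a_hi, grid_resolution)
    gb = np.linspace(b_lo, b_hi, grid_resolution)
    A, B = np.meshgrid(ga, gb, indexing="ij")
    prob = model.predict_proba(A.ravel(), B.ravel())
    return pd.DataFrame({"a": A.ravel(), "b": B.ravel(),
                         "probability": prob})
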