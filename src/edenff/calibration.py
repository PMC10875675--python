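"""Calibration of the exchange–correlation weights against reference energies.

The corrected model is linear in its XC weights:

    E_model(geometry; w) = E_naive(geometry) + w · F(geometry)

with F the vector of iterated-Laplacian functional values (ee then en,
orders 0..K). Calibration is therefore an ordinary least-squares
problem, exposed here both as a scikit-learn estimator
(:class:`LaplacianXCRegressor`) and as the module-level wrappers
:func:`fit_xc_coefficients` / :func:`order_scan`. The estimator's design
matrix has the naïve energy as a fixed-offset first column followed by
the 2(K+1) functional columns, all in hartree
(:func:`build_design_matrix` produces it from geometries).

Two solvers are available: ``linear`` (exact least squares, the
default — the model is linear in the weights) and ``ga_bfgs`` (a seeded
genetic-algorithm global stage polished by BFGS, retained for parity
with nonlinear extensions). The fit quality metric is the relative
absolute error RAE = Σ|E_model − E_ref| / Σ|E_ref|.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .density import DensityTable
from .electrostatics import erf_over_d
from .geometry import DimerGeometry
from .reference import ReferenceSet
from .units import BOHR_PER_ANGSTROM, KJ_PER_MOL_PER_HARTREE
from .xc import XCCoefficients, _eval_lap_poly

__all__ = [
    "relative_absolute_error",
    "build_design_matrix",
    "LaplacianXCRegressor",
    "FitReport",
    "fit_xc_coefficients",
    "order_scan",
]


def relative_absolute_error(predicted, reference, kind: str = "aggregate") -> float:
    """Relative absolute error of predictions against reference energies.

    ``aggregate`` (default): Σ|pred − ref| / Σ|ref| — stable when
    individual reference energies cross zero. ``mean_ratio``: the mean of
    per-point |pred − ref|/|ref| over points with nonzero reference,
    available for sensitivity checks.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.size == 0:
        raise ValueError("predicted and reference must have equal nonzero lengths")
    if not np.abs(reference).sum() > 0:
        raise ValueError("all-zero reference energies: RAE undefined")
    if kind == "aggregate":
        return float(np.abs(predicted - reference).sum() / np.abs(reference).sum())
    if kind == "mean_ratio":
        nz = np.abs(reference) > 0
        return float(np.mean(np.abs(predicted[nz] - reference[nz]) / np.abs(reference[nz])))
    raise ValueError(f"unknown RAE kind {kind!r}")


# ---------------------------------------------------------------------------
# Vectorized design matrix over many dimers


def _monomer_template(table: DensityTable, symbols, charges=None):
    """Per-shell weights/exponents and shell→atom map for one monomer type."""
    if charges is None:
        charges = [0.0] * len(symbols)
    weights, alphas, shell_atom, Zs = [], [], [], []
    for i, (sym, q) in enumerate(zip(symbols, charges)):
        atom = table.atom(sym, (0.0, 0.0, 0.0), q)
        Zs.append(atom.effective_Z)
        for s in atom.shells:
            weights.append(s.weight)
            alphas.append(s.exponent)
            shell_atom.append(i)
    return (np.array(weights), np.array(alphas), np.array(shell_atom, dtype=int),
            np.array(Zs))


def _batch_block(table, symbols_a, coords_a, symbols_b, coords_b, K,
                 charges_a=None, charges_b=None):
    """Naive components and XC features for n dimers sharing monomer types.

    ``coords_a``/``coords_b``: (n, m, 3) in Å. Returns (naive (n, 3) as
    [ee, en, nn] hartree, features (n, 2(K+1))).
    """
    wA, aA, saA, ZA = _monomer_template(table, symbols_a, charges_a)
    wB, aB, saB, ZB = _monomer_template(table, symbols_b, charges_b)
    RA = np.asarray(coords_a, dtype=float) * BOHR_PER_ANGSTROM  # (n, mA, 3)
    RB = np.asarray(coords_b, dtype=float) * BOHR_PER_ANGSTROM
    cA = RA[:, saA, :]  # (n, sA, 3)
    cB = RB[:, saB, :]

    d2_ss = ((cA[:, :, None, :] - cB[:, None, :, :]) ** 2).sum(-1)   # (n, sA, sB)
    d2_an = ((cA[:, :, None, :] - RB[:, None, :, :]) ** 2).sum(-1)   # (n, sA, mB)
    d2_bn = ((cB[:, :, None, :] - RA[:, None, :, :]) ** 2).sum(-1)   # (n, sB, mA)
    d2_nn = ((RA[:, :, None, :] - RB[:, None, :, :]) ** 2).sum(-1)   # (n, mA, mB)
    d_ss, d_an, d_bn, d_nn = (np.sqrt(x) for x in (d2_ss, d2_an, d2_bn, d2_nn))
    if (d_nn < 1e-12).any():
        raise ValueError("coincident intermolecular nuclei in a batch dimer")

    gamma = np.sqrt(aA[:, None] * aB[None, :] / (aA[:, None] + aB[None, :]))
    e_ee = (wA[:, None] * wB[None, :] * erf_over_d(gamma, d_ss)).sum(axis=(1, 2))
    e_en = -((wA[:, None] * ZB[None, :] * erf_over_d(np.sqrt(aA)[:, None], d_an)).sum(axis=(1, 2))
             + (wB[:, None] * ZA[None, :] * erf_over_d(np.sqrt(aB)[:, None], d_bn)).sum(axis=(1, 2)))
    e_nn = (ZA[:, None] * ZB[None, :] / d_nn).sum(axis=(1, 2))
    naive = np.stack([e_ee, e_en, e_nn], axis=1)

    mu = aA[:, None] * aB[None, :] / (aA[:, None] + aB[None, :])
    s0 = wA[:, None] * wB[None, :] * (mu / np.pi) ** 1.5 * np.exp(-mu * d2_ss)
    gA = wA[:, None] * (aA[:, None] / np.pi) ** 1.5 * np.exp(-aA[:, None] * d2_an)
    gB = wB[:, None] * (aB[:, None] / np.pi) ** 1.5 * np.exp(-aB[:, None] * d2_bn)
    ee_feats, en_feats = [], []
    for k in range(K + 1):
        ee_feats.append((s0 * _eval_lap_poly(k, mu, d2_ss)).sum(axis=(1, 2)))
        en_feats.append(
            (ZB[None, :] * gA * _eval_lap_poly(k, aA[:, None], d2_an)).sum(axis=(1, 2))
            + (ZA[None, :] * gB * _eval_lap_poly(k, aB[:, None], d2_bn)).sum(axis=(1, 2)))
    features = np.stack(ee_feats + en_feats, axis=1)
    return naive, features


def build_design_matrix(dimers: list[DimerGeometry], table: DensityTable, K: int,
                        mulliken=None) -> np.ndarray:
    """Design matrix for :class:`LaplacianXCRegressor`: column 0 is the
    naïve interaction energy (hartree), columns 1..2(K+1) the XC
    functional values, one row per dimer.

    ``mulliken`` optionally maps a monomer symbol tuple to its per-atom
    Mulliken charges, applied identically to every occurrence.
    """
    dimers = list(dimers)
    mulliken = mulliken or {}
    X = np.empty((len(dimers), 1 + 2 * (K + 1)))
    groups: dict[tuple, list[int]] = {}
    for i, d in enumerate(dimers):
        groups.setdefault((d.symbols_a, d.symbols_b), []).append(i)
    for (sym_a, sym_b), idx in groups.items():
        ca = np.stack([dimers[i].coords_a for i in idx])
        cb = np.stack([dimers[i].coords_b for i in idx])
        naive, feats = _batch_block(table, sym_a, ca, sym_b, cb, K,
                                    charges_a=mulliken.get(sym_a),
                                    charges_b=mulliken.get(sym_b))
        X[idx, 0] = naive.sum(axis=1)
        X[idx, 1:] = feats
    return X


def naive_components_batch(dimers, table, mulliken=None) -> np.ndarray:
    """(n, 3) array of [ee, en, nn] naïve components (hartree) per dimer."""
    dimers = list(dimers)
    mulliken = mulliken or {}
    out = np.empty((len(dimers), 3))
    groups: dict[tuple, list[int]] = {}
    for i, d in enumerate(dimers):
        groups.setdefault((d.symbols_a, d.symbols_b), []).append(i)
    for (sym_a, sym_b), idx in groups.items():
        ca = np.stack([dimers[i].coords_a for i in idx])
        cb = np.stack([dimers[i].coords_b for i in idx])
        naive, _ = _batch_block(table, sym_a, ca, sym_b, cb, 0,
                                charges_a=mulliken.get(sym_a),
                                charges_b=mulliken.get(sym_b))
        out[idx] = naive
    return out


# ---------------------------------------------------------------------------
# Estimator


class LaplacianXCRegressor(RegressorMixin, BaseEstimator):
    """Least-squares calibration of the XC weights.

    Parameters
    ----------
    order : int
        Highest Laplacian iteration K; the model has 2(K+1) weights.
    method : {'linear', 'ga_bfgs'}
        'linear' solves the least-squares problem exactly; 'ga_bfgs'
        runs a seeded genetic algorithm followed by BFGS polish.
    seed : int
        Random seed for the 'ga_bfgs' stage (ignored by 'linear').
    basis_mode : {'ecp', 'full'}
        Recorded on the fitted :class:`XCCoefficients`.
    sample_weight_beta : float
        If nonzero, Boltzmann-style weighting exp(−β|E_ref|) (β in
        mol/kJ applied to |y| converted to kJ/mol) of the residuals;
        uniform weighting (0) by default.

    The design matrix X must be the output of
    :func:`build_design_matrix`: naïve energy in column 0 (treated as a
    fixed offset, never fitted) and the functional values after it, all
    in hartree; y is the reference interaction energy in hartree.

    Attributes
    ----------
    coef_ : ndarray of shape (2(order+1),)
        Fitted stacked weights [c_0..c_K, d_0..d_K].
    coefficients_ : XCCoefficients
        The same weights in the structured container.
    rae_ : float
        Training relative absolute error.
    residuals_ : ndarray
        Per-sample E_model − E_ref, hartree.
    standard_errors_ : ndarray
        Linear-model standard errors of coef_ ('linear' only).
    optimizer_trace_ : dict
        Solver summary (iterations, objective values).
    """

    def __init__(self, order: int = 6, method: str = "linear", seed: int = 0,
                 basis_mode: str = "ecp", sample_weight_beta: float = 0.0):
        self.order = order
        self.method = method
        self.seed = seed
        self.basis_mode = basis_mode
        self.sample_weight_beta = sample_weight_beta

    def _validate(self, X, y):
        if self.order < 0:
            raise ValueError("order must be ≥ 0")
        if self.method not in ("linear", "ga_bfgs"):
            raise ValueError(f"unknown method {self.method!r}")
        X, y = check_X_y(X, y, y_numeric=True)
        p = 2 * (self.order + 1)
        if X.shape[1] != p + 1:
            raise ValueError(
                f"X has {X.shape[1]} columns; order {self.order} requires "
                f"{p + 1} (naive offset + {p} functionals)")
        if X.shape[0] < p:
            raise ValueError(f"need at least {p} samples to fit {p} weights, got {X.shape[0]}")
        return X, y

    def fit(self, X, y):
        X, y = self._validate(X, y)
        F = X[:, 1:]
        resid = y - X[:, 0]
        if self.sample_weight_beta:
            w = np.exp(-self.sample_weight_beta * np.abs(y) * KJ_PER_MOL_PER_HARTREE)
            sw = np.sqrt(w)
            F, resid = F * sw[:, None], resid * sw

        # column equilibration for conditioning; zero columns flagged as degenerate
        scale = np.linalg.norm(F, axis=0)
        rank = np.linalg.matrix_rank(F)
        if rank < F.shape[1]:
            labels = ([f"ee_k={k}" for k in range(self.order + 1)]
                      + [f"en_k={k}" for k in range(self.order + 1)])
            _, sv, vt = np.linalg.svd(F, full_matrices=False)
            null = vt[rank:]
            degenerate = sorted({labels[j] for row in null
                                 for j in np.nonzero(np.abs(row) > 1e-8)[0]})
            raise ValueError(
                "rank-deficient feature matrix; degenerate functional columns: "
                + ", ".join(degenerate))
        Fs = F / scale

        if self.method == "linear":
            ws, res, _, _ = np.linalg.lstsq(Fs, resid, rcond=None)
            self.optimizer_trace_ = {"method": "linear", "iterations": 1}
        else:
            ws, trace = self._ga_bfgs(Fs, resid)
            self.optimizer_trace_ = trace
        coef = ws / scale

        self.coef_ = coef
        self.coefficients_ = XCCoefficients.from_stacked(
            coef, basis_mode=self.basis_mode,
            metadata={"method": self.method, "seed": self.seed})
        self.n_features_in_ = X.shape[1]
        pred = X[:, 0] + X[:, 1:] @ coef
        self.residuals_ = pred - y
        self.rae_ = relative_absolute_error(pred, y)
        if self.method == "linear":
            dof = max(X.shape[0] - F.shape[1], 1)
            sigma2 = float(((resid - Fs @ ws) ** 2).sum()) / dof
            cov_s = sigma2 * np.linalg.pinv(Fs.T @ Fs)
            self.standard_errors_ = np.sqrt(np.diag(cov_s)) / scale
        return self

    def _ga_bfgs(self, F, y):
        """Seeded GA global stage + BFGS polish on the (equilibrated) SSE."""
        rng = np.random.default_rng(self.seed)
        p = F.shape[1]

        def sse(w):
            r = F @ w - y
            return float(r @ r)

        pop_size, n_gen = 48, 80
        scale0 = np.linalg.norm(y) / max(np.linalg.norm(F, axis=0).max(), 1e-300)
        pop = rng.normal(0.0, scale0, size=(pop_size, p))
        pop[0] = 0.0
        fitness = np.array([sse(ind) for ind in pop])
        history = [float(fitness.min())]
        for _ in range(n_gen):
            order = np.argsort(fitness)
            elite = pop[order[: pop_size // 4]]
            children = []
            while len(children) < pop_size - len(elite):
                i, j = rng.integers(0, len(elite), size=2)
                lam = rng.uniform(-0.25, 1.25, size=p)  # blend crossover
                child = lam * elite[i] + (1 - lam) * elite[j]
                if rng.random() < 0.4:
                    child = child + rng.normal(0.0, scale0 * 0.1, size=p)
                children.append(child)
            pop = np.vstack([elite, children])
            fitness = np.array([sse(ind) for ind in pop])
            history.append(float(fitness.min()))
        best = pop[np.argmin(fitness)]
        polish = minimize(sse, best, jac=lambda w: 2.0 * (F.T @ (F @ w - y)),
                          method="BFGS", options={"gtol": 1e-16, "maxiter": 20000})
        trace = {"method": "ga_bfgs", "generations": n_gen,
                 "ga_best": history[-1], "bfgs_iterations": int(polish.nit),
                 "objective": float(polish.fun), "history_head": history[:5]}
        return polish.x, trace

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {X.shape[1]} columns, expected {self.n_features_in_}")
        return X[:, 0] + X[:, 1:] @ self.coef_


# ---------------------------------------------------------------------------
# Reference-set level wrappers


@dataclass
class FitReport:
    """Outcome of one calibration run."""

    coefficients: XCCoefficients
    rae: float
    residuals_kj_mol: np.ndarray
    optimizer_trace: dict
    seed: int
    data_hash: str = ""
    holdout_rae: float | None = None

    def save(self, path) -> None:
        doc = {
            "coefficients": {
                "basis_mode": self.coefficients.basis_mode,
                "order": self.coefficients.order,
                "ee_weights": self.coefficients.ee_weights,
                "en_weights": self.coefficients.en_weights,
            },
            "rae": float(self.rae),
            "holdout_rae": None if self.holdout_rae is None else float(self.holdout_rae),
            "seed": int(self.seed),
            "data_hash": self.data_hash,
            "optimizer_trace": self.optimizer_trace,
            "residuals_kj_mol": [float(r) for r in self.residuals_kj_mol],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "FitReport":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        c = doc["coefficients"]
        return cls(
            coefficients=XCCoefficients(order=c["order"], ee_weights=c["ee_weights"],
                                        en_weights=c["en_weights"],
                                        basis_mode=c["basis_mode"]),
            rae=doc["rae"], residuals_kj_mol=np.array(doc["residuals_kj_mol"]),
            optimizer_trace=doc["optimizer_trace"], seed=doc["seed"],
            data_hash=doc.get("data_hash", ""), holdout_rae=doc.get("holdout_rae"))


def _refset_hash(refset: ReferenceSet) -> str:
    h = hashlib.sha256()
    for e in refset.entries:
        h.update(e.geometry.coords.tobytes())
        h.update(np.float64(e.energy_kj_mol).tobytes())
    return h.hexdigest()[:16]


def fit_xc_coefficients(refset: ReferenceSet, K: int, table: DensityTable,
                        method: str = "linear", seed: int = 0,
                        basis_mode: str | None = None, mulliken=None,
                        holdout_fraction: float = 0.0,
                        rae_kind: str = "aggregate") -> FitReport:
    """Fit the order-K XC weights to a reference set.

    With ``holdout_fraction`` > 0 a seeded split reserves that fraction
    of entries for a held-out RAE; the fit itself uses the rest.
    """
    if K < 0:
        raise ValueError("order K must be ≥ 0")
    if len(refset) < 2 * (K + 1):
        raise ValueError(f"reference set has {len(refset)} entries; "
                         f"order {K} needs at least {2 * (K + 1)}")
    basis_mode = basis_mode or table.basis_mode
    X = build_design_matrix(refset.geometries, table, K, mulliken=mulliken)
    y = refset.energies / KJ_PER_MOL_PER_HARTREE

    if holdout_fraction > 0:
        rng = np.random.default_rng(seed)
        n = len(refset)
        held = rng.choice(n, size=max(1, int(round(holdout_fraction * n))), replace=False)
        mask = np.ones(n, dtype=bool)
        mask[held] = False
    else:
        mask = np.ones(len(refset), dtype=bool)

    est = LaplacianXCRegressor(order=K, method=method, seed=seed, basis_mode=basis_mode)
    est.fit(X[mask], y[mask])
    holdout_rae = None
    if not mask.all():
        holdout_rae = relative_absolute_error(est.predict(X[~mask]), y[~mask], kind=rae_kind)
    pred_all = est.predict(X)
    residuals_kj = (pred_all - y) * KJ_PER_MOL_PER_HARTREE
    rae = relative_absolute_error(pred_all[mask] * KJ_PER_MOL_PER_HARTREE,
                                  refset.energies[mask], kind=rae_kind)
    return FitReport(coefficients=est.coefficients_, rae=rae,
                     residuals_kj_mol=residuals_kj, optimizer_trace=est.optimizer_trace_,
                     seed=seed, data_hash=_refset_hash(refset), holdout_rae=holdout_rae)


def order_scan(refset: ReferenceSet, max_order: int, table: DensityTable,
               method: str = "linear", seed: int = 0, mulliken=None,
               rae_kind: str = "aggregate") -> pd.DataFrame:
    """Training error as a function of the approximation order 0..max_order.

    Returns one row per order with the RAE and the normalized L2 error
    ``nrmse`` = ‖E_model − E_ref‖₂ / ‖E_ref‖₂. Features are nested across
    orders, so with the exact linear solver ``nrmse`` — the normalized
    form of the fitted objective — is non-increasing in the order; the
    RAE tracks it but, being an L1 ratio over an L2 fit, can fluctuate
    within the residual noise floor.
    """
    if max_order < 0:
        raise ValueError("max_order must be ≥ 0")
    X = build_design_matrix(refset.geometries, table, max_order, mulliken=mulliken)
    y = refset.energies / KJ_PER_MOL_PER_HARTREE
    rows = []
    for K in range(max_order + 1):
        cols = [0] + list(range(1, K + 2)) + list(range(max_order + 2, max_order + K + 3))
        est = LaplacianXCRegressor(order=K, method=method, seed=seed,
                                   basis_mode=table.basis_mode)
        est.fit(X[:, cols], y)
        pred = est.predict(X[:, cols]) * KJ_PER_MOL_PER_HARTREE
        rae = relative_absolute_error(pred, refset.energies, kind=rae_kind)
        nrmse = float(np.linalg.norm(pred - refset.energies)
                      / np.linalg.norm(refset.energies))
        rows.append({"order": K, "rae": rae, "nrmse": nrmse})
    return pd.DataFrame(rows)
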