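"""Growth-curve analysis (GCA) of SNR time courses.

The 200-1000 ms SNR trajectory of each subject and condition is modelled
with centered orthogonal polynomials (linear, quadratic, optionally cubic)
in a linear mixed-effects regression with by-subject random intercepts.
Condition is dummy-coded against a declared reference level, and each
polynomial term interacts with condition, so an interaction coefficient is
the *adjustment* of that shape term relative to the reference condition.
Because the polynomial basis is centered, the model intercept is the mean
SNR over the interval, not the value at time zero.

Estimation is REML (via statsmodels MixedLM).  Degrees of freedom for the
t statistics use the Satterthwaite approximation, computed analytically for
the random-intercept model: for a contrast c, df = 2 f² / Var(f) with
f = c'(X'V⁻¹X)⁻¹c, the variance obtained by the delta method with the
inverse REML Fisher information of (σ², τ00).  P-values of all fixed
effects except the intercept are Benjamini-Hochberg adjusted.

Coefficient magnitudes depend on the basis normalization (unit-norm columns
here); comparisons with fits that scale polynomials differently are
meaningful at the level of sign and significance pattern, not raw size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import CONDITIONS
from .spectral import SNRTimeCourse


class GCAError(ValueError):
    pass


TERM_NAMES = ("Linear", "Quadratic", "Cubic")


# ---------------------------------------------------------------------------
# orthogonal polynomial basis


@dataclass
class PolyBasis:
    """Orthonormal polynomial columns over a set of time points.

    Columns are zero-sum and pairwise orthogonal with unit norm, built by
    Gram-Schmidt on the centered powers (t, t², t³) — the same construction
    R's ``poly()`` uses.
    """

    time_points: np.ndarray
    order: int
    basis: np.ndarray  # (n_points, order)

    @property
    def names(self) -> tuple[str, ...]:
        return TERM_NAMES[: self.order]


def poly_basis(time_points: np.ndarray, order: int = 3) -> PolyBasis:
    """Centered orthonormal polynomial basis of the given order."""
    t = np.asarray(time_points, dtype=float)
    if len(np.unique(t)) != len(t):
        raise GCAError("duplicate time points")
    if len(t) < order + 1:
        raise GCAError(f"need at least {order + 1} distinct time points")
    tc = t - t.mean()
    cols = []
    for k in range(1, order + 1):
        v = tc**k
        v = v - v.mean()  # orthogonal to the intercept direction
        for u in cols:
            v = v - (v @ u) * u
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise GCAError("degenerate time grid: polynomial column collapsed")
        cols.append(v / nrm)
    return PolyBasis(time_points=t, order=order, basis=np.column_stack(cols))


def statistics_grid(
    t0: float = 200.0, t1: float = 1000.0, step: float = 32.0
) -> np.ndarray:
    """The default 26-point statistics grid: 200..1000 ms in 32 ms bins."""
    n = int(round((t1 - t0) / step)) + 1
    return t0 + step * np.arange(n)


# ---------------------------------------------------------------------------
# design construction


@dataclass
class GCADesign:
    """Long-format GCA design: data frame + fixed-effects matrix."""

    frame: pd.DataFrame  # subject, condition, bin_ms, snr
    basis: PolyBasis
    reference: str
    order: int
    X: np.ndarray = field(repr=False, default=None)
    columns: list[str] = field(default_factory=list)
    y: np.ndarray = field(repr=False, default=None)
    groups: np.ndarray = field(repr=False, default=None)

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject"].nunique()


def _tidy_frame(tcs: list[SNRTimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in tcs:
        for t, v in zip(tc.bin_centers, tc.snr):
            rows.append(
                {"subject": tc.subject_id, "condition": tc.condition,
                 "bin_ms": float(t), "snr": float(v)}
            )
    return pd.DataFrame(rows)


def build_design(
    data: list[SNRTimeCourse] | pd.DataFrame,
    reference: str = "TS",
    order: int = 3,
) -> GCADesign:
    """Assemble the long-format design with dummy codes and interactions.

    Every subject must contribute all three conditions on one common time
    grid.  Rows are ordered by subject, then condition, then time, giving
    ``n_subjects * 3 * n_bins`` observations.
    """
    if reference not in CONDITIONS:
        raise GCAError(f"unknown reference level {reference!r}")
    frame = data.copy() if isinstance(data, pd.DataFrame) else _tidy_frame(data)
    if "bin_ms" not in frame.columns and "bin_center_ms" in frame.columns:
        frame = frame.rename(columns={"bin_center_ms": "bin_ms"})
    if frame.empty:
        raise GCAError("empty design: need >= 2 subjects with complete cells")
    subjects = sorted(frame["subject"].unique())
    bins = np.array(sorted(frame["bin_ms"].unique()))
    for s in subjects:
        for c in CONDITIONS:
            cell = frame[(frame["subject"] == s) & (frame["condition"] == c)]
            if not np.array_equal(np.sort(cell["bin_ms"].to_numpy()), bins):
                raise GCAError(
                    f"missing or mismatched cell for subject {s!r}, "
                    f"condition {c!r}"
                )
    frame = frame.sort_values(["subject", "condition", "bin_ms"],
                              kind="mergesort").reset_index(drop=True)

    basis = poly_basis(bins, order)
    bin_index = {t: i for i, t in enumerate(bins)}
    P = basis.basis[[bin_index[t] for t in frame["bin_ms"]], :]

    dummies = [c for c in CONDITIONS if c != reference]
    D = np.column_stack([(frame["condition"] == c).to_numpy(float) for c in dummies])

    cols: list[np.ndarray] = [np.ones(len(frame))]
    names: list[str] = ["Intercept"]
    for k, nm in enumerate(basis.names):
        cols.append(P[:, k])
        names.append(nm)
    for j, c in enumerate(dummies):
        cols.append(D[:, j])
        names.append(c)
    for k, nm in enumerate(basis.names):
        for j, c in enumerate(dummies):
            cols.append(P[:, k] * D[:, j])
            names.append(f"{nm}:{c}")

    X = np.column_stack(cols)
    return GCADesign(
        frame=frame,
        basis=basis,
        reference=reference,
        order=order,
        X=X,
        columns=names,
        y=frame["snr"].to_numpy(float),
        groups=frame["subject"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# mixed model


@dataclass
class FitResult:
    """Random-intercept mixed-model fit of a GCA design."""

    coefficients: pd.DataFrame  # name, estimate, se, t, df, p, p_adj
    sigma2: float
    tau00: float
    icc: float
    n_obs: int
    n_subj: int
    r2_marginal: float
    r2_conditional: float
    reference_level: str
    loglik: float
    fitted: np.ndarray = field(repr=False, default=None)

    def coef(self, name: str) -> pd.Series:
        row = self.coefficients[self.coefficients["name"] == name]
        if row.empty:
            raise GCAError(f"no coefficient named {name!r}")
        return row.iloc[0]

    def to_tsv(self, path: str | Path) -> None:
        """Coefficient table + random-effects block, tab-separated."""
        lines = ["name\testimate\tse\tstatistic\tdf\tp\tp_adjusted"]
        for _, r in self.coefficients.iterrows():
            lines.append(
                f"{r['name']}\t{r['estimate']:.6g}\t{r['se']:.6g}\t"
                f"{r['t']:.4f}\t{r['df']:.1f}\t{r['p']:.3g}\t{r['p_adj']:.3g}"
            )
        lines += [
            "",
            f"sigma2\t{self.sigma2:.6g}",
            f"tau00_subject\t{self.tau00:.6g}",
            f"ICC\t{self.icc:.6g}",
            f"N_subjects\t{self.n_subj}",
            f"Observations\t{self.n_obs}",
            f"R2_marginal\t{self.r2_marginal:.6g}",
            f"R2_conditional\t{self.r2_conditional:.6g}",
            f"reference_level\t{self.reference_level}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _profile_reml(
    X: np.ndarray, y: np.ndarray, group_idx: list[np.ndarray], lam0: float
) -> tuple[np.ndarray, float, float, float]:
    """Exact REML for the random-intercept model by profiling.

    With V = σ²(I + λ ZZ') the restricted likelihood is a smooth function of
    the single ratio λ = τ00/σ²; β and σ² have closed forms given λ.  The
    scalar maximization refines the numerical optimizer's estimate to near
    machine precision.  Returns (β, σ², τ00, REML log-likelihood).
    """
    n, p = X.shape

    def components(lam: float):
        M = np.zeros((p, p))
        b = np.zeros(p)
        logdet_v = 0.0
        blocks = []
        for idx in group_idx:
            Xj, yj = X[idx], y[idx]
            nj = len(idx)
            a = lam / (1.0 + lam * nj)
            xs, ys = Xj.sum(axis=0), yj.sum()
            M += Xj.T @ Xj - a * np.outer(xs, xs)
            b += Xj.T @ yj - a * xs * ys
            logdet_v += np.log1p(lam * nj)
            blocks.append((Xj, yj, nj, a, xs, ys))
        beta = np.linalg.solve(M, b)
        Q = 0.0
        for Xj, yj, nj, a, xs, ys in blocks:
            rj = yj - Xj @ beta
            Q += rj @ rj - a * rj.sum() ** 2
        sigma2 = Q / (n - p)
        sign, logdet_m = np.linalg.slogdet(M)
        ll = -0.5 * (
            (n - p) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_v + logdet_m
        )
        return beta, sigma2, ll

    def neg_ll(lam: float) -> float:
        return -components(lam)[2]

    hi = max(10.0 * lam0, 10.0)
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        neg_ll, bounds=(0.0, hi), method="bounded",
        options={"xatol": 1e-12 * (1.0 + hi)},
    )
    lam = float(res.x)
    if neg_ll(0.0) <= res.fun:  # boundary: no subject variance
        lam = 0.0
    beta, sigma2, ll = components(lam)
    return beta, sigma2, lam * sigma2, ll


def _satterthwaite_df(
    X: np.ndarray, group_idx: list[np.ndarray], sigma2: float, tau00: float
) -> tuple[np.ndarray, np.ndarray]:
    """Satterthwaite dfs and SEs for each coefficient of a random-intercept
    model with V_j = σ²I + τ00·11'."""
    p = X.shape[1]
    n = X.shape[0]
    M = np.zeros((p, p))
    G_sigma = np.zeros((p, p))  # Σ X' V⁻² X
    u_list = []
    Vinv = np.zeros((n, n))
    for idx in group_idx:
        Xj = X[idx]
        nj = len(idx)
        a = tau00 / (sigma2 + nj * tau00)
        # V_j⁻¹ = (I - a 11') / σ²
        XtV = (Xj.T - a * np.outer(Xj.sum(axis=0), np.ones(nj))) / sigma2
        M += XtV @ Xj
        G_sigma += XtV @ XtV.T
        u_list.append(XtV @ np.ones(nj))
        Vinv[np.ix_(idx, idx)] = (np.eye(nj) - a) / sigma2 if nj == 1 else (
            (np.eye(nj) - a * np.ones((nj, nj))) / sigma2
        )
    C = np.linalg.inv(M)
    U = np.column_stack(u_list)  # p x g
    G_tau = U @ U.T

    # REML Fisher information of (σ², τ00)
    W = Vinv @ X
    Pmat = Vinv - W @ C @ W.T
    g = len(group_idx)
    Uind = np.zeros((n, g))
    for j, idx in enumerate(group_idx):
        Uind[idx, j] = 1.0
    PU = Pmat @ Uind
    I11 = 0.5 * np.sum(Pmat**2)
    I12 = 0.5 * np.sum(PU**2)
    I22 = 0.5 * np.sum((Uind.T @ PU) ** 2)
    fisher = np.array([[I11, I12], [I12, I22]])
    try:
        cov_theta = np.linalg.inv(fisher)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(fisher)

    f = np.diag(C).copy()
    dfs = np.empty(p)
    for k in range(p):
        ck = C[:, k]
        g1 = ck @ G_sigma @ ck  # ∂f/∂σ²
        g2 = ck @ G_tau @ ck  # ∂f/∂τ00
        grad = np.array([g1, g2])
        var_f = grad @ cov_theta @ grad
        dfs[k] = 2.0 * f[k] ** 2 / var_f if var_f > 0 else n - p
    return dfs, np.sqrt(f)


def fit_lmm(design: GCADesign, satterthwaite: bool = True) -> FitResult:
    """REML fit of the random-intercept growth-curve model.

    Set ``satterthwaite=False`` to use residual (n - p - 1) degrees of
    freedom instead of the Satterthwaite approximation.
    """
    X, y, groups = design.X, design.y, design.groups
    if design.n_subjects < 2:
        raise GCAError("need >= 2 subjects for a mixed model")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        rdiag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [design.columns[i] for i in np.flatnonzero(rdiag < 1e-10 * rdiag.max())]
        raise GCAError(
            f"fixed-effects matrix is rank deficient (rank {rank} < "
            f"{X.shape[1]}); collinear columns: {bad or design.columns}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
    if not np.all(np.isfinite(res.fe_params)):
        raise GCAError("mixed-model fit did not converge to finite estimates")
    sigma2 = float(res.scale)
    tau00 = float(np.asarray(res.cov_re)[0, 0])

    group_idx = [np.flatnonzero(groups == gl) for gl in pd.unique(groups)]
    # refine the optimizer's estimate on the exact profiled likelihood
    lam0 = tau00 / sigma2 if sigma2 > 0 else 1.0
    beta, sigma2, tau00, loglik = _profile_reml(X, y, group_idx, lam0)
    if satterthwaite:
        dfs, ses = _satterthwaite_df(X, group_idx, sigma2, tau00)
    else:
        p = X.shape[1]
        dfs = np.full(p, len(y) - p - 1, dtype=float)
        ses = np.asarray(res.bse_fe)
    tvals = beta / ses
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dfs)

    p_adj = np.full_like(pvals, np.nan)
    non_int = [i for i, nm in enumerate(design.columns) if nm != "Intercept"]
    p_adj[non_int] = bh_adjust(pvals[non_int])
    p_adj[design.columns.index("Intercept")] = pvals[design.columns.index("Intercept")]

    fitted = X @ beta
    var_fixed = float(np.var(fitted))
    denom = var_fixed + tau00 + sigma2
    icc = tau00 / (tau00 + sigma2) if tau00 + sigma2 > 0 else 0.0

    coef = pd.DataFrame(
        {
            "name": design.columns,
            "estimate": beta,
            "se": ses,
            "t": tvals,
            "df": dfs,
            "p": pvals,
            "p_adj": p_adj,
        }
    )
    return FitResult(
        coefficients=coef,
        sigma2=sigma2,
        tau00=tau00,
        icc=float(icc),
        n_obs=len(y),
        n_subj=design.n_subjects,
        r2_marginal=var_fixed / denom if denom > 0 else 0.0,
        r2_conditional=(var_fixed + tau00) / denom if denom > 0 else 0.0,
        reference_level=design.reference,
        loglik=float(loglik),
        fitted=fitted,
    )


def relevel_and_refit(design: GCADesign, new_reference: str) -> FitResult:
    """Refit with a different reference level.

    A pure reparameterization: fitted values and the REML log-likelihood are
    unchanged; coefficients are re-expressed against the new reference.
    """
    if new_reference not in CONDITIONS:
        raise GCAError(f"unknown reference level {new_reference!r}")
    d2 = build_design(design.frame, reference=new_reference, order=design.order)
    return fit_lmm(d2)


# ---------------------------------------------------------------------------
# multiple-testing correction


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise GCAError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# within-subject SEM


def morey_sem(tcs: list[SNRTimeCourse]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Cousineau-Morey within-subject SEM per condition and time bin.

    Each subject's mean across the k = 3 condition cells is removed at every
    time bin (Cousineau normalization), the grand mean restored, and the
    resulting between-subject SEM inflated by sqrt(k / (k-1)) (Morey bias
    correction).

    Returns ``{condition: (bin_centers, sem)}``.
    """
    frame = _tidy_frame(tcs)
    subjects = sorted(frame["subject"].unique())
    bins = np.array(sorted(frame["bin_ms"].unique()))
    conds = [c for c in CONDITIONS if c in set(frame["condition"])]
    k = len(conds)
    if k < 2:
        raise GCAError("need >= 2 within-subject cells for the Morey correction")
    if len(subjects) < 2:
        raise GCAError("need >= 2 subjects")
    cube = np.full((len(subjects), k, len(bins)), np.nan)
    for i, s in enumerate(subjects):
        for j, c in enumerate(conds):
            cell = frame[(frame["subject"] == s) & (frame["condition"] == c)]
            cell = cell.sort_values("bin_ms")
            if len(cell) != len(bins):
                raise GCAError(f"incomplete cell: subject {s!r}, condition {c!r}")
            cube[i, j] = cell["snr"].to_numpy()
    subj_mean = cube.mean(axis=1, keepdims=True)  # per subject, per bin
    grand = cube.mean(axis=(0, 1), keepdims=True)
    centered = cube - subj_mean + grand
    sem = centered.std(axis=0, ddof=1) / np.sqrt(len(subjects))
    sem = sem * np.sqrt(k / (k - 1.0))
    return {c: (bins, sem[j]) for j, c in enumerate(conds)}


# ---------------------------------------------------------------------------
# peak latency


def peak_latency(
    snr_values: np.ndarray,
    bin_centers: np.ndarray,
    method: str = "raw",
    order: int = 3,
) -> float:
    """Latency (ms) of the trajectory maximum.

    ``method="raw"`` returns the bin center of the maximum (ties -> earliest
    bin); ``method="poly"`` fits the centered orthogonal polynomial of the
    given order by least squares and returns the argmax of the fitted curve
    on a 1 ms grid.  A monotone series peaks at the boundary bin.
    """
    y = np.asarray(snr_values, dtype=float)
    t = np.asarray(bin_centers, dtype=float)
    if len(y) < 3:
        raise GCAError("need at least 3 bins")
    if np.allclose(y, y[0]):
        warnings.warn("flat series: returning the earliest bin")
        return float(t[0])
    if method == "raw":
        return float(t[int(np.argmax(y))])
    if method == "poly":
        pb = poly_basis(t, order)
        Xd = np.column_stack([np.ones(len(t)), pb.basis])
        coefs, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        grid = np.arange(t[0], t[-1] + 0.5, 1.0)
        # evaluate the same orthogonal construction on the fine grid by
        # expressing each basis column as a polynomial (with constant term)
        # in centered time
        tc = t - t.mean()
        V = np.column_stack([tc**k for k in range(0, order + 1)])
        alpha, *_ = np.linalg.lstsq(V, pb.basis, rcond=None)
        gc = grid - t.mean()
        Vg = np.column_stack([gc**k for k in range(0, order + 1)])
        curve = coefs[0] + Vg @ alpha @ coefs[1:]
        return float(grid[int(np.argmax(curve))])
    raise GCAError(f"unknown method {method!r}")
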