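"""REML mixed linear model and genome-wide STR-dosage association.

The model is  y = 1 mu + X b + S u + Z a + e,  with a ~ N(0, G sigma_a^2)
for a marker-derived genomic relationship matrix G and e ~ N(0, I sigma_e^2).
Fixed effects are sex, the top genomic principal components, and initial
body weight nested in tank (one slope per tank).  Variance components are
estimated by REML after a single eigendecomposition of G, profiling the
restricted likelihood in the heritability parameter.

The genome scan defaults to the P3D/EMMAX strategy: variance components are
estimated once under the null model and each locus's dosage covariate is
then tested by a generalised-least-squares Wald t-test, with the residual
scale re-estimated per locus (so the test reduces exactly to the ordinary
regression t-test when G is the identity).  ``mode="exact"`` refits the
variance components for every locus instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

from .genotypes import DosageMatrix
from .relatedness import Grm, PcCovariates

__all__ = [
    "MixedModelSpec",
    "VarianceComponents",
    "build_design",
    "reml_fit",
    "assoc_scan",
    "pve",
    "SUGGESTIVE_ALPHA",
]

#: genome-wide suggestive-association threshold
SUGGESTIVE_ALPHA = 5e-4


@dataclass
class MixedModelSpec:
    """Aligned phenotype vector, fixed-effect design and GRM for one trait."""

    y: np.ndarray
    X: np.ndarray
    grm: Grm
    sample_ids: list[str]
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.y)
        if self.X.shape[0] != n or self.grm.matrix.shape[0] != n or len(self.sample_ids) != n:
            raise ValueError("y, X, GRM and sample_ids must be aligned")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError(
                f"fixed-effect design is rank deficient (columns: {self.column_names})"
            )


@dataclass(frozen=True)
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    loglik: float
    converged: bool
    boundary: bool = False

    @property
    def h2(self) -> float:
        tot = self.sigma_a2 + self.sigma_e2
        return self.sigma_a2 / tot if tot > 0 else 0.0


def build_design(
    pheno: pd.DataFrame,
    grm: Grm,
    pcs: PcCovariates | pd.DataFrame | None = None,
    trait: str = "hbw",
) -> MixedModelSpec:
    """Assemble the association design from a phenotype table and GRM.

    ``pheno`` is indexed by sample id with columns sex, tank, ibw and the
    trait.  Samples are taken in GRM order; GRM samples lacking a phenotype
    are dropped from the analysis (with the matching GRM rows).
    """
    ids = [s for s in grm.sample_ids if s in pheno.index and not pd.isna(pheno.loc[s, trait])]
    if len(ids) < 3:
        raise ValueError("fewer than 3 phenotyped samples overlap the GRM")
    ph = pheno.loc[ids]
    keep = [grm.sample_ids.index(s) for s in ids]
    g = Grm(
        sample_ids=ids,
        matrix=grm.matrix[np.ix_(keep, keep)],
        scale_constant=grm.scale_constant,
    )
    cols: list[np.ndarray] = [np.ones(len(ids))]
    names = ["intercept"]
    sex_d = pd.get_dummies(ph["sex"].astype(str), prefix="sex", drop_first=True)
    for c in sex_d.columns:
        cols.append(sex_d[c].to_numpy(float))
        names.append(c)
    if pcs is not None:
        pc_df = pcs.to_frame() if isinstance(pcs, PcCovariates) else pcs
        pc_df = pc_df.loc[ids]
        for c in pc_df.columns:
            cols.append(pc_df[c].to_numpy(float))
            names.append(str(c))
    ibw = ph["ibw"].to_numpy(float)
    for tank in sorted(ph["tank"].astype(str).unique()):
        ind = (ph["tank"].astype(str) == tank).to_numpy(float)
        cols.append(ibw * ind)
        names.append(f"ibw:tank_{tank}")
    X = np.column_stack(cols)
    return MixedModelSpec(
        y=ph[trait].to_numpy(float), X=X, grm=g, sample_ids=ids, column_names=names
    )


def _check_psd(G: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    if vals.min() < -1e-8 * max(abs(vals.max()), 1.0):
        raise ValueError(f"G is not positive semidefinite (min eigenvalue {vals.min():.3g})")
    return np.clip(vals, 0.0, None), vecs


def _reml_loglik_rotated(h: float, d: np.ndarray, ys: np.ndarray, Xs: np.ndarray) -> tuple[float, float, float]:
    """REML log-likelihood at heritability h, plus (sigma_a2, sigma_e2).

    Uses the rotated representation V = sigma_a2 * diag(d + delta) with
    delta = (1-h)/h; the likelihood includes the ln|X'V^-1 X| REML term
    (Harville form, without the constant ln|X'X|).
    """
    n, q = Xs.shape
    delta = (1.0 - h) / h
    w = d + delta
    Wi = 1.0 / w
    XtWX = Xs.T @ (Wi[:, None] * Xs)
    XtWy = Xs.T @ (Wi * ys)
    b = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ b
    rss = float(np.sum(r * r * Wi))
    sigma_a2 = rss / (n - q)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sigma_a2 <= 0:
        return np.inf, 0.0, 0.0  # perfect fit; boundary handling picks this up
    ll = -0.5 * (
        (n - q) * (np.log(2 * np.pi) + np.log(sigma_a2) + 1.0)
        + np.sum(np.log(w))
        + logdet_xwx
    )
    return float(ll), sigma_a2, sigma_a2 * delta


def _ols_boundary_loglik(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """REML log-likelihood of the sigma_a2 = 0 (pure-residual) boundary model."""
    n, q = X.shape
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ b
    sigma_e2 = float(r @ r) / (n - q)
    if sigma_e2 <= 0:
        return np.inf, 0.0  # y lies exactly in the column space of X
    _, logdet = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * ((n - q) * (np.log(2 * np.pi) + np.log(sigma_e2) + 1.0) + logdet)
    return float(ll), sigma_e2


def reml_fit(spec: MixedModelSpec, n_grid: int = 64) -> VarianceComponents:
    """Estimate (sigma_a2, sigma_e2) by REML.

    After eigendecomposition of G the restricted likelihood is profiled in
    the heritability h = sigma_a2/(sigma_a2+sigma_e2); a coarse grid seeds a
    bounded scalar optimisation.  Estimates that land on the h -> 0 or
    h -> 1 boundary are returned with ``boundary=True`` and the boundary
    model's likelihood.
    """
    y, X = spec.y, spec.X
    n, q = X.shape
    if n < q + 2:
        raise ValueError("need at least q + 2 observations for REML")
    d, U = _check_psd(spec.grm.matrix)
    ys = U.T @ y
    Xs = U.T @ X

    lo, hi = 1e-6, 1.0 - 1e-6
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([_reml_loglik_rotated(h, d, ys, Xs)[0] for h in grid])
    i = int(np.argmax(lls))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda h: -_reml_loglik_rotated(h, d, ys, Xs)[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-10},
    )
    h_hat = float(res.x)
    ll, sa2, se2 = _reml_loglik_rotated(h_hat, d, ys, Xs)

    ll0, se2_0 = _ols_boundary_loglik(y, X)
    if ll0 >= ll or h_hat <= 2e-6:
        return VarianceComponents(0.0, se2_0, max(ll0, ll), converged=True, boundary=True)
    if sa2 + se2 <= 1e-12 * max(float(np.var(y)), 1.0):
        return VarianceComponents(sa2, se2, ll, converged=True, boundary=True)
    boundary = h_hat >= hi - 1e-6
    return VarianceComponents(sa2, se2, ll, converged=bool(res.success), boundary=boundary)


def pve(u_hat: float, dosage_values: np.ndarray, y: np.ndarray) -> float:
    """Phenotypic variance explained: u^2 Var(s) / Var(y), clipped to [0,1]."""
    s = np.asarray(dosage_values, dtype=float)
    yv = float(np.var(np.asarray(y, dtype=float)))
    if yv <= 0:
        raise ValueError("phenotype variance is zero")
    return float(np.clip(u_hat**2 * np.var(s) / yv, 0.0, 1.0))


def _gls_wald(y, X, s, cho):
    """GLS fit of y on [X s] with a pre-factored covariance structure V;
    returns the dosage coefficient, its scale-re-estimated standard error and
    residual df."""
    Xa = np.column_stack([X, s])
    ViX = linalg.cho_solve(cho, Xa, check_finite=False)
    Viy = linalg.cho_solve(cho, y, check_finite=False)
    XtViX = Xa.T @ ViX
    beta = np.linalg.solve(XtViX, Xa.T @ Viy)
    r = y - Xa @ beta
    Vir = linalg.cho_solve(cho, r, check_finite=False)
    df = len(y) - np.linalg.matrix_rank(Xa)
    if df <= 0:
        return float(beta[-1]), np.nan, 0
    scale = float(r @ Vir) / df
    cov = np.linalg.inv(XtViX) * scale
    se = float(np.sqrt(cov[-1, -1]))
    return float(beta[-1]), se, df


def assoc_scan(
    spec: MixedModelSpec,
    dosage: DosageMatrix,
    mode: str = "p3d",
    vc: VarianceComponents | None = None,
    alpha: float = SUGGESTIVE_ALPHA,
    min_obs: int = 10,
) -> pd.DataFrame:
    """Test every locus's dosage against the trait under the mixed model.

    Individuals missing a locus's dosage are dropped for that locus only
    (case-wise deletion; the GRM itself is never re-estimated).  Returns one
    row per locus: n, u_hat, se, p_value, pve, suggestive, degenerate.
    """
    if mode not in ("p3d", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    if vc is None:
        vc = reml_fit(spec)
    n = len(spec.y)
    G = spec.grm.matrix
    V_full = vc.sigma_a2 * G + vc.sigma_e2 * np.eye(n)
    cho_full = linalg.cho_factor(V_full, lower=True, check_finite=False)
    id_pos = {s: i for i, s in enumerate(spec.sample_ids)}
    cols = [c for c in dosage.samples if c in id_pos]
    order = np.array([id_pos[c] for c in cols])
    S = dosage.dosage[cols].to_numpy(float)  # loci x matched samples

    records = []
    for li, locus_id in enumerate(dosage.locus_ids):
        s_row = S[li]
        obs = ~np.isnan(s_row)
        idx = order[obs]
        s_obs = s_row[obs]
        rec = {
            "locus_id": locus_id,
            "n": int(obs.sum()),
            "u_hat": np.nan,
            "se": np.nan,
            "p_value": np.nan,
            "pve": np.nan,
            "suggestive": False,
            "degenerate": True,
        }
        if obs.sum() < min_obs or np.var(s_obs) == 0:
            records.append(rec)
            continue
        y_sub = spec.y[idx]
        X_sub = spec.X[idx]
        if mode == "exact":
            sub_spec = MixedModelSpec(
                y=y_sub,
                X=np.column_stack([X_sub, s_obs]),
                grm=Grm([spec.sample_ids[i] for i in idx], G[np.ix_(idx, idx)], spec.grm.scale_constant),
                sample_ids=[spec.sample_ids[i] for i in idx],
                column_names=spec.column_names + ["dosage"],
            )
            vc_l = reml_fit(sub_spec)
            V = vc_l.sigma_a2 * G[np.ix_(idx, idx)] + vc_l.sigma_e2 * np.eye(len(idx))
            cho = linalg.cho_factor(V, lower=True, check_finite=False)
        elif obs.all():
            cho = cho_full
        else:
            cho = linalg.cho_factor(
                V_full[np.ix_(idx, idx)], lower=True, check_finite=False
            )
        u, se, df = _gls_wald(y_sub, X_sub, s_obs, cho)
        if not np.isfinite(se) or se == 0 or df <= 0:
            records.append(rec)
            continue
        p = float(2.0 * sps.t.sf(abs(u / se), df))
        p = max(p, np.finfo(float).tiny)
        rec.update(
            u_hat=u,
            se=se,
            p_value=p,
            pve=pve(u, s_obs, y_sub),
            suggestive=bool(p < alpha),
            degenerate=False,
        )
        records.append(rec)
    return pd.DataFrame(records).set_index("locus_id")
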