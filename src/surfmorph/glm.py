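"""Vertex-wise general linear models.

Each per-vertex measure Y_i is modelled across subjects j as

    Y_i = b0 + b1*Site + b2*Group + b3*Age + b4*Age^2 + b5*(Age x Group)
          + b6*(Age^2 x Group) + b7*Sex + b8*IQ + b9*Relatedness
          + b10*TotalSA + e

with ordinary least squares fitted independently at every vertex.
Categorical factors are 0/1 indicators (reference levels: site A, control
group, female sex, unrelated); continuous covariates are mean-centered across
the combined sample, and age powers are built from centered age and then
re-centered to limit collinearity, so b2 keeps its interpretation as the
group shift at the sample-average covariate values.

Developmental age trajectories are chosen by a step-up nested-model
procedure: the linear age model is compared to the quadratic by a
vertex-wise F test with RFT cluster correction, and only if the quadratic
wins anywhere is it compared to the cubic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, ShapeError
from .surface import Mesh

CANONICAL_ORDER = [
    "intercept", "site", "group", "age", "age2", "age_x_group",
    "age2_x_group", "sex", "iq", "relatedness", "total_sa",
    "age3", "age3_x_group",
]


@dataclass
class DesignMatrix:
    """Subjects x p design with named columns and a centering record."""

    frame: pd.DataFrame
    centering: dict[str, float] = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=np.float64)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def p(self) -> int:
        return self.frame.shape[1]

    def contrast_vector(self, name: str) -> np.ndarray:
        """Unit contrast selecting a single named coefficient."""
        c = np.zeros(self.p)
        c[self.columns.index(name)] = 1.0
        return c


def build_design(cohort: pd.DataFrame, age_order: int = 2,
                 with_interactions: bool = True, include_iq: bool = True,
                 group_column: str = "group", case_level: str = "case",
                 ) -> DesignMatrix:
    """Build the morphometry design matrix from a cohort table.

    ``age_order`` in {1, 2, 3} controls which age powers enter; interactions
    (age^k x group) are included for every age power when
    ``with_interactions``.  Lower-order designs are exact column subsets of
    higher-order ones, which is what the nested F tests require.
    """
    if age_order not in (1, 2, 3):
        raise DesignError(f"age_order must be 1, 2 or 3, got {age_order}")
    required = {group_column, "age", "sex", "site", "related", "total_sa"}
    if include_iq:
        required.add("iq")
    missing = required - set(cohort.columns)
    if missing:
        raise DesignError(f"cohort missing covariates: {sorted(missing)}")

    n = len(cohort)
    centering: dict[str, float] = {}

    def centered(series: pd.Series, name: str) -> np.ndarray:
        x = series.to_numpy(dtype=np.float64)
        centering[name] = float(x.mean())
        return x - x.mean()

    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    cols["site"] = (cohort["site"] == "B").to_numpy(dtype=np.float64)
    group = (cohort[group_column] == case_level).to_numpy(dtype=np.float64)
    cols["group"] = group
    age_c = centered(cohort["age"], "age")
    powers = {"age": age_c}
    for k, name in ((2, "age2"), (3, "age3")):
        if age_order >= k:
            pk = age_c**k
            centering[name] = float(pk.mean())
            powers[name] = pk - pk.mean()
    for name in ("age", "age2", "age3"):
        if name in powers:
            cols[name] = powers[name]
            if with_interactions:
                cols[f"{name}_x_group"] = powers[name] * group
    cols["sex"] = (cohort["sex"] == "M").to_numpy(dtype=np.float64)
    if include_iq:
        cols["iq"] = centered(cohort["iq"], "iq")
    cols["relatedness"] = (cohort["related"] == "yes").to_numpy(dtype=np.float64)
    cols["total_sa"] = centered(cohort["total_sa"], "total_sa")

    order = [c for c in CANONICAL_ORDER if c in cols]
    frame = pd.DataFrame({c: cols[c] for c in order})
    X = frame.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [order[i] for i in np.flatnonzero(
            np.abs(np.diag(R)) < 1e-8 * np.abs(np.diag(R)).max())]
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")
    return DesignMatrix(frame, centering)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class GLMFit:
    """Per-vertex OLS fit: betas (p x V), residuals (n x V), sigma2 (V,)."""

    design: DesignMatrix
    betas: np.ndarray
    residuals: np.ndarray
    sigma2: np.ndarray
    rss: np.ndarray
    df_resid: int
    xtx_inv: np.ndarray


@dataclass
class StatMap:
    """A per-vertex t or F statistic map with its degrees of freedom."""

    values: np.ndarray
    kind: str  # "t" | "F"
    df: tuple
    contrast: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()


def fit_ols(Y: np.ndarray, X: DesignMatrix) -> GLMFit:
    """Ordinary least squares at every vertex (columns of Y)."""
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.n:
        raise ShapeError(f"Y has {Y.shape[0]} rows, design has {X.n}")
    if X.n <= X.p:
        raise DesignError(
            f"insufficient degrees of freedom: n={X.n} <= p={X.p}"
        )
    Xv = X.values
    xtx_inv = np.linalg.inv(Xv.T @ Xv)
    betas = xtx_inv @ Xv.T @ Y
    resid = Y - Xv @ betas
    rss = (resid**2).sum(axis=0)
    df_resid = X.n - X.p
    sigma2 = rss / df_resid
    return GLMFit(X, betas, resid, sigma2, rss, df_resid, xtx_inv)


def contrast_t(fit: GLMFit, contrast: np.ndarray | str) -> StatMap:
    """t map for a linear combination of coefficients, df = n - p."""
    X = fit.design
    c = X.contrast_vector(contrast) if isinstance(contrast, str) else \
        np.asarray(contrast, dtype=np.float64)
    if c.size != X.p:
        raise ShapeError(f"contrast length {c.size} != p {X.p}")
    if not np.any(c):
        raise ValueError("contrast vector is all zeros")
    num = c @ fit.betas
    var_c = float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(fit.sigma2 * var_c)
    t[~np.isfinite(t)] = 0.0
    label = contrast if isinstance(contrast, str) else "custom"
    return StatMap(t, "t", (fit.df_resid,), label)


def nested_f(fit_reduced: GLMFit, fit_full: GLMFit) -> StatMap:
    """F map comparing nested designs: ((RSSr - RSSf)/q) / (RSSf/dff)."""
    red, full = fit_reduced.design, fit_full.design
    if not set(red.columns) < set(full.columns):
        raise DesignError(
            "designs are not strictly nested "
            f"(reduced {red.columns} vs full {full.columns})"
        )
    q = full.p - red.p
    if fit_reduced.residuals.shape != fit_full.residuals.shape:
        raise ShapeError("fits were computed on different data")
    dff = fit_full.df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((fit_reduced.rss - fit_full.rss) / q) / (fit_full.rss / dff)
    F = np.nan_to_num(F, nan=0.0, posinf=0.0)
    F[F < 0] = 0.0  # numerical noise on near-exact fits
    return StatMap(F, "F", (q, dff), f"order{red.p}_vs_{full.p}")


# ---------------------------------------------------------------------------
# step-up age-model selection


@dataclass
class SelectionStep:
    orders: tuple[int, int]
    fmap: StatMap
    clusters: "object"  # rft.ClusterSet
    significant: bool


@dataclass
class SelectionReport:
    adopted_order: int
    steps: list[SelectionStep]


def stepup_select(Y: np.ndarray, cohort: pd.DataFrame, mesh: Mesh,
                  cluster_alpha: float = 0.05, forming_p: float = 0.001,
                  include_iq: bool = True, selection_interactions: bool = False,
                  ) -> SelectionReport:
    """Step-up nested model selection of the age polynomial order.

    Linear vs quadratic first (F map, RFT cluster correction at
    ``cluster_alpha``); only if any cluster survives is quadratic compared to
    cubic.  The adopted order is global: the highest order whose addition
    significantly improved fit somewhere on the surface.  The selection runs
    on the combined sample with group as a main effect; age-by-group
    interactions are left out of the selection designs by default.
    """
    from . import rft

    designs = {k: build_design(cohort, age_order=k,
                               with_interactions=selection_interactions,
                               include_iq=include_iq)
               for k in (1, 2, 3)}
    fits = {k: fit_ols(Y, d) for k, d in designs.items()}

    steps: list[SelectionStep] = []
    adopted = 1
    for low, high in ((1, 2), (2, 3)):
        fmap = nested_f(fits[low], fits[high])
        smooth = rft.estimate_smoothness(fits[high], mesh)
        clusters = rft.extract_clusters(fmap, mesh, forming_p,
                                        tail="positive", smooth=smooth)
        clusters = rft.cluster_pvalues(clusters, smooth, fmap.df, "F",
                                       two_tailed=False)
        sig = any(c.p_cluster <= cluster_alpha for c in clusters.clusters)
        steps.append(SelectionStep((low, high), fmap, clusters, sig))
        if not sig:
            break
        adopted = high
    return SelectionReport(adopted, steps)


# ---------------------------------------------------------------------------
# global (whole-brain) summary statistics


def global_stats(cohort: pd.DataFrame,
                 measures: tuple[str, ...] = ("age", "iq", "total_cv",
                                              "mean_ct", "total_sa"),
                 correlates: tuple[str, ...] = ("total_cv", "total_sa",
                                                "mean_ct"),
                 ) -> pd.DataFrame:
    """Two-sample pooled-variance t tests (df = n1 + n2 - 2) on global
    measures, and Pearson correlations of IQ with the anatomical globals."""
    case = cohort[cohort["group"] == "case"]
    ctrl = cohort[cohort["group"] == "control"]
    rows = []
    for m in measures:
        if m not in cohort.columns:
            continue
        x, y = case[m].to_numpy(float), ctrl[m].to_numpy(float)
        t, p = stats.ttest_ind(x, y, equal_var=True)
        rows.append(dict(kind="t", measure=m, statistic=float(t),
                         df=len(x) + len(y) - 2, p=float(p),
                         case_mean=x.mean(), control_mean=y.mean()))
    if "iq" in cohort.columns:
        for m in correlates:
            if m not in cohort.columns:
                continue
            x = cohort["iq"].to_numpy(float)
            y = cohort[m].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(
                    f"correlation undefined: constant column in iq vs {m}"
                )
            r, p = stats.pearsonr(x, y)
            rows.append(dict(kind="r", measure=f"iq_vs_{m}",
                             statistic=float(r), df=len(x) - 2, p=float(p),
                             case_mean=np.nan, control_mean=np.nan))
    return pd.DataFrame(rows)
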