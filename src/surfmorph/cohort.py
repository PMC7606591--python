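"""Synthetic two-group cohort and per-vertex measure generator.

The generator emulates a case/control developmental cohort (62 cases aged
6-31 vs 57 controls aged 6-27 by default) with the global marginals of the
study population it stands in for: cases have markedly lower full-scale IQ
(~82 vs ~114) and reduced total cortical surface area (~0.20 vs ~0.23 m^2),
while mean cortical thickness (~2.72 mm) and total grey-matter volume do not
differ between groups.

Per-vertex measures are built on a template mesh as

* CT (mm): subject-level baseline + quadratic age trend + planted group
  effects + spatially smooth Gaussian noise;
* SA (mm^2): template vertex tessellation area scaled by the subject's total
  surface area, modulated by age trend, planted effects and smooth
  multiplicative noise;
* CV (mm^3): the per-vertex product CT * SA times optional log-normal noise.

The product rule for CV is the generative premise that lets the downstream
decomposition stage exhibit SA-driven volume loss and the masking of CV
differences by opposing CT/SA effects, rather than having those outcomes
hard-coded.

Planted effects are expressed in Cohen's-d units of the vertex-level smooth
noise standard deviation, and ground-truth signed masks are returned for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .errors import ShapeError
from .surface import Mesh, SurfaceSmoother, build_adjacency

# Cohort marginals emulated by default (means, sds, ranges).
COHORT_DEFAULTS = {
    "case": dict(n=62, age_range=(6.0, 31.0), age_mean=16.0, age_sd=7.0,
                 iq_mean=82.0, iq_sd=13.0, iq_range=(60.0, 116.0),
                 total_sa_mean=0.20, total_sa_sd=0.0275,
                 mean_ct_mean=2.72, mean_ct_sd=0.14,
                 total_cv_mean=0.59, total_cv_sd=0.23,
                 n_male=30, n_prodromal=9),
    "control": dict(n=57, age_range=(6.0, 27.0), age_mean=15.0, age_sd=6.0,
                    iq_mean=114.0, iq_sd=16.0, iq_range=(76.0, 148.0),
                    total_sa_mean=0.23, total_sa_sd=0.0275,
                    mean_ct_mean=2.73, mean_ct_sd=0.12,
                    total_cv_mean=0.64, total_cv_sd=0.24,
                    n_male=27, n_prodromal=0),
}

#: fraction of subjects flagged as related to another participant
RELATED_FRACTION = 0.1


@dataclass
class EffectSpec:
    """A planted cluster-shaped group effect.

    ``effect_size`` is Cohen's d relative to the vertex-level smooth-noise
    standard deviation of the target feature; ``sign`` gives the direction of
    the case-minus-control difference.  ``age_interaction_slope`` adds a
    per-year change in the group difference (an age-by-group interaction)
    inside the cluster.
    """

    feature: str  # "CT" | "SA"
    seed_vertex: int
    radius_hops: int
    effect_size: float = 1.5
    sign: int = +1
    age_interaction_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.feature not in ("CT", "SA"):
            raise ValueError(f"feature must be CT or SA, got {self.feature!r}")
        if self.radius_hops < 0:
            raise ValueError("radius_hops must be >= 0")
        if self.sign not in (-1, +1):
            raise ValueError("sign must be -1 or +1")


@dataclass
class SyntheticTruth:
    """Ground truth of the generator: signed effect masks and planted shifts."""

    ct_effect_mask: np.ndarray  # (V,) in {-1, 0, +1}
    sa_effect_mask: np.ndarray
    parameters: dict = field(default_factory=dict)


def generate_cohort(n_case: int = 62, n_control: int = 57,
                    age_range: tuple[float, float] | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Generate a cohort table with the default study marginals.

    Ages are truncated-normal within each group's range; IQ, total SA, mean
    CT and total grey volume are truncated normal with the documented group
    means and sds.  Sex and site are balanced; relatedness is a sparse flag;
    a prodromal-psychosis flag is set for a small case subgroup.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("case", n_case), ("control", n_control)):
        d = COHORT_DEFAULTS[group]
        lo, hi = age_range if age_range is not None else d["age_range"]
        age = _truncnorm(rng, d["age_mean"], d["age_sd"], lo, hi, n)
        iq = _truncnorm(rng, d["iq_mean"], d["iq_sd"], *d["iq_range"], n)
        tsa = _truncnorm(rng, d["total_sa_mean"], d["total_sa_sd"],
                         d["total_sa_mean"] - 3.5 * d["total_sa_sd"],
                         d["total_sa_mean"] + 3.5 * d["total_sa_sd"], n)
        mct = _truncnorm(rng, d["mean_ct_mean"], d["mean_ct_sd"],
                         d["mean_ct_mean"] - 3 * d["mean_ct_sd"],
                         d["mean_ct_mean"] + 3 * d["mean_ct_sd"], n)
        tcv = _truncnorm(rng, d["total_cv_mean"], d["total_cv_sd"],
                         0.41, 0.89, n)
        n_male = round(n * d["n_male"] / d["n"])
        sex = np.array(["M"] * n_male + ["F"] * (n - n_male))
        site = np.array(["A", "B"] * (n // 2 + 1))[:n]
        related = rng.random(n) < RELATED_FRACTION
        prodromal = np.full(n, "n/a", dtype=object)
        if group == "case":
            n_pro = min(d["n_prodromal"], n)
            flags = np.array(["yes"] * n_pro + ["no"] * (n - n_pro))
            prodromal = rng.permutation(flags)
        for i in range(n):
            rows.append(dict(
                subject_id=f"{group[:4]}{i:03d}", group=group,
                age=age[i], sex=sex[i], site=site[i], iq=iq[i],
                related="yes" if related[i] else "no",
                total_sa=tsa[i], mean_ct=mct[i], total_cv=tcv[i],
                psychosis_prodromal=prodromal[i],
            ))
    return pd.DataFrame(rows)


def _truncnorm(rng, mean, sd, lo, hi, n):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# per-vertex measures


def hop_ball(mesh: Mesh, seed_vertex: int, radius_hops: int,
             adjacency: sp.csr_matrix | None = None) -> np.ndarray:
    """Boolean mask of vertices within ``radius_hops`` edges of the seed."""
    A = build_adjacency(mesh) if adjacency is None else adjacency
    if not 0 <= seed_vertex < mesh.n_vertices:
        raise IndexError(f"seed_vertex {seed_vertex} out of range")
    dist = dijkstra(A, directed=False, indices=seed_vertex,
                    unweighted=True, limit=radius_hops)
    return np.isfinite(dist)


def generate_measures(mesh: Mesh, cohort: pd.DataFrame,
                      effects: list[EffectSpec] | None = None,
                      noise_fwhm_mm: float = 10.0, seed: int = 0,
                      ct_noise_sd: float = 0.20, sa_rel_noise_sd: float = 0.10,
                      cv_lognoise_sd: float = 0.05,
                      ct_age_lin: float = -0.015, ct_age_quad: float = 0.0006,
                      sa_age_lin: float = 0.004, sa_age_quad: float = -0.0004,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, SyntheticTruth]:
    """Generate (n_subjects, V) CT, SA and CV matrices plus ground truth.

    Noise fields are drawn iid per vertex, smoothed on the surface at
    ``noise_fwhm_mm``, and rescaled so their marginal sd equals the requested
    noise sd — planted effect sizes are therefore in honest d units.  Age
    trends use age centered on the cohort mean; CT declines roughly linearly
    through adolescence with a shallow quadratic, SA rises then falls.
    """
    if cohort.empty:
        raise ValueError("cohort must be non-empty")
    effects = effects or []
    V = mesh.n_vertices
    n = len(cohort)
    for e in effects:
        if not 0 <= e.seed_vertex < V:
            raise IndexError(f"effect seed_vertex {e.seed_vertex} out of range")
    rng = np.random.default_rng(seed)
    adjacency = build_adjacency(mesh)
    smoother = SurfaceSmoother(mesh, noise_fwhm_mm) if noise_fwhm_mm > 0 else None

    def smooth_noise(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros((n, V))
        x = rng.standard_normal((n, V))
        if smoother is not None:
            x = smoother.apply(x)
            s = x.std()
            if s > 0:
                x /= s
        return sd * x

    age_c = cohort["age"].to_numpy() - cohort["age"].to_numpy().mean()
    grp = (cohort["group"] == "case").to_numpy().astype(float)

    masks = {"CT": np.zeros(V, dtype=np.int8), "SA": np.zeros(V, dtype=np.int8)}
    shift = {"CT": np.zeros((n, V)), "SA": np.zeros((n, V))}
    sa_template = mesh.vertex_areas()
    sa_scale = cohort["total_sa"].to_numpy() * 1e6 / mesh.total_area()
    noise_scale = {"CT": ct_noise_sd, "SA": sa_rel_noise_sd}
    for e in effects:
        ball = hop_ball(mesh, e.seed_vertex, e.radius_hops, adjacency)
        masks[e.feature][ball] = e.sign
        delta = e.sign * e.effect_size * noise_scale[e.feature]
        per_subj = grp * delta + grp * e.age_interaction_slope * age_c
        shift[e.feature][:, ball] += per_subj[:, None]

    ct = (cohort["mean_ct"].to_numpy()[:, None]
          + (ct_age_lin * age_c + ct_age_quad * age_c**2)[:, None]
          + shift["CT"] + smooth_noise(ct_noise_sd))
    ct = np.clip(ct, 0.5, None)  # physical floor, mm

    rel = (1.0 + (sa_age_lin * age_c + sa_age_quad * age_c**2)[:, None]
           + shift["SA"] + smooth_noise(sa_rel_noise_sd))
    sa = sa_template[None, :] * sa_scale[:, None] * np.clip(rel, 0.05, None)

    cv = ct * sa
    if cv_lognoise_sd > 0:
        cv = cv * np.exp(smooth_noise(cv_lognoise_sd))

    truth = SyntheticTruth(
        ct_effect_mask=masks["CT"], sa_effect_mask=masks["SA"],
        parameters=dict(
            ct_shift_mm={e.seed_vertex: e.sign * e.effect_size * ct_noise_sd
                         for e in effects if e.feature == "CT"},
            sa_rel_shift={e.seed_vertex: e.sign * e.effect_size * sa_rel_noise_sd
                          for e in effects if e.feature == "SA"},
            noise_fwhm_mm=noise_fwhm_mm, ct_noise_sd=ct_noise_sd,
            sa_rel_noise_sd=sa_rel_noise_sd,
        ),
    )
    return ct, sa, cv, truth


# ---------------------------------------------------------------------------
# overlap scenario builder


def plant_overlap_scenario(mesh: Mesh, overlap_fraction: float, seed: int = 0,
                           radius_hops: int = 6, effect_size: float = 1.5,
                           ) -> list[EffectSpec]:
    """CT(+) and SA(-) effect specs whose hop-ball masks overlap in the
    requested fraction of their union.

    The CT ball is centred on a seeded random vertex; the SA centre is chosen
    by scanning candidate vertices for the ball (same radius) whose
    Jaccard overlap with the CT ball is closest to the target.  On a
    homogeneous mesh the achievable fractions form a fine ladder, so the
    result is within about one adjacency ring of the request.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    A = build_adjacency(mesh)
    ct_seed = int(rng.integers(mesh.n_vertices))
    ct_ball = hop_ball(mesh, ct_seed, radius_hops, A)

    if overlap_fraction == 1.0:
        sa_seed = ct_seed
    else:
        dist = dijkstra(A, directed=False, indices=ct_seed, unweighted=True)
        if overlap_fraction == 0.0:
            cands = np.flatnonzero(dist > 2 * radius_hops + 1)
            if cands.size == 0:
                raise ValueError(
                    "mesh too small for disjoint balls at this radius; "
                    "use a smaller radius_hops or a finer mesh"
                )
            sa_seed = int(cands[np.argmax(dist[cands])])
        else:
            best, best_err = ct_seed, np.inf
            cands = np.flatnonzero(dist <= 2 * radius_hops + 2)
            for c in cands:
                ball = hop_ball(mesh, int(c), radius_hops, A)
                inter = int((ball & ct_ball).sum())
                union = int((ball | ct_ball).sum())
                err = abs(inter / union - overlap_fraction)
                if err < best_err:
                    best, best_err = int(c), err
            sa_seed = best
            ball = hop_ball(mesh, sa_seed, radius_hops, A)
            achieved = (ball & ct_ball).sum() / (ball | ct_ball).sum()
            # a one-ring change moves the fraction by about ring/ball size
            ring = (hop_ball(mesh, ct_seed, radius_hops + 1, A).sum()
                    - ct_ball.sum())
            tol = ring / ct_ball.sum()
            if abs(achieved - overlap_fraction) > tol:
                raise ValueError(
                    f"requested overlap {overlap_fraction:.2f} unreachable at "
                    f"radius {radius_hops} (closest {achieved:.2f}); "
                    "try a larger radius_hops"
                )
    return [
        EffectSpec("CT", ct_seed, radius_hops, effect_size, +1),
        EffectSpec("SA", sa_seed, radius_hops, effect_size, -1),
    ]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age", "sex", "site", "iq", "related",
                "total_sa"}
    missing = required - set(df.columns)
    if missing:
        raise ShapeError(f"cohort table missing columns: {sorted(missing)}")
    return df
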