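"""Spatial overlap of CT and SA differences, and the decomposition of CV
differences into CT-driven, SA-driven, joint, and unexplained components.

Given cluster-corrected signed significance masks for cortical thickness
(CT), surface area (SA) and cortical volume (CV), every significantly
different vertex is classified — regardless of the sign of the difference —
as CT-only, SA-only, or both, with percentages taken over the union of
significant vertices.  A goodness-of-fit chi-square tests whether the three
categories are equally distributed, and a simulation null asks how much
overlap two spatially independent difference maps would produce by chance.

CV-significant vertices are split by direction (case below vs above control)
and attributed to a co-occurring CT difference, SA difference, both, or
neither ("unexplained", i.e. sub-threshold contributions of each).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ShapeError

OVERLAP_CATEGORIES = ("ct_only", "sa_only", "ct_and_sa")
DECOMP_CATEGORIES = ("ct_only", "sa_only", "ct_and_sa")


def round_pct(count: int, total: int, decimals: int = 2) -> float:
    """Percentage 100*count/total rounded half-up to ``decimals`` places."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
            q, rounding=ROUND_HALF_UP)
    )


def _as_mask(m) -> np.ndarray:
    values = getattr(m, "values", m)
    return np.asarray(values).ravel()


# ---------------------------------------------------------------------------
# overlap classification (Table-2 style)


@dataclass
class OverlapTable:
    """Counts and percentages of CT-only / SA-only / overlapping vertices."""

    counts: pd.DataFrame       # rows: categories + total; cols: hemispheres
    percentages: pd.DataFrame  # same layout, half-up 2-decimal percentages
    threshold_label: str = ""


def classify_overlap_counts(ct_mask, sa_mask) -> dict[str, int]:
    """Per-vertex tally of unique and overlapping differences, sign ignored."""
    ct = _as_mask(ct_mask)
    sa = _as_mask(sa_mask)
    if ct.size != sa.size:
        raise ShapeError(f"mask lengths differ: {ct.size} vs {sa.size}")
    ct_sig = ct != 0
    sa_sig = sa != 0
    both = int((ct_sig & sa_sig).sum())
    ct_only = int((ct_sig & ~sa_sig).sum())
    sa_only = int((sa_sig & ~ct_sig).sum())
    return dict(ct_only=ct_only, sa_only=sa_only, ct_and_sa=both,
                total=ct_only + sa_only + both)


def classify_overlap(ct_masks, sa_masks, threshold_label: str = "",
                     hemispheres: tuple[str, ...] | None = None,
                     ) -> OverlapTable:
    """Build an overlap table from per-hemisphere CT and SA masks.

    ``ct_masks``/``sa_masks`` may be single masks or dicts keyed by
    hemisphere; a combined across-hemispheres column is always added.
    Percentages are relative to each column's union of significant vertices.
    """
    if not isinstance(ct_masks, dict):
        ct_masks = {"left": ct_masks}
        sa_masks = {"left": sa_masks}
    hemis = list(hemispheres or ct_masks.keys())
    per_hemi = {h: classify_overlap_counts(ct_masks[h], sa_masks[h])
                for h in hemis}
    combined = {k: sum(per_hemi[h][k] for h in hemis)
                for k in (*OVERLAP_CATEGORIES, "total")}
    cols = {**per_hemi, "combined": combined}
    counts = pd.DataFrame(cols).reindex([*OVERLAP_CATEGORIES, "total"])
    pct = counts.copy().astype(float)
    for c in counts.columns:
        tot = counts.loc["total", c]
        for r in counts.index:
            pct.loc[r, c] = round_pct(int(counts.loc[r, c]), int(tot))
    return OverlapTable(counts, pct, threshold_label)


# ---------------------------------------------------------------------------
# chi-square on category counts


def chi2_equal_distribution(counts) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square against equal expected counts.

    Returns (statistic, df, p) with df = k - 1.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if c.size < 2 or (c < 0).any():
        raise ValueError("need >= 2 non-negative counts")
    if c.sum() == 0:
        raise ValueError("all-zero counts: chi-square undefined")
    stat, p = stats.chisquare(c)
    return float(stat), c.size - 1, float(p)


# ---------------------------------------------------------------------------
# simulation null for the overlap percentage


@dataclass
class NullOverlapResult:
    n_sims: int
    alpha: float
    observed_overlap_pct: float
    null_overlap_pcts: np.ndarray
    p_value: float
    mean_null_pct: float


def expected_null_overlap_pct(alpha: float) -> float:
    """Large-field limit of the null overlap %: 100 * a^2 / (2a - a^2)."""
    return 100.0 * alpha**2 / (2 * alpha - alpha**2)


def simulate_overlap_null(n_vertices: int, alpha: float = 0.05,
                          n_sims: int = 5000, seed: int = 0,
                          observed_overlap_pct: float | None = None,
                          ) -> NullOverlapResult:
    """Null distribution of the overlap % between two independent maps.

    Each simulation draws two independent iid statistic maps and thresholds
    them two-tailed at ``alpha``; a vertex is then significant in either map
    independently with probability exactly ``alpha``, so the four joint
    significance categories are drawn directly as a multinomial — the
    distribution of the overlap percentage is identical to thresholding
    explicit random t maps.  The overlap % is 100*|both|/|either|; the
    empirical p uses the add-one estimator (1 + #{null >= obs}) / (n_sims+1),
    so it is never zero.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if observed_overlap_pct is not None and not \
            0.0 <= observed_overlap_pct <= 100.0:
        raise ValueError("observed_overlap_pct must be in [0, 100]")
    rng = np.random.default_rng(seed)
    p_joint = np.array([alpha * alpha, alpha * (1 - alpha),
                        (1 - alpha) * alpha, (1 - alpha)**2])
    draws = rng.multinomial(n_vertices, p_joint, size=n_sims)
    both = draws[:, 0].astype(float)
    either = draws[:, :3].sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pcts = np.where(either > 0, 100.0 * both / either,
                        100.0 if alpha == 1.0 else 0.0)
    obs = pcts.mean() if observed_overlap_pct is None else observed_overlap_pct
    p = (1 + int((pcts >= obs).sum())) / (n_sims + 1)
    return NullOverlapResult(n_sims, alpha, float(obs), pcts, float(p),
                             float(pcts.mean()))


# ---------------------------------------------------------------------------
# CV decomposition (Table-3 style)


DECOMP_ROWS = ("cv_total", "ct_only", "sa_only", "ct_and_sa",
               "cv_explained", "cv_unexplained")


@dataclass
class DecompositionTable:
    """Attribution of CV-significant vertices to CT/SA differences,
    split by the direction of the CV difference."""

    counts: dict[str, pd.DataFrame]       # keyed by "decrease" / "increase"
    percentages: dict[str, pd.DataFrame]
    threshold_label: str = ""


def decompose_cv_counts(cv_mask, ct_mask, sa_mask,
                        direction: int) -> dict[str, int]:
    """Counts for one CV direction (-1: case < control, +1: case > control).

    Membership of the CT/SA masks ignores their sign; a CV vertex with
    neither is unexplained.
    """
    cv = _as_mask(cv_mask)
    ct = _as_mask(ct_mask)
    sa = _as_mask(sa_mask)
    if not (cv.size == ct.size == sa.size):
        raise ShapeError("mask lengths differ")
    sel = cv == direction
    ct_sig = ct != 0
    sa_sig = sa != 0
    ct_only = int((sel & ct_sig & ~sa_sig).sum())
    sa_only = int((sel & sa_sig & ~ct_sig).sum())
    both = int((sel & ct_sig & sa_sig).sum())
    total = int(sel.sum())
    explained = ct_only + sa_only + both
    return dict(cv_total=total, ct_only=ct_only, sa_only=sa_only,
                ct_and_sa=both, cv_explained=explained,
                cv_unexplained=total - explained)


def decompose_cv(cv_masks, ct_masks, sa_masks, threshold_label: str = "",
                 hemispheres: tuple[str, ...] | None = None,
                 ) -> DecompositionTable:
    """Build the CV decomposition table from per-hemisphere signed masks."""
    if not isinstance(cv_masks, dict):
        cv_masks = {"left": cv_masks}
        ct_masks = {"left": ct_masks}
        sa_masks = {"left": sa_masks}
    hemis = list(hemispheres or cv_masks.keys())
    counts: dict[str, pd.DataFrame] = {}
    pcts: dict[str, pd.DataFrame] = {}
    for label, direction in (("decrease", -1), ("increase", +1)):
        per_hemi = {h: decompose_cv_counts(cv_masks[h], ct_masks[h],
                                           sa_masks[h], direction)
                    for h in hemis}
        combined = {k: sum(per_hemi[h][k] for h in hemis) for k in DECOMP_ROWS}
        frame = pd.DataFrame({**per_hemi, "combined": combined}).reindex(
            list(DECOMP_ROWS))
        pct = frame.copy().astype(float)
        for c in frame.columns:
            tot = int(frame.loc["cv_total", c])
            for r in frame.index:
                pct.loc[r, c] = round_pct(int(frame.loc[r, c]), tot)
        counts[label] = frame
        pcts[label] = pct
    return DecompositionTable(counts, pcts, threshold_label)


# ---------------------------------------------------------------------------
# rendering


def _block_text(counts: pd.DataFrame, pcts: pd.DataFrame, title: str) -> str:
    lines = [title]
    cols = list(counts.columns)
    header = f"{'measure':<16}" + "".join(f"{c:>22}" for c in cols)
    lines.append(header)
    for r in counts.index:
        cells = []
        for c in cols:
            n = int(counts.loc[r, c])
            p = pcts.loc[r, c]
            cells.append(f"{n:,}({p:g})" if n or p else "0(0)")
        lines.append(f"{r:<16}" + "".join(f"{s:>22}" for s in cells))
    return "\n".join(lines)


def render_tables(overlap_tables: dict[str, OverlapTable] | None = None,
                  decomp_tables: dict[str, DecompositionTable] | None = None,
                  ) -> str:
    """Aligned-text report with one block per cluster-significance
    threshold, mirroring the published table layout."""
    if not overlap_tables and not decomp_tables:
        raise ValueError("at least one table required")
    parts: list[str] = []
    for label, tab in (overlap_tables or {}).items():
        parts.append(_block_text(
            tab.counts, tab.percentages,
            f"Spatial overlap of CT and SA differences [{label}]"))
    for label, tab in (decomp_tables or {}).items():
        for direction in ("decrease", "increase"):
            parts.append(_block_text(
                tab.counts[direction], tab.percentages[direction],
                f"CV {direction} decomposition [{label}]"))
    return "\n\n".join(parts) + "\n"


def overlap_to_csv(tab: OverlapTable) -> pd.DataFrame:
    """Long-form counts+percentages frame suitable for CSV export."""
    rows = []
    for r in tab.counts.index:
        for c in tab.counts.columns:
            rows.append(dict(threshold=tab.threshold_label, category=r,
                             hemisphere=c, count=int(tab.counts.loc[r, c]),
                             pct=float(tab.percentages.loc[r, c])))
    return pd.DataFrame(rows)


def decomposition_to_csv(tab: DecompositionTable) -> pd.DataFrame:
    rows = []
    for direction, frame in tab.counts.items():
        for r in frame.index:
            for c in frame.columns:
                rows.append(dict(
                    threshold=tab.threshold_label, direction=direction,
                    category=r, hemisphere=c, count=int(frame.loc[r, c]),
                    pct=float(tab.percentages[direction].loc[r, c])))
    return pd.DataFrame(rows)
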