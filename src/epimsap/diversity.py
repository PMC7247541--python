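"""Per-group, per-panel descriptive diversity statistics.

All operations consume a binary epilocus matrix (the expanded, scorable
view produced by :meth:`epimsap.scoring.EpilocusMatrix.expanded`) together
with per-sample group labels, and summarize marker polymorphism, private
markers and Shannon diversity per combined group and epilocus panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import PANEL_NAMES, PANEL_SUFFIXES, panel_types

__all__ = [
    "polymorphic_markers",
    "private_markers",
    "shannon_index",
    "weighted_mean_shannon",
    "per_individual_polymorphic_counts",
    "chi_square_gof",
    "percent",
    "diversity_table",
]


def _as_matrix(binary) -> np.ndarray:
    x = np.asarray(binary, dtype=float)
    if x.ndim != 2:
        raise ValueError("binary matrix must be 2-D (samples x epiloci)")
    return x


def percent(numerator: float, denominator: float, ndigits: int | None = None):
    """``100 * numerator / denominator``, optionally rounded.

    ``ndigits=0`` rounds to the nearest integer percent and returns an int.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = 100.0 * numerator / denominator
    if ndigits is None:
        return value
    if ndigits == 0:
        return int(round(value))
    return round(value, ndigits)


def polymorphic_markers(binary) -> np.ndarray:
    """Column indices whose presence frequency is strictly inside (0, 1).

    The submatrix is expected to contain the individuals of a single
    group; a marker is polymorphic in the group iff it is neither absent
    from nor fixed in every individual.
    """
    x = _as_matrix(binary)
    if x.shape[0] == 0:
        raise ValueError("cannot assess polymorphism of an empty group")
    freq = x.mean(axis=0)
    return np.flatnonzero((freq > 0.0) & (freq < 1.0))


def private_markers(binary, groups, group) -> np.ndarray:
    """Column indices of markers present only in ``group``.

    A marker is private to a group iff at least one of its individuals
    shows presence while every individual of every other group shows
    absence.
    """
    x = _as_matrix(binary)
    groups = np.asarray(groups)
    if np.unique(groups).size < 2:
        raise ValueError("private markers need at least two groups")
    inside = x[groups == group]
    outside = x[groups != group]
    return np.flatnonzero((inside.sum(axis=0) > 0) & (outside.sum(axis=0) == 0))


def shannon_index(binary) -> tuple[np.ndarray, float]:
    """Per-locus Shannon index H and its mean over all loci of the panel.

    For presence frequency ``p``: ``H = -p ln p - (1-p) ln(1-p)`` with
    ``0 ln 0 := 0``.  Monomorphic loci contribute ``H = 0`` to the mean.
    """
    x = _as_matrix(binary)
    p = x.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(p * np.log(p)) - ((1 - p) * np.log(1 - p))
    h = np.nan_to_num(h, nan=0.0)
    return h, float(h.mean()) if h.size else 0.0


def weighted_mean_shannon(values, weights) -> float:
    """Panel-size-weighted mean of per-panel Shannon values.

    ``sum(w_k * H_k) / sum(w_k)`` — the convention behind a single
    "mean Shannon diversity" figure quoted per group.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must align")
    if weights.sum() <= 0:
        raise ValueError("weights must sum to a positive number")
    return float((values * weights).sum() / weights.sum())


def per_individual_polymorphic_counts(binary, groups) -> pd.Series:
    """Per individual: presences at epiloci polymorphic within its group."""
    if isinstance(binary, pd.DataFrame):
        index = binary.index
    else:
        index = pd.RangeIndex(np.asarray(binary).shape[0])
    x = _as_matrix(binary)
    groups = np.asarray(groups)
    counts = np.zeros(x.shape[0], dtype=int)
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        poly = polymorphic_markers(x[members])
        counts[members] = x[np.ix_(members, poly)].sum(axis=1).astype(int)
    return pd.Series(counts, index=index, name="n_polymorphic_present")


def chi_square_gof(observed, expected_proportions) -> tuple[float, int, float]:
    """Pearson goodness-of-fit test against expected category proportions.

    Returns ``(chi2, df, p)`` with ``df = k - 1``.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected proportions must align")
    if (obs < 0).any():
        raise ValueError("observed counts must be nonnegative")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    expected = props * obs.sum()
    if (expected == 0).any():
        raise ValueError("zero expected count in some category")
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return float(chi2), obs.size - 1, float(p)


def diversity_table(binary: pd.DataFrame, groups, types=None) -> pd.DataFrame:
    """Group x panel summary: totals, polymorphic, private, Shannon.

    One row per group and epilocus panel plus a ``combined`` row per group
    whose Shannon value is the panel-size-weighted mean.  Private counts
    are restricted to polymorphic markers, and private percentages are
    relative to the polymorphic count.
    """
    if types is None:
        types = panel_types(binary.columns)
    types = np.asarray(types)
    x = _as_matrix(binary)
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        members = np.flatnonzero(groups == g)
        panel_shannon, panel_n = [], []
        for suf in PANEL_SUFFIXES:
            cols = np.flatnonzero(types == suf)
            sub = x[np.ix_(members, cols)]
            poly_local = polymorphic_markers(sub)
            poly = cols[poly_local]
            priv = private_markers(x[:, cols], groups, g)
            priv_poly = np.intersect1d(cols[priv], poly)
            _, h_mean = shannon_index(sub)
            n_total = cols.size
            n_poly = poly.size
            rows.append(
                {
                    "group": g,
                    "panel": PANEL_NAMES[suf],
                    "n_markers": n_total,
                    "n_polymorphic": n_poly,
                    "pct_polymorphic": percent(n_poly, n_total) if n_total else 0.0,
                    "n_private": priv_poly.size,
                    "pct_private": (
                        percent(priv_poly.size, n_poly) if n_poly else 0.0
                    ),
                    "shannon_mean": h_mean,
                }
            )
            panel_shannon.append(h_mean)
            panel_n.append(n_total)
        rows.append(
            {
                "group": g,
                "panel": "combined",
                "n_markers": int(sum(panel_n)),
                "n_polymorphic": int(
                    sum(r["n_polymorphic"] for r in rows[-3:])
                ),
                "pct_polymorphic": percent(
                    sum(r["n_polymorphic"] for r in rows[-3:]), sum(panel_n)
                ),
                "n_private": int(sum(r["n_private"] for r in rows[-3:])),
                "pct_private": np.nan,
                "shannon_mean": weighted_mean_shannon(panel_shannon, panel_n),
            }
        )
    return pd.DataFrame(rows)
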