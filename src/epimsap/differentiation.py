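"""Group differentiation: ANOVA, AMOVA with permutation Phi-statistics, NMDS.

The AMOVA implementation follows the classic sums-of-squared-deviations
decomposition of pairwise distances.  For binary epilocus data the squared
distance between two individuals is their mismatch count (squared
Euclidean distance on 0/1 band patterns), which makes the per-locus
closed forms used for permutation testing exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "AmovaResult",
    "OrdinationResult",
    "one_factor_anova",
    "panel_presence_response",
    "pairwise_group_anova",
    "arcsine_transform",
    "pairwise_sq_distances",
    "jaccard_distances",
    "amova_phist",
    "hierarchical_amova",
    "locus_by_locus_amova",
    "nmds",
]


@dataclass
class AnovaResult:
    """One-factor ANOVA summary."""

    factor: str
    f: float
    df_between: int
    df_within: int
    p: float


@dataclass
class AmovaResult:
    """AMOVA decomposition with Phi-statistics and permutation p-values.

    ``table`` has one row per stratum with columns SSD, MSD, df, sigma2
    and variance coefficient (% of total); ``phi`` and ``p_values`` are
    keyed by statistic name (``phi_st``; plus ``phi_ct``/``phi_sc`` for
    hierarchical runs).
    """

    table: pd.DataFrame
    phi: dict
    p_values: dict
    n_permutations: int
    negative_components: bool = False
    undefined: bool = False
    notes: list = field(default_factory=list)


@dataclass
class OrdinationResult:
    """Low-dimensional NMDS embedding."""

    coordinates: pd.DataFrame
    stress: float
    metric: str


# --------------------------------------------------------------------- ANOVA


def one_factor_anova(response, labels, factor: str = "factor") -> AnovaResult:
    """Classical one-factor between/within variance decomposition."""
    y = np.asarray(response, dtype=float)
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if levels.size < 2:
        raise ValueError("one_factor_anova needs at least two factor levels")
    n = y.size
    grand = y.mean()
    ss_between = 0.0
    ss_within = 0.0
    for lv in levels:
        yg = y[labels == lv]
        if yg.size < 2:
            raise ValueError(f"level {lv!r} has fewer than two observations")
        ss_between += yg.size * (yg.mean() - grand) ** 2
        ss_within += ((yg - yg.mean()) ** 2).sum()
    df_b = levels.size - 1
    df_w = n - levels.size
    msb = ss_between / df_b
    msw = ss_within / df_w
    if msw == 0.0:
        f = np.inf if msb > 0 else 0.0
        p = 0.0 if msb > 0 else 1.0
    else:
        f = msb / msw
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(factor=factor, f=float(f), df_between=df_b,
                       df_within=df_w, p=p)


def panel_presence_response(binary, types) -> pd.DataFrame:
    """Stack per-sample presence counts per epilocus panel.

    The default ANOVA response: every sample contributes one observation
    per panel (its number of presences in that panel), so a study with
    three panels yields ``3 * n_samples`` stacked observations.
    """
    x = np.asarray(binary, dtype=float)
    types = np.asarray(types)
    if isinstance(binary, pd.DataFrame):
        sample_ids = list(binary.index)
    else:
        sample_ids = list(range(x.shape[0]))
    rows = []
    for suf in pd.unique(types):
        cols = np.flatnonzero(types == suf)
        counts = x[:, cols].sum(axis=1)
        for sid, c in zip(sample_ids, counts):
            rows.append({"sample_id": sid, "panel": suf, "count": float(c)})
    return pd.DataFrame(rows)


def arcsine_transform(percentages) -> np.ndarray:
    """Arcsine-square-root transform of percentage data (0-100 scale)."""
    p = np.asarray(percentages, dtype=float) / 100.0
    if ((p < 0) | (p > 1)).any():
        raise ValueError("percentages must lie in [0, 100]")
    return np.arcsin(np.sqrt(p))


def pairwise_group_anova(
    response,
    labels,
    pairs: list | None = None,
    adjust: str = "holm",
) -> pd.DataFrame:
    """All pairwise group contrasts with family-wise p adjustment.

    Each contrast is a pooled-variance two-sample comparison reported as
    estimate (difference of means), standard error, t, raw p, and p
    adjusted over the whole comparison family (``holm`` by default;
    ``bonferroni`` and ``fdr_bh`` also accepted).
    """
    y = np.asarray(response, dtype=float)
    labels = np.asarray(labels)
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if pairs is None:
        pairs = [
            (levels[i], levels[j])
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
    rows = []
    for a, b in pairs:
        ya, yb = y[labels == a], y[labels == b]
        na, nb = ya.size, yb.size
        est = ya.mean() - yb.mean()
        df = na + nb - 2
        sp2 = (
            ((na - 1) * ya.var(ddof=1) + (nb - 1) * yb.var(ddof=1)) / df
            if df > 0
            else 0.0
        )
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        if se == 0.0:
            t = 0.0 if est == 0.0 else np.inf * np.sign(est)
            p = 1.0 if est == 0.0 else 0.0
        else:
            t = est / se
            p = float(2 * stats.t.sf(abs(t), df))
        rows.append(
            {"group1": a, "group2": b, "estimate": est, "se": se,
             "t": t, "df": df, "p": p}
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"], method=adjust)[1]
    out.attrs["adjust_method"] = adjust
    return out


# --------------------------------------------------------------------- AMOVA


def pairwise_sq_distances(binary) -> np.ndarray:
    """Pairwise mismatch counts (squared Euclidean on binary patterns)."""
    x = np.asarray(binary, dtype=float)
    return squareform(pdist(x, metric="sqeuclidean"))


def jaccard_distances(binary) -> np.ndarray:
    """Pairwise Jaccard distances on presence/absence patterns."""
    x = np.asarray(binary, dtype=bool)
    return squareform(pdist(x, metric="jaccard"))


def _pair_sum(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared distances over unordered pairs within ``idx``."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum()) / 2.0


def _ss_parts_binary(x: np.ndarray, member_idx: list) -> tuple[float, float]:
    """(SS_total, SS_within) for binary data via per-group presence counts.

    Exact closed form of the distance-based sums of squares: for a locus
    with ``c`` presences among ``m`` individuals, the within-group pair
    sum of squared distances is ``c * (m - c)``.
    """
    n = x.shape[0]
    tot = x.sum(axis=0)
    ss_total = float((tot * (n - tot)).sum()) / n
    ss_within = 0.0
    for idx in member_idx:
        c = x[idx].sum(axis=0)
        m = idx.size
        ss_within += float((c * (m - c)).sum()) / m
    return ss_total, ss_within


def _one_level_components(
    ss_total: float, ss_within: float, sizes: np.ndarray
) -> tuple[float, float, float]:
    """(sigma2_among, sigma2_within, phi_st) of a one-level AMOVA."""
    n = int(sizes.sum())
    g = sizes.size
    ss_among = ss_total - ss_within
    df_a, df_w = g - 1, n - g
    ms_a = ss_among / df_a
    ms_w = ss_within / df_w if df_w > 0 else 0.0
    n0 = (n - (sizes**2).sum() / n) / df_a
    sigma_a = (ms_a - ms_w) / n0
    sigma_w = ms_w
    total = sigma_a + sigma_w
    phi = sigma_a / total if total > 0 else np.nan
    return sigma_a, sigma_w, phi


def amova_phist(
    binary,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """One-level AMOVA on binary epilocus data with permutation Phi_ST.

    Phi_ST is the among-group fraction of the total molecular variance;
    its permutation p-value comes from random relabelings of individuals
    (one-sided, ``(1 + #{phi_perm >= phi_obs}) / (1 + n_perm)``).
    """
    import warnings as _warnings

    if n_perm < 100:
        _warnings.warn(
            f"n_perm={n_perm} gives a coarse permutation p-value", UserWarning
        )
    x = np.asarray(binary, dtype=np.float64)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("AMOVA needs at least two groups")
    member_idx = [np.flatnonzero(groups == g) for g in levels]
    sizes = np.array([idx.size for idx in member_idx])
    n = x.shape[0]

    ss_total, ss_within = _ss_parts_binary(x, member_idx)
    ss_among = ss_total - ss_within
    df_a, df_w = len(levels) - 1, n - len(levels)

    notes = []
    if ss_total == 0.0:
        table = _amova_table(
            ["Among groups", "Within groups"],
            [0.0, 0.0], [df_a, df_w], [0.0, 0.0],
        )
        return AmovaResult(
            table=table, phi={"phi_st": np.nan}, p_values={"phi_st": np.nan},
            n_permutations=0, undefined=True,
            notes=["all samples identical: Phi_ST undefined"],
        )

    sigma_a, sigma_w, phi = _one_level_components(ss_total, ss_within, sizes)
    if sigma_a < 0:
        notes.append("negative among-group variance component")

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        idx_perm = [perm[idx] for idx in member_idx]
        _, ss_w_p = _ss_parts_binary(x, idx_perm)
        _, _, phi_p = _one_level_components(ss_total, ss_w_p, sizes)
        if phi_p >= phi:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)

    table = _amova_table(
        ["Among groups", "Within groups"],
        [ss_among, ss_within],
        [df_a, df_w],
        [sigma_a, sigma_w],
    )
    return AmovaResult(
        table=table,
        phi={"phi_st": float(phi)},
        p_values={"phi_st": float(p)},
        n_permutations=n_perm,
        negative_components=sigma_a < 0,
        notes=notes,
    )


def _amova_table(strata, ssd, df, sigma2) -> pd.DataFrame:
    ssd = list(map(float, ssd))
    df = list(map(int, df))
    sigma2 = list(map(float, sigma2))
    msd = [s / d if d > 0 else np.nan for s, d in zip(ssd, df)]
    sig_total = sum(sigma2)
    pct = [
        100.0 * s / sig_total if sig_total > 0 else np.nan for s in sigma2
    ]
    rows = []
    for i, name in enumerate(strata):
        rows.append(
            {"stratum": name, "SSD": ssd[i], "MSD": msd[i], "df": df[i],
             "variance_coefficient_pct": pct[i], "sigma2": sigma2[i]}
        )
    total_ssd = sum(ssd)
    total_df = sum(df)
    rows.append(
        {"stratum": "Total", "SSD": total_ssd,
         "MSD": total_ssd / total_df if total_df else np.nan,
         "df": total_df, "variance_coefficient_pct": 100.0 if sig_total > 0 else np.nan,
         "sigma2": sig_total}
    )
    return pd.DataFrame(rows)


def _nested_components(x, level1, level2):
    """Variance components of the two-level nested decomposition."""
    lab1 = np.asarray(level1)
    sub = np.asarray(
        [f"{a}\x1f{b}" for a, b in zip(level1, np.asarray(level2))]
    )
    g_levels = list(pd.unique(lab1))
    s_levels = list(pd.unique(sub))
    n = x.shape[0]
    g_idx = [np.flatnonzero(lab1 == g) for g in g_levels]
    s_idx = [np.flatnonzero(sub == s) for s in s_levels]
    s_group = [lab1[idx[0]] for idx in s_idx]
    n_g = np.array([idx.size for idx in g_idx], dtype=float)
    n_s = np.array([idx.size for idx in s_idx], dtype=float)

    ss_total, ss_within_sub = _ss_parts_binary(x, s_idx)
    _, ss_within_grp = _ss_parts_binary(x, g_idx)
    ss_among_groups = ss_total - ss_within_grp
    ss_among_sub = ss_within_grp - ss_within_sub

    G, S = len(g_levels), len(s_levels)
    df_a, df_b, df_w = G - 1, S - G, n - S
    ms_a = ss_among_groups / df_a
    ms_b = ss_among_sub / df_b if df_b > 0 else np.nan
    ms_w = ss_within_sub / df_w if df_w > 0 else 0.0

    sum_ns2_per_g = np.zeros(G)
    for j, g in enumerate(g_levels):
        sel = [k for k, sg in enumerate(s_group) if sg == g]
        sum_ns2_per_g[j] = (n_s[sel] ** 2).sum() / n_g[j]
    n1 = (n - sum_ns2_per_g.sum()) / df_b if df_b > 0 else np.nan
    n2 = (sum_ns2_per_g.sum() - (n_s**2).sum() / n) / df_a
    n3 = (n - (n_g**2).sum() / n) / df_a

    sigma_c = ms_w
    sigma_b = (ms_b - sigma_c) / n1 if df_b > 0 else 0.0
    sigma_a = (ms_a - sigma_c - n2 * sigma_b) / n3
    return {
        "ss": (ss_among_groups, ss_among_sub, ss_within_sub, ss_total),
        "df": (df_a, df_b, df_w),
        "sigma": (sigma_a, sigma_b, sigma_c),
        "groups": (g_levels, g_idx),
        "subpops": (s_levels, s_idx, s_group),
    }


def hierarchical_amova(
    binary,
    level1,
    level2,
    n_perm: int = 999,
    seed: int | None = None,
    level1_name: str = "level1",
    level2_name: str = "level2",
) -> AmovaResult:
    """Two-level nested AMOVA (level2 units nested within level1 strata).

    Permutation scheme: for the top component whole level-2 units are
    reassigned across level-1 strata; for the nested component
    individuals are permuted among level-2 units within their stratum.
    """
    x = np.asarray(binary, dtype=np.float64)
    level1 = np.asarray(level1)
    level2 = np.asarray(level2)
    res = _nested_components(x, level1, level2)
    ss_a, ss_b, ss_w, ss_total = res["ss"]
    df_a, df_b, df_w = res["df"]
    sigma_a, sigma_b, sigma_c = res["sigma"]
    total_sigma = sigma_a + sigma_b + sigma_c
    phi_ct = sigma_a / total_sigma if total_sigma > 0 else np.nan
    phi_sc = (
        sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else np.nan
    )
    phi_st = (
        (sigma_a + sigma_b) / total_sigma if total_sigma > 0 else np.nan
    )

    s_levels, s_idx, s_group = res["subpops"]
    g_levels, _ = res["groups"]
    rng = np.random.default_rng(seed)

    # top level: permute whole subpopulations across level-1 strata
    exceed_ct = 0
    group_counts = [sum(1 for sg in s_group if sg == g) for g in g_levels]
    for _ in range(n_perm):
        order = rng.permutation(len(s_levels))
        new_group = np.empty(len(s_levels), dtype=object)
        pos = 0
        for g, cnt in zip(g_levels, group_counts):
            for k in order[pos:pos + cnt]:
                new_group[k] = g
            pos += cnt
        lab1_p = np.empty(x.shape[0], dtype=object)
        lab2_p = np.empty(x.shape[0], dtype=object)
        for k, idx in enumerate(s_idx):
            lab1_p[idx] = new_group[k]
            lab2_p[idx] = f"sub{k}"  # subpops stay intact as units
        r = _nested_components(x, lab1_p, lab2_p)
        sa, sb, sc = r["sigma"]
        tot = sa + sb + sc
        phi_ct_p = sa / tot if tot > 0 else np.nan
        if not np.isnan(phi_ct_p) and phi_ct_p >= phi_ct:
            exceed_ct += 1
    p_ct = (1.0 + exceed_ct) / (1.0 + n_perm)

    # nested level: permute individuals among subpops within strata
    exceed_sc = 0
    for _ in range(n_perm):
        sub_p = np.array(
            [f"{a}\x1f{b}" for a, b in zip(level1, level2)], dtype=object
        )
        for g in g_levels:
            members = np.flatnonzero(level1 == g)
            sub_p[members] = sub_p[members][rng.permutation(members.size)]
        level2_p = np.array([s.split("\x1f")[1] for s in sub_p])
        r = _nested_components(x, level1, level2_p)
        sa, sb, sc = r["sigma"]
        phi_sc_p = sb / (sb + sc) if (sb + sc) > 0 else np.nan
        if not np.isnan(phi_sc_p) and phi_sc_p >= phi_sc:
            exceed_sc += 1
    p_sc = (1.0 + exceed_sc) / (1.0 + n_perm)

    table = _amova_table(
        [level1_name, f"{level2_name} within {level1_name}", "Error"],
        [ss_a, ss_b, ss_w],
        [df_a, df_b, df_w],
        [sigma_a, sigma_b, sigma_c],
    )
    notes = []
    if sigma_a < 0 or sigma_b < 0:
        notes.append("negative variance component(s) reported as-is")
    return AmovaResult(
        table=table,
        phi={"phi_ct": float(phi_ct), "phi_sc": float(phi_sc),
             "phi_st": float(phi_st)},
        p_values={"phi_ct": float(p_ct), "phi_sc": float(p_sc)},
        n_permutations=n_perm,
        negative_components=(sigma_a < 0 or sigma_b < 0),
        notes=notes,
    )


def locus_by_locus_amova(
    binary,
    groups,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, pd.DataFrame]:
    """Per-locus Phi_ST with permutation p; fraction significant at alpha.

    Monomorphic loci are skipped (flagged in the output) but stay in the
    denominator of the reported fraction, which therefore refers to the
    overall percentage of epiloci.
    """
    x = np.asarray(binary, dtype=np.float64)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    member_idx = [np.flatnonzero(groups == g) for g in levels]
    sizes = np.array([idx.size for idx in member_idx], dtype=float)
    n, L = x.shape
    G = len(levels)
    df_a, df_w = G - 1, n - G
    n0 = (n - (sizes**2).sum() / n) / df_a

    def _phi_per_locus(idx_list) -> np.ndarray:
        tot = x.sum(axis=0)
        ss_total = tot * (n - tot) / n
        ss_within = np.zeros(L)
        for idx in idx_list:
            c = x[idx].sum(axis=0)
            ss_within += c * (idx.size - c) / idx.size
        ms_a = (ss_total - ss_within) / df_a
        ms_w = ss_within / df_w
        sigma_a = (ms_a - ms_w) / n0
        total = sigma_a + ms_w
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, sigma_a / total, np.nan)

    phi_obs = _phi_per_locus(member_idx)
    mono = (x.sum(axis=0) == 0) | (x.sum(axis=0) == n)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(L)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        phi_p = _phi_per_locus([perm[idx] for idx in member_idx])
        exceed += (phi_p >= phi_obs) & ~np.isnan(phi_p)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[mono] = np.nan
    phi_obs = np.where(mono, np.nan, phi_obs)

    if isinstance(binary, pd.DataFrame):
        locus_ids = list(binary.columns)
    else:
        locus_ids = list(range(L))
    out = pd.DataFrame(
        {"locus": locus_ids, "phi_st": phi_obs, "p": p,
         "significant": (p < alpha) & ~mono, "monomorphic": mono}
    )
    fraction = float(out["significant"].sum()) / L
    return fraction, out


# ---------------------------------------------------------------------- NMDS


def nmds(
    binary,
    k: int = 2,
    seed: int | None = None,
    n_restarts: int = 20,
    max_iter: int = 300,
    metric: str = "jaccard",
) -> OrdinationResult:
    """Non-metric MDS embedding of Jaccard distances (SMACOF majorization).

    Runs ``n_restarts`` random initializations and keeps the embedding
    with the lowest normalized stress; deterministic under ``seed``.
    """
    x = np.asarray(binary)
    if x.shape[0] < 3:
        raise ValueError("NMDS needs at least three samples")
    if metric == "jaccard":
        d = jaccard_distances(x)
    elif metric == "mismatch":
        d = pairwise_sq_distances(x) / x.shape[1]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    import inspect

    mds_params = inspect.signature(MDS.__init__).parameters
    if "metric_mds" in mds_params:  # sklearn >= 1.9 API
        nonmetric_kw = {"metric": "precomputed", "metric_mds": False}
    else:
        nonmetric_kw = {"metric": False, "dissimilarity": "precomputed"}
    if "init" in mds_params:
        nonmetric_kw["init"] = "random"
    mds = MDS(
        n_components=k,
        **nonmetric_kw,
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,
        eps=1e-9,
        n_jobs=1,
    )
    coords = mds.fit_transform(d)
    index = (
        binary.index if isinstance(binary, pd.DataFrame)
        else pd.RangeIndex(x.shape[0])
    )
    cdf = pd.DataFrame(
        coords, index=index, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coordinates=cdf, stress=float(mds.stress_),
                            metric=metric)
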