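"""Nested (Procrustes) ANOVA with custom F-ratios and restricted
permutations, per-plant variance decompositions, bootstrap comparisons of
medians, and mean-square correlations.

The sampling design is a four-level hierarchy: locality > plant > segment,
with two within-plant asymmetric effects — *side* (directional asymmetry,
DA: the mean original-vs-reflected difference per plant) and *segment x
side* (fluctuating asymmetry, FA: per-segment deviations from the plant's
mean asymmetry) — and a residual expressing digitization (measurement)
error between replicate digitizations.  Because segments carry no
anatomical left/right cue across plants (side ambiguity), side and
segment x side are only ever defined within plants.

Sums of squares are type I (sequential) in the fixed order
``[centroid size,] locality, plant(locality), segment(plant), side(plant),
segment x side(plant), error``; the design is balanced in side and
replicate, so each categorical SS equals its hierarchical group-mean
decomposition, which is what is computed (and asserted to add up exactly).
Multivariate SS are summed univariate SS across shape coordinates, which is
identical to the squared tangent Procrustes distance formulation.

F-ratios follow the nesting: locality over plant, plant over segment,
segment and side over segment x side (FA), FA over measurement error.  When
a size covariate is included its F is taken over the pooled MS of all
non-error factor rows.  p-values come from restricted permutations that
shuffle labels only at the level appropriate to each effect (see
``docs/methods.md``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "nested_procrustes_anova",
    "total_asymmetry_anova",
    "per_plant_decomposition",
    "bootstrap_median_difference",
    "BootstrapResult",
    "ms_correlations",
    "size_asymmetry_correlation",
]


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

@dataclass
class AnovaRow:
    effect: str
    df: int
    SS: float
    MS: float | None = None
    F: float | None = None
    p: float | None = None
    R2: float | None = None


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    total_ss: float
    total_df: int
    meta: dict = field(default_factory=dict)

    def __getitem__(self, effect: str) -> AnovaRow:
        for row in self.rows:
            if row.effect == effect:
                return row
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"effect": r.effect, "df": r.df, "SS": r.SS, "MS": r.MS,
             "F": r.F, "p": r.p, "R2": r.R2}
            for r in self.rows
        ]
        recs.append({"effect": "total", "df": self.total_df, "SS": self.total_ss,
                     "MS": None, "F": None, "p": None, "R2": None})
        return pd.DataFrame(recs)

    def validate(self, rtol: float = 1e-8) -> None:
        """Assert the type I bookkeeping identities (SS additivity, df sum)."""
        ss = sum(r.SS for r in self.rows)
        if not np.isclose(ss, self.total_ss, rtol=rtol, atol=1e-12):
            raise AssertionError(f"SS additivity violated: {ss} != {self.total_ss}")
        df = sum(r.df for r in self.rows)
        if df != self.total_df:
            raise AssertionError(f"df bookkeeping violated: {df} != {self.total_df}")


def _finish_rows(rows: list[AnovaRow], total_ss: float) -> None:
    for r in rows:
        r.MS = r.SS / r.df if r.df > 0 else None
        r.R2 = r.SS / total_ss if total_ss > 0 else 0.0


def _ratio(num: AnovaRow, den: AnovaRow) -> float | None:
    if den.MS is None or den.MS <= 0 or num.MS is None:
        return None
    return num.MS / den.MS


def _perm_p(f_obs: float | None, f_perm: np.ndarray, n_perm: int) -> float | None:
    if f_obs is None:
        return None
    return (np.sum(f_perm >= f_obs - 1e-12) + 1.0) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# design handling
# ---------------------------------------------------------------------------

def _check_nperm(n_perm: int) -> None:
    if 0 < n_perm < 99:
        warnings.warn(f"n_perm = {n_perm} is low; p-values will be coarse", UserWarning)


def _sorted_layout_multivariate(Y: np.ndarray, design: pd.DataFrame):
    """Sort records into (S, 4, d) blocks ordered side-major within segment.

    Each segment (globally unique within its plant) must appear with exactly
    two sides and two replicates.
    """
    d = design.reset_index(drop=True).copy()
    d["_seg_key"] = (
        d["locality"].astype(str) + "//" + d["plant"].astype(str) + "//" + d["segment"].astype(str)
    )
    seg_codes, seg_keys = pd.factorize(d["_seg_key"], sort=True)
    side_raw = d["side"]
    if side_raw.dtype == bool:
        side = side_raw.astype(int).to_numpy()
    else:
        side_codes, side_levels = pd.factorize(side_raw.astype(str), sort=True)
        if len(side_levels) != 2:
            raise ValueError(f"side must have exactly 2 levels, got {list(side_levels)}")
        side = side_codes
    rep_codes, rep_levels = pd.factorize(d["replicate"].astype(str), sort=True)
    if len(rep_levels) != 2:
        raise ValueError("replicate must have exactly 2 levels")

    order = np.lexsort((rep_codes, side, seg_codes))
    n_seg = len(seg_keys)
    if len(d) != 4 * n_seg:
        raise ValueError("each segment must have exactly 4 records (2 sides x 2 replicates)")
    counts = np.bincount(seg_codes * 4 + side * 2 + rep_codes, minlength=4 * n_seg)
    if not np.all(counts == 1):
        raise ValueError("unbalanced design: every segment needs one record per side x replicate")

    Ys = Y[order].reshape(n_seg, 4, -1)
    seg_rows = order.reshape(n_seg, 4)[:, 0]
    plant_key = d["locality"].astype(str) + "//" + d["plant"].astype(str)
    plant_of_seg, plant_keys = pd.factorize(plant_key.iloc[seg_rows], sort=True)
    loc_of_plant_map = {}
    loc_codes, loc_keys = pd.factorize(d["locality"].astype(str), sort=True)
    for pcode, prow in zip(plant_of_seg, seg_rows):
        loc_of_plant_map[pcode] = loc_codes[prow]
    loc_of_plant = np.array([loc_of_plant_map[p] for p in range(len(plant_keys))])
    return Ys, plant_of_seg, loc_of_plant, len(loc_keys), order


def _group_mean(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    sums = np.zeros((n_groups, values.shape[1]))
    np.add.at(sums, codes, values)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    return sums / counts[:, None]


def _ss_between(child_means, child_weights, parent_of_child, parent_means) -> float:
    diff = child_means - parent_means[parent_of_child]
    return float((child_weights * (diff ** 2).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# the multivariate nested model
# ---------------------------------------------------------------------------

def _size_stage(Y: np.ndarray, sizes: np.ndarray):
    """Sequentially remove the centroid-size regression; return
    (residual Y, SS_size)."""
    x = sizes.astype(float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("degenerate size covariate (constant)")
    Yc = Y - Y.mean(axis=0)
    beta = (xc @ Yc) / sxx
    fitted = np.outer(xc, beta)
    ss_size = float((fitted ** 2).sum())
    return Y - fitted, ss_size


def nested_procrustes_anova(
    Y: np.ndarray,
    design: pd.DataFrame,
    sizes: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    adjust_size: bool = False,
) -> AnovaTable:
    """Multivariate nested Procrustes ANOVA over the combined
    original + reflected, twice-digitized records.

    Parameters
    ----------
    Y : (n, d) array
        Superimposed shape coordinates (or tangent coordinates), one row per
        record.
    design : DataFrame
        Columns ``locality, plant, segment, side, replicate``; every segment
        must appear in 4 records.
    sizes : (n,) array, optional
        Centroid size per record; required when ``adjust_size``.
    n_perm, seed
        Restricted-permutation settings.  ``seed`` is required whenever
        ``n_perm > 0``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    _check_nperm(n_perm)
    if n_perm > 0 and seed is None:
        raise ValueError("a seed is required for permutation p-values")
    rng = np.random.default_rng(seed)

    Ys, plant_of_seg, loc_of_plant, n_loc, order = _sorted_layout_multivariate(Y, design)
    S = Ys.shape[0]
    P = len(loc_of_plant)
    n = 4 * S
    total_df = n - 1

    rows: list[AnovaRow] = []
    total_ss = float(((Y - Y.mean(axis=0)) ** 2).sum())
    err_df_loss = 0

    if adjust_size:
        if sizes is None:
            raise ValueError("adjust_size requires sizes")
        sizes_sorted = np.asarray(sizes, dtype=float)[order]
        Yflat, ss_size = _size_stage(Ys.reshape(n, -1), sizes_sorted)
        Ys = Yflat.reshape(S, 4, -1)
        err_df_loss = 1
    else:
        ss_size = None

    comp = _components_multivariate(Ys, plant_of_seg, loc_of_plant, n_loc)
    (ss_loc, ss_plant, ss_seg, ss_side, ss_int, ss_err,
     m_seg, a_seg, m_plant, seg_counts) = comp

    df_loc = n_loc - 1
    df_plant = P - n_loc
    df_seg = S - P
    df_side = P
    df_int = S - P
    df_err = 2 * S - err_df_loss

    if adjust_size:
        rows.append(AnovaRow("centroid size", 1, ss_size))
    rows.append(AnovaRow("locality", df_loc, ss_loc))
    rows.append(AnovaRow("plant (locality)", df_plant, ss_plant))
    rows.append(AnovaRow("segment (plant)", df_seg, ss_seg))
    rows.append(AnovaRow("side (plant)", df_side, ss_side))
    rows.append(AnovaRow("segment x side (plant)", df_int, ss_int))
    rows.append(AnovaRow("measurement error", df_err, ss_err))
    _finish_rows(rows, total_ss)
    table = AnovaTable(rows, total_ss, total_df,
                       meta={"n_perm": n_perm, "seed": seed, "adjust_size": adjust_size,
                             "n_records": n})
    table.validate()

    loc_r = table["locality"]
    plant_r = table["plant (locality)"]
    seg_r = table["segment (plant)"]
    side_r = table["side (plant)"]
    int_r = table["segment x side (plant)"]
    err_r = table["measurement error"]

    loc_r.F = _ratio(loc_r, plant_r)
    plant_r.F = _ratio(plant_r, seg_r)
    seg_r.F = _ratio(seg_r, int_r)
    side_r.F = _ratio(side_r, int_r)
    int_r.F = _ratio(int_r, err_r)
    if adjust_size:
        size_r = table["centroid size"]
        pooled_ss = ss_loc + ss_plant + ss_seg + ss_side + ss_int
        pooled_df = df_loc + df_plant + df_seg + df_side + df_int
        size_r.F = (size_r.MS / (pooled_ss / pooled_df)) if pooled_ss > 0 else None

    if n_perm > 0:
        _permute_multivariate(table, Ys, m_seg, a_seg, m_plant, seg_counts,
                              plant_of_seg, loc_of_plant, n_loc, n_perm, rng,
                              sizes_segwise=None if not adjust_size else sizes_sorted,
                              raw_Y=Y[order] if adjust_size else None)
    return table


def _components_multivariate(Ys, plant_of_seg, loc_of_plant, n_loc):
    """Balanced hierarchical decomposition from the (S, 4, d) layout."""
    S, _, d = Ys.shape
    m_seg = Ys.mean(axis=1)                                  # (S, d)
    a_seg = (Ys[:, 0:2].mean(axis=1) - Ys[:, 2:4].mean(axis=1)) / 2.0
    P = len(loc_of_plant)
    seg_counts = np.bincount(plant_of_seg, minlength=P).astype(float)
    m_plant = _group_mean(m_seg, plant_of_seg, P)
    n_plant = 4.0 * seg_counts
    loc_w = np.zeros(n_loc)
    np.add.at(loc_w, loc_of_plant, n_plant)
    loc_sum = np.zeros((n_loc, d))
    np.add.at(loc_sum, loc_of_plant, m_plant * n_plant[:, None])
    m_loc = loc_sum / loc_w[:, None]
    grand = (m_loc * loc_w[:, None]).sum(axis=0) / loc_w.sum()

    ss_loc = float((loc_w * ((m_loc - grand) ** 2).sum(axis=1)).sum())
    ss_plant = _ss_between(m_plant, n_plant, loc_of_plant, m_loc)
    ss_seg = _ss_between(m_seg, 4.0 * np.ones(S), plant_of_seg, m_plant)
    abar = _group_mean(a_seg, plant_of_seg, P)
    ss_side = float((n_plant * (abar ** 2).sum(axis=1)).sum())
    ss_int = 4.0 * float(((a_seg - abar[plant_of_seg]) ** 2).sum())
    ss_err = 0.5 * float(((Ys[:, 0] - Ys[:, 1]) ** 2).sum()
                         + ((Ys[:, 2] - Ys[:, 3]) ** 2).sum())
    return (ss_loc, ss_plant, ss_seg, ss_side, ss_int, ss_err,
            m_seg, a_seg, m_plant, seg_counts)


def _permute_multivariate(table, Ys, m_seg, a_seg, m_plant, seg_counts,
                          plant_of_seg, loc_of_plant, n_loc, n_perm, rng,
                          sizes_segwise=None, raw_Y=None):
    """Restricted permutations, one scheme per tested effect."""
    S, _, d = Ys.shape
    P = len(loc_of_plant)
    n_plant = 4.0 * seg_counts
    loc_w = np.zeros(n_loc)
    np.add.at(loc_w, loc_of_plant, n_plant)
    grand = (m_plant * n_plant[:, None]).sum(axis=0) / n_plant.sum()

    loc_r = table["locality"]
    plant_r = table["plant (locality)"]
    seg_r = table["segment (plant)"]
    side_r = table["side (plant)"]
    int_r = table["segment x side (plant)"]
    err_r = table["measurement error"]

    df = {r.effect: r.df for r in table.rows}

    # ---- locality: permute whole plants across localities ------------------
    # SS_loc + SS_plant is invariant, so only SS_loc is recomputed.
    between = float((n_plant * ((m_plant - grand) ** 2).sum(axis=1)).sum())
    testable_loc = loc_r.F is not None and df["locality"] > 0 and df["plant (locality)"] > 0
    f_loc = np.empty(n_perm if testable_loc else 0)
    for b in range(len(f_loc)):
        perm = rng.permutation(P)
        lp = loc_of_plant[perm]
        w = np.zeros(n_loc)
        np.add.at(w, lp, n_plant)
        sums = np.zeros((n_loc, d))
        np.add.at(sums, lp, m_plant * n_plant[:, None])
        ml = sums / w[:, None]
        ssl = float((w * ((ml - grand) ** 2).sum(axis=1)).sum())
        ssp = between - ssl
        ms_l = ssl / df["locality"]
        ms_p = ssp / df["plant (locality)"]
        f_loc[b] = ms_l / ms_p if ms_p > 0 else np.inf
    if testable_loc:
        loc_r.p = _perm_p(loc_r.F, f_loc, n_perm)

    # ---- plant: permute whole segments across plants within locality -------
    # SS_plant + SS_segment is invariant within each locality.
    loc_of_seg = loc_of_plant[plant_of_seg]
    testable_plant = (plant_r.F is not None and df["plant (locality)"] > 0
                      and df["segment (plant)"] > 0)
    f_plant = np.empty(n_perm if testable_plant else 0)
    within = (plant_r.SS + seg_r.SS)
    for b in range(len(f_plant)):
        new_plant = np.empty(S, dtype=int)
        for l in range(n_loc):
            idx = np.where(loc_of_seg == l)[0]
            new_plant[idx] = plant_of_seg[idx[rng.permutation(len(idx))]]
        mp = _group_mean(m_seg, new_plant, P)
        # locality means are unchanged by this shuffle
        loc_sums = np.zeros((n_loc, d))
        np.add.at(loc_sums, loc_of_plant, mp * n_plant[:, None])
        ml = loc_sums / loc_w[:, None]
        ssp = _ss_between(mp, n_plant, loc_of_plant, ml)
        sss = within - ssp
        ms_p = ssp / df["plant (locality)"]
        ms_s = sss / df["segment (plant)"]
        f_plant[b] = ms_p / ms_s if ms_s > 0 else np.inf
    if testable_plant:
        plant_r.p = _perm_p(plant_r.F, f_plant, n_perm)

    # ---- side (DA): flip original/reflected labels per segment -------------
    testable_side = (df["segment x side (plant)"] > 0 and side_r.F is not None)
    f_side = np.empty(n_perm if testable_side else 0)
    for b in range(len(f_side)):
        eps = rng.choice([-1.0, 1.0], size=S)
        ea = a_seg * eps[:, None]
        abar = _group_mean(ea, plant_of_seg, P)
        ss_side_p = float((n_plant * (abar ** 2).sum(axis=1)).sum())
        ss_int_p = 4.0 * float(((ea - abar[plant_of_seg]) ** 2).sum())
        ms_int = ss_int_p / df["segment x side (plant)"]
        ms_side = ss_side_p / df["side (plant)"]
        f_side[b] = ms_side / ms_int if ms_int > 0 else np.inf
    if testable_side:
        side_r.p = _perm_p(side_r.F, f_side, n_perm)

    # ---- segment: shuffle side cells across segments within plant ----------
    # Exchanging each side's cell means among the segments of a plant
    # destroys true segment differences while preserving the plant, side and
    # error structure, so permuted segment variation arises from asymmetry
    # alone -- matching the F-ratio's segment-over-FA denominator logic.
    testable_seg = (df["segment x side (plant)"] > 0 and seg_r.F is not None)
    f_seg = np.empty(n_perm if testable_seg else 0)
    if testable_seg:
        c1 = Ys[:, 0:2].mean(axis=1)
        c2 = Ys[:, 2:4].mean(axis=1)
        m_plant_of_seg = m_plant[plant_of_seg]
        # SS_seg + SS_int is invariant under these shuffles
        invariant = seg_r.SS + int_r.SS
        plant_groups = [np.where(plant_of_seg == p)[0] for p in range(P)]
    for b in range(len(f_seg)):
        c1p = c1.copy()
        c2p = c2.copy()
        for idx in plant_groups:
            c1p[idx] = c1[idx[rng.permutation(len(idx))]]
            c2p[idx] = c2[idx[rng.permutation(len(idx))]]
        m_seg_p = (c1p + c2p) / 2.0
        ss_seg_p = 4.0 * float(((m_seg_p - m_plant_of_seg) ** 2).sum())
        ss_int_p = invariant - ss_seg_p
        ms_s = ss_seg_p / df["segment (plant)"]
        ms_i = ss_int_p / df["segment x side (plant)"]
        f_seg[b] = ms_s / ms_i if ms_i > 0 else np.inf
    if testable_seg:
        seg_r.p = _perm_p(seg_r.F, f_seg, n_perm)

    # ---- FA vs error: shuffle records across the side x replicate cells ----
    testable_int = int_r.F is not None and df["segment x side (plant)"] > 0
    f_int = np.empty(n_perm if testable_int else 0)
    for b in range(len(f_int)):
        idx = np.argsort(rng.random((S, 4)), axis=1)
        Yp = np.take_along_axis(Ys, idx[:, :, None], axis=1)
        c1 = Yp[:, 0:2].mean(axis=1)
        c2 = Yp[:, 2:4].mean(axis=1)
        b_s = (c1 - c2) / 2.0
        bbar = _group_mean(b_s, plant_of_seg, P)
        ss_int_p = 4.0 * float(((b_s - bbar[plant_of_seg]) ** 2).sum())
        ss_err_p = 0.5 * float(((Yp[:, 0] - Yp[:, 1]) ** 2).sum()
                               + ((Yp[:, 2] - Yp[:, 3]) ** 2).sum())
        ms_i = ss_int_p / df["segment x side (plant)"]
        ms_e = ss_err_p / df["measurement error"]
        f_int[b] = ms_i / ms_e if ms_e > 0 else np.inf
    if testable_int:
        int_r.p = _perm_p(int_r.F, f_int, n_perm)

    # ---- centroid size: permute segment sizes ------------------------------
    if sizes_segwise is not None and raw_Y is not None:
        size_r = table["centroid size"]
        n = raw_Y.shape[0]
        Yc = raw_Y - raw_Y.mean(axis=0)
        total_centered = float((Yc ** 2).sum())
        seg_sizes = sizes_segwise.reshape(S, 4)[:, 0]
        pooled_df = sum(df[e] for e in ["locality", "plant (locality)",
                                        "segment (plant)", "side (plant)",
                                        "segment x side (plant)"])
        err_ss = err_r.SS
        f_size = np.empty(n_perm)
        for b in range(n_perm):
            sp = seg_sizes[rng.permutation(S)]
            x = np.repeat(sp, 4)
            xc = x - x.mean()
            sxx = float(xc @ xc)
            ss_size_p = float(((xc @ Yc) ** 2).sum()) / sxx
            pooled = (total_centered - ss_size_p - err_ss) / pooled_df
            f_size[b] = ss_size_p / pooled if pooled > 0 else np.inf
        size_r.p = _perm_p(size_r.F, f_size, n_perm)


# ---------------------------------------------------------------------------
# univariate total-asymmetry model
# ---------------------------------------------------------------------------

def total_asymmetry_anova(
    values: np.ndarray,
    design: pd.DataFrame,
    sizes: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    adjust_size: bool = False,
) -> AnovaTable:
    """Univariate nested ANOVA for the total-asymmetry statistic.

    ``values`` holds one asymmetry value per segment x replicate record;
    ``design`` needs columns ``locality, plant, segment, replicate`` (two
    replicates per segment).  F-ratios: locality over plant, plant over
    segment, segment over measurement error.
    """
    v = np.asarray(values, dtype=float)
    _check_nperm(n_perm)
    if n_perm > 0 and seed is None:
        raise ValueError("a seed is required for permutation p-values")
    rng = np.random.default_rng(seed)

    d = design.reset_index(drop=True).copy()
    d["_seg_key"] = (
        d["locality"].astype(str) + "//" + d["plant"].astype(str) + "//" + d["segment"].astype(str)
    )
    seg_codes, seg_keys = pd.factorize(d["_seg_key"], sort=True)
    rep_codes, rep_levels = pd.factorize(d["replicate"].astype(str), sort=True)
    if len(rep_levels) != 2:
        raise ValueError("replicate must have exactly 2 levels")
    S = len(seg_keys)
    if len(d) != 2 * S:
        raise ValueError("each segment must have exactly 2 records (replicates)")
    order = np.lexsort((rep_codes, seg_codes))
    Y2 = v[order].reshape(S, 2)
    seg_rows = order.reshape(S, 2)[:, 0]
    plant_key = d["locality"].astype(str) + "//" + d["plant"].astype(str)
    plant_of_seg, plant_keys = pd.factorize(plant_key.iloc[seg_rows], sort=True)
    loc_codes, loc_keys = pd.factorize(d["locality"].astype(str), sort=True)
    loc_of_plant = np.zeros(len(plant_keys), dtype=int)
    loc_of_plant[plant_of_seg] = loc_codes[seg_rows]
    n_loc = len(loc_keys)
    P = len(plant_keys)
    n = 2 * S
    total_ss = float(((v - v.mean()) ** 2).sum())
    total_df = n - 1

    err_df_loss = 0
    ss_size = None
    if adjust_size:
        if sizes is None:
            raise ValueError("adjust_size requires sizes")
        sizes_sorted = np.asarray(sizes, dtype=float)[order]
        Yflat, ss_size = _size_stage(Y2.reshape(n, 1), sizes_sorted)
        Y2 = Yflat.reshape(S, 2)
        err_df_loss = 1

    m_seg = Y2.mean(axis=1)
    seg_counts = np.bincount(plant_of_seg, minlength=P).astype(float)
    n_plant = 2.0 * seg_counts
    m_plant = _group_mean(m_seg[:, None], plant_of_seg, P)[:, 0]
    loc_w = np.zeros(n_loc)
    np.add.at(loc_w, loc_of_plant, n_plant)
    loc_sum = np.zeros(n_loc)
    np.add.at(loc_sum, loc_of_plant, m_plant * n_plant)
    m_loc = loc_sum / loc_w
    grand = loc_sum.sum() / loc_w.sum()

    ss_loc = float((loc_w * (m_loc - grand) ** 2).sum())
    ss_plant = float((n_plant * (m_plant - m_loc[loc_of_plant]) ** 2).sum())
    ss_seg = 2.0 * float(((m_seg - m_plant[plant_of_seg]) ** 2).sum())
    ss_err = 0.5 * float(((Y2[:, 0] - Y2[:, 1]) ** 2).sum())

    rows = []
    if adjust_size:
        rows.append(AnovaRow("centroid size", 1, ss_size))
    rows.append(AnovaRow("locality", n_loc - 1, ss_loc))
    rows.append(AnovaRow("plant (locality)", P - n_loc, ss_plant))
    rows.append(AnovaRow("segment (plant)", S - P, ss_seg))
    rows.append(AnovaRow("measurement error", S - err_df_loss, ss_err))
    _finish_rows(rows, total_ss)
    table = AnovaTable(rows, total_ss, total_df,
                       meta={"n_perm": n_perm, "seed": seed, "adjust_size": adjust_size})
    table.validate()

    loc_r, plant_r, seg_r, err_r = (table["locality"], table["plant (locality)"],
                                    table["segment (plant)"], table["measurement error"])
    loc_r.F = _ratio(loc_r, plant_r)
    plant_r.F = _ratio(plant_r, seg_r)
    seg_r.F = _ratio(seg_r, err_r)
    if adjust_size:
        size_r = table["centroid size"]
        pooled_ss = ss_loc + ss_plant + ss_seg
        pooled_df = (n_loc - 1) + (P - n_loc) + (S - P)
        size_r.F = size_r.MS / (pooled_ss / pooled_df) if pooled_ss > 0 else None

    if n_perm == 0:
        return table

    df = {r.effect: r.df for r in table.rows}
    grand_v = float(m_plant @ n_plant) / n_plant.sum()
    between = float((n_plant * (m_plant - grand_v) ** 2).sum())

    f_loc = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(P)
        lp = loc_of_plant[perm]
        w = np.zeros(n_loc)
        np.add.at(w, lp, n_plant)
        s = np.zeros(n_loc)
        np.add.at(s, lp, m_plant * n_plant)
        ml = s / w
        ssl = float((w * (ml - grand_v) ** 2).sum())
        ssp = between - ssl
        f_loc[b] = (ssl / df["locality"]) / (ssp / df["plant (locality)"]) if ssp > 0 else np.inf
    loc_r.p = _perm_p(loc_r.F, f_loc, n_perm)

    loc_of_seg = loc_of_plant[plant_of_seg]
    within = ss_plant + ss_seg
    f_plant = np.empty(n_perm)
    for b in range(n_perm):
        new_plant = np.empty(S, dtype=int)
        for l in range(n_loc):
            idx = np.where(loc_of_seg == l)[0]
            new_plant[idx] = plant_of_seg[idx[rng.permutation(len(idx))]]
        mp = _group_mean(m_seg[:, None], new_plant, P)[:, 0]
        s = np.zeros(n_loc)
        np.add.at(s, loc_of_plant, mp * n_plant)
        ml = s / loc_w
        ssp = float((n_plant * (mp - ml[loc_of_plant]) ** 2).sum())
        sss = within - ssp
        f_plant[b] = (ssp / df["plant (locality)"]) / (sss / df["segment (plant)"]) if sss > 0 else np.inf
    plant_r.p = _perm_p(plant_r.F, f_plant, n_perm)

    # segment vs error: shuffle records across segments within each plant
    f_seg = np.empty(n_perm)
    rec_plant = plant_of_seg.repeat(2)
    flat = Y2.ravel()
    within_seg = ss_seg + ss_err
    for b in range(n_perm):
        shuffled = np.empty_like(flat)
        for p in range(P):
            idx = np.where(rec_plant == p)[0]
            shuffled[idx] = flat[idx[rng.permutation(len(idx))]]
        Yp = shuffled.reshape(S, 2)
        ms = Yp.mean(axis=1)
        sss = 2.0 * float(((ms - m_plant[plant_of_seg]) ** 2).sum())
        sse = within_seg - sss
        f_seg[b] = (sss / df["segment (plant)"]) / (sse / df["measurement error"]) if sse > 0 else np.inf
    seg_r.p = _perm_p(seg_r.F, f_seg, n_perm)

    if adjust_size:
        size_r = table["centroid size"]
        vc = v[order] - v[order].mean()
        total_centered = float((vc ** 2).sum())
        seg_sizes = sizes_sorted.reshape(S, 2)[:, 0]
        pooled_df = (n_loc - 1) + (P - n_loc) + (S - P)
        f_size = np.empty(n_perm)
        for b in range(n_perm):
            sp = np.repeat(seg_sizes[rng.permutation(S)], 2)
            xc = sp - sp.mean()
            ss_size_p = float((xc @ vc) ** 2) / float(xc @ xc)
            pooled = (total_centered - ss_size_p - ss_err) / pooled_df
            f_size[b] = ss_size_p / pooled if pooled > 0 else np.inf
        size_r.p = _perm_p(size_r.F, f_size, n_perm)
    return table


# ---------------------------------------------------------------------------
# per-plant decomposition and comparisons
# ---------------------------------------------------------------------------

def per_plant_decomposition(Y: np.ndarray, design: pd.DataFrame,
                            min_segments: int = 3) -> pd.DataFrame:
    """Within-plant decomposition into symmetric variation (segment), DA
    (side), FA (segment x side) and measurement error.

    Returns one row per plant with MS and R2 per component; plants with
    fewer than ``min_segments`` segments are skipped with a log message.
    No p-values are produced — the per-plant tables are descriptive.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Ys, plant_of_seg, loc_of_plant, n_loc, order = _sorted_layout_multivariate(Y, design)
    d = design.reset_index(drop=True)
    plant_key = d["locality"].astype(str) + "//" + d["plant"].astype(str)
    seg_rows = order.reshape(-1, 4)[:, 0]
    _, plant_keys = pd.factorize(plant_key.iloc[seg_rows], sort=True)
    loc_names = pd.factorize(d["locality"].astype(str), sort=True)[1]

    records = []
    for p, key in enumerate(plant_keys):
        idx = np.where(plant_of_seg == p)[0]
        sp = len(idx)
        if sp < min_segments:
            logger.info("plant %s skipped: only %d segment(s)", key, sp)
            continue
        B = Ys[idx]                     # (sp, 4, d)
        m_seg = B.mean(axis=1)
        a_seg = (B[:, 0:2].mean(axis=1) - B[:, 2:4].mean(axis=1)) / 2.0
        m_p = m_seg.mean(axis=0)
        abar = a_seg.mean(axis=0)
        ss_seg = 4.0 * float(((m_seg - m_p) ** 2).sum())
        ss_side = 4.0 * sp * float((abar ** 2).sum())
        ss_int = 4.0 * float(((a_seg - abar) ** 2).sum())
        ss_err = 0.5 * float(((B[:, 0] - B[:, 1]) ** 2).sum()
                             + ((B[:, 2] - B[:, 3]) ** 2).sum())
        total = ss_seg + ss_side + ss_int + ss_err
        loc, plant = key.split("//", 1)
        records.append({
            "plant": plant, "locality": loc, "n_segments": sp,
            "ms_symmetric": ss_seg / (sp - 1),
            "ms_da": ss_side / 1.0,
            "ms_fa": ss_int / (sp - 1),
            "ms_error": ss_err / (2 * sp),
            "r2_symmetric": ss_seg / total if total > 0 else 0.0,
            "r2_da": ss_side / total if total > 0 else 0.0,
            "r2_fa": ss_int / total if total > 0 else 0.0,
            "ss_total": total,
        })
    return pd.DataFrame(records)


@dataclass
class BootstrapResult:
    median_a: float
    median_b: float
    estimates: np.ndarray
    ci_95: tuple[float, float]
    p_value: float

    @property
    def significant(self) -> bool:
        lo, hi = self.ci_95
        return not (lo <= 0.0 <= hi)


def bootstrap_median_difference(values_a, values_b, n_boot: int = 999,
                                seed: int | None = None) -> BootstrapResult:
    """Bootstrap the difference in group medians (A minus B).

    Resamples each group with replacement; 95% CI is the 2.5/97.5 percentile
    interval of the bootstrap differences; two-sided p is twice the smaller
    tail fraction, floored at 1/n_boot.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 values per group")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    est = np.median(a[ia], axis=1) - np.median(b[ib], axis=1)
    ci = (float(np.percentile(est, 2.5)), float(np.percentile(est, 97.5)))
    frac_le = float(np.mean(est <= 0.0))
    frac_ge = float(np.mean(est >= 0.0))
    p = max(2.0 * min(frac_le, frac_ge), 1.0 / n_boot)
    p = min(p, 1.0)
    return BootstrapResult(float(np.median(a)), float(np.median(b)), est, ci, p)


def ms_correlations(per_plant: pd.DataFrame,
                    columns: Sequence[str] = ("ms_symmetric", "ms_da", "ms_fa")) -> pd.DataFrame:
    """Pearson correlations between per-plant mean squares of the symmetric,
    DA and FA components."""
    if len(per_plant) < 3:
        raise ValueError("need at least 3 plants")
    mat = np.full((len(columns), len(columns)), np.nan)
    for i, ci in enumerate(columns):
        for j, cj in enumerate(columns):
            x, y = per_plant[ci].to_numpy(), per_plant[cj].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                logger.warning("constant column in MS correlation: %s/%s", ci, cj)
                continue
            mat[i, j] = stats.pearsonr(x, y)[0]
    return pd.DataFrame(mat, index=list(columns), columns=list(columns))


def size_asymmetry_correlation(sizes, asymmetry) -> tuple[float, float]:
    """Pearson r between centroid size and total asymmetry, and the
    percentage of asymmetry variance it spans (100 r^2)."""
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(asymmetry, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(stats.pearsonr(x, y)[0])
    return r, 100.0 * r * r
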