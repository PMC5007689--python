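"""Two-channel array normalization, differential statistics, and class calls.

The analysis chain for tile intensities is: per-array centering against the
control-feature means, M/A computation with a small pseudocount, lowess
correction of the intensity-dependent dye bias, a moderated permutation
statistic for differential occupancy, and an SVD-based principal-component
classification in which the first component (the common trend) is discarded
and per-tile loadings on the discriminating component are standardised to
Z-scores.  Occupancy classes are called from linear enrichment folds across
all replicates plus the Z-score criterion.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MTableError",
    "center_intensities",
    "lowess_fit",
    "lowess_correct",
    "build_mtable",
    "m_matrix",
    "fold_matrix",
    "SAMResult",
    "sam_differential",
    "PCAResult",
    "pca_classify",
    "OccupancyCall",
    "call_occupancy",
    "calls_frame",
]

CLASS_PRIORITY = {"CO_BOUND": 0, "A_ONLY": 1, "B_ONLY": 1, "UNCLASSIFIED": 2}


class MTableError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalization


def center_intensities(raw: pd.DataFrame, control_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Divide each channel of each array by its mean over control tiles.

    ``raw`` is the long intensity table (tile_id, is_control, protein,
    replicate, ch1, ch2).  Control tiles are taken from ``control_ids`` or,
    if omitted, from the ``is_control`` column.
    """
    out = raw.copy()
    if control_ids is not None:
        ctrl_mask = out["tile_id"].isin(set(control_ids))
    else:
        ctrl_mask = out["is_control"].astype(bool)
    if not ctrl_mask.any():
        raise MTableError("no control tiles on the array")
    for (_, _), idx in out.groupby(["protein", "replicate"]).groups.items():
        rows = out.loc[idx]
        sub = rows[ctrl_mask.loc[idx]]
        if sub.empty:
            raise MTableError("an array has no control tiles")
        for ch in ("ch1", "ch2"):
            mean = sub[ch].mean()
            if mean <= 0:
                raise MTableError(f"non-positive control mean for {ch}")
            out.loc[idx, ch] = rows[ch] / mean
    return out


def lowess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    robust_iters: int = 3,
) -> np.ndarray:
    """Locally weighted linear regression evaluated at every point.

    Tricube weights over the ``span`` fraction of nearest neighbours in x,
    local linear fit per point, followed by ``robust_iters`` bisquare
    reweighting passes on the residuals.  This is the exact per-point
    definition (no interpolation shortcuts) so it can be checked against a
    brute-force weighted-least-squares oracle to machine precision.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n < 10:
        raise MTableError("lowess needs at least 10 points")
    if not (0 < span <= 1):
        raise MTableError("span must be in (0, 1]")
    if np.ptp(x) == 0:
        raise MTableError("all A values identical")
    k = max(2, int(np.ceil(span * n)))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    robust = np.ones(n)
    fit_s = np.zeros(n)
    for pass_no in range(robust_iters + 1):
        lo = 0
        for i in range(n):
            # slide the k-neighbour window along the sorted x
            hi = lo + k
            while hi < n and xs[hi] - xs[i] < xs[i] - xs[lo]:
                lo += 1
                hi += 1
            d = np.abs(xs[lo:hi] - xs[i])
            h = d.max()
            if h > 0:
                w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
            else:
                w = np.ones_like(d)
            w = w * robust[lo:hi]
            u = xs[lo:hi] - xs[i]
            yy = ys[lo:hi]
            sw = w.sum()
            if sw <= 0:
                fit_s[i] = yy.mean()
                continue
            swu = (w * u).sum()
            swuu = (w * u * u).sum()
            swy = (w * yy).sum()
            swuy = (w * u * yy).sum()
            denom = sw * swuu - swu * swu
            if abs(denom) <= 1e-12 * max(sw * swuu, 1e-300):
                fit_s[i] = swy / sw
            else:
                fit_s[i] = (swuu * swy - swu * swuy) / denom
        if pass_no == robust_iters:
            break
        resid = ys - fit_s
        s = np.median(np.abs(resid))
        if s <= 0:
            # noise-free limit: a majority lies exactly on the fit; keep only
            # those points so isolated outliers cannot drag the local fits
            robust = (np.abs(resid) <= 1e-12).astype(float)
        else:
            robust = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    fit = np.empty(n)
    fit[order] = fit_s
    return fit


def lowess_correct(
    m_raw: np.ndarray,
    a: np.ndarray,
    span: float = 0.3,
    robust_iters: int = 3,
) -> np.ndarray:
    """Corrected M = raw M minus the lowess trend of M against A."""
    return np.asarray(m_raw, float) - lowess_fit(a, m_raw, span=span, robust_iters=robust_iters)


def build_mtable(
    raw: pd.DataFrame,
    control_ids: Sequence[str] | None = None,
    span: float = 0.3,
    robust_iters: int = 3,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full normalization chain: centering, M/A, lowess correction.

    Returns the long M-table with columns A, M_raw, M and linear ``fold``
    (2**M) per tile/protein/replicate.  The pseudocount is added to the raw
    intensities before any logs to keep ratios finite.
    """
    raw = raw.copy()
    raw["ch1"] = raw["ch1"] + pseudocount
    raw["ch2"] = raw["ch2"] + pseudocount
    centered = center_intensities(raw, control_ids)
    centered["A"] = 0.5 * np.log2(centered["ch1"] * centered["ch2"])
    centered["M_raw"] = np.log2(centered["ch1"] / centered["ch2"])
    centered["M"] = np.nan
    for _, idx in centered.groupby(["protein", "replicate"]).groups.items():
        sub = centered.loc[idx]
        centered.loc[idx, "M"] = lowess_correct(
            sub["M_raw"].to_numpy(), sub["A"].to_numpy(), span=span, robust_iters=robust_iters
        )
    centered["fold"] = 2.0 ** centered["M"]
    return centered


def m_matrix(mtable: pd.DataFrame, value: str = "M") -> pd.DataFrame:
    """Wide tiles x arrays matrix; columns are (protein, replicate)."""
    wide = mtable.pivot_table(index="tile_id", columns=["protein", "replicate"], values=value)
    if wide.isna().any().any():
        raise MTableError("tile set differs between arrays")
    return wide


def fold_matrix(mtable: pd.DataFrame) -> pd.DataFrame:
    return m_matrix(mtable, value="fold")


# ---------------------------------------------------------------------------
# moderated permutation statistic


@dataclass
class SAMResult:
    d: np.ndarray
    s: np.ndarray
    s0: float
    delta_grid: np.ndarray
    fdr: np.ndarray
    n_significant: np.ndarray
    median_false: np.ndarray

    def significant(self, delta: float) -> np.ndarray:
        return np.abs(self.d) >= delta

    def threshold_for_fdr(self, max_fdr: float) -> float:
        """Smallest grid delta whose estimated FDR is within the bound."""
        ok = np.nonzero(self.fdr <= max_fdr)[0]
        if len(ok) == 0:
            raise MTableError(f"no delta on the grid achieves FDR <= {max_fdr}")
        return float(self.delta_grid[ok[0]])


def _d_stat(group_a: np.ndarray, group_b: np.ndarray, s0: float | None = None):
    ka, kb = group_a.shape[1], group_b.shape[1]
    mean_a = group_a.mean(axis=1)
    mean_b = group_b.mean(axis=1)
    ssa = ((group_a - mean_a[:, None]) ** 2).sum(axis=1)
    ssb = ((group_b - mean_b[:, None]) ** 2).sum(axis=1)
    pooled = (ssa + ssb) / (ka + kb - 2)
    s = np.sqrt(pooled * (1.0 / ka + 1.0 / kb))
    if s0 is None:
        s0 = float(np.median(s))
    denom = s + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, (mean_b - mean_a) / np.where(denom > 0, denom, 1.0), 0.0)
    return d, s, s0


def sam_differential(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_permutations: int = 200,
    delta_grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SAMResult:
    """Moderated d statistic with a permutation estimate of the FDR.

    ``d_i = (mean_B - mean_A) / (s_i + s0)`` with the two-sample pooled
    standard error ``s_i`` and the fudge factor ``s0`` set to the median of
    the ``s_i``.  For each delta, the FDR estimate is the median count of
    permuted ``|d*|`` exceeding delta divided by the observed count.
    """
    group_a = np.asarray(group_a, float)
    group_b = np.asarray(group_b, float)
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise MTableError("need >= 2 replicates per group")
    if n_permutations < 10:
        raise MTableError("n_permutations must be >= 10")
    rng = rng if rng is not None else np.random.default_rng(0)
    if delta_grid is None:
        delta_grid = np.linspace(0.1, 5.0, 50)
    delta_grid = np.asarray(delta_grid, float)

    d, s, s0 = _d_stat(group_a, group_b)
    observed = np.array([(np.abs(d) >= delta).sum() for delta in delta_grid])

    combined = np.concatenate([group_a, group_b], axis=1)
    ka = group_a.shape[1]
    false_counts = np.empty((n_permutations, len(delta_grid)))
    for p in range(n_permutations):
        perm = rng.permutation(combined.shape[1])
        pa = combined[:, perm[:ka]]
        pb = combined[:, perm[ka:]]
        d_star, _, _ = _d_stat(pa, pb, s0=s0)
        abs_d = np.abs(d_star)
        false_counts[p] = (abs_d[None, :] >= delta_grid[:, None]).sum(axis=1)
    median_false = np.median(false_counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed > 0, np.minimum(1.0, median_false / np.maximum(observed, 1)), 0.0)
    return SAMResult(
        d=d,
        s=s,
        s0=s0,
        delta_grid=delta_grid,
        fdr=fdr,
        n_significant=observed,
        median_false=median_false,
    )


# ---------------------------------------------------------------------------
# SVD classification


@dataclass
class PCAResult:
    variance_fractions: np.ndarray
    array_scores: pd.DataFrame       # arrays x components
    loadings: pd.DataFrame           # tiles x components (scaled by singular values)
    z: pd.Series                     # per-tile Z on the discriminating component
    component: int = 1               # 0-based index of the discriminating component
    sign_convention: str = "protein A arrays positive"


def pca_classify(m_wide: pd.DataFrame, protein_a: str = "A") -> PCAResult:
    """SVD principal components of the tiles x arrays corrected-M matrix.

    Columns are centered; the first component (the common trend) is excluded
    from interpretation and per-tile loadings on the second are standardised
    to Z-scores.  The sign is fixed so the mean second-component score of
    protein-A arrays is positive.  A degenerate second component (variance
    fraction ~ 0) yields all-zero Z-scores.
    """
    if m_wide.shape[0] < m_wide.shape[1]:
        raise MTableError("need at least as many tiles as arrays")
    x = m_wide.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    total = (sv**2).sum()
    frac = sv**2 / total if total > 0 else np.zeros_like(sv)
    comp = 1
    if sv[0] <= 0 or sv[comp] <= 1e-12 * sv[0]:
        z = np.zeros(x.shape[0])
        sign = 1.0
    else:
        load = u[:, comp] * sv[comp]
        sd = load.std()
        z = load / sd if sd > 0 else np.zeros_like(load)
        a_cols = [
            j
            for j, col in enumerate(m_wide.columns)
            if (col[0] if isinstance(col, tuple) else str(col).split("_")[0]) == protein_a
        ]
        if not a_cols:
            raise MTableError(f"no arrays for protein {protein_a!r}")
        sign = 1.0 if vt[comp, a_cols].mean() >= 0 else -1.0
        z = sign * z
    cols = [f"PC{i + 1}" for i in range(len(sv))]
    array_labels = [
        "_".join(str(p) for p in c) if isinstance(c, tuple) else str(c) for c in m_wide.columns
    ]
    scores = pd.DataFrame(vt.T * sv, index=array_labels, columns=cols)
    scores["PC2"] = scores["PC2"] * (sign if sv[comp] > 0 else 1.0)
    loadings = pd.DataFrame(u * sv, index=m_wide.index, columns=cols)
    loadings["PC2"] = loadings["PC2"] * (sign if sv[comp] > 0 else 1.0)
    return PCAResult(
        variance_fractions=frac,
        array_scores=scores,
        loadings=loadings,
        z=pd.Series(z, index=m_wide.index, name="Z"),
    )


# ---------------------------------------------------------------------------
# occupancy calls


@dataclass
class OccupancyCall:
    repeat_id: str
    occupancy_class: str
    tile_id: str | None
    folds_a: tuple
    folds_b: tuple
    z: float
    support: float
    validated: bool | None = None


def _tile_class(fa: np.ndarray, fb: np.ndarray, z: float, fold_both: float,
                fold_none: float, z_cut: float) -> tuple[str, float]:
    """Class of one tile plus its support (min fold over implicated arrays)."""
    if fa.min() >= fold_both and fb.min() >= fold_both:
        return "CO_BOUND", float(min(fa.min(), fb.min()))
    if fa.min() >= fold_both and fb.max() <= fold_none and z >= z_cut:
        return "A_ONLY", float(fa.min())
    if fb.min() >= fold_both and fa.max() <= fold_none and z <= -z_cut:
        return "B_ONLY", float(fb.min())
    return "UNCLASSIFIED", 0.0


def call_occupancy(
    mtable: pd.DataFrame,
    pca: PCAResult,
    tile_map: pd.DataFrame,
    fold_both: float = 4.0,
    fold_none: float = 1.0,
    z_cut: float = 5.0,
) -> list[OccupancyCall]:
    """Per-repeat occupancy classes from tile folds and Z-scores.

    Tile rules (linear fold scale, conjunction over all replicates):
    co-bound requires fold >= ``fold_both`` for both proteins everywhere;
    single-protein classes require fold >= ``fold_both`` for one protein and
    <= ``fold_none`` for the other in every replicate, plus the Z criterion
    (Z >= z_cut for A-only, Z <= -z_cut for B-only).  A repeat takes the
    class of its best-supported tile (co-bound beats single-protein beats
    unclassified; ties broken by the largest minimum implicated fold).
    """
    folds = fold_matrix(mtable)
    proteins = sorted({c[0] for c in folds.columns})
    if len(proteins) != 2:
        raise MTableError("expected exactly two proteins")
    pa, pb = proteins
    reps_a = [c for c in folds.columns if c[0] == pa]
    reps_b = [c for c in folds.columns if c[0] == pb]
    if len(reps_a) != len(reps_b):
        raise MTableError("replicate counts differ between proteins")
    z = pca.z.reindex(folds.index)
    tmap = tile_map.dropna(subset=["repeat_id"])
    tiles_per_repeat = tmap.groupby("repeat_id")["tile_id"].apply(list)

    calls = []
    fa_all = folds[reps_a].to_numpy()
    fb_all = folds[reps_b].to_numpy()
    tile_pos = {t: i for i, t in enumerate(folds.index)}
    for repeat_id, tile_ids in tiles_per_repeat.items():
        best = ("UNCLASSIFIED", 0.0, None)  # class, support, tile
        for t in tile_ids:
            i = tile_pos.get(t)
            if i is None:
                raise MTableError(f"tile {t!r} missing from the M-table")
            cls, support = _tile_class(
                fa_all[i], fb_all[i], float(z.iloc[i]), fold_both, fold_none, z_cut
            )
            if (CLASS_PRIORITY[cls], -support) < (CLASS_PRIORITY[best[0]], -best[1]):
                best = (cls, support, t)
        cls, support, tile_id = best
        if tile_id is None:
            tile_id = tile_ids[0]
        i = tile_pos[tile_id]
        calls.append(
            OccupancyCall(
                repeat_id=repeat_id,
                occupancy_class=cls,
                tile_id=tile_id,
                folds_a=tuple(np.round(fa_all[i], 6)),
                folds_b=tuple(np.round(fb_all[i], 6)),
                z=float(z.iloc[i]),
                support=support,
            )
        )
    calls.sort(key=lambda c: c.repeat_id)
    return calls


def calls_frame(calls: Sequence[OccupancyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.repeat_id,
                c.occupancy_class,
                c.tile_id,
                ",".join(f"{v:g}" for v in c.folds_a),
                ",".join(f"{v:g}" for v in c.folds_b),
                c.z,
                c.validated,
            )
            for c in calls
        ],
        columns=["repeat_id", "class", "tile_id", "folds_a", "folds_b", "z", "validated"],
    )
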