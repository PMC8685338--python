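"""Group-level statistics: vertex-wise two-sample t-tests with BH-FDR,
signed cluster extraction, global comparison, covariate-adjusted Spearman
correlations with clinical variables, and a demographics table.

Sign convention: group A minus group B throughout. The pipeline passes the
patient group as A, so negative t means lower values in patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sstats
from scipy.sparse.csgraph import connected_components

from .mesh import CortexMask, TriangleMesh, vertex_areas
from .reho import SurfaceScalarMap
from .synthetic import SubjectRecord

log = logging.getLogger(__name__)

__all__ = [
    "GroupComparisonResult",
    "ClusterTable",
    "CorrelationResult",
    "two_sample_t",
    "bh_fdr",
    "vertexwise_group_test",
    "extract_clusters",
    "global_group_test",
    "partial_spearman",
    "correlate_clusters",
    "demographics_table",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    t_map: SurfaceScalarMap
    p_map: SurfaceScalarMap
    q: float
    significant: np.ndarray  # boolean, subset of the cortex mask
    df: float

    def __post_init__(self) -> None:
        sig = np.asarray(self.significant, dtype=bool)
        if np.any(sig & ~self.t_map.mask.keep):
            raise ValueError("significance mask extends outside the cortex mask")
        object.__setattr__(self, "significant", sig)


@dataclass(frozen=True)
class ClusterTable:
    """Per-cluster rows; ``to_frame`` mirrors the reporting schema
    (sign, peak vertex, peak t, area in mm², vertex count, members)."""

    rows: tuple[dict, ...]

    def to_frame(self, index_base: int = 0) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "sign": r["sign"],
                "peak_vertex": r["peak_vertex"] + index_base,
                "peak_t": r["peak_t"],
                "cluster_area_mm2": r["area_mm2"],
                "n_vertices": r["n_vertices"],
                "member_vertices": ",".join(
                    str(v + index_base) for v in r["members"]
                ),
            })
        cols = ["sign", "peak_vertex", "peak_t", "cluster_area_mm2",
                "n_vertices", "member_vertices"]
        return pd.DataFrame(recs, columns=cols)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class CorrelationResult:
    region_id: str
    variable: str
    r: float
    p: float
    q: float | None  # BH-adjusted p, None before family correction
    n: int
    covariates: tuple[str, ...]
    valid: bool = True


def two_sample_t(
    a: np.ndarray, b: np.ndarray, variance: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample t-test, group A minus group B; returns (t, p, df).

    ``variance="pooled"`` is the Student test; ``"welch"`` uses the
    Welch–Satterthwaite correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variance == "pooled":
        res = sstats.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
    elif variance == "welch":
        res = sstats.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    t = float(res.statistic)
    if not np.isfinite(t):
        raise ValueError("zero variance in both groups: t undefined")
    return t, float(res.pvalue), float(df)


def bh_fdr(pvals: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags.

    Rejects all p <= p_(k*) where k* = max{k : p_(k) <= k q / m}; stable
    sort handles ties. Empty input yields an empty flag array.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(sorted_p <= thresh)
    flags = np.zeros(m, dtype=bool)
    if passing.size:
        k_star = passing[-1]
        flags[order[: k_star + 1]] = True
    return flags


def _stack_maps(maps: Sequence[SurfaceScalarMap]) -> np.ndarray:
    ref = maps[0]
    for m in maps[1:]:
        if m.mesh.n_vertices != ref.mesh.n_vertices or not np.array_equal(
            m.mask.keep, ref.mask.keep
        ):
            raise ValueError("all maps must share mesh size and cortex mask")
    return np.vstack([m.values for m in maps])


def vertexwise_group_test(
    maps_a: Sequence[SurfaceScalarMap],
    maps_b: Sequence[SurfaceScalarMap],
    q: float = 0.05,
    variance: str = "pooled",
) -> GroupComparisonResult:
    """Per-vertex two-sample t over masked-in vertices with joint BH-FDR.

    The FDR family is every masked-in vertex of all supplied maps (both
    hemispheres when their maps are concatenated upstream).
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 maps per group")
    data_a = _stack_maps(list(maps_a) + list(maps_b))[: len(maps_a)]
    data_b = _stack_maps(list(maps_b))
    ref = maps_a[0]
    keep = ref.mask.keep
    n_a, n_b = data_a.shape[0], data_b.shape[0]

    xa = data_a[:, keep]
    xb = data_b[:, keep]
    if variance == "pooled":
        res = sstats.ttest_ind(xa, xb, axis=0, equal_var=True)
        df = float(n_a + n_b - 2)
    elif variance == "welch":
        res = sstats.ttest_ind(xa, xb, axis=0, equal_var=False)
        df = float(n_a + n_b - 2)  # per-vertex dfs differ; report the Student df
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    t_in = np.asarray(res.statistic, dtype=np.float64)
    p_in = np.asarray(res.pvalue, dtype=np.float64)
    bad = ~np.isfinite(t_in)
    if bad.any():
        log.warning("%d vertices with zero variance in both groups masked", bad.sum())
        t_in[bad] = 0.0
        p_in[bad] = 1.0

    t_full = np.full(keep.shape, np.nan)
    p_full = np.full(keep.shape, np.nan)
    t_full[keep] = t_in
    p_full[keep] = p_in

    sig = np.zeros(keep.shape, dtype=bool)
    sig[keep] = bh_fdr(p_in, q=q)

    mask = CortexMask(keep.copy())
    return GroupComparisonResult(
        t_map=SurfaceScalarMap(t_full, ref.mesh, mask),
        p_map=SurfaceScalarMap(p_full, ref.mesh, mask),
        q=q,
        significant=sig,
        df=df,
    )


def extract_clusters(
    result: GroupComparisonResult,
    mesh: TriangleMesh,
    areas: np.ndarray | None = None,
) -> ClusterTable:
    """Signed connected components of significant vertices.

    Positive-t and negative-t vertices are clustered separately on the mesh
    edge graph. Each row reports the peak (argmax |t|), the summed member
    vertex areas (mm²), and the member count — both size conventions.
    """
    if areas is None:
        areas = vertex_areas(mesh)
    t = result.t_map.values
    adj = mesh.adjacency()
    rows = []
    for sign, selector in (("+", t > 0), ("-", t < 0)):
        sel = result.significant & selector
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            continue
        sub = adj[np.ix_(idx, idx)]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            peak = members[np.argmax(np.abs(t[members]))]
            rows.append({
                "sign": sign,
                "peak_vertex": int(peak),
                "peak_t": float(t[peak]),
                "area_mm2": float(areas[members].sum()),
                "n_vertices": int(members.size),
                "members": tuple(int(v) for v in members),
            })
    rows.sort(key=lambda r: -abs(r["peak_t"]))
    return ClusterTable(tuple(rows))


def global_group_test(
    global_a: Sequence[float], global_b: Sequence[float], variance: str = "pooled"
) -> tuple[float, float]:
    """Two-sample t on global-mean map values; returns (t, p)."""
    t, p, _ = two_sample_t(np.asarray(global_a), np.asarray(global_b), variance)
    return t, p


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Spearman correlation of x and y after OLS-residualizing both on covariates.

    Returns (rho, two-sided p from the t approximation). Constant residuals
    make rho undefined; (nan, nan) is returned rather than raising.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or np.size(covariates) == 0:
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match n")
    if n < cov.shape[1] + 3:
        raise ValueError("need n >= number of covariates + 3")
    design = np.column_stack([np.ones(n), cov])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # residuals constant (relative to the input scale) leave rho undefined
    tol_x = 1e-12 * max(1.0, float(np.ptp(x)))
    tol_y = 1e-12 * max(1.0, float(np.ptp(y)))
    if np.ptp(rx) <= tol_x or np.ptp(ry) <= tol_y:
        return float("nan"), float("nan")
    rho, _ = sstats.spearmanr(rx, ry)
    rho = float(np.clip(rho, -1.0, 1.0))
    dof = n - 2 - cov.shape[1]
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(dof / (1.0 - rho**2))
    p = float(2.0 * sstats.t.sf(abs(t), dof))
    return rho, p


def correlate_clusters(
    cluster_means: pd.DataFrame,
    records: Sequence[SubjectRecord],
    variables: Sequence[str],
    q: float = 0.05,
    covariates: Sequence[str] = ("age", "sex"),
) -> list[CorrelationResult]:
    """Partial Spearman of each (region, clinical variable) pair in patients.

    ``cluster_means``: one row per patient (aligned with the SZ records, in
    order), one column per region. Age and sex are residualized out by
    default; BH-FDR is applied across the full region-by-variable family.
    Missing clinical values are handled pairwise-complete and counted.
    """
    sz = [r for r in records if r.group == "SZ"]
    if len(sz) != len(cluster_means):
        raise ValueError(
            f"cluster_means rows ({len(cluster_means)}) != patient count ({len(sz)})"
        )
    cov_cols = []
    for name in covariates:
        if name == "sex":
            cov_cols.append([1.0 if r.sex == "F" else 0.0 for r in sz])
        else:
            cov_cols.append([getattr(r, name) for r in sz])
    cov = np.array(cov_cols, dtype=np.float64).T if cov_cols else None

    results: list[CorrelationResult] = []
    for region in cluster_means.columns:
        x = cluster_means[region].to_numpy(dtype=np.float64)
        for var in variables:
            y = np.array([getattr(r, var) for r in sz], dtype=np.float64)
            ok = np.isfinite(x) & np.isfinite(y)
            n_ok = int(ok.sum())
            if n_ok < len(sz):
                log.info(
                    "%s x %s: %d of %d records pairwise-complete",
                    region, var, n_ok, len(sz),
                )
            c_ok = cov[ok] if cov is not None else None
            if n_ok < (0 if c_ok is None else c_ok.shape[1]) + 3:
                results.append(CorrelationResult(
                    str(region), var, float("nan"), float("nan"), None,
                    n_ok, tuple(covariates), valid=False,
                ))
                continue
            r, p = partial_spearman(x[ok], y[ok], c_ok)
            results.append(CorrelationResult(
                str(region), var, r, p, None, n_ok, tuple(covariates),
                valid=np.isfinite(r),
            ))

    valid_idx = [i for i, res in enumerate(results) if res.valid]
    if valid_idx:
        pvals = np.array([results[i].p for i in valid_idx])
        m = pvals.size
        order = np.argsort(pvals, kind="stable")
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate(
            (pvals[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        adj = np.minimum(adj, 1.0)
        for j, i in enumerate(valid_idx):
            res = results[i]
            results[i] = CorrelationResult(
                res.region_id, res.variable, res.r, res.p, float(adj[j]),
                res.n, res.covariates, res.valid,
            )
    return results


def chi_square_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table; Yates correction optional."""
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    chi2, p, _, _ = sstats.chi2_contingency(t, correction=yates)
    return float(chi2), float(p)


def demographics_table(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Group descriptives (mean ± SD) with two-sample t-tests for continuous
    variables and a Pearson chi-square (no continuity correction) for sex."""
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g_a, g_b = "SZ", "HC"
    a = [r for r in records if r.group == g_a]
    b = [r for r in records if r.group == g_b]

    rows = []
    counts = np.array([
        [sum(r.sex == "M" for r in a), sum(r.sex == "F" for r in a)],
        [sum(r.sex == "M" for r in b), sum(r.sex == "F" for r in b)],
    ])
    chi2, p_sex = chi_square_2x2(counts)
    rows.append({
        "variable": "sex (M/F)",
        f"{g_a}": f"{counts[0, 0]}/{counts[0, 1]}",
        f"{g_b}": f"{counts[1, 0]}/{counts[1, 1]}",
        "test": "chi2", "statistic": chi2, "p": p_sex,
    })

    for var in ("age", "illness_duration", "panss_positive", "panss_negative",
                "panss_general", "panss_total"):
        va = np.array([getattr(r, var) for r in a], dtype=np.float64)
        vb = np.array([getattr(r, var) for r in b], dtype=np.float64)
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        row = {"variable": var}
        row[g_a] = f"{va.mean():.2f} ± {va.std(ddof=1):.2f}" if va.size >= 2 else "—"
        row[g_b] = f"{vb.mean():.2f} ± {vb.std(ddof=1):.2f}" if vb.size >= 2 else "—"
        if va.size >= 2 and vb.size >= 2 and (va.var() + vb.var()) > 0:
            t, p, _ = two_sample_t(va, vb)
            row.update(test="t", statistic=t, p=p)
        else:
            row.update(test="", statistic=np.nan, p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
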