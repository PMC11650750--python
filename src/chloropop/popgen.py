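"""Population-structure statistics for dominant-profile haplotype data.

Implements hierarchical haploid AMOVA (analysis of molecular variance) with
Phi fixation indices and permutation tests, pairwise reef PhiPT, principal
coordinates analysis, binned isolation-by-distance regression, Mantel
tests, thermal Euclidean distances and small exact tests.

AMOVA follows the classic squared-distance decomposition: the sum of
squares of a group equals (1/n) * sum over within-group pairs of squared
inter-individual distances, and variance components are solved from the
expected mean squares of the nested (region / reef / colony) design with
the standard unbalanced-design coefficients. With the default "mismatch01"
haplotype distance (0 if two colonies carry the same dominant profile, 1
otherwise) the statistics depend on the data only through per-group profile
counts, which makes permutation tests cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from chloropop.profiles import DiagnosticPanel


@dataclass(frozen=True)
class ColonyRecord:
    """One sampled colony: reef/region membership, location and profile."""

    colony_id: str
    reef_id: str
    region_id: str
    profile: str
    host_lineage: str | None = None
    x_km: float | None = None
    y_km: float | None = None
    secondary_profile: str | None = None
    minor_fraction: float = 0.0


@dataclass(frozen=True)
class AmovaRow:
    level: str
    df: int
    ss: float
    ms: float
    variance: float
    percent: float


@dataclass
class AmovaResult:
    rows: list[AmovaRow]
    phi: dict[str, float]  # phi_rt, phi_pr, phi_pt (nan when degenerate)
    p_values: dict[str, float]
    n_permutations: int
    seed: int | None
    n: int
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(r.level, r.df, r.ss, r.ms, r.variance, r.percent) for r in self.rows],
            columns=["Source", "df", "SS", "MS", "Est Var", "%"],
        )
        return df

    @property
    def total_ss(self) -> float:
        return sum(r.ss for r in self.rows)


def haplotype_distance(
    profile_i: str,
    profile_j: str,
    mode: str = "mismatch01",
    panel: DiagnosticPanel | None = None,
) -> float:
    """Distance between two dominant profiles.

    mismatch01: 0 if equal else 1. panel_snp_count: number of diagnostic
    panel sites at which the two profiles carry different bases.
    """
    if mode == "mismatch01":
        return 0.0 if profile_i == profile_j else 1.0
    if mode == "panel_snp_count":
        if panel is None:
            raise ValueError("panel_snp_count mode requires a DiagnosticPanel")
        for p in (profile_i, profile_j):
            if p not in panel.profile_bases:
                raise KeyError(f"unknown profile label {p!r}")
        a = panel.profile_bases[profile_i]
        b = panel.profile_bases[profile_j]
        return float(sum(1 for s in panel.site_names if a[s] != b[s]))
    raise ValueError(f"unknown distance mode {mode!r}")


def _profile_sq_distance(profile_ids, mode, panel):
    k = len(profile_ids)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = haplotype_distance(profile_ids[i], profile_ids[j], mode, panel)
            m[i, j] = m[j, i] = d * d
    return m


def _ssd(counts: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Group sum of squares from profile counts.

    SS = (1/n) * sum_{i<j in group} d^2_ij = 0.5 * c' M c / n, broadcast
    over any leading axes of ``counts``.
    """
    n = counts.sum(axis=-1)
    quad = 0.5 * np.einsum("...i,ij,...j->...", counts, m, counts)
    return np.divide(quad, n, out=np.zeros_like(quad, dtype=float), where=n > 0)


def _index_colonies(colonies: Sequence[ColonyRecord]):
    reefs = sorted({c.reef_id for c in colonies})
    regions = sorted({c.region_id for c in colonies})
    profiles = sorted({c.profile for c in colonies})
    reef_idx = {r: i for i, r in enumerate(reefs)}
    region_idx = {g: i for i, g in enumerate(regions)}
    prof_idx = {p: i for i, p in enumerate(profiles)}
    reef_of = np.array([reef_idx[c.reef_id] for c in colonies])
    prof_of = np.array([prof_idx[c.profile] for c in colonies])
    reef_region = {}
    for c in colonies:
        prev = reef_region.setdefault(reef_idx[c.reef_id], region_idx[c.region_id])
        if prev != region_idx[c.region_id]:
            raise ValueError(f"reef {c.reef_id!r} assigned to multiple regions")
    region_of_reef = np.array([reef_region[i] for i in range(len(reefs))])
    return reefs, regions, profiles, reef_of, region_of_reef, prof_of


def _reef_counts(reef_of, prof_of, n_reefs, n_prof):
    counts = np.zeros((n_reefs, n_prof), dtype=np.int64)
    np.add.at(counts, (reef_of, prof_of), 1)
    return counts


def _three_level_components(reef_counts, region_of_reef, m, n_regions):
    """SS, df and variance components of the nested three-level design."""
    n_reefs = reef_counts.shape[0]
    region_counts = np.zeros((n_regions, reef_counts.shape[1]))
    np.add.at(region_counts, region_of_reef, reef_counts)
    total_counts = reef_counts.sum(axis=0)
    n = int(total_counts.sum())
    n_p = reef_counts.sum(axis=1).astype(float)  # per reef
    n_g = region_counts.sum(axis=1).astype(float)  # per region

    ss_total = float(_ssd(total_counts, m))
    ss_wp = float(_ssd(reef_counts, m).sum())
    ss_regions = float(_ssd(region_counts, m).sum())
    ss_ap = ss_regions - ss_wp  # among reefs within regions
    ss_ar = ss_total - ss_regions  # among regions

    df_ar = n_regions - 1
    df_ap = n_reefs - n_regions
    df_wp = n - n_reefs
    if df_ar < 1 or df_ap < 1 or df_wp < 1:
        raise ValueError(
            "degenerate design: need >=2 regions, more reefs than regions, "
            "and more colonies than reefs"
        )

    ms_ar, ms_ap, ms_wp = ss_ar / df_ar, ss_ap / df_ap, ss_wp / df_wp

    # unbalanced-design coefficients for the expected mean squares
    sum_np2_over_ng = float(
        sum((n_p[region_of_reef == g] ** 2).sum() / n_g[g] for g in range(n_regions))
    )
    n_prime = (n - sum_np2_over_ng) / df_ap
    n_dprime = (sum_np2_over_ng - float((n_p**2).sum()) / n) / df_ar
    n_tprime = (n - float((n_g**2).sum()) / n) / df_ar

    var_c = ms_wp
    var_b = (ms_ap - var_c) / n_prime
    var_a = (ms_ar - var_c - n_dprime * var_b) / n_tprime
    return {
        "n": n,
        "ss": (ss_ar, ss_ap, ss_wp),
        "df": (df_ar, df_ap, df_wp),
        "ms": (ms_ar, ms_ap, ms_wp),
        "var": (var_a, var_b, var_c),
    }


def _phi_from_components(var_a, var_b, var_c):
    tot = var_a + var_b + var_c
    phi_rt = var_a / tot if tot > 0 else np.nan
    phi_pt = (var_a + var_b) / tot if tot > 0 else np.nan
    denom = var_b + var_c
    phi_pr = var_b / denom if denom > 0 else np.nan
    return phi_rt, phi_pr, phi_pt


def amova(
    colonies: Sequence[ColonyRecord],
    distance_mode: str = "mismatch01",
    n_perm: int = 999,
    seed: int | None = None,
    panel: DiagnosticPanel | None = None,
    clamp_negative: bool = False,
) -> AmovaResult:
    """Three-level haploid AMOVA (regions / reefs / colonies) on profiles.

    Variance is partitioned among regions, among reefs within regions and
    within reefs; Phi_RT, Phi_PR and Phi_PT are the corresponding fixation
    indices. Permutation p-values use the schemes conventional for each
    statistic (Phi_PT: colonies permuted across all reefs; Phi_PR: colonies
    permuted among reefs within their region; Phi_RT: whole reefs permuted
    among regions) with the +1-corrected estimator
    p = (count >= observed + 1) / (n_perm + 1).

    Negative variance components are reported as computed unless
    ``clamp_negative``; percents use the (optionally clamped) components.
    When all colonies share one profile every SS is 0 and the Phi statistics
    are undefined: they are reported as NaN with ``degenerate=True``.
    """
    if not colonies:
        raise ValueError("no colonies")
    reefs, regions, profiles, reef_of, region_of_reef, prof_of = _index_colonies(
        colonies
    )
    if len(reefs) < 2:
        raise ValueError("AMOVA needs >= 2 reefs")
    m = _profile_sq_distance(profiles, distance_mode, panel)
    reef_counts = _reef_counts(reef_of, prof_of, len(reefs), len(profiles))
    comp = _three_level_components(reef_counts, region_of_reef, m, len(regions))
    var_a, var_b, var_c = comp["var"]
    phi_rt, phi_pr, phi_pt = _phi_from_components(var_a, var_b, var_c)
    degenerate = not np.isfinite(phi_pt)

    shown = [max(v, 0.0) if clamp_negative else v for v in (var_a, var_b, var_c)]
    total_var = sum(shown)
    percents = [100.0 * v / total_var if total_var > 0 else np.nan for v in shown]

    rows = [
        AmovaRow("Among regions", comp["df"][0], comp["ss"][0], comp["ms"][0],
                 shown[0], percents[0]),
        AmovaRow("Among reefs within regions", comp["df"][1], comp["ss"][1],
                 comp["ms"][1], shown[1], percents[1]),
        AmovaRow("Within reefs", comp["df"][2], comp["ss"][2], comp["ms"][2],
                 shown[2], percents[2]),
    ]

    p_values: dict[str, float] = {}
    if n_perm > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        p_values = _amova_permutation_p(
            reef_of, region_of_reef, prof_of, m, len(reefs), len(regions),
            len(profiles), (phi_rt, phi_pr, phi_pt), n_perm, rng,
        )

    return AmovaResult(
        rows=rows,
        phi={"phi_rt": phi_rt, "phi_pr": phi_pr, "phi_pt": phi_pt},
        p_values=p_values,
        n_permutations=n_perm,
        seed=seed,
        n=comp["n"],
        degenerate=degenerate,
    )


def _batch_reef_counts(prof_perm, reef_of, n_reefs, n_prof):
    """Per-permutation reef x profile counts; prof_perm is (B, N)."""
    b = prof_perm.shape[0]
    idx = (
        np.arange(b)[:, None] * (n_reefs * n_prof)
        + reef_of[None, :] * n_prof
        + prof_perm
    )
    flat = np.bincount(idx.ravel(), minlength=b * n_reefs * n_prof)
    return flat.reshape(b, n_reefs, n_prof).astype(float)


def _amova_permutation_p(
    reef_of, region_of_reef, prof_of, m, n_reefs, n_regions, n_prof,
    observed, n_perm, rng,
):
    phi_rt_obs, phi_pr_obs, phi_pt_obs = observed
    n = len(prof_of)
    n_p = np.bincount(reef_of, minlength=n_reefs).astype(float)
    df_ar, df_ap, df_wp = n_regions - 1, n_reefs - n_regions, n - n_reefs

    def batch_phi(prof_perm, region_assign=None):
        """Phi statistics for each permuted profile vector (B, N)."""
        reg = region_of_reef if region_assign is None else region_assign
        rc = _batch_reef_counts(prof_perm, reef_of, n_reefs, n_prof)
        b = rc.shape[0]
        gc = np.zeros((b, n_regions, n_prof))
        for g in range(n_regions):
            gc[:, g] = rc[:, reg == g].sum(axis=1)
        tc = rc.sum(axis=1)
        ss_total = _ssd(tc, m)
        ss_wp = _ssd(rc, m).sum(axis=1)
        ss_regions = _ssd(gc, m).sum(axis=1)
        ms_ar = (ss_total - ss_regions) / df_ar
        ms_ap = (ss_regions - ss_wp) / df_ap
        ms_wp = ss_wp / df_wp
        n_g = np.array([n_p[reg == g].sum() for g in range(n_regions)])
        sum_np2_over_ng = sum(
            (n_p[reg == g] ** 2).sum() / n_g[g] for g in range(n_regions)
        )
        n_prime = (n - sum_np2_over_ng) / df_ap
        n_dprime = (sum_np2_over_ng - (n_p**2).sum() / n) / df_ar
        n_tprime = (n - (n_g**2).sum() / n) / df_ar
        var_c = ms_wp
        var_b = (ms_ap - var_c) / n_prime
        var_a = (ms_ar - var_c - n_dprime * var_b) / n_tprime
        tot = var_a + var_b + var_c
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_rt = np.where(tot > 0, var_a / tot, np.nan)
            phi_pt = np.where(tot > 0, (var_a + var_b) / tot, np.nan)
            denom = var_b + var_c
            phi_pr = np.where(denom > 0, var_b / denom, np.nan)
        return phi_rt, phi_pr, phi_pt

    def perm_p(null, obs):
        null = null[np.isfinite(null)]
        return (int((null >= obs - 1e-12).sum()) + 1) / (n_perm + 1)

    # Phi_PT: permute colonies across everything
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    _, _, phi_pt_null = batch_phi(prof_of[perms])
    # Phi_PR: permute colonies among reefs within regions
    region_of_ind = region_of_reef[reef_of]
    within = np.tile(np.arange(n), (n_perm, 1))
    for g in range(n_regions):
        cols = np.flatnonzero(region_of_ind == g)
        sub = np.argsort(rng.random((n_perm, len(cols))), axis=1)
        within[:, cols] = cols[sub]
    _, phi_pr_null, _ = batch_phi(prof_of[within])
    # Phi_RT: permute whole reefs among regions
    phi_rt_null = np.empty(n_perm)
    reef_counts = _reef_counts(reef_of, prof_of, n_reefs, n_prof)
    for b in range(n_perm):
        assign = region_of_reef[rng.permutation(n_reefs)]
        comp = _three_level_components(reef_counts, assign, m, n_regions)
        phi_rt_null[b] = _phi_from_components(*comp["var"])[0]

    return {
        "phi_pt": perm_p(phi_pt_null, phi_pt_obs),
        "phi_pr": perm_p(phi_pr_null, phi_pr_obs),
        "phi_rt": perm_p(phi_rt_null, phi_rt_obs),
    }


def _two_level_phi(counts: np.ndarray, m: np.ndarray) -> float:
    """Phi_PT of a two-level design from reef x profile counts."""
    n_pops = counts.shape[0]
    n_p = counts.sum(axis=1).astype(float)
    n = float(n_p.sum())
    ss_total = float(_ssd(counts.sum(axis=0), m))
    if ss_total == 0.0:
        return 0.0  # no molecular variation at all: no differentiation
    ss_w = float(_ssd(counts, m).sum())
    df_a, df_w = n_pops - 1, int(n) - n_pops
    if df_w < 1:
        return np.nan
    ms_a = (ss_total - ss_w) / df_a
    ms_w = ss_w / df_w
    n_prime = (n - (n_p**2).sum() / n) / df_a
    var_a = (ms_a - ms_w) / n_prime
    tot = var_a + ms_w
    return var_a / tot if tot > 0 else np.nan


def pairwise_phipt(
    colonies: Sequence[ColonyRecord],
    distance_mode: str = "mismatch01",
    n_perm: int = 0,
    seed: int | None = None,
    panel: DiagnosticPanel | None = None,
    allow_small: bool = False,
    floor_at_zero: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reef-by-reef Phi_PT from two-level AMOVAs on each reef pair.

    Returns (phi matrix, p-value matrix) as DataFrames indexed by reef.
    Negative Phi is reported as computed unless ``floor_at_zero``. Reefs
    with < 2 colonies are excluded unless ``allow_small``.
    """
    reefs, regions, profiles, reef_of, _, prof_of = _index_colonies(colonies)
    if len(reefs) < 2:
        raise ValueError("need >= 2 reefs")
    m = _profile_sq_distance(profiles, distance_mode, panel)
    counts = _reef_counts(reef_of, prof_of, len(reefs), len(profiles))
    keep = [i for i, r in enumerate(reefs)
            if allow_small or counts[i].sum() >= 2]
    kept = [reefs[i] for i in keep]
    rng = np.random.default_rng(seed)

    phi = pd.DataFrame(0.0, index=kept, columns=kept)
    pvals = pd.DataFrame(np.nan, index=kept, columns=kept)
    for ai in range(len(keep)):
        for bi in range(ai + 1, len(keep)):
            pair = counts[[keep[ai], keep[bi]]]
            val = _two_level_phi(pair.astype(float), m)
            if floor_at_zero and np.isfinite(val):
                val = max(val, 0.0)
            phi.iloc[ai, bi] = phi.iloc[bi, ai] = val
            if n_perm > 0 and np.isfinite(val):
                labels = np.repeat([0, 1], pair.sum(axis=1))
                profs = np.concatenate(
                    [np.repeat(np.arange(len(profiles)), pair[r]) for r in (0, 1)]
                )
                null = np.empty(n_perm)
                for b in range(n_perm):
                    shuffled = profs[rng.permutation(len(profs))]
                    c = np.zeros((2, len(profiles)))
                    np.add.at(c, (labels, shuffled), 1)
                    null[b] = _two_level_phi(c, m)
                null = null[np.isfinite(null)]
                p = (int((null >= val - 1e-12).sum()) + 1) / (n_perm + 1)
                pvals.iloc[ai, bi] = pvals.iloc[bi, ai] = p
    return phi, pvals


@dataclass
class PcoaResult:
    coordinates: np.ndarray  # (items, positive axes)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    percent: np.ndarray  # percent of positive-eigenvalue variance per axis
    labels: list[str] | None = None


def pcoa(distances: np.ndarray, labels: Sequence[str] | None = None) -> PcoaResult:
    """Principal coordinates analysis via Gower double-centering.

    B = -1/2 J D^2 J is eigendecomposed; coordinates are eigenvectors
    scaled by sqrt(eigenvalue) for positive eigenvalues, and each axis'
    percent is its eigenvalue over the positive-eigenvalue total.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * abs(eigval).max()) if n else 0.0
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    percent = 100.0 * eigval[pos] / eigval[pos].sum()
    return PcoaResult(
        coordinates=coords,
        eigenvalues=eigval[pos],
        percent=percent,
        labels=list(labels) if labels is not None else None,
    )


def default_ibd_bins(max_km: float = 88.0) -> np.ndarray:
    """Bin edges 0, 1, 2, then 2-km steps up to (at least) ``max_km``."""
    edges = [0.0, 1.0, 2.0]
    while edges[-1] < max_km:
        edges.append(edges[-1] + 2.0)
    return np.array(edges)


@dataclass
class IbdResult:
    bin_edges: np.ndarray
    bin_mid: np.ndarray  # midpoints of non-empty bins
    bin_mean: np.ndarray  # mean genetic distance per non-empty bin
    bin_count: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def ibd_regression(
    genetic_d: np.ndarray,
    geographic_d_km: np.ndarray,
    bin_edges: np.ndarray | None = None,
) -> IbdResult:
    """Isolation-by-distance regression on distance-binned means.

    Reef pairs (i<j, geographic distance > 0) are assigned to half-open
    bins (lower, upper]; the mean genetic distance of each non-empty bin is
    regressed on the bin midpoint by ordinary least squares.
    """
    gd = np.asarray(genetic_d, dtype=float)
    km = np.asarray(geographic_d_km, dtype=float)
    if gd.shape != km.shape or gd.ndim != 2 or gd.shape[0] != gd.shape[1]:
        raise ValueError("matrices must be square and conformable")
    iu = np.triu_indices(gd.shape[0], k=1)
    g, k = gd[iu], km[iu]
    keep = k > 0  # same-reef / zero-distance pairs excluded
    g, k = g[keep], k[keep]
    if bin_edges is None:
        bin_edges = default_ibd_bins(float(k.max()))
    edges = np.asarray(bin_edges, dtype=float)
    if k.max() > edges[-1]:
        raise ValueError("bin edges do not cover the largest distance")
    which = np.searchsorted(edges, k, side="left") - 1  # (lower, upper]
    mids, means, counts = [], [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        mids.append((edges[b] + edges[b + 1]) / 2.0)
        means.append(float(g[sel].mean()))
        counts.append(int(sel.sum()))
    if len(mids) < 3:
        raise ValueError("too few non-empty bins for a regression")
    mids_a, means_a = np.array(mids), np.array(means)
    if np.allclose(means_a, means_a[0]):
        slope, intercept, r, p = 0.0, float(means_a[0]), 0.0, 1.0
    else:
        res = stats.linregress(mids_a, means_a)
        slope, intercept, r, p = res.slope, res.intercept, res.rvalue, res.pvalue
    return IbdResult(
        bin_edges=edges,
        bin_mid=mids_a,
        bin_mean=means_a,
        bin_count=np.array(counts),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r**2),
        p_value=float(p),
    )


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None


def mantel(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test: Pearson r of lower-triangle entries, one-tailed
    (positive association) permutation p by joint row/column shuffles of
    the second matrix; p = (count >= observed + 1) / (n_perm + 1)."""
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square with matching labels")
    n = a.shape[0]
    il = np.tril_indices(n, k=-1)
    x = a[il]

    def corr(y):
        xm, ym = x - x.mean(), y - y.mean(axis=-1, keepdims=True)
        denom = np.sqrt((xm**2).sum() * (ym**2).sum(axis=-1))
        return (ym @ xm) / denom

    r = float(corr(b[il][None, :])[0])
    p = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        bp = b[perms[:, :, None], perms[:, None, :]]
        null = corr(bp[:, il[0], il[1]])
        p = (int((null >= r - 1e-12).sum()) + 1) / (n_perm + 1)
    return MantelResult(r=r, p_value=float(p), n_permutations=n_perm, seed=seed)


def thermal_distance(
    reefs: Sequence[tuple[float, float]] | pd.DataFrame,
    standardize: bool = False,
) -> np.ndarray:
    """Euclidean distances in (mean temperature, SD of daily fluctuation)
    space; optionally z-standardize each dimension first."""
    if isinstance(reefs, pd.DataFrame):
        arr = reefs[["mean_temp", "sd_daily_temp"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(reefs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("need (mean_temp, sd_daily_temp) per reef")
    if np.isnan(arr).any():
        raise ValueError("missing thermal field")
    if standardize:
        sd = arr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        arr = (arr - arr.mean(axis=0)) / sd
    return squareform(pdist(arr))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (probability-based:
    the sum of hypergeometric probabilities of tables as or less probable
    than the observed one)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("cell counts must be integers")
        t = np.round(t).astype(int)
    if t.sum() == 0:
        raise ValueError("table has no observations")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence (no continuity correction).

    Rows/columns with zero margins are dropped with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        t = t[row_ok][:, col_ok]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need >= 2 rows and columns with positive margins")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(dof), float(p)


def reef_profile_counts(colonies: Sequence[ColonyRecord]) -> pd.DataFrame:
    """Reef x profile counts of dominant profiles."""
    df = pd.DataFrame(
        [(c.reef_id, c.profile) for c in colonies], columns=["reef", "profile"]
    )
    return pd.crosstab(df["reef"], df["profile"])


def reef_genetic_distance(
    colonies: Sequence[ColonyRecord],
    method: str = "phipt",
    distance_mode: str = "mismatch01",
    panel: DiagnosticPanel | None = None,
    floor_at_zero: bool = True,
) -> pd.DataFrame:
    """Reef-level genetic distance matrix from dominant-profile composition.

    ``phipt``: pairwise Phi_PT (floored at 0 by default so the result is a
    proper dissimilarity). ``frequency``: Euclidean distance between reef
    profile-frequency vectors.
    """
    if method == "phipt":
        phi, _ = pairwise_phipt(
            colonies, distance_mode=distance_mode, panel=panel,
            floor_at_zero=floor_at_zero,
        )
        if floor_at_zero:
            phi = phi.fillna(0.0)
        return phi
    if method == "frequency":
        counts = reef_profile_counts(colonies)
        freqs = counts.div(counts.sum(axis=1), axis=0).to_numpy()
        return pd.DataFrame(
            squareform(pdist(freqs)), index=counts.index, columns=counts.index
        )
    raise ValueError(f"unknown method {method!r}")


def reef_geographic_distance(
    colonies: Sequence[ColonyRecord],
) -> pd.DataFrame:
    """Pairwise reef distances in km from colony x/y coordinates."""
    coords: dict[str, tuple[float, float]] = {}
    for c in colonies:
        if c.x_km is None or c.y_km is None:
            raise ValueError(f"colony {c.colony_id!r} lacks coordinates")
        coords.setdefault(c.reef_id, (c.x_km, c.y_km))
    reefs = sorted(coords)
    arr = np.array([coords[r] for r in reefs])
    return pd.DataFrame(squareform(pdist(arr)), index=reefs, columns=reefs)
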