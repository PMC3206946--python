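"""Binary Bray-Curtis dissimilarity, NMDS ordination, and PERMANOVA.

Community structure among sampling units (quadrats or
minimal-sampling-area-sized replicates) is summarised by the binary
Bray-Curtis dissimilarity (identical to the Sorensen dissimilarity on
presence/absence data), visualised by nonmetric multidimensional
scaling, and partitioned by permutational multivariate ANOVA
(PERMANOVA):

* one-way, for fixed-factor comparisons (e.g. between two assemblages),
  tested by unrestricted permutation of raw sampling units;
* two-factor nested random (Region, and Site nested in Region), the
  design used for spatial-variability surveys.  The region pseudo-F is
  MS_Region / MS_Site(Region) per the random nested model; significance
  is assessed by permuting intact sites across regions for the region
  term and units within regions for the site term (an exchangeability-
  based reading of restricted permutation under the reduced model; an
  ``unrestricted`` scheme is available for comparison).

Variance components are estimated from the expected-mean-square ladder
with Searle averaged coefficients (exact for balanced designs) and
reported both in squared-dissimilarity units and, via their square
roots, on the percentage Bray-Curtis dissimilarity scale.  Negative
components are reported raw and flagged, never truncated.

Distance matrices use :class:`skbio.DistanceMatrix` as the container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .incidence import ValidationError


# ---------------------------------------------------------------------------
# dissimilarities
# ---------------------------------------------------------------------------

def bray_curtis_binary(x: Sequence[int], y: Sequence[int]) -> float:
    """Sorensen (binary Bray-Curtis) dissimilarity ``1 - 2a / (2a + b + c)``.

    ``a`` counts shared presences, ``b`` and ``c`` the presences unique
    to each unit.  Undefined when both units are empty.
    """
    xb = np.asarray(x, dtype=bool)
    yb = np.asarray(y, dtype=bool)
    if xb.shape != yb.shape:
        raise ValidationError("incidence vectors differ in length")
    shared = int(np.sum(xb & yb))
    total = int(xb.sum() + yb.sum())
    if total == 0:
        raise ValidationError(
            "Bray-Curtis dissimilarity is undefined for two empty units"
        )
    return 1.0 - 2.0 * shared / total


def pairwise_braycurtis(
    x: np.ndarray, ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Binary Bray-Curtis distance matrix among the rows of a 0/1 matrix."""
    xb = np.asarray(x, dtype=bool)
    rowsums = xb.sum(axis=1)
    if np.any(rowsums == 0):
        empty = np.nonzero(rowsums == 0)[0]
        raise ValidationError(
            f"unit(s) {empty.tolist()} have no taxa; Bray-Curtis undefined for empty pairs"
        )
    shared = (xb.astype(np.int64) @ xb.T.astype(np.int64)).astype(float)
    denom = rowsums[:, None] + rowsums[None, :]
    d = 1.0 - 2.0 * shared / denom
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=[str(i) for i in ids] if ids is not None else None)


def pairwise_euclidean(x: np.ndarray, ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Euclidean distance matrix (mainly for univariate cross-checks)."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(np.atleast_2d(np.asarray(x, dtype=float))))
    return DistanceMatrix(d, ids=[str(i) for i in ids] if ids is not None else None)


def vc_to_diss(vc: float) -> float:
    """Variance component on the dissimilarity (%) scale: sqrt(VC).

    Negative components (possible under the ANOVA estimator) are
    returned as ``-sqrt(|VC|)``, keeping the sign as the flag.
    """
    return float(np.sign(vc) * np.sqrt(abs(vc)))


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    seed: int
    restarts: int
    converged: bool
    degenerate: bool = False
    ids: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        frame = pd.DataFrame(self.coordinates, columns=cols)
        if self.ids:
            frame.insert(0, "id", list(self.ids))
        return frame


def nmds(
    dm: DistanceMatrix,
    ndim: int = 2,
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Nonmetric MDS minimising Kruskal stress-1; best of ``restarts`` kept.

    A distance matrix whose off-diagonal entries are all equal carries
    no rank information: any configuration fits perfectly, so it is
    flagged degenerate with stress 0.
    """
    d = dm.data
    n = d.shape[0]
    if n < ndim + 1:
        raise ValidationError(f"need at least {ndim + 1} units for {ndim}-D NMDS")
    off = d[np.triu_indices(n, k=1)]
    if np.ptp(off) == 0:
        coords = MDS(
            n_components=ndim,
            metric="precomputed",
            normalized_stress=False,
            random_state=seed,
            n_init=1,
            init="random",
        ).fit_transform(d)
        return OrdinationResult(
            coordinates=coords,
            stress=0.0,
            seed=seed,
            restarts=restarts,
            converged=True,
            degenerate=True,
            ids=tuple(dm.ids),
        )
    model = MDS(
        n_components=ndim,
        metric_mds=False,
        metric="precomputed",
        n_init=restarts,
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
        init="random",
    )
    coords = model.fit_transform(d)
    return OrdinationResult(
        coordinates=coords,
        stress=float(model.stress_),
        seed=seed,
        restarts=restarts,
        converged=bool(model.n_iter_ < max_iter),
        ids=tuple(dm.ids),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaTable:
    """Per-source partition of a distance matrix, PRIMER-style.

    ``table`` rows: one per source plus Total, with columns
    df, SS, MS, pseudo_F, p_perm, VC, bc_diss.
    """

    table: pd.DataFrame
    n_perm: int
    seed: int | None = None
    degenerate: bool = False

    def row(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _codes(labels: Sequence) -> tuple[np.ndarray, list]:
    codes, uniques = pd.factorize(np.asarray(labels), sort=True)
    return codes.astype(np.int64), list(uniques)


def _grouped_within_ss(d2: np.ndarray, label_matrix: np.ndarray, n_groups: int) -> np.ndarray:
    """Within-group SS for each row of permuted integer labels.

    SS_within = sum_g (1 / n_g) * sum_{i<j in g} d2_ij, vectorised over
    permutations via masked matrix products.
    """
    n_perm = label_matrix.shape[0]
    ss = np.zeros(n_perm)
    for g in range(n_groups):
        mask = (label_matrix == g).astype(float)
        counts = mask.sum(axis=1)
        pair_sums = ((mask @ d2) * mask).sum(axis=1)  # = 2 * sum_{i<j in g} d2
        with np.errstate(invalid="ignore", divide="ignore"):
            ss += np.where(counts > 0, pair_sums / (2.0 * np.maximum(counts, 1)), 0.0)
    return ss


def _perm_pvalue(f_perm: np.ndarray, f_obs: float) -> float:
    # (count >= observed + 1) / (B + 1): standard bias-avoiding estimator
    return float((np.sum(f_perm >= f_obs - 1e-12) + 1) / (len(f_perm) + 1))


def permanova_oneway(
    dm: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> PermanovaTable:
    """One-way PERMANOVA with unrestricted permutation of raw units.

    With a Euclidean distance matrix on univariate data the pseudo-F is
    exactly the classical one-way ANOVA F.  The group variance component
    uses the ANOVA estimator with the averaged group-size multiplier
    n0 = (N - sum n_g^2 / N) / (g - 1).
    """
    d2 = dm.data.astype(float) ** 2
    codes, levels = _codes(groups)
    n = d2.shape[0]
    if len(codes) != n:
        raise ValidationError(
            f"{len(codes)} group labels for {n} units in the distance matrix"
        )
    g = len(levels)
    if g < 2:
        raise ValidationError("need at least 2 groups")
    counts = np.bincount(codes, minlength=g).astype(float)

    ss_total = d2.sum() / (2.0 * n)
    ss_within = float(_grouped_within_ss(d2, codes[None, :], g)[0])
    ss_between = ss_total - ss_within
    df_between, df_within = g - 1, n - g
    if df_within < 1:
        raise ValidationError("no residual degrees of freedom (one unit per group)")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    degenerate = ss_total <= 1e-12
    if degenerate or ms_within == 0:
        f_obs = float("nan") if degenerate else float("inf")
    else:
        f_obs = ms_between / ms_within

    p = float("nan")
    if n_perm >= 1 and not degenerate:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
        ss_w_perm = _grouped_within_ss(d2, perms, g)
        ss_b_perm = ss_total - ss_w_perm
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (ss_b_perm / df_between) / (ss_w_perm / df_within)
        p = _perm_pvalue(f_perm, f_obs)

    n0 = (n - np.sum(counts**2) / n) / df_between
    vc_between = (ms_between - ms_within) / n0
    vc_within = ms_within

    table = pd.DataFrame(
        {
            "source": ["Groups", "Residual", "Total"],
            "df": [df_between, df_within, n - 1],
            "SS": [ss_between, ss_within, ss_total],
            "MS": [ms_between, ms_within, np.nan],
            "pseudo_F": [f_obs, np.nan, np.nan],
            "p_perm": [p, np.nan, np.nan],
            "VC": [vc_between, vc_within, np.nan],
            "bc_diss": [vc_to_diss(vc_between), vc_to_diss(vc_within), np.nan],
        }
    )
    return PermanovaTable(table=table, n_perm=n_perm, seed=seed, degenerate=degenerate)


def _nested_ss(d2: np.ndarray, region_codes: np.ndarray, site_codes: np.ndarray):
    n = d2.shape[0]
    n_regions = region_codes.max() + 1
    n_sites = site_codes.max() + 1
    ss_total = d2.sum() / (2.0 * n)
    ss_within_region = float(_grouped_within_ss(d2, region_codes[None, :], n_regions)[0])
    ss_resid = float(_grouped_within_ss(d2, site_codes[None, :], n_sites)[0])
    ss_region = ss_total - ss_within_region
    ss_site = ss_within_region - ss_resid
    return ss_total, ss_region, ss_site, ss_resid, ss_within_region


def _searle_coefficients(region_codes: np.ndarray, site_codes: np.ndarray):
    """Averaged EMS multipliers for the unbalanced two-level nested random model.

    E[MS_site]   = sigma_e^2 + c1 * sigma_site^2
    E[MS_region] = sigma_e^2 + c2 * sigma_site^2 + c3 * sigma_region^2

    For a balanced design (n units per site, s sites per region) these
    reduce to c1 = c2 = n and c3 = n * s.
    """
    n = len(region_codes)
    regions = np.unique(region_codes)
    r = len(regions)
    site_sizes = np.bincount(site_codes).astype(float)
    region_sizes = np.bincount(region_codes).astype(float)
    region_of_site = np.full(site_sizes.shape, -1, dtype=int)
    for s_code in range(len(site_sizes)):
        units = np.nonzero(site_codes == s_code)[0]
        region_of_site[s_code] = region_codes[units[0]]

    sum_sq_by_region = np.zeros(r)
    for s_code, sz in enumerate(site_sizes):
        sum_sq_by_region[region_of_site[s_code]] += sz**2
    term = np.sum(sum_sq_by_region / region_sizes)

    df_site = len(site_sizes) - r
    df_region = r - 1
    c1 = (n - term) / df_site
    c2 = (term - np.sum(site_sizes**2) / n) / df_region
    c3 = (n - np.sum(region_sizes**2) / n) / df_region
    return c1, c2, c3, region_of_site


def permanova_nested(
    dm: DistanceMatrix,
    region: Sequence,
    site: Sequence,
    n_perm: int = 9999,
    seed: int | None = 0,
    scheme: str = "residual",
) -> PermanovaTable:
    """Two-factor nested PERMANOVA: random Region, random Site(Region).

    pseudo-F_Region = MS_Region / MS_Site(Region);
    pseudo-F_Site = MS_Site(Region) / MS_Residual.

    ``scheme='residual'`` (default) permutes intact sites across regions
    for the region test and units within regions for the site test;
    ``scheme='unrestricted'`` permutes raw units for both.  Variance
    components come from the EMS ladder with Searle averaged
    multipliers and are reported raw (negative values flagged by sign
    in ``bc_diss``).
    """
    if scheme not in ("residual", "unrestricted"):
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    d2 = dm.data.astype(float) ** 2
    n = d2.shape[0]
    region_codes, region_levels = _codes(region)
    if len(region_codes) != n:
        raise ValidationError("label length does not match distance matrix")
    # key sites on (region, site) so every site maps to exactly one region
    site_keys = [f"{rc}::{s}" for rc, s in zip(region_codes, np.asarray(site))]
    site_codes, site_levels = _codes(site_keys)

    r = len(region_levels)
    n_sites = len(site_levels)
    sites_per_region = np.zeros(r, dtype=int)
    for key in site_levels:
        sites_per_region[int(key.split("::", 1)[0])] += 1
    if r < 2:
        raise ValidationError("need at least 2 regions")
    if np.any(sites_per_region < 2):
        lonely = [region_levels[i] for i in np.nonzero(sites_per_region < 2)[0]]
        raise ValidationError(
            f"region(s) {lonely} have a single site: the region test is undefined; "
            "pool these sites or drop the region level"
        )

    df_region = r - 1
    df_site = n_sites - r
    df_resid = n - n_sites
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom (one unit per site)")

    ss_total, ss_region, ss_site, ss_resid, _ = _nested_ss(d2, region_codes, site_codes)
    ms_region = ss_region / df_region
    ms_site = ss_site / df_site
    ms_resid = ss_resid / df_resid
    f_region = ms_region / ms_site if ms_site > 0 else float("nan")
    f_site = ms_site / ms_resid if ms_resid > 0 else float("nan")

    c1, c2, c3, region_of_site = _searle_coefficients(region_codes, site_codes)
    vc_resid = ms_resid
    vc_site = (ms_site - ms_resid) / c1
    vc_region = (ms_region - ms_resid - c2 * vc_site) / c3

    p_region = p_site = float("nan")
    if n_perm >= 1:
        rng = np.random.default_rng(seed)
        p_region = _region_test(
            d2, region_codes, site_codes, region_of_site,
            df_region, df_site, ss_total, ss_resid, f_region, n_perm, rng, scheme,
        )
        p_site = _site_test(
            d2, region_codes, site_codes,
            df_site, df_resid, ss_total, f_site, n_perm, rng, scheme,
        )

    table = pd.DataFrame(
        {
            "source": ["Region", "Site(Region)", "Residual", "Total"],
            "df": [df_region, df_site, df_resid, n - 1],
            "SS": [ss_region, ss_site, ss_resid, ss_total],
            "MS": [ms_region, ms_site, ms_resid, np.nan],
            "pseudo_F": [f_region, f_site, np.nan, np.nan],
            "p_perm": [p_region, p_site, np.nan, np.nan],
            "VC": [vc_region, vc_site, vc_resid, np.nan],
            "bc_diss": [vc_to_diss(vc_region), vc_to_diss(vc_site), vc_to_diss(vc_resid), np.nan],
        }
    )
    return PermanovaTable(table=table, n_perm=n_perm, seed=seed)


def _region_test(
    d2, region_codes, site_codes, region_of_site,
    df_region, df_site, ss_total, ss_resid, f_obs, n_perm, rng, scheme,
):
    n = d2.shape[0]
    n_regions = region_codes.max() + 1
    if scheme == "unrestricted":
        perms = rng.permuted(np.tile(region_codes, (n_perm, 1)), axis=1)
    else:
        # permute intact sites across regions: shuffle the site -> region map
        perms = np.empty((n_perm, n), dtype=np.int64)
        for b in range(n_perm):
            shuffled = rng.permutation(region_of_site)
            perms[b] = shuffled[site_codes]
    ss_wr_perm = _grouped_within_ss(d2, perms, n_regions)
    ss_region_perm = ss_total - ss_wr_perm
    ss_site_perm = ss_wr_perm - ss_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_region_perm / df_region) / (ss_site_perm / df_site)
    return _perm_pvalue(f_perm, f_obs)


def _site_test(
    d2, region_codes, site_codes,
    df_site, df_resid, ss_total, f_obs, n_perm, rng, scheme,
):
    n = d2.shape[0]
    n_regions = region_codes.max() + 1
    n_sites = site_codes.max() + 1
    if scheme == "unrestricted":
        perms = rng.permuted(np.tile(site_codes, (n_perm, 1)), axis=1)
        region_label_matrix = None
    else:
        # permute unit -> site assignment within each region
        perms = np.tile(site_codes, (n_perm, 1))
        for g in range(n_regions):
            idx = np.nonzero(region_codes == g)[0]
            block = rng.permuted(np.tile(site_codes[idx], (n_perm, 1)), axis=1)
            perms[:, idx] = block
    ss_resid_perm = _grouped_within_ss(d2, perms, n_sites)
    if scheme == "unrestricted":
        # region grouping implied by permuted site labels
        site_to_region = np.empty(n_sites, dtype=np.int64)
        for s_code in range(n_sites):
            site_to_region[s_code] = region_codes[np.nonzero(site_codes == s_code)[0][0]]
        region_perms = site_to_region[perms]
        ss_wr_perm = _grouped_within_ss(d2, region_perms, n_regions)
    else:
        ss_wr = float(_grouped_within_ss(d2, region_codes[None, :], n_regions)[0])
        ss_wr_perm = np.full(len(perms), ss_wr)
    ss_site_perm = ss_wr_perm - ss_resid_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_site_perm / df_site) / (ss_resid_perm / df_resid)
    return _perm_pvalue(f_perm, f_obs)
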