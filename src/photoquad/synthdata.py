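"""Synthetic patchy-community generator for pipeline testing.

Benthic communities on coralligenous outcrops are spatially patchy:
each species occupies clumps of neighbouring quadrats rather than an
independent scatter.  The generator emulates this with one thresholded
Gaussian random field per species on the quadrat lattice:

* a white-noise field is smoothed with a Gaussian kernel whose width
  (``patchiness``, in quadrat units) sets the spatial correlation
  length, then renormalised to unit marginal variance;
* the field is thresholded at the normal quantile of the species'
  target occupancy, so the marginal occupancy probability is exact by
  construction while the spatial arrangement is clumped;
* ``patchiness = 0`` degenerates to independent Bernoulli occupancy per
  quadrat, the exchangeable null under which contiguous and randomized
  species-area curves have the same expectation.

Per-species occupancy probabilities follow a logit-normal distribution
(many rare species, a few common ones), the qualitative shape of
incidence frequency distributions in these assemblages.

A hierarchical wrapper emulates the survey design the toolkit targets:
3 regions x 2-3 sites per region, one contiguous plot per site (default
8 x 8 quadrats, i.e. 64, inside the 44-93 range of real plots), with
species turnover injected at the region and site levels by making a
fraction of the pool exclusive to one region (or site).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit, ndtri

from .incidence import IncidenceGrid, ValidationError, boustrophedon_order


@dataclass
class CommunityConfig:
    """Parameters of one simulated plot.

    Defaults emulate a single coralligenous plot: 64 contiguous 25-cm
    quadrats, a pool of 80 taxa with logit-normal occupancy, and a
    correlation length of 2 quadrats.
    """

    s_pool: int = 80
    grid_rows: int = 8
    grid_cols: int = 8
    side_cm: float = 25.0
    patchiness: float = 2.0
    logit_mean: float = -1.5
    logit_sd: float = 1.2
    occupancy: np.ndarray | None = None  # explicit per-species probabilities
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_pool < 1:
            raise ValidationError("s_pool must be >= 1")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValidationError("grid dimensions must be positive")
        if self.patchiness < 0:
            raise ValidationError("patchiness must be >= 0")
        if self.occupancy is not None:
            occ = np.asarray(self.occupancy, dtype=float)
            if occ.shape != (self.s_pool,):
                raise ValidationError("occupancy must have one probability per species")
            if np.any((occ <= 0) | (occ >= 1)):
                raise ValidationError("occupancy probabilities must lie in (0, 1)")
            self.occupancy = occ


def sample_occupancy(cfg: CommunityConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-species occupancy probabilities (explicit, or logit-normal draws)."""
    if cfg.occupancy is not None:
        return cfg.occupancy
    return expit(rng.normal(cfg.logit_mean, cfg.logit_sd, size=cfg.s_pool))


def _field_norm(shape: tuple[int, int], sigma: float) -> float:
    """SD of a unit-impulse response: rescales the smoothed field to unit variance."""
    impulse = np.zeros(shape)
    impulse[shape[0] // 2, shape[1] // 2] = 1.0
    kernel = gaussian_filter(impulse, sigma, mode="wrap")
    return float(np.sqrt(np.sum(kernel**2)))


def gaussian_field(
    shape: tuple[int, int], corr_len: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Gaussian field with unit marginal variance on a torus lattice."""
    white = rng.standard_normal(shape)
    if corr_len <= 0:
        return white
    smooth = gaussian_filter(white, corr_len, mode="wrap")
    return smooth / _field_norm(shape, corr_len)


def simulate_grid(
    cfg: CommunityConfig,
    rng: np.random.Generator | None = None,
    occupancy: np.ndarray | None = None,
    taxa: Sequence[str] | None = None,
    **metadata,
) -> IncidenceGrid:
    """Simulate one plot as an :class:`IncidenceGrid`.

    Species i occupies the quadrats where its Gaussian field exceeds the
    normal quantile of ``1 - p_i``, giving exact marginal occupancy and
    ``patchiness``-long clumps.  Quadrats are ordered along a
    boustrophedon (serpentine) photographing path.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    probs = occupancy if occupancy is not None else sample_occupancy(cfg, rng)
    shape = (cfg.grid_rows, cfg.grid_cols)
    occ = np.empty((cfg.grid_rows * cfg.grid_cols, cfg.s_pool), dtype=np.uint8)
    for i, p in enumerate(probs):
        if p <= 0:
            occ[:, i] = 0
            continue
        z = gaussian_field(shape, cfg.patchiness, rng)
        occ[:, i] = (z > ndtri(1.0 - p)).ravel().astype(np.uint8)
    rows, cols = np.divmod(np.arange(cfg.grid_rows * cfg.grid_cols), cfg.grid_cols)
    order = boustrophedon_order(rows, cols)
    names = tuple(taxa) if taxa is not None else tuple(
        f"sp{i:03d}" for i in range(cfg.s_pool)
    )
    return IncidenceGrid(
        incidence=occ[order],
        taxa=names,
        row=rows[order],
        col=cols[order],
        side_cm=cfg.side_cm,
        **metadata,
    )


@dataclass
class HierarchyConfig:
    """Region/site survey hierarchy wrapped around :class:`CommunityConfig`.

    ``region_turnover`` (``site_turnover``) is the fraction of the
    species pool that is exclusive to a single random region (site)
    instead of shared; larger values raise between-region (between-site)
    Bray-Curtis dissimilarity.
    """

    n_regions: int = 3
    sites_per_region: int = 3
    replicates_per_site: int = 3
    region_turnover: float = 0.6
    site_turnover: float = 0.15
    base: CommunityConfig = field(default_factory=CommunityConfig)
    assemblage: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.sites_per_region < 1 or self.replicates_per_site < 1:
            raise ValidationError("hierarchy counts must be >= 1")
        for name in ("region_turnover", "site_turnover"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


def simulate_hierarchy(cfg: HierarchyConfig) -> list[IncidenceGrid]:
    """Simulate one plot per site across the region/site hierarchy.

    A global pool of ``base.s_pool`` species gets global occupancy
    probabilities; species availability is then restricted: each species
    is region-exclusive with probability ``region_turnover`` and (when
    available in a region) site-exclusive with probability
    ``site_turnover``.  All grids share the full taxon list so they can
    enter one community matrix.
    """
    rng = np.random.default_rng(cfg.base.seed)
    probs = sample_occupancy(cfg.base, rng)
    s = cfg.base.s_pool

    region_excl = rng.random(s) < cfg.region_turnover
    region_home = rng.integers(cfg.n_regions, size=s)
    grids: list[IncidenceGrid] = []
    for ri in range(cfg.n_regions):
        in_region = ~region_excl | (region_home == ri)
        site_excl = rng.random(s) < cfg.site_turnover
        site_home = rng.integers(cfg.sites_per_region, size=s)
        for si in range(cfg.sites_per_region):
            available = in_region & (~site_excl | (site_home == si))
            local = np.where(available, probs, 0.0)
            grid = simulate_grid(
                cfg.base,
                rng=rng,
                occupancy=local,
                plot_id=f"R{ri + 1}S{si + 1}",
                site=f"R{ri + 1}-S{si + 1}",
                region=f"R{ri + 1}",
                assemblage=cfg.assemblage,
            )
            grids.append(grid)
    return grids


def hierarchy_replicates(
    cfg: HierarchyConfig, block_rows: int = 2, block_cols: int = 4
):
    """Simulate the hierarchy and aggregate each plot into MSA-sized replicates.

    Returns one concatenated replicate table (pandas DataFrame), trimmed
    to ``replicates_per_site`` blocks per site.
    """
    import pandas as pd

    from .accumulation import aggregate_blocks

    tables = []
    for grid in simulate_hierarchy(cfg):
        blocks = aggregate_blocks(grid, block_rows=block_rows, block_cols=block_cols)
        if len(blocks) < cfg.replicates_per_site:
            raise ValidationError(
                f"plot {grid.plot_id} yields {len(blocks)} blocks < "
                f"replicates_per_site={cfg.replicates_per_site}"
            )
        tables.append(blocks.iloc[: cfg.replicates_per_site])
    return pd.concat(tables, ignore_index=True)
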