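"""Species-accumulation curves, sampling-effort estimation and block aggregation.

Two flavours of species-area curve are produced from a plot of
contiguous quadrats:

* **contiguous** — spatially explicit: for each sample size *n* the mean
  (and SD) of union richness over every run of *n* consecutive quadrats
  in acquisition order.  This respects the spatial arrangement of the
  community and is the curve from which minimal sampling areas are
  derived.
* **randomized** — sample-based rarefaction: quadrat order is permuted
  (999 permutations by default) and richness of the first *n* quadrats
  is averaged, ignoring spatial arrangement.  Its exact expectation is
  the classical hypergeometric rarefaction formula, available here as
  :func:`rarefaction_expectation`.

In patchy communities the randomized curve sits above the contiguous one
at intermediate *n*: combining scattered quadrats accumulates species
faster than enlarging one contiguous area.

The module also tiles a plot into non-overlapping blocks of quadrats
(minimal-sampling-area-sized replicates, 2 rows by 4 columns by default)
and evaluates richness over combinations of such replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .incidence import IncidenceGrid, ValidationError

SD_DDOF = 0  # population SD over the evaluated combinations


@dataclass
class SpeciesAreaCurve:
    """Mean richness vs. area series from contiguous or randomized accumulation."""

    n: np.ndarray
    area_cm2: np.ndarray
    mean_s: np.ndarray
    sd_s: np.ndarray
    n_combos: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        self.area_cm2 = np.asarray(self.area_cm2, dtype=float)
        self.mean_s = np.asarray(self.mean_s, dtype=float)
        self.sd_s = np.asarray(self.sd_s, dtype=float)
        self.n_combos = np.asarray(self.n_combos, dtype=int)
        if not np.all(np.diff(self.n) > 0):
            raise ValidationError("curve sample sizes must be strictly increasing")

    @property
    def total_richness(self) -> float:
        return float(self.mean_s[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n,
                "area_cm2": self.area_cm2,
                "mean_S": self.mean_s,
                "sd_S": self.sd_s,
                "n_combos": self.n_combos,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, mode: str = "unknown") -> "SpeciesAreaCurve":
        return cls(
            n=frame["n"].to_numpy(),
            area_cm2=frame["area_cm2"].to_numpy(),
            mean_s=frame["mean_S"].to_numpy(),
            sd_s=frame["sd_S"].to_numpy(),
            n_combos=frame["n_combos"].to_numpy(),
            mode=mode,
        )


def contiguous_windows(n_quadrats: int, window: int) -> list[tuple[int, ...]]:
    """All runs of ``window`` consecutive acquisition indices; N - n + 1 of them."""
    if not 1 <= window <= n_quadrats:
        raise ValidationError(
            f"window length {window} outside 1..{n_quadrats}"
        )
    return [tuple(range(s, s + window)) for s in range(n_quadrats - window + 1)]


def contiguous_sac(grid: IncidenceGrid, windows_2d: bool = False) -> SpeciesAreaCurve:
    """Spatially explicit species-area curve over contiguous quadrat runs.

    Default mode slides 1-D windows along acquisition order.  With
    ``windows_2d`` the windows are instead all axis-aligned rectangles of
    quadrats (every shape and placement that fits the plot), a
    sensitivity-analysis variant for plots whose photographing path is
    unknown.
    """
    if grid.n_quadrats == 0:
        raise ValidationError("empty grid")
    if windows_2d:
        return _rect_window_sac(grid)
    n_q = grid.n_quadrats
    x = grid.incidence.astype(np.int32)
    csum = np.vstack([np.zeros((1, grid.n_taxa), dtype=np.int32), np.cumsum(x, axis=0)])
    ns, means, sds, combos = [], [], [], []
    for n in range(1, n_q + 1):
        # richness of window starting at s: taxa with any presence in rows s..s+n-1
        window_counts = csum[n : n_q + 1] - csum[0 : n_q + 1 - n]
        rich = (window_counts > 0).sum(axis=1)
        ns.append(n)
        means.append(float(rich.mean()))
        sds.append(float(rich.std(ddof=SD_DDOF)))
        combos.append(rich.size)
    return SpeciesAreaCurve(
        n=np.array(ns),
        area_cm2=np.array(ns) * grid.quadrat_area_cm2,
        mean_s=np.array(means),
        sd_s=np.array(sds),
        n_combos=np.array(combos),
        mode="contiguous",
    )


def _rect_window_sac(grid: IncidenceGrid) -> SpeciesAreaCurve:
    """Rectangular 2-D windows pooled by quadrat count."""
    nr, nc = grid.n_rows, grid.n_cols
    occ = np.zeros((nr, nc, grid.n_taxa), dtype=bool)
    filled = np.zeros((nr, nc), dtype=bool)
    occ[grid.row, grid.col] = grid.incidence.astype(bool)
    filled[grid.row, grid.col] = True
    by_n: dict[int, list[int]] = {}
    for h in range(1, nr + 1):
        for w in range(1, nc + 1):
            n = h * w
            for r0 in range(nr - h + 1):
                for c0 in range(nc - w + 1):
                    if not filled[r0 : r0 + h, c0 : c0 + w].all():
                        continue
                    rich = int(occ[r0 : r0 + h, c0 : c0 + w].any(axis=(0, 1)).sum())
                    by_n.setdefault(n, []).append(rich)
    ns = sorted(by_n)
    means = [float(np.mean(by_n[n])) for n in ns]
    sds = [float(np.std(by_n[n], ddof=SD_DDOF)) for n in ns]
    combos = [len(by_n[n]) for n in ns]
    return SpeciesAreaCurve(
        n=np.array(ns),
        area_cm2=np.array(ns) * grid.quadrat_area_cm2,
        mean_s=np.array(means),
        sd_s=np.array(sds),
        n_combos=np.array(combos),
        mode="contiguous-2d",
    )


def random_sac(
    grid: IncidenceGrid, n_perm: int = 999, seed: int | None = None
) -> SpeciesAreaCurve:
    """Randomized (sample-based rarefaction) species-area curve.

    Richness of the first *n* quadrats is averaged over ``n_perm``
    random orderings of the quadrats; reproducible under ``seed``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n_q = grid.n_quadrats
    x = grid.incidence.astype(bool)
    orders = rng.permuted(np.tile(np.arange(n_q), (n_perm, 1)), axis=1)
    seen = np.cumsum(x[orders], axis=1) > 0          # (n_perm, n, taxa)
    rich = seen.sum(axis=2)                           # (n_perm, n)
    ns = np.arange(1, n_q + 1)
    return SpeciesAreaCurve(
        n=ns,
        area_cm2=ns * grid.quadrat_area_cm2,
        mean_s=rich.mean(axis=0),
        sd_s=rich.std(axis=0, ddof=SD_DDOF),
        n_combos=np.full(n_q, n_perm),
        mode="randomized",
    )


def rarefaction_expectation(grid: IncidenceGrid, n: int | None = None) -> np.ndarray:
    """Exact expected richness of *n* quadrats drawn without replacement.

    E[S_n] = sum_i (1 - C(N - f_i, n) / C(N, n)) with f_i the number of
    quadrats occupied by taxon i — the closed-form mean of the
    randomized curve.
    """
    n_q = grid.n_quadrats
    freq = grid.incidence.sum(axis=0).astype(int)
    ns = np.arange(1, n_q + 1) if n is None else np.atleast_1d(n).astype(int)
    out = np.empty(len(ns), dtype=float)
    from scipy.special import gammaln

    def log_comb(a: np.ndarray, b: int) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        with np.errstate(invalid="ignore"):
            val = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        return val

    for j, m in enumerate(ns):
        keep = freq > 0
        f = freq[keep]
        ratio = np.where(
            n_q - f >= m,
            np.exp(log_comb(n_q - f, m) - log_comb(np.array(n_q), m)),
            0.0,
        )
        out[j] = np.sum(1.0 - ratio)
    return out


def effort_for_fraction(
    curve: SpeciesAreaCurve, total_s: float, fraction: float
) -> tuple[int, float]:
    """Smallest *n* whose mean richness reaches ``fraction`` of ``total_s``.

    Returns ``(n, achieved_fraction)``.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    if total_s <= 0:
        raise ValidationError("total richness must be positive")
    target = fraction * total_s - 1e-9
    hit = np.nonzero(curve.mean_s >= target)[0]
    if hit.size == 0:
        raise ValidationError(
            "curve never reaches the requested fraction; is it complete to n = N?"
        )
    i = int(hit[0])
    return int(curve.n[i]), float(curve.mean_s[i] / total_s)


def aggregate_blocks(
    grid: IncidenceGrid, block_rows: int = 2, block_cols: int = 4
) -> pd.DataFrame:
    """Tile the plot into non-overlapping blocks and OR the member quadrats.

    Each complete ``block_rows`` x ``block_cols`` block becomes one
    replicate row (a minimal-sampling-area-sized sampling unit: 2 x 4
    quadrats of 25 cm give 50 x 100 cm); incomplete blocks are
    discarded.  Returns a wide table with metadata columns followed by
    taxa, in row-major block order.
    """
    if block_rows < 1 or block_cols < 1:
        raise ValidationError("block dimensions must be positive")
    if block_rows > grid.n_rows or block_cols > grid.n_cols:
        raise ValidationError(
            f"block {block_rows}x{block_cols} larger than grid extent "
            f"{grid.n_rows}x{grid.n_cols}"
        )
    needed = block_rows * block_cols
    brow = grid.row // block_rows
    bcol = grid.col // block_cols
    records = []
    keys = sorted(set(zip(brow.tolist(), bcol.tolist())))
    for k, (br, bc) in enumerate(keys):
        members = np.nonzero((brow == br) & (bcol == bc))[0]
        if members.size != needed:
            continue
        union = grid.incidence[members].max(axis=0)
        rec = {
            "replicate": f"{grid.plot_id or 'plot'}-B{br}{bc}",
            "plot_id": grid.plot_id,
            "site": grid.site,
            "region": grid.region,
            "assemblage": grid.assemblage,
            "block_row": br,
            "block_col": bc,
        }
        rec.update(dict(zip(grid.taxa, union.tolist())))
        records.append(rec)
    if not records:
        raise ValidationError("no complete blocks fit the grid")
    return pd.DataFrame.from_records(records)


REPLICATE_META_COLUMNS = (
    "replicate",
    "plot_id",
    "site",
    "region",
    "assemblage",
    "block_row",
    "block_col",
)


def replicate_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Split a replicate table into (binary matrix, taxon list)."""
    taxa = [c for c in table.columns if c not in REPLICATE_META_COLUMNS]
    return table[taxa].to_numpy(dtype=np.uint8), taxa


def replicate_combinations_richness(
    replicates: pd.DataFrame | np.ndarray,
    r: int = 3,
    max_combos: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Mean and SD of union richness over combinations of ``r`` replicates.

    Exhaustive when C(m, r) <= ``max_combos``; otherwise a seeded random
    subset of combinations of that size is evaluated.  Returns
    ``(mean, sd, n_combos_used)``.
    """
    if isinstance(replicates, pd.DataFrame):
        x, _ = replicate_matrix(replicates)
    else:
        x = np.asarray(replicates, dtype=np.uint8)
    m = x.shape[0]
    if r < 1 or r > m:
        raise ValidationError(f"r={r} outside 1..{m} replicates")
    total = comb(m, r)
    if total <= max_combos:
        combos = itertools.combinations(range(m), r)
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        combos = (tuple(rng.choice(m, size=r, replace=False)) for _ in range(max_combos))
        n_used = max_combos
    rich = np.fromiter(
        (int(x[list(c)].any(axis=0).sum()) for c in combos), dtype=float, count=n_used
    )
    return float(rich.mean()), float(rich.std(ddof=SD_DDOF)), n_used
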