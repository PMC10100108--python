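"""Grid searches over inversion times and flip angles.

The two-stage protocol optimization: first a TI grid search records, for
every feasible (TI1, TI2) pair at each TR_MP2RAGE, the maximum B1-averaged
CNR_total over a flip-angle grid; then, at the chosen TIs, flip-angle CNR
maps are built for all channels and the final pair is selected by
maximizing the FLAWS_min total CNR subject to retaining a fraction
(default 85%) of the maximum total UNI CNR.

A T1-sensitivity analysis repeats the flip-angle argmax over a grid of
plausible WM/GM T1 values and reports the spread of the optimal angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnr import B1Grid, CNRMap, NoiseModel, grid_channel_cnrs
from .epg import TissueParams
from .sequence import InfeasibleTimingError, SequenceParams, is_feasible

__all__ = [
    "TIGrid",
    "FAGrid",
    "T1Range",
    "ti_grid_search",
    "fa_cnr_maps",
    "select_fa",
    "t1_sensitivity",
    "contour_report",
]


@dataclass(frozen=True)
class TIGrid:
    """TI1/TI2 candidate values in ms.

    Defaults follow the published search: TI1 from 600 ms upward in steps
    of 200 ms, TI2 2000-3200 ms in steps of 200 ms; infeasible pairs are
    masked by the block-timing check at evaluation time.
    """

    ti1_values: tuple = tuple(float(v) for v in range(600, 1601, 200))
    ti2_values: tuple = tuple(float(v) for v in range(2000, 3201, 200))

    def __post_init__(self) -> None:
        if not self.ti1_values or not self.ti2_values:
            raise ValueError("TI grids must be non-empty")


@dataclass(frozen=True)
class FAGrid:
    """Nominal flip-angle grid in degrees.

    ``coarse()`` is the survey grid (alpha1 1-9, alpha2 1-17, step 2);
    ``fine()`` the refinement grid (both 1-10, step 1).
    """

    alpha1_values: tuple
    alpha2_values: tuple

    def __post_init__(self) -> None:
        if not self.alpha1_values or not self.alpha2_values:
            raise ValueError("FA grids must be non-empty")
        if any(a <= 0 for a in self.alpha1_values + self.alpha2_values):
            raise ValueError("flip angles must be positive")

    @classmethod
    def coarse(cls) -> "FAGrid":
        return cls(tuple(float(a) for a in range(1, 10, 2)),
                   tuple(float(a) for a in range(1, 18, 2)))

    @classmethod
    def fine(cls) -> "FAGrid":
        return cls(tuple(float(a) for a in range(1, 11)),
                   tuple(float(a) for a in range(1, 11)))

    @property
    def pairs(self) -> list[tuple[float, float]]:
        return [(a1, a2) for a1 in self.alpha1_values for a2 in self.alpha2_values]


@dataclass(frozen=True)
class T1Range:
    """WM/GM T1 grids for the sensitivity analysis (4 x 4 = 16 sets).

    The published analysis states only the count (16) and the spans
    (WM 800-1150 ms, GM 1550-1900 ms); evenly spaced 4 x 4 Cartesian
    sampling realizes it.
    """

    wm_values: tuple = tuple(np.linspace(800.0, 1150.0, 4))
    gm_values: tuple = tuple(np.linspace(1550.0, 1900.0, 4))

    @property
    def n_sets(self) -> int:
        return len(self.wm_values) * len(self.gm_values)


def fa_cnr_maps(
    seq: SequenceParams,
    fa_grid: FAGrid,
    tissues: Mapping[str, TissueParams],
    b1: B1Grid | None = None,
    noise: NoiseModel | None = None,
) -> CNRMap:
    """B1-averaged CNR maps of all channels over the flip-angle grid."""
    b1 = b1 or B1Grid()
    if noise is None or noise.sigma is None:
        raise ValueError("a calibrated NoiseModel (sigma set) is required")
    pairs = fa_grid.pairs
    channels = grid_channel_cnrs(seq, tissues, list(b1.scales), pairs, noise)
    shape = (len(fa_grid.alpha1_values), len(fa_grid.alpha2_values))
    return CNRMap(
        alpha1_grid=np.asarray(fa_grid.alpha1_values, dtype=float),
        alpha2_grid=np.asarray(fa_grid.alpha2_values, dtype=float),
        channels={k: v.reshape(shape) for k, v in channels.items()},
        tr_mp2rage=seq.tr_mp2rage,
    )


def ti_grid_search(
    trs: Sequence[float],
    ti_grid: TIGrid,
    fa_grid: FAGrid,
    tissues: Mapping[str, TissueParams],
    base_seq: SequenceParams,
    b1: B1Grid | None = None,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Maximum CNR_total over the FA grid for every feasible TI pair and TR.

    ``base_seq`` supplies everything except TR and TIs (TR_GRE, block
    length, center index, spoiling, eff).  Returns one row per feasible
    (TR, TI1, TI2) with the maximum and the argmax flip pair.
    """
    rows = []
    any_feasible = False
    for tr in trs:
        for ti1 in ti_grid.ti1_values:
            for ti2 in ti_grid.ti2_values:
                try:
                    seq = replace(base_seq, tr_mp2rage=float(tr), ti1=float(ti1),
                                  ti2=float(ti2))
                except ValueError:
                    continue
                if not is_feasible(seq):
                    continue
                any_feasible = True
                cmap = fa_cnr_maps(seq, fa_grid, tissues, b1=b1, noise=noise)
                total = cmap.channels["cnr_total"]
                i, j = np.unravel_index(np.argmax(total), total.shape)
                rows.append({
                    "tr_mp2rage": float(tr), "ti1": float(ti1), "ti2": float(ti2),
                    "max_cnr_total": float(total[i, j]),
                    "best_alpha1": float(cmap.alpha1_grid[i]),
                    "best_alpha2": float(cmap.alpha2_grid[j]),
                })
    if not any_feasible:
        raise InfeasibleTimingError("no feasible TI pair on the requested grid")
    return pd.DataFrame(rows)


def select_fa(cnr_map: CNRMap, uni_fraction: float = 0.85):
    """Constrained flip-angle selection.

    Among pairs retaining at least ``uni_fraction`` of the maximum total
    UNI CNR, return the one maximizing the FLAWS_min total CNR; ties are
    broken toward smaller alpha2, then smaller alpha1 (lower SAR).

    Returns
    -------
    (alpha1, alpha2), info
        ``info`` has the retained UNI fraction (percent), the achieved
        FLAWS total and the unconstrained UNI maximum.
    """
    uni_total = cnr_map.channels["uni_total"]
    flaws_total = cnr_map.channels["flaws_total"]
    uni_max = float(uni_total.max())
    feasible = uni_total >= uni_fraction * uni_max
    if not feasible.any():
        raise ValueError("empty feasible set; uni_fraction too large")
    masked = np.where(feasible, flaws_total, -np.inf)
    best = masked.max()
    # tie-break toward smaller alpha2 then alpha1 among near-equal maxima
    cand = np.argwhere(masked >= best - 1e-12)
    cand = sorted(map(tuple, cand), key=lambda ij: (ij[1], ij[0]))
    i, j = cand[0]
    pair = (float(cnr_map.alpha1_grid[i]), float(cnr_map.alpha2_grid[j]))
    info = {
        "uni_fraction_retained": 100.0 * float(uni_total[i, j]) / uni_max
        if uni_max != 0 else np.nan,
        "flaws_total": float(flaws_total[i, j]),
        "uni_total_max": uni_max,
        "uni_total": float(uni_total[i, j]),
    }
    return pair, info


def t1_sensitivity(
    seq: SequenceParams,
    fa_grid: FAGrid,
    tissues: Mapping[str, TissueParams],
    t1_range: T1Range | None = None,
    b1: B1Grid | None = None,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Spread of the optimal flip angles over plausible WM/GM T1 values.

    For each T1 set the flip-angle argmax is recorded for two objectives:
    maximum CNR_total and maximum total UNI CNR.  Returns mean and SD of
    the optimal alpha1/alpha2 per objective.
    """
    t1_range = t1_range or T1Range()
    opts = {"cnr_total": [], "uni_total": []}
    for t1_wm in t1_range.wm_values:
        for t1_gm in t1_range.gm_values:
            varied = dict(tissues)
            varied["WM"] = replace(tissues["WM"], T1=float(t1_wm))
            varied["GM"] = replace(tissues["GM"], T1=float(t1_gm))
            cmap = fa_cnr_maps(seq, fa_grid, varied, b1=b1, noise=noise)
            for objective in opts:
                arr = cmap.channels[objective]
                i, j = np.unravel_index(np.argmax(arr), arr.shape)
                opts[objective].append((cmap.alpha1_grid[i], cmap.alpha2_grid[j]))
    rows = []
    for objective, pairs in opts.items():
        arr = np.asarray(pairs)
        rows.append({
            "objective": objective,
            "alpha1_mean": arr[:, 0].mean(), "alpha1_sd": arr[:, 0].std(),
            "alpha2_mean": arr[:, 1].mean(), "alpha2_sd": arr[:, 1].std(),
            "n_sets": len(pairs),
        })
    return pd.DataFrame(rows)


def contour_report(cnr_map: CNRMap, out_dir: str | Path, levels: int = 8,
                   prefix: str = "cnr") -> dict:
    """Write per-channel contour figures and a CSV of the grid.

    Returns the paths written.  A constant map yields an empty contour set
    without error.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    a2, a1 = np.meshgrid(cnr_map.alpha2_grid, cnr_map.alpha1_grid)
    for name, values in cnr_map.channels.items():
        fig, ax = plt.subplots(figsize=(4.5, 3.6))
        if np.ptp(values) > 0:
            cs = ax.contour(a2, a1, values, levels=levels)
            ax.clabel(cs, inline=True, fontsize=7)
        ax.set_xlabel("alpha2 (deg)")
        ax.set_ylabel("alpha1 (deg)")
        ax.set_title(f"{name} (TR {cnr_map.tr_mp2rage:.0f} ms)")
        path = out_dir / f"{prefix}_{name}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths[name] = path
    csv_path = out_dir / f"{prefix}_grid.csv"
    cnr_map.to_frame().to_csv(csv_path, index=False)
    paths["csv"] = csv_path
    return paths
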