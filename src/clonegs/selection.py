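"""Selection differentials, breeding-cycle efficiency and selection coincidence.

The genomic selection differential SD_GS at selection proportion ``sp`` is
the mean stage-one BLUP merit of the top ⌈sp·n⌉ clones ranked by their
genomic predictions, minus the population mean merit; the phenotypic
differential SD_PS ranks by the BLUP itself. Relative efficiency folds in
cycle-time shortening:

    Efficiency = SD_GS / (SD_PS × GB/PB)

with GB/PB the ratio of the genomic to the conventional breeding-cycle
length. Cohen's kappa measures the coincidence of the selected sets of two
ranking methods at a common proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PROPORTIONS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
DEFAULT_CYCLE_RATIOS = (1.00, 0.80, 0.65, 0.60, 0.40, 0.20)


def top_fraction(values, sp: float, ids=None) -> np.ndarray:
    """Indices of the top ⌈sp·n⌉ entries; ties at the cut break by id
    (stable, logged)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not 0 < sp <= 1:
        raise ValueError("selection proportion must lie in (0, 1]")
    k = ceil(sp * n)
    ids = np.arange(n) if ids is None else np.asarray(ids)
    order = np.lexsort((ids, -values))
    if k < n and values[order[k - 1]] == values[order[k]]:
        logger.info("top_fraction: tie at the selection cut broken by id order")
    return order[:k]


def selection_differential(ranking_values, merit_values, sp: float,
                           ids=None) -> float:
    """Mean merit of the selected top fraction minus the overall mean merit."""
    merit = np.asarray(merit_values, dtype=float)
    sel = top_fraction(ranking_values, sp, ids)
    return float(merit[sel].mean() - merit.mean())


def efficiency(sd_gs: float, sd_ps: float, ratio: float) -> float:
    """SD_GS / (SD_PS × GB/PB); exact quotient."""
    if ratio <= 0:
        raise ValueError("cycle-length ratio must be positive")
    if sd_ps == 0:
        raise ValueError("phenotypic selection differential is zero; "
                         "efficiency undefined")
    return sd_gs / (sd_ps * ratio)


def cohen_kappa(selected_a, selected_b) -> float:
    """Cohen's kappa for two binary selection vectors:
    κ = (p_o − p_e)/(1 − p_e) with p_e from the marginal frequencies."""
    a = np.asarray(selected_a).astype(int)
    b = np.asarray(selected_b).astype(int)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("selection vectors must be 1-d and equal length")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("selection vectors must be binary 0/1")
    n = len(a)
    po = float(np.mean(a == b))
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        if po == 1.0:
            return 1.0  # both constant and identical
        logger.warning("cohen_kappa: both vectors constant but different; "
                       "kappa defined as 0")
        return 0.0
    return float((po - pe) / (1.0 - pe))


def selection_mask(values, sp: float, ids=None) -> np.ndarray:
    mask = np.zeros(len(np.asarray(values)), dtype=int)
    mask[top_fraction(values, sp, ids)] = 1
    return mask


@dataclass
class SelectionGrid:
    proportions: tuple = DEFAULT_PROPORTIONS
    cycle_ratios: tuple = DEFAULT_CYCLE_RATIOS

    def __post_init__(self):
        if not all(0 < sp < 1 for sp in self.proportions):
            raise ValueError("selection proportions must lie in (0, 1)")
        if not all(0 < r <= 1 for r in self.cycle_ratios):
            raise ValueError("cycle ratios must lie in (0, 1]")


def selection_report(rankings: dict, merit, grid: SelectionGrid | None = None,
                     ids=None, trait: str = "") -> pd.DataFrame:
    """Tidy table of SD_GS, SD_PS and efficiency per (method, sp, ratio).

    ``rankings`` maps method name -> per-clone genomic predictions
    (GEBV/GEGV); ``merit`` is the stage-one BLUP vector defining both the
    phenotypic ranking and the merit scale.
    """
    grid = grid or SelectionGrid()
    merit = np.asarray(merit, dtype=float)
    rows = []
    for sp in grid.proportions:
        sd_ps = selection_differential(merit, merit, sp, ids)
        for method, pred in rankings.items():
            sd_gs = selection_differential(pred, merit, sp, ids)
            for ratio in grid.cycle_ratios:
                rows.append({"trait": trait, "method": method, "sp": sp,
                             "ratio": ratio, "sd_gs": sd_gs, "sd_ps": sd_ps,
                             "efficiency": efficiency(sd_gs, sd_ps, ratio)})
    return pd.DataFrame(rows)


def kappa_report(rankings: dict, grid: SelectionGrid | None = None,
                 ids=None, merit=None) -> pd.DataFrame:
    """Pairwise selection coincidence (kappa) between ranking methods over
    the SP grid; with ``merit`` given, each method is also compared against
    phenotypic (BLUP) selection under the name "BLUP"."""
    grid = grid or SelectionGrid()
    all_rank = dict(rankings)
    if merit is not None:
        all_rank["BLUP"] = np.asarray(merit, dtype=float)
    names = list(all_rank)
    rows = []
    for sp in grid.proportions:
        masks = {m: selection_mask(v, sp, ids) for m, v in all_rank.items()}
        for i, ma in enumerate(names):
            for mb in names[i + 1:]:
                rows.append({"method_a": ma, "method_b": mb, "sp": sp,
                             "kappa": cohen_kappa(masks[ma], masks[mb])})
    return pd.DataFrame(rows)
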