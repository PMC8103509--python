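"""Lin's concordance correlation coefficient and reproducible-feature sets.

A feature is called concordant between two scans when its CCC over the
ten ROI-matched value pairs is strictly greater than 0.9. A scenario's
reproducible set is the intersection of the concordant sets over all 21
scan pairs of one scanner model; the surviving features can then be
thinned by a greedy Spearman de-duplication (|rho| > 0.90 drops the
later feature in catalog order).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .features.catalog import FEATURE_NAMES

__all__ = [
    "PairwiseConcordance",
    "ConcordanceSummary",
    "lins_ccc",
    "pairwise_concordance",
    "all_pairs_intersection",
    "spearman_dedup",
    "scan_pairs",
    "summarize",
]

N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class PairwiseConcordance:
    scan_a: str
    scan_b: str
    ccc: dict[str, float]
    concordant: frozenset[str]
    cutoff: float = 0.9

    @property
    def count(self) -> int:
        return len(self.concordant)

    @property
    def percentage(self) -> float:
        return self.count / N_FEATURES * 100.0


@dataclass(frozen=True)
class ConcordanceSummary:
    scenario: str
    pairs: tuple[PairwiseConcordance, ...]
    intersection: frozenset[str]
    deduplicated: frozenset[str]


def lins_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population moments:

        rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

    Identical constant vectors score 1 by convention (perfect agreement
    with no variation to disagree about).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 2:
        raise ValueError("need at least 2 paired values")
    mx, my = x.mean(), y.mean()
    sxy = np.mean((x - mx) * (y - my))
    denom = x.var() + y.var() + (mx - my) ** 2
    if denom == 0:
        return 1.0
    return float(2.0 * sxy / denom)


def _pivot(df: pd.DataFrame, scan: str) -> pd.DataFrame:
    sub = df[df["scan_id"] == scan].sort_values("roi_label")
    return sub.set_index("roi_label")


def pairwise_concordance(
    df: pd.DataFrame, pair: tuple[str, str], cutoff: float = 0.9,
    features: list[str] | None = None,
) -> PairwiseConcordance:
    """Per-feature CCC between two scans over their ROI-matched rows.

    Concordance uses strict inequality: CCC exactly at the cutoff does
    not count. ``features`` restricts the scored set (e.g. after an NZV
    filter); the denominator of ``percentage`` stays 91 regardless.
    """
    a, b = pair
    fa, fb = _pivot(df, a), _pivot(df, b)
    if len(fa) == 0 or len(fb) == 0:
        raise ValueError(f"scan missing from table: {pair}")
    if list(fa.index) != list(fb.index):
        raise ValueError(f"ROI labels differ between {a} and {b}")
    feats = features if features is not None else [
        c for c in df.columns if c in FEATURE_NAMES
    ]
    ccc = {f: lins_ccc(fa[f].to_numpy(), fb[f].to_numpy()) for f in feats}
    concordant = frozenset(f for f, v in ccc.items() if v > cutoff)
    return PairwiseConcordance(a, b, ccc, concordant, cutoff)


def all_pairs_intersection(results) -> frozenset[str]:
    """Features concordant in every pairwise comparison."""
    results = list(results)
    if not results:
        raise ValueError("need at least one pairwise result")
    out = frozenset(results[0].concordant)
    for r in results[1:]:
        out &= r.concordant
    return out


def spearman_dedup(
    df: pd.DataFrame, features, threshold: float = 0.90
) -> tuple[list[str], list[str]]:
    """Greedy catalog-order pass: keep a feature iff |Spearman rho| <=
    threshold against every already-kept feature. A constant feature has
    undefined rho and is treated as correlated with nothing (kept)."""
    feats = [f for f in FEATURE_NAMES if f in set(features)]
    if len(df) < 3:
        raise ValueError("need >= 3 rows for rank correlation")
    kept: list[str] = []
    dropped: list[str] = []
    for f in feats:
        x = df[f].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0:
            kept.append(f)
            continue
        high = False
        for g in kept:
            y = df[g].to_numpy(dtype=np.float64)
            if np.ptp(y) == 0:
                continue
            rho = stats.spearmanr(x, y).statistic
            if np.isfinite(rho) and abs(rho) > threshold:
                high = True
                break
        (dropped if high else kept).append(f)
    return kept, dropped


def scan_pairs(scan_ids) -> list[tuple[str, str]]:
    """All unordered pairs, in stable input order (7 scans -> 21 pairs)."""
    return list(combinations(list(scan_ids), 2))


def summarize(
    df: pd.DataFrame,
    scan_ids,
    scenario: str,
    cutoff: float = 0.9,
    spearman_threshold: float = 0.90,
    features_per_pair: dict[tuple[str, str], list[str]] | None = None,
) -> ConcordanceSummary:
    """Pairwise CCC for every scan pair, the all-pairs intersection, and
    the Spearman-de-duplicated subset (computed on the first scan-set's
    rows restricted to the intersection)."""
    if len(list(scan_ids)) < 2:
        raise ValueError("need >= 2 scans to form pairs")
    results = []
    for pair in scan_pairs(scan_ids):
        feats = features_per_pair.get(pair) if features_per_pair else None
        results.append(pairwise_concordance(df, pair, cutoff, features=feats))
    inter = all_pairs_intersection(results)
    sub = df[df["scan_id"].isin(list(scan_ids))]
    if inter and len(sub) >= 3:
        kept, _ = spearman_dedup(sub, inter, spearman_threshold)
    else:
        kept = sorted(inter)
    return ConcordanceSummary(
        scenario=scenario,
        pairs=tuple(results),
        intersection=inter,
        deduplicated=frozenset(kept),
    )
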