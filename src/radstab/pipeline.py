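"""End-to-end orchestration of the four reproducibility approaches.

Per scanner model (7 scans at 7 in-plane spacings, 21 scan pairs):

(i)   extract features from the original scans, pairwise CCC;
(ii)  as (i), then near-zero-variance filter and *pairwise* ComBat (two
      batches per run, one per scan) before the CCC;
(iii) resample all 7 scans to one NUIR with one interpolation method,
      re-extract, pairwise CCC;
(iv)  as (iii) followed by pairwise ComBat.

A sweep covers the full grid: per scanner, one extraction pass on the
originals plus one per (interpolation method x NUIR) combination —
1 + 10 x 7 = 71 passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np
import pandas as pd

from .combat import harmonize
from .concordance import (
    N_FEATURES,
    ConcordanceSummary,
    PairwiseConcordance,
    all_pairs_intersection,
    pairwise_concordance,
    scan_pairs,
    spearman_dedup,
    summarize,
)
from .core import ImageVolume, RoiMask, ScanMeta
from .features import extract_table
from .phantom import TABLE_SPACINGS_MM
from .resampling import VOLUME_METHODS, resample_mask, resample_volume

__all__ = [
    "APPROACHES",
    "SWEEP_METHODS",
    "ScenarioConfig",
    "RunReport",
    "select_scans",
    "resample_dataset",
    "run_approach",
    "compare_reports",
    "render_table",
    "sweep_plan",
    "sweep",
]

APPROACHES = ("i", "ii", "iii", "iv")
#: the ten interpolation methods of a full sweep
SWEEP_METHODS = VOLUME_METHODS + ("LabelGaussian",)

Scan = tuple[ImageVolume, RoiMask, ScanMeta]


@dataclass(frozen=True)
class ScenarioConfig:
    approach: str
    scanner_model: str
    im: str | None = None
    nuir_mm: float | None = None
    bin_width: float = 25.0
    cutoff: float = 0.9
    spearman_threshold: float = 0.90
    nzv_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}")
        if self.approach in ("iii", "iv") and (self.im is None or self.nuir_mm is None):
            raise ValueError("approaches iii/iv require an IM and a NUIR")


@dataclass
class RunReport:
    config: ScenarioConfig
    summary: ConcordanceSummary
    features: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def pair_counts(self) -> dict[tuple[str, str], int]:
        return {(p.scan_a, p.scan_b): p.count for p in self.summary.pairs}


def select_scans(dataset: list[Scan], scanner_model: str) -> list[Scan]:
    """The scans of one model, sorted by in-plane spacing (finest first)."""
    scans = [s for s in dataset if s[2].scanner_model == scanner_model]
    return sorted(scans, key=lambda s: s[2].in_plane_spacing_mm)


def _resample_scan(scan: Scan, im: str, nuir_mm: float) -> Scan:
    vol, mask, meta = scan
    # LabelGaussian is mask-only: the image then takes the Gaussian kernel
    img_method = "Gaussian" if im == "LabelGaussian" else im
    mask_method = "LabelGaussian" if im == "LabelGaussian" else "NN"
    vol2 = resample_volume(vol, nuir_mm, img_method)
    mask2 = resample_mask(mask, vol, nuir_mm, mask_method)
    return vol2, mask2, meta


def resample_dataset(scans: list[Scan], im: str, nuir_mm: float) -> list[Scan]:
    return [_resample_scan(s, im, nuir_mm) for s in scans]


def _pairwise_combat_summary(
    df: pd.DataFrame, scan_ids, config: ScenarioConfig, scenario: str
) -> ConcordanceSummary:
    """NZV filter + two-batch ComBat per scan pair, then CCC per pair."""
    results: list[PairwiseConcordance] = []
    for pair in scan_pairs(scan_ids):
        sub = df[df["scan_id"].isin(pair)]
        harmonized, report = harmonize(
            sub, batch_col="batch", nzv_threshold=config.nzv_threshold
        )
        results.append(
            pairwise_concordance(
                harmonized, pair, config.cutoff, features=report.retained
            )
        )
    inter = all_pairs_intersection(results)
    sub_all = df[df["scan_id"].isin(list(scan_ids))]
    kept = (
        spearman_dedup(sub_all, inter, config.spearman_threshold)[0] if inter else []
    )
    return ConcordanceSummary(
        scenario=scenario,
        pairs=tuple(results),
        intersection=inter,
        deduplicated=frozenset(kept),
    )


def run_approach(config: ScenarioConfig, dataset: list[Scan]) -> RunReport:
    """Execute one approach for one scanner model on a dataset."""
    scans = select_scans(dataset, config.scanner_model)
    if len(scans) != 7:
        raise ValueError(
            f"expected 7 scans for model {config.scanner_model!r}, got {len(scans)}"
        )
    if config.approach in ("iii", "iv"):
        scans = resample_dataset(scans, config.im, config.nuir_mm)
    table = extract_table(scans, bin_width=config.bin_width)
    df = table.to_dataframe()
    scan_ids = [s[2].scan_id for s in scans]
    tag = (
        f"approach-{config.approach}/{config.scanner_model}"
        + (f"/{config.im}@{config.nuir_mm}mm" if config.im else "")
    )
    if config.approach in ("ii", "iv"):
        summary = _pairwise_combat_summary(df, scan_ids, config, tag)
    else:
        summary = summarize(
            df, scan_ids, tag, config.cutoff, config.spearman_threshold
        )
    prov = {
        "config": config.__dict__,
        "scan_ids": scan_ids,
        "spacings_mm": [s[2].in_plane_spacing_mm for s in scans],
        "seeds": [s[2].seed for s in scans],
    }
    return RunReport(config=config, summary=summary, features=df, provenance=prov)


def compare_reports(report: RunReport, baseline: RunReport) -> pd.DataFrame:
    """Per-pair increment in concordant-feature count vs the baseline
    approach, plus the pair spacing gap; aligned pair-for-pair."""
    base = baseline.pair_counts
    spacing = {
        s_id: sp
        for s_id, sp in zip(
            baseline.provenance["scan_ids"], baseline.provenance["spacings_mm"]
        )
    }
    rows = []
    for p in report.summary.pairs:
        key = (p.scan_a, p.scan_b)
        if key not in base:
            raise ValueError(f"pair {key} missing from baseline")
        rows.append(
            {
                "scan_a": p.scan_a,
                "scan_b": p.scan_b,
                "delta_spacing_mm": abs(spacing[p.scan_a] - spacing[p.scan_b]),
                "count": p.count,
                "baseline_count": base[key],
                "increment": p.count - base[key],
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["median_increment"] = float(median(df["increment"])) if len(df) else 0.0
    return df


def render_table(summary: ConcordanceSummary, scan_ids) -> pd.DataFrame:
    """Lower-triangular 6x6 matrix of "count (percent%)" cells, one row
    per scan 2..7 and one column per scan 1..6."""
    ids = list(scan_ids)
    counts = {(p.scan_a, p.scan_b): p for p in summary.pairs}
    out = pd.DataFrame("", index=ids[1:], columns=ids[:-1])
    for (a, b), p in counts.items():
        row, col = (b, a) if ids.index(a) < ids.index(b) else (a, b)
        out.loc[row, col] = f"{p.count} ({p.count / N_FEATURES * 100:.1f}%)"
    return out


def sweep_plan(
    ims=SWEEP_METHODS,
    nuirs=TABLE_SPACINGS_MM,
    scanner_models=("Discovery-STE", "LightSpeed-Pro-32"),
) -> dict:
    """Bookkeeping for a sweep without running it: extraction passes per
    scanner (1 original + IMs x NUIRs) and total result rows (21 per
    scenario)."""
    n_combo = len(ims) * len(nuirs)
    scenarios = [
        (m, im, nuir) for m in scanner_models for im in ims for nuir in nuirs
    ]
    return {
        "extraction_passes_per_scanner": 1 + n_combo,
        "scenarios": scenarios,
        "n_scenarios": len(scenarios),
        "pairs_per_scenario": 21,
        "total_rows": len(scenarios) * 21,
    }


def sweep(
    dataset: list[Scan],
    ims=SWEEP_METHODS,
    nuirs=TABLE_SPACINGS_MM,
    scanner_models=("Discovery-STE", "LightSpeed-Pro-32"),
    cutoff: float = 0.9,
) -> pd.DataFrame:
    """Run approach (iii) over the IM x NUIR grid; long-format rows
    (scanner, im, nuir, scan_a, scan_b, count, percentage) suitable for
    trendline plots."""
    rows = []
    for model in scanner_models:
        for im in ims:
            for nuir in nuirs:
                cfg = ScenarioConfig("iii", model, im=im, nuir_mm=nuir, cutoff=cutoff)
                rep = run_approach(cfg, dataset)
                for p in rep.summary.pairs:
                    rows.append(
                        {
                            "scanner": model,
                            "im": im,
                            "nuir_mm": nuir,
                            "scan_a": p.scan_a,
                            "scan_b": p.scan_b,
                            "count": p.count,
                            "percentage": p.percentage,
                        }
                    )
    return pd.DataFrame(rows)
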