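"""End-to-end runs: images → series table → analysis JSON.

``run_measure`` turns a set of photographs plus a point file into the
series table (one row per image); ``run_series_analysis`` turns a series
table into the full quantification/inference record: baseline-subtracted
series, through-origin reduction rates, Gompertz fits, the normalized limit
of detection against a named control, and per-timepoint pairwise bootstrap
p-values with significance onsets between replicate groups.

The reduction *signal* is the darkening magnitude baseline − value under
the default ``signal_direction="darkening"`` (reduced graphene oxide is
darker, so V falls over time); ``"brightening"`` flips the sign for assays
whose signal raises V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import GoredoxError
from .image_core import load_image
from .io import parse_sim_filename
from .quantification import (
    ReductionSeries,
    baseline_subtract,
    fit_gompertz,
    fit_rate_through_origin,
    lod_normalized,
    measure_sample,
)
from .sampling import PointSet, build_glare_mask
from .stats import significance_onset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeasureItem:
    """One image to measure: path plus its sample identity and time."""

    path: Path
    sample_id: str
    time_h: float
    group: str | None = None

    @classmethod
    def from_path(
        cls,
        path: str | Path,
        sample_id: str | None = None,
        time_h: float | None = None,
    ) -> "MeasureItem":
        """Build an item, reading sample/time/replicate from the
        ``{sample}_{time_h}h_{rep}`` filename convention when possible."""
        p = Path(path)
        parsed = parse_sim_filename(p)
        if parsed is not None and sample_id is None and time_h is None:
            sample, t, rep = parsed
            return cls(p, f"{sample}.{rep}", t, group=sample)
        return cls(
            p,
            sample_id if sample_id is not None else p.stem,
            time_h if time_h is not None else 0.0,
        )


def run_measure(
    items: list[MeasureItem],
    points_by_sample: dict[str, PointSet],
    config: RunConfig,
) -> pd.DataFrame:
    """Measure every image against its sample's points; one row per image.

    Points are looked up by the item's ``sample_id``, falling back to its
    ``group`` (so one point file can serve all replicates of a sample when
    framing is fixed).  Each point set must meet ``config.min_points``; when
    a ROI is configured, points are validated against it and its glare mask
    and any failure aborts with the per-point reason.
    """
    rows = []
    for item in items:
        if not item.path.exists():
            raise GoredoxError(f"missing image file: {item.path}")
        pts = points_by_sample.get(item.sample_id)
        if pts is None and item.group is not None:
            base = points_by_sample.get(item.group)
            if base is not None:
                pts = PointSet(item.sample_id, base.points)
        if pts is None:
            raise GoredoxError(
                f"no points for sample {item.sample_id!r} (image {item.path})"
            )
        if len(pts) < config.min_points:
            raise GoredoxError(
                f"sample {item.sample_id!r}: {len(pts)} points < "
                f"minimum {config.min_points}"
            )
        image = load_image(item.path)
        roi = config.roi
        mask = None
        if roi is not None:
            mask = build_glare_mask(
                image, roi, config.glare_v_threshold, config.glare_s_threshold
            )
        meas = measure_sample(
            image, pts, side=config.box_side, time_h=item.time_h, roi=roi, mask=mask
        )
        row = {
            "sample_id": meas.sample_id,
            "time_h": meas.time_h,
            "mean_value": meas.mean_value,
            "sd_value": meas.sd_value,
            "n_points": meas.n_points,
        }
        if item.group is not None:
            row["group"] = item.group
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.duplicated(subset=["sample_id", "time_h"]).any():
        raise GoredoxError("duplicate (sample_id, time_h) measurements")
    return df.sort_values(["sample_id", "time_h"]).reset_index(drop=True)


def _signal(values: np.ndarray, direction: str) -> np.ndarray:
    """Baseline-subtracted reduction signal from raw mean values."""
    baseline = values[0]
    return baseline - values if direction == "darkening" else values - baseline


def run_series_analysis(
    table: pd.DataFrame,
    config: RunConfig,
    control: str | None = None,
    do_gompertz: bool = True,
) -> dict:
    """Full analysis of a series table; returns a JSON-serialisable record.

    Sections: per-sample baseline-subtracted series (the sample's earliest
    time is the baseline; a missing t = 0 row is logged, not an error),
    through-origin rates and Gompertz fits on the reduction signal, the
    normalized LOD against ``control`` (control replicate signals pooled
    over timepoints; the maximum is taken over all non-control signals),
    and pairwise per-timepoint bootstrap tests between replicate groups
    (requires a ``group`` column with >= 2 members per group on a shared
    time grid).  The effective config is embedded for exact replay.
    """
    for col in ("sample_id", "time_h", "mean_value"):
        if col not in table.columns:
            raise GoredoxError(f"series table missing column {col!r}")
    out: dict = {"config": config.to_dict(), "series": {}, "rates": {}, "gompertz": {}}
    direction = config.signal_direction

    signals: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sid, grp in table.groupby("sample_id", sort=True):
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy(dtype=float)
        v = grp["mean_value"].to_numpy(dtype=float)
        sd = (
            grp["sd_value"].to_numpy(dtype=float)
            if "sd_value" in grp.columns
            else np.zeros_like(v)
        )
        if t[0] != 0.0:
            logger.info(
                "sample %s lacks a t=0 row; using earliest time %.4g h as baseline",
                sid,
                t[0],
            )
        series = baseline_subtract(
            ReductionSeries(str(sid), tuple(t), tuple(v), tuple(sd))
        )
        sig = _signal(v, direction)
        signals[str(sid)] = (t, sig)
        out["series"][str(sid)] = {
            "time_h": list(t),
            "baseline_value": series.baseline_value,
            "value_minus_baseline": list(series.mean_value),
            "signal": list(sig),
            "sd_value": list(sd),
        }
        if t.size >= 2:
            rate = fit_rate_through_origin(t, sig)
            out["rates"][str(sid)] = {
                "slope_per_h": rate.slope,
                "slope_se": rate.slope_se,
                "n": rate.n,
            }
        if do_gompertz and t.size >= 4:
            try:
                params, rnorm = fit_gompertz(t, sig)
                out["gompertz"][str(sid)] = {
                    "A": params.A,
                    "mu_per_h": params.mu,
                    "lam_h": params.lam,
                    "residual_norm": rnorm,
                }
            except (GoredoxError, ValueError) as exc:
                out["gompertz"][str(sid)] = {"error": str(exc)}

    groups: dict[str, list[str]] = {}
    if "group" in table.columns:
        for g, sub in table.groupby("group", sort=True):
            groups[str(g)] = sorted(sub["sample_id"].astype(str).unique())

    if control is not None:
        members = groups.get(control, [control] if control in signals else [])
        if not members:
            raise GoredoxError(f"control sample/group {control!r} not in table")
        control_vals = np.concatenate([signals[m][1] for m in members])
        others = [s for s in signals if s not in members]
        if others:
            max_detected = float(max(signals[s][1].max() for s in others))
            out["lod"] = {
                "control": control,
                "normalized_lod": lod_normalized(control_vals, max_detected),
                "max_detected": max_detected,
            }
        else:
            out["lod"] = {"control": control, "error": "no non-control samples"}

    out["pairwise"] = {}
    testable = {g: m for g, m in groups.items() if len(m) >= 2}
    for ga, gb in combinations(sorted(testable), 2):
        ta = [signals[s][0] for s in testable[ga]]
        tb = [signals[s][0] for s in testable[gb]]
        grid = ta[0]
        if any(a.shape != grid.shape or not np.array_equal(a, grid) for a in ta + tb):
            raise GoredoxError(f"mismatched time grids for groups {ga!r} vs {gb!r}")
        reps_a = np.column_stack([signals[s][1] for s in testable[ga]])
        reps_b = np.column_stack([signals[s][1] for s in testable[gb]])
        res = significance_onset(
            grid,
            reps_a,
            reps_b,
            alpha=config.alpha,
            B=config.bootstrap_B,
            seed=config.bootstrap_seed,
            alternative=config.bootstrap_alternative,
        )
        out["pairwise"][f"{ga}|{gb}"] = {
            "time_h": list(res.times_h),
            "p_values": list(res.p_values),
            "alpha": res.alpha,
            "onset_time_h": res.onset_time_h,
        }
    return out
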