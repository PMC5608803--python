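"""End-to-end analysis: volumes -> T1/R1 series -> RRM fits -> ROI statistics.

``run_fit`` drives the full chain on one dataset: the PD-reference T1
inversion per frame, conversion to relaxation rates, baseline R10
estimation, and the reference-region least-squares identification of
(Ktrans, ve) for the tissue of interest, either voxel by voxel against the
ROI-mean reference curve (default) or on ROI-mean curves.

``bonferroni_pairwise`` and ``cohort_report`` implement the longitudinal
statistics: all pairwise Welch two-sample tests between measurement days on
per-animal ROI summary values, Bonferroni-adjusted over the number of pairs,
with significance tiers at p < 0.05 and p < 0.01.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import FitConfig, FitResult, fit_rrm
from .phantom import RR_LABEL, TOI_LABEL
from .protocol import AcquisitionProtocol
from .series import DynamicSeries
from .signal_model import estimate_r10, estimate_t1, r1_from_t1

__all__ = [
    "RoiSummary",
    "ComparisonResult",
    "FitOutput",
    "run_fit",
    "analyze_cohort",
    "bonferroni_pairwise",
    "cohort_report",
]

logger = logging.getLogger(__name__)

#: a voxel is excluded from fitting when more than this fraction of its
#: frames fail the T1 inversion's validity condition
MAX_INVALID_FRACTION = 0.25

SIG, HIGH_SIG = 0.05, 0.01


@dataclass
class RoiSummary:
    """Per-ROI fit summary: median and IQR over usable voxels."""

    roi_label: int
    n_voxels: int
    ktrans_median: float
    ktrans_q25: float
    ktrans_q75: float
    ve_median: float
    ve_q25: float
    ve_q75: float
    frac_flagged: float
    animal: int | None = None
    day: int | None = None


@dataclass
class ComparisonResult:
    """One Bonferroni-adjusted pairwise day comparison."""

    group_a: object
    group_b: object
    p_raw: float
    p_adjusted: float
    tier: str  # "none" | "p<0.05" | "p<0.01"


@dataclass
class FitOutput:
    """Everything ``run_fit`` produces for one dataset."""

    summary: RoiSummary
    voxel_table: pd.DataFrame
    maps: dict = field(default_factory=dict)   # name -> 3D array (voxelwise mode)
    rr_curve: DynamicSeries | None = None
    r10_rr: float = float("nan")


def _roi_mean_series(dynamic: np.ndarray, mask: np.ndarray, label: int,
                     protocol: AcquisitionProtocol) -> tuple[DynamicSeries, float]:
    """ROI-mean dynamic signal per frame (signal averaged before inversion)."""
    vox = dynamic[mask == label]
    return DynamicSeries(times=protocol.frame_times(), values=vox.mean(axis=0),
                         unit="a.u.", time_unit="s")


def _r1_chain(s_ref: float, s_dce: DynamicSeries, protocol: AcquisitionProtocol):
    t1 = estimate_t1(s_ref, s_dce, protocol)
    r1 = r1_from_t1(t1)
    state = estimate_r10(r1, protocol.n_baseline)
    return r1, state


def run_fit(reference: np.ndarray, dynamic: np.ndarray, mask: np.ndarray,
            protocol: AcquisitionProtocol,
            config: FitConfig | None = None,
            mode: str = "voxelwise") -> FitOutput:
    """Fit the reference-region model on a volumetric dataset.

    The reference-region curve is always the ROI mean (signal averaged over
    label-1 voxels frame by frame, then inverted): skeletal muscle is
    homogeneous, and averaging before inversion keeps the reference curve
    quiet.  ``mode="voxelwise"`` fits every tissue-of-interest voxel against
    it and summarises by median/IQR; ``mode="roi_mean"`` fits the single
    ROI-mean tissue curve.  Missing labels are a hard error; voxels failing
    validity or baseline checks are flagged and excluded from the quantiles.
    """
    config = config or FitConfig()
    if mode not in ("voxelwise", "roi_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    if reference.shape != mask.shape or dynamic.shape[:3] != mask.shape:
        raise ValueError("reference, dynamic and mask grids do not match")
    if dynamic.shape[3] != protocol.n_frames:
        raise ValueError("dynamic frame count does not match the protocol")
    for label, name in ((RR_LABEL, "reference region"), (TOI_LABEL, "tissue of interest")):
        if not (mask == label).any():
            raise ValueError(f"mask contains no {name} (label {label}) voxels")

    # reference-region curve from ROI-mean signals
    s_dce_rr = _roi_mean_series(dynamic, mask, RR_LABEL, protocol)
    s_ref_rr = float(reference[mask == RR_LABEL].mean())
    r1_rr, rr_state = _r1_chain(s_ref_rr, s_dce_rr, protocol)
    if rr_state is None:
        raise ValueError("reference region has no valid baseline frames")
    r10_rr = rr_state.r10

    rows = []
    results: list[tuple[tuple, FitResult]] = []
    if mode == "roi_mean":
        s_dce_toi = _roi_mean_series(dynamic, mask, TOI_LABEL, protocol)
        s_ref_toi = float(reference[mask == TOI_LABEL].mean())
        jobs = [(("roi",), s_ref_toi, s_dce_toi)]
    else:
        idx = np.argwhere(mask == TOI_LABEL)
        times = protocol.frame_times()
        jobs = [(tuple(i), float(reference[tuple(i)]),
                 DynamicSeries(times=times, values=dynamic[tuple(i)],
                               unit="a.u.", time_unit="s"))
                for i in idx]

    for key, s_ref_v, s_dce_v in jobs:
        flags: list[str] = []
        fit: FitResult | None = None
        r1_v = None
        try:
            t1_v = estimate_t1(s_ref_v, s_dce_v, protocol)
            r1_v = r1_from_t1(t1_v)
        except ValueError:
            flags.append("inversion-error")
        if r1_v is not None:
            invalid_frac = 1.0 - r1_v.n_valid / len(r1_v)
            if invalid_frac > MAX_INVALID_FRACTION:
                flags.append("validity-excluded")
            state = estimate_r10(r1_v, protocol.n_baseline)
            if state is None:
                flags.append("no-baseline")
            if not flags:
                base = r1_v.values[: protocol.n_baseline][r1_v.valid[: protocol.n_baseline]]
                noise = float(base.std(ddof=1)) if base.size >= 2 else None
                fit = fit_rrm(r1_v, r1_rr, state.r10, r10_rr,
                              kinetics_rr=config.kinetics_rr, config=config,
                              baseline_noise=noise)
                flags.extend(fit.flags)
        usable = (fit is not None and fit.kinetics is not None
                  and fit.converged and not flags)
        rows.append({
            "voxel": key if mode == "voxelwise" else "roi_mean",
            "ktrans_min^-1": fit.kinetics.ktrans if fit and fit.kinetics else np.nan,
            "ve": fit.kinetics.ve if fit and fit.kinetics else np.nan,
            "ratio_R": fit.ratio_r if fit else np.nan,
            "residual_s^-1": fit.residual if fit else np.nan,
            "converged": bool(fit.converged) if fit else False,
            "flags": ";".join(flags),
            "usable": usable,
        })
        results.append((key, fit))

    table = pd.DataFrame(rows)
    usable = table[table["usable"]]
    n_all = len(table)
    if usable.empty:
        logger.warning("no usable voxels after validity filtering")
        summary = RoiSummary(roi_label=TOI_LABEL, n_voxels=n_all,
                             ktrans_median=np.nan, ktrans_q25=np.nan, ktrans_q75=np.nan,
                             ve_median=np.nan, ve_q25=np.nan, ve_q75=np.nan,
                             frac_flagged=1.0)
    else:
        kq = usable["ktrans_min^-1"].quantile([0.25, 0.5, 0.75])
        vq = usable["ve"].quantile([0.25, 0.5, 0.75])
        summary = RoiSummary(roi_label=TOI_LABEL, n_voxels=n_all,
                             ktrans_median=float(kq[0.5]), ktrans_q25=float(kq[0.25]),
                             ktrans_q75=float(kq[0.75]),
                             ve_median=float(vq[0.5]), ve_q25=float(vq[0.25]),
                             ve_q75=float(vq[0.75]),
                             frac_flagged=1.0 - len(usable) / n_all)

    maps = {}
    if mode == "voxelwise":
        for name, col in (("ktrans", "ktrans_min^-1"), ("ve", "ve"), ("ratio_R", "ratio_R")):
            vol = np.full(mask.shape, np.nan)
            for (key, _), val in zip(results, table[col]):
                vol[key] = val
            maps[name] = vol
    return FitOutput(summary=summary, voxel_table=table, maps=maps,
                     rr_curve=r1_rr, r10_rr=r10_rr)


def analyze_cohort(cohort, config: FitConfig | None = None) -> pd.DataFrame:
    """Fit every animal-day ROI curve pair of a synthetic cohort.

    Returns a tidy table with one row per animal and day: fitted Ktrans and
    ve (as ``ktrans_median`` / ``ve_median``, each animal-day contributing a
    single ROI-level fit), convergence, flags and a ``usable`` indicator.
    Feed the usable rows to :func:`cohort_report` for the day-pair
    statistics.
    """
    config = config or FitConfig()
    rows = []
    for rec in cohort.records:
        c = rec.curves
        r1_rr, rr_state = _r1_chain(c.s_ref_rr, c.s_dce_rr, cohort.spec.protocol)
        r1_toi, toi_state = _r1_chain(c.s_ref_toi, c.s_dce_toi, cohort.spec.protocol)
        flags: list[str] = []
        fit = None
        if rr_state is None or toi_state is None:
            flags.append("no-baseline")
        else:
            nb = cohort.spec.protocol.n_baseline
            base = r1_toi.values[:nb][r1_toi.valid[:nb]]
            noise = float(base.std(ddof=1)) if base.size >= 2 else None
            fit = fit_rrm(r1_toi, r1_rr, toi_state.r10, rr_state.r10,
                          kinetics_rr=config.kinetics_rr, config=config,
                          baseline_noise=noise)
            flags.extend(fit.flags)
        usable = (fit is not None and fit.kinetics is not None
                  and fit.converged and not flags)
        rows.append({
            "animal": rec.animal, "day": rec.day,
            "ktrans_median": fit.kinetics.ktrans if fit and fit.kinetics else np.nan,
            "ve_median": fit.kinetics.ve if fit and fit.kinetics else np.nan,
            "ktrans_true_min^-1": rec.kinetics_true.ktrans,
            "ve_true": rec.kinetics_true.ve,
            "converged": bool(fit.converged) if fit else False,
            "flags": ";".join(flags), "usable": usable,
        })
    return pd.DataFrame(rows)


def bonferroni_pairwise(groups: dict) -> list[ComparisonResult]:
    """All pairwise Welch tests between groups, Bonferroni-adjusted.

    ``groups`` maps a label (e.g. measurement day) to a collection of values
    (e.g. per-animal ROI medians).  Groups with fewer than two values are
    excluded with a warning.  The adjustment multiplies each raw p by the
    number of tested pairs (capped at 1); tiers mark p < 0.05 and p < 0.01
    on the adjusted values.
    """
    usable = {}
    for label, vals in groups.items():
        vals = np.asarray(list(vals), dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            logger.warning("group %r has fewer than 2 values; excluded", label)
            continue
        usable[label] = vals
    if len(usable) < 2:
        return []
    pairs = list(itertools.combinations(sorted(usable), 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        p_raw = float(stats.ttest_ind(usable[a], usable[b], equal_var=False).pvalue)
        p_adj = min(1.0, p_raw * m)
        tier = "p<0.01" if p_adj < HIGH_SIG else ("p<0.05" if p_adj < SIG else "none")
        out.append(ComparisonResult(group_a=a, group_b=b, p_raw=p_raw,
                                    p_adjusted=p_adj, tier=tier))
    return out


def cohort_report(summary_table: pd.DataFrame,
                  value_columns: tuple = ("ktrans_median", "ve_median")) -> dict:
    """Longitudinal day-pair comparisons for each kinetic parameter.

    ``summary_table`` needs one row per animal and day with the given value
    columns (the per-animal ROI medians).  Returns a mapping parameter ->
    tidy comparison DataFrame; parameters whose column is absent or entirely
    non-finite are reported with an empty table and noted in the log.
    """
    report = {}
    for col in value_columns:
        if col not in summary_table.columns or not np.isfinite(
                summary_table[col].to_numpy(dtype=float)).any():
            logger.warning("column %r missing or empty; excluded from report", col)
            report[col] = pd.DataFrame(
                columns=["group_a", "group_b", "p_raw", "p_adjusted", "tier"])
            continue
        groups = {day: sub[col].to_numpy(dtype=float)
                  for day, sub in summary_table.groupby("day")}
        comps = bonferroni_pairwise(groups)
        report[col] = pd.DataFrame(
            [{"group_a": c.group_a, "group_b": c.group_b, "p_raw": c.p_raw,
              "p_adjusted": c.p_adjusted, "tier": c.tier} for c in comps],
            columns=["group_a", "group_b", "p_raw", "p_adjusted", "tier"])
    return report
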