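"""Replicate-agreement and slide-quality metrics.

Four statistics quantify slide quality before vs after spatial
normalization:

* %CV — 100 * sigma / mu over a replicate group (sample standard
  deviation, n-1 denominator); the primary noise metric, with a
  conventional 15% slide-acceptance cutoff on the slide-mean %CV of
  biological replicates.
* Pearson's rho between corresponding spots of duplicate slides.
* Z'-factor, 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|, separating positive
  from negative (buffer) controls; 1 is the noise-free limit.
* Welch's t for the positive-vs-negative mean difference.

Replicates are only comparable within one dilution step (successive
half-dilutions differ two-fold by design), so group dispersion is computed
per dilution stratum and averaged. For the same reason a Pearson rho pooled
across dilution steps is inflated by the dilution range itself; see
:func:`dilution_correlations` for the per-stratum diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .layout import Slide, SpotRole
from .spatial import NormalizedSlide

logger = logging.getLogger("rppanorm")

__all__ = [
    "cv_percent",
    "pearson",
    "z_prime",
    "welch_t",
    "QCReport",
    "BeforeAfterReport",
    "slide_cv",
    "held_out_control_cv",
    "control_separation",
    "compare_before_after",
    "dilution_correlations",
    "DEFAULT_CV_CUTOFF",
]

DEFAULT_CV_CUTOFF = 15.0


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation as a percentage: 100 * sigma / mu.

    Sample standard deviation (n-1). Requires at least two values and a
    nonzero mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("%CV needs at least two values")
    mu = x.mean()
    if mu == 0:
        raise ValueError("%CV undefined for zero-mean values")
    return float(100.0 * x.std(ddof=1) / mu)


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation between paired measurements."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two equal-length vectors of >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for a constant input")
    return float(np.corrcoef(x, y)[0, 1])


def z_prime(positives: Sequence[float], negatives: Sequence[float]) -> float:
    """Z'-factor: 1 - 3(sigma_p + sigma_n) / |mu_p - mu_n|.

    Screening-assay quality statistic; larger is better and 1 is attained
    only with zero dispersion in both control groups.
    """
    p = np.asarray(positives, dtype=float)
    n = np.asarray(negatives, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValueError("z_prime needs at least two values per group")
    sep = abs(p.mean() - n.mean())
    if sep == 0:
        raise ValueError("z_prime undefined for equal group means")
    return float(1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / sep)


def welch_t(a: Sequence[float], b: Sequence[float]) -> float:
    """Welch's t statistic for unequal-variance group mean difference."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs at least two values per group")
    with warnings.catch_warnings():
        # scipy warns about precision on near-constant groups (e.g. clean
        # buffer spots); the statistic itself is well defined there
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(x, y, equal_var=False).statistic)


# ---------------------------------------------------------------------------
# slide-level reports
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-group %CV summary for one slide.

    ``group_cv`` maps replicate-group label to %CV (mean over dilution
    strata); ``mean_cv`` is their unweighted mean and ``passed`` compares
    it with ``cutoff``. Groups that resolve to fewer than two valid spots
    in every stratum are listed in ``unresolved`` and excluded.
    """

    group_cv: dict[str, float]
    mean_cv: float
    cutoff: float
    passed: bool
    unresolved: list[str] = field(default_factory=list)
    values_used: str = "intensity"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": list(self.group_cv), "cv_percent": list(self.group_cv.values())}
        )


def _spot_values(
    data: Union[Slide, NormalizedSlide], values: str = "auto"
) -> tuple[pd.DataFrame, str]:
    """Valid spots with a 'value' column: raw, corrected, or auto-detected."""
    if isinstance(data, NormalizedSlide):
        df = data.slide.spots.copy()
        df["corrected"] = data.corrected
        kind = "corrected" if values in ("auto", "corrected") else "intensity"
    else:
        df = data.spots
        if values == "corrected" and "corrected" not in df.columns:
            raise ValueError("slide carries no corrected column")
        kind = "corrected" if values == "corrected" or (
            values == "auto" and "corrected" in df.columns) else "intensity"
    df = df[df["valid"]].copy()
    df["value"] = df[kind].astype(float)
    return df, kind


def slide_cv(
    data: Union[Slide, NormalizedSlide],
    grouping: Mapping[str, str],
    cutoff: float = DEFAULT_CV_CUTOFF,
    values: str = "auto",
) -> QCReport:
    """Per-replicate-group %CV and the slide-mean %CV with a pass flag.

    ``grouping`` maps sample_id to a replicate-group label. Within each
    group, %CV is computed per dilution step (replicates of one group are
    only identical within a step) and the group %CV is the unweighted mean
    over steps; the slide %CV is the unweighted mean over groups.
    ``values`` selects "intensity", "corrected", or "auto" (corrected when
    present).
    """
    df, kind = _spot_values(data, values)
    df = df[df["sample_id"].isin(grouping)]
    df["group"] = df["sample_id"].map(grouping)

    group_cv: dict[str, float] = {}
    unresolved: list[str] = []
    for label, grp in df.groupby("group", sort=True):
        strata = [
            cv_percent(sub["value"].to_numpy())
            for _, sub in grp.groupby("dilution_step")
            if len(sub) >= 2 and sub["value"].mean() != 0
        ]
        if not strata:
            unresolved.append(str(label))
            continue
        group_cv[str(label)] = float(np.mean(strata))
    for label in set(map(str, grouping.values())) - set(group_cv) - set(unresolved):
        unresolved.append(label)
    if unresolved:
        warnings.warn(
            f"{len(unresolved)} replicate group(s) unresolved; excluded from "
            f"the slide mean", stacklevel=2,
        )
    if not group_cv:
        raise ValueError("no replicate group resolved to >= 2 valid spots")
    mean_cv = float(np.mean(list(group_cv.values())))
    return QCReport(
        group_cv=group_cv, mean_cv=mean_cv, cutoff=cutoff,
        passed=mean_cv <= cutoff, unresolved=sorted(unresolved),
        values_used=kind,
    )


def held_out_control_cv(
    data: Union[Slide, NormalizedSlide],
    exclude_positions: Optional[set[tuple[int, int]]] = None,
    values: str = "auto",
) -> dict[int, float]:
    """%CV of positive-control spots per dilution step.

    All positive controls of one dilution are intra-slide technical
    replicates, so their %CV per step measures residual spatial noise.
    ``exclude_positions`` drops the (row, col) positions used as anchors,
    leaving only held-out dilutions to score the normalization honestly.
    """
    df, _ = _spot_values(data, values)
    df = df[df["role"] == SpotRole.POSITIVE_CONTROL.value]
    if exclude_positions:
        keep = [
            (int(r), int(c)) not in exclude_positions
            for r, c in zip(df["row"], df["col"])
        ]
        df = df[np.asarray(keep, dtype=bool)]
    return {
        int(step): cv_percent(sub["value"].to_numpy())
        for step, sub in df.groupby("dilution_step")
        if len(sub) >= 2
    }


def control_separation(
    data: Union[Slide, NormalizedSlide], values: str = "auto"
) -> tuple[float, float]:
    """Mean per-dilution Z'-factor and Welch t of positive vs buffer spots.

    Positive controls are stratified by dilution step (pooling steps would
    inflate sigma_p with the dilution range itself); each stratum is
    compared against all valid buffer spots and the statistics are
    averaged over strata.
    """
    df, _ = _spot_values(data, values)
    neg = df.loc[df["role"] == SpotRole.NEGATIVE_CONTROL.value, "value"].to_numpy()
    pos = df[df["role"] == SpotRole.POSITIVE_CONTROL.value]
    if neg.size < 2 or pos.empty:
        raise ValueError("need >= 2 negative controls and positive controls")
    zs, ts = [], []
    for _, sub in pos.groupby("dilution_step"):
        if len(sub) >= 2:
            zs.append(z_prime(sub["value"].to_numpy(), neg))
            ts.append(welch_t(sub["value"].to_numpy(), neg))
    return float(np.mean(zs)), float(np.mean(ts))


@dataclass
class BeforeAfterReport:
    """Paired before/after QC for one slide (optionally a duplicate pair)."""

    before: QCReport
    after: QCReport
    delta_cv: dict[str, float]
    mean_delta_cv: float
    rho_before: Optional[float] = None
    rho_after: Optional[float] = None
    z_prime_before: Optional[float] = None
    z_prime_after: Optional[float] = None
    welch_before: Optional[float] = None
    welch_after: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        groups = sorted(set(self.before.group_cv) & set(self.after.group_cv))
        return pd.DataFrame({
            "group": groups,
            "cv_before": [self.before.group_cv[g] for g in groups],
            "cv_after": [self.after.group_cv[g] for g in groups],
            "delta": [self.delta_cv[g] for g in groups],
        })


def compare_before_after(
    raw: Slide,
    normalized: NormalizedSlide,
    grouping: Mapping[str, str],
    cutoff: float = DEFAULT_CV_CUTOFF,
    duplicate: Optional[tuple[Slide, NormalizedSlide]] = None,
) -> BeforeAfterReport:
    """Replicate QC before vs after normalization, with optional pair rho.

    ``duplicate`` supplies a second slide printed with the same samples at
    equivalent locations; Pearson rho is then computed across matched
    valid spots of the two slides, before (raw intensities) and after
    (corrected). Z' and Welch t compare positive-control strata against
    buffer spots on the primary slide.
    """
    if normalized.slide.layout.params() != raw.layout.params():
        raise ValueError("raw and normalized slides use different layouts")
    before = slide_cv(raw, grouping, cutoff=cutoff, values="intensity")
    after = slide_cv(normalized, grouping, cutoff=cutoff, values="corrected")
    delta = {
        g: after.group_cv[g] - before.group_cv[g]
        for g in set(before.group_cv) & set(after.group_cv)
    }
    report = BeforeAfterReport(
        before=before, after=after, delta_cv=delta,
        mean_delta_cv=after.mean_cv - before.mean_cv,
    )
    try:
        report.z_prime_before, report.welch_before = control_separation(
            raw, values="intensity")
        report.z_prime_after, report.welch_after = control_separation(
            normalized, values="corrected")
    except ValueError:
        logger.info("control separation skipped: insufficient control spots")

    if duplicate is not None:
        raw2, norm2 = duplicate
        if raw2.layout.params() != raw.layout.params():
            raise ValueError("duplicate slide uses a different layout")
        both = raw.spots["valid"].to_numpy() & raw2.spots["valid"].to_numpy()
        report.rho_before = pearson(
            raw.spots.loc[both, "intensity"], raw2.spots.loc[both, "intensity"])
        report.rho_after = pearson(
            normalized.corrected[both], norm2.corrected[both])
    return report


def dilution_correlations(
    a: Union[Slide, NormalizedSlide],
    b: Union[Slide, NormalizedSlide],
    role: SpotRole = SpotRole.SAMPLE,
    values: str = "auto",
) -> tuple[float, dict[int, float]]:
    """Pooled vs per-dilution Pearson rho between two duplicate slides.

    A rho pooled across all dilution steps is inflated by the two-fold
    spacing of the steps themselves; per-step rho is the honest
    reproducibility measure. Returns (pooled_rho, {step: rho}).
    """
    da, _ = _spot_values(a, values)
    db, _ = _spot_values(b, values)
    da = da[da["role"] == role.value].set_index(["row", "col"])
    db = db[db["role"] == role.value].set_index(["row", "col"])
    common = da.index.intersection(db.index)
    da, db = da.loc[common], db.loc[common]
    pooled = pearson(da["value"], db["value"])
    per_step = {
        int(step): pearson(sub["value"], db.loc[sub.index, "value"])
        for step, sub in da.groupby("dilution_step")
        if len(sub) >= 3
    }
    return pooled, per_step
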