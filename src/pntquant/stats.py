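"""Cohort statistics: method/group comparisons, Bland-Altman agreement and
simulated observer repeatability.

Summaries follow the study conventions: continuous variables as mean plus or
minus the standard error of the mean (SEM), paired t-tests within a group
between the two contouring methods, Welch t-tests between groups, and
Bland-Altman mean difference, 95% limits of agreement and the coefficient of
repeatability (1.96 times the SD of the differences; the factor is
configurable since some literature uses 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateStatisticsError, ValidationError
from .flow import aortic_stroke_volume
from .phantom import SubjectRecord, build_phantom
from .quantify import QuantConfig, VentricularMeasures, body_surface_area, ventricular_measures
from .segmentation import SegmentationConfig, segment_subject

MEASURE_FIELDS = ("lvedv", "lvesv", "lvsv", "lvef", "lvm", "lvm_indexed")


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def paired_t(x, y) -> tuple[float, float]:
    """Classical paired t-test on x - y; two-sided p with n-1 df.

    Identical vectors give (0, 1); a constant non-zero difference has no
    within-pair variance and raises DegenerateStatisticsError.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired vectors must be 1D and of equal length")
    if x.size < 2:
        raise ValidationError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise DegenerateStatisticsError("differences are a non-zero constant")
    t = d.mean() / (sd / math.sqrt(d.size))
    p = 2.0 * sps.t.sf(abs(t), d.size - 1)
    return float(t), float(p)


def independent_t(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Independent-samples t-test; Welch (unequal variances) by default."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least two observations")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise DegenerateStatisticsError("both groups have zero variance")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    coefficient_of_repeatability: float
    n: int

    def __post_init__(self) -> None:
        if not self.loa_lower - 1e-12 <= self.mean_difference <= self.loa_upper + 1e-12:
            raise ValidationError("limits of agreement must bracket the mean difference")
        if self.coefficient_of_repeatability < 0:
            raise ValidationError("coefficient of repeatability must be >= 0")


def bland_altman(x, y, cr_factor: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements (differences x - y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("need two 1D vectors with at least two pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = cr_factor * sd
    return BlandAltmanResult(
        mean_difference=mean,
        sd_difference=sd,
        loa_lower=mean - half,
        loa_upper=mean + half,
        coefficient_of_repeatability=half,
        n=int(d.size),
    )


def plot_bland_altman(result: BlandAltmanResult, x, y, ax=None, title: str = ""):
    """Conventional Bland-Altman plot (mean vs difference with LoA lines)."""
    import matplotlib.pyplot as plt

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2.0, x - y, s=18)
    ax.axhline(result.mean_difference, color="k")
    for loa in (result.loa_lower, result.loa_upper):
        ax.axhline(loa, color="k", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    return ax


# ---------------------------------------------------------------------------
# cohort-level analyses
# ---------------------------------------------------------------------------

@dataclass
class SubjectMeasures:
    """A subject with both methods' ventricular measures and the flow SV."""

    record: SubjectRecord
    minc: VentricularMeasures
    mex: VentricularMeasures
    aortic_sv: float | None = None

    def by_method(self, method: str) -> VentricularMeasures:
        return self.minc if method == "minc" else self.mex


def measure_cohort(
    records: list[SubjectRecord],
    seg_config: SegmentationConfig | None = None,
    quant_config: QuantConfig | None = None,
    with_flow: bool = True,
) -> list[SubjectMeasures]:
    """Run segmentation, quantification and (optionally) flow on a cohort."""
    seg_config = seg_config or SegmentationConfig()
    quant_config = quant_config or QuantConfig()
    out = []
    for rec in records:
        seg = segment_subject(rec.cine, seg_config)
        bsa = body_surface_area(rec.height, rec.weight, quant_config)
        minc = ventricular_measures(seg, rec.cine, "minc", quant_config, bsa=bsa)
        mex = ventricular_measures(seg, rec.cine, "mex", quant_config, bsa=bsa)
        sv = aortic_stroke_volume(rec.velocity).aortic_sv if with_flow else None
        out.append(SubjectMeasures(record=rec, minc=minc, mex=mex, aortic_sv=sv))
    return out


def measures_frame(measured: list[SubjectMeasures]) -> pd.DataFrame:
    """Long-format per-subject table (one row per subject and method)."""
    rows = []
    for m in measured:
        for method in ("minc", "mex"):
            vm = m.by_method(method)
            rows.append(
                {
                    "subject_id": m.record.subject_id,
                    "group": m.record.group,
                    "method": method,
                    "lvedv": vm.lvedv,
                    "lvesv": vm.lvesv,
                    "lvsv": vm.lvsv,
                    "lvef": vm.lvef,
                    "lvm": vm.lvm,
                    "lvm_indexed": vm.lvm_indexed,
                    "pnt_mass": vm.pnt_mass,
                    "pnt_fraction": vm.pnt_fraction,
                    "aortic_sv": m.aortic_sv,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CohortSummary:
    """Mean +/- SEM per group and method with paired and between-group p-values."""

    table: pd.DataFrame = field(repr=False)
    n_per_group: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.table


def cohort_table(measured: list[SubjectMeasures]) -> CohortSummary:
    """Summary table shaped like the published method comparison.

    For every measure and group: mean and SEM under each method and the
    paired p-value between methods; plus between-group (Welch) p-values per
    method. Degenerate paired comparisons (identical methods) report p = 1.
    """
    if not measured:
        raise ValidationError("empty cohort")
    groups = sorted({m.record.group for m in measured})
    by_group = {g: [m for m in measured if m.record.group == g] for g in groups}
    for g, ms in by_group.items():
        if len(ms) < 2:
            raise ValidationError(f"group {g!r} needs at least two subjects")

    rows = []
    for measure in MEASURE_FIELDS:
        row: dict = {"measure": measure}
        for g in groups:
            vals = {
                method: np.array([getattr(m.by_method(method), measure) for m in by_group[g]])
                for method in ("minc", "mex")
            }
            n = len(by_group[g])
            for method in ("minc", "mex"):
                row[f"{g}_{method}_mean"] = vals[method].mean()
                row[f"{g}_{method}_sem"] = vals[method].std(ddof=1) / math.sqrt(n)
            try:
                _, p = paired_t(vals["minc"], vals["mex"])
            except DegenerateStatisticsError:
                p = float("nan")
            row[f"{g}_paired_p"] = p
        if len(groups) == 2:
            g0, g1 = groups
            for method in ("minc", "mex"):
                a = np.array([getattr(m.by_method(method), measure) for m in by_group[g0]])
                b = np.array([getattr(m.by_method(method), measure) for m in by_group[g1]])
                try:
                    _, p = independent_t(a, b)
                except DegenerateStatisticsError:
                    p = float("nan")
                row[f"between_{method}_p"] = p
        rows.append(row)
    return CohortSummary(
        table=pd.DataFrame(rows).set_index("measure"),
        n_per_group={g: len(ms) for g, ms in by_group.items()},
    )


def flow_concordance(
    measured: list[SubjectMeasures], method: str
) -> tuple[float, float, float]:
    """Volumetric-minus-aortic stroke-volume concordance for one method.

    Returns (mean difference ml, SEM ml, p-value of a one-sample t vs 0).
    """
    if not measured:
        raise ValidationError("empty cohort")
    if any(m.aortic_sv is None for m in measured):
        raise ValidationError("flow measurements missing for some subjects")
    d = np.array([m.by_method(method).lvsv - m.aortic_sv for m in measured])
    if d.size < 2:
        raise ValidationError("need at least two subjects")
    mean = float(d.mean())
    sem = float(d.std(ddof=1) / math.sqrt(d.size))
    if d.std(ddof=1) == 0:
        p = 1.0 if mean == 0 else 0.0
    else:
        p = float(sps.ttest_1samp(d, 0.0).pvalue)
    return mean, sem, p


# ---------------------------------------------------------------------------
# simulated observer repeatability
# ---------------------------------------------------------------------------

def observer_repeatability(
    records: list[SubjectRecord],
    perturbation_seed: int,
    noise_redraw: bool = True,
    roi_rotation_deg: float = 15.0,
    seg_config: SegmentationConfig | None = None,
    quant_config: QuantConfig | None = None,
) -> dict:
    """Bland-Altman repeatability of LVEDV/LVESV under re-measurement.

    Repeated measurement is simulated on the first ceil(n/2) subjects by
    re-rendering the acquisition with fresh noise (same anatomy) and rotating
    the free-wall reference sector — nuisance perturbations standing in for a
    second observer. With both perturbations disabled the repeat run is
    identical and every Bland-Altman result is all-zero.

    Returns {(measure, method): BlandAltmanResult}.
    """
    if not records:
        raise ValidationError("empty cohort")
    seg_config = seg_config or SegmentationConfig()
    quant_config = quant_config or QuantConfig()
    half = records[: max(math.ceil(len(records) / 2), 2)]
    if len(half) < 2:
        raise ValidationError("repeatability needs at least two subjects")
    rng = np.random.default_rng(perturbation_seed)

    first = measure_cohort(half, seg_config, quant_config, with_flow=False)
    second = []
    for rec in half:
        rec2 = rec
        if noise_redraw:
            if rec.spec is None:
                raise ValidationError("subject records lack the phantom spec for re-rendering")
            new_seed = int(rng.integers(0, 2**31 - 1))
            cine, velocity, truth = build_phantom(rec.spec, new_seed)
            rec2 = SubjectRecord(
                subject_id=rec.subject_id, group=rec.group, height=rec.height,
                weight=rec.weight, cine=cine, velocity=velocity, truth=truth,
                spec=rec.spec, seed=new_seed,
            )
        cfg2 = seg_config
        if roi_rotation_deg:
            delta = float(rng.uniform(-roi_rotation_deg, roi_rotation_deg))
            cfg2 = SegmentationConfig(
                intensity_band_sd=seg_config.intensity_band_sd,
                min_trabecula_width=seg_config.min_trabecula_width,
                smooth_closing_radius=seg_config.smooth_closing_radius,
                freewall_roi_policy=seg_config.freewall_roi_policy,
                freewall_sector_deg=seg_config.freewall_sector_deg,
                freewall_angle_deg=seg_config.freewall_angle_deg + delta,
                basal_enclosure_threshold=seg_config.basal_enclosure_threshold,
            )
        second.extend(measure_cohort([rec2], cfg2, quant_config, with_flow=False))

    out = {}
    for measure in ("lvedv", "lvesv"):
        for method in ("minc", "mex"):
            a = [getattr(m.by_method(method), measure) for m in first]
            b = [getattr(m.by_method(method), measure) for m in second]
            out[(measure, method)] = bland_altman(a, b)
    return out
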