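"""Vertebral morphometrics: decomposing tail length into vertebra count and
vertebra length.

Measurements arrive as ordered per-vertebra lengths starting at the first
sacral vertebra.  By convention the first six vertebrae are "sacral" and
everything posterior is "caudal"; this fixed rule makes caudal counts and
per-position lengths comparable across individuals regardless of where the
anatomical boundary actually falls.  The module provides:

* per-column summaries (caudal count, total, longest vertebra and position);
* allometric size correction by regressing a response on sacral length;
* group comparisons (rank-sum, Kruskal-Wallis, two-way ANCOVA on logs);
* per-position median profiles and detection of the elongated segment (the
  run of caudal positions where the longer-tailed group's median exceeds the
  median longest vertebra of the shorter-tailed group);
* the counterfactual vertebra-insertion statistic: how much of the group
  difference in total caudal length is compensated by giving each
  short-tailed individual k extra copies of its own longest vertebra; and
* the two-predictor decomposition model
  total caudal length ~ longest vertebra + caudal count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

N_SACRAL = 6

#: Adult minima for the species: specimens below either are excluded.
ADULT_MIN_TOTAL_MM = 106.0
ADULT_MIN_TAIL_MM = 46.0


@dataclass
class VertebralColumn:
    """Ordered vertebra lengths for one individual, position 1 = first sacral."""

    individual_id: str
    lengths_mm: np.ndarray
    population: str = ""
    habitat: str = ""

    def __post_init__(self):
        self.lengths_mm = np.asarray(self.lengths_mm, float)
        if len(self.lengths_mm) < N_SACRAL + 1:
            raise ValueError(
                f"{self.individual_id}: need at least {N_SACRAL + 1} vertebrae "
                "(6 sacral + >= 1 caudal)")
        if np.any(self.lengths_mm <= 0):
            raise ValueError(f"{self.individual_id}: vertebra lengths must be > 0")

    @property
    def caudal(self) -> np.ndarray:
        """Caudal lengths re-indexed to caudal positions 1..N."""
        return self.lengths_mm[N_SACRAL:]


@dataclass
class ColumnSummary:
    individual_id: str
    population: str
    habitat: str
    sacral_sum: float
    caudal_count: int
    caudal_total: float
    longest_caudal: float
    longest_position: int           # 1-based caudal position
    caudal_lengths: np.ndarray
    residual: dict = field(default_factory=dict)  # filled by size_correct


def summarize_column(c: VertebralColumn) -> ColumnSummary:
    caudal = c.caudal
    return ColumnSummary(
        individual_id=c.individual_id,
        population=c.population,
        habitat=c.habitat,
        sacral_sum=float(c.lengths_mm[:N_SACRAL].sum()),
        caudal_count=int(len(caudal)),
        caudal_total=float(caudal.sum()),
        longest_caudal=float(caudal.max()),
        longest_position=int(np.argmax(caudal)) + 1,
        caudal_lengths=caudal.copy(),
    )


def summaries_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"individual_id": s.individual_id, "population": s.population,
               "habitat": s.habitat, "sacral_sum": s.sacral_sum,
               "caudal_count": s.caudal_count, "caudal_total": s.caudal_total,
               "longest_caudal": s.longest_caudal,
               "longest_position": s.longest_position}
        row.update({f"resid_{k}": v for k, v in s.residual.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def size_correct(summaries, response: str = "caudal_total"):
    """Regress a summary field on sacral length; attach residuals.

    One pooled ordinary-least-squares fit across all individuals (with
    intercept); residuals are stored on each summary under
    ``residual[response]``.  Returns (slope, intercept, r2).
    """
    summaries = list(summaries)
    if len(summaries) < 3:
        raise ValueError("size correction needs at least three individuals")
    sac = np.array([s.sacral_sum for s in summaries])
    resp = np.array([float(getattr(s, response)) for s in summaries])
    if np.var(sac) <= 0:
        raise ValueError("sacral length has zero variance; cannot size-correct")
    x = sm.add_constant(sac)
    fit = sm.OLS(resp, x).fit()
    for s, r in zip(summaries, fit.resid):
        s.residual[response] = float(r)
    return float(fit.params[1]), float(fit.params[0]), float(fit.rsquared)


def compare_groups(summaries, group_field: str = "habitat",
                   two_way_field: str = "population") -> dict:
    """Rank and ANCOVA comparisons of tail components between groups.

    Rank-sum (Mann-Whitney, two-sided, mid-rank ties) on the size-corrected
    caudal total, the caudal count, and the size-corrected longest vertebra
    for the two-group case; Kruskal-Wallis on caudal count across all
    groups; and a two-way ANCOVA of log caudal total and log longest
    vertebra on the grouping factor, ``two_way_field``, and log sacral
    length.
    """
    summaries = list(summaries)
    df = summaries_frame(summaries)
    groups = df[group_field].unique().tolist()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if (df.groupby(group_field).size() < 2).any():
        raise ValueError("every group needs at least two members")

    size_correct(summaries, "caudal_total")
    size_correct(summaries, "longest_caudal")
    df = summaries_frame(summaries)

    report: dict = {"groups": groups}
    if len(groups) == 2:
        a = df[df[group_field] == groups[0]]
        b = df[df[group_field] == groups[1]]
        for trait, col in (("caudal_total", "resid_caudal_total"),
                           ("caudal_count", "caudal_count"),
                           ("longest_caudal", "resid_longest_caudal")):
            u, p = stats.mannwhitneyu(a[col], b[col], alternative="two-sided")
            report[f"ranksum_{trait}"] = {"U": float(u), "p": float(p)}

    counts = [df.loc[df[group_field] == g, "caudal_count"].to_numpy()
              for g in groups]
    if len(groups) >= 2:
        hstat, p = stats.kruskal(*counts)
        report["kruskal_caudal_count"] = {"chi2": float(hstat), "p": float(p)}

    anc = df.assign(log_total=np.log(df["caudal_total"]),
                    log_longest=np.log(df["longest_caudal"]),
                    log_sacral=np.log(df["sacral_sum"]))
    for name, resp in (("caudal_total", "log_total"),
                       ("longest_caudal", "log_longest")):
        terms = [f"C({group_field})", "log_sacral"]
        if two_way_field and anc[two_way_field].nunique() > 1 and \
                two_way_field != group_field:
            terms.insert(1, f"C({two_way_field})")
        fit = smf.ols(f"{resp} ~ " + " + ".join(terms), data=anc).fit()
        an = sm.stats.anova_lm(fit, typ=2)
        report[f"ancova_{name}"] = {
            str(idx): {"F": float(row["F"]), "p": float(row["PR(>F)"])}
            for idx, row in an.iterrows() if np.isfinite(row["F"])}
    return report


@dataclass
class ProfileComparison:
    positions: np.ndarray          # caudal positions with medians in both groups
    median_a: np.ndarray
    median_b: np.ndarray
    reference: float               # median of per-individual longest in group B
    elongated_segment: tuple | None  # (first, last) caudal positions, or None
    flagged_positions: list        # positions with < 50% representation
    cumulative_a: np.ndarray
    cumulative_b: np.ndarray


def _position_medians(columns, max_pos: int):
    """Per-position medians where >= half the group has that vertebra."""
    med = np.full(max_pos, np.nan)
    frac = np.zeros(max_pos)
    n = len(columns)
    for p in range(max_pos):
        vals = [c.caudal[p] for c in columns if len(c.caudal) > p]
        frac[p] = len(vals) / n
        if len(vals) >= 0.5 * n and vals:
            med[p] = np.median(vals)
    return med, frac


def profile_compare(group_a, group_b) -> ProfileComparison:
    """Compare per-position caudal profiles; B is the shorter-tailed reference.

    The elongated segment is the maximal contiguous run of caudal positions
    at which group A's median length exceeds the reference value, defined as
    the median over group-B individuals of each one's longest caudal
    vertebra.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    max_pos = max(max(len(c.caudal) for c in group_a),
                  max(len(c.caudal) for c in group_b))
    med_a, frac_a = _position_medians(group_a, max_pos)
    med_b, frac_b = _position_medians(group_b, max_pos)
    reference = float(np.median([c.caudal.max() for c in group_b]))

    exceed = np.where(np.isnan(med_a), False, med_a > reference)
    best, cur_start, best_span = None, None, 0
    for i, flag in enumerate(list(exceed) + [False]):
        if flag and cur_start is None:
            cur_start = i
        elif not flag and cur_start is not None:
            if i - cur_start > best_span:
                best_span, best = i - cur_start, (cur_start + 1, i)  # 1-based
            cur_start = None
    flagged = [int(p) + 1 for p in range(max_pos)
               if (0 < frac_a[p] < 0.5) or (0 < frac_b[p] < 0.5)]
    cum_a = np.nancumsum(np.nan_to_num(med_a, nan=0.0))
    cum_b = np.nancumsum(np.nan_to_num(med_b, nan=0.0))
    both = ~np.isnan(med_a) & ~np.isnan(med_b)
    return ProfileComparison(positions=np.flatnonzero(both) + 1,
                             median_a=med_a, median_b=med_b,
                             reference=reference, elongated_segment=best,
                             flagged_positions=flagged,
                             cumulative_a=cum_a, cumulative_b=cum_b)


@dataclass
class CounterfactualResult:
    k: int
    compensation: float | None     # None when forest is not longer on average
    numerator: float               # mean counterfactual - mean prairie total
    denominator: float             # mean forest - mean prairie total
    counterfactual_totals: np.ndarray


def insertion_counterfactual(short_group, long_group,
                             k: int | None = None,
                             mode: str = "individual_longest") -> CounterfactualResult:
    """The "prairie + k" counterfactual tail experiment.

    For each column of the short-tailed group, ``k`` extra vertebrae are
    inserted at the middle caudal position (floor(N/2) after re-indexing);
    each inserted vertebra is a copy of that individual's own longest caudal
    vertebra (``mode="individual_longest"``, the upper-bound construction)
    or of the group median length at the insertion point
    (``mode="local_median"``).  The compensation fraction is the share of
    the between-group difference in mean total caudal length recovered:

        (mean counterfactual - mean short) / (mean long - mean short).

    ``k`` defaults to the rounded difference in mean caudal counts.  When
    the long-tailed group is not actually longer on average the fraction is
    undefined and ``compensation`` is None.
    """
    short_group, long_group = list(short_group), list(long_group)
    if not short_group or not long_group:
        raise ValueError("both groups must be nonempty")
    if k is None:
        k = int(round(np.mean([len(c.caudal) for c in long_group])
                      - np.mean([len(c.caudal) for c in short_group])))
    if k < 0:
        raise ValueError("k must be >= 0")
    if mode not in ("individual_longest", "local_median"):
        raise ValueError(f"unknown mode {mode!r}")

    totals_cf = []
    for c in short_group:
        caudal = c.caudal
        mid = len(caudal) // 2
        if mode == "individual_longest":
            insert_len = caudal.max()
        else:
            vals = [o.caudal[mid] for o in short_group if len(o.caudal) > mid]
            insert_len = float(np.median(vals))
        totals_cf.append(caudal.sum() + k * insert_len)
    totals_cf = np.asarray(totals_cf)

    mean_short = float(np.mean([c.caudal.sum() for c in short_group]))
    mean_long = float(np.mean([c.caudal.sum() for c in long_group]))
    numerator = float(totals_cf.mean() - mean_short)
    denominator = mean_long - mean_short
    comp = numerator / denominator if denominator > 0 else None
    return CounterfactualResult(k=int(k), compensation=comp,
                                numerator=numerator, denominator=denominator,
                                counterfactual_totals=totals_cf)


@dataclass
class DecompositionFit:
    coef_longest: float
    coef_count: float
    intercept: float
    r2: float
    condition_number: float
    n: int


def decomposition_fit(summaries) -> DecompositionFit:
    """OLS of total caudal length on longest vertebra and caudal count.

    A high R^2 says the two constituent traits jointly explain nearly all
    of the variation in total tail length.
    """
    summaries = list(summaries)
    if len(summaries) < 4:
        raise ValueError("decomposition fit needs at least four individuals")
    longest = np.array([s.longest_caudal for s in summaries])
    count = np.array([s.caudal_count for s in summaries], float)
    total = np.array([s.caudal_total for s in summaries])
    if np.var(longest) <= 0 or np.var(count) <= 0:
        raise ValueError("constant predictor; decomposition fit degenerate")
    x = sm.add_constant(np.column_stack([longest, count]))
    fit = sm.OLS(total, x).fit()
    cond = float(np.linalg.cond(x))
    if cond > 1e10:
        raise ValueError(f"predictors nearly collinear (condition number {cond:.2e})")
    return DecompositionFit(coef_longest=float(fit.params[1]),
                            coef_count=float(fit.params[2]),
                            intercept=float(fit.params[0]),
                            r2=float(fit.rsquared),
                            condition_number=cond, n=len(summaries))


def tail_body_stats(samples: pd.DataFrame) -> dict:
    """Tail/body ratio distributions and habitat test from a sample table.

    ``samples`` needs columns ``tail_mm``, ``body_mm`` and ``habitat``.
    Nonpositive measurements are rejected record-wise; records below the
    adult minima (total length < 106 mm or tail < 46 mm) are excluded and
    counted.  Group means are compared with the Kruskal-Wallis test across
    habitat classes.
    """
    df = samples.copy()
    bad = (df["tail_mm"] <= 0) | (df["body_mm"] <= 0)
    n_bad = int(bad.sum())
    df = df[~bad]
    total = df["tail_mm"] + df["body_mm"]
    juvenile = (total < ADULT_MIN_TOTAL_MM) | (df["tail_mm"] < ADULT_MIN_TAIL_MM)
    n_juv = int(juvenile.sum())
    df = df[~juvenile].copy()
    df["ratio"] = df["tail_mm"] / df["body_mm"]
    report = {"n_rejected_nonpositive": n_bad, "n_excluded_juvenile": n_juv,
              "n_retained": int(len(df)),
              "group_means": df.groupby("habitat")["ratio"].mean().to_dict(),
              "group_medians": df.groupby("habitat")["ratio"].median().to_dict()}
    groups = [g["ratio"].to_numpy() for _, g in df.groupby("habitat")]
    if len(groups) >= 2 and all(len(g) for g in groups):
        try:
            h, p = stats.kruskal(*groups)
            report["kruskal"] = {"chi2": float(h), "p": float(p)}
        except ValueError:  # all values identical across groups
            report["kruskal"] = {"chi2": 0.0, "p": 1.0}
    report["ratios"] = df[["habitat", "ratio"]]
    return report
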