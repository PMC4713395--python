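"""Stratified mortality and SMR analysis.

Produces the result tables of the pipeline: treatment-intensity
distribution by age band (and by the <80 / ≥80 dichotomy), hospital
mortality per age × intensity stratum, and the standardized mortality
ratio

    SMR = observed deaths / expected deaths,
    expected deaths = Σ per-stay SAPS II predicted mortality,

with an exact Poisson 95 % confidence interval on the observed count
(expected treated as fixed). Expected deaths use the *full* SAPS II
probability; the age-adjusted score serves only as the age-independent
severity index.

Displayed percentages are rounded half away from zero to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filters import AGE_BANDS, age_band_frame

__all__ = [
    "StratumSummary",
    "TestResult",
    "AnalysisReport",
    "round_half_away",
    "compute_smr",
    "mortality_by_group_and_age",
    "mortality_table_from_counts",
    "intensity_distribution",
    "column_percentages",
    "chi_square_test",
    "kruskal_wallis",
    "anova",
    "smr_trend",
    "run_full_analysis",
    "ALL_AGES",
]

ALL_AGES = "All ages"


def round_half_away(values, decimals: int = 1):
    """Round half away from zero (the display convention of the tables)."""
    values = np.asarray(values, dtype=np.float64)
    factor = 10.0**decimals
    out = np.sign(values) * np.floor(np.abs(values) * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class StratumSummary:
    """Counts, mortality and SMR for one age × intensity stratum."""

    age_label: str
    intensity_group: int
    n: int
    observed_deaths: int
    mortality_pct: float
    expected_deaths: Optional[float] = None
    smr: Optional[float] = None
    smr_ci: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    df: object  # int, or (df1, df2) for the F test
    p_value: float


def compute_smr(observed: float, expected: float) -> tuple[float, tuple[float, float]]:
    """SMR = observed/expected with an exact Poisson 95 % CI on observed.

    The interval is the Garwood interval on the observed count divided by
    the (fixed) expected count; ``observed = 0`` gives a lower limit of 0.
    """
    if expected <= 0:
        raise ValueError("SMR undefined: expected deaths must be > 0")
    if observed < 0:
        raise ValueError("observed deaths must be >= 0")
    low = 0.0 if observed == 0 else stats.chi2.ppf(0.025, 2 * observed) / 2.0
    high = stats.chi2.ppf(0.975, 2 * (observed + 1)) / 2.0
    return observed / expected, (low / expected, high / expected)


def _required(frame: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort frame missing required columns {missing}")


def _summaries_from_aggregates(
    n: int, deaths: int, expected: Optional[float], age_label: str, group: int
) -> StratumSummary:
    pct = round_half_away(100.0 * deaths / n, 1) if n else 0.0
    smr = ci = None
    if expected is not None and expected > 0:
        smr, ci = compute_smr(deaths, expected)
    return StratumSummary(
        age_label=age_label,
        intensity_group=group,
        n=int(n),
        observed_deaths=int(deaths),
        mortality_pct=float(pct),
        expected_deaths=None if expected is None else float(expected),
        smr=smr,
        smr_ci=ci,
    )


def _summary_frame(summaries: list[StratumSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "age_label": s.age_label,
            "intensity_group": s.intensity_group,
            "n": s.n,
            "observed_deaths": s.observed_deaths,
            "mortality_pct": s.mortality_pct,
            "expected_deaths": s.expected_deaths,
            "smr": s.smr,
            "smr_ci_low": None if s.smr_ci is None else s.smr_ci[0],
            "smr_ci_high": None if s.smr_ci is None else s.smr_ci[1],
        }
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "age_label", "intensity_group", "n", "observed_deaths", "mortality_pct",
            "expected_deaths", "smr", "smr_ci_low", "smr_ci_high",
        ],
    )


def mortality_by_group_and_age(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mortality and SMR per (age band ∪ "All ages") × intensity group.

    ``cohort`` must be filtered, scored and classified (columns
    ``predicted_mortality``, ``intensity_group``, ``hospital_death``).
    Empty cohort → empty table.
    """
    if len(cohort) == 0:
        return _summary_frame([])
    _required(cohort, ["predicted_mortality", "intensity_group", "hospital_death"])
    work = cohort if "age_band" in cohort.columns else age_band_frame(cohort)
    summaries: list[StratumSummary] = []
    groups = sorted(work["intensity_group"].unique())
    for group in groups:
        sub = work[work["intensity_group"] == group]
        for label in (ALL_AGES, *AGE_BANDS):
            block = sub if label == ALL_AGES else sub[sub["age_band"] == label]
            if len(block) == 0:
                continue
            summaries.append(
                _summaries_from_aggregates(
                    n=len(block),
                    deaths=int(block["hospital_death"].sum()),
                    expected=float(block["predicted_mortality"].sum()),
                    age_label=label,
                    group=int(group),
                )
            )
    return _summary_frame(summaries)


def mortality_table_from_counts(stratum_table: pd.DataFrame) -> pd.DataFrame:
    """Mortality table from aggregate stratum counts (no per-stay data).

    ``stratum_table`` has columns ``intensity_group``, ``age_band``, ``n``,
    ``deaths`` (one row per stratum, e.g. the printed reference counts);
    expected deaths and SMR are unavailable at this granularity.
    """
    summaries: list[StratumSummary] = []
    for group in sorted(stratum_table["intensity_group"].unique()):
        sub = stratum_table[stratum_table["intensity_group"] == group]
        summaries.append(
            _summaries_from_aggregates(
                int(sub["n"].sum()), int(sub["deaths"].sum()), None, ALL_AGES, int(group)
            )
        )
        for band in AGE_BANDS:
            row = sub[sub["age_band"] == band]
            if len(row) == 0:
                continue
            summaries.append(
                _summaries_from_aggregates(
                    int(row["n"].sum()), int(row["deaths"].sum()), None, band, int(group)
                )
            )
    return _summary_frame(summaries)


def intensity_distribution(
    source: pd.DataFrame, age_partition: str = "band"
) -> pd.DataFrame:
    """Intensity-group × age contingency table of stay counts.

    ``source`` is either a classified cohort frame or an aggregate stratum
    table (columns ``intensity_group``, ``age_band``, ``n``).
    ``age_partition`` is ``"band"`` (six SAPS II bands) or ``"binary"``
    (<80 / ≥80). Rows: intensity groups; columns: age categories.
    """
    if age_partition not in ("band", "binary"):
        raise ValueError("age_partition must be 'band' or 'binary'")
    if "n" in source.columns and "age_band" in source.columns and "stay_id" not in source.columns:
        long = source.copy()
    else:
        work = source if "age_band" in source.columns else age_band_frame(source)
        long = (
            work.groupby(["intensity_group", "age_band"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
    if age_partition == "binary":
        long = long.assign(
            age_col=np.where(long["age_band"] == ">=80", ">=80", "<80")
        )
        columns = ["<80", ">=80"]
    else:
        long = long.assign(age_col=long["age_band"])
        columns = list(AGE_BANDS)
    table = (
        long.pivot_table(
            index="intensity_group", columns="age_col", values="n",
            aggfunc="sum", fill_value=0,
        )
        .reindex(columns=columns, fill_value=0)
    )
    table = table.loc[sorted(table.index)]
    table.index.name = "intensity_group"
    table.columns.name = "age"
    return table.astype(np.int64)


def column_percentages(counts: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Column percentages of a contingency table, display-rounded."""
    totals = counts.sum(axis=0)
    pct = 100.0 * counts / totals
    return pct.apply(lambda col: round_half_away(col, decimals))


def chi_square_test(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, dtype=np.float64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult("chi_square", float(stat), int(df), float(p))


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected) across ≥ 2 groups."""
    _check_groups(samples)
    flat = np.concatenate([np.asarray(s, dtype=np.float64) for s in samples])
    if np.all(flat == flat[0]):  # scipy rejects the all-identical degenerate case
        return TestResult("kruskal_wallis", 0.0, len(samples) - 1, 1.0)
    stat, p = stats.kruskal(*samples)
    return TestResult("kruskal_wallis", float(stat), len(samples) - 1, float(p))


def anova(samples: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA F test across ≥ 2 groups."""
    _check_groups(samples)
    flat = np.concatenate([np.asarray(s, dtype=np.float64) for s in samples])
    k = len(samples)
    df = (k - 1, len(flat) - k)
    if np.all(flat == flat[0]):
        return TestResult("anova", 0.0, df, 1.0)
    stat, p = stats.f_oneway(*samples)
    return TestResult("anova", float(stat), df, float(p))


def _check_groups(samples) -> None:
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 1 for s in samples):
        raise ValueError("every group must contain at least one observation")


def smr_trend(
    mortality_table: pd.DataFrame, group: int
) -> tuple[float, tuple[float, float]]:
    """Weighted linear trend of SMR over the six age bands for one group.

    Regresses the per-band SMR on the band index with inverse-variance
    weights (Poisson variance O/E² per band); returns the slope and its
    95 % confidence interval. Used to ask whether SMR rises with age in a
    treatment-intensity group or is flat (CI covering 0).
    """
    import statsmodels.api as sm

    sub = mortality_table[
        (mortality_table["intensity_group"] == group)
        & (mortality_table["age_label"] != ALL_AGES)
    ].copy()
    if sub["smr"].isna().any() or len(sub) < 3:
        raise ValueError("need per-band SMR values for the trend fit")
    order = {band: i for i, band in enumerate(AGE_BANDS)}
    sub["x"] = sub["age_label"].map(order)
    sub = sub.sort_values("x")
    variance = np.maximum(sub["observed_deaths"].to_numpy(), 1.0) / (
        sub["expected_deaths"].to_numpy() ** 2
    )
    model = sm.WLS(
        sub["smr"].to_numpy(),
        sm.add_constant(sub["x"].to_numpy(dtype=np.float64)),
        weights=1.0 / variance,
    ).fit()
    slope = float(model.params[1])
    lo, hi = model.conf_int()[1]
    return slope, (float(lo), float(hi))


@dataclass
class AnalysisReport:
    """Deterministic end-to-end report; serializable to CSV + JSON."""

    n_stays: int
    n_deaths: int
    hospital_mortality_pct: float
    mean_age: float
    sd_age: float
    pct_aged_80_plus: float
    mean_age_adjusted_saps2: float
    intensity_by_age_band: pd.DataFrame
    intensity_by_age_band_pct: pd.DataFrame
    intensity_by_age_binary: pd.DataFrame
    intensity_by_age_binary_pct: pd.DataFrame
    mortality_table: pd.DataFrame
    age_adjusted_saps2_by_band: pd.DataFrame
    mortality_by_age_band: pd.DataFrame
    tests: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_stays": self.n_stays,
            "n_deaths": self.n_deaths,
            "hospital_mortality_pct": self.hospital_mortality_pct,
            "mean_age": self.mean_age,
            "sd_age": self.sd_age,
            "pct_aged_80_plus": self.pct_aged_80_plus,
            "mean_age_adjusted_saps2": self.mean_age_adjusted_saps2,
            "intensity_by_age_band": self.intensity_by_age_band.to_dict(),
            "intensity_by_age_binary": self.intensity_by_age_binary.to_dict(),
            "mortality_table": self.mortality_table.to_dict(orient="records"),
            "age_adjusted_saps2_by_band": self.age_adjusted_saps2_by_band.to_dict(
                orient="records"
            ),
            "mortality_by_age_band": self.mortality_by_age_band.to_dict(
                orient="records"
            ),
            "tests": {
                name: {
                    "test_name": t.test_name,
                    "statistic": t.statistic,
                    "df": list(t.df) if isinstance(t.df, tuple) else t.df,
                    "p_value": t.p_value,
                }
                for name, t in self.tests.items()
            },
        }

    def write_dir(self, out_dir) -> None:
        """Write table2/3/4-style CSVs, the SMR curves and report.json."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.intensity_by_age_band.to_csv(out / "table2_counts.csv")
        self.intensity_by_age_band_pct.to_csv(out / "table2_pct.csv")
        self.intensity_by_age_binary.to_csv(out / "table3_counts.csv")
        self.intensity_by_age_binary_pct.to_csv(out / "table3_pct.csv")
        self.mortality_table.to_csv(out / "table4_mortality.csv", index=False)
        smr = self.mortality_table[self.mortality_table["age_label"] != ALL_AGES]
        smr[["age_label", "intensity_group", "smr", "smr_ci_low", "smr_ci_high"]].to_csv(
            out / "smr_by_age_group.csv", index=False
        )
        with open(out / "report.json", "w") as handle:
            json.dump(self.to_dict(), handle, indent=2, default=str)


def run_full_analysis(cohort: pd.DataFrame) -> AnalysisReport:
    """Run every summary on a filtered, scored, classified cohort frame."""
    _required(
        cohort,
        ["age", "hospital_death", "intensity_group", "predicted_mortality",
         "saps2_age_adjusted"],
    )
    work = cohort if "age_band" in cohort.columns else age_band_frame(cohort)
    n = len(work)
    deaths = int(work["hospital_death"].sum())
    age = work["age"].to_numpy(dtype=np.float64)

    counts_band = intensity_distribution(work, "band")
    counts_binary = intensity_distribution(work, "binary")
    mortality = mortality_by_group_and_age(work)

    saps_by_band = (
        work.groupby("age_band", observed=True)["saps2_age_adjusted"]
        .agg(["count", "mean", "std"])
        .reindex(AGE_BANDS)
        .rename_axis("age_band")
        .reset_index()
    )
    mort_by_band = (
        work.groupby("age_band", observed=True)["hospital_death"]
        .agg(n="count", deaths="sum")
        .reindex(AGE_BANDS)
        .rename_axis("age_band")
        .reset_index()
    )
    mort_by_band["mortality_pct"] = round_half_away(
        100.0 * mort_by_band["deaths"] / mort_by_band["n"], 1
    )

    tests: dict[str, TestResult] = {}
    if n > 0 and counts_band.to_numpy().sum() > 0:
        nonzero = counts_band.loc[
            counts_band.sum(axis=1) > 0, counts_band.sum(axis=0) > 0
        ]
        if nonzero.shape[0] >= 2 and nonzero.shape[1] >= 2:
            tests["intensity_by_age_chi2"] = chi_square_test(nonzero.to_numpy())
        band_groups = [
            work.loc[work["age_band"] == band, "intensity_group"].to_numpy()
            for band in AGE_BANDS
            if (work["age_band"] == band).any()
        ]
        if len(band_groups) >= 2:
            tests["intensity_by_age_kruskal"] = kruskal_wallis(band_groups)
        saps_groups = [
            work.loc[work["age_band"] == band, "saps2_age_adjusted"].to_numpy()
            for band in AGE_BANDS
            if (work["age_band"] == band).any()
        ]
        if len(saps_groups) >= 2:
            tests["age_adjusted_saps2_by_age_anova"] = anova(saps_groups)

    return AnalysisReport(
        n_stays=n,
        n_deaths=deaths,
        hospital_mortality_pct=round_half_away(100.0 * deaths / n, 1) if n else 0.0,
        mean_age=float(age.mean()) if n else float("nan"),
        sd_age=float(age.std(ddof=1)) if n > 1 else float("nan"),
        pct_aged_80_plus=round_half_away(100.0 * (age >= 80).mean(), 1) if n else 0.0,
        mean_age_adjusted_saps2=(
            float(work["saps2_age_adjusted"].mean()) if n else float("nan")
        ),
        intensity_by_age_band=counts_band,
        intensity_by_age_band_pct=column_percentages(counts_band),
        intensity_by_age_binary=counts_binary,
        intensity_by_age_binary_pct=column_percentages(counts_binary),
        mortality_table=mortality,
        age_adjusted_saps2_by_band=saps_by_band,
        mortality_by_age_band=mort_by_band,
        tests=tests,
    )
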