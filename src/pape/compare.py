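"""Statistical comparison of exposure-estimation methods.

Two families of analyses:

* :class:`MethodComparison` — a paired comparison of per-participant
  inhaled doses from the wearable system (``id_new``) versus the Standard
  Method (``id_std``): means and SDs of both columns, the mean difference,
  a 95% CI on the (std - new) differences (the orientation used in the
  study report; the mirrored interval is printed alongside), a two-sided
  paired t-test and the Pearson correlation of the pairs.  ``fit()``
  returns a results object with a ``summary()`` table and a boxplot
  method, in the spirit of statsmodels.

* :func:`location_battery` — the nonparametric battery over the seven
  static acquisition points: Shapiro-Wilk normality per point, a Friedman
  test across points with participants as blocks, pairwise Wilcoxon
  signed-rank post hocs with Bonferroni adjustment on rejection, plus
  helpers for the morning/afternoon Wilcoxon pairing and the
  Kruskal-Wallis comparison of respiratory rate across participants.

The packaged reference dataset (20 participants' PM2.5 doses computed with
both methods in the pilot walking campaign, together with the printed
inputs of the Standard Method) is exposed via :func:`load_reference_doses`
and :func:`reproduce_reference_comparison`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import StandardInputs, standard_dose

__all__ = [
    "MethodComparison",
    "MethodComparisonResults",
    "LocationTestReport",
    "compare_methods",
    "location_battery",
    "time_of_day_test",
    "rr_between_participants",
    "load_reference_doses",
    "reproduce_reference_comparison",
]


@dataclass
class MethodComparisonResults:
    """Estimates and tests from a paired dose comparison (units: ug)."""

    n: int
    mean_new: float
    sd_new: float
    mean_std: float
    sd_std: float
    mean_diff: float       # new - std
    pct_diff: float        # 100 * mean_diff / mean_std
    ci95_low: float        # on (std - new), the report's orientation
    ci95_high: float
    t_stat: float
    p_value: float         # two-sided paired t
    pearson_r: float
    r_p_value: float

    def summary(self) -> str:
        lines = [
            "Paired inhaled-dose comparison (wearable NEW vs Standard Method STD)",
            "=" * 68,
            f"participants                 n = {self.n}",
            f"ID_STD  mean (SD)            {self.mean_std:8.2f} ({self.sd_std:.2f}) ug",
            f"ID_NEW  mean (SD)            {self.mean_new:8.2f} ({self.sd_new:.2f}) ug",
            f"mean difference NEW - STD    {self.mean_diff:8.2f} ug ({self.pct_diff:.1f}% of STD)",
            f"95% CI on STD - NEW          ({self.ci95_low:.2f}, {self.ci95_high:.2f}) ug",
            f"  (mirrored, NEW - STD)      ({-self.ci95_high:.2f}, {-self.ci95_low:.2f}) ug",
            f"paired t (two-sided)         t = {self.t_stat:.3f}, p = {self.p_value:.4f}",
            f"Pearson correlation          r = {self.pearson_r:.3f}, p = {self.r_p_value:.4f}",
        ]
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if not k.startswith("_")}

    def plot_box(self, ax=None):
        """Side-by-side boxplots of the two dose distributions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.boxplot([self._id_std, self._id_new], tick_labels=["STD", "NEW"])
        ax.set_ylabel("PM2.5 inhaled dose (ug)")
        ax.set_title("Standard Method vs wearable system")
        return ax


class MethodComparison:
    """Paired-comparison model for per-participant doses from two methods.

    Parameters
    ----------
    id_new, id_std : array-like
        Doses (ug) paired by participant, equal length >= 3.
    """

    def __init__(self, id_new, id_std, participant_ids=None):
        self.id_new = np.asarray(id_new, dtype=float)
        self.id_std = np.asarray(id_std, dtype=float)
        if len(self.id_new) != len(self.id_std):
            raise ValueError("id_new and id_std must be paired (equal length)")
        if len(self.id_new) < 3:
            raise ValueError("need at least 3 pairs")
        self.participant_ids = participant_ids

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, new_col: str = "id_new_ug",
                       std_col: str = "id_std_ug",
                       id_col: str = "participant") -> "MethodComparison":
        ids = df[id_col].tolist() if id_col in df.columns else None
        return cls(df[new_col], df[std_col], participant_ids=ids)

    def fit(self) -> MethodComparisonResults:
        new, std = self.id_new, self.id_std
        n = len(new)
        diffs = std - new  # report orientation
        se = diffs.std(ddof=1) / np.sqrt(n)
        if se > 0:
            lo, hi = stats.t.interval(0.95, n - 1, loc=diffs.mean(), scale=se)
            t_stat, p = stats.ttest_rel(new, std)
        else:  # identical pairing up to a constant shift
            lo = hi = diffs.mean()
            t_stat = 0.0 if diffs.mean() == 0 else np.inf * np.sign(-diffs.mean())
            p = 1.0 if diffs.mean() == 0 else 0.0
        if np.std(new) > 0 and np.std(std) > 0:
            r, rp = stats.pearsonr(new, std)
        else:
            r, rp = np.nan, np.nan
        res = MethodComparisonResults(
            n=n,
            mean_new=float(new.mean()), sd_new=float(new.std(ddof=1)),
            mean_std=float(std.mean()), sd_std=float(std.std(ddof=1)),
            mean_diff=float(new.mean() - std.mean()),
            pct_diff=float(100.0 * (new.mean() - std.mean()) / std.mean()),
            ci95_low=float(lo), ci95_high=float(hi),
            t_stat=float(t_stat), p_value=float(p),
            pearson_r=float(r), r_p_value=float(rp),
        )
        res._id_new = new  # retained for plotting
        res._id_std = std
        return res


def compare_methods(id_new, id_std) -> MethodComparisonResults:
    """Functional shorthand for ``MethodComparison(id_new, id_std).fit()``."""
    return MethodComparison(id_new, id_std).fit()


# -- location / time-of-day batteries --------------------------------------

@dataclass
class LocationTestReport:
    """Results of the nonparametric battery over the static points."""

    channel: str
    shapiro_p: dict                      # point label -> normality p
    friedman_stat: float
    friedman_p: float
    posthoc: pd.DataFrame | None = None  # pair, p_raw, p_adj (Bonferroni)
    wilcoxon_tod_p: float | None = None  # morning vs afternoon
    kruskal_stat: float | None = None
    kruskal_p: float | None = None
    alpha: float = 0.05

    def significant_pairs(self) -> list:
        if self.posthoc is None:
            return []
        hit = self.posthoc[self.posthoc["p_adj"] < self.alpha]
        return list(hit["pair"])


def location_battery(point_table: pd.DataFrame, channel: str = "",
                     alpha: float = 0.05,
                     posthoc_always: bool = False) -> LocationTestReport:
    """Nonparametric location battery on a participants x points table.

    Rows are participants (complete blocks — any NaN is rejected), columns
    are static-point labels.  Shapiro-Wilk runs per point; the Friedman
    test compares points with participants as blocks; when it rejects at
    ``alpha`` (or ``posthoc_always``), all C(k,2) pairwise Wilcoxon
    signed-rank tests are run with Bonferroni adjustment.
    """
    if point_table.isna().any().any():
        raise ValueError("Friedman requires complete blocks (no missing cells)")
    if point_table.shape[1] < 2 or point_table.shape[0] < 3:
        raise ValueError("need >= 2 points and >= 3 participants")
    cols = list(point_table.columns)
    shapiro_p = {c: float(stats.shapiro(point_table[c]).pvalue) for c in cols}
    fr = stats.friedmanchisquare(*[point_table[c].to_numpy() for c in cols])
    report = LocationTestReport(channel=channel, shapiro_p=shapiro_p,
                                friedman_stat=float(fr.statistic),
                                friedman_p=float(fr.pvalue), alpha=alpha)
    if fr.pvalue < alpha or posthoc_always:
        pairs = list(itertools.combinations(cols, 2))
        m = len(pairs)
        rows = []
        for a, b in pairs:
            d = point_table[a].to_numpy() - point_table[b].to_numpy()
            if np.allclose(d, 0):
                p_raw = 1.0
            else:
                p_raw = float(stats.wilcoxon(point_table[a], point_table[b]).pvalue)
            rows.append((f"{a}-{b}", p_raw, min(1.0, p_raw * m)))
        report.posthoc = pd.DataFrame(rows, columns=["pair", "p_raw", "p_adj"])
    return report


def time_of_day_test(morning, afternoon) -> float:
    """Wilcoxon signed-rank p for paired morning vs afternoon values."""
    return float(stats.wilcoxon(np.asarray(morning, float),
                                np.asarray(afternoon, float)).pvalue)


def rr_between_participants(groups) -> tuple[float, float]:
    """Kruskal-Wallis across participants (each group one participant's
    respiratory-rate values); returns (statistic, p)."""
    stat, p = stats.kruskal(*[np.asarray(g, float) for g in groups])
    return float(stat), float(p)


# -- packaged reference dataset --------------------------------------------

def load_reference_doses() -> pd.DataFrame:
    """Load the packaged per-participant PM2.5 dose reference (20 rows).

    Columns: participant, vm_new_median_lpm, vm_new_iqr_lpm, vm_std_lpm,
    c_new_median_ugm3, c_new_iqr_ugm3, c_std_ugm3, id_new_ug, id_std_ug.
    """
    with resources.files("pape.data").joinpath("pm25_dose_reference.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    expected = {"participant", "vm_std_lpm", "c_std_ugm3", "id_new_ug", "id_std_ug"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"reference dataset malformed: missing columns {sorted(missing)}")
    return df


def reproduce_reference_comparison(df: pd.DataFrame | None = None,
                                   duration_min: float = 35.0):
    """Paired comparison on the reference doses plus a per-row check that
    each Standard Method dose reproduces from its printed inputs.

    Returns ``(results, check)`` where ``check`` is a DataFrame with the
    recomputed Standard Method dose per row and the absolute deviation
    from the tabulated value (2-decimal printing makes <= 0.005 ug the
    expected ceiling).
    """
    if df is None:
        df = load_reference_doses()
    results = MethodComparison.from_dataframe(df).fit()
    recomputed = [
        standard_dose(StandardInputs(c_std={"pm2_5": row.c_std_ugm3},
                                     vm_std_lpm=row.vm_std_lpm,
                                     duration_min=duration_min))
        for row in df.itertuples()
    ]
    check = pd.DataFrame({
        "participant": df["participant"],
        "id_std_ug": df["id_std_ug"],
        "id_std_recomputed_ug": recomputed,
    })
    check["abs_dev_ug"] = (check["id_std_recomputed_ug"].round(2)
                           - check["id_std_ug"]).abs()
    return results, check
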