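"""Single-cell trajectory analysis for mother-machine infection assays.

Consumes tidy per-channel time series (one row per founder cell per hourly
time point) and derives the study's summary quantities: population curves
with SEM, per-founder fate classes, division-count distributions before
death, filamentation fraction curves, extinction-time extrapolations and
receptor-expression (initial fluorescence) comparisons between killed and
surviving cells.

Tidy input schema (CSV-compatible; the synthetic generator emits the same):

    replicate_id, channel_id, cell_id, time_h, length_um, occupancy,
    event, end_label, gfp_t0

``event`` holds zero or more semicolon-separated events observed since the
previous time point (``division``, ``lysis``, ``flush``); ``length_um`` is
NaN once the cell is gone; ``end_label`` is the 24-h live/dead staining
outcome (``live``, ``dead`` or ``absent``), repeated on every row of the
cell; ``gfp_t0`` is the cell's initial receptor-reporter fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TIDY_COLUMNS",
    "FATES",
    "PopulationCurve",
    "ExtinctionFit",
    "ReceptorTestReport",
    "read_tidy_csv",
    "cell_table",
    "classify_fates",
    "impute_flushed_fates",
    "expected_flushed_fates",
    "division_count_distribution",
    "division_distribution_from_counts",
    "aggregate_population",
    "extinction_time_regression",
    "filamentation_fraction_curve",
    "compare_receptor_distributions",
    "read_supplementary_sheet",
]

TIDY_COLUMNS = [
    "replicate_id", "channel_id", "cell_id", "time_h", "length_um",
    "occupancy", "event", "end_label", "gfp_t0",
]

FATES = ("lysed", "survived_nongrowing", "survived_growing", "filamented", "flushed")

#: filamentation definition: longer than twice the typical vegetative length
DEFAULT_FILAMENT_THRESHOLD = 7.0


def read_tidy_csv(path) -> pd.DataFrame:
    """Load and validate a tidy trajectory CSV."""
    df = pd.read_csv(path)
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table is missing columns: {missing}")
    return df


def _count_events(series: pd.Series, name: str) -> int:
    n = 0
    for ev in series.dropna():
        if not ev:
            continue
        n += sum(1 for part in str(ev).split(";") if part == name)
    return n


def _event_time(g: pd.DataFrame, name: str) -> float:
    hit = g["event"].fillna("").str.split(";").map(lambda parts: name in parts)
    times = g.loc[hit, "time_h"]
    return float(times.iloc[0]) if len(times) else np.nan


def cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse the tidy table to one row per founder cell.

    Columns: n_divisions, lysis_time_h, flushed, max_length_um, end_label,
    gfp_t0.
    """
    rows = []
    for (rep, chan, cell), g in df.groupby(["replicate_id", "channel_id", "cell_id"],
                                           sort=True):
        g = g.sort_values("time_h")
        end = g["end_label"].dropna()
        rows.append(dict(
            replicate_id=rep, channel_id=chan, cell_id=cell,
            n_divisions=_count_events(g["event"], "division"),
            lysis_time_h=_event_time(g, "lysis"),
            flushed=bool(_count_events(g["event"], "flush")),
            max_length_um=float(g["length_um"].max()),
            end_label=end.iloc[-1] if len(end) else None,
            gfp_t0=float(g["gfp_t0"].dropna().iloc[0]) if g["gfp_t0"].notna().any() else np.nan,
        ))
    return pd.DataFrame(rows)


def classify_fates(df: pd.DataFrame,
                   filament_threshold: float = DEFAULT_FILAMENT_THRESHOLD) -> pd.DataFrame:
    """Assign each founder cell one fate.

    Rules (precedence top to bottom):

    - ``filamented``: maximum observed length > ``filament_threshold`` um;
    - ``lysed``: a lysis event was observed;
    - ``flushed``: the cell was lost from its channel before 24 h;
    - ``survived_growing`` / ``survived_nongrowing``: alive at 24 h (live
      staining label) with >= 1 / 0 observed divisions.

    A lysis event combined with a live end-label is contradictory and
    raises a record-level validation error.
    """
    cells = df if {"n_divisions", "lysis_time_h"}.issubset(df.columns) else cell_table(df)
    lysed = cells["lysis_time_h"].notna()
    bad = lysed & (cells["end_label"] == "live")
    if bad.any():
        ids = cells.loc[bad, "cell_id"].tolist()
        raise ValueError(f"cells with both a lysis event and a live end-label: {ids}")
    fate = np.full(len(cells), "", dtype=object)
    filamented = cells["max_length_um"] > filament_threshold
    growing = cells["n_divisions"] >= 1
    fate[:] = np.where(growing, "survived_growing", "survived_nongrowing")
    fate[cells["flushed"].to_numpy(bool)] = "flushed"
    fate[lysed.to_numpy()] = "lysed"
    fate[filamented.to_numpy()] = "filamented"
    out = cells.copy()
    out["fate"] = fate
    out["divisions_before_death"] = np.where(
        lysed.to_numpy(), cells["n_divisions"].to_numpy(), np.nan
    )
    return out


def _observed_fate_freqs(fates: pd.DataFrame) -> pd.Series:
    obs = fates.loc[fates["fate"] != "flushed", "fate"]
    if obs.empty:
        raise ValueError("cannot impute: every cell was flushed")
    return obs.value_counts(normalize=True)


def impute_flushed_fates(fates: pd.DataFrame,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign flushed cells a fate drawn from the observed fate frequencies.

    The fate of cells pushed out of their channel cannot be observed; each
    is assigned a fate sampled from the empirical distribution of the
    non-flushed cells.  Returns a copy with ``fate_imputed`` (True for the
    reassigned cells) and no remaining ``flushed`` fates.
    """
    out = fates.copy()
    out["fate_imputed"] = False
    flushed_idx = out.index[out["fate"] == "flushed"]
    if len(flushed_idx) == 0:
        return out
    freqs = _observed_fate_freqs(fates)
    if rng is None:
        rng = np.random.default_rng()
    draws = rng.choice(freqs.index.to_numpy(), size=len(flushed_idx), p=freqs.to_numpy())
    out.loc[flushed_idx, "fate"] = draws
    out.loc[flushed_idx, "fate_imputed"] = True
    return out


def expected_flushed_fates(fates: pd.DataFrame) -> pd.Series:
    """Expectation-based (fractional) fate allocation for flushed cells."""
    n_flushed = int((fates["fate"] == "flushed").sum())
    return _observed_fate_freqs(fates) * n_flushed


def division_count_distribution(records) -> tuple[pd.Series, float]:
    """Distribution of divisions before death over {0, 1, 2, 3+}, and mean.

    ``records`` is either a fate table (uses lysed cells'
    ``divisions_before_death``) or an array of per-cell division counts.
    Counts of 3 or more are pooled into the "3+" class for the
    distribution; the mean uses the recorded values.
    """
    if isinstance(records, pd.DataFrame):
        counts = records.loc[records["fate"] == "lysed", "divisions_before_death"]
        counts = counts.dropna().to_numpy(dtype=float)
    else:
        counts = np.asarray(records, dtype=float)
    if counts.size == 0:
        return pd.Series(dtype=float), float("nan")
    labels = np.where(counts >= 3, "3+", counts.astype(int).astype(str))
    freq = (pd.Series(labels).value_counts(normalize=True)
            .reindex(["0", "1", "2", "3+"], fill_value=0.0))
    return freq, float(counts.mean())


def division_distribution_from_counts(categories, counts) -> tuple[pd.Series, float]:
    """Same summary from pre-tabulated category counts.

    ``categories`` may contain "3+" (or "3"), taken at value 3 for the
    mean since exact counts above the pooled class are unknown.
    """
    values = []
    for cat, cnt in zip(categories, counts):
        v = 3.0 if str(cat).strip() in ("3+", "3 or more", ">=3", "3") else float(cat)
        values.extend([v] * int(cnt))
    return division_count_distribution(np.array(values))


@dataclass
class PopulationCurve:
    """Mean population size over time with its standard error.

    ``sem`` is NaN wherever fewer than two units contribute.
    """

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_units: int

    def value_at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.mean[i])


def aggregate_population(df: pd.DataFrame, scale_to: int | None = None) -> PopulationCurve:
    """Total occupancy over time, averaged across replicates.

    Occupancy is a channel-level quantity (repeated on every cell row of a
    channel); channels are summed within each replicate and the mean and
    SEM are taken across replicates on a common time grid.  ``scale_to``
    rescales linearly from the number of observed channels to a device
    channel count (e.g. 200 observed -> 6000 device channels).
    """
    chan = (df.groupby(["replicate_id", "time_h", "channel_id"], sort=True)["occupancy"]
            .first().reset_index())
    totals = (chan.groupby(["replicate_id", "time_h"], sort=True)["occupancy"]
              .sum().unstack("time_h"))
    if totals.isna().any().any():
        raise ValueError("replicates are not on a common time grid")
    if scale_to is not None:
        n_chan = df.groupby("replicate_id")["channel_id"].nunique()
        totals = totals.mul(scale_to / n_chan, axis=0)
    times = totals.columns.to_numpy(dtype=float)
    mean = totals.mean(axis=0).to_numpy()
    n = totals.shape[0]
    sem = (totals.std(axis=0, ddof=1) / np.sqrt(n)).to_numpy() if n > 1 else np.full(times.size, np.nan)
    return PopulationCurve(times=times, mean=mean, sem=sem, n_units=n)


@dataclass
class ExtinctionFit:
    """Linear extrapolation of the declining survival curve to zero."""

    slope: float
    intercept: float
    x_intercept: float
    n_points: int
    t_start: float
    t_end: float
    no_extinction: bool = False


def extinction_time_regression(times, values, t_start: float = 2.0,
                               t_end: float = 7.0) -> ExtinctionFit:
    """OLS fit of population (or survival fraction) vs time on a window.

    Fits ``y = a + b t`` on points with ``t_start <= t <= t_end`` and
    extrapolates the x-axis intercept ``-a/b``, the predicted eradication
    time.  The intercept is invariant to any positive rescaling of y, so
    the normalisation of the survival fraction is immaterial.  A
    non-negative slope is flagged (``no_extinction``) instead of returning
    a meaningless intercept.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    sel = (t >= t_start) & (t <= t_end) & np.isfinite(y)
    if sel.sum() < 3:
        raise ValueError("need at least 3 points inside the regression window")
    fit = stats.linregress(t[sel], y[sel])
    if fit.slope >= 0:
        return ExtinctionFit(float(fit.slope), float(fit.intercept), float("nan"),
                             int(sel.sum()), t_start, t_end, no_extinction=True)
    return ExtinctionFit(float(fit.slope), float(fit.intercept),
                         float(-fit.intercept / fit.slope), int(sel.sum()),
                         t_start, t_end)


def filamentation_fraction_curve(
    df: pd.DataFrame, threshold: float = DEFAULT_FILAMENT_THRESHOLD
) -> tuple[PopulationCurve, float, float]:
    """Fraction of live cells currently longer than the threshold, vs time.

    Evaluated on current length at each time point (a cell counts while it
    is elongated and present), averaged across replicates.  Returns the
    curve plus the maximum of the mean curve and the time at which it
    occurs.
    """
    live = df[df["length_um"].notna()].copy()
    live["filamenting"] = live["length_um"] > threshold
    frac = (live.groupby(["replicate_id", "time_h"], sort=True)["filamenting"]
            .mean().unstack("time_h"))
    times = frac.columns.to_numpy(dtype=float)
    mean = frac.mean(axis=0).to_numpy()
    n = frac.shape[0]
    sem = (frac.std(axis=0, ddof=1) / np.sqrt(n)).to_numpy() if n > 1 else np.full(times.size, np.nan)
    curve = PopulationCurve(times=times, mean=mean, sem=sem, n_units=n)
    i_max = int(np.nanargmax(mean))
    return curve, float(mean[i_max]), float(times[i_max])


@dataclass
class ReceptorTestReport:
    """Two-sample comparison of initial receptor-reporter fluorescence.

    Normality is checked per group (Shapiro-Wilk at ``alpha``); the
    parametric two-sample t test is chosen when both groups look normal,
    the Mann-Whitney rank test otherwise.  Both statistics are always
    reported; ``chosen`` flags which drives ``p_value``.
    """

    n_killed: int
    n_survived: int
    mean_killed: float
    mean_survived: float
    median_killed: float
    median_survived: float
    shapiro_p_killed: float
    shapiro_p_survived: float
    both_normal: bool
    t_statistic: float
    t_p_value: float
    u_statistic: float
    u_p_value: float
    chosen: str
    p_value: float
    direction: str


def compare_receptor_distributions(values_killed, values_survived,
                                   alpha: float = 0.05) -> ReceptorTestReport:
    """Compare receptor levels of eventually-killed vs surviving cells."""
    killed = np.asarray(values_killed, dtype=float)
    survived = np.asarray(values_survived, dtype=float)
    if killed.size == 0 or survived.size == 0:
        raise ValueError("both groups must be non-empty")
    small = killed.size < 3 or survived.size < 3
    if small:
        sp_k = sp_s = float("nan")
        both_normal = False  # normality unassessable; rank test forced
    else:
        sp_k = float(stats.shapiro(killed).pvalue) if np.ptp(killed) > 0 else 0.0
        sp_s = float(stats.shapiro(survived).pvalue) if np.ptp(survived) > 0 else 0.0
        both_normal = (sp_k > alpha) and (sp_s > alpha)
    if np.ptp(np.concatenate([killed, survived])) == 0:
        t_stat = t_p = u_stat = np.nan
        u_p = t_p = 1.0
        chosen = "rank"
        p = 1.0
        direction = "none"
    else:
        t_stat, t_p = stats.ttest_ind(killed, survived, equal_var=False)
        u_stat, u_p = stats.mannwhitneyu(killed, survived, alternative="two-sided")
        chosen = "t" if both_normal else "rank"
        p = t_p if chosen == "t" else u_p
        direction = ("killed>survived" if np.mean(killed) > np.mean(survived)
                     else "killed<survived")
    return ReceptorTestReport(
        n_killed=killed.size, n_survived=survived.size,
        mean_killed=float(np.mean(killed)), mean_survived=float(np.mean(survived)),
        median_killed=float(np.median(killed)), median_survived=float(np.median(survived)),
        shapiro_p_killed=sp_k, shapiro_p_survived=sp_s, both_normal=both_normal,
        t_statistic=float(t_stat), t_p_value=float(t_p),
        u_statistic=float(u_stat), u_p_value=float(u_p),
        chosen=chosen, p_value=float(p), direction=direction,
    )


def read_supplementary_sheet(path, data_key: str) -> pd.DataFrame:
    """Read one dataset from the published supplementary spreadsheet.

    ``data_key`` such as "Data V" selects the first sheet whose name
    contains it (case-insensitive).  The sheet is returned as-is (first
    row as header); downstream code selects columns by substring (e.g.
    "parental" vs "ompC").
    """
    sheets = pd.read_excel(path, sheet_name=None)
    key = data_key.lower().replace(" ", "")
    for name, frame in sheets.items():
        if key in name.lower().replace(" ", ""):
            return frame
    raise KeyError(f"no sheet matching {data_key!r} in {path}")
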